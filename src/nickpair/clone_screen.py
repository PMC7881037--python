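"""In-silico clone screening and allele-dosage genotyping.

After paired-nickase editing of a locus present in k copies (e.g. an APP
duplication carrier with k = 3), single-cell clones are screened by
restriction digest (an indel destroying an endogenous EcoRI site yields a
digestion-resistant band), long-range PCR (to exclude large deletions that
remove a primer site), and amplicon deep sequencing. The fraction of
edited-allele reads estimates how many of the k copies carry the edit:
roughly 1/3 deletion reads at a triplicated locus means one copy was
knocked out.

The dosage caller models edited-read counts as binomial draws with success
probability ``p_j = (j/k)(1 - eps) + (1 - j/k) eps`` for j edited copies,
where ``eps`` is a symmetric misclassification rate that keeps all
likelihoods finite. The maximum-likelihood j is reported, with ties broken
toward smaller j and an ambiguity flag when the best-vs-second
log-likelihood gap falls below a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import SequenceRecord, revcomp

#: Log-likelihood gap below which a dosage call is flagged ambiguous.
DEFAULT_AMBIGUITY_GAP = 2.0
#: Default symmetric read-misclassification rate.
DEFAULT_EPSILON = 1e-3


class PrimerError(ValueError):
    """In-silico PCR failure: primer not found or amplicon ambiguous."""


class ModelError(ValueError):
    """Amplicon/allele model violates its constraints."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with a concrete recognition site and cut offset.

    ``cut_offset`` is the top-strand cut position counted from the 5' end of
    the recognition site (EcoRI G^AATTC has offset 1).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ModelError("cut_offset outside recognition site")


ECORI = RestrictionEnzyme("EcoRI", "GAATTC", 1)


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Start positions of every (possibly overlapping) recognition occurrence."""
    sites = []
    start = seq.find(enzyme.recognition)
    while start != -1:
        sites.append(start)
        start = seq.find(enzyme.recognition, start + 1)
    return sites


def in_silico_digest(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths after complete digestion, 5' to 3'.

    Cuts at every top-strand recognition occurrence; fragment lengths sum to
    the input length.

    >>> in_silico_digest("AAAAGAATTCAA", ECORI)
    [5, 7]
    """
    if not seq:
        raise ValueError("empty sequence")
    cuts = sorted({s + enzyme.cut_offset for s in find_sites(seq, enzyme)})
    cuts = [c for c in cuts if 0 < c < len(seq)]
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass(frozen=True)
class AmpliconModel:
    """Reference amplicon with its edit window and known allele sequences."""

    reference: str
    edit_window: tuple[int, int]
    alleles: tuple[tuple[str, str], ...]  # (label, sequence)

    def __post_init__(self) -> None:
        s, e = self.edit_window
        if not (0 <= s < e <= len(self.reference)):
            raise ModelError("edit_window outside amplicon bounds")
        seqs = [a[1] for a in self.alleles]
        if len(set(seqs)) != len(seqs):
            raise ModelError("allele sequences must be distinct")

    def allele(self, label: str) -> str:
        for lab, seq in self.alleles:
            if lab == label:
                return seq
        raise KeyError(label)


def rflp_disruption_screen(
    amplicon: AmpliconModel,
    window: tuple[int, int],
    enzyme: RestrictionEnzyme = ECORI,
) -> tuple[bool, int | None]:
    """Predict whether an edited window disrupts a restriction site.

    Returns ``(disruptable, resistant_band_length)``: disruptable is true
    iff the window overlaps at least one recognition occurrence in the
    reference amplicon; the resistant band is the fragment left uncut when
    every overlapped site is destroyed while the remaining sites still cut.
    Raises :class:`ModelError` when the amplicon carries no site at all
    (the screen is not applicable).
    """
    seq = amplicon.reference
    sites = find_sites(seq, enzyme)
    if not sites:
        raise ModelError(f"no {enzyme.name} site in amplicon")
    ws, we = window
    site_len = len(enzyme.recognition)
    destroyed = [s for s in sites if ws < s + site_len and s < we]
    if not destroyed:
        return (False, None)
    surviving_cuts = sorted(
        {s + enzyme.cut_offset for s in sites if s not in destroyed}
    )
    surviving_cuts = [c for c in surviving_cuts if 0 < c < len(seq)]
    bounds = [0] + surviving_cuts + [len(seq)]
    # the resistant band is the surviving fragment containing the (first)
    # destroyed site's cut point
    probe = destroyed[0] + enzyme.cut_offset
    for a, b in zip(bounds, bounds[1:]):
        if a <= probe < b:
            return (True, b - a)
    return (True, len(seq))


def find_amplicon(
    template: SequenceRecord, fwd_primer: str, rev_primer: str
) -> tuple[tuple[int, int], int]:
    """Exact-match in-silico PCR.

    The forward primer must match the template top strand; the reverse
    complement of the reverse primer must match downstream of it. Returns
    the half-open amplicon interval and its length. Raises
    :class:`PrimerError` when a primer is absent or when more than one
    amplicon is possible (ambiguous primer placement).
    """
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise PrimerError("primers must be at least 15 nt")
    seq = template.sequence
    fwd = fwd_primer.upper()
    rev_rc = revcomp(rev_primer.upper())

    fwd_hits = [m for m in _find_all(seq, fwd)]
    if not fwd_hits:
        raise PrimerError("primer not found: forward primer has no match")
    rev_hits = [m for m in _find_all(seq, rev_rc)]
    amplicons = [
        (f, r + len(rev_rc))
        for f in fwd_hits
        for r in rev_hits
        if r >= f + len(fwd)
    ]
    if not amplicons:
        raise PrimerError(
            "primer not found: no reverse-primer match downstream of forward"
        )
    if len(amplicons) > 1:
        raise PrimerError(f"ambiguous amplicon: {len(amplicons)} candidates")
    (start, end), = amplicons
    return ((start, end), end - start)


def _find_all(seq: str, query: str) -> list[int]:
    hits = []
    i = seq.find(query)
    while i != -1:
        hits.append(i)
        i = seq.find(query, i + 1)
    return hits


@dataclass
class ReadClassification:
    """Per-allele read counts from exact-length, mismatch-bounded matching."""

    counts: dict[str, int] = field(default_factory=dict)
    unclassified: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unclassified


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def classify_reads(
    reads: Sequence[str], model: AmpliconModel, max_mismatch: int = 2
) -> ReadClassification:
    """Assign each read to the allele it matches within ``max_mismatch``.

    A read is only compared against alleles of exactly its length; it is
    counted for the allele with the fewest mismatches when that minimum is
    unique and at most ``max_mismatch``, otherwise it is unclassified.
    Raises :class:`ModelError` when two same-length alleles lie within
    ``max_mismatch`` of each other, since reads could then not be assigned
    reliably.
    """
    labels = [lab for lab, _ in model.alleles]
    arrays = {lab: _seq_to_array(seq) for lab, seq in model.alleles}
    # discriminability check among same-length alleles
    for i, (la, aa) in enumerate(arrays.items()):
        for lb, ab in list(arrays.items())[i + 1 :]:
            if aa.shape == ab.shape and int((aa != ab).sum()) <= max_mismatch:
                raise ModelError(
                    f"alleles {la!r} and {lb!r} are within {max_mismatch} mismatches"
                )

    result = ReadClassification(counts={lab: 0 for lab in labels})
    # group reads by length and compare in bulk
    by_len: dict[int, list[str]] = {}
    for read in reads:
        by_len.setdefault(len(read), []).append(read)
    for length, group in by_len.items():
        cands = [(lab, arr) for lab, arr in arrays.items() if arr.size == length]
        if not cands:
            result.unclassified += len(group)
            continue
        mat = np.frombuffer(
            "".join(group).encode("ascii"), dtype=np.uint8
        ).reshape(len(group), length)
        mm = np.stack([(mat != arr).sum(axis=1) for _, arr in cands], axis=1)
        best = mm.min(axis=1)
        n_best = (mm == best[:, None]).sum(axis=1)
        ok = (best <= max_mismatch) & (n_best == 1)
        winners = mm.argmin(axis=1)
        for ci, (lab, _) in enumerate(cands):
            result.counts[lab] += int((ok & (winners == ci)).sum())
        result.unclassified += int((~ok).sum())
    return result


@dataclass(frozen=True)
class DosageCall:
    """Maximum-likelihood edited-copy count at a locus of known copy number."""

    copy_number: int
    edited_copies: int
    observed_fraction: float
    log_likelihoods: tuple[float, ...]
    confidence_interval: tuple[float, float]
    flag: str  # "confident" | "ambiguous"


def classify_dosage(
    edited: int,
    total: int,
    k: int,
    error_rate: float = DEFAULT_EPSILON,
    ambiguity_gap: float = DEFAULT_AMBIGUITY_GAP,
) -> DosageCall:
    """Call how many of k copies are edited from edited/total read counts.

    For each candidate j in 0..k the edited-read count is modelled as
    Binomial(total, p_j) with ``p_j = (j/k)(1 - eps) + (1 - j/k) eps``; the
    call maximizes the likelihood (ties toward smaller j) and is flagged
    ambiguous when the best-vs-second log-likelihood gap is below
    ``ambiguity_gap``. The observed fraction is reported with its central
    exact (Clopper-Pearson) 95% binomial interval.

    >>> classify_dosage(33, 100, k=3, error_rate=0.0).edited_copies
    1
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= edited <= total:
        raise ValueError("edited must lie in [0, total]")
    if k < 1:
        raise ValueError("copy number k must be >= 1")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")

    js = np.arange(k + 1)
    p = (js / k) * (1.0 - error_rate) + (1.0 - js / k) * error_rate
    with np.errstate(divide="ignore"):
        ll = stats.binom.logpmf(edited, total, p)
    # smallest j within numerical noise of the maximum: ties (e.g. the exact
    # symmetry at edited = total/2) resolve toward fewer edited copies
    j_hat = int(np.flatnonzero(ll >= ll.max() - 1e-9)[0])
    finite = np.sort(ll[np.isfinite(ll)])[::-1]
    if finite.size >= 2:
        gap = float(finite[0] - finite[1])
    else:
        gap = float("inf")
    flag = "confident" if gap >= ambiguity_gap else "ambiguous"

    # central exact binomial interval on the edited fraction
    alpha = 0.05
    lo = 0.0 if edited == 0 else float(stats.beta.ppf(alpha / 2, edited, total - edited + 1))
    hi = 1.0 if edited == total else float(stats.beta.ppf(1 - alpha / 2, edited + 1, total - edited))
    return DosageCall(
        copy_number=k,
        edited_copies=j_hat,
        observed_fraction=edited / total,
        log_likelihoods=tuple(float(x) for x in ll),
        confidence_interval=(lo, hi),
        flag=flag,
    )


def simulate_amplicon_reads(
    k: int,
    j: int,
    model: AmpliconModel,
    n: int,
    error_rate: float = 0.0,
    seed: int = 0,
    edited_label: str | None = None,
    wildtype_label: str = "WT",
) -> list[str]:
    """Simulate full-length amplicon reads from a clone with j of k copies edited.

    Each read derives from the edited allele with probability j/k and the
    wild type otherwise, then receives independent per-base substitution
    errors at ``error_rate`` (to a uniformly chosen different base).
    Deterministic for a fixed seed.
    """
    if k < 1 or not 0 <= j <= k:
        raise ValueError("require k >= 1 and 0 <= j <= k")
    if n <= 0:
        raise ValueError("n must be positive")
    if edited_label is None:
        edited_label = next(
            lab for lab, _ in model.alleles if lab != wildtype_label
        )
    wt = _seq_to_array(model.allele(wildtype_label))
    ed = _seq_to_array(model.allele(edited_label))
    rng = np.random.default_rng(seed)
    is_edited = rng.random(n) < j / k

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    base_index = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(bases):
        base_index[b] = i

    out = [""] * n
    for template, mask in ((wt, ~is_edited), (ed, is_edited)):
        count = int(mask.sum())
        if count == 0:
            continue
        mat = np.tile(template, (count, 1))
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            n_err = int(err.sum())
            if n_err:
                # shift by 1..3 modulo 4: always a *different* base, uniform
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                mat[err] = bases[(base_index[mat[err]] + shift) % 4]
        idx = np.nonzero(mask)[0]
        for pos, row in zip(idx, mat):
            out[int(pos)] = row.tobytes().decode("ascii")
    return out
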