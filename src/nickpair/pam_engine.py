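"""PAM motif compilation, guide-site scanning, and double-nick pair search.

The double-nicking strategy pairs two Cas9 nickase (Cas9n) guides in PAM-out
orientation: the minus-strand guide sits on the left (its PAM facing left),
the plus-strand guide on the right (PAM facing right), and their 5' ends face
each other across an offset of 0-20 nt. Both nicks, 3 nt 5' of each PAM,
produce a staggered break whose 5' overhang spans the region between them.

Geometry (0-based half-open reference coordinates):

* plus strand:  protospacer [s, s+20), PAM [s+20, s+23),
  5' end at s, nick boundary at s+17 (between protospacer bases 17 and 18).
* minus strand: protospacer occupies [s, s+20) with PAM [s-3, s);
  guide 5' end at s+19, nick boundary at s+3.

Offset between a minus-strand guide L and a plus-strand guide R is the number
of reference bases strictly between the facing 5' ends:
``R.five_prime_end - L.five_prime_end - 1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

from .genome_io import SequenceRecord, revcomp

PROTOSPACER_LEN = 20
PAM_LEN = 3
#: Cut boundary 3 nt 5' of the PAM, i.e. between protospacer bases 17 and 18.
NICK_OFFSET_FROM_PAM = 3

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class PamError(ValueError):
    """Invalid PAM motif."""


class ContigMixError(ValueError):
    """Guides from more than one contig passed to a single-contig operation."""


def expand_iupac(motif: str) -> set[str]:
    """Expand a degenerate IUPAC motif into its concrete DNA words.

    >>> sorted(expand_iupac("NGG"))
    ['AGG', 'CGG', 'GGG', 'TGG']
    """
    try:
        choices = [IUPAC[c] for c in motif.upper()]
    except KeyError as exc:
        raise PamError(f"invalid IUPAC character {exc.args[0]!r} in {motif!r}") from None
    if not motif:
        raise PamError("empty motif")
    return {"".join(w) for w in product(*choices)}


@dataclass(frozen=True)
class PamSpec:
    """A named PAM motif, e.g. Cas9n-NGG or the VQR variant's NGA."""

    name: str
    motif: str
    variant_note: str = ""

    def __post_init__(self) -> None:
        if len(self.motif) != PAM_LEN:
            raise PamError(f"PAM motif must be {PAM_LEN} nt, got {self.motif!r}")
        expand_iupac(self.motif)  # validates characters


#: Wild-type SpCas9 nickase, NGG PAM.
CAS9N_NGG = PamSpec("Cas9n-NGG", "NGG", "SpCas9n D10A")
#: VQR PAM-relaxed nickase (D1135V/R1335Q/T1337R), NGA PAM.
CAS9NVQR_NGA = PamSpec("Cas9nVQR-NGA", "NGA", "D1135V/R1335Q/T1337R")

DEFAULT_PAM_SPECS = (CAS9N_NGG, CAS9NVQR_NGA)


@dataclass(frozen=True)
class GuideSite:
    """One protospacer + PAM occurrence on a reference sequence."""

    contig: str
    strand: str  # "+" or "-"
    protospacer_start: int  # reference-leftmost protospacer base
    protospacer: str  # 20 nt, guide orientation
    pam: str  # 3 nt, guide orientation
    pam_label: str = ""

    @property
    def pam_start(self) -> int:
        if self.strand == "+":
            return self.protospacer_start + PROTOSPACER_LEN
        return self.protospacer_start - PAM_LEN

    @property
    def five_prime_end(self) -> int:
        if self.strand == "+":
            return self.protospacer_start
        return self.protospacer_start + PROTOSPACER_LEN - 1

    @property
    def nick_position(self) -> int:
        """Cut boundary under the half-open convention.

        The nick falls between protospacer bases 17 and 18 counted from the
        guide 5' end; the returned integer is the index of the base just 3'
        of the cut on the reference top strand.
        """
        if self.strand == "+":
            return self.protospacer_start + PROTOSPACER_LEN - NICK_OFFSET_FROM_PAM
        return self.protospacer_start + NICK_OFFSET_FROM_PAM


def scan_guides(record: SequenceRecord, pam: PamSpec) -> list[GuideSite]:
    """Find every guide site for one PAM spec on both strands.

    A site requires 20 N-free protospacer bases immediately 5' of a PAM
    match. Minus-strand hits are reported in reference coordinates with
    sequences in guide orientation. Output is sorted by
    (protospacer_start, strand).
    """
    seq = record.sequence
    words = sorted(expand_iupac(pam.motif))
    alt = "|".join(words)
    sites: list[GuideSite] = []

    # plus strand: 20 non-N bases then the PAM, overlapping matches allowed
    plus_re = re.compile(rf"(?=([ACGT]{{{PROTOSPACER_LEN}}})({alt}))")
    for m in plus_re.finditer(seq):
        sites.append(
            GuideSite(record.id, "+", m.start(), m.group(1), m.group(2), pam.name)
        )

    # minus strand: a PAM match at reference [s-3, s) on the bottom strand is
    # the reverse complement of the motif on the top strand, followed by the
    # 20-nt protospacer footprint [s, s+20).
    rc_alt = "|".join(sorted(revcomp(w) for w in words))
    minus_re = re.compile(rf"(?=({rc_alt})([ACGT]{{{PROTOSPACER_LEN}}}))")
    for m in minus_re.finditer(seq):
        start = m.start() + PAM_LEN
        sites.append(
            GuideSite(
                record.id,
                "-",
                start,
                revcomp(m.group(2)),
                revcomp(m.group(1)),
                pam.name,
            )
        )

    sites.sort(key=lambda g: (g.protospacer_start, g.strand))
    return sites


def scan_guides_multi(record: SequenceRecord, pam_specs: Iterable[PamSpec]) -> list[GuideSite]:
    """Pooled guide set across several PAM specs, sorted like scan_guides."""
    sites: list[GuideSite] = []
    for spec in pam_specs:
        sites.extend(scan_guides(record, spec))
    sites.sort(key=lambda g: (g.protospacer_start, g.strand))
    return sites


@dataclass(frozen=True)
class PairRule:
    """Constraints for a valid double-nicking pair (PAM-out only)."""

    offset_min: int = 0
    offset_max: int = 20
    allow_mixed_pams: bool = True

    def __post_init__(self) -> None:
        if self.offset_min > self.offset_max:
            raise ValueError("offset_min must be <= offset_max")


@dataclass(frozen=True)
class NickasePair:
    """A PAM-out guide pair with its offset and edited-window geometry."""

    left: GuideSite  # minus strand
    right: GuideSite  # plus strand

    @property
    def offset(self) -> int:
        return self.right.five_prime_end - self.left.five_prime_end - 1

    @property
    def pam_labels(self) -> tuple[str, str]:
        return (self.left.pam_label, self.right.pam_label)

    @property
    def overhang_window(self) -> tuple[int, int]:
        """Interval between the two nick boundaries (the predicted 5' overhang)."""
        return (self.left.nick_position, self.right.nick_position)

    @property
    def guide_span_window(self) -> tuple[int, int]:
        """Interval from the left protospacer start to the right PAM end."""
        return (
            self.left.protospacer_start,
            self.right.pam_start + PAM_LEN,
        )

    def window(self, mode: str = "overhang") -> tuple[int, int]:
        if mode == "overhang":
            return self.overhang_window
        if mode == "guide_span":
            return self.guide_span_window
        raise ValueError(f"unknown window mode {mode!r}")


def enumerate_pairs(guides: Sequence[GuideSite], rule: PairRule) -> list[NickasePair]:
    """All PAM-out pairs whose 5'-to-5' offset lies within the rule's window.

    The minus-strand guide must sit left of the plus-strand guide
    (``left.five_prime_end < right.five_prime_end``). With
    ``allow_mixed_pams=False`` both guides must carry the same PAM label.
    Output is sorted by overhang-window start. Guides must come from a
    single contig.
    """
    contigs = {g.contig for g in guides}
    if len(contigs) > 1:
        raise ContigMixError(f"guides span multiple contigs: {sorted(contigs)}")
    minus = sorted(
        (g for g in guides if g.strand == "-"), key=lambda g: g.five_prime_end
    )
    plus = sorted(
        (g for g in guides if g.strand == "+"), key=lambda g: g.five_prime_end
    )
    plus_ends = [g.five_prime_end for g in plus]

    import bisect

    pairs: list[NickasePair] = []
    for left in minus:
        # PAM-out requires the plus guide's 5' end strictly right of the
        # minus guide's, even if offset_min were relaxed below zero
        lo = max(left.five_prime_end + 1 + rule.offset_min, left.five_prime_end + 1)
        hi = left.five_prime_end + 1 + rule.offset_max
        i = bisect.bisect_left(plus_ends, lo)
        j = bisect.bisect_right(plus_ends, hi)
        for right in plus[i:j]:
            if not rule.allow_mixed_pams and left.pam_label != right.pam_label:
                continue
            pairs.append(NickasePair(left, right))
    pairs.sort(key=lambda p: (p.overhang_window, p.right.protospacer_start))
    return pairs


def design_pairs_for_interval(
    genome: Sequence[SequenceRecord],
    contig: str,
    target: tuple[int, int],
    pam_specs: Iterable[PamSpec] = DEFAULT_PAM_SPECS,
    rule: PairRule = PairRule(),
    mode: str = "overhang",
) -> list[NickasePair]:
    """Rank candidate nickase pairs whose edited window overlaps a target.

    Ranking: (1) overlap length with the target, descending; (2) distance of
    the window center to the target center, ascending; (3) window start,
    ascending. Only the region around the target is scanned, so designs on
    chromosome-scale contigs stay cheap.
    """
    by_id = {r.id: r for r in genome}
    if contig not in by_id:
        raise KeyError(f"unknown contig {contig!r}")
    start, end = target
    if start >= end:
        raise ValueError("empty target interval")
    record = by_id[contig]
    # widest possible reach of a window touching the target: guide + PAM
    # footprint (23) plus max offset on either side, plus slack
    margin = 2 * (PROTOSPACER_LEN + PAM_LEN) + rule.offset_max
    lo = max(0, start - margin)
    hi = min(record.length, end + margin)
    sub = SequenceRecord(record.id, record.sequence[lo:hi])
    guides = [
        GuideSite(
            g.contig,
            g.strand,
            g.protospacer_start + lo,
            g.protospacer,
            g.pam,
            g.pam_label,
        )
        for g in scan_guides_multi(sub, pam_specs)
    ]
    pairs = enumerate_pairs(guides, rule)

    tc = (start + end) / 2.0

    def overlap(p: NickasePair) -> int:
        ws, we = p.window(mode)
        return max(0, min(we, end) - max(ws, start))

    hits = [p for p in pairs if overlap(p) > 0]
    hits.sort(
        key=lambda p: (
            -overlap(p),
            abs(sum(p.window(mode)) / 2.0 - tc),
            p.window(mode)[0],
        )
    )
    return hits
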