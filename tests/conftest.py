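"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's scanning/pairing/interval code:
guide sites are found by testing every position and strand against the
expanded motif set, pairs by an exhaustive Cartesian product, and coverage
by marking a per-position boolean array.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from nickpair import (
    AmpliconModel,
    GenomeSimSpec,
    PairRule,
    PamSpec,
    SequenceRecord,
    simulate_genome,
)

IUPAC_ORACLE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def oracle_expand(motif: str) -> set[str]:
    return {"".join(w) for w in product(*(IUPAC_ORACLE[c] for c in motif))}


def oracle_scan(seq: str, motif: str):
    """Every (strand, protospacer_start) guide site, by direct position tests.

    Returns tuples (strand, protospacer_start, protospacer, pam) in guide
    orientation, matching the package's GuideSite fields.
    """
    words = oracle_expand(motif)
    L = len(seq)
    hits = []
    for s in range(L):
        # plus strand: protospacer [s, s+20), PAM [s+20, s+23)
        if s + 23 <= L:
            proto, pam = seq[s : s + 20], seq[s + 20 : s + 23]
            if pam in words and "N" not in proto:
                hits.append(("+", s, proto, pam))
        # minus strand: protospacer footprint [s, s+20), PAM [s-3, s)
        if s - 3 >= 0 and s + 20 <= L:
            proto_f, pam_f = seq[s : s + 20], seq[s - 3 : s]
            if rc(pam_f) in words and "N" not in proto_f:
                hits.append(("-", s, rc(proto_f), rc(pam_f)))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def oracle_pair_coverage(
    seq: str,
    motifs: list[str],
    offset_min: int,
    offset_max: int,
    mode: str,
    scans: dict[str, list] | None = None,
) -> np.ndarray:
    """Per-position targetability from the exhaustive pair Cartesian product.

    Every (minus guide, plus guide) combination is tested against the offset
    window; windows of passing pairs are painted onto a boolean array.
    ``scans`` optionally supplies precomputed oracle_scan results per motif.
    """
    minus_sites, plus_sites = [], []
    for motif in motifs:
        hits = scans[motif] if scans is not None else oracle_scan(seq, motif)
        for strand, start, _, _ in hits:
            (plus_sites if strand == "+" else minus_sites).append(start)
    covered = np.zeros(len(seq), dtype=bool)
    if not minus_sites or not plus_sites:
        return covered
    mi = np.asarray(sorted(set(minus_sites)))
    pl = np.asarray(sorted(set(plus_sites)))
    off = pl[None, :] - (mi[:, None] + 19) - 1  # full Cartesian offset matrix
    ii, jj = np.nonzero((off >= offset_min) & (off <= offset_max))
    for i, j in zip(ii, jj):
        ls, rs = int(mi[i]), int(pl[j])
        if mode == "overhang":
            covered[ls + 3 : rs + 17] = True
        else:  # guide_span
            covered[ls : rs + 23] = True
    return covered


def bool_array_to_intervals(arr: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], arr, [False]]).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


@pytest.fixture(scope="session")
def random_record():
    def make(length: int = 2000, seed: int = 0, gc: float = 0.41) -> SequenceRecord:
        return simulate_genome(GenomeSimSpec(length=length, gc_fraction=gc, seed=seed))

    return make


@pytest.fixture(scope="session")
def del23_amplicon():
    """Synthetic ~150-bp amplicon with a central EcoRI site and a 23-bp
    deletion allele, mirroring a paired-nick edit at a triplicated locus."""
    rng = np.random.default_rng(20)
    left = "".join(rng.choice(list("ACGT"), size=70))
    right = "".join(rng.choice(list("ACGT"), size=74))
    wt = left + "GAATTC" + right  # 150 nt, EcoRI site at [70, 76)
    deletion = wt[:64] + wt[87:]  # 23-bp deletion spanning the site
    return AmpliconModel(
        reference=wt,
        edit_window=(60, 90),
        alleles=(("WT", wt), ("del23", deletion)),
    )


@pytest.fixture(scope="session")
def default_rule():
    return PairRule(0, 20, True)


@pytest.fixture(scope="session")
def ngg_spec():
    return PamSpec("NGG", "NGG")


@pytest.fixture(scope="session")
def nga_spec():
    return PamSpec("NGA", "NGA")
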