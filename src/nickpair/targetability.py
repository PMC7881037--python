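"""Genome-wide targetability coverage for paired-nickase PAM sets.

A base position is *targetable* under a PAM set when it is covered by the
predicted edited window of at least one valid PAM-out nickase pair formed
from guides of that set. Coverage for a set of contigs is the merged covered
length divided by the total number of bases supplied (N bases included in
the denominator), so the full-assembly total is reproduced when a complete
reference genome is scanned.

Two window definitions are supported:

* ``overhang`` (default) — the interval between the two nick boundaries,
  i.e. the predicted 5' overhang of the staggered break;
* ``guide_span`` — from the left protospacer start to the right PAM end.

Combined ("used together") sets pool the guides of all their PAM specs
before pairing, so heterotypic pairs (one NGG guide + one NGA guide) count;
``combine_homotypic_only`` instead unions the homotypic coverages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_io import (
    IntervalSet,
    SequenceRecord,
    interval_difference,
    interval_union,
    iter_fasta,
    merge_intervals,
    write_bed,
)
from .pam_engine import (
    NickasePair,
    PairRule,
    PamSpec,
    enumerate_pairs,
    scan_guides_multi,
)

WINDOW_MODES = ("overhang", "guide_span")


@dataclass
class CoverageReport:
    """Targetable-site counts and fractions per PAM-set label."""

    denominator: int
    per_set: dict[str, tuple[int, float]] = field(default_factory=dict)
    union_count: int = 0
    union_fraction: float = 0.0
    differences: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "denominator": self.denominator,
            "per_set": {
                label: {"targetable_count": c, "fraction": f}
                for label, (c, f) in self.per_set.items()
            },
            "union": {
                "targetable_count": self.union_count,
                "fraction": self.union_fraction,
            },
            "differences": {
                f"{a}\\{b}": c for (a, b), c in self.differences.items()
            },
        }


def pair_windows(pairs: Iterable[NickasePair], mode: str) -> list[tuple[int, int]]:
    if mode not in WINDOW_MODES:
        raise ValueError(f"unknown window mode {mode!r}")
    return [p.window(mode) for p in pairs]


def targetable_intervals(
    record: SequenceRecord,
    pam_specs: Sequence[PamSpec],
    rule: PairRule = PairRule(),
    mode: str = "overhang",
) -> IntervalSet:
    """Merged union of edited windows of all valid pairs on one contig."""
    if not pam_specs:
        raise ValueError("at least one PAM spec required")
    guides = scan_guides_multi(record, pam_specs)
    pairs = enumerate_pairs(guides, rule)
    return merge_intervals(pair_windows(pairs, mode), record.id)


def _set_intervals_per_contig(
    genome: Sequence[SequenceRecord],
    set_definitions: Mapping[str, Sequence[PamSpec]],
    rule: PairRule,
    mode: str,
    combine_homotypic_only: bool,
) -> dict[str, dict[str, IntervalSet]]:
    """label -> contig -> merged IntervalSet."""
    out: dict[str, dict[str, IntervalSet]] = {lab: {} for lab in set_definitions}
    for record in genome:
        for label, specs in set_definitions.items():
            if combine_homotypic_only and len(specs) > 1:
                iv = IntervalSet(record.id, [])
                for spec in specs:
                    iv = interval_union(
                        iv, targetable_intervals(record, [spec], rule, mode)
                    )
            else:
                iv = targetable_intervals(record, specs, rule, mode)
            out[label][record.id] = iv
    return out


def coverage_report(
    genome: Sequence[SequenceRecord],
    set_definitions: Mapping[str, Sequence[PamSpec]],
    rule: PairRule = PairRule(),
    mode: str = "overhang",
    combine_homotypic_only: bool = False,
) -> CoverageReport:
    """Compute per-set, union, and pairwise-difference coverage statistics.

    The denominator is the total length of all supplied sequences, N bases
    included. Differences are computed by interval subtraction on the merged
    sets, per contig, then summed.
    """
    if not genome:
        raise ValueError("empty genome")
    labels = list(set_definitions)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate set labels")

    denom = sum(r.length for r in genome)
    per_contig = _set_intervals_per_contig(
        genome, set_definitions, rule, mode, combine_homotypic_only
    )

    report = CoverageReport(denominator=denom)
    for label in labels:
        count = sum(iv.covered_length() for iv in per_contig[label].values())
        report.per_set[label] = (count, count / denom if denom else 0.0)

    union_total = 0
    for record in genome:
        u = IntervalSet(record.id, [])
        for label in labels:
            u = interval_union(u, per_contig[label][record.id])
        union_total += u.covered_length()
    report.union_count = union_total
    report.union_fraction = union_total / denom if denom else 0.0

    for a in labels:
        for b in labels:
            if a == b:
                continue
            diff = 0
            for record in genome:
                diff += interval_difference(
                    per_contig[a][record.id], per_contig[b][record.id]
                ).covered_length()
            report.differences[(a, b)] = diff
    return report


def run_genome_coverage(
    fasta_path: str | Path,
    set_definitions: Mapping[str, Sequence[PamSpec]],
    rule: PairRule = PairRule(),
    mode: str = "overhang",
    combine_homotypic_only: bool = False,
    json_out: str | Path | None = None,
    bed_out_dir: str | Path | None = None,
) -> CoverageReport:
    """Streamed whole-genome coverage run with JSON and per-set BED output.

    Contigs are processed one at a time; pairs cannot span contigs, so the
    streamed result is identical to an in-memory computation. BED files are
    one per set label, named ``<label>.targetable.bed``.
    """
    labels = list(set_definitions)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate set labels")

    denom = 0
    counts = {lab: 0 for lab in labels}
    union_total = 0
    diffs = {(a, b): 0 for a in labels for b in labels if a != b}

    bed_handles = {}
    if bed_out_dir is not None:
        bed_dir = Path(bed_out_dir)
        bed_dir.mkdir(parents=True, exist_ok=True)
        safe = {lab: lab.replace("/", "_").replace(" ", "_") for lab in labels}
        bed_handles = {
            lab: open(bed_dir / f"{safe[lab]}.targetable.bed", "w") for lab in labels
        }
    try:
        n_contigs = 0
        for record in iter_fasta(fasta_path):
            n_contigs += 1
            denom += record.length
            per_label: dict[str, IntervalSet] = {}
            for label in labels:
                specs = set_definitions[label]
                if combine_homotypic_only and len(specs) > 1:
                    iv = IntervalSet(record.id, [])
                    for spec in specs:
                        iv = interval_union(
                            iv, targetable_intervals(record, [spec], rule, mode)
                        )
                else:
                    iv = targetable_intervals(record, specs, rule, mode)
                per_label[label] = iv
                counts[label] += iv.covered_length()
                if label in bed_handles:
                    for s, e in iv:
                        bed_handles[label].write(f"{record.id}\t{s}\t{e}\n")
            u = IntervalSet(record.id, [])
            for label in labels:
                u = interval_union(u, per_label[label])
            union_total += u.covered_length()
            for a in labels:
                for b in labels:
                    if a != b:
                        diffs[(a, b)] += interval_difference(
                            per_label[a], per_label[b]
                        ).covered_length()
        if n_contigs == 0:
            raise ValueError(f"empty genome: {fasta_path}")
    finally:
        for handle in bed_handles.values():
            handle.close()

    report = CoverageReport(denominator=denom)
    for label in labels:
        report.per_set[label] = (
            counts[label],
            counts[label] / denom if denom else 0.0,
        )
    report.union_count = union_total
    report.union_fraction = union_total / denom if denom else 0.0
    report.differences = diffs

    if json_out is not None:
        Path(json_out).parent.mkdir(parents=True, exist_ok=True)
        with open(json_out, "w") as out:
            json.dump(report.to_dict(), out, indent=2, sort_keys=True)
            out.write("\n")
    return report
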