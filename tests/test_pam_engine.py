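"""PAM expansion, guide scanning, and double-nick pair enumeration."""

import pytest
from hypothesis import given, settings, strategies as st

from nickpair import (
    GuideSite,
    PairRule,
    PamSpec,
    SequenceRecord,
    design_pairs_for_interval,
    enumerate_pairs,
    expand_iupac,
    scan_guides,
    scan_guides_multi,
)
from nickpair.pam_engine import ContigMixError, PamError

from conftest import oracle_scan


class TestExpandIupac:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("NGG", {"AGG", "CGG", "GGG", "TGG"}),
            ("NGA", {"AGA", "CGA", "GGA", "TGA"}),
            ("NRG", {"AAG", "AGG", "CAG", "CGG", "GAG", "GGG", "TAG", "TGG"}),
            ("GAA", {"GAA"}),
        ],
    )
    def test_expansion(self, motif, expected):
        assert expand_iupac(motif) == expected

    def test_invalid_code_rejected(self):
        with pytest.raises(PamError):
            expand_iupac("NGX")

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=3, max_size=3))
    @settings(max_examples=40, deadline=None)
    def test_expansion_size_is_product_of_degeneracies(self, motif):
        sizes = {"A": 1, "C": 1, "G": 1, "T": 1, "R": 2, "Y": 2, "S": 2,
                 "W": 2, "K": 2, "M": 2, "B": 3, "D": 3, "H": 3, "V": 3, "N": 4}
        n = 1
        for c in motif:
            n *= sizes[c]
        assert len(expand_iupac(motif)) == n


class TestScanGuides:
    def test_single_plus_site_geometry(self):
        rec = SequenceRecord("t", "A" * 20 + "TGG")
        (g,) = scan_guides(rec, PamSpec("NGG", "NGG"))
        assert g.strand == "+"
        assert g.protospacer == "A" * 20
        assert g.pam == "TGG"
        assert g.pam_start == 20
        assert g.five_prime_end == 0
        assert g.nick_position == 17  # cut between reference positions 16|17

    def test_minus_site_geometry(self):
        # top strand CCA then 20 T's = bottom-strand guide (A's) with TGG PAM
        rec = SequenceRecord("t", "CCA" + "T" * 20)
        (g,) = scan_guides(rec, PamSpec("NGG", "NGG"))
        assert g.strand == "-"
        assert g.protospacer_start == 3
        assert g.protospacer == "A" * 20
        assert g.pam == "TGG"
        assert g.pam_start == 0
        assert g.five_prime_end == 22
        assert g.nick_position == 6

    def test_too_short_yields_empty(self):
        rec = SequenceRecord("t", "A" * 19 + "TGG")  # 22 nt: no room
        assert scan_guides(rec, PamSpec("NGG", "NGG")) == []

    def test_n_in_protospacer_excluded(self):
        rec = SequenceRecord("t", "A" * 10 + "N" + "A" * 9 + "TGG")
        assert scan_guides(rec, PamSpec("NGG", "NGG")) == []

    @pytest.mark.parametrize("motif", ["NGG", "NGA"])
    @pytest.mark.parametrize("seed", [13, 14, 15])
    def test_matches_brute_force_on_random_sequence(
        self, random_record, motif, seed
    ):
        rec = random_record(length=2000, seed=seed)
        got = [
            (g.strand, g.protospacer_start, g.protospacer, g.pam)
            for g in scan_guides(rec, PamSpec(motif, motif))
        ]
        assert got == oracle_scan(rec.sequence, motif)

    @pytest.mark.parametrize("seed", range(5))
    def test_strand_symmetry_under_reverse_complement(self, random_record, seed):
        rec = random_record(length=1500, seed=100 + seed)
        fwd = scan_guides(rec, PamSpec("NGA", "NGA"))
        rev = scan_guides(rec.reverse_complement(), PamSpec("NGA", "NGA"))
        L = rec.length

        def key(g):
            return (g.strand, g.protospacer_start, g.protospacer, g.pam)

        def reflect(g):
            # protospacer footprint [s, s+20) maps to [L-s-20, L-s)
            return (
                "-" if g.strand == "+" else "+",
                L - g.protospacer_start - 20,
                g.protospacer,
                g.pam,
            )

        assert sorted(map(key, fwd)) == sorted(map(reflect, rev))


def _mk_minus(five_prime_end, contig="c", label="NGG"):
    start = five_prime_end - 19
    return GuideSite(contig, "-", start, "A" * 20, "AGG", label)


def _mk_plus(five_prime_end, contig="c", label="NGG"):
    return GuideSite(contig, "+", five_prime_end, "A" * 20, "AGG", label)


class TestEnumeratePairs:
    def test_offset_formula(self):
        pairs = enumerate_pairs([_mk_minus(100), _mk_plus(111)], PairRule())
        assert len(pairs) == 1 and pairs[0].offset == 10

    def test_offset_21_excluded(self):
        assert enumerate_pairs([_mk_minus(100), _mk_plus(122)], PairRule()) == []

    def test_offset_bounds_inclusive(self):
        assert len(enumerate_pairs([_mk_minus(100), _mk_plus(101)], PairRule())) == 1
        assert len(enumerate_pairs([_mk_minus(100), _mk_plus(121)], PairRule())) == 1

    def test_pam_in_orientation_rejected(self):
        # plus guide left of minus guide = PAM-in: never a valid pair
        assert enumerate_pairs([_mk_plus(100), _mk_minus(111)], PairRule()) == []

    def test_mixed_pams_flag(self):
        guides = [_mk_minus(100, label="NGG"), _mk_plus(111, label="NGA")]
        assert len(enumerate_pairs(guides, PairRule(allow_mixed_pams=True))) == 1
        assert enumerate_pairs(guides, PairRule(allow_mixed_pams=False)) == []

    def test_contig_mix_rejected(self):
        with pytest.raises(ContigMixError):
            enumerate_pairs([_mk_minus(100, "a"), _mk_plus(111, "b")], PairRule())

    def test_window_geometry(self):
        (p,) = enumerate_pairs([_mk_minus(100), _mk_plus(111)], PairRule())
        # left nick at 81+3, right nick at 111+17
        assert p.overhang_window == (84, 128)
        assert p.guide_span_window == (81, 134)

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_double_loop_equivalence(self, random_record, seed):
        rec = random_record(length=3000, seed=50 + seed)
        guides = scan_guides_multi(
            rec, [PamSpec("NGG", "NGG"), PamSpec("NGA", "NGA")]
        )
        rule = PairRule(0, 20, True)
        got = {
            (p.left.protospacer_start, p.right.protospacer_start, p.pam_labels)
            for p in enumerate_pairs(guides, rule)
        }
        expected = set()
        for left in guides:
            for right in guides:
                if left.strand == "-" and right.strand == "+":
                    off = right.five_prime_end - left.five_prime_end - 1
                    if 0 <= off <= 20:
                        expected.add(
                            (
                                left.protospacer_start,
                                right.protospacer_start,
                                (left.pam_label, right.pam_label),
                            )
                        )
        assert got == expected


@pytest.fixture()
def nga_only_contig():
    """300-nt contig with exactly one valid NGA pair: a poly-C background
    carrying one PAM-out NGA guide pair around position 150."""
    seq = list("C" * 300)
    # minus guide: PAM TCA at [127,130) (revcomp TGA = NGA), proto [130,150)
    seq[127:130] = "TCA"
    # plus guide: proto [160,180), PAM AGA at [180,183); offset 160-149-1=10
    seq[180:183] = "AGA"
    return SequenceRecord("toy", "".join(seq))


class TestDesignPairsForInterval:
    def test_single_nga_pair_found(self, nga_only_contig):
        pairs = design_pairs_for_interval(
            [nga_only_contig], "toy", (140, 170), [PamSpec("NGA", "NGA")]
        )
        assert len(pairs) == 1
        assert pairs[0].offset == 10
        assert pairs[0].left.protospacer_start == 130
        assert pairs[0].right.protospacer_start == 160

    def test_ngg_only_scan_misses_nga_site(self, nga_only_contig):
        assert (
            design_pairs_for_interval(
                [nga_only_contig], "toy", (140, 170), [PamSpec("NGG", "NGG")]
            )
            == []
        )
        both = design_pairs_for_interval(
            [nga_only_contig],
            "toy",
            (140, 170),
            [PamSpec("NGG", "NGG"), PamSpec("NGA", "NGA")],
        )
        assert len(both) >= 1  # adding the relaxed PAM rescues the target

    def test_pam_free_target_is_empty(self):
        rec = SequenceRecord("a", "A" * 400)
        assert design_pairs_for_interval([rec], "a", (100, 300)) == []

    def test_unknown_contig_and_empty_target(self, nga_only_contig):
        with pytest.raises(KeyError):
            design_pairs_for_interval([nga_only_contig], "nope", (0, 10))
        with pytest.raises(ValueError):
            design_pairs_for_interval([nga_only_contig], "toy", (10, 10))

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_full_scan_plus_overlap_filter(
        self, random_record, seed
    ):
        rec = random_record(length=2000, seed=200 + seed)
        target = (900, 1100)
        specs = [PamSpec("NGG", "NGG"), PamSpec("NGA", "NGA")]
        designed = design_pairs_for_interval([rec], rec.id, target, specs)
        full = enumerate_pairs(scan_guides_multi(rec, specs), PairRule())

        def overlaps(p):
            ws, we = p.overhang_window
            return min(we, target[1]) > max(ws, target[0])

        expected = {
            (p.left.protospacer_start, p.right.protospacer_start, p.pam_labels)
            for p in full
            if overlaps(p)
        }
        got = {
            (p.left.protospacer_start, p.right.protospacer_start, p.pam_labels)
            for p in designed
        }
        assert got == expected
        # ranking: overlap lengths non-increasing
        ovl = [
            min(p.overhang_window[1], target[1]) - max(p.overhang_window[0], target[0])
            for p in designed
        ]
        assert ovl == sorted(ovl, reverse=True)
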