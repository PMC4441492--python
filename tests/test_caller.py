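import numpy as np
import pytest

from csrseq import SimJunctionConfig, revcomp, simulate_junctions
from csrseq.caller import (
    CallerParams,
    SegmentMatch,
    dedup_reads,
    render_threewise,
    resolve_boundary,
    scan_reference,
    segment_junction,
)
from csrseq.refdata import SwitchRegion, ValidationError, build_reference_set

from conftest import bruteforce_boundary, segment_from_truth


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScanReference:
    def test_exact_substring_self_match(self, refs):
        region = refs.donor
        read = region.sequence[300:360]
        hits = scan_reference(read, region, "+")
        best = hits[0]
        assert (best.query_start, best.query_end) == (0, 60)
        assert (best.ref_start, best.ref_end) == (300, 360)
        assert best.mismatches == 0

    def test_reverse_strand_symmetry(self, refs):
        region = refs.donor
        read = revcomp(region.sequence[300:360])
        hits = scan_reference(read, region, "-")
        best = hits[0]
        assert (best.ref_start, best.ref_end) == (300, 360)
        assert best.strand == "-"
        assert best.mismatches == 0

    def test_scattered_mismatches_vs_banded_bruteforce(self):
        rng = np.random.default_rng(5)
        region = SwitchRegion("toy", _rand_seq(rng, 200))
        read = list(region.sequence[50:130])
        for pos in (20, 55):  # two scattered substitutions
            read[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[pos]]
        read = "".join(read)
        hits = scan_reference(read, region, "+", CallerParams(max_mismatch_rate=0.1))
        best = max(hits, key=lambda h: h.score)
        assert best.mismatches == 2
        # exhaustive O(n*m) gap-free oracle: best window over every diagonal
        oracle_best = None
        for diag in range(-len(read) + 1, len(region.sequence)):
            lo = max(0, -diag)
            hi = min(len(read), len(region.sequence) - diag)
            for qs in range(lo, hi):
                for qe in range(qs + 20, hi + 1):
                    mism = sum(
                        read[q] != region.sequence[q + diag] for q in range(qs, qe)
                    )
                    if mism / (qe - qs) > 0.1:
                        continue
                    score = (qe - qs) - 4 * mism
                    if oracle_best is None or score > oracle_best[0]:
                        oracle_best = (score, qs, qe, mism)
        assert (best.query_start, best.query_end) == (oracle_best[1], oracle_best[2])

    def test_empty_read_rejected(self, refs):
        with pytest.raises(ValidationError):
            scan_reference("", refs.donor, "+")


def _boundary_refs(rng, left_tail, right_head):
    """References where the donor ends in left_tail and acceptor starts with
    right_head at known positions."""
    donor = SwitchRegion("Smu", _rand_seq(rng, 150) + left_tail + _rand_seq(rng, 150))
    acceptor = SwitchRegion("Sg1", _rand_seq(rng, 150) + right_head + _rand_seq(rng, 150))
    return build_reference_set([donor, acceptor], "Smu", "Sg1")


class TestResolveBoundary:
    def test_microhomology_example_gct(self):
        # donor continues ...AGGCT, acceptor begins GCTTA...; read ...AGGCTTA...
        rng = np.random.default_rng(6)
        refs = _boundary_refs(rng, "AGGCT", "GCTTA")
        donor, acceptor = refs.donor.sequence, refs.acceptor.sequence
        read = donor[105:155] + acceptor[153:203]  # shares "GCT"
        left = SegmentMatch(0, 50, "Smu", 105, 155, "+", 0, 50)
        right = SegmentMatch(50, 100, "Sg1", 153, 203, "+", 0, 50)
        boundary = resolve_boundary(read, left, right, refs)
        oracle = bruteforce_boundary(read, donor, 105, acceptor, 153 - 50)
        assert boundary.kind == "microhomology"
        assert boundary.overlap_len >= 3
        assert (boundary.kind, boundary.overlap_len) == (oracle[0], oracle[1])

    def test_blunt_seam(self, refs):
        cfg = SimJunctionConfig(
            seed=21, n_reads=5, compound_fraction=0.0,
            boundary_mix={"blunt": 1.0, "microhomology": 0.0, "insertion": 0.0},
        )
        _, truth = simulate_junctions(cfg, refs)
        for t in truth.reads:
            left, right = (segment_from_truth(f) for f in t.fragments)
            boundary = resolve_boundary(t.seq, left, right, refs)
            assert boundary.kind == "blunt"
            assert boundary.overlap_len == 0
            assert boundary.insertion_seq == ""

    def test_insertion_uppercased(self):
        rng = np.random.default_rng(7)
        refs = _boundary_refs(rng, "AGGCC", "GGTTA")
        donor, acceptor = refs.donor.sequence, refs.acceptor.sequence
        ins = "tt"
        if donor[155] == "T" or acceptor[149] == "T":  # keep the seam clean
            ins = "cc" if donor[155] != "C" and acceptor[149] != "C" else "aa"
        read = donor[105:155] + ins + acceptor[150:200]
        left = SegmentMatch(0, 50, "Smu", 105, 155, "+", 0, 50)
        right = SegmentMatch(52, len(read), "Sg1", 150, 200, "+", 0, 50)
        boundary = resolve_boundary(read.upper(), left, right, refs)
        oracle = bruteforce_boundary(read.upper(), donor, 105, acceptor, 150 - 52)
        assert (boundary.kind, boundary.overlap_len, boundary.insertion_seq) == oracle
        assert boundary.kind == "insertion"
        assert boundary.insertion_seq == ins.upper()

    def test_breakpoint_coordinates_delimit_window(self, refs):
        cfg = SimJunctionConfig(
            seed=22, n_reads=10, compound_fraction=0.0,
            boundary_mix={"blunt": 0.0, "microhomology": 1.0, "insertion": 0.0},
        )
        _, truth = simulate_junctions(cfg, refs)
        for t in truth.reads:
            left, right = (segment_from_truth(f) for f in t.fragments)
            b = resolve_boundary(t.seq, left, right, refs)
            assert b.kind == "microhomology"
            # reported breaks delimit the ambiguity window on each reference
            donor_local = b.left_break_ref - refs.donor.genomic_offset
            acceptor_local = b.right_break_ref - refs.acceptor.genomic_offset
            assert refs.donor.sequence[donor_local] == t.seq[b.query_left_end - 1]
            assert refs.acceptor.sequence[acceptor_local] == t.seq[b.query_right_start]

    def test_placement_invariant_to_fragment_trimming(self, refs):
        # OL depends on the read and reference continuations only: shifting
        # the fragment ends inside the homology window must not change it
        cfg = SimJunctionConfig(
            seed=23, n_reads=10, compound_fraction=0.0,
            boundary_mix={"blunt": 0.0, "microhomology": 1.0, "insertion": 0.0},
            mh_length_fixed=6,
        )
        _, truth = simulate_junctions(cfg, refs)
        for t in truth.reads:
            left, right = (segment_from_truth(f) for f in t.fragments)
            reference_call = resolve_boundary(t.seq, left, right, refs)
            for shift in (1, 3, 5):
                trimmed_left = SegmentMatch(
                    left.query_start, left.query_end - shift, left.region_name,
                    left.ref_start, left.ref_end - shift, "+", 0, left.score - shift,
                )
                grown_right = SegmentMatch(
                    right.query_start + shift, right.query_end, right.region_name,
                    right.ref_start + shift, right.ref_end, "+", 0, right.score - shift,
                )
                b = resolve_boundary(t.seq, trimmed_left, grown_right, refs)
                assert (b.kind, b.overlap_len, b.insertion_seq) == (
                    reference_call.kind,
                    reference_call.overlap_len,
                    reference_call.insertion_seq,
                )

    def test_degenerate_identical_fragments_rejected(self, refs):
        seg = SegmentMatch(0, 30, "Smu", 100, 130, "+", 0, 30)
        with pytest.raises(ValidationError):
            resolve_boundary(refs.donor.sequence[100:160], seg, seg, refs)


class TestSegmentJunction:
    def test_clean_two_fragment_read(self, refs):
        read = refs.donor.sequence[0:300] + refs.acceptor.sequence[400:700]
        call = segment_junction(read, refs, read_id="r1")
        assert call.callable
        assert len(call.fragments) == 2
        assert len(call.boundaries) == 1
        assert call.fragments[0].region_name == "Smu"
        assert call.fragments[1].region_name == "Sg1"

    def test_compound_three_fragment_read(self, refs):
        donor, acceptor = refs.donor.sequence, refs.acceptor.sequence
        read = donor[0:200] + donor[900:1100] + acceptor[100:300]
        call = segment_junction(read, refs, read_id="r2")
        assert call.callable
        assert len(call.fragments) == 3
        assert len(call.boundaries) == 2
        assert [f.region_name for f in call.fragments] == ["Smu", "Smu", "Sg1"]

    def test_pure_donor_read_uncallable(self, refs):
        call = segment_junction(refs.donor.sequence[100:500], refs, read_id="r3")
        assert not call.callable
        assert "acceptor" in call.note
        assert call.fragments  # partial matches are carried along

    def test_orientation_normalisation(self, refs):
        read = refs.donor.sequence[0:300] + refs.acceptor.sequence[400:700]
        fwd = segment_junction(read, refs, read_id="f")
        rev = segment_junction(revcomp(read), refs, read_id="r")
        assert rev.was_reverse_complemented
        assert rev.read_seq == fwd.read_seq
        assert [(f.region_name, f.strand, f.ref_start) for f in rev.fragments] == [
            (f.region_name, f.strand, f.ref_start) for f in fwd.fragments
        ]

    def test_too_short_read_rejected(self, refs):
        with pytest.raises(ValidationError):
            segment_junction("ACGT" * 5, refs)


class TestDedup:
    def test_exact_duplicates_dropped_keep_first(self):
        reads = [("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "TTTTGGGG")]
        assert dedup_reads(reads) == [("a", "ACGTACGT"), ("c", "TTTTGGGG")]

    def test_same_junction_different_elsewhere_both_kept(self, refs):
        # identical +/-40nt around the junction, different elsewhere
        donor, acceptor = refs.donor.sequence, refs.acceptor.sequence
        r1 = donor[0:300] + acceptor[400:700]
        r2 = donor[50:300] + acceptor[400:650]
        assert r1[260:340] in r2  # shared junction neighbourhood
        assert dedup_reads([("a", r1), ("b", r2)]) == [("a", r1), ("b", r2)]

    def test_empty_input(self):
        assert dedup_reads([]) == []


class TestRenderThreewise:
    def _bracket_window(self, block_lines):
        anno = block_lines[6]
        assert anno.count("[") == 1 and anno.count("]") == 1
        return anno.index("]") - anno.index("[") - 1

    def test_overlap_render_has_bracketed_columns_with_double_pipes(self, refs):
        cfg = SimJunctionConfig(
            seed=24, n_reads=3, compound_fraction=0.0,
            boundary_mix={"blunt": 0.0, "microhomology": 1.0, "insertion": 0.0},
            mh_length_fixed=3,
        )
        _, truth = simulate_junctions(cfg, refs)
        t = truth.reads[0]
        call = segment_junction(t.seq, refs, read_id=t.read_id)
        text = render_threewise(call, refs)
        lines = text.splitlines()
        assert self._bracket_window(lines) == 3
        anno = lines[6]
        window = slice(anno.index("[") + 1, anno.index("]"))
        assert lines[2][window] == "|||"  # identity to donor inside window
        assert lines[4][window] == "|||"  # identity to acceptor inside window

    def test_blunt_render_zero_bracketed_columns(self, refs):
        cfg = SimJunctionConfig(
            seed=25, n_reads=1, compound_fraction=0.0,
            boundary_mix={"blunt": 1.0, "microhomology": 0.0, "insertion": 0.0},
        )
        _, truth = simulate_junctions(cfg, refs)
        call = segment_junction(truth.reads[0].seq, refs, read_id="b")
        lines = render_threewise(call, refs).splitlines()
        assert self._bracket_window(lines) == 0

    def test_mutation_near_break_lowercased_without_pipe(self, refs):
        cfg = SimJunctionConfig(
            seed=26, n_reads=1, compound_fraction=0.0,
            boundary_mix={"blunt": 1.0, "microhomology": 0.0, "insertion": 0.0},
        )
        _, truth = simulate_junctions(cfg, refs)
        t = truth.reads[0]
        seam = t.fragments[0].query_end
        pos = seam - 6  # 6 nt left of the break, outside the protected core
        old = t.seq[pos]
        new = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
        mutated = t.seq[:pos] + new + t.seq[pos + 1 :]
        call = segment_junction(mutated, refs, read_id="m")
        lines = render_threewise(call, refs).splitlines()
        col = 24 + (pos - max(0, call.boundaries[0].query_right_start - 40))
        assert lines[3][col] == new.lower()
        assert lines[2][col] == " "

    def test_deterministic_byte_for_byte(self, refs):
        read = refs.donor.sequence[0:300] + refs.acceptor.sequence[400:700]
        call = segment_junction(read, refs, read_id="d")
        assert render_threewise(call, refs) == render_threewise(call, refs)

    def test_uncallable_render(self, refs):
        call = segment_junction(refs.donor.sequence[100:500], refs, read_id="u")
        assert "uncallable" in render_threewise(call, refs)
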