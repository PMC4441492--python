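import numpy as np
import pytest

from csrseq.refdata import ConfigurationError
from csrseq.shm import classify_motif
from csrseq.simulate import (
    SimJunctionConfig,
    SimSHMConfig,
    make_reference,
    make_shm_reference,
    maximal_exact_matches,
    simulate_junctions,
    simulate_shm_clones,
    write_fasta,
)


def brute_mems(a, b, min_len=1):
    """Quadratic maximal-exact-match oracle."""
    out = []
    for i in range(len(a)):
        for j in range(len(b)):
            if a[i] != b[j] or a[i] == "N":
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1] and a[i - 1] != "N":
                continue  # not left-maximal
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k] and a[i + k] != "N":
                k += 1
            if k >= min_len:
                out.append((k, i, j))
    return out


def brute_seam(read, left_target, left_diag, right_target, right_diag, left_cut, right_cut):
    """Independent perfect-extension scanner (plain loops)."""
    e = left_cut
    while e < len(read):
        t = e + left_diag
        if not (0 <= t < len(left_target)) or read[e] != left_target[t] or read[e] == "N":
            break
        e += 1
    s = right_cut
    while s > 0:
        t = s - 1 + right_diag
        if not (0 <= t < len(right_target)) or read[s - 1] != right_target[t] or read[s - 1] == "N":
            break
        s -= 1
    if e > s:
        return ("microhomology", e - s, "")
    if e == s:
        return ("blunt", 0, "")
    return ("insertion", 0, read[e:s])


def check_truth_seams(refs, truth):
    """Verify every emitted read's realized boundaries against the truth."""
    for t in truth.reads:
        for i, want in enumerate(t.boundaries):
            lf, rf = t.fragments[i], t.fragments[i + 1]
            lt = refs[lf.region_name].oriented(lf.strand)
            rt = refs[rf.region_name].oriented(rf.strand)
            if lf.strand == "+":
                d_l = lf.ref_start - lf.query_start
            else:
                d_l = (len(lt) - lf.ref_end) - lf.query_start
            if rf.strand == "+":
                d_r = rf.ref_start - rf.query_start
            else:
                d_r = (len(rt) - rf.ref_end) - rf.query_start
            got = brute_seam(
                t.seq, lt, d_l, rt, d_r, lf.query_end, rf.query_start
            )
            assert got == (want.kind, want.overlap_len, want.insertion_seq), (
                t.read_id, i, got, want,
            )


class TestMaximalExactMatches:
    def test_against_quadratic_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            assert sorted(maximal_exact_matches(a, b, 2)) == sorted(brute_mems(a, b, 2))

    def test_n_matches_nothing(self):
        assert maximal_exact_matches("ANNA", "ANNA", 2) == []


class TestMakeReference:
    def test_deterministic_fasta_bytes(self, sim_cfg, tmp_path):
        r1 = make_reference(sim_cfg)
        r2 = make_reference(sim_cfg)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta([(r.name, r.sequence) for r in r1], p1)
        write_fasta([(r.name, r.sequence) for r in r2], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_every_tract_length_realizable(self, sim_cfg, refs):
        lens = {l for l, _, _ in maximal_exact_matches(refs.donor.sequence, refs.acceptor.sequence)}
        assert set(range(1, sim_cfg.max_shared_homology + 1)) <= lens
        assert max(lens) <= sim_cfg.max_shared_homology

    def test_zero_repeat_density_motifs_at_background_rate(self):
        cfg = SimJunctionConfig(seed=30, repeat_density=0.0, max_shared_homology=12)
        refs = make_reference(cfg)
        for motif in cfg.repeat_motifs:
            count = refs.donor.sequence.count(motif)
            # binomial expectation ~ n/4^5; allow a generous ceiling
            expected = cfg.ref_length / 4 ** len(motif)
            assert count <= expected * 4 + 3

    def test_disjoint_motifs_share_no_20mer(self):
        cfg = SimJunctionConfig(
            seed=31, shared_motifs=False, max_shared_homology=12,
            repeat_motifs=("GAGCT", "GGGGT"),
        )
        refs = make_reference(cfg)
        mems = maximal_exact_matches(refs.donor.sequence, refs.acceptor.sequence, 20)
        assert mems == []


class TestSimulateJunctions:
    def test_deterministic_under_seed(self, sim_cfg, refs):
        reads1, _ = simulate_junctions(sim_cfg, refs)
        reads2, _ = simulate_junctions(sim_cfg, refs)
        assert reads1 == reads2

    def test_blunt_only_truth(self, refs):
        cfg = SimJunctionConfig(
            seed=32, n_reads=40, compound_fraction=0.0,
            boundary_mix={"blunt": 1.0, "microhomology": 0.0, "insertion": 0.0},
        )
        _, truth = simulate_junctions(cfg, refs)
        assert all(b.overlap_len == 0 and b.kind == "blunt"
                   for t in truth.reads for b in t.boundaries)
        check_truth_seams(refs, truth)

    def test_fixed_overlap_realized_exactly(self, refs):
        cfg = SimJunctionConfig(
            seed=33, n_reads=100, compound_fraction=0.0,
            boundary_mix={"blunt": 0.0, "microhomology": 1.0, "insertion": 0.0},
            mh_length_fixed=5,
        )
        _, truth = simulate_junctions(cfg, refs)
        assert all(t.boundaries[0].overlap_len == 5 for t in truth.reads)
        check_truth_seams(refs, truth)

    def test_all_inversion_compound(self, refs):
        cfg = SimJunctionConfig(
            seed=34, n_reads=20, compound_fraction=1.0,
            event_mix={"intra_donor": 0.0, "intra_acceptor": 0.0,
                       "inversion": 1.0, "microdeletion": 0.0},
        )
        _, truth = simulate_junctions(cfg, refs)
        assert all(any(f.strand == "-" for f in t.fragments) for t in truth.reads)
        check_truth_seams(refs, truth)

    def test_generator_honesty_mixed_conditions(self, refs):
        cfg = SimJunctionConfig(seed=35, n_reads=80, compound_fraction=0.3)
        _, truth = simulate_junctions(cfg, refs)
        check_truth_seams(refs, truth)

    def test_mutations_spare_protected_seams(self, refs):
        cfg = SimJunctionConfig(seed=36, n_reads=40, mutation_rate=0.02)
        _, truth = simulate_junctions(cfg, refs)
        assert any(t.mutations for t in truth.reads)
        check_truth_seams(refs, truth)  # boundaries still realized exactly

    def test_unrealizable_overlap_is_config_error(self, refs):
        cfg = SimJunctionConfig(
            seed=37, n_reads=5, compound_fraction=0.0,
            boundary_mix={"blunt": 0.0, "microhomology": 1.0, "insertion": 0.0},
            mh_length_fixed=200,  # longer than any shared tract
        )
        with pytest.raises(ConfigurationError):
            simulate_junctions(cfg, refs)


class TestSimulateSHM:
    def test_zero_frequency_clones_identical(self):
        cfg = SimSHMConfig(seed=40, n_clones=5, target_frequency=0.0)
        ref = make_shm_reference(cfg)
        clones, truth = simulate_shm_clones(cfg, ref)
        assert all(seq == ref for _, seq in clones)
        assert all(not t.mutations for t in truth)

    def test_planted_count_near_expectation(self):
        cfg = SimSHMConfig(seed=41, n_clones=50, ref_length=500, target_frequency=5e-3)
        clones, truth = simulate_shm_clones(cfg)
        planted = sum(len(t.mutations) for t in truth)
        expected = 50 * 500 * 5e-3  # = 125
        sd = np.sqrt(expected)
        assert abs(planted - expected) < 5 * sd

    def test_hotspot_bias_enriches_focal_positions(self):
        ref = make_shm_reference(SimSHMConfig(seed=42))
        hot = {i for i in range(len(ref))
               if classify_motif(ref, i) in ("hotspot_RGYW", "hotspot_WRCY")}
        base_rate = len(hot) / len(ref)
        cfg = SimSHMConfig(seed=42, n_clones=200, hotspot_bias=10.0)
        _, truth = simulate_shm_clones(cfg, ref)
        muts = [(p - 1) for t in truth for p, _, _ in t.mutations]
        hot_frac = sum(1 for p in muts if p in hot) / len(muts)
        assert hot_frac > 2 * base_rate

    def test_truth_matches_emitted_sequence(self):
        cfg = SimSHMConfig(seed=43, n_clones=20)
        ref = make_shm_reference(cfg)
        clones, truth = simulate_shm_clones(cfg, ref)
        for (cid, seq), t in zip(clones, truth):
            assert cid == t.clone_id
            rebuilt = list(ref)
            for pos, ref_base, alt in t.mutations:
                assert rebuilt[pos - 1] == ref_base
                rebuilt[pos - 1] = alt
            assert "".join(rebuilt) == seq

    def test_transition_bias(self):
        cfg = SimSHMConfig(seed=44, n_clones=300, transition_bias=8.0)
        _, truth = simulate_shm_clones(cfg)
        tr = tv = 0
        pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for t in truth:
            for _, r, a in t.mutations:
                if (r, a) in pairs:
                    tr += 1
                else:
                    tv += 1
        assert tr / (tr + tv) > 0.6  # expectation 8/10

    def test_bad_frequency_rejected(self):
        with pytest.raises(ConfigurationError):
            SimSHMConfig(target_frequency=0.2)
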