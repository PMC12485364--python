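"""Tests of the coalescent + JC69 simulator: coalescent distributions,
rate scaling, the time-shift construction and the counting paths."""

import math

import numpy as np
import pytest

from skewd.patterns import count_patterns, read_alignment
from skewd.simulate import (
    ScenarioConfig,
    SegmentedGeneTree,
    _branch_mutation_lengths,
    _clade_masks,
    _pattern_probs_for_trees,
    _sim_tip_states,
    scale_to_mutation_lengths,
    sim_dataset,
    sim_gene_tree,
    sim_gene_trees,
    sim_locus_alignment,
    time_shift_transform,
)
from skewd.theory import GenerationParams, pattern_freqs, to_mutation_units


def _mrca_times(batch):
    """Times of mrca(P1,P2), mrca(P1,P3), mrca(P2,P3) per locus."""
    n = len(batch)
    masks = _clade_masks(batch.parent)
    out = {}
    for pair, bits in {(0, 1): 3, (0, 2): 5, (1, 2): 6}.items():
        t = np.full(n, np.inf)
        for v in (4, 5, 6):
            hit = (masks[:, v] & bits) == bits
            t[hit] = np.minimum(t[hit], batch.time[hit, v])
        out[pair] = t
    return out


class TestCoalescent:
    def test_sister_coalescence_probability(self, rng):
        # P(P1,P2 coalesce within the internal branch) = 1 - exp(-T_I / 2N)
        sc = ScenarioConfig(
            T_S=2e4, T_I=2e4, T_O=2e4, two_N=2e4, genome_size_bp=1_000_000
        )
        batch = sim_gene_trees(sc, 100_000, rng)
        m = _mrca_times(batch)
        frac = np.mean(m[(0, 1)] < sc.T_S + sc.T_I)
        exp = 1.0 - math.exp(-sc.T_I / sc.two_N)
        se = math.sqrt(exp * (1 - exp) / len(batch))
        assert abs(frac - exp) < 3 * se

    def test_discordance_fraction(self, rng):
        # fraction of gene trees where P1,P2 are not the closest ingroup
        # pair = (2/3) exp(-T_I / 2N)
        sc = ScenarioConfig(
            T_S=2e4, T_I=2e4, T_O=2e4, two_N=2e4, genome_size_bp=1_000_000
        )
        batch = sim_gene_trees(sc, 100_000, rng)
        m = _mrca_times(batch)
        disc = (m[(0, 2)] < m[(0, 1)]) | (m[(1, 2)] < m[(0, 1)])
        exp = (2.0 / 3.0) * math.exp(-sc.T_I / sc.two_N)
        se = math.sqrt(exp * (1 - exp) / len(batch))
        assert abs(disc.mean() - exp) < 3 * se

    def test_no_pulse_without_gamma(self, rng):
        sc = ScenarioConfig(T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, genome_size_bp=1_000_000)
        batch = sim_gene_trees(sc, 1000, rng)
        assert not batch.migrant.any()
        # without the pulse P1,P3 can never coalesce before the P123 epoch
        m = _mrca_times(batch)
        assert np.all(m[(0, 2)] >= sc.T_S + sc.T_I)

    def test_pulse_lets_p1_p3_coalesce_early(self, rng):
        sc = ScenarioConfig(
            T_S=1e5,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            gamma=1.0,
            T_G=0.5e5,
            genome_size_bp=1_000_000,
        )
        batch = sim_gene_trees(sc, 20_000, rng)
        assert batch.migrant.all()
        m = _mrca_times(batch)
        early = m[(0, 2)] < sc.T_S
        # residence (T_S - T_G)/(lambda1*2N) = 5e4/1e4 -> 1 - e^-5
        exp = 1.0 - math.exp(-(sc.T_S - sc.T_G) / sc.two_N)
        se = math.sqrt(exp * (1 - exp) / len(batch))
        assert abs(early.mean() - exp) < 3 * se

    def test_internal_matches_msprime(self, rng):
        """The vectorised sampler and msprime produce the same tree
        distribution (summaries compared on an introgression scenario)."""
        sc = ScenarioConfig(
            T_S=5e4,
            T_I=5e4,
            T_O=5e4,
            two_N=1e4,
            gamma=0.3,
            T_G=2e4,
            genome_size_bp=1_000_000,
        )
        n = 30_000
        bi = sim_gene_trees(sc, n, np.random.default_rng(11), backend="internal")
        bm = sim_gene_trees(sc, n, np.random.default_rng(22), backend="msprime")
        for col in (4, 6):
            a, b = bi.time[:, col], bm.time[:, col]
            se = math.sqrt((a.var() + b.var()) / n)
            assert abs(a.mean() - b.mean()) < 4 * se
        sib_i = (bi.parent[:, 0] == bi.parent[:, 1]).mean()
        sib_m = (bm.parent[:, 0] == bm.parent[:, 1]).mean()
        se = math.sqrt(2 * sib_i * (1 - sib_i) / n)
        assert abs(sib_i - sib_m) < 4 * se


class TestRateScaling:
    def test_uniform_rate(self):
        gt = SegmentedGeneTree(
            parent=np.array([4, 4, 5, 6, 5, 6, -1]),
            time=np.zeros(7),
            segments={0: [("P1", 1e5)]},
        )
        sc = ScenarioConfig(T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, genome_size_bp=100)
        assert scale_to_mutation_lengths(gt, sc)[0] == pytest.approx(1e5 * sc.mu)

    def test_accelerated_tip(self):
        gt = SegmentedGeneTree(
            parent=np.zeros(7, dtype=int), time=np.zeros(7), segments={0: [("P1", 1e5)]}
        )
        sc = ScenarioConfig(
            T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, lambda_p1=1.5, genome_size_bp=100
        )
        assert scale_to_mutation_lengths(gt, sc)[0] == pytest.approx(1.5e5 * sc.mu)

    def test_mixed_segments_are_linear(self):
        T_G, T_S = 4e4, 1e5
        gt = SegmentedGeneTree(
            parent=np.zeros(7, dtype=int),
            time=np.zeros(7),
            segments={2: [("P3", T_G), ("P1", T_S - T_G)]},
            migrant=True,
        )
        sc = ScenarioConfig(
            T_S=T_S,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            lambda_p1=2.0,
            gamma=0.5,
            T_G=T_G,
            genome_size_bp=100,
        )
        expect = sc.mu * (T_G + 2.0 * (T_S - T_G))
        assert scale_to_mutation_lengths(gt, sc)[2] == pytest.approx(expect)

    def test_sampled_tree_segments_sum_to_durations(self, rng):
        sc = ScenarioConfig(
            T_S=1e5,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            gamma=0.5,
            T_G=0.5e5,
            lambda_p1=1.5,
            genome_size_bp=100,
        )
        for _ in range(20):
            gt = sim_gene_tree(sc, rng)
            for v in range(6):
                dur = gt.time[gt.parent[v]] - gt.time[v]
                assert sum(d for _, d in gt.segments[v]) == pytest.approx(dur)

    def test_segment_scaling_matches_batch_lengths(self, rng):
        sc = ScenarioConfig(
            T_S=1e5,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            gamma=0.5,
            T_G=0.5e5,
            lambda_p1=1.5,
            lambda_p3=0.7,
            lambda_o=2.0,
            genome_size_bp=100,
        )
        for _ in range(20):
            gt = sim_gene_tree(sc, rng)
            batch_ml = _branch_mutation_lengths(
                sim_gene_trees_like(gt), sc
            )
            seg_ml = scale_to_mutation_lengths(gt, sc)
            for v in range(6):
                assert seg_ml[v] == pytest.approx(batch_ml[0, v])


def sim_gene_trees_like(gt):
    from skewd.simulate import TreeBatch

    return TreeBatch(
        time=gt.time[None, :],
        parent=gt.parent[None, :],
        migrant=np.array([gt.migrant]),
    )


class TestTimeShift:
    def test_identity_without_rate_variation(self):
        sc = ScenarioConfig(T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, genome_size_bp=100)
        assert time_shift_transform(sc) == sc

    def test_accelerated_p1_shift_values(self):
        sc = ScenarioConfig(
            T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, lambda_p1=1.5, genome_size_bp=100
        )
        sh = time_shift_transform(sc)
        assert sh.T_S == pytest.approx(1.5e5)
        assert sh.sample_times == (0.0, 5e4, 5e4, 5e4)
        assert sh.lambda_p1 == 1.0

    def test_decelerated_tip_sampled_in_past(self):
        sc = ScenarioConfig(
            T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, lambda_p1=0.5, genome_size_bp=100
        )
        sh = time_shift_transform(sc)
        assert sh.T_S == sc.T_S
        assert sh.sample_times == (5e4, 0.0, 0.0, 0.0)

    def test_multiple_shifted_tips_rejected(self):
        sc = ScenarioConfig(
            T_S=1e5,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            lambda_p1=1.5,
            lambda_o=2.0,
            genome_size_bp=100,
        )
        with pytest.raises(ValueError):
            time_shift_transform(sc)

    def test_equivalence_with_direct_scaling(self):
        """Pooled pattern counts under the two constructions agree within
        three binomial standard errors (4 Mb each)."""
        sc = ScenarioConfig(
            T_S=1e5,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            lambda_p1=1.5,
            genome_size_bp=4_000_000,
        )
        c1 = sim_dataset(sc, rng=np.random.default_rng(5))
        c2 = sim_dataset(time_shift_transform(sc), rng=np.random.default_rng(6))
        for a, b in zip(c1.blocks.totals, c2.blocks.totals):
            assert abs(a - b) <= 3.0 * math.sqrt(a + b + 1)


class TestSequenceEvolution:
    def test_zero_branch_lengths_give_identical_sequences(self, rng):
        parent = np.array([4, 4, 5, 6, 5, 6, -1], dtype=np.int8)
        aln = sim_locus_alignment({v: 0.0 for v in range(6)}, parent, 500, rng)
        assert len(set(aln.values())) == 1

    def test_saturation_on_long_branch(self, rng):
        parent = np.array([4, 4, 5, 6, 5, 6, -1], dtype=np.int8)
        bl = {v: 0.0 for v in range(6)}
        bl[3] = 50.0  # outgroup branch saturates
        aln = sim_locus_alignment(bl, parent, 100_000, rng)
        match = np.mean(
            np.frombuffer(aln["O"].encode(), dtype=np.uint8)
            == np.frombuffer(aln["P1"].encode(), dtype=np.uint8)
        )
        assert abs(match - 0.25) < 3 * math.sqrt(0.25 * 0.75 / 100_000)

    def test_negative_branch_rejected(self, rng):
        parent = np.array([4, 4, 5, 6, 5, 6, -1], dtype=np.int8)
        with pytest.raises(ValueError):
            sim_locus_alignment({0: -1e-3}, parent, 10, rng)

    def test_fixed_tree_matches_pruning_oracle(self, rng):
        """Site-pattern frequencies on one fixed gene tree agree with a
        brute-force JC69 pruning computation (independent oracle)."""
        parent = np.array([4, 4, 5, 6, 5, 6, -1], dtype=np.int8)
        bl = np.array([0.01, 0.004, 0.006, 0.03, 0.002, 0.005, 0.0])

        def jc_p(d):
            m = np.full((4, 4), 0.25 - 0.25 * math.exp(-4 * d / 3))
            np.fill_diagonal(m, 0.25 + 0.75 * math.exp(-4 * d / 3))
            return m

        mats = [jc_p(d) for d in bl]
        probs = {}
        for name, tips in {"ABBA": (0, 1, 1, 0), "BABA": (1, 0, 1, 0)}.items():
            tot = 0.0
            for s4 in range(4):
                for s5 in range(4):
                    for s6 in range(4):
                        states = list(tips) + [s4, s5, s6]
                        pr = 0.25
                        for v in range(6):
                            pr *= mats[v][states[parent[v]], states[v]]
                        tot += pr
            probs[name] = 12 * tot
        n = 2_000_000
        ml = np.repeat(bl[None, :], 1, axis=0)
        tips = _sim_tip_states(ml, parent[None, :], rng, n)
        s = tips[0]
        abba = np.mean((s[0] == s[3]) & (s[1] == s[2]) & (s[0] != s[1]))
        baba = np.mean((s[0] == s[2]) & (s[1] == s[3]) & (s[0] != s[1]))
        for obs, exp in ((abba, probs["ABBA"]), (baba, probs["BABA"])):
            se = math.sqrt(exp * (1 - exp) / n)
            assert abs(obs - exp) < 3 * se


class TestPerTreeProbabilities:
    def test_pruning_matches_brute_force(self):
        """Vectorised pruning equals the 4^3-state brute-force sum of JC69
        transition products on a fixed gene tree (independent oracle)."""
        parent = np.array([4, 4, 5, 6, 5, 6, -1], dtype=np.int8)
        bl = np.array([0.01, 0.004, 0.006, 0.03, 0.002, 0.005, 0.0])

        def jc_p(d):
            m = np.full((4, 4), 0.25 - 0.25 * math.exp(-4 * d / 3))
            np.fill_diagonal(m, 0.25 + 0.75 * math.exp(-4 * d / 3))
            return m

        mats = [jc_p(d) for d in bl]
        got = _pattern_probs_for_trees(bl[None, :], parent[None, :])[0]
        for k, tips in enumerate(((0, 1, 1, 0), (1, 0, 1, 0), (1, 1, 0, 0))):
            tot = 0.0
            for s4 in range(4):
                for s5 in range(4):
                    for s6 in range(4):
                        states = list(tips) + [s4, s5, s6]
                        pr = 0.25
                        for v in range(6):
                            pr *= mats[v][states[parent[v]], states[v]]
                        tot += pr
            assert got[k] == pytest.approx(12 * tot, abs=1e-14)

    def test_multinomial_mode_matches_per_site_means(self):
        """The multinomial counting mode draws from the same distribution as
        per-site simulation (pooled totals within three binomial SE)."""
        sc = ScenarioConfig(
            T_S=1e5,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            lambda_p1=1.5,
            genome_size_bp=8_000_000,
        )
        c1 = sim_dataset(sc, rng=np.random.default_rng(71), method="multinomial")
        c2 = sim_dataset(sc, rng=np.random.default_rng(72), method="per_site")
        for a, b in zip(c1.blocks.totals, c2.blocks.totals):
            assert abs(a - b) <= 3 * math.sqrt(a + b + 1)

    def test_multinomial_mode_rejects_fasta(self, tmp_path):
        sc = ScenarioConfig(
            T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, genome_size_bp=10_000
        )
        with pytest.raises(ValueError):
            sim_dataset(sc, method="multinomial", emit_fasta=str(tmp_path / "x.fa"))


class TestDataset:
    def test_counts_match_theory(self):
        """Simulated genome-wide pattern frequencies agree with the exact
        expectation within three binomial standard errors (20 Mb)."""
        sc = ScenarioConfig(
            T_S=1e5,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            lambda_p1=1.5,
            genome_size_bp=20_000_000,
            seed=42,
        )
        counts = sim_dataset(sc)
        f = pattern_freqs(
            to_mutation_units(
                GenerationParams(T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, mu=2e-8),
                (1.5, 1.0, 1.0),
            )
        )
        n = sc.genome_size_bp
        for obs, exp in zip(counts.blocks.totals, (f.p_abba, f.p_baba, f.p_bbaa)):
            se = math.sqrt(exp * (1 - exp) * n)
            assert abs(obs - exp * n) < 3 * se

    def test_clock_balance_in_counts(self):
        sc = ScenarioConfig(
            T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, genome_size_bp=20_000_000, seed=9
        )
        counts = sim_dataset(sc)
        na, nb = counts.n_abba, counts.n_baba
        assert abs(na - nb) <= 3 * math.sqrt(na + nb)

    def test_same_seed_reproduces_counts(self):
        sc = ScenarioConfig(
            T_S=1e5,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            lambda_p1=1.5,
            genome_size_bp=500_000,
            seed=3,
        )
        c1 = sim_dataset(sc)
        c2 = sim_dataset(sc)
        assert np.array_equal(c1.blocks.counts, c2.blocks.counts)

    def test_fasta_path_equals_counting_path(self, tmp_path):
        sc = ScenarioConfig(
            T_S=1e5,
            T_I=1e5,
            T_O=1e5,
            two_N=1e4,
            lambda_p1=1.5,
            genome_size_bp=1_000_000,
            seed=11,
        )
        fa = tmp_path / "aln.fa"
        internal = sim_dataset(sc, emit_fasta=str(fa), n_blocks=20)
        aln = read_alignment(str(fa))
        recount = count_patterns(aln, n_blocks=20)
        assert np.array_equal(internal.blocks.counts, recount.counts)

    def test_block_totals_sum_to_genome_totals(self):
        sc = ScenarioConfig(
            T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, genome_size_bp=200_000, seed=2
        )
        out, per_locus = sim_dataset(sc, n_blocks=10, return_per_locus=True)
        assert np.array_equal(out.blocks.totals, per_locus.sum(axis=0))
        assert out.blocks.ends[-1] == sc.genome_size_bp

    def test_locus_length_does_not_change_expected_counts(self):
        """100 bp vs 1000 bp loci at fixed genome size: free recombination
        between loci leaves expected pattern counts unchanged."""
        kw = dict(
            T_S=1e5, T_I=1e5, T_O=1e5, two_N=1e4, lambda_p1=1.5,
            genome_size_bp=5_000_000,
        )
        c100 = sim_dataset(
            ScenarioConfig(**kw, locus_length_bp=100), rng=np.random.default_rng(21)
        )
        c1000 = sim_dataset(
            ScenarioConfig(**kw, locus_length_bp=1000), rng=np.random.default_rng(22)
        )
        for a, b in zip(c100.blocks.totals, c1000.blocks.totals):
            assert abs(a - b) <= 3 * math.sqrt(a + b + 1)
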