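import numpy as np
import pytest

from matphase.blocks import filter_informative, partition
from matphase.io import build_read_matrix
from matphase.simulate import (
    SimConfig,
    add_noise,
    run_benchmark,
    simulate_reads,
    simulate_trial,
    simulate_truth,
)


class TestTruth:
    def test_all_het_pair_is_complementary(self):
        pair = simulate_truth(50, all_het=True, seed=3)
        assert np.all(pair.hp * pair.hm == -1)

    def test_reproducible_given_seed(self):
        a = simulate_truth(30, seed=11)
        b = simulate_truth(30, seed=11)
        assert np.array_equal(a.hp, b.hp) and np.array_equal(a.hm, b.hm)

    def test_requested_length(self):
        assert simulate_truth(10, seed=0).l == 10

    def test_het_fraction_controls_heterozygosity(self):
        pair = simulate_truth(2000, all_het=False, het_fraction=0.3, seed=5)
        frac = np.mean(pair.hp != pair.hm)
        assert abs(frac - 0.3) < 0.05


class TestReads:
    def test_read_count_derived_from_coverage(self):
        config = SimConfig(l=700, coverage=3.0, mean_snps_per_read=7.4)
        assert config.resolved_n_reads() == 284

    def test_mean_snps_per_read(self):
        config = SimConfig(l=700, coverage=5.0, error_rate=0.0)
        pair = simulate_truth(700, seed=2)
        frags = simulate_reads(pair, config, seed=2)
        mean_k = np.mean([f.n_sites for f in frags])
        assert abs(mean_k - 7.4) < 0.3

    def test_observations_consistent_with_one_parent(self):
        config = SimConfig(l=120, coverage=4.0, error_rate=0.0)
        pair = simulate_truth(120, seed=7)
        for frag in simulate_reads(pair, config, seed=7):
            sites = np.array([j for j, _ in frag.sites])
            vals = np.array([v for _, v in frag.sites], dtype=float)
            assert (
                np.array_equal(vals, pair.hp[sites])
                or np.array_equal(vals, pair.hm[sites])
            )

    def test_fixed_seed_reproducible(self):
        config = SimConfig(l=100, coverage=3.0)
        pair = simulate_truth(100, seed=1)
        assert simulate_reads(pair, config, seed=9) == simulate_reads(pair, config, seed=9)

    def test_column_coverage_concentrates_around_target(self):
        config = SimConfig(l=700, coverage=6.0, error_rate=0.0)
        pair = simulate_truth(700, seed=4)
        frags = simulate_reads(pair, config, seed=4)
        rm = build_read_matrix(frags, 700)
        mean_cov = rm.n_observed / 700
        assert abs(mean_cov - 6.0) / 6.0 < 0.1


class TestNoise:
    def test_zero_rate_is_identity(self, b2ar_read_matrix):
        out = add_noise(b2ar_read_matrix, 0.0, seed=0)
        assert (out.matrix != b2ar_read_matrix.matrix).nnz == 0

    def test_flip_fraction_matches_rate(self):
        rng = np.random.default_rng(0)
        M = rng.choice([-1.0, 1.0], size=(100, 100))
        from matphase.completion import as_read_matrix

        rm = as_read_matrix(M)
        noisy = add_noise(rm, 0.1, seed=5, kind="flip")
        flipped = (noisy.densify() != M).mean()
        sigma = np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(flipped - 0.1) < 3 * sigma

    def test_uniform_contamination_flips_half_as_often(self):
        rng = np.random.default_rng(0)
        M = rng.choice([-1.0, 1.0], size=(100, 100))
        from matphase.completion import as_read_matrix

        noisy = add_noise(as_read_matrix(M), 0.2, seed=5, kind="uniform")
        flipped = (noisy.densify() != M).mean()
        assert abs(flipped - 0.1) < 0.01

    def test_flip_twice_with_same_seed_restores(self, b2ar_read_matrix):
        once = add_noise(b2ar_read_matrix, 0.3, seed=42, kind="flip")
        twice = add_noise(once, 0.3, seed=42, kind="flip")
        assert (twice.matrix != b2ar_read_matrix.matrix).nnz == 0

    def test_omega_unchanged(self, b2ar_read_matrix):
        noisy = add_noise(b2ar_read_matrix, 0.4, seed=1)
        assert (noisy.matrix != 0).sum() == b2ar_read_matrix.n_observed

    def test_rate_validated(self, b2ar_read_matrix):
        with pytest.raises(ValueError):
            add_noise(b2ar_read_matrix, 0.7, seed=0, kind="flip")


class TestTrial:
    def test_connected_single_block(self):
        config = SimConfig(l=80, coverage=6.0, error_rate=0.1)
        truth, rm = simulate_trial(config, seed=3)
        blocks = partition(filter_informative(rm, 2))
        assert len(blocks) == 1
        assert blocks[0].n_sites == 80


class TestBenchmark:
    def test_noiseless_cell_is_exact_for_all_solvers(self):
        df = run_benchmark(
            [(4, 0.0)], ["opt", "svt", "nuc"], trials=2, l=40,
            n_reads_by_coverage={4: 40}, seed=5,
        )
        assert np.allclose(df["mean_rr_percent"], 100.0)
        assert np.allclose(df["mean_swer"], 0.0)
        assert (df["n_failed"] == 0).all()

    def test_deterministic_given_master_seed(self):
        kwargs = dict(cells=[(4, 0.1)], solvers=["opt"], trials=2, l=40,
                      n_reads_by_coverage={4: 40}, seed=8)
        a = run_benchmark(**kwargs)
        b = run_benchmark(**kwargs)
        assert a.equals(b)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(l=1)
        with pytest.raises(ValueError):
            SimConfig(error_rate=0.7)
        with pytest.raises(ValueError):
            SimConfig(mean_snps_per_read=1.0)
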