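import numpy as np
import pytest

from matphase import datasets
from matphase.extraction import HaplotypePair
from matphase.metrics import (
    block_stats,
    classify_switches,
    count_switches,
    evaluate_pair,
    hamming_distance,
    reconstruction_rate,
    smr,
    swer,
)


def _pair(hp, hm):
    return HaplotypePair(np.asarray(hp, dtype=float), np.asarray(hm, dtype=float))


class TestHammingDistance:
    def test_identical_vectors(self):
        assert hamming_distance(datasets.B2AR_HM, datasets.B2AR_HM) == 0

    def test_complementary_worked_haplotypes_differ_at_het_sites(self):
        # the two worked-example haplotypes differ at their 8 heterozygous sites
        assert hamming_distance(datasets.B2AR_HM, datasets.B2AR_HP) == int(
            (datasets.B2AR_HM != datasets.B2AR_HP).sum()
        )

    def test_missing_counts_as_mismatch_against_a_call(self):
        assert hamming_distance(np.array([1, 1, 0.0]), np.array([1, -1, 1.0])) == 2

    def test_missing_equals_missing(self):
        assert hamming_distance(np.zeros(3), np.zeros(3)) == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance(np.zeros(2), np.zeros(3))


class TestReconstructionRate:
    def test_perfect_estimate(self, b2ar_truth):
        assert reconstruction_rate(b2ar_truth, b2ar_truth) == 1.0

    def test_label_swap_invariance(self, b2ar_truth):
        assert reconstruction_rate(b2ar_truth.swapped(), b2ar_truth) == 1.0

    def test_one_error_on_better_strand(self):
        truth = _pair([1] * 10, [-1] * 10)
        est_hp = np.ones(10)
        est_hp[4] = -1
        # a heterozygous miscall appears on both strands of the estimate
        assert reconstruction_rate(_pair(est_hp, -est_hp), truth) == pytest.approx(0.9)

    def test_equals_one_iff_better_strand_error_free(self, rng):
        for _ in range(10):
            hp = rng.choice([-1.0, 1.0], size=12)
            hm = -hp
            est_hp = hp.copy()
            flip = rng.random() < 0.5
            if flip:
                est_hp[int(rng.integers(12))] *= -1
            rr = reconstruction_rate(_pair(est_hp, -est_hp), _pair(hp, hm))
            assert (rr == 1.0) == (not flip)


class TestSwitches:
    def test_four_snp_worked_example(self):
        truth = _pair([1, 1, 1, 1], [-1, -1, -1, -1])
        est = _pair([1, 1, -1, -1], [-1, -1, 1, 1])
        count, positions = count_switches(est, truth)
        assert count == 1
        assert positions == [2]
        assert swer(est, truth) == pytest.approx(0.25)
        assert classify_switches(est, truth) == (0, 1)  # sustained -> long

    def test_isolated_flip_is_two_switches_one_short(self):
        truth = _pair([1, 1, 1, 1], [-1, -1, -1, -1])
        est_hp = np.array([1.0, -1.0, 1.0, 1.0])
        est = _pair(est_hp, -est_hp)
        count, _ = count_switches(est, truth)
        assert count == 2
        assert classify_switches(est, truth) == (1, 0)

    def test_perfect_phasing(self, b2ar_truth):
        assert count_switches(b2ar_truth, b2ar_truth)[0] == 0
        assert classify_switches(b2ar_truth, b2ar_truth) == (0, 0)

    def test_homozygous_sites_excluded(self):
        truth = _pair([1, 1, 1, 1], [-1, 1, -1, 1])  # sites 1 and 3 homozygous
        est = _pair([1, 1, -1, 1], [-1, 1, 1, 1])
        # het sites are 0 and 2; origin flips between them -> one switch
        assert count_switches(est, truth)[0] == 1

    def test_missing_sites_skipped(self):
        truth = _pair([1, 1, 1, 1], [-1, -1, -1, -1])
        est = _pair([1, 0, -1, -1], [-1, 0, 1, 1])
        assert count_switches(est, truth)[0] == 1

    def test_label_flip_symmetry_and_accounting(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            hp = r.choice([-1.0, 1.0], size=20)
            truth = _pair(hp, -hp)
            est_hp = hp * np.where(r.random(20) < 0.25, -1, 1)
            est = _pair(est_hp, -est_hp)
            n, _ = count_switches(est, truth)
            assert count_switches(est.swapped(), truth)[0] == n
            short, long_ = classify_switches(est, truth)
            assert 2 * short + long_ == n
            assert swer(est, truth) * truth.l == pytest.approx(n)


class TestSMR:
    def test_fully_phased(self, b2ar_truth):
        assert smr(b2ar_truth) == 0.0

    def test_partial(self):
        hp = np.ones(100)
        hp[:7] = 0
        hm = -hp
        assert smr(_pair(hp, hm)) == pytest.approx(0.07)

    def test_empty_estimate(self):
        assert smr(_pair(np.zeros(5), np.zeros(5))) == 1.0

    def test_complement_of_phased_fraction(self, rng):
        hp = rng.choice([-1.0, 0.0, 1.0], size=50)
        hm = np.where(hp == 0, 0.0, -hp)
        phased = np.mean(hp != 0)
        assert smr(_pair(hp, hm)) + phased == pytest.approx(1.0)


class TestBlockStats:
    def test_single_correct_block(self):
        assert block_stats([(1000.0, 1.0)]) == (1000.0, 1000.0)

    def test_adjusted_n50_walkthrough(self):
        mean, an50 = block_stats([(1000.0, 1.0), (1000.0, 0.5)])
        assert mean == 1000.0
        assert an50 == 1000.0

    def test_no_blocks_undefined(self):
        assert block_stats([]) == (None, None)

    def test_snp_count_mode_on_worked_example(self, b2ar_read_matrix):
        from matphase.blocks import partition
        from matphase.metrics import block_spans

        blocks = partition(b2ar_read_matrix)
        spans = block_spans(blocks, site_map=None)
        mean, _ = block_stats([(s, 1.0) for s in spans])
        assert mean == 10.0


def test_evaluate_pair_aggregates_all_metrics(b2ar_truth):
    report = evaluate_pair(b2ar_truth, b2ar_truth)
    assert report.rr == 1.0
    assert report.swer == 0.0
    assert report.smr == 0.0
    assert report.switch_count == report.short_switches == report.long_switches == 0
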