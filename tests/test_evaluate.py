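from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import endbias as eb
from endbias.evaluate import _rank_sum
from test_endprofile import manual_labels

from conftest import uniform_cpm_table


def single_sample(counts, ids=None):
    ids = ids or [f"m{i}" for i in range(len(counts))]
    return eb.CountTable(pd.DataFrame({"s1": counts}, index=ids,
                                      dtype=float))


class TestSaturationCurve:
    def test_all_reads_on_one_species(self):
        curve = eb.saturation_curve(single_sample([100, 0, 0]),
                                    bin_size=20, threshold=10, seed=0)
        assert curve.detected[0] == 1
        assert (curve.detected == 1).all()

    def test_two_species_detected_in_first_bin(self):
        # 20 reads consumed in one bin of 20 necessarily include all
        # 10 reads of each species, whatever the shuffle
        curve = eb.saturation_curve(single_sample([10, 10]),
                                    bin_size=20, threshold=10, seed=123)
        assert curve.detected[0] == 2

    def test_monotone_and_bounded_with_correct_plateau(self, sim_pool):
        table, _ = eb.simulate_counts(
            sim_pool, eb.BiasSpec.tgirt_like(seed=30, depth=50_000))
        curve = eb.saturation_curve(table, seed=1)
        assert (np.diff(curve.detected) >= 0).all()
        assert curve.plateau() <= len(sim_pool)
        expected_plateau = int((table.values.sum(axis=1) >= 10).sum())
        assert curve.plateau() == expected_plateau

    def test_seed_reproducible(self, sim_pool):
        table, _ = eb.simulate_counts(
            sim_pool, eb.BiasSpec(seed=31, depth=20_000))
        a = eb.saturation_curve(table, seed=9)
        b = eb.saturation_curve(table, seed=9)
        assert (a.detected == b.detected).all()

    def test_truncation_limits_curve(self):
        curve = eb.saturation_curve(single_sample([5000]), bin_size=100,
                                    threshold=10, seed=0, max_reads=1000)
        assert curve.reads[-1] == 1000

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            eb.saturation_curve(single_sample([100]), threshold=0)


class TestAbundanceSummary:
    def test_uniform_pool_hits_expected_cpm(self):
        pool = eb.simulate_pool(n=962, seed=33)
        summary = eb.abundance_summary(uniform_cpm_table(pool),
                                       expected=1e6 / 962)
        assert summary.loc["s1", "median"] == pytest.approx(1039.5, abs=0.05)
        assert summary.loc["s1", "median_deviation"] == pytest.approx(0.0)

    def test_median_deviation_permutation_invariant(self):
        t = single_sample([5, 1, 9, 3, 2])
        s1 = eb.abundance_summary(eb.cpm(t), expected=2e5)
        perm = eb.CountTable(t.values.sample(frac=1, random_state=0))
        s2 = eb.abundance_summary(eb.cpm(perm), expected=2e5)
        assert s1.loc["s1", "median_deviation"] == \
            pytest.approx(s2.loc["s1", "median_deviation"])

    def test_quartiles_match_sort_based_oracle(self):
        values = [10.0, 40.0, 20.0, 70.0, 30.0, 60.0, 50.0]
        ab = eb.AbundanceTable(
            pd.DataFrame({"s1": values}), scale="cpm_corrected")
        summary = eb.abundance_summary(ab, expected=40.0)
        x = sorted(values)

        def interp(p):
            h = (len(x) - 1) * p
            lo = int(np.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])

        assert summary.loc["s1", "q1"] == pytest.approx(interp(0.25))
        assert summary.loc["s1", "median"] == pytest.approx(interp(0.5))
        assert summary.loc["s1", "q3"] == pytest.approx(interp(0.75))
        assert summary.loc["s1", "ci95_low"] == pytest.approx(interp(0.025))


class TestReplicateCorrelation:
    def test_duplicated_column_perfect_rho(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        corr = eb.replicate_correlation(eb.CountTable(df))
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_rank_reversed_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                           "b": [9.0, 7.0, 5.0, 2.0]})
        corr = eb.replicate_correlation(eb.CountTable(df))
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_brute_force_spearman(self):
        a = [3.0, 1.0, 4.0, 1.5, 5.0]
        b = [2.0, 0.5, 6.0, 1.0, 4.0]
        corr = eb.replicate_correlation(
            eb.CountTable(pd.DataFrame({"a": a, "b": b})))
        ra = pd.Series(a).rank()
        rb = pd.Series(b).rank()
        d2 = ((ra - rb) ** 2).sum()
        rho = 1 - 6 * d2 / (5 * (25 - 1))
        assert corr.loc["a", "b"] == pytest.approx(rho)

    def test_constant_column_warns_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning):
            corr = eb.replicate_correlation(eb.CountTable(df))
        assert np.isnan(corr.loc["a", "b"])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            eb.replicate_correlation(single_sample([1, 2]))


class TestSequenceFactors:
    def test_basic_columns(self):
        pool = eb.ReferencePool(entries=[("gc", "GGCCGGCC"),
                                         ("at", "AATTAATTAA")])
        f = eb.sequence_factors(pool, adapter_seq="GATCGGAAGA")
        assert f.loc["gc", "gc"] == pytest.approx(1.0)
        assert f.loc["at", "length"] == 10
        assert set(f.columns) == {"length", "gc", "self_fold", "co_fold",
                                  "free_5p", "free_3p"}
        assert np.isfinite(f["co_fold"]).all()
        assert (f["free_5p"] <= f["length"]).all()

    def test_unstructured_sequence_scores_zero(self):
        pool = eb.ReferencePool(entries=[("a", "AAAAAAA")])
        f = eb.sequence_factors(pool)
        assert f.loc["a", "self_fold"] == 0.0
        assert np.isnan(f.loc["a", "co_fold"])

    def test_pluggable_provider(self):
        class Stub:
            def self_fold(self, seq):
                from endbias.fold import SelfFoldResult
                return SelfFoldResult(pairs=-7, pairing=[], free_5p=0,
                                      free_3p=0)

            def duplex_score(self, a, b):
                return -3.5

        pool = eb.ReferencePool(entries=[("x", "ACGTAC")])
        f = eb.sequence_factors(pool, adapter_seq="ACGTAC", provider=Stub())
        assert f.loc["x", "self_fold"] == -7.0
        assert f.loc["x", "co_fold"] == -3.5


def exact_ranksum_p(group, rest):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = np.concatenate([group, rest])
    m = len(group)

    def u_stat(idx):
        g = pooled[list(idx)]
        r = np.delete(pooled, list(idx))
        return sum((gi > r).sum() + 0.5 * (gi == r).sum() for gi in g)

    u_obs = u_stat(range(m))
    us = np.array([u_stat(c)
                   for c in combinations(range(len(pooled)), m)])
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestOutlierFactorTest:
    def make_factors(self, over, under, rest, col="length"):
        idx = ([f"o{i}" for i in range(len(over))]
               + [f"u{i}" for i in range(len(under))]
               + [f"n{i}" for i in range(len(rest))])
        f = pd.DataFrame({col: list(over) + list(under) + list(rest)},
                         index=idx)
        labels = manual_labels([f"o{i}" for i in range(len(over))],
                               [f"u{i}" for i in range(len(under))],
                               [f"n{i}" for i in range(len(rest))])
        return f, labels

    def test_exchangeable_groups_not_significant(self):
        # over group interleaves the rest symmetrically: U == mn/2
        f, labels = self.make_factors(over=[2, 5, 8],
                                      under=[1, 3, 4],
                                      rest=[6, 7, 9])
        p = eb.outlier_factor_test(f, labels)
        assert p.loc["length", "over_vs_rest"] >= 0.9

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        f, labels = self.make_factors(over=rng.normal(10, 1, 8),
                                      under=rng.normal(0, 1, 8),
                                      rest=rng.normal(0, 1, 30))
        p = eb.outlier_factor_test(f, labels)
        assert p.loc["length", "over_vs_rest"] < 0.01

    def test_matches_exact_enumeration_for_small_groups(self):
        rng = np.random.default_rng(7)
        group = rng.normal(0.6, 1, 4)
        rest = rng.normal(0, 1, 8)
        assert _rank_sum(group, rest) == \
            pytest.approx(exact_ranksum_p(group, rest))

    def test_covers_all_six_factors_and_both_contrasts(self, sim_pool):
        factors = eb.sequence_factors(sim_pool, adapter_seq="GATCGGAAGAGC")
        table, _ = eb.simulate_counts(
            sim_pool, eb.BiasSpec.tgirt_like(seed=40, depth=500_000))
        errors = eb.measurement_errors(eb.cpm(table), 1e6 / len(sim_pool))
        labels = eb.classify_representation(errors, threshold_sd=2.0)
        p = eb.outlier_factor_test(factors, labels)
        assert list(p.index) == ["length", "gc", "self_fold", "co_fold",
                                 "free_5p", "free_3p"]
        assert list(p.columns) == ["over_vs_rest", "under_vs_rest"]
        assert ((p.to_numpy() >= 0) & (p.to_numpy() <= 1)).all()

    def test_empty_group_rejected(self):
        f, labels = self.make_factors(over=[], under=[1.0], rest=[2.0, 3.0])
        with pytest.raises(ValueError):
            eb.outlier_factor_test(f, labels)


class TestLengthAbundanceFit:
    def test_exact_line_recovered(self):
        pool = eb.ReferencePool(entries=[
            ("l19", "A" * 19), ("l21", "C" * 21), ("l23", "G" * 23),
            ("l25", "T" * 25)])
        lengths = np.array([19, 21, 23, 25])
        v = 10 ** (0.09 * lengths + 0.9) - 0.5
        ab = eb.AbundanceTable(pd.DataFrame({"s1": v}, index=pool.ids),
                               scale="cpm_corrected")
        fit = eb.length_abundance_fit(ab, pool)
        assert fit.slope == pytest.approx(0.09, abs=1e-9)
        assert fit.intercept == pytest.approx(0.9, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_length_independent_abundances(self, sim_pool):
        table, _ = eb.simulate_counts(
            sim_pool, eb.BiasSpec(seed=50, depth=1_000_000))
        fit = eb.length_abundance_fit(eb.cpm(table), sim_pool)
        assert fit.slope == pytest.approx(0.0, abs=0.01)
        assert fit.r_squared < 0.05

    def test_simulated_length_slope_recovered(self):
        pool = eb.simulate_pool(n=300, seed=51)
        spec = eb.BiasSpec(length_slope=0.09, seed=51, depth=10_000_000)
        table, _ = eb.simulate_counts(pool, spec)
        fit = eb.length_abundance_fit(eb.cpm(table), pool)
        assert fit.slope == pytest.approx(0.09, abs=0.01)

    def test_single_length_rejected(self):
        pool = eb.ReferencePool(entries=[("a", "A" * 20), ("b", "C" * 20),
                                         ("c", "G" * 20)])
        ab = eb.AbundanceTable(
            pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=pool.ids),
            scale="cpm_corrected")
        with pytest.raises(ValueError):
            eb.length_abundance_fit(ab, pool)
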