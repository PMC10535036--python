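import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabolodiv.diversity import (
    AnovaResult,
    IncidenceCounts,
    SACurve,
    anova_tukey,
    asymptote_summary,
    broken_stick_proportions,
    chao1,
    correlate_richness_diversity,
    jackknife,
    pielou,
    rank_abundance_fit,
    shannon,
    species_accumulation,
)
from metabolodiv.feature_io import PresenceMatrix, binarize

from conftest import make_table, simple_metas

positive_abundances = st.lists(
    st.floats(0.01, 1e6, allow_nan=False), min_size=1, max_size=30
)


class TestShannonPielou:
    @pytest.mark.parametrize(
        "abundances,expected",
        [
            ([1, 1, 1, 1], math.log(4)),
            ([5], 0.0),
            ([2, 1, 1], 1.039721),  # -sum p ln p with p = (.5, .25, .25)
        ],
    )
    def test_hand_worked_values(self, abundances, expected):
        assert shannon(abundances) == pytest.approx(expected, abs=1e-6)

    def test_zeros_dropped(self):
        assert shannon([2, 0, 1, 0, 1]) == pytest.approx(shannon([2, 1, 1]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    @pytest.mark.parametrize(
        "h,s,expected",
        [(math.log(4), 4, 1.0), (1.039721, 3, 0.946395)],
    )
    def test_pielou_values(self, h, s, expected):
        assert pielou(h, s) == pytest.approx(expected, abs=1e-6)

    def test_pielou_single_species_undefined(self):
        assert math.isnan(pielou(0.0, 1))

    def test_pielou_invalid_richness(self):
        with pytest.raises(ValueError):
            pielou(1.0, 0)

    @given(positive_abundances)
    @settings(max_examples=100, deadline=None)
    def test_entropy_bounds_and_evenness(self, abundances):
        """0 <= H' <= ln S, with equality at ln S iff uniform; J' in [0, 1]."""
        h = shannon(abundances)
        s = sum(1 for a in abundances if a > 0)
        assert -1e-9 <= h <= math.log(s) + 1e-9
        if s > 1:
            assert 0.0 <= pielou(h, s) <= 1.0 + 1e-9
        uniform = shannon([3.7] * max(s, 1))
        assert uniform == pytest.approx(math.log(max(s, 1)), abs=1e-9)


class TestRichnessEstimators:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (IncidenceCounts(10, 3, 1, 5), 14.5),
            (IncidenceCounts(10, 0, 4, 5), 10.0),
            (IncidenceCounts(8, 2, 0, 5), 9.0),  # bias-corrected branch
        ],
    )
    def test_chao1_values(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts,order,expected",
        [
            (IncidenceCounts(10, 3, 1, 5), 1, 12.4),
            (IncidenceCounts(10, 3, 1, 5), 2, 13.75),
            (IncidenceCounts(10, 0, 0, 5), 1, 10.0),
        ],
    )
    def test_jackknife_values(self, counts, order, expected):
        assert jackknife(counts, order) == pytest.approx(expected)

    def test_jackknife_contract_errors(self):
        with pytest.raises(ValueError):
            jackknife(IncidenceCounts(5, 1, 0, 1), 1)
        with pytest.raises(ValueError):
            jackknife(IncidenceCounts(5, 1, 0, 5), 3)

    @given(
        s=st.integers(1, 50),
        q1=st.integers(0, 20),
        q2=st.integers(0, 20),
        m=st.integers(2, 12),
    )
    @settings(max_examples=100, deadline=None)
    def test_estimators_never_below_observed(self, s, q1, q2, m):
        if q1 + q2 > s:
            return
        c = IncidenceCounts(s, q1, q2, m)
        assert chao1(c) >= s
        assert jackknife(c, 1) >= s
        # order 2 can dip below jack1 but never below S_obs for m >= 2
        assert jackknife(c, 2) >= s - q2  # loose algebraic floor
        if q2 == 0:
            assert jackknife(c, 2) >= s

    def test_chao1_matches_independent_implementation(self):
        """Cross-check against scikit-bio on abundance-as-incidence counts."""
        skbio = pytest.importorskip("skbio.diversity.alpha")
        # counts vector with 3 singletons, 2 doubletons, 5 others
        counts = [1, 1, 1, 2, 2, 5, 7, 9, 4, 3]
        ours = chao1(IncidenceCounts(10, 3, 2, 5))
        assert ours == pytest.approx(float(skbio.chao1(counts, bias_corrected=False)))


class TestSpeciesAccumulation:
    def test_saturated_matrix_constant_curve(self):
        t = make_table(np.ones((4, 3)), simple_metas(3))
        c = species_accumulation(binarize(t), n_permutations=10, seed=0)
        assert np.allclose(c.mean_richness, 4.0)

    def test_full_accumulation_equals_observed_richness(self):
        rng = np.random.default_rng(5)
        t = make_table(rng.integers(0, 2, (12, 5)).astype(float), simple_metas(5))
        p = binarize(t)
        s_obs = int((p.incidence() >= 1).sum())
        for method in ("permutation", "exact"):
            c = species_accumulation(p, n_permutations=20, seed=1, method=method)
            assert c.mean_richness[-1] == pytest.approx(s_obs)

    def test_permutation_mean_equals_exhaustive_enumeration(self):
        """3-sample toy: compare against brute force over all 6 orderings."""
        mat = np.array(
            [[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=bool
        )
        t = make_table(mat.astype(float), simple_metas(3))
        p = binarize(t)
        # oracle: enumerate every ordering of the 3 samples
        expect = np.zeros(3)
        orders = list(itertools.permutations(range(3)))
        for order in orders:
            seen = np.zeros(mat.shape[0], dtype=bool)
            for k, j in enumerate(order):
                seen |= mat[:, j]
                expect[k] += seen.sum()
        expect /= len(orders)
        exact = species_accumulation(p, method="exact")
        assert np.allclose(exact.mean_richness, expect)
        perm = species_accumulation(p, n_permutations=4000, seed=2)
        assert np.allclose(perm.mean_richness, expect, atol=0.05)

    def test_empty_matrix_rejected(self):
        import pandas as pd

        empty = PresenceMatrix(pd.DataFrame(), pd.DataFrame(), 0.0)
        with pytest.raises(ValueError):
            species_accumulation(empty)


class TestAsymptoteSummary:
    @pytest.mark.parametrize(
        "asym,total,pct",
        [
            (1172, 3407, 34.39),
            (100, 100, 100.0),
            (848, 4521, 18.75),  # truncated, not rounded half-up
        ],
    )
    def test_common_feature_percentages(self, asym, total, pct):
        assert asymptote_summary(asym, total)["common_fraction_pct"] == pytest.approx(pct)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            asymptote_summary(10, 0)


class TestRankAbundance:
    def test_broken_stick_two_species(self):
        assert broken_stick_proportions(2) == pytest.approx([0.75, 0.25])

    def test_single_species(self):
        fit = rank_abundance_fit([5.0], "broken_stick")
        assert fit.fitted_proportions == pytest.approx([1.0])

    def test_perfect_fit_zero_deviance(self):
        props = broken_stick_proportions(6)
        fit = rank_abundance_fit(props * 1000, "broken_stick")
        assert fit.deviance == pytest.approx(0.0, abs=1e-9)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="broken_stick"):
            rank_abundance_fit([1, 2], "zipf")

    def test_broken_stick_proportions_sum_to_one(self):
        for s in (1, 2, 7, 40):
            assert broken_stick_proportions(s).sum() == pytest.approx(1.0)

    def test_alternative_models_fit_their_own_shape_better(self):
        rng = np.random.default_rng(0)
        geom = 200.0 * 0.6 ** np.arange(12)
        dev = {m: rank_abundance_fit(geom, m).deviance for m in ("broken_stick", "preemption")}
        assert dev["preemption"] < dev["broken_stick"]


class TestCorrelation:
    def test_exact_linearity(self):
        c = correlate_richness_diversity([1, 2, 3], [3, 5, 7])
        assert c.r == pytest.approx(1.0) and c.R2 == pytest.approx(100.0)

    def test_anticorrelation(self):
        assert correlate_richness_diversity([1, 2, 3], [-1, -2, -3]).r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        c = correlate_richness_diversity([1, 2, 3, 4], [2, 1, 4, 3])
        assert c.r == pytest.approx(0.6) and c.R2 == pytest.approx(36.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate_richness_diversity([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=15),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_r2_identity(self, xs, rnd):
        ys = [x + rnd.random() for x in xs]
        if np.std(xs) == 0 or np.std(ys) == 0:
            return
        c = correlate_richness_diversity(xs, ys)
        assert c.R2 == pytest.approx(100.0 * c.r**2)
        assert abs(c.r) <= 1 + 1e-12


class TestAnovaTukey:
    def test_identical_groups_share_letter(self):
        res = anova_tukey([1, 2, 3, 1, 2, 3], ["g1"] * 3 + ["g2"] * 3)
        assert res.F == pytest.approx(0.0)
        assert res.tukey_letters["g1"] == res.tukey_letters["g2"]

    def test_hand_computed_f(self):
        # groups {1,2} and {3,4}: SSB = 4 (df 1), SSW = 1 (df 2) -> F = 8
        res = anova_tukey([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.F == pytest.approx(8.0)

    def test_distinct_letter_for_shifted_group(self):
        vals = [0, 0.1, 0, 0.1, 10, 10.1]
        groups = ["g1", "g1", "g2", "g2", "g3", "g3"]
        res = anova_tukey(vals, groups, alpha=0.05)
        assert set(res.tukey_letters["g3"]).isdisjoint(res.tukey_letters["g1"])
        assert set(res.tukey_letters["g3"]).isdisjoint(res.tukey_letters["g2"])
        assert set(res.tukey_letters["g1"]) & set(res.tukey_letters["g2"])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([1, 2, 3], ["a", "a", "b"])

    def test_f_matches_scipy_on_random_data(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        res = anova_tukey(vals, groups)
        f, p = stats.f_oneway(vals[:10], vals[10:20], vals[20:])
        assert res.F == pytest.approx(float(f)) and res.p_value == pytest.approx(float(p))
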