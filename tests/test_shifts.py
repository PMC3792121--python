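"""STARS, PCA indices, chronological clustering, traffic lights, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from enashift import (
    CcConfig,
    StarsConfig,
    anomaly,
    chronological_clustering,
    coefficient_of_variation,
    make_block_series,
    pca_index,
    stars,
    stars_on_scores,
    traffic_light,
)


class TestStars:
    def test_constant_series_has_no_shift(self):
        r = stars(np.full(30, 3.7))
        assert r.shift_years == []
        assert len(r.regime_means) == 1

    def test_planted_step_flagged_at_step_year(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(15), np.full(15, 10.0)]) + rng.normal(0, 0.1, 30)
        r = stars(x, StarsConfig(alpha=0.05, cutoff=5, huber=3.0))
        assert r.shift_years == [15]
        assert r.rsi[15] > 0
        assert not r.end_truncated[0]
        # independent check: the step is where adjacent 5-year windows differ
        t, _ = sps.ttest_ind(x[10:15], x[15:20])
        assert abs(t) > sps.t.ppf(0.975, 8)

    def test_regime_means_bracket_the_step(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([np.zeros(15), np.full(15, 10.0)]) + rng.normal(0, 0.1, 30)
        r = stars(x)
        assert r.regime_means[0] == pytest.approx(0.0, abs=0.2)
        assert r.regime_means[-1] == pytest.approx(10.0, abs=0.2)

    def test_late_shift_is_flagged_truncated(self):
        x = np.concatenate([np.zeros(28), np.full(2, 50.0)])
        r = stars(x, StarsConfig(cutoff=5))
        assert r.shift_years == [28]
        assert r.end_truncated == [True]
        assert r.confirmed_years == []

    def test_series_shorter_than_two_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            stars(np.zeros(9), StarsConfig(cutoff=5))

    def test_year_index_carried_through(self):
        years = np.arange(1974, 2004)
        x = pd.Series(np.concatenate([np.zeros(15), np.full(15, 8.0)]), index=years)
        r = stars(x)
        assert r.shift_years == [1989]
        assert r.regime_bounds[0] == (1974, 1988)


class TestPca:
    def test_perfectly_correlated_pair_loads_on_pc1(self):
        x = np.linspace(1, 5, 12)
        m = pd.DataFrame({"a": x, "b": 2 * x}, index=range(12))
        p = pca_index(m, transform=False)
        assert p.variance_explained[0] == pytest.approx(100.0)

    def test_two_variable_loadings_match_closed_form(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(2.0, 0.5, size=(40, 2)), columns=["a", "b"])
        p = pca_index(m, transform=False)
        # correlation-matrix eigenvectors of a 2x2 are (1,1)/sqrt2, (1,-1)/sqrt2
        np.testing.assert_allclose(np.abs(p.loadings.to_numpy()),
                                   1 / np.sqrt(2), atol=1e-9)
        r = np.corrcoef(m["a"], m["b"])[0, 1]
        assert p.variance_explained[0] == pytest.approx(100 * (1 + abs(r)) / 2)

    def test_scores_are_centred_and_sign_deterministic(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.lognormal(0, 1, (20, 4)), columns=list("abcd"))
        p = pca_index(m)
        np.testing.assert_allclose(p.scores.mean(axis=0), 0.0, atol=1e-9)
        for c in p.loadings.columns:
            imax = p.loadings[c].abs().idxmax()
            assert p.loadings.loc[imax, c] > 0
        assert np.all(np.diff(p.variance_explained) <= 1e-9)

    def test_zero_variance_variable_named_in_error(self):
        m = pd.DataFrame({"a": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            pca_index(m)

    def test_duplicated_variable_does_not_move_score_shifts(self):
        rng = np.random.default_rng(4)
        base = np.concatenate([np.zeros(15), np.full(18, 5.0)])
        m = pd.DataFrame({f"v{i}": base + rng.normal(0, 0.5, 33) for i in range(3)},
                         index=range(1974, 2007))
        m2 = m.copy()
        m2["v0_dup"] = m["v0"]
        y1 = stars_on_scores(pca_index(m), 1).shift_years
        y2 = stars_on_scores(pca_index(m2), 1).shift_years
        assert y1 == y2 == [1989]

    def test_negative_anomalies_use_signed_transform(self):
        m = pd.DataFrame({"a": np.linspace(-3, 3, 12), "b": np.linspace(4, -2, 12)})
        p = pca_index(m, transform=True)  # must not raise on negatives
        assert np.isfinite(p.scores.to_numpy()).all()


class TestChronologicalClustering:
    def test_separated_blocks_yield_single_junction_boundary(self):
        m = make_block_series(10, 10, mean_shift=10.0, noise_sd=1.0, seed=0)
        p = chronological_clustering(m, CcConfig(seed=0))
        assert p.boundary_years == [1984]
        assert p.segments == [(1974, 1983), (1984, 1993)]

    def test_homogeneous_noise_stays_one_segment(self):
        m = make_block_series(10, 10, mean_shift=0.0, noise_sd=1.0, seed=1)
        p = chronological_clustering(m, CcConfig(seed=1))
        assert p.boundary_years == []

    def test_deterministic_given_seed(self):
        m = make_block_series(8, 8, mean_shift=3.0, noise_sd=1.0, seed=2)
        p1 = chronological_clustering(m, CcConfig(seed=9))
        p2 = chronological_clustering(m, CcConfig(seed=9))
        assert p1.segments == p2.segments and p1.p_values == p2.p_values

    def test_short_series_rejected(self):
        m = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="4 years"):
            chronological_clustering(m)

    def test_segments_cover_years_contiguously(self):
        m = make_block_series(12, 9, mean_shift=6.0, noise_sd=1.0, seed=5)
        p = chronological_clustering(m, CcConfig(seed=5))
        covered = [y for s, e in p.segments for y in range(s, e + 1)]
        assert covered == list(m.index)


class TestTrafficLight:
    def test_monotone_series_fills_quintiles_in_order(self):
        m = pd.DataFrame({"up": np.arange(10.0)})
        t = traffic_light(m)
        assert list(t.categories.loc["up"]) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_reversed_series_reverses_bins(self):
        m = pd.DataFrame({"down": np.arange(10.0)[::-1]})
        t = traffic_light(m)
        assert list(t.categories.loc["down"]) == [5, 5, 4, 4, 3, 3, 2, 2, 1, 1]

    def test_bins_match_rank_quantile_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=33)
        t = traffic_light(pd.DataFrame({"v": x}))
        oracle = np.ceil(5 * sps.rankdata(x, method="min") / 33).astype(int)
        assert list(t.categories.loc["v"]) == list(oracle)

    def test_constant_variable_gets_middle_bin_with_warning(self):
        m = pd.DataFrame({"flat": np.ones(10), "up": np.arange(10.0)})
        with pytest.warns(UserWarning, match="flat"):
            t = traffic_light(m)
        assert set(t.categories.loc["flat"]) == {3}

    def test_rows_sorted_by_ordering_descending(self):
        m = pd.DataFrame({"a": np.arange(8.0), "b": np.arange(8.0) ** 2,
                          "c": -np.arange(8.0)})
        t = traffic_light(m, ordering={"a": 0.2, "b": 0.9, "c": -0.5})
        assert t.order == ["b", "a", "c"]

    @given(st.integers(5, 40), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_quintile_counts_differ_by_at_most_one_without_ties(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        t = traffic_light(pd.DataFrame({"v": x}))
        counts = t.categories.loc["v"].value_counts().reindex(range(1, 6), fill_value=0)
        assert counts.max() - counts.min() <= 1


class TestRegimeSummaries:
    def test_cv_examples(self):
        s = pd.Series([1.0, 3.0], index=[2000, 2001])
        cv = coefficient_of_variation(s, [(2000, 2001)])
        assert cv[(2000, 2001)] == pytest.approx(np.sqrt(2) / 2)
        const = pd.Series(np.full(5, 4.0), index=range(5))
        assert coefficient_of_variation(const, [(0, 4)])[(0, 4)] == 0.0

    @given(st.floats(0.1, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_cv_invariant_under_positive_rescaling(self, scale):
        s = pd.Series([2.0, 3.5, 1.2, 4.4], index=range(4))
        a = coefficient_of_variation(s, [(0, 3)])[(0, 3)]
        b = coefficient_of_variation(scale * s, [(0, 3)])[(0, 3)]
        assert a == pytest.approx(b)

    def test_cv_zero_mean_is_missing(self):
        s = pd.Series([-1.0, 1.0], index=[0, 1])
        assert np.isnan(coefficient_of_variation(s, [(0, 1)])[(0, 1)])

    def test_cv_period_outside_span_rejected(self):
        s = pd.Series([1.0, 2.0], index=[2000, 2001])
        with pytest.raises(ValueError, match="outside"):
            coefficient_of_variation(s, [(1999, 2001)])

    def test_anomaly_modes(self):
        s = pd.Series([2.0, 5.0, 8.0], index=[1, 2, 3])
        init = anomaly(s, "initial")
        assert init.iloc[0] == 0.0
        mean = anomaly(s, "mean")
        assert mean.sum() == pytest.approx(0.0)
        np.testing.assert_allclose(np.diff(init), np.diff(s))  # linear stays linear
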