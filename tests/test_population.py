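import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import wilcoxon_enumeration_p
from stimchoice import (
    confidence_ellipse,
    normalize_effects,
    paired_tests,
    range_bias,
    rectify_effect,
    remove_outliers,
    wilcoxon_signed_rank,
)
from stimchoice.population import condition_effects, population_panels


class TestWilcoxon:
    def test_six_negative_differences_exact_p(self):
        res = wilcoxon_signed_rank(np.array([-1.0, -2.0, -0.5, -3.0, -1.5, -2.5]))
        assert res.p_value == pytest.approx(0.03125)
        assert res.exact

    def test_antisymmetric_differences_near_one(self):
        res = wilcoxon_signed_rank(np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0]))
        assert res.p_value >= 0.99

    def test_matches_enumeration_oracle_n8(self, rng):
        for _ in range(20):
            d = rng.normal(size=8)
            assert wilcoxon_signed_rank(d).p_value == pytest.approx(
                wilcoxon_enumeration_p(d), abs=1e-12
            )

    def test_matches_enumeration_with_ties(self, rng):
        for _ in range(20):
            d = rng.integers(-4, 5, size=9).astype(float)
            assert wilcoxon_signed_rank(d).p_value == pytest.approx(
                wilcoxon_enumeration_p(d), abs=1e-12
            )

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False).filter(
                lambda v: abs(v) > 1e-6
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_property_matches_enumeration(self, diffs):
        d = np.array(diffs)
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            wilcoxon_enumeration_p(d), abs=1e-12
        )

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank(np.zeros(8))
        assert res.p_value == 1.0
        assert res.degenerate

    def test_normal_approximation_close_to_exact(self, rng):
        # Straddle the exact/approximate switch at n=26 vs n=25.
        d = rng.normal(loc=0.3, size=26)
        approx = wilcoxon_signed_rank(d, exact_threshold=25).p_value
        exact = wilcoxon_signed_rank(d, exact_threshold=40).p_value
        assert approx == pytest.approx(exact, abs=0.01)

    def test_scipy_agreement_no_ties(self, rng):
        d = rng.normal(size=15)
        mine = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, method="exact", alternative="two-sided")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestPairedTests:
    def test_mean_difference_and_p_values(self, rng):
        off = rng.normal(size=30)
        on = off + 0.5 + rng.normal(scale=0.3, size=30)
        res = paired_tests(off, on)
        assert res.mean_diff == pytest.approx((on - off).mean())
        assert res.p_wilcoxon < 0.01
        assert res.p_ttest < 0.01

    def test_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            paired_tests(np.zeros(6), np.zeros(5))

    def test_rank_sum_variant(self, rng):
        off = rng.normal(size=20)
        on = off + 2.0
        res = paired_tests(off, on, variant="rank_sum")
        assert res.p_wilcoxon < 0.01


class TestRemoveOutliers:
    def test_worked_21_point_example(self):
        pts = np.zeros((21, 2))
        pts[0] = (10.0, 10.0)
        kept, removed, info = remove_outliers(pts, k=3.0)
        # z = (10 - 10/21) / 2.182 = 4.36 > 3 on both axes.
        mean = 10 / 21
        sd = math.sqrt((20 * mean**2 + (10 - mean) ** 2) / 20)
        assert (10 - mean) / sd > 3
        assert len(removed) == 1 and tuple(removed[0]) == (10.0, 10.0)
        assert len(kept) == 20

    def test_single_axis_excursion_removed(self, rng):
        pts = rng.normal(size=(30, 2)) * 0.5
        pts[3, 1] = 40.0  # >3 SD on y only
        _, removed, _ = remove_outliers(pts)
        assert any(row[1] == 40.0 for row in removed)

    def test_identical_points_none_removed(self):
        pts = np.ones((10, 2))
        kept, removed, info = remove_outliers(pts)
        assert len(removed) == 0
        assert info["zero_sd_axes"] == [0, 1]

    def test_statistics_computed_once_not_iterated(self):
        # After removing the big outlier the next point is >3 SD of the
        # remainder; a single-pass rule must keep it.
        pts = np.zeros((40, 2))
        pts[0] = (100.0, 0.0)
        pts[1] = (10.0, 0.0)
        kept, removed, _ = remove_outliers(pts)
        assert len(removed) == 1
        assert tuple(removed[0]) == (100.0, 0.0)

    def test_standard_normal_clouds_rarely_trimmed(self, rng):
        # Monte-Carlo truth for this rule on N(0,1)^2 clouds of n=50 is
        # ~0.84 zero-removal probability; assert a stable lower bound.
        zero = 0
        for _ in range(300):
            _, removed, _ = remove_outliers(rng.standard_normal((50, 2)))
            zero += len(removed) == 0
        assert zero / 300 >= 0.80


class TestConfidenceEllipse:
    def test_identity_covariance_radius(self):
        r = math.sqrt(2)
        pts = np.array([(r, 0.0), (-r, 0.0), (0.0, r), (0.0, -r), (0.0, 0.0)])
        assert np.allclose(np.cov(pts.T, ddof=1), np.eye(2))
        ell = confidence_ellipse(pts, level=0.90)
        assert ell.semi_axes[0] == pytest.approx(math.sqrt(4.605170), abs=1e-4)
        assert ell.semi_axes[1] == pytest.approx(2.1460, abs=1e-3)

    def test_rotation_equivariance(self, rng):
        pts = rng.normal(size=(200, 2)) @ np.array([[2.0, 0.3], [0.0, 0.7]])
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        e1 = confidence_ellipse(pts)
        e2 = confidence_ellipse(pts @ rot.T)
        assert e2.semi_axes == pytest.approx(e1.semi_axes, rel=1e-9)
        np.testing.assert_allclose(rot @ np.array(e1.center), e2.center, atol=1e-9)
        diff = (e2.angle - e1.angle - theta) % math.pi
        assert min(diff, math.pi - diff) < 1e-9

    def test_monte_carlo_coverage(self, rng):
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        pts = rng.multivariate_normal([1.0, -2.0], cov, size=40_000)
        ell = confidence_ellipse(pts, level=0.90)
        # Fraction of points inside the ellipse boundary.
        sample_cov = np.cov(pts.T, ddof=1)
        inv = np.linalg.inv(sample_cov)
        centered = pts - pts.mean(axis=0)
        d2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
        coverage = (d2 <= stats.chi2.ppf(0.90, 2)).mean()
        assert abs(coverage - 0.90) < 0.02
        assert ell.semi_axes[0] >= ell.semi_axes[1] >= 0

    def test_singular_covariance_rejected(self):
        pts = np.array([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
        with pytest.raises(ValueError, match="singular"):
            confidence_ellipse(pts)


class TestRectify:
    def test_choice_variability_sign(self):
        assert rectify_effect(-0.5, "choice_variability", "offer1") == 0.5
        assert rectify_effect(-0.5, "choice_variability", "offer2") == 0.5

    def test_order_bias_flips_only_offer2(self):
        assert rectify_effect(-0.3, "order_bias", "offer2") == pytest.approx(0.3)
        assert rectify_effect(-0.3, "order_bias", "offer1") == pytest.approx(-0.3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            rectify_effect(0.1, "nonsense", "offer1")


class TestRangeBias:
    def test_collinear_gives_r_one(self):
        dv = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = range_bias(0.5 * dv, dv, outlier_k=None)
        assert res["r"] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            range_bias(np.r_[0.1, 0.2, 0.3, 0.4], np.ones(4), outlier_k=None)

    def test_null_r_small(self, rng):
        res = range_bias(rng.normal(size=200), rng.normal(size=200))
        assert abs(res["r"]) < 0.2


class TestNormalize:
    def test_simple_division(self):
        out = normalize_effects(pd.Series([4.0, 2.0, 1.0]))
        assert out.tolist() == [1.0, 0.5, 0.25]

    def test_unique_max_maps_to_one(self, rng):
        vals = rng.normal(size=8)
        vals[3] = vals.max() + 1.0
        out = normalize_effects(pd.Series(vals))
        assert out.iloc[3] == 1.0
        assert (out <= 1.0).all()

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=2,
            max_size=8,
        ).filter(lambda v: max(v) > 1e-6)
    )
    def test_idempotence(self, vals):
        once = normalize_effects(pd.Series(vals))
        twice = normalize_effects(once)
        assert np.allclose(once, twice)

    def test_all_nonpositive_skipped_with_error(self):
        with pytest.raises(ValueError, match="nonpositive"):
            normalize_effects(pd.Series([-1.0, -2.0, 0.0]))


def _fake_deltas(rng, effects=None):
    """Synthetic per-session delta table over 2 windows x 4 levels."""
    effects = effects or {}
    rows = []
    for window in ("offer1", "offer2"):
        for level in ("15uA", "25uA", "50uA", "125uA"):
            shift = effects.get((window, level), 0.0)
            for s in range(12):
                dv = rng.normal(scale=2.0)
                rows.append(
                    {
                        "session_id": f"{window}.{level}.s{s}",
                        "window": window,
                        "level": level,
                        "delta_eta": rng.normal(scale=0.3) - shift,
                        "delta_epsilon": rng.normal(scale=0.1),
                        "delta_rho": rng.normal(scale=0.2),
                        "dV": dv,
                        "rho_off": 2.0 + rng.normal(scale=0.1),
                        "rho_on": 2.0 + rng.normal(scale=0.1),
                        "eta_off": 2.5 + rng.normal(scale=0.2),
                        "eta_on": 2.5 + rng.normal(scale=0.2) - shift,
                        "epsilon_off": rng.normal(scale=0.1),
                        "epsilon_on": rng.normal(scale=0.1),
                    }
                )
    return pd.DataFrame(rows)


class TestConditionEffects:
    def test_normalized_max_is_one_per_family(self, rng):
        table = condition_effects(_fake_deltas(rng, {("offer2", "15uA"): 1.0}))
        for effect, grp in table.groupby("effect"):
            if grp["normalized"].notna().any():
                assert grp["normalized"].max() == pytest.approx(1.0)

    def test_rectification_applied_before_averaging(self, rng):
        deltas = _fake_deltas(rng)
        table = condition_effects(deltas)
        row = table[
            (table["effect"] == "choice_variability")
            & (table["window"] == "offer1")
            & (table["level"] == "25uA")
        ].iloc[0]
        sub = deltas[(deltas["window"] == "offer1") & (deltas["level"] == "25uA")]
        assert row["value"] == pytest.approx(-sub["delta_eta"].mean())

    def test_range_effect_pools_windows(self, rng):
        table = condition_effects(_fake_deltas(rng))
        rb = table[table["effect"] == "range_bias"]
        assert set(rb["window"]) == {"pooled"}
        assert (rb["n"] >= 20).all()  # 12 sessions per window, minus outliers

    def test_significance_flag_threshold(self, rng):
        table = condition_effects(_fake_deltas(rng, {("offer2", "15uA"): 1.0}))
        hit = table[
            (table["effect"] == "choice_variability")
            & (table["window"] == "offer2")
            & (table["level"] == "15uA")
        ].iloc[0]
        assert hit["p"] < 0.01 and bool(hit["significant"])


class TestPopulationPanels:
    def test_panel_rows_and_ellipse(self, rng):
        panels = population_panels(_fake_deltas(rng))
        assert {"rho", "eta", "epsilon"} <= set(panels["parameter"])
        eta2 = panels[(panels["window"] == "offer2") & (panels["parameter"] == "eta")]
        assert len(eta2) == 1
        assert np.isfinite(eta2.iloc[0]["ellipse_major"])
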