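"""Population-level inference and the cross-condition effect-size table.

Paired nonparametric/parametric session contrasts, 3-SD outlier screening,
bivariate confidence ellipses, effect rectification (choice variability and
order bias), per-level range-bias correlations, and max-normalization of
condition means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EFFECT_KINDS = ("choice_variability", "order_bias")


@dataclass
class WilcoxonResult:
    statistic: float  # sum of positive signed ranks
    p_value: float
    n: int  # nonzero differences used
    n_zero: int
    exact: bool
    degenerate: bool = False  # all differences zero


@dataclass
class PairedTestResult:
    n: int
    mean_diff: float
    p_wilcoxon: float
    p_ttest: float
    wilcoxon: WilcoxonResult


@dataclass
class EllipseSpec:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle: float  # radians, orientation of the major axis
    level: float


def wilcoxon_signed_rank(
    diffs: np.ndarray, exact_threshold: int = 25
) -> WilcoxonResult:
    """Two-tailed one-sample Wilcoxon signed-rank test on differences.

    Zeros are dropped. For n <= ``exact_threshold`` the null distribution of
    the positive-rank sum is enumerated exactly (ties handled via average
    ranks); above it, a normal approximation with tie and continuity
    corrections is used. All differences zero yields p = 1 with a
    degeneracy flag.
    """
    d = np.asarray(diffs, dtype=float)
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_zero, exact=True, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        # Exact null distribution over doubled ranks (integers even with ties).
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        dp = np.zeros(total + 1)
        dp[0] = 1.0
        for r in r2:
            new = dp.copy()
            new[r:] += dp[: total + 1 - r]
            dp = new
        dp /= 2.0**n
        w2 = int(round(2 * w_pos))
        p_le = float(dp[: w2 + 1].sum())
        p_ge = float(dp[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_pos, p, n, n_zero, exact=True)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return WilcoxonResult(w_pos, 1.0, n, n_zero, exact=False, degenerate=True)
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w_pos, p, n, n_zero, exact=False)


def paired_tests(
    values_off: np.ndarray,
    values_on: np.ndarray,
    exact_threshold: int = 25,
    variant: str = "signed_rank",
) -> PairedTestResult:
    """Two-tailed Wilcoxon and paired t test on stimON - stimOFF pairs.

    ``variant='rank_sum'`` substitutes a two-sample rank-sum test for the
    (default) paired signed-rank test.
    """
    off = np.asarray(values_off, dtype=float)
    on = np.asarray(values_on, dtype=float)
    if off.shape != on.shape:
        raise ValueError("paired vectors must have equal length")
    if len(off) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = on - off
    wres = wilcoxon_signed_rank(diffs, exact_threshold=exact_threshold)
    if variant == "rank_sum":
        p_w = float(stats.ranksums(on, off).pvalue)
    elif variant == "signed_rank":
        p_w = wres.p_value
    else:
        raise ValueError(f"unknown Wilcoxon variant {variant!r}")
    if np.allclose(diffs, 0):
        p_t = 1.0
    else:
        p_t = float(stats.ttest_rel(on, off).pvalue)
    return PairedTestResult(
        n=len(off),
        mean_diff=float(diffs.mean()),
        p_wilcoxon=p_w,
        p_ttest=p_t,
        wilcoxon=wres,
    )


def remove_outliers(
    points: np.ndarray, k: float = 3.0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Screen (n, 2) points: drop any farther than k sample SDs from the
    mean on either axis. Means/SDs are computed once on the full set.

    Returns (kept, removed, info); a zero-SD axis removes nothing there.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0, ddof=1)
    zero_sd = sd == 0
    out = np.zeros(len(pts), dtype=bool)
    for ax in range(2):
        if not zero_sd[ax]:
            out |= np.abs(pts[:, ax] - mean[ax]) > k * sd[ax]
    info = {"zero_sd_axes": [int(a) for a in np.flatnonzero(zero_sd)], "n_removed": int(out.sum())}
    return pts[~out], pts[out], info


def confidence_ellipse(points: np.ndarray, level: float = 0.90) -> EllipseSpec:
    """Bivariate confidence ellipse from the sample mean and covariance.

    The boundary sits at Mahalanobis radius sqrt(q) with q the chi-square(2)
    quantile at ``level``.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    cov = np.cov(pts.T, ddof=1)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= 1e-300:
        raise ValueError("singular covariance")
    q = stats.chi2.ppf(level, df=2)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    angle = math.atan2(eigvecs[1, 0], eigvecs[0, 0])
    mean = pts.mean(axis=0)
    return EllipseSpec(
        center=(float(mean[0]), float(mean[1])),
        semi_axes=(float(np.sqrt(eigvals[0] * q)), float(np.sqrt(eigvals[1] * q))),
        angle=angle,
        level=level,
    )


def rectify_effect(delta: float, effect_kind: str, window: str) -> float:
    """Sign effects so the expected stimulation effect is positive.

    choice_variability: Dcv = -(delta eta), any window. order_bias:
    +(delta epsilon) for offer1 sessions, -(delta epsilon) for offer2.
    """
    if effect_kind == "choice_variability":
        return -delta
    if effect_kind == "order_bias":
        if window == "offer1":
            return delta
        if window == "offer2":
            return -delta
        raise ValueError(f"unknown window {window!r}")
    raise ValueError(f"unknown effect kind {effect_kind!r}")


def range_bias(
    delta_rho: np.ndarray, delta_V: np.ndarray, outlier_k: float | None = 3.0
) -> dict:
    """Pearson correlation r(delta rho, delta V) across sessions.

    Applies the k-SD outlier screen to the (delta rho, delta V) pairs first
    (pass ``outlier_k=None`` to skip). Returns r, two-tailed p, and n.
    """
    pts = np.column_stack([np.asarray(delta_rho, float), np.asarray(delta_V, float)])
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(pts) < 3:
        raise ValueError("need at least 3 sessions with finite values")
    n_removed = 0
    if outlier_k is not None:
        pts, removed, _ = remove_outliers(pts, k=outlier_k)
        n_removed = len(removed)
    if np.ptp(pts[:, 1]) == 0:
        raise ValueError("zero variance in delta V")
    if np.ptp(pts[:, 0]) == 0:
        raise ValueError("zero variance in delta rho")
    res = stats.pearsonr(pts[:, 0], pts[:, 1])
    return {
        "r": float(res.statistic),
        "p": float(res.pvalue),
        "n": len(pts),
        "n_removed": n_removed,
    }


def normalize_effects(means: pd.Series | dict) -> pd.Series:
    """Divide condition means by the family maximum (which maps to 1)."""
    s = pd.Series(means, dtype=float)
    top = s.max()
    if not np.isfinite(top) or top <= 0:
        raise ValueError("all condition means nonpositive; normalization skipped")
    return s / top


def condition_effects(
    deltas: pd.DataFrame,
    alpha: float = 0.01,
    outlier_k: float = 3.0,
    exact_threshold: int = 25,
) -> pd.DataFrame:
    """Build the effect table over (window x level) conditions.

    For each condition: the rectified choice-variability effect (-delta eta)
    and the rectified order-bias effect, with mean, SE, Wilcoxon and paired-t
    p-values. The range-dependent bias pools windows per level and reports
    Pearson r(delta rho, delta V). Each family's values are normalized by
    the family maximum; ``significant`` flags p < ``alpha``.
    """
    levels = list(dict.fromkeys(deltas["level"]))
    windows = list(dict.fromkeys(deltas["window"]))
    rows = []
    for effect, column in (
        ("choice_variability", "delta_eta"),
        ("order_bias", "delta_epsilon"),
    ):
        for window in windows:
            for level in levels:
                sub = deltas[(deltas["window"] == window) & (deltas["level"] == level)]
                vals = sub[column].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                rect = np.array(
                    [rectify_effect(v, effect, window) for v in vals]
                )
                if len(rect) == 0:
                    continue
                wres = wilcoxon_signed_rank(rect, exact_threshold=exact_threshold)
                if np.allclose(rect, 0) or len(rect) < 2:
                    p_t = 1.0
                else:
                    p_t = float(stats.ttest_1samp(rect, 0.0).pvalue)
                rows.append(
                    {
                        "effect": effect,
                        "window": window,
                        "level": level,
                        "n": len(rect),
                        "value": float(rect.mean()),
                        "se": float(rect.std(ddof=1) / math.sqrt(len(rect)))
                        if len(rect) > 1
                        else float("nan"),
                        "p": wres.p_value,
                        "p_ttest": p_t,
                    }
                )
    for level in levels:
        sub = deltas[deltas["level"] == level]
        try:
            rb = range_bias(
                sub["delta_rho"].to_numpy(dtype=float),
                sub["dV"].to_numpy(dtype=float),
                outlier_k=outlier_k,
            )
        except ValueError:
            continue
        rows.append(
            {
                "effect": "range_bias",
                "window": "pooled",
                "level": level,
                "n": rb["n"],
                "value": rb["r"],
                "se": float("nan"),
                "p": rb["p"],
                "p_ttest": float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    table["normalized"] = np.nan
    for effect in table["effect"].unique():
        mask = table["effect"] == effect
        try:
            table.loc[mask, "normalized"] = normalize_effects(
                table.loc[mask, "value"]
            ).to_numpy()
        except ValueError:
            pass  # all-nonpositive family: left unnormalized
    table["significant"] = table["p"] < alpha
    return table


def population_panels(
    deltas: pd.DataFrame,
    parameters: tuple[str, ...] = (
        "rho",
        "eta",
        "epsilon",
        "xi",
        "theta_juice",
        "theta_side",
        "theta_order",
        "error_rate",
        "mean_rt",
    ),
    ellipse_level: float = 0.90,
    exact_threshold: int = 25,
    variant: str = "signed_rank",
) -> pd.DataFrame:
    """stimOFF-vs-stimON scatter summaries per window and parameter.

    One row per (window, parameter): group means, paired test p-values, and
    the parameters of the confidence ellipse around the (OFF, ON) cloud.
    """
    rows = []
    for window in dict.fromkeys(deltas["window"]):
        sub = deltas[deltas["window"] == window]
        for param in parameters:
            off_col, on_col = f"{param}_off", f"{param}_on"
            if off_col not in sub.columns or on_col not in sub.columns:
                continue
            pair = sub[[off_col, on_col]].to_numpy(dtype=float)
            pair = pair[np.isfinite(pair).all(axis=1)]
            if len(pair) < 5:
                continue
            res = paired_tests(pair[:, 0], pair[:, 1],
                               exact_threshold=exact_threshold, variant=variant)
            try:
                ell = confidence_ellipse(pair, level=ellipse_level)
                ell_fields = {
                    "ellipse_cx": ell.center[0],
                    "ellipse_cy": ell.center[1],
                    "ellipse_major": ell.semi_axes[0],
                    "ellipse_minor": ell.semi_axes[1],
                    "ellipse_angle": ell.angle,
                }
            except ValueError:
                ell_fields = {}
            rows.append(
                {
                    "window": window,
                    "parameter": param,
                    "n": res.n,
                    "mean_off": float(pair[:, 0].mean()),
                    "mean_on": float(pair[:, 1].mean()),
                    "mean_diff": res.mean_diff,
                    "p_wilcoxon": res.p_wilcoxon,
                    "p_ttest": res.p_ttest,
                    **ell_fields,
                }
            )
    return pd.DataFrame(rows)
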