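"""Probit choice models and derived behavioral statistics.

Five models share the linear predictor X = a0 + a1*log(q_B/q_A) + a2*x2,
with choice B ~ Phi(X), differing only in the bias regressor x2:

order
    +1 on AB trials, -1 on BA trials. a2 is the order bias epsilon; a
    negative value favors the first offer.
side
    +1 when juice A's target is on the right, -1 when on the left. a2 is
    the side bias xi; a positive value means a left-target preference.
hyst_juice
    +1 if the last valid choice was juice B, -1 if juice A.
hyst_side
    +1 if juice B's target occupies the side chosen on the last valid trial.
hyst_order
    +1 if juice B occupies the presentation slot (first/second) of the
    juice chosen on the last valid trial.

Forced trials (a null offer) and error trials are excluded from all fits;
hysteresis trials without a preceding valid choice are excluded from the
hysteresis fits only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.special import log_ndtr, ndtr

BIAS_KINDS = ("order", "side", "hyst_juice", "hyst_side", "hyst_order")

PARAM_BY_KIND = {
    "order": "epsilon",
    "side": "xi",
    "hyst_juice": "theta_juice",
    "hyst_side": "theta_side",
    "hyst_order": "theta_order",
}


class FitError(RuntimeError):
    """Raised when a probit fit cannot be attempted on the given data."""


class DataError(ValueError):
    """Raised for structurally invalid trial data."""


@dataclass(frozen=True)
class ModelSpec:
    """Which bias regressor enters the probit."""

    bias_kind: str

    def __post_init__(self) -> None:
        if self.bias_kind not in BIAS_KINDS:
            raise ValueError(f"unknown bias kind {self.bias_kind!r}")

    @property
    def param_name(self) -> str:
        return PARAM_BY_KIND[self.bias_kind]

    @property
    def is_hysteresis(self) -> bool:
        return self.bias_kind.startswith("hyst_")


@dataclass
class ProbitFit:
    a0: float
    a1: float
    a2: float
    loglik: float
    converged: bool
    separation: bool
    n_used: int
    message: str = ""


@dataclass
class ChoiceParams:
    """Derived statistics of one fitted model."""

    rho: float
    eta: float
    bias: float
    bias_name: str
    reliable: bool


def build_regressor(trials: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Per-trial regressors for one model.

    Expects time-ordered trials of a single session. Returns a frame indexed
    like ``trials`` with columns ``x1`` (log q_B/q_A), ``x2``, ``y``
    (choice B indicator), ``stim_on`` and ``reference_missing`` (hysteresis
    regressor undefined; x2 is 0 there). Forced and error trials are
    excluded; their reasons are available via :func:`exclusion_reasons`.
    """
    forced = trials["forced"].to_numpy() == 1
    choice = trials["choice"].to_numpy(dtype=object)
    has_choice = np.array([c in ("A", "B") for c in choice])
    include = ~forced & has_choice

    q_a = trials["q_A"].to_numpy(dtype=float)
    q_b = trials["q_B"].to_numpy(dtype=float)
    if np.any((q_a <= 0) | (q_b <= 0)) and np.any(
        ((q_a <= 0) | (q_b <= 0)) & ~forced
    ):
        raise DataError("non-forced trial with non-positive quantity")

    with np.errstate(divide="ignore", invalid="ignore"):
        x1 = np.log(q_b / q_a)

    if spec.bias_kind == "order":
        x2 = np.where(trials["order"].to_numpy() == "AB", 1.0, -1.0)
        missing = np.zeros(len(trials), dtype=bool)
    elif spec.bias_kind == "side":
        x2 = np.where(trials["side_A"].to_numpy() == "right", 1.0, -1.0)
        missing = np.zeros(len(trials), dtype=bool)
    else:
        x2, missing = _hysteresis_regressor(trials, spec.bias_kind)

    out = pd.DataFrame(
        {
            "x1": x1,
            "x2": x2,
            "y": np.where(choice == "B", 1.0, 0.0),
            "stim_on": trials["stim_on"].to_numpy(),
            "reference_missing": missing,
        },
        index=trials.index,
    )
    return out[include]


def exclusion_reasons(trials: pd.DataFrame) -> pd.Series:
    """Reason each excluded trial does not enter a probit fit."""
    forced = trials["forced"] == 1
    error = trials["choice"].isna()
    reasons = pd.Series("", index=trials.index, dtype=object)
    reasons[error] = "error_trial"
    reasons[forced & ~error] = "forced_choice"
    return reasons[reasons != ""]


def _hysteresis_regressor(
    trials: pd.DataFrame, kind: str
) -> tuple[np.ndarray, np.ndarray]:
    """Hysteresis x2 from the most recent trial with a valid choice."""
    n = len(trials)
    x2 = np.zeros(n)
    missing = np.ones(n, dtype=bool)
    orders = trials["order"].to_numpy()
    sides_a = trials["side_A"].to_numpy()
    choice = trials["choice"].to_numpy(dtype=object)
    prev: tuple[str, str, int] | None = None
    for i in range(n):
        if prev is not None:
            missing[i] = False
            if kind == "hyst_juice":
                x2[i] = 1.0 if prev[0] == "B" else -1.0
            elif kind == "hyst_side":
                side_b = "left" if sides_a[i] == "right" else "right"
                x2[i] = 1.0 if side_b == prev[1] else -1.0
            else:  # hyst_order
                b_pos = 2 if orders[i] == "AB" else 1
                x2[i] = 1.0 if b_pos == prev[2] else -1.0
        ch = choice[i]
        if ch in ("A", "B"):
            if ch == "A":
                side = sides_a[i]
                pos = 1 if orders[i] == "AB" else 2
            else:
                side = "left" if sides_a[i] == "right" else "right"
                pos = 2 if orders[i] == "AB" else 1
            prev = (ch, side, pos)
    return x2, missing


# ---------------------------------------------------------------------------
# Maximum-likelihood probit


def _nll_grad(beta: np.ndarray, Z: np.ndarray, y: np.ndarray):
    t = Z @ beta
    lp = log_ndtr(t)
    lq = log_ndtr(-t)
    nll = -(y * lp + (1.0 - y) * lq).sum()
    logphi = -0.5 * t * t - 0.5 * math.log(2 * math.pi)
    lam1 = np.exp(logphi - lp)
    lam0 = np.exp(logphi - lq)
    w = y * lam1 - (1.0 - y) * lam0
    return nll, -(Z * w[:, None]).sum(axis=0)


def _hessian(beta: np.ndarray, Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    t = Z @ beta
    lp = log_ndtr(t)
    lq = log_ndtr(-t)
    logphi = -0.5 * t * t - 0.5 * math.log(2 * math.pi)
    lam1 = np.exp(logphi - lp)
    lam0 = np.exp(logphi - lq)
    w = y * lam1 * (lam1 + t) + (1.0 - y) * lam0 * (lam0 - t)
    return (Z * w[:, None]).T @ Z


def _newton(beta0: np.ndarray, Z: np.ndarray, y: np.ndarray, max_iter: int = 60):
    """Damped Newton descent on the (convex) probit negative log-likelihood."""
    beta = beta0.astype(float).copy()
    nll, grad = _nll_grad(beta, Z, y)
    for _ in range(max_iter):
        if np.linalg.norm(grad) <= 1e-9:
            break
        H = _hessian(beta, Z, y)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            step = grad
        # Quadratic model predicts a decrease of ~0.5*g.step; once that is
        # below float precision the line search cannot succeed.
        pred = grad @ step
        if pred < 1e-13 and np.linalg.norm(grad) <= 1e-7:
            break
        if pred < 1e-16:
            break
        scale = 1.0
        for _ in range(40):
            cand = beta - scale * step
            nll_new, grad_new = _nll_grad(cand, Z, y)
            if nll_new <= nll - 1e-14:
                beta, nll, grad = cand, nll_new, grad_new
                break
            scale *= 0.5
        else:
            break
    return beta, nll, grad


def _is_separated(Z: np.ndarray, y: np.ndarray) -> bool:
    """Complete-separation check: LP feasibility of a strict separator."""
    # Cheap refutation: both outcomes observed at an identical design point.
    pts1 = {tuple(row) for row in Z[y == 1]}
    pts0 = {tuple(row) for row in Z[y == 0]}
    if pts1 & pts0:
        return False
    s = np.where(y == 1, 1.0, -1.0)
    A_ub = -(Z * s[:, None])
    b_ub = -np.ones(len(y))
    res = linprog(
        c=np.zeros(Z.shape[1]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * Z.shape[1],
        method="highs",
    )
    return res.status == 0


def fit_probit(
    x1: np.ndarray,
    x2: np.ndarray,
    y: np.ndarray,
    n_starts: int = 5,
    min_trials: int = 10,
    seed: int = 0,
    check_separation: bool = True,
) -> ProbitFit:
    """MLE of P(choice B) = Phi(a0 + a1*x1 + a2*x2).

    Newton descent with jittered restarts (the likelihood is concave, so the
    restarts are a numerical safeguard). Convergence requires gradient norm
    <= 1e-6. Complete separation is detected by linear-programming
    feasibility; a separated fit is reported at the optimizer's stopping
    point with ``separation=True``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_trials:
        raise FitError(f"only {n} usable trials (need >= {min_trials})")
    if y.min() == y.max():
        raise FitError("degenerate outcomes: all trials have the same choice")
    if len(np.unique(x1)) < 2:
        raise FitError("need >= 2 distinct log quantity ratios")

    fit_a2 = bool(np.ptp(x2) > 0)
    message = ""
    if not fit_a2 and np.any(x2 != 0):
        message = "constant nonzero bias regressor absorbed into intercept; a2 set to 0"
    cols = [np.ones(n), x1] + ([x2] if fit_a2 else [])
    Z = np.column_stack(cols)

    rng = np.random.default_rng(seed)
    start0 = np.zeros(Z.shape[1])
    start0[1] = 1.0
    starts = [start0, np.zeros(Z.shape[1])]
    while len(starts) < max(n_starts, 1):
        starts.append(start0 + rng.normal(scale=0.5, size=Z.shape[1]))

    best = None
    for b0 in starts[: max(n_starts, 1)]:
        beta, nll, grad = _newton(b0, Z, y)
        if best is None or nll < best[1]:
            best = (beta, nll, grad)
        # The negative log-likelihood is strictly convex, so once any start
        # converges the remaining restarts would reach the same optimum.
        if np.linalg.norm(grad) <= 1e-9:
            break
    beta, nll, grad = best
    converged = bool(np.linalg.norm(grad) <= 1e-6)

    separated = False
    # A vanishing deviance is the signature of (near-)separation even when
    # the gradient test passes.
    suspicious = not converged or np.abs(beta).max() > 25.0 or nll < 0.01
    if check_separation and suspicious:
        separated = _is_separated(Z, y)

    a2 = float(beta[2]) if fit_a2 else 0.0
    return ProbitFit(
        a0=float(beta[0]),
        a1=float(beta[1]),
        a2=a2,
        loglik=float(-nll),
        converged=converged,
        separation=separated,
        n_used=n,
        message=message,
    )


def fit_model(
    trials: pd.DataFrame,
    spec: ModelSpec,
    n_starts: int = 5,
    min_trials: int = 10,
    seed: int = 0,
) -> ProbitFit:
    """Build regressors for ``spec`` and fit the probit."""
    reg = build_regressor(trials, spec)
    if spec.is_hysteresis:
        reg = reg[~reg["reference_missing"]]
    return fit_probit(
        reg["x1"].to_numpy(),
        reg["x2"].to_numpy(),
        reg["y"].to_numpy(),
        n_starts=n_starts,
        min_trials=min_trials,
        seed=seed,
    )


def derive_params(fit: ProbitFit, spec: ModelSpec) -> ChoiceParams:
    """Relative value, steepness, and tagged bias from fitted coefficients.

    rho = exp(-a0/a1) is the quantity ratio q_B/q_A at indifference; it is
    NaN (flagged unreliable) when a1 = 0.
    """
    if fit.a1 == 0:
        rho = float("nan")
        reliable = False
    else:
        rho = math.exp(-fit.a0 / fit.a1)
        reliable = fit.converged and not fit.separation
    return ChoiceParams(
        rho=rho,
        eta=fit.a1,
        bias=fit.a2,
        bias_name=spec.param_name,
        reliable=reliable,
    )
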