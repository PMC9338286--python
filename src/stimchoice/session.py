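"""Per-session analysis: stim split, model fits per group, deltas, summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    BIAS_KINDS,
    ChoiceParams,
    FitError,
    ModelSpec,
    ProbitFit,
    build_regressor,
    derive_params,
    fit_probit,
)

GROUPS = ("stimOFF", "stimON")


class SessionValidationError(ValueError):
    pass


@dataclass
class GroupSummary:
    n_trials: int
    error_rate: float
    error_rate_excl_no_init: float
    mean_rt: float


@dataclass
class SessionResult:
    """All per-session statistics for the population stage."""

    session_id: str
    window: str
    level: str
    fits: dict = field(default_factory=dict)  # (kind, group) -> ProbitFit
    params: dict = field(default_factory=dict)  # (kind, group) -> ChoiceParams
    fit_errors: dict = field(default_factory=dict)  # (kind, group) -> str
    deltas: dict = field(default_factory=dict)  # name -> float
    dV_A: float = float("nan")
    dV_B: float = float("nan")
    dV: float = float("nan")
    summaries: dict = field(default_factory=dict)  # group -> GroupSummary


def _validate_session(trials: pd.DataFrame) -> None:
    if trials["session_id"].nunique() > 1:
        raise SessionValidationError("trials from more than one session")
    if trials["condition_window"].nunique() > 1:
        raise SessionValidationError("mixed stimulation windows within a session")
    if ((trials["forced"].to_numpy() == 1) & (trials["stim_on"].to_numpy() == 1)).any():
        raise SessionValidationError("forced trial flagged as stimulated")


def split_by_stim(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition one session's trials into (stimOFF, stimON).

    Forced trials are never stimulated and therefore always land in stimOFF.
    """
    _validate_session(trials)
    on = trials["stim_on"] == 1
    return trials[~on], trials[on]


def session_summaries(trials: pd.DataFrame) -> dict[str, GroupSummary]:
    """Error rates and mean response times per stim group.

    A trial counts as an error iff it did not end in juice delivery
    (``error_code`` set). The ``excl_no_init`` variant drops failures to
    initiate the trial from numerator and denominator. Mean RT is taken
    over trials that ended in juice delivery.
    """
    _validate_session(trials)
    stim = trials["stim_on"].to_numpy() == 1
    is_err = trials["error_code"].notna().to_numpy()
    no_init = (trials["error_code"] == "no_initiation").to_numpy()
    rt = trials["rt_ms"].to_numpy(dtype=float)
    out = {}
    for name, mask in (("stimOFF", ~stim), ("stimON", stim)):
        n = int(mask.sum())
        if n == 0:
            out[name] = GroupSummary(0, float("nan"), float("nan"), float("nan"))
            continue
        err = is_err & mask
        n_init = int((mask & ~no_init).sum())
        rate_excl = float((err & ~no_init).sum() / n_init) if n_init else float("nan")
        delivered = rt[mask & ~is_err]
        out[name] = GroupSummary(
            n_trials=n,
            error_rate=float(err.sum() / n),
            error_rate_excl_no_init=rate_excl,
            mean_rt=float(delivered.mean()) if len(delivered) else float("nan"),
        )
    return out


def _session_value_ranges(trials: pd.DataFrame, rho_off: float):
    """(dV_A, dV_B, dV) from the session's offered quantities.

    Ranges run over non-forced offers; the minimum is 0 when null offers of
    that juice exist. dV_A is expressed in juice-B value units via the
    stimOFF relative value.
    """
    nonforced = trials[trials["forced"] == 0]
    q_a = nonforced["q_A"].to_numpy()
    q_b = nonforced["q_B"].to_numpy()
    min_a = 0 if (trials["q_A"] == 0).any() else int(q_a.min())
    min_b = 0 if (trials["q_B"] == 0).any() else int(q_b.min())
    dva = rho_off * (q_a.max() - min_a)
    dvb = float(q_b.max() - min_b)
    return dva, dvb, dva - dvb


def analyze_session(
    trials: pd.DataFrame,
    models: Sequence[str] = BIAS_KINDS,
    min_trials: int = 10,
    n_starts: int = 5,
    seed: int = 0,
) -> SessionResult:
    """Fit the requested models per stim group and derive all deltas.

    Hysteresis regressors are built on the full time-ordered session before
    the stim split, so a stimON trial's reference choice may come from a
    stimOFF trial (and vice versa). Fit failures for one model are recorded
    and do not abort the others.
    """
    if not trials["trial_index"].is_monotonic_increasing:
        trials = trials.sort_values("trial_index")
    _validate_session(trials)
    result = SessionResult(
        session_id=str(trials["session_id"].iloc[0]),
        window=str(trials["condition_window"].iloc[0]),
        level=str(trials["condition_level"].iloc[0]),
    )

    for kind in models:
        spec = ModelSpec(kind)
        try:
            reg = build_regressor(trials, spec)
        except Exception as exc:  # data errors affect every group
            for group in GROUPS:
                result.fit_errors[(kind, group)] = str(exc)
            continue
        x1 = reg["x1"].to_numpy()
        x2 = reg["x2"].to_numpy()
        yy = reg["y"].to_numpy()
        reg_stim = reg["stim_on"].to_numpy()
        usable = (
            ~reg["reference_missing"].to_numpy()
            if spec.is_hysteresis
            else np.ones(len(reg), dtype=bool)
        )
        for group, flag in (("stimOFF", 0), ("stimON", 1)):
            sel = usable & (reg_stim == flag)
            try:
                fit = fit_probit(
                    x1[sel],
                    x2[sel],
                    yy[sel],
                    n_starts=n_starts,
                    min_trials=min_trials,
                    seed=seed,
                )
            except FitError as exc:
                result.fit_errors[(kind, group)] = str(exc)
                continue
            result.fits[(kind, group)] = fit
            result.params[(kind, group)] = derive_params(fit, spec)

    # Deltas: rho/eta from the order model (the primary fit); bias per model.
    def _delta(kind: str, attr: str) -> float:
        p_off = result.params.get((kind, "stimOFF"))
        p_on = result.params.get((kind, "stimON"))
        if p_off is None or p_on is None:
            return float("nan")
        return getattr(p_on, attr) - getattr(p_off, attr)

    result.deltas["delta_rho"] = _delta("order", "rho")
    result.deltas["delta_eta"] = _delta("order", "eta")
    for kind in models:
        name = ModelSpec(kind).param_name
        result.deltas[f"delta_{name}"] = _delta(kind, "bias")

    p_off = result.params.get(("order", "stimOFF"))
    if p_off is not None and np.isfinite(p_off.rho):
        result.dV_A, result.dV_B, result.dV = _session_value_ranges(
            trials, p_off.rho
        )
    result.summaries = session_summaries(trials)
    return result


def analyze_many(
    trials: pd.DataFrame,
    models: Sequence[str] = BIAS_KINDS,
    min_trials: int = 10,
    n_starts: int = 5,
) -> list[SessionResult]:
    """Analyze every session in a concatenated trial table."""
    results = []
    for _, grp in trials.groupby("session_id", sort=False):
        results.append(
            analyze_session(grp, models=models, min_trials=min_trials, n_starts=n_starts)
        )
    return results


def results_long(results: Sequence[SessionResult]) -> pd.DataFrame:
    """Long-format table: one row per session x model x group x parameter."""
    rows = []
    for res in results:
        for (kind, group), params in res.params.items():
            fit = res.fits[(kind, group)]
            for pname, value in (
                ("rho", params.rho),
                ("eta", params.eta),
                (params.bias_name, params.bias),
                ("loglik", fit.loglik),
                ("n_used", fit.n_used),
            ):
                rows.append(
                    (res.session_id, res.window, res.level, kind, group, pname, value)
                )
    return pd.DataFrame(
        rows,
        columns=["session_id", "window", "level", "model", "group", "parameter", "value"],
    )


def deltas_frame(results: Sequence[SessionResult]) -> pd.DataFrame:
    """Wide per-session summary used by the population stage."""
    rows = []
    for res in results:
        row: dict = {
            "session_id": res.session_id,
            "window": res.window,
            "level": res.level,
            "dV_A": res.dV_A,
            "dV_B": res.dV_B,
            "dV": res.dV,
        }
        row.update(res.deltas)
        for kind, group in res.params:
            p = res.params[(kind, group)]
            suffix = "off" if group == "stimOFF" else "on"
            if kind == "order":
                row[f"rho_{suffix}"] = p.rho
                row[f"eta_{suffix}"] = p.eta
            row[f"{p.bias_name}_{suffix}"] = p.bias
        for group, summ in res.summaries.items():
            suffix = "off" if group == "stimOFF" else "on"
            row[f"error_rate_{suffix}"] = summ.error_rate
            row[f"error_rate_excl_no_init_{suffix}"] = summ.error_rate_excl_no_init
            row[f"mean_rt_{suffix}"] = summ.mean_rt
        rows.append(row)
    return pd.DataFrame(rows)
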