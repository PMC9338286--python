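"""Synthetic sequential-offer choice sessions.

Generates counterbalanced session designs and simulates trial-by-trial
choices from a probit-governed ground truth, including order/side/hysteresis
biases, error trials, response times, and three configurable stimulation
effects (range-proportional value shift, additive order-bias shift,
multiplicative steepness change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io import COLUMNS, ERROR_CODES, canonicalize

DEFAULT_ERROR_MIX: dict[str, float] = {
    "no_initiation": 0.50,
    "center_fix_break": 0.25,
    "no_choice": 0.15,
    "peripheral_fix_break": 0.10,
}


class DesignError(ValueError):
    """Raised when a requested design cannot straddle indifference."""


@dataclass(frozen=True)
class StimEffects:
    """Stimulation effects applied on stimON trials.

    value_shift_gain
        Fraction ``c`` of each juice's session value range added to that
        juice's value on stimulated trials.
    delta_epsilon
        Additive shift of the order-bias coefficient (probit units).
    eta_gain
        Multiplicative factor on the steepness; applied when the session's
        stimulation window is ``offer2``.
    """

    value_shift_gain: float = 0.0
    delta_epsilon: float = 0.0
    eta_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.eta_gain <= 0:
            raise ValueError("eta_gain must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters of one session."""

    rho: float
    eta: float
    epsilon: float = 0.0
    xi: float = 0.0
    theta_juice: float = 0.0
    theta_side: float = 0.0
    theta_order: float = 0.0
    stim_window: str = "offer2"  # offer1 | offer2 | none
    stim: StimEffects = field(default_factory=StimEffects)
    error_rate_off: float = 0.0
    error_rate_on: float = 0.0
    rt_median_off: float = 400.0
    rt_median_on: float = 400.0
    rt_sigma: float = 0.15
    error_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_MIX)
    )

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.stim_window not in ("offer1", "offer2", "none"):
            raise ValueError(f"invalid stim_window {self.stim_window!r}")
        for name in ("error_rate_off", "error_rate_on"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        bad = set(self.error_mix) - set(ERROR_CODES)
        if bad:
            raise ValueError(f"unknown error codes {sorted(bad)}")


@dataclass(frozen=True)
class DesignConfig:
    """Parameters from which a session design is derived.

    ``rho``/``eta`` are the nominal values used to place offer types around
    indifference; the realized session may be generated from a different
    :class:`GroundTruth`.
    """

    q_max_a: int
    q_max_b: int
    rho: float
    eta: float
    n_trials: int = 400
    stim_fraction: float = 0.5
    n_offer_types: int = 8
    include_forced: bool = True
    straddle_halfwidth: float = 2.0  # |log(qB/(rho*qA))| <= hw/eta counts as split
    min_split_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.q_max_a < 1 or self.q_max_b < 1:
            raise ValueError("quantity ranges must include at least 1 drop")
        if self.rho <= 0 or self.eta <= 0:
            raise ValueError("rho and eta must be > 0")
        if not 0.0 <= self.stim_fraction <= 1.0:
            raise ValueError("stim_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SessionDesign:
    """A concrete session design: offer types plus layout parameters."""

    juiceA_label: str
    juiceB_label: str
    offer_types: tuple[tuple[int, int], ...]  # (q_A, q_B); 0 marks a null offer
    n_trials: int
    stim_fraction: float
    seed: int

    def __post_init__(self) -> None:
        for q_a, q_b in self.offer_types:
            if q_a < 0 or q_b < 0:
                raise ValueError("quantities must be >= 0")
            if q_a == 0 and q_b == 0:
                raise ValueError("offer type cannot be doubly null")

    @property
    def nonforced_types(self) -> tuple[tuple[int, int], ...]:
        return tuple((a, b) for a, b in self.offer_types if a > 0 and b > 0)

    @property
    def forced_types(self) -> tuple[tuple[int, int], ...]:
        return tuple((a, b) for a, b in self.offer_types if a == 0 or b == 0)


def make_design(
    config: DesignConfig,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> SessionDesign:
    """Choose offer types whose log quantity ratios straddle indifference.

    Candidate (q_A, q_B) pairs are ranked by distance of log(q_B/q_A) from
    log(rho); the closest ``n_offer_types`` are kept (ties included, so a
    symmetric configuration yields a symmetric design). Raises
    :class:`DesignError` if the quantity ranges cannot straddle indifference
    or fewer than ``min_split_fraction`` of the chosen types fall within the
    split-choice band ``|log(q_B/(rho*q_A))| <= straddle_halfwidth/eta``.
    """
    cand = [
        (qa, qb)
        for qa in range(1, config.q_max_a + 1)
        for qb in range(1, config.q_max_b + 1)
    ]
    lr = np.array([math.log(qb / (config.rho * qa)) for qa, qb in cand])
    if np.all(lr > 0) or np.all(lr < 0):
        raise DesignError(
            "quantity ranges cannot straddle indifference "
            f"(all offers on one side of rho={config.rho})"
        )
    order = np.argsort(np.abs(lr), kind="stable")
    n_keep = min(config.n_offer_types, len(cand))
    threshold = np.abs(lr)[order[n_keep - 1]]
    keep = np.abs(lr) <= threshold + 1e-12
    chosen = [cand[i] for i in np.flatnonzero(keep)]
    chosen_lr = lr[keep]
    # Guarantee both sides of indifference are represented.
    if np.all(chosen_lr >= 0) or np.all(chosen_lr <= 0):
        want_neg = bool(np.all(chosen_lr >= 0))
        side = np.flatnonzero(lr < 0 if want_neg else lr > 0)
        if len(side) == 0:
            raise DesignError("offer types cannot straddle indifference")
        best = side[np.argmin(np.abs(lr)[side])]
        chosen.append(cand[best])
        chosen_lr = np.append(chosen_lr, lr[best])
    split = np.abs(chosen_lr) <= config.straddle_halfwidth / config.eta
    if split.mean() < config.min_split_fraction:
        raise DesignError(
            f"only {split.mean():.0%} of offer types fall in the split-choice "
            f"band (need >= {config.min_split_fraction:.0%}); widen the "
            "quantity ranges or revise rho/eta"
        )
    offer_types = sorted(set(chosen))
    if config.include_forced:
        forced = {(1, 0), (0, 1), (config.q_max_a, 0), (0, config.q_max_b)}
        offer_types.extend(sorted(forced - set(offer_types)))
    return SessionDesign(
        juiceA_label=labels[0],
        juiceB_label=labels[1],
        offer_types=tuple(offer_types),
        n_trials=config.n_trials,
        stim_fraction=config.stim_fraction,
        seed=seed,
    )


def make_trial_layout(design: SessionDesign) -> pd.DataFrame:
    """Expand a design into a shuffled, counterbalanced trial skeleton.

    Per offer type the AB/BA order and the left/right side of juice A are
    balanced up to rounding. Stimulation is assigned to a pseudo-random
    subset of non-forced trials of size round(stim_fraction * n_nonforced).
    """
    rng = np.random.default_rng(design.seed)
    n_types = len(design.offer_types)
    base, extra = divmod(design.n_trials, n_types)
    counts = np.full(n_types, base, dtype=int)
    counts[rng.choice(n_types, size=extra, replace=False)] += 1

    rows: list[tuple[int, int, str, str, int]] = []
    combos = [("AB", "left"), ("AB", "right"), ("BA", "left"), ("BA", "right")]
    pairs = ([("AB", "left"), ("BA", "right")], [("AB", "right"), ("BA", "left")])
    for (q_a, q_b), k in zip(design.offer_types, counts):
        forced = int(q_a == 0 or q_b == 0)
        base_k, rem = divmod(k, 4)
        cell = combos * base_k
        # Remainder assignments keep |#AB-#BA| and |#A-left-#A-right| <= 1.
        if rem == 1:
            cell += [combos[int(rng.integers(4))]]
        elif rem == 2:
            cell += pairs[int(rng.integers(2))]
        elif rem == 3:
            drop = combos[int(rng.integers(4))]
            cell += [c for c in combos if c != drop]
        for order_, side_a in cell:
            rows.append((q_a, q_b, order_, side_a, forced))
    perm = rng.permutation(len(rows))
    rows = [rows[i] for i in perm]

    df = pd.DataFrame(rows, columns=["q_A", "q_B", "order", "side_A", "forced"])
    stim = np.zeros(len(df), dtype=int)
    nonforced_idx = np.flatnonzero(df["forced"].to_numpy() == 0)
    n_stim = int(round(design.stim_fraction * len(nonforced_idx)))
    if n_stim > 0:
        stim[rng.choice(nonforced_idx, size=n_stim, replace=False)] = 1
    df["stim_on"] = stim
    return df


def value_ranges(design: SessionDesign, rho: float) -> tuple[float, float]:
    """Session value ranges (juice-B units): ``(dV_A, dV_B)``.

    The range of juice J runs from its minimum to its maximum offered value;
    the minimum is 0 whenever null offers of J exist (forced choices).
    """
    q_a = [a for a, _ in design.nonforced_types]
    q_b = [b for _, b in design.nonforced_types]
    has_null_a = any(a == 0 for a, _ in design.offer_types)
    has_null_b = any(b == 0 for _, b in design.offer_types)
    min_a = 0 if has_null_a else min(q_a)
    min_b = 0 if has_null_b else min(q_b)
    return rho * (max(q_a) - min_a), float(max(q_b) - min_b)


def _hysteresis_step(
    prev: tuple[str, str, int] | None, order_: str, side_a: str
) -> tuple[int, int, int]:
    """Regressor triple (juice, side, order) given the last valid choice."""
    if prev is None:
        return 0, 0, 0
    prev_juice, prev_side, prev_pos = prev
    h_j = 1 if prev_juice == "B" else -1
    side_b = "left" if side_a == "right" else "right"
    h_s = 1 if side_b == prev_side else -1
    b_pos = 2 if order_ == "AB" else 1
    h_o = 1 if b_pos == prev_pos else -1
    return h_j, h_s, h_o


def simulate_session(
    truth: GroundTruth,
    design: SessionDesign,
    seed: int,
    session_id: str = "s000",
    level_label: str = "15uA",
) -> pd.DataFrame:
    """Simulate one session; returns a canonical trial table.

    Identical (truth, design, seed) yields identical output. Choices are
    drawn as choice B ~ Bernoulli(Phi(X)) with
    X = eta_eff*log(V_B_eff/V_A_eff) + eps_eff*(order) + xi*(side) +
    hysteresis terms, where values are V_A = rho*q_A, V_B = q_B and the
    stimulation effects modify eta, epsilon, and the values on stimON trials.
    """
    layout = make_trial_layout(design)
    n = len(layout)
    rng = np.random.default_rng(seed)
    u_choice = rng.random(n)
    u_err = rng.random(n)
    u_code = rng.random(n)
    z_rt = rng.standard_normal(n)

    q_a = layout["q_A"].to_numpy(dtype=float)
    q_b = layout["q_B"].to_numpy(dtype=float)
    forced = layout["forced"].to_numpy(dtype=bool)
    stim = layout["stim_on"].to_numpy(dtype=bool)
    if truth.stim_window == "none":
        stim = np.zeros(n, dtype=bool)
    o = np.where(layout["order"].to_numpy() == "AB", 1.0, -1.0)
    s = np.where(layout["side_A"].to_numpy() == "right", 1.0, -1.0)

    dV_A, dV_B = value_ranges(design, truth.rho)
    c = truth.stim.value_shift_gain
    v_a = truth.rho * q_a + np.where(stim, c * dV_A, 0.0)
    v_b = q_b + np.where(stim, c * dV_B, 0.0)
    eta_eff = truth.eta * np.where(
        stim & (truth.stim_window == "offer2"), truth.stim.eta_gain, 1.0
    )
    eps_eff = truth.epsilon + np.where(stim, truth.stim.delta_epsilon, 0.0)

    with np.errstate(divide="ignore"):
        x_base = np.where(
            forced, 0.0, eta_eff * np.log(np.where(forced, 1.0, v_b / v_a))
        )
    x_base = x_base + eps_eff * o + truth.xi * s

    err_rate = np.where(stim, truth.error_rate_on, truth.error_rate_off)
    is_err = u_err < err_rate

    thetas = (truth.theta_juice, truth.theta_side, truth.theta_order)
    choice = np.full(n, None, dtype=object)
    if all(t == 0.0 for t in thetas):
        p_b = ndtr(x_base)
        pick_b = u_choice < p_b
        choice[~forced & ~is_err] = np.where(pick_b, "B", "A")[~forced & ~is_err]
    else:
        orders = layout["order"].to_numpy()
        sides_a = layout["side_A"].to_numpy()
        prev: tuple[str, str, int] | None = None
        for i in range(n):
            if is_err[i]:
                continue
            if forced[i]:
                ch = "A" if q_a[i] > 0 else "B"
            else:
                h_j, h_s, h_o = _hysteresis_step(prev, orders[i], sides_a[i])
                x = (
                    x_base[i]
                    + thetas[0] * h_j
                    + thetas[1] * h_s
                    + thetas[2] * h_o
                )
                ch = "B" if u_choice[i] < ndtr(x) else "A"
            choice[i] = ch
            side = sides_a[i] if ch == "A" else (
                "left" if sides_a[i] == "right" else "right"
            )
            if ch == "A":
                pos = 1 if orders[i] == "AB" else 2
            else:
                pos = 2 if orders[i] == "AB" else 1
            prev = (ch, side, pos)
    # Forced choices in the vectorized branch.
    forced_ok = forced & ~is_err
    if forced_ok.any():
        choice[forced_ok] = np.where(q_a[forced_ok] > 0, "A", "B")

    codes, cum = _code_thresholds(truth.error_mix)
    err_code = np.full(n, None, dtype=object)
    err_code[is_err] = codes[np.searchsorted(cum, u_code[is_err], side="right")]

    rt_median = np.where(stim, truth.rt_median_on, truth.rt_median_off)
    rt = np.exp(np.log(rt_median) + truth.rt_sigma * z_rt)
    rt = np.where(is_err, np.nan, rt)

    df = pd.DataFrame(
        {
            "session_id": session_id,
            "trial_index": np.arange(n),
            "condition_window": truth.stim_window,
            "condition_level": level_label,
            "q_A": layout["q_A"],
            "q_B": layout["q_B"],
            "order": layout["order"],
            "side_A": layout["side_A"],
            "forced": layout["forced"],
            "stim_on": stim.astype(int),
            "choice": choice,
            "error_code": err_code,
            "rt_ms": rt,
        },
        columns=COLUMNS,
    )
    return canonicalize(df)


def _code_thresholds(mix: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    codes = np.array(list(mix.keys()), dtype=object)
    w = np.array(list(mix.values()), dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("error_mix weights must be nonnegative and sum > 0")
    cum = np.cumsum(w / w.sum())[:-1]
    return codes, cum


@dataclass(frozen=True)
class ConditionCell:
    """One (stimulation window, current-level label) experiment cell."""

    window: str
    level: str
    n_sessions: int
    truth: GroundTruth
    design: DesignConfig
    # Optional per-session overrides; each entry maps DesignConfig field
    # name -> sequence of values sampled per session (e.g. varying q_max_b).
    design_choices: Mapping[str, Sequence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.truth.stim_window != self.window:
            object.__setattr__(
                self, "truth", replace(self.truth, stim_window=self.window)
            )


def simulate_experiment(
    cells: Sequence[ConditionCell], seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Simulate a multi-condition experiment.

    Returns the concatenated trial table and a manifest recording, per cell
    and per session, the ground-truth parameters and realized design. Session
    ids are ``{window}.{level}.s{k:03d}`` and must be unique across cells.
    """
    seen: set[tuple[str, str]] = set()
    frames: list[pd.DataFrame] = []
    manifest: dict = {"seed": seed, "cells": []}
    rng = np.random.default_rng(seed)
    for cell in cells:
        key = (cell.window, cell.level)
        if key in seen:
            raise ValueError(f"duplicate condition cell {key}")
        seen.add(key)
        cell_entry = {
            "window": cell.window,
            "level": cell.level,
            "n_sessions": cell.n_sessions,
            "truth": _truth_dict(cell.truth),
            "sessions": [],
        }
        for k in range(cell.n_sessions):
            cfg = cell.design
            for name, choices in cell.design_choices.items():
                cfg = replace(cfg, **{name: choices[int(rng.integers(len(choices)))]})
            design_seed = int(rng.integers(2**31))
            sim_seed = int(rng.integers(2**31))
            design = make_design(cfg, seed=design_seed)
            sid = f"{cell.window}.{cell.level}.s{k:03d}"
            frames.append(
                simulate_session(
                    cell.truth, design, sim_seed, session_id=sid,
                    level_label=cell.level,
                )
            )
            cell_entry["sessions"].append(
                {
                    "session_id": sid,
                    "design_seed": design_seed,
                    "sim_seed": sim_seed,
                    "q_max_a": cfg.q_max_a,
                    "q_max_b": cfg.q_max_b,
                    "offer_types": [list(t) for t in design.offer_types],
                }
            )
        manifest["cells"].append(cell_entry)
    trials = pd.concat(frames, ignore_index=True)
    return trials, manifest


def _truth_dict(truth: GroundTruth) -> dict:
    return {
        "rho": truth.rho,
        "eta": truth.eta,
        "epsilon": truth.epsilon,
        "xi": truth.xi,
        "theta_juice": truth.theta_juice,
        "theta_side": truth.theta_side,
        "theta_order": truth.theta_order,
        "stim_window": truth.stim_window,
        "stim": {
            "value_shift_gain": truth.stim.value_shift_gain,
            "delta_epsilon": truth.stim.delta_epsilon,
            "eta_gain": truth.stim.eta_gain,
        },
        "error_rate_off": truth.error_rate_off,
        "error_rate_on": truth.error_rate_on,
        "rt_median_off": truth.rt_median_off,
        "rt_median_on": truth.rt_median_on,
        "rt_sigma": truth.rt_sigma,
    }
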