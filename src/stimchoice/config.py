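"""YAML run configuration parsed into simulator/analysis objects."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .simulate import ConditionCell, DesignConfig, GroundTruth, StimEffects


@dataclass
class AnalysisOptions:
    outlier_k: float = 3.0
    ellipse_level: float = 0.90
    alpha: float = 0.01  # significance threshold for effect-table asterisks
    wilcoxon_variant: str = "signed_rank"
    exact_threshold: int = 25
    exclude_no_initiation: bool = False
    min_trials: int = 10
    n_starts: int = 5
    models: tuple[str, ...] = (
        "order",
        "side",
        "hyst_juice",
        "hyst_side",
        "hyst_order",
    )


@dataclass
class RunConfig:
    seed: int
    cells: list[ConditionCell]
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_truth(d: Mapping[str, Any]) -> GroundTruth:
    d = dict(d)
    stim = d.pop("stim", {}) or {}
    return GroundTruth(stim=StimEffects(**stim), **d)


def _build_design(base: Mapping[str, Any], override: Mapping[str, Any] | None):
    merged: dict[str, Any] = dict(base)
    if override:
        merged.update(override)
    valid = {f.name for f in fields(DesignConfig)}
    unknown = set(merged) - valid
    if unknown:
        raise ValueError(f"unknown design fields {sorted(unknown)}")
    # List-valued fields become per-session sampling choices.
    choices = {k: v for k, v in merged.items() if isinstance(v, list)}
    for k, v in choices.items():
        merged[k] = v[0]
    return DesignConfig(**merged), choices


def load_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse a run configuration from a YAML file or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")

    seed = int(raw.get("seed", 0))
    base_design = raw.get("design", {}) or {}
    cells = []
    for entry in raw.get("conditions", []):
        entry = dict(entry)
        truth_cfg = dict(entry.get("truth", {}))
        truth_cfg.setdefault("stim_window", entry["window"])
        truth = _build_truth(truth_cfg)
        design_cfg = dict(base_design)
        design_cfg.setdefault("rho", truth.rho)
        design_cfg.setdefault("eta", truth.eta)
        design, choices = _build_design(design_cfg, entry.get("design"))
        cells.append(
            ConditionCell(
                window=entry["window"],
                level=str(entry["level"]),
                n_sessions=int(entry["n_sessions"]),
                truth=truth,
                design=design,
                design_choices=choices,
            )
        )
    if not cells:
        raise ValueError("configuration defines no condition cells")

    analysis = AnalysisOptions(**(raw.get("analysis", {}) or {}))
    if isinstance(analysis.models, list):
        analysis.models = tuple(analysis.models)
    return RunConfig(seed=seed, cells=cells, analysis=analysis, raw=raw)


def reseed(config: RunConfig, seed: int) -> RunConfig:
    raw = dict(config.raw)
    raw["seed"] = seed
    return replace(config, seed=seed, raw=raw)
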