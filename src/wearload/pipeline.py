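"""End-to-end orchestration: simulate -> window -> estimate -> validate -> compare.

One :func:`run_pipeline` call reproduces the whole study workflow on
synthetic data: raw trials for every (participant, condition) cell, the
20/60/10-s windowing, the load-rate statistic per device and for the
force plate, the outlier exclusions, the three model specifications with
bootstrap cross-validation, and the ANOVA/Bonferroni comparisons between
models and between devices.  Identical config + seed gives an identical
report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import ComparisonReport, compare_groups
from .errors import UsageError
from .loadrate import mean_load_rate_from_accel, mean_load_rate_from_force
from .signal_io import extract_window
from .synthetic import (
    DeviceSpec,
    SimulationConfig,
    TrialCondition,
    draw_profiles,
    make_roster,
    simulate_summary_dataset,
    simulate_trial,
    study_conditions,
)
from .validation import (
    ExclusionRule,
    apply_exclusions,
    bootstrap_validate,
    fit_model,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "build_observations"]

#: study-replica devices: a chest-worn smartphone (clean coupling) and a
#: wrist-worn smartwatch (weaker coupling, noisier)
DEFAULT_DEVICES = (
    DeviceSpec(name="SP1", attenuation_scale=1.05, noise_sd=0.25),
    DeviceSpec(name="SW1", attenuation_scale=0.80, noise_sd=0.55),
)


def _replica_completion() -> dict[int, list[TrialCondition]]:
    # participant 12 only completed the 5 and 8 km/h trials
    return {12: [c for c in study_conditions() if c.speed_kmh in (5.0, 8.0)]}


def _replica_exclusions() -> list[ExclusionRule]:
    # participant 1 entirely, and participant 2's 5 km/h trials, were outliers
    return [
        ExclusionRule(participant_id=1, reason="outlier (all trials)"),
        ExclusionRule(participant_id=2, speed_kmh=5.0, reason="outlier (5 km/h)"),
    ]


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: str | Path = "results/run"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    devices: tuple[DeviceSpec, ...] = DEFAULT_DEVICES
    head_s: float = 20.0
    keep_s: float = 60.0
    tail_s: float = 10.0
    B: int = 100  # 1000 for a full replication
    seed: int = 0
    family_alpha: float = 0.05
    specs: tuple[str, ...] = ("M1", "M2", "M3")
    strata: tuple[str, ...] = ("overall",)  # may add "speed" and/or "device"
    source: str = "signal"  # "signal" (raw trials) or "summary" (generative table)
    replica_completion: bool = True
    replica_exclusions: bool = True

    def validate(self) -> None:
        self.sim.validate()
        if self.B < 1:
            raise UsageError("B must be >= 1")
        unknown = set(self.specs) - {"M1", "M2", "M3"}
        if unknown:
            raise UsageError(f"unknown model specs: {sorted(unknown)}")
        if self.source not in ("signal", "summary"):
            raise UsageError(f"source must be 'signal' or 'summary': {self.source!r}")
        if self.sim.trial_duration_s < self.head_s + self.keep_s:
            raise UsageError("trial_duration_s shorter than head + keep window")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        devices = tuple(DeviceSpec(**d) for d in raw.pop("devices", [])) or DEFAULT_DEVICES
        for key in ("specs", "strata"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, devices=devices, **raw)


@dataclass
class RunReport:
    """All tables one run produces, plus provenance."""

    observations: pd.DataFrame
    metrics: pd.DataFrame  # stratum, device, model, r2/rmser means and CIs
    model_comparisons: dict  # device -> {"r2": ComparisonReport, "rmser": ComparisonReport}
    device_comparison: ComparisonReport | None
    exclusion_log: list
    n_analysed_trials: int
    config: RunConfig
    version: str = __version__


def build_observations(config: RunConfig) -> tuple[pd.DataFrame, list]:
    """Assemble the analysed observation table for a run.

    Signal mode simulates raw trials, windows them and computes the
    load-rate statistic per device; summary mode draws (x, y) pairs
    directly from the generative model under a single pseudo-device.
    Returns the table and the exclusion log.
    """
    config.validate()
    completion = _replica_completion() if config.replica_completion else None
    exclusions = _replica_exclusions() if config.replica_exclusions else []
    planned = make_roster(config.sim.n_participants)
    analysed, log = apply_exclusions(planned, completion, exclusions)

    if config.source == "summary":
        table = simulate_summary_dataset(config.sim, roster=analysed)
        table.insert(1, "device", "wearable")
        return table, log

    profiles = draw_profiles(config.sim)
    rows = []
    for pid, cond in analysed:
        bundle = simulate_trial(profiles[pid], cond, config.sim, devices=list(config.devices))
        force_win = extract_window(
            bundle.forceplate_series, config.head_s, config.keep_s, config.tail_s
        )
        y = mean_load_rate_from_force(force_win).value
        for name, series in bundle.wearable_series.items():
            accel_win = extract_window(series, config.head_s, config.keep_s, config.tail_s)
            x = mean_load_rate_from_accel(accel_win, profiles[pid].mass).value
            rows.append(
                {
                    "participant_id": pid,
                    "device": name,
                    "bodyweight_pct": cond.bodyweight_pct,
                    "speed_kmh": cond.speed_kmh,
                    "x": x,
                    "y": y,
                }
            )
    return pd.DataFrame(rows), log


def _metric_row(device: str, model: str, res) -> dict:
    return {
        "stratum": res.stratum,
        "device": device,
        "model": model,
        "r2_mean": res.r2_mean,
        "r2_lo": res.r2_ci[0],
        "r2_hi": res.r2_ci[1],
        "rmser_mean": res.rmser_mean,
        "rmser_lo": res.rmser_ci[0],
        "rmser_hi": res.rmser_ci[1],
    }


def run_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Execute every stage and (optionally) write CSV reports under ``out_dir``."""
    config.validate()
    table, log = build_observations(config)
    devices = sorted(table["device"].unique())

    metric_rows = []
    boot_by_device_model = {}
    for device in devices:
        sub = table[table["device"] == device].reset_index(drop=True)
        for spec in config.specs:
            fit_model(sub, spec)  # fail fast with the stage name if singular
            overall = bootstrap_validate(sub, spec, B=config.B, seed=config.seed)
            boot_by_device_model[(device, spec)] = overall
            metric_rows.append(_metric_row(device, spec, overall))
            if "speed" in config.strata:
                for res in bootstrap_validate(
                    sub, spec, B=config.B, seed=config.seed, stratify_by="speed"
                ).values():
                    metric_rows.append(_metric_row(device, spec, res))
    metrics = pd.DataFrame(metric_rows)

    model_comparisons = {}
    for device in devices:
        if len(config.specs) >= 2 and config.B >= 2:
            r2_groups = {
                spec: boot_by_device_model[(device, spec)].r2_samples
                for spec in config.specs
            }
            rmser_groups = {
                spec: boot_by_device_model[(device, spec)].rmser_samples
                for spec in config.specs
            }
            model_comparisons[device] = {
                "r2": compare_groups(r2_groups, config.family_alpha, higher_is_better=True),
                "rmser": compare_groups(
                    rmser_groups, config.family_alpha, higher_is_better=False
                ),
            }

    device_comparison = None
    if len(devices) >= 2 and "M3" in config.specs and config.B >= 2:
        device_comparison = compare_groups(
            {d: boot_by_device_model[(d, "M3")].r2_samples for d in devices},
            config.family_alpha,
            higher_is_better=True,
        )

    report = RunReport(
        observations=table,
        metrics=metrics,
        model_comparisons=model_comparisons,
        device_comparison=device_comparison,
        exclusion_log=log,
        n_analysed_trials=int(table.groupby("device").size().iloc[0]) if len(table) else 0,
        config=config,
    )
    if write:
        _write_report(report, Path(config.out_dir))
    return report


def _comparison_frame(comparisons: dict) -> pd.DataFrame:
    rows = []
    for device, by_metric in comparisons.items():
        for metric, rep in by_metric.items():
            for _, r in rep.pairwise.iterrows():
                rows.append(
                    {
                        "device": device,
                        "metric": metric,
                        "pair": r["pair"],
                        "t": r["t"],
                        "p": r["p"],
                        "alpha_adjusted": r["alpha_adjusted"],
                        "significant": r["significant"],
                        "anova_F": rep.F,
                        "anova_p": rep.p,
                        "best_group": rep.best_group,
                    }
                )
    return pd.DataFrame(rows)


def _write_report(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.observations.to_csv(out_dir / "observations.csv", index=False)
    report.metrics.to_csv(out_dir / "metrics.csv", index=False)
    _comparison_frame(report.model_comparisons).to_csv(
        out_dir / "model_comparison.csv", index=False
    )
    if report.device_comparison is not None:
        dc = report.device_comparison
        dc.pairwise.assign(anova_F=dc.F, anova_p=dc.p, best_group=dc.best_group).to_csv(
            out_dir / "device_comparison.csv", index=False
        )
    (out_dir / "exclusions.log").write_text("\n".join(report.exclusion_log) + "\n")
    cfg = dataclasses.asdict(report.config)
    cfg["out_dir"] = str(cfg["out_dir"])
    (out_dir / "run.json").write_text(
        json.dumps(
            {
                "version": report.version,
                "seed": report.config.seed,
                "n_analysed_trials": report.n_analysed_trials,
                "config": cfg,
            },
            indent=2,
            default=str,
        )
    )
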