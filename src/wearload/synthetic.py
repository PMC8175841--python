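"""Synthetic gait / anti-gravity-treadmill data generator.

Emulates the study design end-to-end so every downstream stage is testable
without any download: 12 participants x (6 bodyweight-support levels:
30-110% of body weight) x (3 belt speeds: 5, 8, 12 km/h), 90-s trials,
wearables sampled at 50 Hz and the treadmill force plate at 128 Hz.

Two levels of fidelity are provided:

* :func:`simulate_summary_dataset` draws per-trial (x, y) mean load-rate
  pairs directly from the random-intercept-and-slope generative model
  ``y = alpha + beta*x + a_i + b_i*x + eps`` — the process the validation
  stage is meant to recover.
* :func:`simulate_trial` synthesises raw signals: a periodic vertical
  ground-reaction-force waveform (dual-peak at walking speed, single-peak
  impulses when running) whose per-stride mean equals the supported body
  weight, plus wearable acceleration channels derived from it via
  Newton's second law, attenuated, mixed onto three axes, offset by
  gravity and corrupted with sensor noise.

The waveforms are deliberately minimal: they reproduce the features the
pipeline is sensitive to (periodicity, supported-weight conservation,
sharpness growing with speed, two gait regimes) and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .signal_io import STANDARD_GRAVITY, AccelSeries, ForceSeries

__all__ = [
    "SPEEDS_KMH",
    "BODYWEIGHT_PCTS",
    "TrialCondition",
    "ParticipantProfile",
    "SimulationConfig",
    "DeviceSpec",
    "TrialBundle",
    "study_conditions",
    "make_roster",
    "draw_profiles",
    "simulate_summary_dataset",
    "simulate_trial",
    "grf_waveform",
]

SPEEDS_KMH = (5.0, 8.0, 12.0)
BODYWEIGHT_PCTS = (30.0, 60.0, 80.0, 90.0, 100.0, 110.0)

#: wearable axis mixing: mostly vertical, small fore-aft and mediolateral parts
_AXIS_MIX = np.array([0.15, 0.10, 0.9837])
_AXIS_MIX = _AXIS_MIX / np.linalg.norm(_AXIS_MIX)

_RUN_SPEED_THRESHOLD_KMH = 6.5  # walk/run transition: dual-peak below, impulsive above


@dataclass(frozen=True, order=True)
class TrialCondition:
    """One cell of the factorial design: supported bodyweight percent x belt speed."""

    bodyweight_pct: float
    speed_kmh: float

    def __post_init__(self) -> None:
        # 0 is allowed (full unweighting) for synthetic edge cases; the study
        # design itself spans 30-110%
        if not (0.0 <= self.bodyweight_pct <= 110.0):
            raise UsageError(f"bodyweight_pct out of [0, 110]: {self.bodyweight_pct}")
        if self.speed_kmh <= 0:
            raise UsageError(f"speed_kmh must be > 0: {self.speed_kmh}")


@dataclass
class ParticipantProfile:
    """Subject-level truth: mass, random regression effects and gait plumbing.

    ``random_intercept_a`` (N/s) and ``random_slope_b`` (dimensionless) are
    the subject's deviations from the population regression line;
    ``attenuation`` scales upper-body acceleration amplitude relative to
    the ground reaction force (soft-tissue/posture damping).
    """

    participant_id: int
    mass: float  # kg
    random_intercept_a: float = 0.0
    random_slope_b: float = 0.0
    step_freq_base: float = 1.4  # Hz at zero speed; affine in speed
    attenuation: float = 0.8

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise UsageError(f"mass must be > 0 kg: {self.mass}")
        if not (0.0 < self.attenuation <= 1.0):
            raise UsageError(f"attenuation out of (0, 1]: {self.attenuation}")
        if self.step_freq_base <= 0:
            raise UsageError(f"step_freq_base must be > 0: {self.step_freq_base}")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults replicate the study conditions.

    The fixed effects and variance components are the generative truth of
    the random-intercept-and-slope model; ``x_scale``/``x_sigma`` set the
    lognormal distribution of the wearable-side load rate, with location
    increasing in both speed and supported bodyweight.
    """

    n_participants: int = 12
    fixed_intercept_alpha: float = 2000.0  # N/s
    fixed_slope_beta: float = 0.9
    sd_intercept: float = 1500.0  # N/s
    sd_slope: float = 0.20
    sd_residual: float = 2500.0  # N/s
    x_scale: float = 12000.0  # N/s, wearable load-rate scale at 8 km/h, 100% bw
    x_sigma: float = 0.25  # lognormal shape of trial-to-trial spread
    wearable_rate: float = 50.0  # Hz
    forceplate_rate: float = 128.0  # Hz
    trial_duration_s: float = 90.0
    accel_noise_sd: float = 0.3  # m/s^2 per axis
    attenuation_jitter: float = 0.12  # lognormal sigma of per-trial coupling variation
    mass_mean: float = 71.0  # kg, cohort body mass
    mass_sd: float = 9.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise UsageError("n_participants must be >= 1")
        for name in ("sd_intercept", "sd_slope", "sd_residual", "accel_noise_sd",
                     "attenuation_jitter"):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be >= 0")
        for name in ("wearable_rate", "forceplate_rate", "x_scale"):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be > 0")
        if self.trial_duration_s <= 0:
            raise UsageError("trial_duration_s must be > 0")


@dataclass(frozen=True)
class DeviceSpec:
    """A simulated wearable: name, attenuation multiplier and noise override."""

    name: str = "wearable"
    attenuation_scale: float = 1.0  # multiplies the participant's attenuation
    noise_sd: float | None = None  # m/s^2; None -> config.accel_noise_sd


@dataclass
class TrialBundle:
    """Raw signals for one (participant, condition) trial."""

    profile: ParticipantProfile
    condition: TrialCondition
    wearable_series: dict[str, AccelSeries]
    forceplate_series: ForceSeries


def study_conditions() -> list[TrialCondition]:
    """The full 6 x 3 factorial design (18 conditions)."""
    return [
        TrialCondition(bodyweight_pct=p, speed_kmh=s)
        for p in BODYWEIGHT_PCTS
        for s in SPEEDS_KMH
    ]


def make_roster(
    n_participants: int,
    conditions: list[TrialCondition] | None = None,
    overrides: dict[int, list[TrialCondition]] | None = None,
) -> list[tuple[int, TrialCondition]]:
    """Planned trial list: full cross product, with per-participant overrides.

    ``overrides`` maps a participant id (1-based) to the subset of conditions
    that participant actually runs.  Ordering is deterministic:
    (participant, bodyweight_pct, speed_kmh).
    """
    if n_participants < 1:
        raise UsageError("n_participants must be >= 1")
    conditions = list(conditions) if conditions is not None else study_conditions()
    if not conditions:
        raise UsageError("conditions must be non-empty")
    overrides = overrides or {}
    ids = list(range(1, n_participants + 1))
    unknown = set(overrides) - set(ids)
    if unknown:
        raise UsageError(f"override references unknown participant(s): {sorted(unknown)}")
    roster = []
    for pid in ids:
        conds = overrides.get(pid, conditions)
        for cond in sorted(conds):
            roster.append((pid, cond))
    return roster


def draw_profiles(config: SimulationConfig, rng: np.random.Generator | None = None
                  ) -> dict[int, ParticipantProfile]:
    """Draw subject-level truth for every participant, reproducibly from the seed."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    profiles = {}
    for pid in range(1, config.n_participants + 1):
        mass = float(np.clip(rng.normal(config.mass_mean, config.mass_sd), 45.0, 110.0))
        profiles[pid] = ParticipantProfile(
            participant_id=pid,
            mass=mass,
            random_intercept_a=float(rng.normal(0.0, config.sd_intercept)),
            random_slope_b=float(rng.normal(0.0, config.sd_slope)),
            step_freq_base=float(np.clip(rng.normal(1.4, 0.1), 1.0, 1.8)),
            attenuation=float(np.clip(rng.normal(0.75, 0.08), 0.4, 1.0)),
        )
    return profiles


def _x_location(config: SimulationConfig, cond: TrialCondition) -> float:
    # load-rate scale grows with belt speed and supported weight
    return config.x_scale * (cond.speed_kmh / 8.0) * (0.4 + 0.6 * cond.bodyweight_pct / 100.0)


def simulate_summary_dataset(
    config: SimulationConfig,
    roster: list[tuple[int, TrialCondition]] | None = None,
) -> pd.DataFrame:
    """Observation table drawn from the random-intercept-and-slope model.

    For each roster row, x is lognormal with condition-dependent location
    (increasing in speed and bodyweight), and
    ``y = alpha + beta*x + a_i + b_i*x + eps``, with the per-participant
    effects drawn once and reused across that participant's rows.

    Returns a DataFrame with columns ``participant_id, bodyweight_pct,
    speed_kmh, x, y``.
    """
    config.validate()
    roster = roster if roster is not None else make_roster(config.n_participants)
    if not roster:
        raise UsageError("roster must be non-empty")
    rng = np.random.default_rng(config.seed)
    pids = sorted({pid for pid, _ in roster})
    effects = {
        pid: (
            float(rng.normal(0.0, config.sd_intercept)),
            float(rng.normal(0.0, config.sd_slope)),
        )
        for pid in pids
    }
    rows = []
    for pid, cond in roster:
        a_i, b_i = effects[pid]
        loc = _x_location(config, cond)
        x = float(loc * rng.lognormal(-0.5 * config.x_sigma**2, config.x_sigma))
        mean_y = (
            config.fixed_intercept_alpha + config.fixed_slope_beta * x + a_i + b_i * x
        )
        # load rates are positive: left-truncate the residual at -mean_y
        # (affects well under 1% of draws at the default noise levels)
        y = mean_y + float(rng.normal(0.0, config.sd_residual))
        for _ in range(100):
            if y > 0 or config.sd_residual == 0:
                break
            y = mean_y + float(rng.normal(0.0, config.sd_residual))
        y = max(y, 1e-6)
        rows.append(
            {
                "participant_id": pid,
                "bodyweight_pct": cond.bodyweight_pct,
                "speed_kmh": cond.speed_kmh,
                "x": x,
                "y": y,
            }
        )
    return pd.DataFrame(rows)


def _step_frequency(profile: ParticipantProfile, speed_kmh: float) -> float:
    # affine cadence model: ~2.0 Hz at 5 km/h up to ~2.8 Hz at 12 km/h
    return profile.step_freq_base + 0.12 * speed_kmh


def _duty_factor(speed_kmh: float) -> float:
    # fraction of the step cycle with foot-floor contact when running
    return float(np.clip(1.1 - 0.055 * speed_kmh, 0.30, 0.95))


def grf_waveform(t: np.ndarray, condition: TrialCondition, profile: ParticipantProfile) -> np.ndarray:
    """Periodic vertical ground-reaction force (N) at times ``t`` (s).

    The per-cycle time average equals the supported weight
    ``(bodyweight_pct/100) * mass * g`` exactly, because each shape
    function has unit mean over the step cycle.  Walking (below 6.5 km/h)
    uses a smooth dual-peak shape; running uses raised-cosine impulses
    separated by flight phases, sharper at higher speed.
    """
    supported = condition.bodyweight_pct / 100.0 * profile.mass * STANDARD_GRAVITY
    f_step = _step_frequency(profile, condition.speed_kmh)
    phase = np.mod(t * f_step, 1.0)
    if condition.speed_kmh < _RUN_SPEED_THRESHOLD_KMH:
        # continuous double-support loading with an M-shaped profile; both
        # harmonics have zero mean so the cycle average is exactly `supported`
        shape = 1.0 + 0.15 * np.cos(2 * np.pi * phase) + 0.35 * np.cos(4 * np.pi * phase)
    else:
        duty = _duty_factor(condition.speed_kmh)
        shape = np.where(
            phase < duty,
            (1.0 - np.cos(2 * np.pi * phase / duty)) / duty,
            0.0,
        )
    return supported * shape


def _trial_rng(profile: ParticipantProfile, condition: TrialCondition,
               config: SimulationConfig) -> np.random.Generator:
    # per-trial stream independent of call order
    key = (
        int(config.seed) % (2**31),
        int(profile.participant_id),
        int(round(condition.bodyweight_pct * 10)),
        int(round(condition.speed_kmh * 10)),
    )
    return np.random.default_rng(key)


def simulate_trial(
    profile: ParticipantProfile,
    condition: TrialCondition,
    config: SimulationConfig,
    devices: list[DeviceSpec] | None = None,
) -> TrialBundle:
    """Synthesise raw signals for one trial.

    The force plate samples the ground-reaction waveform at
    ``forceplate_rate``.  Each wearable carries the same waveform divided
    by body mass, scaled by the participant/device attenuation, mixed onto
    three axes (mostly vertical), offset by gravity on the vertical axis
    and corrupted with white sensor noise, sampled at ``wearable_rate``.
    """
    config.validate()
    devices = devices if devices is not None else [DeviceSpec()]
    rng = _trial_rng(profile, condition, config)

    t_force = np.arange(int(config.trial_duration_s * config.forceplate_rate)) / config.forceplate_rate
    force = grf_waveform(t_force, condition, profile)
    force_series = ForceSeries(
        timestamps=t_force, values=force, calibrated=True,
        nominal_rate=config.forceplate_rate,
    )

    t_wear = np.arange(int(config.trial_duration_s * config.wearable_rate)) / config.wearable_rate
    accel_mag = grf_waveform(t_wear, condition, profile) / profile.mass
    wearables = {}
    for dev in devices:
        att = profile.attenuation * dev.attenuation_scale
        if config.attenuation_jitter > 0:
            # day-to-day coupling variation (strap tension, posture, tissue
            # motion): a mean-one multiplicative factor drawn once per trial
            att *= rng.lognormal(
                -0.5 * config.attenuation_jitter**2, config.attenuation_jitter
            )
        noise_sd = dev.noise_sd if dev.noise_sd is not None else config.accel_noise_sd
        signal = att * accel_mag
        channels = np.outer(signal, _AXIS_MIX)
        channels[:, 2] += STANDARD_GRAVITY
        if noise_sd > 0:
            channels = channels + rng.normal(0.0, noise_sd, size=channels.shape)
        wearables[dev.name] = AccelSeries(
            timestamps=t_wear,
            ax=channels[:, 0],
            ay=channels[:, 1],
            az=channels[:, 2],
            device_id=dev.name,
            nominal_rate=config.wearable_rate,
        )
    return TrialBundle(
        profile=profile,
        condition=condition,
        wearable_series=wearables,
        forceplate_series=force_series,
    )
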