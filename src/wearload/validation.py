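"""Model fitting and bootstrap cross-validated agreement statistics.

The observation table pairs, per trial and device, the wearable-estimated
mean load rate (x, the predictor) with the force-plate value (y, the
response).  Three nested specifications are fitted by maximum likelihood:

* M1 — fixed effects only: ``y = alpha + beta*x``
* M2 — adds a per-participant random intercept ``a_i``
* M3 — adds random intercept and slope ``a_i + b_i*x``

Agreement is summarised by R^2 (squared Pearson correlation between the
conditional predictions and the observed values — the one definition that
puts M1-M3 on a single scale) and RMSER, the root-mean-squared error
divided by the mean observed force-plate load rate.

Uncertainty comes from bootstrap cross-validation: B resamples of the
rows with replacement, a fresh fit on each resample, and evaluation on
the out-of-bag rows (rows never drawn).  Out-of-bag rows belonging to a
participant absent from the resample are predicted from fixed effects
alone.  Confidence intervals are 2.5/97.5 percentiles of the B values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConvergenceError, InsufficientDataError, UsageError
from .synthetic import TrialCondition

__all__ = [
    "MODEL_SPECS",
    "ExclusionRule",
    "FittedModel",
    "BootstrapResult",
    "apply_exclusions",
    "fit_model",
    "predict",
    "agreement_metrics",
    "bootstrap_validate",
]

MODEL_SPECS = ("M1", "M2", "M3")

#: relative residual threshold below which data are treated as exactly linear
_PERFECT_FIT_RTOL = 1e-12


@dataclass(frozen=True)
class ExclusionRule:
    """Drop a whole participant, or one participant's trials at one speed."""

    participant_id: int
    speed_kmh: float | None = None  # None -> all of the participant's trials
    reason: str = "outlier"


def apply_exclusions(
    planned: list[tuple[int, TrialCondition]],
    completion: dict[int, list[TrialCondition]] | None = None,
    exclusions: list[ExclusionRule] | None = None,
) -> tuple[list[tuple[int, TrialCondition]], list[str]]:
    """Reduce the planned roster to the analysed trial list.

    ``completion`` maps a participant to the conditions actually completed
    (participants absent from the map are assumed complete).  ``exclusions``
    then removes whole participants or (participant, speed) subsets.
    Returns the surviving trials and a log naming every removed trial and
    its rule; a rule matching nothing is logged as a warning, not an error.
    """
    completion = completion or {}
    exclusions = exclusions or []
    log: list[str] = []

    surviving = []
    for pid, cond in planned:
        if pid in completion and cond not in completion[pid]:
            log.append(f"not completed: participant {pid}, {cond.bodyweight_pct:g}% at {cond.speed_kmh:g} km/h")
            continue
        surviving.append((pid, cond))

    for rule in exclusions:
        matched = [
            (pid, cond)
            for pid, cond in surviving
            if pid == rule.participant_id
            and (rule.speed_kmh is None or cond.speed_kmh == rule.speed_kmh)
        ]
        if not matched:
            log.append(f"warning: rule {rule} matched no trials")
            continue
        for pid, cond in matched:
            log.append(
                f"excluded ({rule.reason}): participant {pid}, "
                f"{cond.bodyweight_pct:g}% at {cond.speed_kmh:g} km/h"
            )
        surviving = [tc for tc in surviving if tc not in matched]
    return surviving, log


@dataclass
class FittedModel:
    """Fixed effects, predicted random effects and variance components."""

    alpha: float  # N/s
    beta: float  # dimensionless
    random_effects: dict  # participant -> (a_i, b_i); empty for M1
    var_components: dict  # var_intercept, var_slope, var_residual
    spec: str
    converged: bool = True
    loglike: float | None = None
    alpha_se: float | None = None  # standard errors of the fixed effects
    beta_se: float | None = None


def _check_table(table: pd.DataFrame, spec: str) -> None:
    if spec not in MODEL_SPECS:
        raise UsageError(f"unknown model spec {spec!r}; one of {MODEL_SPECS}")
    if len(table) == 0:
        raise InsufficientDataError("empty observation table")
    if spec != "M1" and table["participant_id"].nunique() < 2:
        raise InsufficientDataError(
            f"{spec} needs >= 2 participants, got {table['participant_id'].nunique()}"
        )


def fit_model(table: pd.DataFrame, spec: str = "M3") -> FittedModel:
    """Fit one model specification by maximum likelihood.

    ``table`` needs columns ``participant_id``, ``x``, ``y``.  M1 is
    ordinary least squares; M2/M3 are linear mixed models (ML, not REML,
    so the nested specifications are comparable).  Perfectly linear data
    short-circuit to the exact line with zero variance components, where
    the mixed-model profiled likelihood is undefined.
    """
    _check_table(table, spec)
    x = table["x"].to_numpy(dtype=float)
    y = table["y"].to_numpy(dtype=float)

    ols = sm.OLS(y, sm.add_constant(x)).fit()
    sse = float(np.sum(ols.resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if spec == "M1" or sse <= _PERFECT_FIT_RTOL * max(tss, 1.0):
        re = {}
        if spec != "M1":
            re = {pid: (0.0, 0.0) for pid in table["participant_id"].unique()}
        return FittedModel(
            alpha=float(ols.params[0]),
            beta=float(ols.params[1]),
            random_effects=re,
            var_components={
                "var_intercept": 0.0,
                "var_slope": 0.0,
                "var_residual": sse / max(len(table) - 2, 1),
            },
            spec=spec,
            loglike=float(ols.llf),
            alpha_se=float(ols.bse[0]),
            beta_se=float(ols.bse[1]),
        )

    # rescale both variables by the mean |x| so the random-intercept and
    # random-slope variances are of comparable magnitude; load rates are
    # O(10^4) N/s and slopes O(1), which otherwise stalls the optimiser
    s = float(np.mean(np.abs(x))) or 1.0
    xs, ys = x / s, y / s
    groups = table["participant_id"].to_numpy()
    exog = np.column_stack([np.ones_like(xs), xs])
    exog_re = exog if spec == "M3" else np.ones((len(xs), 1))
    # the ML log-likelihood of a mixed model can never fall below the nested
    # OLS fit; an "optimum" that does is an optimizer failure, so cascade
    # through optimizers and keep the best valid solution
    ols_scaled_llf = float(sm.OLS(ys, exog).fit().llf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(ys, exog, groups=groups, exog_re=exog_re)
        result, last_exc = None, None
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                candidate = model.fit(reml=False, maxiter=200, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if not np.all(np.isfinite(np.asarray(candidate.params, dtype=float))):
                continue
            if not np.isfinite(candidate.llf):
                continue
            if result is None or candidate.llf > result.llf:
                result = candidate
            if result.llf >= ols_scaled_llf - 1e-6 * max(abs(ols_scaled_llf), 1.0):
                break
        if result is None:
            raise ConvergenceError(f"{spec} fit failed: {last_exc}")
        if result.llf < ols_scaled_llf - 0.05 * max(abs(ols_scaled_llf), 1.0):
            raise ConvergenceError(
                f"{spec} fit is worse than the nested OLS fit "
                f"(llf {result.llf:.3f} < {ols_scaled_llf:.3f}); singular or failed"
            )

        fe = np.asarray(result.fe_params, dtype=float)
        cov_re = np.asarray(result.cov_re, dtype=float)
        bse_fe = np.asarray(result.bse_fe, dtype=float)
        try:
            blups = result.random_effects
        except (ValueError, np.linalg.LinAlgError):
            # a random-effect variance collapsed to zero (singular cov_re);
            # the corresponding BLUPs are identically zero
            blups = {pid: np.zeros(2 if spec == "M3" else 1) for pid in np.unique(groups)}
    var_intercept = float(cov_re[0, 0]) * s * s
    var_slope = float(cov_re[1, 1]) if spec == "M3" and cov_re.shape[0] >= 2 else 0.0
    random_effects = {}
    for pid, eff in blups.items():
        eff = np.asarray(eff, dtype=float)
        a_i = float(eff[0]) * s
        b_i = float(eff[1]) if spec == "M3" and eff.size > 1 else 0.0
        random_effects[pid] = (a_i, b_i)
    return FittedModel(
        alpha=float(fe[0]) * s,
        beta=float(fe[1]),
        random_effects=random_effects,
        var_components={
            "var_intercept": max(var_intercept, 0.0),
            "var_slope": max(var_slope, 0.0),
            "var_residual": float(result.scale) * s * s,
        },
        spec=spec,
        converged=bool(getattr(result, "converged", True)),
        loglike=float(result.llf),
        alpha_se=float(bse_fe[0]) * s,
        beta_se=float(bse_fe[1]),
    )


def predict(model: FittedModel, table: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Conditional predictions (fixed + predicted random effects).

    Rows whose participant has no predicted random effects — e.g. a
    participant absent from a bootstrap resample — fall back to the fixed
    effects alone.  Returns the predictions and the count of such rows.
    """
    x = table["x"].to_numpy(dtype=float)
    pred = model.alpha + model.beta * x
    n_fixed_only = 0
    if model.random_effects:
        pids = table["participant_id"].to_numpy()
        for i, pid in enumerate(pids):
            eff = model.random_effects.get(pid)
            if eff is None:
                n_fixed_only += 1
            else:
                pred[i] += eff[0] + eff[1] * x[i]
    return pred, n_fixed_only


def agreement_metrics(observed, predicted) -> tuple[float | None, float]:
    """(R^2, RMSER) between observed and predicted load rates.

    R^2 is the squared Pearson correlation; it is undefined (None) when
    either vector has zero variance.  RMSER = sqrt(mean squared error) /
    mean(observed) and is always computed.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise UsageError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise InsufficientDataError("need >= 2 observations for agreement metrics")
    mean_obs = obs.mean()
    if mean_obs == 0.0:
        raise UsageError("mean of observed values is zero; RMSER undefined")
    rmser = float(np.sqrt(np.mean((obs - pred) ** 2)) / mean_obs)
    so, sp = obs.std(), pred.std()
    if so == 0.0 or sp == 0.0:
        return None, rmser
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r * r, rmser


@dataclass
class BootstrapResult:
    """B out-of-bag (R^2, RMSER) pairs with means and 95% percentile CIs."""

    r2_samples: np.ndarray
    rmser_samples: np.ndarray
    r2_mean: float
    r2_ci: tuple[float, float]
    rmser_mean: float
    rmser_ci: tuple[float, float]
    B: int
    seed: int
    spec: str
    stratum: str = "overall"
    log: list = field(default_factory=list)

    @classmethod
    def from_samples(cls, r2, rmser, B, seed, spec, stratum="overall", log=None):
        r2 = np.asarray(r2, dtype=float)
        rmser = np.asarray(rmser, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN slices on degenerate strata
            return cls(
                r2_samples=r2,
                rmser_samples=rmser,
                r2_mean=float(np.nanmean(r2)),
                r2_ci=(float(np.nanpercentile(r2, 2.5)), float(np.nanpercentile(r2, 97.5))),
                rmser_mean=float(np.nanmean(rmser)),
                rmser_ci=(
                    float(np.nanpercentile(rmser, 2.5)),
                    float(np.nanpercentile(rmser, 97.5)),
                ),
                B=int(B),
                seed=int(seed),
                spec=spec,
                stratum=stratum,
                log=list(log or []),
            )


def _bootstrap_one_stratum(
    table: pd.DataFrame,
    spec: str,
    B: int,
    seed: int,
    rng: np.random.Generator,
    stratum: str,
    cluster: bool,
    max_redraws: int = 50,
) -> BootstrapResult:
    n = len(table)
    idx_all = np.arange(n)
    pids = table["participant_id"].to_numpy()
    unique_pids = np.unique(pids)
    r2s = np.empty(B)
    rmsers = np.empty(B)
    log: list[str] = []
    for b in range(B):
        for attempt in range(max_redraws):
            if cluster:
                drawn_pids = rng.choice(unique_pids, size=unique_pids.size, replace=True)
                idx = np.concatenate([idx_all[pids == p] for p in drawn_pids])
            else:
                idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(idx_all, np.unique(idx))
            if oob.size < 2:
                log.append(f"resample {b}: {oob.size} out-of-bag rows, redrawn")
                continue
            resample = table.iloc[idx].reset_index(drop=True)
            try:
                model = fit_model(resample, spec)
            except (ConvergenceError, InsufficientDataError) as exc:
                log.append(f"resample {b}: fit failed ({exc}), redrawn")
                continue
            oob_table = table.iloc[oob]
            pred, n_fixed_only = predict(model, oob_table)
            if n_fixed_only:
                log.append(
                    f"resample {b}: {n_fixed_only} out-of-bag rows predicted "
                    "from fixed effects only (participant absent from resample)"
                )
            r2, rmser = agreement_metrics(oob_table["y"].to_numpy(), pred)
            r2s[b] = np.nan if r2 is None else r2
            rmsers[b] = rmser
            break
        else:
            raise ConvergenceError(
                f"resample {b}: no usable resample after {max_redraws} redraws"
            )
    return BootstrapResult.from_samples(r2s, rmsers, B, seed, spec, stratum, log)


def bootstrap_validate(
    table: pd.DataFrame,
    spec: str = "M3",
    B: int = 1000,
    seed: int = 0,
    stratify_by: str | None = None,
    cluster: bool = False,
):
    """Bootstrap cross-validation of one model specification.

    Draws B resamples of the rows with replacement (or of whole
    participants when ``cluster=True``), refits ``spec`` on each, and
    evaluates R^2/RMSER on the out-of-bag rows.  ``stratify_by`` in
    {"speed", "device"} repeats the procedure independently within each
    stratum and returns a dict keyed by stratum label; otherwise a single
    :class:`BootstrapResult` is returned.  Fully reproducible under a
    fixed seed.
    """
    _check_table(table, spec)
    if B < 1:
        raise UsageError("B must be >= 1")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        return _bootstrap_one_stratum(table, spec, B, seed, rng, "overall", cluster)
    column = {"speed": "speed_kmh", "device": "device"}.get(stratify_by)
    if column is None or column not in table.columns:
        raise UsageError(f"cannot stratify by {stratify_by!r}")
    results = {}
    for value in sorted(table[column].unique()):
        sub = table[table[column] == value].reset_index(drop=True)
        label = f"{stratify_by}={value:g}" if isinstance(value, float) else f"{stratify_by}={value}"
        results[label] = _bootstrap_one_stratum(sub, spec, B, seed, rng, label, cluster)
    return results
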