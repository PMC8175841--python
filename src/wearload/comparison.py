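"""Comparison statistics over bootstrap metric distributions.

One-way ANOVA asks whether the mean bootstrapped R^2 (or RMSER) differs
between models or between devices; Bonferroni-corrected two-sample t
tests then locate the differences; a Kolmogorov-Smirnov check (against a
normal with the sample's own mean and SD — the Lilliefors caveat applies
and is accepted) screens the bootstrap distributions for normality.

The ANOVA treats the bootstrap values as plain samples, inheriting their
dependence structure; this mirrors the procedure it reproduces and is a
documented caveat, not an endorsement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import DegenerateSampleError, InsufficientDataError, UsageError

__all__ = [
    "ComparisonReport",
    "bonferroni_alpha",
    "anova_oneway",
    "pairwise_bonferroni",
    "ks_normality",
    "compare_groups",
]


def bonferroni_alpha(family_alpha: float, k: int) -> float:
    """Per-comparison significance threshold: family alpha divided by k comparisons."""
    if not (0.0 < family_alpha < 1.0):
        raise UsageError(f"family_alpha must be in (0, 1): {family_alpha}")
    if k < 1:
        raise UsageError(f"number of comparisons must be >= 1: {k}")
    return family_alpha / k


def _as_groups(groups) -> dict:
    if isinstance(groups, dict):
        out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        out = {f"group{i + 1}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}
    if len(out) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for name, v in out.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {name!r} has < 2 values")
    return out


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value over labelled samples."""
    g = _as_groups(groups)
    F, p = _st.f_oneway(*g.values())
    return float(F), float(p)


def pairwise_bonferroni(groups, family_alpha: float = 0.05) -> pd.DataFrame:
    """All unordered pairwise two-sample t tests with a Bonferroni threshold.

    Returns a DataFrame with columns ``pair, t, p, alpha_adjusted,
    significant``; ``significant`` is p < family_alpha / (number of pairs).
    """
    g = _as_groups(groups)
    pairs = list(combinations(sorted(g), 2))
    threshold = bonferroni_alpha(family_alpha, len(pairs))
    rows = []
    for a, b in pairs:
        t, p = _st.ttest_ind(g[a], g[b])
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "t": float(t),
                "p": float(p),
                "alpha_adjusted": threshold,
                "significant": bool(p < threshold),
            }
        )
    return pd.DataFrame(rows)


def ks_normality(sample) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD."""
    v = np.asarray(sample, dtype=float)
    if v.size < 5:
        raise InsufficientDataError(f"need >= 5 values for a KS check, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise DegenerateSampleError("constant sample: normality check undefined")
    stat, p = _st.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p)


@dataclass
class ComparisonReport:
    """ANOVA + Bonferroni pairwise comparisons + per-group normality checks."""

    groups: dict
    F: float
    p: float
    alpha_adjusted: float
    pairwise: pd.DataFrame
    normality: dict  # group -> (KS statistic, p)
    best_group: str | None = None


def compare_groups(groups, family_alpha: float = 0.05, higher_is_better: bool = True
                   ) -> ComparisonReport:
    """Full comparison of labelled metric samples (e.g. bootstrapped R^2 per model).

    Identifies the best group (highest mean when ``higher_is_better``, else
    lowest) only when every pairwise comparison involving it is significant.
    """
    g = _as_groups(groups)
    F, p = anova_oneway(g)
    pw = pairwise_bonferroni(g, family_alpha)
    normality = {}
    for name, v in g.items():
        try:
            normality[name] = ks_normality(v)
        except (DegenerateSampleError, InsufficientDataError):
            normality[name] = (np.nan, np.nan)
    means = {name: v.mean() for name, v in g.items()}
    candidate = (max if higher_is_better else min)(means, key=means.get)
    involved = pw[pw["pair"].str.contains(rf"(?:^|\s){candidate}(?:\s|$)")]
    best = candidate if bool(involved["significant"].all()) and len(involved) else None
    return ComparisonReport(
        groups=g,
        F=F,
        p=p,
        alpha_adjusted=pw["alpha_adjusted"].iloc[0] if len(pw) else family_alpha,
        pairwise=pw,
        normality=normality,
        best_group=best,
    )
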