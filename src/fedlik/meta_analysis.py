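"""Common-effect (fixed-effect) inverse-variance meta-analysis.

The comparator method: each site contributes only its coefficient estimate
and standard error; the pooled estimate is the inverse-variance weighted
mean

    w_i = 1 / SE_i^2,   pooled = sum(w_i * theta_i) / sum(w_i),
    SE(pooled) = 1 / sqrt(sum(w_i)),

one separate meta-analysis per model parameter.  Between-site heterogeneity
is assessed with Cochran's Q (chi-square with k-1 degrees of freedom under
homogeneity) and summarised by I^2, the proportion of total variation in
effects attributable to true heterogeneity rather than chance:

    Q = sum(w_i * (theta_i - pooled)^2),   I^2 = max(0, (Q - (k-1)) / Q).

Random-effects extensions are deliberately out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "pool_inverse_variance",
    "cochran_q",
    "i_squared",
    "heterogeneity_p",
    "forest_data",
]


@dataclass(frozen=True)
class StudyEstimate:
    """One site's coefficient (log-odds scale) and its standard error."""

    label: str
    estimate: float
    se: float

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"study {self.label!r}: se must be > 0, got {self.se}")


@dataclass
class MetaResult:
    pooled: float
    pooled_se: float
    ci: tuple[float, float]
    level: float
    labels: tuple[str, ...]
    weights: np.ndarray
    Q: float
    df: int
    p_heterogeneity: float
    i_squared: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema": "fedlik.meta_result/1",
            "pooled": self.pooled,
            "pooled_se": self.pooled_se,
            "ci": list(self.ci),
            "level": self.level,
            "labels": list(self.labels),
            "weights": self.weights.tolist(),
            "Q": self.Q,
            "df": self.df,
            "p_heterogeneity": self.p_heterogeneity,
            "i_squared": self.i_squared,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def cochran_q(studies: list[StudyEstimate], pooled: float) -> float:
    """Weighted sum of squared deviations of study estimates from the pooled
    effect, weights ``1/SE^2``."""
    if len(studies) < 2:
        raise ValueError("Cochran's Q needs at least two studies")
    w = np.array([1.0 / s.se**2 for s in studies])
    theta = np.array([s.estimate for s in studies])
    return float(np.sum(w * (theta - pooled) ** 2))


def i_squared(Q: float, k: int) -> float:
    """Proportion of total variation due to true heterogeneity:
    ``max(0, (Q - (k-1)) / Q)``, clamped at zero whenever Q <= k-1."""
    if k < 2:
        raise ValueError("I^2 needs at least two studies")
    if Q < 0:
        raise ValueError(f"Q must be >= 0, got {Q}")
    if Q == 0.0:
        return 0.0
    return float(max(0.0, (Q - (k - 1)) / Q))


def heterogeneity_p(Q: float, df: int) -> float:
    """Upper-tail chi-square probability of Q on ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(Q, df))


def pool_inverse_variance(
    studies: list[StudyEstimate], level: float = 0.95
) -> MetaResult:
    """Common-effect inverse-variance pooling with heterogeneity statistics.

    With a single study the pooled estimate is that study's estimate and the
    heterogeneity statistics degenerate (Q = 0, df = 0, p = 1, I^2 = 0).
    """
    if not studies:
        raise ValueError("need at least one study")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    w = np.array([1.0 / s.se**2 for s in studies])
    theta = np.array([s.estimate for s in studies])
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    k = len(studies)
    if k >= 2:
        Q = cochran_q(studies, pooled)
        df = k - 1
        p_het = heterogeneity_p(Q, df)
        i2 = i_squared(Q, k)
    else:
        Q, df, p_het, i2 = 0.0, 0, 1.0, 0.0
    return MetaResult(
        pooled=pooled,
        pooled_se=pooled_se,
        ci=(pooled - z * pooled_se, pooled + z * pooled_se),
        level=level,
        labels=tuple(s.label for s in studies),
        weights=w,
        Q=Q,
        df=df,
        p_heterogeneity=p_het,
        i_squared=i2,
    )


def forest_data(studies: list[StudyEstimate], meta: MetaResult) -> pd.DataFrame:
    """Forest-plot table: one row per study (estimate, Wald CI, weight %)
    plus the pooled row.  Study weight percentages sum to 100."""
    z = stats.norm.ppf(0.5 + meta.level / 2.0)
    wpct = 100.0 * meta.weights / meta.weights.sum()
    rows = [
        {
            "label": s.label,
            "estimate": s.estimate,
            "ci_lower": s.estimate - z * s.se,
            "ci_upper": s.estimate + z * s.se,
            "weight_pct": float(wp),
        }
        for s, wp in zip(studies, wpct)
    ]
    rows.append(
        {
            "label": "pooled (common effect)",
            "estimate": meta.pooled,
            "ci_lower": meta.ci[0],
            "ci_upper": meta.ci[1],
            "weight_pct": np.nan,
        }
    )
    return pd.DataFrame(rows)
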