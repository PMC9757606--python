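"""Frequentist random-effects pairwise meta-analysis.

Implements DerSimonian–Laird pooling with Cochran's Q and the H heterogeneity
index, plus comparison-adjusted funnel-plot coordinates.  All computation is
on the analysis scale (log OR or mean difference); odds-ratio intervals are
obtained by exponentiating the endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DataValidationError
from .preprocess import StudyEffect

Z975 = 1.959963984540054  # normal 97.5% critical value


@dataclass(frozen=True)
class PairwiseResult:
    """DL pooled effect with heterogeneity statistics for one comparison."""

    comparison: tuple[str, str]
    k: int
    pooled: float
    se: float
    ci95: tuple[float, float]
    tau2: float
    Q: float
    df: int
    H: float

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(point, lo, hi) exponentiated for dichotomous outcomes."""
        return (math.exp(self.pooled), math.exp(self.ci95[0]), math.exp(self.ci95[1]))


def h_index(Q: float, k: int) -> float:
    """Heterogeneity index H = sqrt(Q / max(1, k − 1)), floored at 1.

    Values above 3 indicate heterogeneity strong enough to trigger the
    leave-one-out sensitivity procedure.
    """
    if Q < 0:
        raise DataValidationError(f"Q must be >= 0, got {Q}")
    if k < 1:
        raise DataValidationError(f"k must be >= 1, got {k}")
    return max(1.0, math.sqrt(Q / max(1, k - 1)))


def dl_pool(effects: Sequence[StudyEffect]) -> PairwiseResult:
    """DerSimonian–Laird random-effects pooling of per-study effects.

    Fixed-effect weights ``w_i = 1/v_i`` give Cochran's
    ``Q = Σ w_i (y_i − ŷ_FE)²``; the moment estimator is
    ``τ² = max(0, (Q − df) / (Σw − Σw²/Σw))``; random-effects weights
    ``w*_i = 1/(v_i + τ²)`` give the pooled effect and its normal 95% CI.
    """
    if not effects:
        raise DataValidationError("dl_pool needs at least one study effect")
    comparisons = {e.comparison for e in effects}
    if len(comparisons) != 1:
        raise DataValidationError(f"mixed comparisons in dl_pool: {sorted(comparisons)}")
    comparison = effects[0].comparison
    k = len(effects)
    w = [1.0 / e.v for e in effects]
    sw = sum(w)
    y_fe = sum(wi * e.y for wi, e in zip(w, effects)) / sw
    Q = sum(wi * (e.y - y_fe) ** 2 for wi, e in zip(w, effects))
    df = k - 1
    if df > 0:
        c = sw - sum(wi**2 for wi in w) / sw
        tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    ws = [1.0 / (e.v + tau2) for e in effects]
    sws = sum(ws)
    pooled = sum(wi * e.y for wi, e in zip(ws, effects)) / sws
    se = math.sqrt(1.0 / sws)
    return PairwiseResult(
        comparison=comparison,
        k=k,
        pooled=pooled,
        se=se,
        ci95=(pooled - Z975 * se, pooled + Z975 * se),
        tau2=tau2,
        Q=Q,
        df=df,
        H=h_index(Q, k),
    )


def funnel_data(
    effects: Sequence[StudyEffect],
    pooled: PairwiseResult,
    sort_by_se: bool = False,
) -> pd.DataFrame:
    """Comparison-adjusted funnel coordinates: per-study effect, standard
    error, and effect centered on the comparison's pooled estimate.  Plot
    ``se`` on an inverted axis against ``centered``; asymmetry about zero
    suggests small-study/publication bias."""
    if not effects:
        raise DataValidationError("funnel_data needs at least one study effect")
    rows = [
        {
            "study_id": e.study_id,
            "y": e.y,
            "v": e.v,
            "se": e.se,
            "weight": 1.0 / (e.v + pooled.tau2),
            "centered": e.y - pooled.pooled,
        }
        for e in effects
    ]
    df = pd.DataFrame(rows)
    if sort_by_se:
        df = df.sort_values("se", ascending=False, kind="stable").reset_index(drop=True)
    return df
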