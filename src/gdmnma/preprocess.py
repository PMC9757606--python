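"""Summary-statistic conversion, arm pooling, and per-study effect sizes.

Trials in this literature frequently report skewed continuous outcomes as a
median with a range and/or interquartile range.  Before meta-analysis those
summaries are converted to a mean and standard deviation with the standard
closed forms:

* ``hozo`` (Hozo, Djulbegovic & Hozo 2005): mean ≈ (a + 2m + b) / 4 from the
  minimum *a*, median *m* and maximum *b*; SD ≈ range/4 for 15 < n ≤ 70,
  range/6 for n > 70, and the full small-sample formula for n ≤ 15.
* ``wan`` (Wan, Wang, Liu & Tong 2014): the same mean for range-only input,
  (q1 + m + q3)/3 for IQR-only input, and normal-quantile denominators
  2·Φ⁻¹((n − 0.375)/(n + 0.25)) for the range and
  2·Φ⁻¹((0.75n − 0.125)/(n + 0.25)) for the IQR.

Multiple arms on the same treatment are pooled with the n-weighted mean; the
default pooled SD is the n-weighted mean of arm SDs (see
:func:`pool_arms`), with a variance-preserving alternative behind
``sd_method="variance"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from scipy.stats import norm

from .dataio import ArmRecord, StudyRecord
from .errors import (
    DataValidationError,
    NonInformativeStudyError,
    UnsupportedInputError,
)


@dataclass(frozen=True)
class SummaryStats:
    """Arm-level summary: n plus mean/sd, or the quantile summaries
    (median with range and/or IQR) that can be converted to them."""

    n: int
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    minimum: float | None = None
    maximum: float | None = None

    def validate(self) -> None:
        if self.n <= 0:
            raise DataValidationError(f"n must be > 0, got {self.n}")
        qs = [q for q in (self.minimum, self.q1, self.median, self.q3, self.maximum)
              if q is not None]
        if qs != sorted(qs):
            raise DataValidationError(
                "quantile summaries must satisfy min <= q1 <= median <= q3 <= max"
            )


@dataclass(frozen=True)
class StudyEffect:
    """One study's contrast on the analysis scale (log OR or mean difference)."""

    study_id: str
    comparison: tuple[str, str]
    y: float
    v: float

    def __post_init__(self):
        if not (self.v > 0) or not math.isfinite(self.v):
            raise DataValidationError(
                f"study {self.study_id!r}: effect variance must be finite and > 0"
            )

    @property
    def se(self) -> float:
        return math.sqrt(self.v)


def median_to_mean_sd(s: SummaryStats, method: str = "wan") -> SummaryStats:
    """Estimate mean and SD from a median plus range and/or IQR.

    Returns a copy of ``s`` with ``mean`` and ``sd`` filled in.  When both
    the range and the IQR are present the ``wan`` method averages the two
    quantile-based SD estimators and uses the combined mean estimator
    (a + 2q1 + 2m + 2q3 + b)/8; ``hozo`` uses the range only.
    """
    s.validate()
    if s.median is None:
        raise UnsupportedInputError("median required for conversion")
    has_range = s.minimum is not None and s.maximum is not None
    has_iqr = s.q1 is not None and s.q3 is not None
    if not has_range and not has_iqr:
        raise UnsupportedInputError(
            "conversion needs a range (min, max) and/or an IQR (q1, q3)"
        )
    n, m = s.n, s.median
    if method == "hozo":
        if not has_range:
            raise UnsupportedInputError("hozo conversion needs the range (min, max)")
        a, b = s.minimum, s.maximum
        mean = (a + 2.0 * m + b) / 4.0
        rng = b - a
        if n <= 15:
            sd = math.sqrt(((a - 2.0 * m + b) ** 2 / 4.0 + rng**2) / 12.0)
        elif n <= 70:
            sd = rng / 4.0
        else:
            sd = rng / 6.0
    elif method == "wan":
        # Normal-quantile denominators; xi terms are 2*Phi^-1(.) factors.
        xi_range = 2.0 * norm.ppf((n - 0.375) / (n + 0.25))
        xi_iqr = 2.0 * norm.ppf((0.75 * n - 0.125) / (n + 0.25))
        if has_range and has_iqr:
            a, b, q1, q3 = s.minimum, s.maximum, s.q1, s.q3
            mean = (a + 2.0 * q1 + 2.0 * m + 2.0 * q3 + b) / 8.0
            sd = (b - a) / (2.0 * xi_range) + (q3 - q1) / (2.0 * xi_iqr)
        elif has_range:
            a, b = s.minimum, s.maximum
            mean = (a + 2.0 * m + b) / 4.0
            sd = (b - a) / xi_range
        else:
            q1, q3 = s.q1, s.q3
            mean = (q1 + m + q3) / 3.0
            sd = (q3 - q1) / xi_iqr
    else:
        raise UnsupportedInputError(f"unknown conversion method {method!r}")
    return replace(s, mean=mean, sd=max(sd, 0.0))


def pool_arms(arms: Sequence[SummaryStats], sd_method: str = "printed") -> SummaryStats:
    """Combine several arms (same treatment) into one summary.

    The pooled mean is the sample-size-weighted mean ``Σ x̄_j n_j / Σ n_j``.
    Two pooled-SD conventions are offered:

    * ``"printed"`` (default): the n-weighted mean of the arm SDs,
      ``Σ SD_j n_j / Σ n_j`` — the literal combination rule used in this
      workflow's source tables (its (SD_j + x̄_j) terms cancel the mean
      exactly, leaving the weighted SD average).
    * ``"variance"``: the conventional variance-preserving pooled SD, which
      also counts between-arm mean dispersion.
    """
    if not arms:
        raise DataValidationError("pool_arms needs at least one arm")
    for a in arms:
        a.validate()
        if a.mean is None or a.sd is None:
            raise DataValidationError("pool_arms needs mean, sd and n for every arm")
    n_tot = sum(a.n for a in arms)
    mean = sum(a.mean * a.n for a in arms) / n_tot
    if sd_method == "printed":
        sd = sum(a.sd * a.n for a in arms) / n_tot
    elif sd_method == "variance":
        if n_tot > 1:
            ss = sum((a.n - 1) * a.sd**2 + a.n * (a.mean - mean) ** 2 for a in arms)
            sd = math.sqrt(ss / (n_tot - 1))
        else:
            sd = arms[0].sd
    else:
        raise DataValidationError(f"unknown sd_method {sd_method!r}")
    return SummaryStats(n=n_tot, mean=mean, sd=sd)


def study_log_or(
    study: StudyRecord, pair: tuple[str, str], correction: float = 0.5
) -> StudyEffect:
    """Log odds ratio of ``pair[0]`` vs ``pair[1]`` from a study's 2×2 table.

    ``y = log[(a/b)/(c/d)]`` with ``v = 1/a + 1/b + 1/c + 1/d``.  If any cell
    is zero, ``correction`` (Haldane 0.5 by default) is added to all four
    cells of that study only.  A study with zero events — or zero
    non-events — in both arms is non-informative for the OR and raises
    :class:`NonInformativeStudyError` (it still enters the Bayesian
    arm-based likelihood).
    """
    arm1, arm2 = study.arm_for(pair[0]), study.arm_for(pair[1])
    if arm1.events is None or arm2.events is None:
        raise DataValidationError(
            f"study {study.study_id!r}: both arms must report events for an OR"
        )
    a, b = float(arm1.events), float(arm1.size - arm1.events)
    c, d = float(arm2.events), float(arm2.size - arm2.events)
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise NonInformativeStudyError(
            f"study {study.study_id!r}: no (or only) events in both arms;"
            " non-informative for OR"
        )
    if min(a, b, c, d) == 0:
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    y = math.log((a / b) / (c / d))
    v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return StudyEffect(study_id=study.study_id, comparison=pair, y=y, v=v)


def study_mean_diff(study: StudyRecord, pair: tuple[str, str]) -> StudyEffect:
    """Mean difference of ``pair[0]`` vs ``pair[1]``:
    ``y = x̄_1 − x̄_2``, ``v = sd_1²/n_1 + sd_2²/n_2``."""
    arm1, arm2 = study.arm_for(pair[0]), study.arm_for(pair[1])
    for arm in (arm1, arm2):
        if arm.mean is None or arm.sd is None:
            raise DataValidationError(
                f"study {study.study_id!r}, arm {arm.treatment!r}: mean/sd missing"
                " (convert quantile summaries first)"
            )
    y = arm1.mean - arm2.mean
    v = arm1.sd**2 / arm1.size + arm2.sd**2 / arm2.size
    return StudyEffect(study_id=study.study_id, comparison=pair, y=y, v=v)


def study_effect(
    study: StudyRecord, pair: tuple[str, str], measure: str, correction: float = 0.5
) -> StudyEffect:
    if measure == "OR":
        return study_log_or(study, pair, correction=correction)
    return study_mean_diff(study, pair)
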