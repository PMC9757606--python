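"""Synthetic arm-level RCT networks with known ground truth.

The generator emulates the structure of the gestational-diabetes evidence
base: a connected three-treatment network (metformin, insulin, glyburide)
with direct comparisons metformin–insulin (15 trials), glyburide–insulin
(10) and metformin–glyburide (4), per-arm sizes around 100 (≈5,800
participants over 29 two-arm trials), study-level IADPSG / non-IADPSG
labels, dichotomous outcomes ranging from rare (stillbirth-like, natural
zero cells) to common (cesarean-like), and continuous outcomes on the
gestational-weight-gain (kg) or birth-weight (g) scale, with a fraction of
studies reporting median/range/IQR summaries that are round-tripped through
the quantile-to-moment conversion.

For each trial on edge (A, B) a baseline is drawn (study log-odds or mean
``mu_i``), a trial-specific effect ``delta_i ~ Normal(d_B - d_A,
tau_true^2)``, and arm outcomes from the exact likelihood the analysis
assumes.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .dataio import (
    ArmRecord,
    DEFAULT_ORDER,
    IADPSG,
    NON_IADPSG,
    OutcomeDataset,
    StudyRecord,
    edge_key,
)
from .errors import DataValidationError
from .nma import NMAModelSpec
from .preprocess import SummaryStats, median_to_mean_sd

log = logging.getLogger(__name__)

#: Direct-comparison trial counts of the emulated 29-trial network.
PAPER_GEOMETRY: dict[tuple[str, str], int] = {
    ("metformin", "insulin"): 15,
    ("insulin", "glyburide"): 10,
    ("metformin", "glyburide"): 4,
}

#: True relative effects (log OR) emulating the neonatal-hypoglycemia
#: ordering metformin < insulin < glyburide: met vs ins OR 0.65
#: (log -0.431) and ins vs gly OR 0.63 (log -0.462).
HYPOGLYCEMIA_D_TRUE: dict[str, float] = {
    "metformin": -0.431,
    "insulin": 0.0,
    "glyburide": 0.462,
}

#: Baseline log-odds archetypes: rare events (stillbirth-like, ~0.5-2%)
#: exercise zero cells; common events (cesarean-like, ~20-50%) do not.
BASELINE_ARCHETYPES = {
    "rare": (-4.6, 0.5),
    "moderate": (-2.2, 0.4),
    "common": (-1.1, 0.5),
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth and design of one synthetic network."""

    seed: int
    measure: str = "OR"
    treatments: tuple[str, ...] = DEFAULT_ORDER
    d_true: Mapping[str, float] = field(
        default_factory=lambda: dict(HYPOGLYCEMIA_D_TRUE))
    tau_true: float = 0.15
    baseline_dist: tuple[float, float] = BASELINE_ARCHETYPES["common"]
    geometry: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(PAPER_GEOMETRY))
    size_range: tuple[int, int] = (50, 150)
    iadpsg_fraction: float = 0.5
    median_report_fraction: float = 0.0
    # continuous outcomes only: typical within-arm SD (e.g. 3 kg for total
    # gestational weight gain, 450 g for birth weight) with log-normal
    # between-arm spread
    arm_sd_typical: float = 3.0
    arm_sd_sigma: float = 0.2

    def validate(self) -> None:
        if self.tau_true < 0:
            raise DataValidationError("tau_true must be >= 0")
        if not (0 <= self.iadpsg_fraction <= 1):
            raise DataValidationError("iadpsg_fraction must be in [0, 1]")
        if not (0 <= self.median_report_fraction <= 1):
            raise DataValidationError("median_report_fraction must be in [0, 1]")
        if any(c < 0 for c in self.geometry.values()):
            raise DataValidationError("trial counts must be >= 0")
        if self.size_range[0] < 2 or self.size_range[1] < self.size_range[0]:
            raise DataValidationError("invalid size_range")
        for a, b in self.geometry:
            if a not in self.d_true or b not in self.d_true:
                raise DataValidationError(f"geometry edge ({a}, {b}) missing from d_true")

    def contrast(self, a: str, b: str) -> float:
        """True effect of a relative to b on the analysis scale."""
        return self.d_true[a] - self.d_true[b]

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "measure": self.measure,
            "treatments": list(self.treatments),
            "d_true": dict(self.d_true),
            "tau_true": self.tau_true,
            "baseline_dist": list(self.baseline_dist),
            "geometry": {f"{a}|{b}": c for (a, b), c in self.geometry.items()},
            "size_range": list(self.size_range),
            "iadpsg_fraction": self.iadpsg_fraction,
            "median_report_fraction": self.median_report_fraction,
            "arm_sd_typical": self.arm_sd_typical,
            "arm_sd_sigma": self.arm_sd_sigma,
        }


def _via_quantiles(mean: float, sd: float, n: int, rng) -> tuple[float, float]:
    """Emit an arm as median/range/IQR of its generating normal and convert
    back with the quantile method, emulating a trial that reports quantile
    summaries."""
    # expected order-statistic positions of the quartiles and extremes for a
    # normal sample of size n (the same finite-n constants the conversion
    # method is calibrated against)
    z_iqr = norm.ppf((0.75 * n - 0.125) / (n + 0.25))
    z_ext = norm.ppf((n - 0.375) / (n + 0.25))
    s = SummaryStats(
        n=n,
        median=mean,
        q1=mean - z_iqr * sd,
        q3=mean + z_iqr * sd,
        minimum=mean - z_ext * sd,
        maximum=mean + z_ext * sd,
    )
    conv = median_to_mean_sd(s, method="wan")
    return conv.mean, conv.sd


def generate_network(truth: SyntheticTruth) -> OutcomeDataset:
    """Draw one arm-level dataset from the ground truth.

    Edge iteration order and all random draws are fixed by the seed, so the
    result is fully reproducible; a zero-trial geometry yields a valid empty
    dataset."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    studies: list[StudyRecord] = []
    idx = 0
    for (a, b) in sorted(truth.geometry, key=lambda e: edge_key(*e)):
        lo_t, hi_t = edge_key(a, b)
        for _ in range(truth.geometry[(a, b)]):
            idx += 1
            sid = f"S{idx:02d}_{lo_t[:3]}_{hi_t[:3]}"
            mu = rng.normal(*truth.baseline_dist)
            delta = rng.normal(truth.contrast(hi_t, lo_t), truth.tau_true)
            n_lo = int(rng.integers(truth.size_range[0], truth.size_range[1] + 1))
            n_hi = int(rng.integers(truth.size_range[0], truth.size_range[1] + 1))
            criteria = IADPSG if rng.random() < truth.iadpsg_fraction else NON_IADPSG
            if truth.measure == "OR":
                arms = (
                    ArmRecord(sid, lo_t, n_lo,
                              events=int(rng.binomial(n_lo, expit(mu)))),
                    ArmRecord(sid, hi_t, n_hi,
                              events=int(rng.binomial(n_hi, expit(mu + delta)))),
                )
            else:
                sds = truth.arm_sd_typical * np.exp(
                    truth.arm_sd_sigma * rng.standard_normal(2))
                m_lo = rng.normal(mu, sds[0] / np.sqrt(n_lo))
                m_hi = rng.normal(mu + delta, sds[1] / np.sqrt(n_hi))
                if rng.random() < truth.median_report_fraction:
                    m_lo, sd_lo = _via_quantiles(m_lo, sds[0], n_lo, rng)
                    m_hi, sd_hi = _via_quantiles(m_hi, sds[1], n_hi, rng)
                    log.debug("study %s emitted via quantile summaries", sid)
                else:
                    sd_lo, sd_hi = sds
                arms = (
                    ArmRecord(sid, lo_t, n_lo, mean=float(m_lo), sd=float(sd_lo)),
                    ArmRecord(sid, hi_t, n_hi, mean=float(m_hi), sd=float(sd_hi)),
                )
            studies.append(StudyRecord(study_id=sid, arms=arms, criteria=criteria))
    outcome = "synthetic-" + ("dichotomous" if truth.measure == "OR" else "continuous")
    return OutcomeDataset(outcome=outcome, measure=truth.measure,
                          studies=tuple(studies)).validate()


def recovery_experiment(
    truth: SyntheticTruth,
    reps: int,
    spec: NMAModelSpec,
) -> pd.DataFrame:
    """Repeated generate → fit → summarize.

    Returns one row per basic contrast (each treatment vs the network
    reference) with posterior-median bias, RMSE, and the fraction of
    replications whose 95% CrI covers the truth.  Replication seeds are
    derived from ``truth.seed``/``spec.seed`` and kept below 2^31.
    """
    if reps < 1:
        raise DataValidationError("reps must be >= 1")
    from . import nma as _nma

    gen_seeds = np.random.SeedSequence(truth.seed).generate_state(reps) % (2**31)
    fit_seeds = np.random.SeedSequence(spec.seed).generate_state(reps) % (2**31)
    ref = None
    errors: dict[str, list[float]] = {}
    covered: dict[str, list[bool]] = {}
    for r in range(reps):
        ds = generate_network(replace(truth, seed=int(gen_seeds[r])))
        draws = _nma.fit(ds, replace(spec, seed=int(fit_seeds[r])))
        ref = draws.reference
        for t in draws.treatments:
            if t == ref:
                continue
            x = draws.contrast_draws((t, ref))
            lo, mid, hi = np.percentile(x, [2.5, 50.0, 97.5])
            true = truth.contrast(t, ref)
            errors.setdefault(t, []).append(float(mid) - true)
            covered.setdefault(t, []).append(bool(lo <= true <= hi))
    rows = []
    for t in errors:
        e = np.asarray(errors[t])
        rows.append(
            {
                "parameter": f"d[{t} vs {ref}]",
                "true": truth.contrast(t, ref),
                "bias": float(e.mean()),
                "rmse": float(np.sqrt(np.mean(e**2))),
                "coverage": float(np.mean(covered[t])),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
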