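"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import math
from dataclasses import replace

import pytest
from scipy.special import expit, logit

import gdmnma as g
from gdmnma.preprocess import study_log_or


def or_study(sid, r1, n1, r2, n2, t1="metformin", t2="insulin", criteria="unknown"):
    return g.StudyRecord(
        sid,
        (g.ArmRecord(sid, t1, n1, events=r1), g.ArmRecord(sid, t2, n2, events=r2)),
        criteria=criteria,
    )


def wmd_study(sid, m1, s1, n1, m2, s2, n2, t1="metformin", t2="insulin",
              criteria="unknown"):
    return g.StudyRecord(
        sid,
        (g.ArmRecord(sid, t1, n1, mean=m1, sd=s1),
         g.ArmRecord(sid, t2, n2, mean=m2, sd=s2)),
        criteria=criteria,
    )


@pytest.fixture
def toy_or_dataset():
    """Three two-arm dichotomous trials on one comparison."""
    studies = (
        or_study("T1", 10, 50, 15, 50),
        or_study("T2", 8, 40, 14, 45),
        or_study("T3", 12, 60, 20, 55),
    )
    return g.OutcomeDataset("toy", "OR", studies).validate()


@pytest.fixture
def network_or_dataset():
    """A small connected three-treatment network."""
    studies = (
        or_study("A1", 10, 100, 20, 100, "metformin", "insulin"),
        or_study("A2", 12, 110, 18, 105, "metformin", "insulin", criteria="IADPSG"),
        or_study("B1", 25, 100, 18, 100, "glyburide", "insulin", criteria="non-IADPSG"),
        or_study("B2", 22, 90, 15, 95, "glyburide", "insulin"),
        or_study("C1", 9, 80, 21, 85, "metformin", "glyburide", criteria="IADPSG"),
    )
    return g.OutcomeDataset("toy-network", "OR", studies).validate()


def planted_outlier_dataset(seed: int, k: int = 6, tau: float = 0.5,
                            sizes=(200, 400)):
    """Single-comparison network with one study whose log OR is placed
    exactly 5 marginal SDs (sqrt(v + tau^2)) below the true mean contrast,
    on the common-events side so its inverse-variance weight stays typical.
    Returns (dataset, outlier_study_id)."""
    truth = g.SyntheticTruth(seed=seed, geometry={("metformin", "insulin"): k},
                             tau_true=tau, size_range=sizes)
    ds = g.generate_network(truth)
    s = ds.studies[0]
    eff = study_log_or(s, ("metformin", "insulin"))
    target_y = truth.contrast("metformin", "insulin") - 5.0 * math.sqrt(eff.v + tau**2)
    a1, a2 = s.arms
    l1 = logit((a1.events + 0.5) / (a1.size + 1))
    ne = min(max(int(round(a2.size * expit(l1 - target_y))), 0), a2.size)
    planted = replace(s, arms=(a1, replace(a2, events=ne)))
    return replace(ds, studies=(planted,) + ds.studies[1:]), s.study_id


def fast_spec(measure="OR", seed=1, **kw):
    """Reduced sampler settings for unit tests."""
    kw.setdefault("chains", 2)
    kw.setdefault("burn_in", 500)
    kw.setdefault("samples", 1500)
    return g.spec_for_measure(measure, seed=seed, **kw)
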