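"""Per-outcome orchestration: main fit, heterogeneity-triggered sensitivity
analysis, diagnostic-criteria subgroup analysis, and report tables.

The workflow for one outcome is: DerSimonian–Laird pairwise meta-analysis on
every direct comparison, a network heterogeneity summary (the unweighted mean
of per-edge H indices), the Bayesian consistency fit with league table and
treatment ranking, and — when network H exceeds 3 — a greedy leave-one-out
sensitivity analysis that removes the study whose omission lowers H the most,
repeatedly, until H drops to the threshold or no admissible removal remains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nma
from .dataio import NetworkGeometry, OutcomeDataset, build_geometry, IADPSG, NON_IADPSG, UNKNOWN
from .errors import DataValidationError, NonInformativeStudyError
from .nma import (
    NMAModelSpec,
    PosteriorDraws,
    RankProbabilities,
    RelativeEffectSummary,
)
from .pairwise import PairwiseResult, dl_pool, funnel_data
from .preprocess import study_effect

log = logging.getLogger(__name__)


@dataclass
class EdgeAnalysis:
    """Pairwise result for one direct comparison, plus bookkeeping."""

    comparison: tuple[str, str]
    result: PairwiseResult | None
    effects: list
    excluded: list[str]  # non-informative studies (OR only)


@dataclass
class OutcomeBundle:
    """Everything computed for one outcome."""

    dataset: OutcomeDataset
    geometry: NetworkGeometry
    edge_analyses: dict[tuple[str, str], EdgeAnalysis]
    network_H: float
    draws: PosteriorDraws
    league: list[RelativeEffectSummary]
    ranks: RankProbabilities
    psrf: dict[str, float]


@dataclass
class SensitivityReport:
    initial_H: float
    threshold: float
    trace: list[tuple[str, float]]  # (omitted study, network H after omission)
    final_study_ids: tuple[str, ...]
    exhausted: bool
    bundle: OutcomeBundle | None


@dataclass
class SubgroupResult:
    label: str
    study_ids: tuple[str, ...]
    n_studies: int
    connected: bool
    bundle: OutcomeBundle | None
    edge_analyses: dict[tuple[str, str], EdgeAnalysis] = field(default_factory=dict)


def analyze_edges(ds: OutcomeDataset) -> dict[tuple[str, str], EdgeAnalysis]:
    """DL pairwise analysis on every direct comparison.  Comparisons are
    ordered later-vs-earlier reversed: effect of the registry-earlier
    treatment relative to the later one (Met vs Ins, Met vs Gly, Ins vs Gly),
    matching the reporting convention.  Studies non-informative for the OR
    (no events in either arm) are excluded here and listed."""
    geo = build_geometry(ds)
    out: dict[tuple[str, str], EdgeAnalysis] = {}
    for (a, b) in sorted(geo.edges):
        pair = (a, b)  # a vs b with a earlier in registry order
        effects, excluded = [], []
        for s in ds.studies:
            if a in s.treatments and b in s.treatments:
                try:
                    effects.append(study_effect(s, pair, ds.measure))
                except NonInformativeStudyError:
                    excluded.append(s.study_id)
        res = dl_pool(effects) if effects else None
        out[pair] = EdgeAnalysis(comparison=pair, result=res, effects=effects,
                                 excluded=excluded)
    return out


def network_h(ds: OutcomeDataset) -> float:
    """Network heterogeneity summary: unweighted mean of per-edge H indices
    (single-study edges contribute H = 1).  NaN when no edge is estimable —
    the 'not applicable' case for outcomes whose studies are all
    non-informative."""
    analyses = analyze_edges(ds)
    hs = [ea.result.H for ea in analyses.values() if ea.result is not None]
    return float(np.mean(hs)) if hs else float("nan")


def run_outcome(
    ds: OutcomeDataset,
    spec: NMAModelSpec,
    direction: str = "lower",
) -> OutcomeBundle:
    """Full per-outcome analysis: pairwise per edge, network H, Bayesian
    consistency fit, league table (Met vs Ins / Met vs Gly / Ins vs Gly row
    order), and rank probabilities."""
    ds.validate()
    edge_analyses = analyze_edges(ds)
    hs = [ea.result.H for ea in edge_analyses.values() if ea.result is not None]
    H = float(np.mean(hs)) if hs else float("nan")
    draws = nma.fit(ds, spec)
    league = nma.league_table(draws)
    ranks = nma.rank_probabilities(draws, direction=direction)
    return OutcomeBundle(
        dataset=ds,
        geometry=build_geometry(ds),
        edge_analyses=edge_analyses,
        network_H=H,
        draws=draws,
        league=league,
        ranks=ranks,
        psrf=nma.psrf(draws),
    )


def _admissible_removals(ds: OutcomeDataset) -> list[str]:
    """Studies whose removal keeps >= 2 studies on each edge they occupy."""
    from .dataio import edge_key

    geo = build_geometry(ds)
    ok = []
    for s in ds.studies:
        ts = s.treatments
        edges = [edge_key(ts[i], ts[j]) for i in range(len(ts))
                 for j in range(i + 1, len(ts))]
        if all(geo.edges[e] - 1 >= 2 for e in edges):
            ok.append(s.study_id)
    return ok


def sensitivity_leave_one_out(
    ds: OutcomeDataset,
    spec: NMAModelSpec,
    threshold: float = 3.0,
    direction: str = "lower",
    refit: bool = True,
) -> SensitivityReport:
    """Heterogeneity-triggered leave-one-out procedure.

    When the network H exceeds ``threshold`` (strictly), repeatedly omit the
    single study whose removal minimizes the recomputed network H, subject to
    every direct comparison retaining at least two studies and to H strictly
    decreasing, until H <= threshold or no admissible omission helps (then
    ``exhausted`` is set with the best-achieved H).  The reduced dataset is
    refit (pairwise + NMA) unless ``refit=False`` (omission trace only)."""
    ds.validate()
    initial_H = network_h(ds)
    trace: list[tuple[str, float]] = []
    cur = ds
    exhausted = False
    if math.isfinite(initial_H) and initial_H > threshold:
        H_cur = initial_H
        while H_cur > threshold:
            best_id, best_H = None, H_cur
            for sid in _admissible_removals(cur):
                H_try = network_h(cur.drop(sid))
                if math.isfinite(H_try) and H_try < best_H:
                    best_id, best_H = sid, H_try
            if best_id is None:
                exhausted = True
                break
            cur = cur.drop(best_id)
            trace.append((best_id, best_H))
            H_cur = best_H
    bundle = run_outcome(cur, spec, direction=direction) if (trace and refit) else None
    return SensitivityReport(
        initial_H=initial_H,
        threshold=threshold,
        trace=trace,
        final_study_ids=tuple(s.study_id for s in cur.studies),
        exhausted=exhausted,
        bundle=bundle,
    )


def subgroup_by_criteria(
    ds: OutcomeDataset,
    spec: NMAModelSpec,
    direction: str = "lower",
) -> list[SubgroupResult]:
    """Stratify by GDM diagnostic criteria (IADPSG vs older criteria) and
    refit each subgroup independently.  Studies with unknown criteria are
    excluded with a logged warning; a subgroup whose network is disconnected
    is reported pairwise-only with an explicit flag."""
    ds.validate()
    unknown = [s.study_id for s in ds.studies if s.criteria == UNKNOWN]
    if unknown:
        log.warning("subgroup analysis excludes %d studies with unknown criteria: %s",
                    len(unknown), unknown)
    results: list[SubgroupResult] = []
    for label in (IADPSG, NON_IADPSG):
        ids = tuple(s.study_id for s in ds.studies if s.criteria == label)
        if not ids:
            continue
        sub = ds.subset(ids)
        geo = build_geometry(sub)
        if geo.connected and len(sub.treatments) >= 2:
            bundle = run_outcome(sub, spec, direction=direction)
            results.append(SubgroupResult(label=label, study_ids=ids,
                                          n_studies=len(ids), connected=True,
                                          bundle=bundle))
        else:
            results.append(SubgroupResult(label=label, study_ids=ids,
                                          n_studies=len(ids), connected=False,
                                          bundle=None,
                                          edge_analyses=analyze_edges(sub)))
    return results


# ----------------------------------------------------------------------------
# report assembly


def league_rows(bundle: OutcomeBundle, outcome: str | None = None) -> pd.DataFrame:
    """Report-table rows for one outcome: comparison, effect type, posterior
    point estimate and 95% CrI, with network H and study/participant counts."""
    ds = bundle.dataset
    rows = []
    for summ in bundle.league:
        rows.append(
            {
                "outcome": outcome or ds.outcome,
                "H": round(bundle.network_H, 3) if math.isfinite(bundle.network_H) else None,
                "N_studies": len(ds.studies),
                "n_participants": ds.n_total,
                "comparison": f"{summ.pair[0]} vs {summ.pair[1]}",
                "effect_type": summ.scale,
                "point": summ.point,
                "ci_low": summ.cri95[0],
                "ci_high": summ.cri95[1],
                "significant": summ.significant,
            }
        )
    return pd.DataFrame(rows)


def funnel_rows(bundle: OutcomeBundle) -> pd.DataFrame:
    """Comparison-adjusted funnel coordinates for every direct comparison."""
    frames = []
    for pair, ea in bundle.edge_analyses.items():
        if ea.result is None:
            continue
        df = funnel_data(ea.effects, ea.result)
        df.insert(0, "comparison", f"{pair[0]} vs {pair[1]}")
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["comparison", "study_id", "y", "v", "se", "weight", "centered"])
    return pd.concat(frames, ignore_index=True)


def bundle_to_json(bundle: OutcomeBundle) -> dict:
    ds = bundle.dataset
    return {
        "outcome": ds.outcome,
        "measure": ds.measure,
        "N_studies": len(ds.studies),
        "n_participants": ds.n_total,
        "network_H": bundle.network_H if math.isfinite(bundle.network_H) else None,
        "edges": {
            f"{a} vs {b}": None
            if ea.result is None
            else {
                "k": ea.result.k,
                "pooled": ea.result.pooled,
                "ci95": list(ea.result.ci95),
                "tau2": ea.result.tau2,
                "Q": ea.result.Q,
                "H": ea.result.H,
                "excluded_non_informative": ea.excluded,
            }
            for (a, b), ea in bundle.edge_analyses.items()
        },
        "league": [
            {
                "pair": list(s.pair),
                "point": s.point,
                "cri95": list(s.cri95),
                "scale": s.scale,
                "significant": s.significant,
            }
            for s in bundle.league
        ],
        "rank_probabilities": {
            t: bundle.ranks.matrix[i].tolist()
            for i, t in enumerate(bundle.ranks.treatments)
        },
        "sucra": bundle.ranks.sucra,
        "psrf": bundle.psrf,
        "warnings": list(bundle.draws.warnings),
    }
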