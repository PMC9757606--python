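"""Arm-level data model, CSV input/output, and treatment-network geometry.

The unit of input is one row per study arm: a study identifier, the treatment
given to that arm, and either an event count (dichotomous outcomes, analysed
as odds ratios) or a mean and standard deviation (continuous outcomes,
analysed as mean differences), plus the arm size.  Rows sharing a study_id
form one randomized trial.  An optional ``criteria`` column labels each study
by the diagnostic criteria used to define gestational diabetes (IADPSG or
older criteria), which drives the subgroup analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import DataValidationError, FormatError

#: Fixed CSV schema.  Blank cell = value absent.
CSV_COLUMNS = ("study_id", "treatment", "criteria", "events", "size", "mean", "sd")

IADPSG = "IADPSG"
NON_IADPSG = "non-IADPSG"
UNKNOWN = "unknown"
CRITERIA_VALUES = (IADPSG, NON_IADPSG, UNKNOWN)


@dataclass(frozen=True)
class Treatment:
    """A treatment node: short key plus display label."""

    id: str
    label: str


#: The three agents compared in the gestational-diabetes network.  The
#: registry is open-ended — any string key is accepted in input files — but
#: these three are the packaged default and define the canonical node order
#: (reference treatment first).
DEFAULT_REGISTRY: tuple[Treatment, ...] = (
    Treatment("metformin", "Metformin"),
    Treatment("insulin", "Insulin"),
    Treatment("glyburide", "Glyburide"),
)
DEFAULT_ORDER = tuple(t.id for t in DEFAULT_REGISTRY)


def treatment_sort_key(tid: str, order: Sequence[str] = DEFAULT_ORDER):
    """Sort key placing registry treatments first (registry order), then
    unknown treatments alphabetically."""
    try:
        return (0, order.index(tid), "")
    except ValueError:
        return (1, 0, tid)


@dataclass(frozen=True)
class ArmRecord:
    """One study arm: counts for dichotomous outcomes or mean/sd for
    continuous ones, never both."""

    study_id: str
    treatment: str
    size: int
    events: int | None = None
    mean: float | None = None
    sd: float | None = None

    def validate(self, measure: str, where: str = "") -> None:
        loc = where or f"study {self.study_id!r}, arm {self.treatment!r}"
        if self.size <= 0:
            raise DataValidationError(f"{loc}: size must be > 0, got {self.size}")
        dichotomous = self.events is not None
        continuous = self.mean is not None or self.sd is not None
        if dichotomous and continuous:
            raise DataValidationError(f"{loc}: both events and mean/sd present")
        if measure == "OR":
            if not dichotomous:
                raise DataValidationError(f"{loc}: events required for an OR outcome")
            if self.events < 0:
                raise DataValidationError(f"{loc}: events must be >= 0")
            if self.events > self.size:
                raise DataValidationError(
                    f"{loc}: events ({self.events}) exceed size ({self.size})"
                )
        elif measure == "WMD":
            if self.mean is None or self.sd is None:
                raise DataValidationError(f"{loc}: mean and sd required for a WMD outcome")
            if self.sd <= 0:
                raise DataValidationError(f"{loc}: sd must be > 0, got {self.sd}")
        else:
            raise DataValidationError(f"unknown measure {measure!r}")


@dataclass(frozen=True)
class StudyRecord:
    """One randomized trial: >= 2 arms with distinct treatments."""

    study_id: str
    arms: tuple[ArmRecord, ...]
    criteria: str = UNKNOWN

    def validate(self, measure: str) -> None:
        if len(self.arms) < 2:
            raise DataValidationError(
                f"study {self.study_id!r}: single-arm study (needs >= 2 arms)"
            )
        treatments = [a.treatment for a in self.arms]
        if len(set(treatments)) != len(treatments):
            raise DataValidationError(
                f"study {self.study_id!r}: duplicate treatment arms {treatments}"
            )
        if self.criteria not in CRITERIA_VALUES:
            raise DataValidationError(
                f"study {self.study_id!r}: criteria must be one of {CRITERIA_VALUES},"
                f" got {self.criteria!r}"
            )
        for arm in self.arms:
            arm.validate(measure)

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(a.treatment for a in self.arms)

    def arm_for(self, treatment: str) -> ArmRecord:
        for a in self.arms:
            if a.treatment == treatment:
                return a
        raise KeyError(treatment)

    @property
    def n_total(self) -> int:
        return sum(a.size for a in self.arms)


@dataclass(frozen=True)
class OutcomeDataset:
    """All studies reporting one outcome on one measure (OR or WMD)."""

    outcome: str
    measure: str
    studies: tuple[StudyRecord, ...]

    def validate(self) -> "OutcomeDataset":
        if self.measure not in ("OR", "WMD"):
            raise DataValidationError(f"measure must be OR or WMD, got {self.measure!r}")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate study_ids: {dupes}")
        for s in self.studies:
            s.validate(self.measure)
        return self

    @property
    def treatments(self) -> tuple[str, ...]:
        seen = {t for s in self.studies for t in s.treatments}
        return tuple(sorted(seen, key=treatment_sort_key))

    @property
    def n_total(self) -> int:
        return sum(s.n_total for s in self.studies)

    def subset(self, study_ids: Iterable[str]) -> "OutcomeDataset":
        keep = set(study_ids)
        return replace(self, studies=tuple(s for s in self.studies if s.study_id in keep))

    def drop(self, study_id: str) -> "OutcomeDataset":
        return replace(
            self, studies=tuple(s for s in self.studies if s.study_id != study_id)
        )

    def filter_arms(self, treatments: Iterable[str]) -> "OutcomeDataset":
        """Keep only arms on the given treatments, dropping studies left with
        fewer than two arms.  This is the explicit extraction step for
        multi-arm trials whose extra arms (diet, acarbose, ...) fall outside
        the analysed network."""
        keep = set(treatments)
        studies = []
        for s in self.studies:
            arms = tuple(a for a in s.arms if a.treatment in keep)
            if len(arms) >= 2:
                studies.append(replace(s, arms=arms))
        return replace(self, studies=tuple(studies))


@dataclass(frozen=True)
class NetworkGeometry:
    """Treatment graph of a dataset: nodes, per-edge trial counts, connectivity."""

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    connected: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": list(self.nodes),
                "edges": [
                    {"a": a, "b": b, "trials": k} for (a, b), k in sorted(self.edges.items())
                ],
                "connected": self.connected,
            },
            indent=2,
        )

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"treatment_a": a, "treatment_b": b, "trials": k}
                for (a, b), k in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["treatment_a", "treatment_b", "trials"])


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (registry-ordered) undirected edge key."""
    return tuple(sorted((a, b), key=treatment_sort_key))  # type: ignore[return-value]


def build_geometry(ds: OutcomeDataset) -> NetworkGeometry:
    """Count trials per direct comparison and decide connectivity.

    An empty dataset yields an empty, trivially connected geometry.  A
    multi-arm study contributes one trial to each pair of its treatments.
    """
    g = nx.Graph()
    g.add_nodes_from(ds.treatments)
    edges: dict[tuple[str, str], int] = {}
    for s in ds.studies:
        ts = s.treatments
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                key = edge_key(ts[i], ts[j])
                edges[key] = edges.get(key, 0) + 1
                g.add_edge(*key)
    connected = nx.is_connected(g) if g.number_of_nodes() > 0 else True
    return NetworkGeometry(nodes=ds.treatments, edges=edges, connected=connected)


def connected_components(ds: OutcomeDataset) -> list[set[str]]:
    g = nx.Graph()
    g.add_nodes_from(ds.treatments)
    for s in ds.studies:
        ts = s.treatments
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                g.add_edge(ts[i], ts[j])
    return [set(c) for c in nx.connected_components(g)]


def _cell(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def read_arm_csv(path, measure: str, outcome: str | None = None) -> OutcomeDataset:
    """Read and validate an arm-level CSV into an :class:`OutcomeDataset`.

    Required columns: ``study_id``, ``treatment``, ``size``, plus ``events``
    (measure ``"OR"``) or ``mean``/``sd`` (measure ``"WMD"``).  ``criteria``
    is optional, defaulting to ``unknown``.  Rows are grouped into studies by
    ``study_id`` in order of first appearance; validation failures name the
    offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"study_id": str, "treatment": str, "criteria": str},
                     float_precision="round_trip")
    required = {"study_id", "treatment", "size"}
    required |= {"events"} if measure == "OR" else {"mean", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    return frame_to_dataset(df, measure, outcome or str(path))


def frame_to_dataset(df: pd.DataFrame, measure: str, outcome: str) -> OutcomeDataset:
    groups: dict[str, list[ArmRecord]] = {}
    criteria: dict[str, str] = {}
    for idx, row in enumerate(df.to_dict("records"), start=1):
        sid = str(row["study_id"])
        where = f"row {idx} (study {sid!r})"
        try:
            size = int(row["size"])
        except (TypeError, ValueError):
            raise DataValidationError(f"{where}: size is not an integer: {row['size']!r}")
        ev = _cell(row, "events")
        arm = ArmRecord(
            study_id=sid,
            treatment=str(row["treatment"]),
            size=size,
            events=int(ev) if ev is not None else None,
            mean=float(_cell(row, "mean")) if _cell(row, "mean") is not None else None,
            sd=float(_cell(row, "sd")) if _cell(row, "sd") is not None else None,
        )
        arm.validate(measure, where=where)
        groups.setdefault(sid, []).append(arm)
        label = _cell(row, "criteria") or UNKNOWN
        if sid in criteria and criteria[sid] != label:
            raise DataValidationError(f"{where}: conflicting criteria labels for study")
        criteria[sid] = label
    studies = tuple(
        StudyRecord(study_id=sid, arms=tuple(arms), criteria=criteria[sid])
        for sid, arms in groups.items()
    )
    return OutcomeDataset(outcome=outcome, measure=measure, studies=studies).validate()


def dataset_to_frame(ds: OutcomeDataset) -> pd.DataFrame:
    rows = []
    for s in ds.studies:
        for a in s.arms:
            rows.append(
                {
                    "study_id": s.study_id,
                    "treatment": a.treatment,
                    "criteria": s.criteria,
                    "events": a.events,
                    "size": a.size,
                    "mean": a.mean,
                    "sd": a.sd,
                }
            )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_arm_csv(ds: OutcomeDataset, path) -> None:
    # %.17g keeps write->read an exact round trip for float64 summaries
    dataset_to_frame(ds).to_csv(path, index=False, float_format="%.17g")


def dataset_summary(ds: OutcomeDataset) -> dict:
    geo = build_geometry(ds)
    return {
        "outcome": ds.outcome,
        "measure": ds.measure,
        "studies": len(ds.studies),
        "participants": ds.n_total,
        "treatments": list(ds.treatments),
        "edges": {f"{a}|{b}": k for (a, b), k in sorted(geo.edges.items())},
        "connected": geo.connected,
        "criteria_counts": {
            c: sum(1 for s in ds.studies if s.criteria == c) for c in CRITERIA_VALUES
        },
    }
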