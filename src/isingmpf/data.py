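"""Ingest and prepare binary survey matrices.

Handles the messiness of historical/comparative trait data: unknown answers,
inconsistent coding of the same entity by (or within) observers, uneven
sampling across groups, and the curation filter that keeps only entities with
few missing answers.  Missing answers are carried as NaN and resolved
downstream (dynamically, by the partial-data objective) — with a naive
modal-imputation baseline provided for comparison only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = np.nan

#: Refuse to expand an entity with more than this many disputed questions.
MAX_DISPUTED = 10


@dataclass
class RawRecord:
    """One coded record: an entity's answers in {+1, -1, NaN}."""

    entity_id: str
    answers: np.ndarray
    group_label: str | None = None
    source_weight: float = 1.0

    def __post_init__(self) -> None:
        self.answers = np.asarray(self.answers, dtype=float)
        known = self.answers[~np.isnan(self.answers)]
        if not np.all(np.isin(known, (-1.0, 1.0))):
            raise ValueError(
                f"record {self.entity_id!r}: answers must be +1, -1, or unknown"
            )
        if self.source_weight <= 0:
            raise ValueError(f"record {self.entity_id!r}: weight must be positive")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.answers).sum())


@dataclass
class ObservationSet:
    """Weighted (possibly expanded) observations: the D of the MPF objective.

    ``values`` is (m, n) with entries +1 / -1 / NaN; ``weights`` are positive;
    ``sources`` ties each row back to the entity it came from (expansion
    products of one entity share its source id).
    """

    values: np.ndarray
    weights: np.ndarray
    sources: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        m = len(self.values)
        if self.weights is None:
            self.weights = np.ones(m)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("all observation weights must be positive")
        if self.sources is None:
            self.sources = np.arange(m)
        self.sources = np.asarray(self.sources)

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    @classmethod
    def from_array(cls, values, weights=None, sources=None) -> "ObservationSet":
        return cls(values=values, weights=weights, sources=sources)

    def to_json_dict(self) -> dict:
        """Serializable form: configurations as 0/1/? strings plus weights."""
        def encode(row):
            return "".join(
                "?" if np.isnan(v) else ("1" if v > 0 else "0") for v in row
            )

        return {
            "n": int(self.n),
            "items": [
                {"config": encode(v), "weight": float(w), "source": str(s)}
                for v, w, s in zip(self.values, self.weights, self.sources)
            ],
        }


# ---------------------------------------------------------------------------
# CSV ingest
# ---------------------------------------------------------------------------

_CELL_MAP = {"1": 1.0, "0": -1.0, "": UNKNOWN, "NA": UNKNOWN, "nan": UNKNOWN}


def read_matrix(path_or_buf, group_col: str | None = None,
                weight_col: str | None = None) -> list[RawRecord]:
    """Read a trait matrix CSV into records.

    First column is the entity id; remaining columns are question ids with
    cells in {1, 0, empty/NA}.  1 -> +1, 0 -> -1, empty/NA -> unknown.
    Duplicate entity ids are preserved — they encode inconsistent coding.
    """
    df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    meta = [c for c in (group_col, weight_col) if c is not None]
    qcols = [c for c in df.columns[1:] if c not in meta]
    bad = []
    records = []
    for _, row in df.iterrows():
        answers = []
        for q in qcols:
            cell = row[q].strip()
            if cell in _CELL_MAP:
                answers.append(_CELL_MAP[cell])
            else:
                bad.append((row[id_col], q, cell))
                answers.append(UNKNOWN)
        if not bad:
            records.append(
                RawRecord(
                    entity_id=str(row[id_col]),
                    answers=np.array(answers),
                    group_label=str(row[group_col]) if group_col else None,
                    source_weight=float(row[weight_col]) if weight_col else 1.0,
                )
            )
    if bad:
        listing = ", ".join(f"(entity {e!r}, question {q!r}, value {v!r})" for e, q, v in bad)
        raise ValueError(f"non-binary cell values: {listing}")
    return records


def write_matrix(records: list[RawRecord], path, question_ids=None) -> None:
    """Write records back to the CSV dialect read_matrix accepts."""
    n = len(records[0].answers)
    if question_ids is None:
        question_ids = [f"q{i}" for i in range(n)]
    rows = []
    for r in records:
        cells = {"entity_id": r.entity_id}
        for q, v in zip(question_ids, r.answers):
            cells[q] = "" if np.isnan(v) else ("1" if v > 0 else "0")
        rows.append(cells)
    pd.DataFrame(rows).to_csv(path, index=False)


def curate(records: list[RawRecord], max_missing: int = 5) -> list[RawRecord]:
    """Keep records with at most ``max_missing`` unknown answers."""
    return [r for r in records if r.n_missing <= max_missing]


# ---------------------------------------------------------------------------
# Inconsistency handling
# ---------------------------------------------------------------------------

def resolve_inconsistencies(
    records: list[RawRecord], model: str = "independent"
) -> ObservationSet:
    """Turn (possibly inconsistent) records into a weighted observation set.

    Entities coded more than once get either

    * ``"shared"``  — each of the k distinct records kept with weight 1/k
      (answers to one question are taken to depend on all the others), or
    * ``"independent"`` — disagreement on d questions is read as independent
      per-question uncertainty: all 2^d combinations of the disputed answers
      are emitted, each with weight 2^-d.

    Unknown answers are untouched here; they are the business of the
    partial-data objective, so inconsistency and missingness can coexist on
    one entity.
    """
    if model not in ("shared", "independent"):
        raise ValueError(f"unknown error model {model!r}")
    by_entity: dict[str, list[RawRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.entity_id not in by_entity:
            order.append(r.entity_id)
        by_entity.setdefault(r.entity_id, []).append(r)

    values, weights, sources = [], [], []
    for eid in order:
        group = by_entity[eid]
        source_weight = group[0].source_weight
        stacked = np.vstack([r.answers for r in group])
        masks = np.isnan(stacked)
        if len(group) > 1 and not np.all(masks == masks[0]):
            raise ValueError(
                f"entity {eid!r}: records disagree on which questions are "
                "unknown (ambiguous mask)"
            )
        # distinct rows, preserving first-seen order
        distinct = []
        for row in stacked:
            if not any(np.array_equal(row, d, equal_nan=True) for d in distinct):
                distinct.append(row)
        if model == "shared" or len(distinct) == 1:
            k = len(distinct)
            for row in distinct:
                values.append(row)
                weights.append(source_weight / k)
                sources.append(eid)
        else:
            known = np.where(~masks[0])[0]
            block = np.vstack(distinct)[:, known]
            disputed = known[block.max(axis=0) != block.min(axis=0)]
            d = len(disputed)
            if d > MAX_DISPUTED:
                raise ValueError(
                    f"entity {eid!r}: {d} disputed questions exceeds the "
                    f"expansion cap ({MAX_DISPUTED})"
                )
            base = distinct[0].copy()
            for combo in itertools.product((-1.0, 1.0), repeat=d):
                row = base.copy()
                row[disputed] = combo
                values.append(row)
                weights.append(source_weight / 2**d)
                sources.append(eid)
    return ObservationSet(
        values=np.array(values), weights=np.array(weights), sources=np.array(sources)
    )


def reweight_groups(
    obs: ObservationSet, group_labels, target_proportions: dict
) -> ObservationSet:
    """Rescale weights so each group's total weight matches its target share.

    Total weight is preserved; targets must sum to 1 and every targeted group
    must appear in the data.
    """
    labels = np.asarray(group_labels)
    if len(labels) != len(obs.values):
        raise ValueError("one group label per observation required")
    total = sum(target_proportions.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"target proportions sum to {total}, expected 1")
    grand = obs.total_weight
    new_w = obs.weights.copy()
    for g, frac in target_proportions.items():
        in_g = labels == g
        current = obs.weights[in_g].sum()
        if current == 0:
            raise ValueError(f"group {g!r} has no observations")
        new_w[in_g] *= frac * grand / current
    return ObservationSet(values=obs.values, weights=new_w, sources=obs.sources)


def naive_impute(records: list[RawRecord]) -> list[RawRecord]:
    """Fill unknowns with each question's modal known value (baseline only).

    Ties break to +1 (fixed convention).  This is the "epistemic fallacy"
    baseline the partial-data objective is meant to replace.
    """
    stacked = np.vstack([r.answers for r in records])
    n = stacked.shape[1]
    modes = np.empty(n)
    for q in range(n):
        col = stacked[:, q]
        known = col[~np.isnan(col)]
        if len(known) == 0:
            raise ValueError(f"question {q} has no known answers; cannot impute")
        modes[q] = 1.0 if (known > 0).sum() >= (known < 0).sum() else -1.0
    out = []
    for r in records:
        filled = r.answers.copy()
        miss = np.isnan(filled)
        filled[miss] = modes[miss]
        out.append(
            RawRecord(r.entity_id, filled, r.group_label, r.source_weight)
        )
    return out


def impute_observation_set(obs: ObservationSet) -> ObservationSet:
    """Modal imputation applied directly to an observation set."""
    vals = obs.values.copy()
    for q in range(obs.n):
        col = vals[:, q]
        known = col[~np.isnan(col)]
        if len(known) == 0:
            raise ValueError(f"question {q} has no known answers; cannot impute")
        mode = 1.0 if (known > 0).sum() >= (known < 0).sum() else -1.0
        col[np.isnan(col)] = mode
    return ObservationSet(values=vals, weights=obs.weights.copy(), sources=obs.sources)
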