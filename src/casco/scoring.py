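"""Scoring engine: patient record -> component points -> total -> stage.

Missing-data policy (default ``"prorate"``): a component with fewer than
half of its inputs observed contributes 0 points and marks the result
incomplete; a questionnaire component with at least half of its items
answered is prorated to the full budget (mean answered-item severity x
budget), following QLQ-C30 scale-scoring convention.  ``"strict"`` mode
refuses a total (NaN, no stage) whenever any input is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instrument import (
    ComponentSpec,
    InstrumentDefinition,
    InstrumentError,
    StagingRule,
    STAGE_LABELS,
)


class ScoringError(ValueError):
    """Raised for domain errors: bad weights, out-of-range responses."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


@dataclass
class PatientRecord:
    """One subject's inputs to the score.

    ``labs`` maps marker id (e.g. ``"crp"``) to a numeric value in the
    instrument's units; ``responses`` maps item id (e.g. ``"php1"``) to an
    ordinal level ``1..n_levels``.  ``ecog`` and ``clinician_rating`` are
    external validity criteria only and never enter the score.
    """

    subject_id: str
    group: str = "cancer"
    sex: str | None = None
    age: float | None = None
    weight_current: float | None = None
    weight_preillness: float | None = None
    lbm_depleted: bool | None = None
    labs: dict[str, float] = field(default_factory=dict)
    responses: dict[str, int] = field(default_factory=dict)
    ecog: int | None = None
    clinician_rating: int | None = None

    def lab(self, marker_id: str) -> float | None:
        value = self.labs.get(marker_id)
        return None if _is_missing(value) else float(value)

    def response(self, item_id: str) -> int | None:
        value = self.responses.get(item_id)
        return None if _is_missing(value) else int(value)


@dataclass
class ComponentScore:
    name: str
    points: float
    budget: float
    n_missing_inputs: int = 0
    prorated: bool = False
    missing: bool = False  # fewer than half the inputs observed


@dataclass
class ScoreResult:
    subject_id: str
    per_component: list[ComponentScore]
    total: float
    stage: str | None
    complete: bool

    def component(self, name: str) -> ComponentScore:
        for c in self.per_component:
            if c.name == name:
                return c
        raise KeyError(name)


def percent_weight_loss(pre: float, current: float) -> float:
    """Percent body-weight loss relative to pre-illness weight, >= 0.

    Weight gain scores no loss (clamped at zero).
    """
    if pre <= 0 or current <= 0:
        raise ScoringError(f"weights must be positive (pre={pre}, current={current})")
    return max(0.0, 100.0 * (pre - current) / pre)


def score_bwc(record: PatientRecord, spec: ComponentSpec) -> ComponentScore:
    """Weight-loss band points plus lean-body-mass depletion points."""
    if spec.name != "BWC":
        raise ScoringError(f"expected BWC spec, got {spec.name}")
    n_missing = 0
    points = 0.0
    weights_known = not (
        _is_missing(record.weight_preillness) or _is_missing(record.weight_current)
    )
    if weights_known:
        loss = percent_weight_loss(record.weight_preillness, record.weight_current)
        points += spec.band_points(loss)
    else:
        n_missing += 1
    if _is_missing(record.lbm_depleted):
        n_missing += 1
    elif record.lbm_depleted:
        points += spec.lbm_points
    # two logical inputs: the weight pair and the LBM assessment
    return ComponentScore(
        "BWC", points, spec.budget, n_missing, missing=n_missing == 2
    )


def score_imd(record: PatientRecord, spec: ComponentSpec) -> ComponentScore:
    """Sum of marker points over markers outside their reference range."""
    if spec.name != "IMD":
        raise ScoringError(f"expected IMD spec, got {spec.name}")
    points = 0.0
    n_missing = 0
    for rule in spec.markers:
        value = record.lab(rule.marker_id)
        if value is None:
            n_missing += 1
        elif rule.is_abnormal(value, record.sex):
            points += rule.points
    missing = (len(spec.markers) - n_missing) * 2 < len(spec.markers)
    return ComponentScore(
        "IMD", 0.0 if missing else points, spec.budget, n_missing, missing=missing
    )


def score_questionnaire(record: PatientRecord, spec: ComponentSpec) -> ComponentScore:
    """Linearly rescaled ordinal items; half-or-more answered prorates."""
    if spec.name not in ("PHP", "ANO", "QoL"):
        raise ScoringError(f"expected questionnaire spec, got {spec.name}")
    k = len(spec.items)
    fractions: list[float] = []
    for item in spec.items:
        level = record.response(item.item_id)
        if level is None:
            continue
        if not 1 <= level <= item.n_levels:
            raise ScoringError(
                f"response {level} outside 1..{item.n_levels} for item "
                f"{item.item_id!r}"
            )
        fractions.append(item.fraction(level))
    answered = len(fractions)
    if answered * 2 < k:
        return ComponentScore(spec.name, 0.0, spec.budget, k - answered, missing=True)
    points = float(np.mean(fractions)) * spec.budget
    return ComponentScore(
        spec.name,
        points,
        spec.budget,
        k - answered,
        prorated=answered < k,
    )


def stage(total: float, rule: StagingRule) -> str:
    """Map a total score to its cachexia stage label."""
    if not 0 <= total <= rule.max_score:
        raise ScoringError(f"total {total} outside [0, {rule.max_score}]")
    if total <= rule.cut_none:
        return "no_cachexia"
    if total <= rule.cut_mild:
        return "mild"
    if total <= rule.cut_moderate:
        return "moderate"
    return "severe"


def score_total(
    record: PatientRecord,
    instrument: InstrumentDefinition,
    policy: str = "prorate",
) -> ScoreResult:
    """Score every component, sum to the 0-100 total, assign the stage."""
    if policy not in ("prorate", "strict"):
        raise ScoringError(f"unknown missing-data policy {policy!r}")
    per_component: list[ComponentScore] = []
    for spec in instrument.components:
        if spec.name == "BWC":
            per_component.append(score_bwc(record, spec))
        elif spec.name == "IMD":
            per_component.append(score_imd(record, spec))
        else:
            per_component.append(score_questionnaire(record, spec))
    any_missing_input = any(c.n_missing_inputs > 0 for c in per_component)
    complete = not any(c.missing for c in per_component)
    if policy == "strict" and any_missing_input:
        return ScoreResult(record.subject_id, per_component, float("nan"), None, False)
    total = sum(c.points for c in per_component)
    return ScoreResult(
        record.subject_id,
        per_component,
        total,
        stage(total, instrument.staging),
        complete,
    )


def score_cohort(
    cohort: pd.DataFrame,
    instrument: InstrumentDefinition,
    policy: str = "prorate",
) -> pd.DataFrame:
    """Score every row of a cohort table; order-preserving.

    Rows that fail to score (e.g. unparseable or non-positive weights) are
    flagged in the ``error`` column and carry NaN scores; the remaining
    subjects are scored normally.
    """
    from .io import record_from_row, check_cohort_schema

    check_cohort_schema(cohort, instrument)
    rows = []
    for _, row in cohort.iterrows():
        base = {"subject_id": str(row["subject_id"]), "error": ""}
        try:
            record = record_from_row(row, instrument)
            result = score_total(record, instrument, policy=policy)
            for comp in result.per_component:
                base[comp.name.lower()] = comp.points
            base["total"] = result.total
            base["stage"] = result.stage
            base["complete"] = result.complete
        except (ScoringError, InstrumentError, ValueError) as exc:
            for spec in instrument.components:
                base[spec.name.lower()] = float("nan")
            base.update(total=float("nan"), stage=None, complete=False)
            base["error"] = str(exc)
        rows.append(base)
    cols = ["subject_id", "bwc", "imd", "php", "ano", "qol", "total",
            "stage", "complete", "error"]
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["n_flagged"] = int((out["error"] != "").sum())
    return out
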