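"""Constructed reference patients: all-normal, worst-case, single-component.

Useful for instrument verification: the all-normal profile must score 0,
the worst-case profile must reach the scale maximum, and a profile
abnormal in exactly one component isolates that component's budget.
"""

from __future__ import annotations

import numpy as np

from .instrument import InstrumentDefinition
from .scoring import PatientRecord


def _normal_labs(instrument: InstrumentDefinition, sex: str, rng) -> dict[str, float]:
    labs = {}
    for rule in instrument.marker_rules():
        cut = rule.cut_for(sex)
        if rule.abnormal_direction == "high":
            labs[rule.marker_id] = cut * rng.uniform(0.3, 0.8)
        else:
            labs[rule.marker_id] = cut * rng.uniform(1.1, 1.6)
    return labs


def _abnormal_labs(instrument: InstrumentDefinition, sex: str, rng) -> dict[str, float]:
    labs = {}
    for rule in instrument.marker_rules():
        cut = rule.cut_for(sex)
        if rule.abnormal_direction == "high":
            labs[rule.marker_id] = cut * rng.uniform(1.5, 3.0)
        else:
            labs[rule.marker_id] = cut * rng.uniform(0.4, 0.8)
    return labs


def normal_record(
    instrument: InstrumentDefinition, subject_id: str = "normal", seed: int = 0
) -> PatientRecord:
    """A subject with no weight loss, normal labs and best responses."""
    rng = np.random.default_rng(seed)
    return PatientRecord(
        subject_id=subject_id,
        sex="female",
        weight_current=70.0,
        weight_preillness=70.0,
        lbm_depleted=False,
        labs=_normal_labs(instrument, "female", rng),
        responses={it.item_id: it.best_level() for it in instrument.items()},
    )


def worst_record(
    instrument: InstrumentDefinition, subject_id: str = "worst", seed: int = 0
) -> PatientRecord:
    """Worst possible value for every component input (scale maximum)."""
    rng = np.random.default_rng(seed)
    return PatientRecord(
        subject_id=subject_id,
        sex="female",
        weight_current=56.0,       # 20% loss: deepest weight-loss band
        weight_preillness=70.0,
        lbm_depleted=True,
        labs=_abnormal_labs(instrument, "female", rng),
        responses={it.item_id: it.worst_level() for it in instrument.items()},
    )


def record_worst_in(
    instrument: InstrumentDefinition, component: str, seed: int = 0
) -> PatientRecord:
    """All-normal except one component taken to its worst case."""
    rng = np.random.default_rng(seed)
    record = normal_record(instrument, subject_id=f"worst_{component}", seed=seed)
    if component == "BWC":
        record.weight_preillness = 70.0
        record.weight_current = 56.0
        record.lbm_depleted = True
    elif component == "IMD":
        record.labs = _abnormal_labs(instrument, record.sex, rng)
    elif component in ("PHP", "ANO", "QoL"):
        for item in instrument.items(component):
            record.responses[item.item_id] = item.worst_level()
    else:
        raise ValueError(f"unknown component {component!r}")
    return record


def record_abnormal_markers(
    instrument: InstrumentDefinition, marker_ids, seed: int = 0
) -> PatientRecord:
    """All-normal except the listed lab markers pushed out of range."""
    rng = np.random.default_rng(seed)
    record = normal_record(instrument, subject_id="markers", seed=seed)
    bad = _abnormal_labs(instrument, record.sex, rng)
    for mid in marker_ids:
        record.labs[mid] = bad[mid]
    return record
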