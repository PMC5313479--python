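"""Declarative definition of the CASCO and MiniCASCO staging instruments.

The CAchexia SCOre (CASCO) is a 0-100 composite of five weighted
components: body weight loss and composition (BWC, 40 points),
inflammation / metabolic disturbances / immunosuppression (IMD, 20),
physical performance (PHP, 15), anorexia (ANO, 15) and quality of life
(QoL, 10).  MiniCASCO (MCASCO) is the reduced-item variant for routine
clinical use: the same component budgets and staging rule, a four-marker
blood panel (albumin, hemoglobin, CRP, absolute lymphocyte count) and a
14-question short form.

An instrument is data, not code: :class:`InstrumentDefinition` carries the
component budgets, weight-loss band table, lab-marker rules with editable
reference thresholds, ordinal questionnaire items, and the staging
cut-offs.  Two built-in presets ("casco", "minicasco") ship with the
package; any variant can be loaded from a YAML/JSON mapping with the same
schema and is validated on load.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from typing import Any, Mapping, Sequence

import yaml

COMPONENT_NAMES = ("BWC", "IMD", "PHP", "ANO", "QoL")
QUESTIONNAIRE_COMPONENTS = ("PHP", "ANO", "QoL")
MARKER_IDS = (
    "crp", "il6", "albumin", "prealbumin", "lactate", "triglycerides",
    "urea", "hemoglobin", "ros", "homa", "lymphocytes",
)
STAGE_LABELS = ("no_cachexia", "mild", "moderate", "severe")


class InstrumentError(ValueError):
    """Raised when an instrument config is malformed or violates invariants."""


@dataclass(frozen=True)
class ItemSpec:
    """One ordinal questionnaire item.

    ``reverse_coded`` is true when a *higher* response level means better
    status (SNAQ appetite anchors and the two QLQ-C30 global items); for
    such items level 1 is the worst response.
    """

    item_id: str
    component: str
    text: str
    n_levels: int = 4
    reverse_coded: bool = False

    def worst_level(self) -> int:
        return 1 if self.reverse_coded else self.n_levels

    def best_level(self) -> int:
        return self.n_levels if self.reverse_coded else 1

    def fraction(self, level: int) -> float:
        """Severity fraction in [0, 1]: 0 = best response, 1 = worst."""
        if not 1 <= level <= self.n_levels:
            raise InstrumentError(
                f"response {level} outside 1..{self.n_levels} for item {self.item_id}"
            )
        if self.reverse_coded:
            return (self.n_levels - level) / (self.n_levels - 1)
        return (level - 1) / (self.n_levels - 1)


@dataclass(frozen=True)
class MarkerRule:
    """Reference-range rule awarding points when a blood marker is abnormal.

    ``threshold_male`` optionally overrides the cut for male subjects
    (used for hemoglobin, where anemia is <12 g/dL female, <13 g/dL male).
    """

    marker_id: str
    units: str
    abnormal_direction: str  # "high" or "low"
    threshold: float
    points: float
    threshold_male: float | None = None

    def cut_for(self, sex: str | None) -> float:
        if self.threshold_male is not None and sex == "male":
            return self.threshold_male
        return self.threshold

    def is_abnormal(self, value: float, sex: str | None = None) -> bool:
        cut = self.cut_for(sex)
        return value > cut if self.abnormal_direction == "high" else value < cut


@dataclass(frozen=True)
class WeightLossBand:
    """Band of percent weight loss: applies when loss <= upper (first match)."""

    upper: float  # inclusive upper edge in percent; inf for the open top band
    points: float


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    budget: float
    items: tuple[ItemSpec, ...] = ()
    markers: tuple[MarkerRule, ...] = ()
    bands: tuple[WeightLossBand, ...] = ()
    lbm_points: float = 0.0

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item_max_points(self) -> float:
        """Per-item maximum; items split the budget evenly."""
        if not self.items:
            raise InstrumentError(f"component {self.name} has no items")
        return self.budget / len(self.items)

    def band_points(self, pct_loss: float) -> float:
        for band in self.bands:
            if pct_loss <= band.upper:
                return band.points
        raise InstrumentError(f"no weight-loss band covers {pct_loss}%")


@dataclass(frozen=True)
class StagingRule:
    """Score-to-stage mapping with inclusive integer boundaries.

    no cachexia <= cut_none; mild in (cut_none, cut_mild]; moderate in
    (cut_mild, cut_moderate]; severe above.  Comparisons are on the real
    total, so a prorated score of 14.4 stages as "mild".
    """

    cut_none: float = 14
    cut_mild: float = 28
    cut_moderate: float = 46
    max_score: float = 100

    @property
    def cuts(self) -> tuple[float, float, float]:
        return (self.cut_none, self.cut_mild, self.cut_moderate)


@dataclass(frozen=True)
class InstrumentDefinition:
    variant: str
    components: tuple[ComponentSpec, ...]
    staging: StagingRule
    version: str = "1.0"

    def component(self, name: str) -> ComponentSpec:
        for comp in self.components:
            if comp.name == name:
                return comp
        raise KeyError(name)

    @property
    def max_total(self) -> float:
        return sum(c.budget for c in self.components)

    def items(self, component: str | None = None) -> tuple[ItemSpec, ...]:
        out: list[ItemSpec] = []
        for comp in self.components:
            if component is None or comp.name == component:
                out.extend(comp.items)
        return tuple(out)

    def item_map(self) -> dict[str, ItemSpec]:
        return {it.item_id: it for it in self.items()}

    def marker_rules(self) -> tuple[MarkerRule, ...]:
        return self.component("IMD").markers

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "variant": self.variant,
            "version": self.version,
            "staging": asdict(self.staging),
            "components": [
                {
                    "name": c.name,
                    "budget": c.budget,
                    "lbm_points": c.lbm_points,
                    "bands": [asdict(b) for b in c.bands],
                    "markers": [asdict(m) for m in c.markers],
                    "items": [asdict(i) for i in c.items],
                }
                for c in self.components
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, allow_unicode=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Built-in presets
# ---------------------------------------------------------------------------

_PHP_TEXTS = [
    "Have you noticed any particular decrease in the physical activities "
    "that you normally carry out during the day?",
    "Have you had any problems doing strenuous activities, like carrying a "
    "heavy shopping bag or a suitcase?",
    "Have you noticed any loss of handgrip force?",
    "Did you have to put more effort on climbing stairs?",
    "Have you felt tired after walking approximately half a kilometer?",
]

# SNAQ anchors run from worst (level 1: "very poor") to best, hence reverse.
_ANO_TEXTS = [
    "My appetite is...",
    "When I eat...",
    "Food tastes...",
    "Normally I eat...",
]

_QOL_TEXTS = [
    "Do you need to stay in bed or a chair during the day?",
    "Do you need help with eating, dressing, washing yourself or using the toilet?",
    "Were you limited in doing either your work or other daily activities?",
    "Were you limited in pursuing your hobbies or other leisure time activities?",
    "Were you short of breath?",
    "Have you had pain?",
    "Did you need to rest?",
    "Have you had trouble sleeping?",
    "Have you felt weak?",
    "Have you felt nauseated?",
    "Have you vomited?",
    "Have you been constipated?",
    "Have you had diarrhea?",
    "Did pain interfere with your daily activities?",
    "Have you had difficulty in concentrating on things, like reading a "
    "newspaper or watching television?",
    "Did you feel tense?",
    "Did you worry?",
    "Did you feel irritable?",
    "Did you feel depressed?",
    "Have you had difficulty remembering things?",
    "Has your physical condition or medical treatment interfered with your family life?",
    "Has your physical condition or medical treatment interfered with your social activities?",
    "Has your physical condition or medical treatment caused you financial difficulties?",
    "How would you rate your overall health during the past week?",
    "How would you rate your overall quality of life during the past week?",
]

# Default weight-loss bands: 0 / >0-5 / >5-10 / >10-15 / >15 percent.
_DEFAULT_BANDS = (
    WeightLossBand(0.0, 0.0),
    WeightLossBand(5.0, 7.5),
    WeightLossBand(10.0, 15.0),
    WeightLossBand(15.0, 22.5),
    WeightLossBand(math.inf, 30.0),
)

# Editable reference-range defaults (standard adult ranges); all config.
_CASCO_MARKERS = (
    MarkerRule("crp", "mg/L", "high", 5.0, 4.0),
    MarkerRule("il6", "pg/mL", "high", 10.0, 4.0),
    MarkerRule("albumin", "g/dL", "low", 3.5, 1.0),
    MarkerRule("prealbumin", "mg/dL", "low", 20.0, 1.0),
    MarkerRule("lactate", "mg/dL", "high", 19.8, 1.0),
    MarkerRule("triglycerides", "mg/dL", "high", 150.0, 1.0),
    MarkerRule("urea", "mg/dL", "high", 50.0, 1.0),
    MarkerRule("hemoglobin", "g/dL", "low", 12.0, 1.0, threshold_male=13.0),
    MarkerRule("ros", "FORT units", "high", 310.0, 1.0),
    MarkerRule("homa", "index", "high", 2.5, 1.0),
    MarkerRule("lymphocytes", "cells/uL", "low", 1000.0, 4.0),
)

# MiniCASCO blood panel: CRP carries the inflammation sub-budget, albumin
# and hemoglobin split the metabolic sub-budget, lymphocytes keep their
# 4-point immunosuppression share; the IMD budget of 20 is preserved.
_MCASCO_MARKERS = (
    MarkerRule("crp", "mg/L", "high", 5.0, 8.0),
    MarkerRule("albumin", "g/dL", "low", 3.5, 4.0),
    MarkerRule("hemoglobin", "g/dL", "low", 12.0, 4.0, threshold_male=13.0),
    MarkerRule("lymphocytes", "cells/uL", "low", 1000.0, 4.0),
)


def _php_items(indices: Sequence[int]) -> tuple[ItemSpec, ...]:
    return tuple(
        ItemSpec(f"php{i + 1}", "PHP", _PHP_TEXTS[i], n_levels=4) for i in indices
    )


def _ano_items(indices: Sequence[int]) -> tuple[ItemSpec, ...]:
    return tuple(
        ItemSpec(f"ano{i + 1}", "ANO", _ANO_TEXTS[i], n_levels=5, reverse_coded=True)
        for i in indices
    )


def _qol_items(indices: Sequence[int]) -> tuple[ItemSpec, ...]:
    out = []
    for i in indices:
        is_global = i >= 23  # the two global health/QoL items
        out.append(
            ItemSpec(
                f"qol{i + 1}",
                "QoL",
                _QOL_TEXTS[i],
                n_levels=7 if is_global else 4,
                reverse_coded=is_global,
            )
        )
    return tuple(out)


def _casco_definition() -> InstrumentDefinition:
    components = (
        ComponentSpec("BWC", 40.0, bands=_DEFAULT_BANDS, lbm_points=10.0),
        ComponentSpec("IMD", 20.0, markers=_CASCO_MARKERS),
        ComponentSpec("PHP", 15.0, items=_php_items(range(5))),
        ComponentSpec("ANO", 15.0, items=_ano_items(range(4))),
        ComponentSpec("QoL", 10.0, items=_qol_items(range(25))),
    )
    return InstrumentDefinition("CASCO", components, StagingRule())


def _mcasco_definition() -> InstrumentDefinition:
    # Short form: stairs + walking (PHP), appetite + satiety (ANO), and the
    # ten-question QoL subset, incl. the reverse-coded global-health item.
    components = (
        ComponentSpec("BWC", 40.0, bands=_DEFAULT_BANDS, lbm_points=10.0),
        ComponentSpec("IMD", 20.0, markers=_MCASCO_MARKERS),
        ComponentSpec("PHP", 15.0, items=_php_items([3, 4])),
        ComponentSpec("ANO", 15.0, items=_ano_items([0, 1])),
        ComponentSpec("QoL", 10.0, items=_qol_items([0, 2, 3, 5, 6, 8, 13, 14, 20, 23])),
    )
    return InstrumentDefinition("MCASCO", components, StagingRule())


_PRESETS = {"casco": _casco_definition, "minicasco": _mcasco_definition}


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------

def _build_from_dict(cfg: Mapping[str, Any]) -> InstrumentDefinition:
    try:
        staging = StagingRule(**cfg.get("staging", {}))
        components = []
        for comp in cfg["components"]:
            components.append(
                ComponentSpec(
                    name=comp["name"],
                    budget=float(comp["budget"]),
                    lbm_points=float(comp.get("lbm_points", 0.0)),
                    bands=tuple(WeightLossBand(**b) for b in comp.get("bands", [])),
                    markers=tuple(MarkerRule(**m) for m in comp.get("markers", [])),
                    items=tuple(ItemSpec(**i) for i in comp.get("items", [])),
                )
            )
        return InstrumentDefinition(
            variant=cfg["variant"],
            components=tuple(components),
            staging=staging,
            version=str(cfg.get("version", "1.0")),
        )
    except (KeyError, TypeError) as exc:
        raise InstrumentError(f"malformed instrument config: {exc}") from exc


def load_instrument(source: str | Mapping[str, Any] = "casco") -> InstrumentDefinition:
    """Load and validate an instrument.

    ``source`` may be a built-in preset name ("casco", "minicasco"), a
    mapping with the config schema, or a path to a YAML/JSON file.
    Raises :class:`InstrumentError` listing every invariant violation.
    """
    if isinstance(source, Mapping):
        definition = _build_from_dict(source)
    elif source in _PRESETS:
        definition = _PRESETS[source]()
    else:
        try:
            with open(source, encoding="utf-8") as fh:
                cfg = yaml.safe_load(fh)
        except OSError as exc:
            raise InstrumentError(
                f"unknown preset or unreadable config file: {source!r}"
            ) from exc
        if not isinstance(cfg, Mapping):
            raise InstrumentError(f"config root must be a mapping, got {type(cfg)}")
        definition = _build_from_dict(cfg)

    violations = validate_instrument(definition)
    if violations:
        raise InstrumentError(
            "invalid instrument definition:\n  - " + "\n  - ".join(violations)
        )
    return definition


def validate_instrument(instrument: InstrumentDefinition) -> list[str]:
    """Check every structural invariant; returns violations as data."""
    v: list[str] = []
    names = [c.name for c in instrument.components]
    if len(set(names)) != len(names):
        v.append("duplicate component names")
    for name in names:
        if name not in COMPONENT_NAMES:
            v.append(f"unknown component name {name!r}")

    if instrument.variant == "CASCO":
        if set(names) != set(COMPONENT_NAMES):
            v.append(f"CASCO must have components {COMPONENT_NAMES}, got {names}")
    total_budget = sum(c.budget for c in instrument.components)
    if abs(total_budget - instrument.staging.max_score) > 1e-9:
        v.append(
            f"component budgets sum to {total_budget}, expected "
            f"{instrument.staging.max_score}"
        )

    seen_items: set[str] = set()
    seen_markers: set[str] = set()
    for comp in instrument.components:
        if comp.budget <= 0:
            v.append(f"{comp.name}: budget must be positive")
        for it in comp.items:
            if it.item_id in seen_items:
                v.append(f"{comp.name}: duplicate item_id {it.item_id!r}")
            seen_items.add(it.item_id)
            if it.n_levels < 2:
                v.append(f"{comp.name}/{it.item_id}: n_levels must be >= 2")
            if not it.text.strip():
                v.append(f"{comp.name}/{it.item_id}: empty item text")
            if it.component != comp.name:
                v.append(
                    f"{comp.name}/{it.item_id}: item declares component "
                    f"{it.component!r}"
                )
        for mk in comp.markers:
            if mk.marker_id in seen_markers:
                v.append(f"{comp.name}: duplicate marker {mk.marker_id!r}")
            seen_markers.add(mk.marker_id)
            if mk.marker_id not in MARKER_IDS:
                v.append(f"{comp.name}: unknown marker {mk.marker_id!r}")
            if mk.points < 0:
                v.append(f"{comp.name}/{mk.marker_id}: negative points")
            if not math.isfinite(mk.threshold):
                v.append(f"{comp.name}/{mk.marker_id}: non-finite threshold")
            if mk.abnormal_direction not in ("high", "low"):
                v.append(
                    f"{comp.name}/{mk.marker_id}: abnormal_direction must be "
                    "'high' or 'low'"
                )
        if comp.name in QUESTIONNAIRE_COMPONENTS:
            if not comp.items:
                v.append(f"{comp.name}: questionnaire component without items")
        if comp.name == "IMD":
            marker_total = sum(m.points for m in comp.markers)
            if abs(marker_total - comp.budget) > 1e-9:
                v.append(
                    f"IMD: marker points sum to {marker_total}, budget {comp.budget}"
                )
        if comp.name == "BWC":
            if not comp.bands:
                v.append("BWC: missing weight-loss band table")
            else:
                uppers = [b.upper for b in comp.bands]
                if uppers != sorted(uppers) or uppers[-1] != math.inf:
                    v.append("BWC: bands must have increasing uppers ending at inf")
                band_max = max(b.points for b in comp.bands)
                if abs(band_max + comp.lbm_points - comp.budget) > 1e-9:
                    v.append(
                        f"BWC: max band ({band_max}) + LBM points "
                        f"({comp.lbm_points}) != budget {comp.budget}"
                    )

    st = instrument.staging
    if not (0 < st.cut_none < st.cut_mild < st.cut_moderate < st.max_score):
        v.append(
            f"staging cuts {st.cuts} must be strictly increasing within "
            f"(0, {st.max_score})"
        )
    return v
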