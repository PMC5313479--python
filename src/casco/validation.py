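"""Cohort-level psychometric validation of the staging instruments.

:class:`CohortValidation` is a model object built from a cohort table; its
:meth:`~CohortValidation.fit` runs the full pipeline -- scoring both
instrument variants, internal consistency per questionnaire scale,
patient-vs-control discriminant validity, concurrent validity against
external criteria with Bonferroni control, full-vs-short-form agreement,
and clustering-based staging cut-point estimation -- and returns a
:class:`ValidationResults` with a ``summary()`` table plus JSON/markdown
export.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cutoffs import CutoffEstimate, estimate_cutoffs
from .instrument import InstrumentDefinition, load_instrument
from .io import check_cohort_schema
from .psychometrics import (
    CorrelationResult,
    GroupComparison,
    ReliabilityResult,
    PsychometricsError,
    concurrent_validity,
    cronbach_alpha,
    discriminant_test,
)
from .scoring import score_cohort


class CohortValidation:
    """Psychometric validation pipeline over a scored cohort.

    Parameters
    ----------
    cohort : DataFrame
        Cohort table in the documented CSV schema (one column per lab
        marker and item id; ``group`` in {cancer, control}).
    instrument : InstrumentDefinition, optional
        Full instrument (default: built-in "casco" preset).
    short_form : InstrumentDefinition, optional
        Reduced variant for the agreement analysis (default "minicasco").
    family_alpha : float
        Family-wise significance level for the Bonferroni correction.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        instrument: InstrumentDefinition | None = None,
        short_form: InstrumentDefinition | None = None,
        family_alpha: float = 0.05,
        cutoff_k: int = 4,
    ):
        check_cohort_schema(cohort)
        self.cohort = cohort.reset_index(drop=True)
        self.instrument = instrument or load_instrument("casco")
        self.short_form = short_form or load_instrument("minicasco")
        self.family_alpha = family_alpha
        self.cutoff_k = cutoff_k

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CohortValidation":
        from .io import read_cohort_csv

        return cls(read_cohort_csv(path), **kwargs)

    def fit(self) -> "ValidationResults":
        cohort = self.cohort
        scores = score_cohort(cohort, self.instrument)
        short_scores = score_cohort(cohort, self.short_form)
        is_patient = (cohort["group"] == "cancer").to_numpy()

        # reliability: pooled subjects, listwise within each scale
        reliability: list[ReliabilityResult] = []
        for comp in ("PHP", "ANO", "QoL"):
            item_ids = [it.item_id for it in self.instrument.items(comp)]
            present = [c for c in item_ids if c in cohort.columns]
            if len(present) >= 2:
                reliability.append(
                    cronbach_alpha(cohort[present], scale=comp)
                )

        # discriminant validity: patients vs controls on the total score
        notices: list[str] = []
        discriminant: GroupComparison | None = None
        totals = scores["total"].to_numpy(dtype=float)
        if is_patient.any() and (~is_patient).any():
            discriminant = discriminant_test(totals[is_patient], totals[~is_patient])
        else:
            notices.append(
                "discriminant test skipped: cohort contains a single group"
            )

        # concurrent validity: patients only, vs external criteria
        concurrent: list[CorrelationResult] = []
        pat_scores = scores.loc[is_patient]
        criteria_cols = [
            c for c in ("clinician_rating", "ecog") if c in cohort.columns
        ]
        if is_patient.any() and criteria_cols:
            try:
                concurrent = concurrent_validity(
                    pat_scores,
                    cohort.loc[is_patient, criteria_cols],
                    mcasco_total=short_scores.loc[is_patient, "total"],
                    family_alpha=self.family_alpha,
                )
            except PsychometricsError as exc:
                notices.append(f"concurrent validity skipped: {exc}")
        elif not criteria_cols:
            notices.append("concurrent validity skipped: no criterion columns")

        # staging cut-points from the patients' score distribution
        cutoffs: CutoffEstimate | None = None
        pat_totals = totals[is_patient]
        pat_totals = pat_totals[~np.isnan(pat_totals)]
        if len(pat_totals) >= self.cutoff_k:
            try:
                cutoffs = estimate_cutoffs(pat_totals, k=self.cutoff_k)
            except ValueError as exc:
                notices.append(f"cutoff estimation skipped: {exc}")
        else:
            notices.append("cutoff estimation skipped: too few scored patients")

        return ValidationResults(
            model=self,
            scores=scores,
            short_scores=short_scores,
            reliability=reliability,
            discriminant=discriminant,
            concurrent=concurrent,
            cutoffs=cutoffs,
            notices=notices,
        )


@dataclass
class ValidationResults:
    model: CohortValidation
    scores: pd.DataFrame
    short_scores: pd.DataFrame
    reliability: list[ReliabilityResult]
    discriminant: GroupComparison | None
    concurrent: list[CorrelationResult]
    cutoffs: CutoffEstimate | None
    notices: list[str] = field(default_factory=list)

    def group_means(self) -> pd.DataFrame:
        df = self.scores.copy()
        df["group"] = self.model.cohort["group"].to_numpy()
        return df.groupby("group")["total"].agg(["mean", "std", "count"])

    def to_dict(self) -> dict:
        out: dict = {
            "instrument": self.model.instrument.variant,
            "short_form": self.model.short_form.variant,
            "group_totals": {
                g: {k: float(v) for k, v in row.items()}
                for g, row in self.group_means().iterrows()
            },
            "reliability": [asdict(r) for r in self.reliability],
            "discriminant": asdict(self.discriminant) if self.discriminant else None,
            "concurrent": [asdict(c) for c in self.concurrent],
            "cutoffs": asdict(self.cutoffs) if self.cutoffs else None,
            "notices": list(self.notices),
        }
        return out

    def summary(self) -> str:
        lines = [
            "Cohort validation report",
            "========================",
            f"instrument: {self.model.instrument.variant} "
            f"(short form: {self.model.short_form.variant})",
            "",
            "Total score by group (mean / sd / n):",
        ]
        for g, row in self.group_means().iterrows():
            lines.append(
                f"  {g:<8s} {row['mean']:7.2f} / {row['std']:6.2f} / "
                f"{int(row['count'])}"
            )
        lines += ["", "Internal consistency (Cronbach's alpha):"]
        for r in self.reliability:
            lines.append(
                f"  {r.scale:<4s} alpha = {r.alpha:6.3f}  "
                f"(k = {r.k_items}, n = {r.n_used})"
            )
        if self.discriminant:
            d = self.discriminant
            lines += [
                "",
                "Discriminant validity (patients vs controls, Welch t):",
                f"  t = {d.t_stat:.2f}, df = {d.df:.1f}, p = {d.p_value:.3g}, "
                f"r = {d.effect_r:.2f}",
                f"  95% CI of mean difference: [{d.ci_low:.2f}, {d.ci_high:.2f}]",
            ]
        if self.concurrent:
            lines += ["", "Concurrent validity (patients only, Bonferroni-adjusted):"]
            for c in self.concurrent:
                flag = "*" if c.significant else " "
                lines.append(
                    f"  {c.name:<18s} {c.method:<8s} r = {c.r:6.3f}  "
                    f"p = {c.p_value:.3g} {flag} (n = {c.n_used})"
                )
        if self.cutoffs:
            cut = self.cutoffs
            lines += [
                "",
                "Estimated staging cut-points (Ward clustering of patient scores):",
                f"  breakpoints: {', '.join(f'{b:.1f}' for b in cut.breakpoints)}",
                f"  integer boundaries: {cut.integer_bounds}",
                f"  cluster sizes: {cut.cluster_sizes}",
                f"  ANOVA F = {cut.anova_f:.2f}, df = {cut.anova_df}, "
                f"eps^2 = {cut.effect_size:.2f}",
            ]
        for note in self.notices:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"

    def to_markdown(self) -> str:
        return "```\n" + self.summary() + "```\n"
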