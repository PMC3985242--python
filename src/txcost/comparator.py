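"""Hemodialysis comparator arm and incremental strategy comparison.

The dialysis arm is intentionally spare: hospital-based session tariffs plus
an annual adjunct-medication bundle (erythropoietin, calcitriol) per
patient, with no adverse-event layer.  Budget-impact questions
("what if everyone dialysed instead?", "what does swapping one regimen line
cost?") reduce to building two strategies and diffing their cost reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Tuple

from .core import CohortSpec, CostReport, CurrencyRate, to_usd
from .money import ValidationError, round_half_away

__all__ = [
    "DialysisArm",
    "ComparisonReport",
    "dialysis_annual_cost",
    "compare_strategies",
    "CohortMismatchWarning",
]


class CohortMismatchWarning(UserWarning):
    """Raised when compared reports differ in cohort size or currency rate."""


@dataclass(frozen=True)
class DialysisArm:
    """All-patients-on-hemodialysis scenario.

    ``sessions_per_year`` defaults to 156 (three sessions a week);
    ``adjunct_annual_per_patient`` is an opaque annual bundle of supporting
    medications per patient.
    """

    session_tariff: int
    cohort: CohortSpec
    sessions_per_year: int = 156
    adjunct_annual_per_patient: int = 0
    name: str = "hemodialysis"

    def __post_init__(self) -> None:
        for field_name in ("session_tariff", "sessions_per_year", "adjunct_annual_per_patient"):
            value = getattr(self, field_name)
            if not isinstance(value, int) or value < 0:
                raise ValidationError(f"{field_name} must be a non-negative integer")


@dataclass(frozen=True)
class ComparisonReport:
    """Signed incremental budget impact of strategy B relative to A."""

    name_a: str
    name_b: str
    total_irr_a: int
    total_irr_b: int
    per_patient_irr_a: int
    per_patient_irr_b: int
    incremental_total_irr: int
    incremental_per_patient_irr: int
    incremental_total_usd: int
    incremental_per_patient_usd: int
    per_patient_ratio: Fraction
    component_deltas_irr: Dict[str, int]
    warnings: Tuple[str, ...] = ()

    @property
    def per_patient_ratio_decimal(self) -> float:
        return float(self.per_patient_ratio)


def dialysis_annual_cost(arm: DialysisArm, rate: CurrencyRate) -> CostReport:
    """Annual payer cost if the whole cohort received hemodialysis.

    Components: dialysis sessions (tariff x sessions/year x patients) and
    the adjunct medication bundle (annual per-patient x patients).
    """
    n = arm.cohort.n_patients
    components = {
        "dialysis": arm.session_tariff * arm.sessions_per_year * n,
        "adjunct_treatment": arm.adjunct_annual_per_patient * n,
    }
    total = sum(components.values())
    per_patient_exact = Fraction(total, n) if n else Fraction(0)
    if n == 0 and total != 0:
        raise ValidationError("per-patient cost undefined: zero patients with nonzero cost")
    per_patient = round_half_away(per_patient_exact)
    return CostReport(
        strategy_name=arm.name,
        n_patients=n,
        rate=rate,
        component_totals_irr=components,
        total_irr=total,
        per_patient_irr_exact=per_patient_exact,
        per_patient_irr=per_patient,
        component_totals_usd={k: to_usd(v, rate) for k, v in components.items()},
        total_usd=to_usd(total, rate),
        per_patient_usd=to_usd(per_patient, rate),
    )


def compare_strategies(report_a: CostReport, report_b: CostReport) -> ComparisonReport:
    """Incremental totals and per-patient figures of B minus A, exactly.

    Reports built over different cohort sizes or currency rates are still
    compared (the per-patient figures remain meaningful) but carry a
    warning.  The per-patient ratio is B/A on the display values, as an
    exact rational; it is 1 for identical reports and 0-division-safe.
    """
    notes = []
    if report_a.n_patients != report_b.n_patients:
        notes.append(
            f"cohort sizes differ ({report_a.n_patients} vs {report_b.n_patients}); "
            "cohort-level increments mix population sizes"
        )
    if report_a.rate != report_b.rate:
        notes.append("currency rates differ; USD increments use each report's own rate")
    for note in notes:
        warnings.warn(note, CohortMismatchWarning, stacklevel=2)

    keys = sorted(set(report_a.component_totals_irr) | set(report_b.component_totals_irr))
    deltas = {
        k: report_b.component_totals_irr.get(k, 0) - report_a.component_totals_irr.get(k, 0)
        for k in keys
    }
    if report_a.per_patient_irr == 0:
        ratio = Fraction(1) if report_b.per_patient_irr == 0 else Fraction(0)
    else:
        ratio = Fraction(report_b.per_patient_irr, report_a.per_patient_irr)
    return ComparisonReport(
        name_a=report_a.strategy_name,
        name_b=report_b.strategy_name,
        total_irr_a=report_a.total_irr,
        total_irr_b=report_b.total_irr,
        per_patient_irr_a=report_a.per_patient_irr,
        per_patient_irr_b=report_b.per_patient_irr,
        incremental_total_irr=report_b.total_irr - report_a.total_irr,
        incremental_per_patient_irr=report_b.per_patient_irr - report_a.per_patient_irr,
        incremental_total_usd=report_b.total_usd - report_a.total_usd,
        incremental_per_patient_usd=report_b.per_patient_usd - report_a.per_patient_usd,
        per_patient_ratio=ratio,
        component_deltas_irr=deltas,
        warnings=tuple(notes),
    )
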