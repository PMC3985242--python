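"""Domain types and the deterministic first-year cost engine.

The model is a payer-perspective, one-year, undiscounted cost build-up for a
cohort of incident kidney-transplant recipients:

* a global lump-sum hospitalization tariff (a multiple of the national
  tariff unit K) charged once per recipient-donor operation pair;
* maintenance immunosuppressive regimen lines costed as
  units/day x unit price x eligible patients x duration;
* adverse events, each a marginal first-year occurrence probability over a
  fixed bundle of billed treatment items, contributing probability x bundle
  cost per patient in expectation;
* miscellaneous supportive-medication lines, same shape as maintenance.

All arithmetic is exact (integers and rationals); displayed values are
rounded half-away-from-zero at the edge, and cohort-level expected costs are
computed from the *unrounded* per-patient expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Literal, NamedTuple, Optional, Sequence, Tuple

from .money import Rational, ValidationError, as_rational, round_half_away

__all__ = [
    "CurrencyRate",
    "CohortSpec",
    "GlobalTariff",
    "RegimenLine",
    "TreatmentItem",
    "AdverseEventProfile",
    "StrategyDefinition",
    "AEBreakdown",
    "CostReport",
    "global_tariff_total",
    "hospitalization_cohort_cost",
    "regimen_line_cohort_cost",
    "maintenance_total",
    "treatment_item_cost",
    "ae_unit_cost_per_patient",
    "ae_expected_costs",
    "ae_component_totals",
    "ae_analytic_expectation",
    "strategy_report",
    "to_usd",
    "COMPONENT_ORDER",
]

ItemKind = Literal["drug_course", "procedure", "hospitalization", "fixed_tariff"]

#: Component keys of a strategy report, in presentation order.
COMPONENT_ORDER = ("hospitalization", "maintenance", "adverse_events", "miscellaneous")


def _check_money(value: int, name: str) -> int:
    if not isinstance(value, int) or isinstance(value, bool):
        raise ValidationError(f"{name} must be an integer amount of IRR, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class CurrencyRate:
    """Exchange rate, IRR per 1 USD (12,260 in the study year)."""

    irr_per_usd: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "irr_per_usd", as_rational(self.irr_per_usd))
        if self.irr_per_usd <= 0:
            raise ValidationError("irr_per_usd must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """The patient population and time horizon.

    ``patient_weight_kg`` is a reference weight used only to sanity-check
    weight-based doses (tacrolimus 0.2 mg/kg/day, ganciclovir 5 mg/kg);
    costing never touches it.
    """

    n_patients: int
    horizon_days: int = 365
    patient_weight_kg: Fraction = Fraction(70)

    def __post_init__(self) -> None:
        if not isinstance(self.n_patients, int) or self.n_patients < 0:
            raise ValidationError("n_patients must be a non-negative integer")
        if self.horizon_days < 1:
            raise ValidationError("horizon_days must be >= 1")
        object.__setattr__(self, "patient_weight_kg", as_rational(self.patient_weight_kg))
        if self.patient_weight_kg <= 0:
            raise ValidationError("patient_weight_kg must be positive")


@dataclass(frozen=True)
class GlobalTariff:
    """A lump-sum episode tariff expressed as multiplier x K units."""

    k_value: int
    multiplier: int

    def __post_init__(self) -> None:
        _check_money(self.k_value, "k_value")
        if not isinstance(self.multiplier, int) or self.multiplier < 1:
            raise ValidationError("multiplier must be a positive integer")

    def total(self) -> int:
        return self.multiplier * self.k_value


@dataclass(frozen=True)
class RegimenLine:
    """One maintenance or miscellaneous drug line.

    Cost is driven either by the per-patient fields
    (units/day x unit price x eligible patients) or, when the sub-cohort is
    a dosage-form mixture that cannot be decomposed, by
    ``cohort_daily_cost_override`` — the total cost per day for the whole
    eligible sub-cohort.  Exactly one of the two must be active.
    """

    drug_name: str
    dosage_form: str = ""
    units_per_day: Fraction = Fraction(0)
    unit_price: int = 0
    n_eligible: int = 0
    duration_days: int = 365
    cohort_daily_cost_override: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "units_per_day", as_rational(self.units_per_day))
        if self.units_per_day < 0:
            raise ValidationError(f"{self.drug_name}: units_per_day must be >= 0")
        _check_money(self.unit_price, f"{self.drug_name}: unit_price")
        if not isinstance(self.n_eligible, int) or self.n_eligible < 0:
            raise ValidationError(f"{self.drug_name}: n_eligible must be a non-negative integer")
        if self.duration_days < 1:
            raise ValidationError(f"{self.drug_name}: duration_days must be >= 1")
        if self.cohort_daily_cost_override is not None:
            _check_money(self.cohort_daily_cost_override, f"{self.drug_name}: cohort_daily_cost_override")
            if self.units_per_day * self.unit_price * self.n_eligible != 0:
                raise ValidationError(
                    f"{self.drug_name}: ambiguous line — cohort_daily_cost_override is set "
                    "but units_per_day x unit_price x n_eligible is also nonzero"
                )

    def daily_cost_per_patient(self) -> Fraction:
        """units/day x unit price; zero when the override drives the line."""
        if self.cohort_daily_cost_override is not None:
            return Fraction(0)
        return self.units_per_day * self.unit_price


@dataclass(frozen=True)
class TreatmentItem:
    """One billed element of an adverse-event bundle.

    ``duration`` is days for drug courses and hospitalization, a session
    count for procedures, and ignored for fixed tariffs.
    """

    kind: ItemKind
    label: str
    unit_price: int
    duration: Fraction = Fraction(0)
    units_per_day: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        if self.kind not in ("drug_course", "procedure", "hospitalization", "fixed_tariff"):
            raise ValidationError(f"{self.label}: unknown item kind {self.kind!r}")
        _check_money(self.unit_price, f"{self.label}: unit_price")
        object.__setattr__(self, "duration", as_rational(self.duration))
        object.__setattr__(self, "units_per_day", as_rational(self.units_per_day))
        if self.duration < 0:
            raise ValidationError(f"{self.label}: duration must be >= 0")
        if self.units_per_day < 0:
            raise ValidationError(f"{self.label}: units_per_day must be >= 0")
        if self.kind == "drug_course" and self.units_per_day == 0:
            raise ValidationError(f"{self.label}: drug_course items need units_per_day > 0")


@dataclass(frozen=True)
class AdverseEventProfile:
    """A named adverse event: first-year occurrence probability plus the
    treatment bundle billed for each patient who experiences it."""

    name: str
    probability: Fraction
    items: Tuple[TreatmentItem, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "probability", as_rational(self.probability))
        if not 0 <= self.probability <= 1:
            raise ValidationError(f"{self.name}: probability must lie in [0, 1]")
        object.__setattr__(self, "items", tuple(self.items))


@dataclass(frozen=True)
class StrategyDefinition:
    """A complete therapy strategy over a cohort.

    Any component may be absent/empty; an empty strategy costs zero.
    """

    name: str
    cohort: CohortSpec
    hospitalization: Optional[GlobalTariff] = None
    maintenance_lines: Tuple[RegimenLine, ...] = ()
    adverse_events: Tuple[AdverseEventProfile, ...] = ()
    misc_lines: Tuple[RegimenLine, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "maintenance_lines", tuple(self.maintenance_lines))
        object.__setattr__(self, "adverse_events", tuple(self.adverse_events))
        object.__setattr__(self, "misc_lines", tuple(self.misc_lines))


class AEExpected(NamedTuple):
    expected_per_patient: Fraction      # exact p x unit cost
    expected_display: int               # rounded half-away for display
    cohort_total: int                   # p x unit cost x n, rounded at the end only


@dataclass(frozen=True)
class AEBreakdown:
    unit_cost_per_patient: int
    expected_per_patient: Fraction
    expected_display: int
    cohort_total: int


@dataclass(frozen=True)
class CostReport:
    """Per-component and total first-year costs, IRR and USD, cohort and
    per-patient.  ``per_patient_irr_exact`` keeps the unrounded division."""

    strategy_name: str
    n_patients: int
    rate: CurrencyRate
    component_totals_irr: Dict[str, int]
    total_irr: int
    per_patient_irr_exact: Fraction
    per_patient_irr: int
    component_totals_usd: Dict[str, int]
    total_usd: int
    per_patient_usd: int
    per_event_breakdown: Dict[str, AEBreakdown] = field(default_factory=dict)

    @property
    def component_shares(self) -> Dict[str, float]:
        """Each component's share of the total (fractions summing to ~1)."""
        if self.total_irr == 0:
            return {k: 0.0 for k in self.component_totals_irr}
        return {
            k: float(Fraction(v, self.total_irr))
            for k, v in self.component_totals_irr.items()
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def to_usd(amount_irr: Rational, rate: CurrencyRate) -> int:
    """Convert IRR to whole USD, rounding half away from zero."""
    return round_half_away(Fraction(amount_irr) / rate.irr_per_usd)


def global_tariff_total(tariff: GlobalTariff) -> int:
    """The lump sum paid per recipient-donor operation pair."""
    return tariff.total()


def hospitalization_cohort_cost(tariff: GlobalTariff, cohort: CohortSpec) -> int:
    """Hospitalization tariff x incident patients."""
    return global_tariff_total(tariff) * cohort.n_patients


def regimen_line_cohort_cost(line: RegimenLine) -> int:
    """Cohort-level annual cost of one regimen line."""
    if line.cohort_daily_cost_override is not None:
        return line.cohort_daily_cost_override * line.duration_days
    cost = line.units_per_day * line.unit_price * line.n_eligible * line.duration_days
    return round_half_away(cost)


def maintenance_total(lines: Sequence[RegimenLine]) -> int:
    return sum(regimen_line_cohort_cost(line) for line in lines)


def treatment_item_cost(item: TreatmentItem) -> int:
    """Cost of one bundle item for one affected patient."""
    if item.kind == "drug_course":
        cost = item.units_per_day * item.unit_price * item.duration
    elif item.kind in ("procedure", "hospitalization"):
        cost = item.unit_price * item.duration
    else:  # fixed_tariff
        cost = Fraction(item.unit_price)
    return round_half_away(cost)


def ae_unit_cost_per_patient(ae: AdverseEventProfile) -> int:
    """Full bundle cost billed for each patient who experiences the event."""
    return sum(treatment_item_cost(item) for item in ae.items)


def ae_expected_costs(ae: AdverseEventProfile, cohort: CohortSpec) -> AEExpected:
    """Expected cost of one adverse event.

    The displayed per-patient expectation is rounded half-away-from-zero,
    but the cohort total multiplies the *unrounded* expectation by the
    cohort size (so hypertension's exact 36,682.5 IRR yields a cohort total
    of 80,701,500, not 36,683 x 2,200).
    """
    unit_cost = ae_unit_cost_per_patient(ae)
    expected = ae.probability * unit_cost
    cohort_total = round_half_away(expected * cohort.n_patients)
    return AEExpected(expected, round_half_away(expected), cohort_total)


def ae_component_totals(
    aes: Sequence[AdverseEventProfile], cohort: CohortSpec
) -> Tuple[int, int]:
    """(sum of rounded per-patient expectations, sum of cohort totals)."""
    per_patient_display = 0
    cohort_total = 0
    for ae in aes:
        exp = ae_expected_costs(ae, cohort)
        per_patient_display += exp.expected_display
        cohort_total += exp.cohort_total
    return per_patient_display, cohort_total


def ae_analytic_expectation(aes: Sequence[AdverseEventProfile]) -> Fraction:
    """Unrounded expected adverse-event cost per patient, sum of p_e x c_e."""
    return sum(
        (ae.probability * ae_unit_cost_per_patient(ae) for ae in aes),
        start=Fraction(0),
    )


def strategy_report(strategy: StrategyDefinition, rate: CurrencyRate) -> CostReport:
    """Aggregate a strategy into the four-component cost report.

    Per-patient IRR is the exact cohort total divided by cohort size, with
    the display value rounded half away from zero; every USD figure is the
    converted counterpart of the corresponding (display) IRR figure.
    """
    cohort = strategy.cohort
    components: Dict[str, int] = {}
    components["hospitalization"] = (
        hospitalization_cohort_cost(strategy.hospitalization, cohort)
        if strategy.hospitalization is not None
        else 0
    )
    components["maintenance"] = maintenance_total(strategy.maintenance_lines)
    _, ae_cohort_total = ae_component_totals(strategy.adverse_events, cohort)
    components["adverse_events"] = ae_cohort_total
    components["miscellaneous"] = maintenance_total(strategy.misc_lines)

    total = sum(components.values())
    if cohort.n_patients == 0:
        if total != 0:
            raise ValidationError("per-patient cost undefined: zero patients with nonzero cost")
        per_patient_exact = Fraction(0)
    else:
        per_patient_exact = Fraction(total, cohort.n_patients)
    per_patient = round_half_away(per_patient_exact)

    breakdown = {}
    for ae in strategy.adverse_events:
        exp = ae_expected_costs(ae, cohort)
        breakdown[ae.name] = AEBreakdown(
            unit_cost_per_patient=ae_unit_cost_per_patient(ae),
            expected_per_patient=exp.expected_per_patient,
            expected_display=exp.expected_display,
            cohort_total=exp.cohort_total,
        )

    return CostReport(
        strategy_name=strategy.name,
        n_patients=cohort.n_patients,
        rate=rate,
        component_totals_irr=components,
        total_irr=total,
        per_patient_irr_exact=per_patient_exact,
        per_patient_irr=per_patient,
        component_totals_usd={k: to_usd(v, rate) for k, v in components.items()},
        total_usd=to_usd(total, rate),
        per_patient_usd=to_usd(per_patient, rate),
        per_event_breakdown=breakdown,
    )
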