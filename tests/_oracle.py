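"""Independent brute-force cost oracle used to cross-check the engine.

Everything here is re-derived from raw dataclass fields with plain
``Fraction`` arithmetic and an integer-only rounding formula — none of the
engine's cost functions are called — so agreement between the two paths is
a real check, not a tautology.
"""

from fractions import Fraction

from txcost.core import StrategyDefinition


def oracle_round(x: Fraction) -> int:
    """Nearest integer, ties away from zero: sign(x) * (2|p| + q) // (2q)."""
    x = Fraction(x)
    p, q = abs(x.numerator), x.denominator
    magnitude = (2 * p + q) // (2 * q)
    return -magnitude if x < 0 else magnitude


def oracle_line_cost(line) -> int:
    if line.cohort_daily_cost_override is not None:
        return line.cohort_daily_cost_override * line.duration_days
    return oracle_round(
        Fraction(line.units_per_day)
        * line.unit_price
        * line.n_eligible
        * line.duration_days
    )


def oracle_item_cost(item) -> int:
    if item.kind == "drug_course":
        return oracle_round(Fraction(item.units_per_day) * item.unit_price * item.duration)
    if item.kind == "fixed_tariff":
        return item.unit_price
    return oracle_round(Fraction(item.unit_price) * item.duration)


def oracle_ae_cohort_total(ae, n_patients: int) -> int:
    bundle = sum(oracle_item_cost(it) for it in ae.items)
    return oracle_round(Fraction(ae.probability) * bundle * n_patients)


def oracle_strategy_components(strategy: StrategyDefinition) -> dict:
    """Component cohort totals, re-derived from scratch."""
    n = strategy.cohort.n_patients
    hosp = 0
    if strategy.hospitalization is not None:
        hosp = strategy.hospitalization.multiplier * strategy.hospitalization.k_value * n
    return {
        "hospitalization": hosp,
        "maintenance": sum(oracle_line_cost(l) for l in strategy.maintenance_lines),
        "adverse_events": sum(
            oracle_ae_cohort_total(ae, n) for ae in strategy.adverse_events
        ),
        "miscellaneous": sum(oracle_line_cost(l) for l in strategy.misc_lines),
    }


def oracle_expected_ae_per_patient(aes) -> Fraction:
    """Sum over events of probability x bundle cost, exact."""
    total = Fraction(0)
    for ae in aes:
        bundle = sum(oracle_item_cost(it) for it in ae.items)
        total += Fraction(ae.probability) * bundle
    return total
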