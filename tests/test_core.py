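"""Deterministic cost-engine checks against the published study tables, plus
the engine's structural invariants on hand-built and randomized inputs."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txcost import (
    AdverseEventProfile,
    CohortSpec,
    CurrencyRate,
    GlobalTariff,
    RegimenLine,
    StrategyDefinition,
    TreatmentItem,
    ValidationError,
    ae_component_totals,
    ae_expected_costs,
    ae_unit_cost_per_patient,
    global_tariff_total,
    hospitalization_cohort_cost,
    maintenance_total,
    regimen_line_cohort_cost,
    strategy_report,
    to_usd,
    treatment_item_cost,
)

RATE = CurrencyRate(Fraction(12260))
COHORT = CohortSpec(n_patients=2200)


# ---------------------------------------------------------------------------
# Global tariff and hospitalization
# ---------------------------------------------------------------------------

def test_global_tariff_650k():
    assert global_tariff_total(GlobalTariff(k_value=60_000, multiplier=650)) == 39_000_000
    assert global_tariff_total(GlobalTariff(k_value=0, multiplier=650)) == 0
    assert global_tariff_total(GlobalTariff(k_value=60_000, multiplier=1)) == 60_000


def test_global_tariff_rejects_nonpositive_multiplier():
    with pytest.raises(ValidationError):
        GlobalTariff(k_value=60_000, multiplier=0)


@pytest.mark.parametrize("n, expected", [(2200, 85_800_000_000), (1, 39_000_000), (0, 0)])
def test_hospitalization_cohort_cost(n, expected):
    tariff = GlobalTariff(k_value=60_000, multiplier=650)
    assert hospitalization_cohort_cost(tariff, CohortSpec(n_patients=n)) == expected


# ---------------------------------------------------------------------------
# Regimen lines (maintenance therapy)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "line, expected",
    [
        # mycophenolate mofetil: 4 x 11,000 x 2,200 x 365
        (RegimenLine("MMF", units_per_day=4, unit_price=11_000, n_eligible=2200,
                     duration_days=365), 35_332_000_000),
        # cyclosporine: cohort-wide daily cost, dosage-form mixture unresolvable
        (RegimenLine("CsA", duration_days=365, cohort_daily_cost_override=5_167_800),
         1_886_247_000),
        # tacrolimus: 28 half-mg tabs/day x 1,000 IRR x 220 eligible
        (RegimenLine("Tac", units_per_day=28, unit_price=1_000, n_eligible=220,
                     duration_days=365), 2_248_400_000),
        (RegimenLine("Pred", units_per_day=1, unit_price=130, n_eligible=2200,
                     duration_days=365), 104_390_000),
        (RegimenLine("nobody", units_per_day=3, unit_price=500, n_eligible=0,
                     duration_days=30), 0),
    ],
)
def test_regimen_line_cohort_cost(line, expected):
    assert regimen_line_cohort_cost(line) == expected


def test_maintenance_total_matches_published_sum(strategy):
    assert maintenance_total(strategy.maintenance_lines) == 39_571_037_000
    assert maintenance_total([]) == 0


def test_ambiguous_line_with_both_drivers_rejected():
    with pytest.raises(ValidationError):
        RegimenLine("bad", units_per_day=2, unit_price=100, n_eligible=10,
                    duration_days=10, cohort_daily_cost_override=1000)


# ---------------------------------------------------------------------------
# Treatment items and adverse-event bundles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "item, expected",
    [
        (TreatmentItem("drug_course", "ganciclovir", unit_price=250_000,
                       units_per_day=2, duration=7), 3_500_000),
        (TreatmentItem("procedure", "dialysis", unit_price=743_200, duration=10), 7_432_000),
        (TreatmentItem("hospitalization", "ward", unit_price=1_600_000, duration=7), 11_200_000),
        (TreatmentItem("fixed_tariff", "re-transplant", unit_price=39_000_000), 39_000_000),
    ],
)
def test_treatment_item_cost_by_kind(item, expected):
    assert treatment_item_cost(item) == expected


def test_item_validation():
    with pytest.raises(ValidationError):
        TreatmentItem("procedure", "bad", unit_price=-1, duration=1)
    with pytest.raises(ValidationError):
        TreatmentItem("procedure", "bad", unit_price=1, duration=-1)
    with pytest.raises(ValidationError):
        TreatmentItem("made_up_kind", "bad", unit_price=1)


# Published per-patient bundle costs for each adverse event.
AE_UNIT_COSTS = {
    "CMV": 14_700_000,
    "Other infections": 651_600,
    "Delayed graft function": 26_729_600,
    "Acute rejection": 29_750_000,
    "Hyperlipidemia": 401_500,
    "Hypertension": 54_750,
    "Graft failure": 46_432_000,
    "Thrombocytopenia": 13_000_000,
}


def test_ae_unit_costs_per_patient(events_by_name):
    assert set(events_by_name) == set(AE_UNIT_COSTS)
    for name, expected in AE_UNIT_COSTS.items():
        assert ae_unit_cost_per_patient(events_by_name[name]) == expected
    assert sum(AE_UNIT_COSTS.values()) == 131_719_450


def test_ae_unit_cost_empty_bundle_is_zero():
    assert ae_unit_cost_per_patient(AdverseEventProfile("none", Fraction(1, 2))) == 0


# (expected exact, display, cohort total) per event, from probability x bundle.
AE_EXPECTED = {
    "CMV": (Fraction(3_087_000), 3_087_000, 6_791_400_000),
    "Other infections": (Fraction(651_600), 651_600, 1_433_520_000),
    "Delayed graft function": (Fraction(4_544_032), 4_544_032, 9_996_870_400),
    "Acute rejection": (Fraction(5_355_000), 5_355_000, 11_781_000_000),
    "Hyperlipidemia": (Fraction(56_210), 56_210, 123_662_000),
    "Hypertension": (Fraction(733_65, 2), 36_683, 80_701_500),  # exact 36,682.5
    "Graft failure": (Fraction(4_875_360), 4_875_360, 10_725_792_000),
    "Thrombocytopenia": (Fraction(1_040_000), 1_040_000, 2_288_000_000),
}


def test_ae_expected_costs_per_event(events_by_name):
    for name, (exact, display, cohort_total) in AE_EXPECTED.items():
        got = ae_expected_costs(events_by_name[name], COHORT)
        assert got.expected_per_patient == exact, name
        assert got.expected_display == display, name
        assert got.cohort_total == cohort_total, name


def test_hypertension_cohort_total_uses_unrounded_expectation(events_by_name):
    # 36,682.5 x 2,200 = 80,701,500; rounding first would give 80,702,600.
    got = ae_expected_costs(events_by_name["Hypertension"], COHORT)
    assert got.cohort_total == 80_701_500
    assert got.expected_display * 2200 == 80_702_600  # the wrong order, for contrast


def test_ae_component_totals_published(strategy):
    per_patient, cohort_total = ae_component_totals(strategy.adverse_events, COHORT)
    assert per_patient == 19_645_885       # sum of rounded per-event expectations
    assert cohort_total == 43_220_945_900  # sum of unrounded-based cohort totals
    assert ae_component_totals([], COHORT) == (0, 0)


def test_ae_expected_degenerate_probabilities(events_by_name):
    zero = AdverseEventProfile("never", 0, events_by_name["CMV"].items)
    assert ae_expected_costs(zero, COHORT) == (0, 0, 0)
    with pytest.raises(ValidationError):
        AdverseEventProfile("bad", Fraction(6, 5))


# ---------------------------------------------------------------------------
# Strategy report (the headline aggregation)
# ---------------------------------------------------------------------------

def test_strategy_report_headline_totals(strategy, rate):
    report = strategy_report(strategy, rate)
    assert report.component_totals_irr == {
        "hospitalization": 85_800_000_000,
        "maintenance": 39_571_037_000,
        "adverse_events": 43_220_945_900,
        "miscellaneous": 2_126_344_000,
    }
    assert report.total_irr == 170_718_326_900
    assert report.total_irr == sum(report.component_totals_irr.values())
    assert report.per_patient_irr_exact == Fraction(170_718_326_900, 2200)
    assert report.per_patient_irr == 77_599_240   # 77,599,239.5 rounds up
    assert report.total_usd == 13_924_823
    assert report.per_patient_usd == 6_329
    assert report.component_totals_usd == {
        "hospitalization": 6_998_369,
        "maintenance": 3_227_654,
        "adverse_events": 3_525_363,
        "miscellaneous": 173_438,
    }


def test_component_shares_roughly_half_hospitalization(strategy, rate):
    shares = strategy_report(strategy, rate).component_shares
    assert shares["hospitalization"] == pytest.approx(0.50, abs=0.01)
    assert shares["adverse_events"] == pytest.approx(0.26, abs=0.01)
    assert shares["maintenance"] == pytest.approx(0.23, abs=0.01)
    assert shares["miscellaneous"] == pytest.approx(0.01, abs=0.01)
    assert sum(shares.values()) == pytest.approx(1.0)


def test_misc_lines_total(strategy):
    assert maintenance_total(strategy.misc_lines) == 2_126_344_000


def test_empty_strategy_is_all_zero(rate):
    report = strategy_report(StrategyDefinition("empty", CohortSpec(n_patients=10)), rate)
    assert report.total_irr == 0
    assert report.per_patient_irr == 0
    assert all(v == 0 for v in report.component_totals_irr.values())
    assert report.component_shares == {k: 0.0 for k in report.component_totals_irr}


def test_zero_patients_with_nonzero_cost_is_an_error(rate):
    # a regimen line billed to eligible patients outside the incident cohort
    line = RegimenLine("x", units_per_day=1, unit_price=100, n_eligible=5,
                       duration_days=10)
    strategy = StrategyDefinition("bad", CohortSpec(n_patients=0),
                                  maintenance_lines=(line,))
    with pytest.raises(ValidationError):
        strategy_report(strategy, rate)
    # zero patients with zero cost is fine
    empty = StrategyDefinition("empty", CohortSpec(n_patients=0))
    assert strategy_report(empty, rate).total_irr == 0


# ---------------------------------------------------------------------------
# Currency conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "irr, usd",
    [
        (39_571_037_000, 3_227_654),
        (43_220_945_900, 3_525_363),
        (85_800_000_000, 6_998_369),
        (2_126_344_000, 173_438),
        (170_718_326_900, 13_924_823),
        (77_599_240, 6_329),
        (12_260, 1),
        (0, 0),
    ],
)
def test_to_usd_matches_published_cells(irr, usd):
    assert to_usd(irr, RATE) == usd


def test_to_usd_rejects_nonpositive_rate():
    with pytest.raises(ValidationError):
        CurrencyRate(0)


# ---------------------------------------------------------------------------
# Invariants on randomized small strategies
# ---------------------------------------------------------------------------

@st.composite
def small_events(draw):
    n = draw(st.integers(0, 4))
    events = []
    for i in range(n):
        items = tuple(
            TreatmentItem("procedure", f"it{j}",
                          unit_price=draw(st.integers(0, 10**6)),
                          duration=draw(st.integers(0, 30)))
            for j in range(draw(st.integers(1, 3)))
        )
        prob = Fraction(draw(st.integers(0, 1000)), 1000)
        events.append(AdverseEventProfile(f"e{i}", prob, items))
    return tuple(events)


@given(events=small_events(), n=st.integers(1, 5000))
@settings(max_examples=150, deadline=None)
def test_additivity_and_scaling_of_ae_totals(events, n):
    cohort = CohortSpec(n_patients=n)
    doubled = CohortSpec(n_patients=2 * n)
    _, total = ae_component_totals(events, cohort)
    _, total2 = ae_component_totals(events, doubled)
    per_event = sum(ae_expected_costs(e, cohort).cohort_total for e in events)
    assert total == per_event                      # additivity over events
    exact = sum((e.probability * ae_unit_cost_per_patient(e) for e in events),
                start=Fraction(0))
    assert abs(total - exact * n) <= len(events)   # rounding only, per event
    # doubling the cohort doubles the exact total; rounded totals track it
    assert abs(total2 - 2 * total) <= 2 * len(events)
    # per-patient expectations are cohort-size invariant
    for e in events:
        assert (ae_expected_costs(e, cohort).expected_per_patient
                == ae_expected_costs(e, doubled).expected_per_patient)


@given(
    price=st.integers(0, 10**6), bump=st.integers(1, 10**4),
    units=st.integers(0, 10), duration=st.integers(1, 365),
    n_eligible=st.integers(0, 3000),
)
@settings(max_examples=150, deadline=None)
def test_monotonicity_in_price(price, bump, units, duration, n_eligible):
    base = RegimenLine("a", units_per_day=units, unit_price=price,
                       n_eligible=n_eligible, duration_days=duration)
    more = RegimenLine("a", units_per_day=units, unit_price=price + bump,
                       n_eligible=n_eligible, duration_days=duration)
    assert regimen_line_cohort_cost(more) >= regimen_line_cohort_cost(base)
    item_a = TreatmentItem("procedure", "x", unit_price=price, duration=duration)
    item_b = TreatmentItem("procedure", "x", unit_price=price + bump, duration=duration)
    assert treatment_item_cost(item_b) >= treatment_item_cost(item_a)
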