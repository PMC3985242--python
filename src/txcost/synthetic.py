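"""Randomized strategy generation and the bundled study inputs.

The generator emits structurally valid strategies with the same shape as
the study inputs — a hospitalization tariff, regimen lines, Bernoulli
adverse events over fixed treatment-item bundles, miscellaneous lines — so
the whole pipeline is testable without external data.  Its job is
structural coverage, not clinical realism: prices and durations are drawn
uniformly on integer ranges and probabilities on a rational grid, keeping
every generated strategy inside exact arithmetic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import NamedTuple, Optional, Tuple

from .comparator import DialysisArm
from .core import (
    AdverseEventProfile,
    CohortSpec,
    CurrencyRate,
    GlobalTariff,
    RegimenLine,
    StrategyDefinition,
    TreatmentItem,
)
from .money import ValidationError, as_rational

__all__ = ["GeneratorSpec", "generate_strategy", "paper_fixture", "PaperFixture", "fixture_path"]

_FIXTURE_NAME = "iran_rtt_2011.yaml"


@dataclass(frozen=True)
class GeneratorSpec:
    """Ranges (inclusive) from which a random strategy is drawn."""

    seed: int
    n_events: Tuple[int, int] = (1, 5)
    n_items_per_event: Tuple[int, int] = (1, 4)
    probability_range: Tuple[Fraction, Fraction] = (Fraction(0), Fraction(1))
    unit_price_range: Tuple[int, int] = (50, 2_000_000)
    duration_range: Tuple[int, int] = (1, 365)
    n_maintenance_lines: Tuple[int, int] = (0, 4)
    cohort_size_range: Tuple[int, int] = (50, 5_000)
    price_jitter_cv: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "probability_range",
            (as_rational(self.probability_range[0]), as_rational(self.probability_range[1])),
        )
        for name in ("n_events", "n_items_per_event", "unit_price_range",
                     "duration_range", "n_maintenance_lines", "cohort_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: empty range ({lo}, {hi})")
        lo, hi = self.probability_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("probability_range must be a sub-interval of [0, 1]")
        if self.price_jitter_cv < 0:
            raise ValidationError("price_jitter_cv must be >= 0")


_ITEM_KINDS = ("drug_course", "procedure", "hospitalization", "fixed_tariff")


def _draw_probability(rng: random.Random, lo: Fraction, hi: Fraction) -> Fraction:
    # Uniform on the grid of thousandths inside [lo, hi]; exact rational.
    lo_m = -((-lo.numerator * 1000) // lo.denominator)   # ceil(lo * 1000)
    hi_m = (hi.numerator * 1000) // hi.denominator        # floor(hi * 1000)
    if lo_m > hi_m:                                       # interval narrower than the grid
        return lo
    return Fraction(rng.randint(lo_m, hi_m), 1000)


def _jitter(rng: random.Random, price: int, cv: float) -> int:
    if cv == 0:
        return price
    return max(1, int(round(price * max(0.0, rng.gauss(1.0, cv)))))


def _draw_item(rng: random.Random, spec: GeneratorSpec, index: int) -> TreatmentItem:
    kind = rng.choice(_ITEM_KINDS)
    price = _jitter(rng, rng.randint(*spec.unit_price_range), spec.price_jitter_cv)
    duration = rng.randint(*spec.duration_range)
    if kind == "drug_course":
        return TreatmentItem(
            kind=kind, label=f"drug-{index}", unit_price=price,
            units_per_day=Fraction(rng.randint(1, 6)), duration=Fraction(duration),
        )
    if kind == "fixed_tariff":
        return TreatmentItem(kind=kind, label=f"tariff-{index}", unit_price=price)
    return TreatmentItem(
        kind=kind, label=f"{kind}-{index}", unit_price=price, duration=Fraction(duration)
    )


def _draw_line(rng: random.Random, spec: GeneratorSpec, n_patients: int, index: int) -> RegimenLine:
    duration = rng.randint(*spec.duration_range)
    if rng.random() < 0.2:
        # cohort-daily-cost-override line (unresolvable dosage-form mixture)
        return RegimenLine(
            drug_name=f"mixture-{index}",
            units_per_day=Fraction(0),
            unit_price=0,
            n_eligible=0,
            duration_days=duration,
            cohort_daily_cost_override=rng.randint(*spec.unit_price_range) * rng.randint(1, n_patients),
        )
    return RegimenLine(
        drug_name=f"line-{index}",
        units_per_day=Fraction(rng.randint(0, 8)),
        unit_price=_jitter(rng, rng.randint(*spec.unit_price_range), spec.price_jitter_cv),
        n_eligible=rng.randint(0, n_patients),
        duration_days=duration,
    )


def generate_strategy(spec: GeneratorSpec) -> StrategyDefinition:
    """Draw a random, fully valid strategy.  Deterministic given the seed."""
    rng = random.Random(spec.seed)
    n_patients = rng.randint(*spec.cohort_size_range)
    cohort = CohortSpec(n_patients=n_patients, horizon_days=365)

    hospitalization: Optional[GlobalTariff] = None
    if rng.random() < 0.8:
        hospitalization = GlobalTariff(
            k_value=rng.randint(10_000, 100_000), multiplier=rng.randint(1, 1000)
        )

    maintenance = tuple(
        _draw_line(rng, spec, n_patients, i)
        for i in range(rng.randint(*spec.n_maintenance_lines))
    )
    events = []
    for e in range(rng.randint(*spec.n_events)):
        items = tuple(
            _draw_item(rng, spec, i) for i in range(rng.randint(*spec.n_items_per_event))
        )
        events.append(
            AdverseEventProfile(
                name=f"event-{e}",
                probability=_draw_probability(rng, *spec.probability_range),
                items=items,
            )
        )
    misc = tuple(
        _draw_line(rng, spec, n_patients, i + 100) for i in range(rng.randint(0, 3))
    )
    return StrategyDefinition(
        name=f"synthetic-{spec.seed}",
        cohort=cohort,
        hospitalization=hospitalization,
        maintenance_lines=maintenance,
        adverse_events=tuple(events),
        misc_lines=misc,
    )


class PaperFixture(NamedTuple):
    strategy: StrategyDefinition
    dialysis: DialysisArm
    rate: CurrencyRate


def fixture_path() -> str:
    """Filesystem path of the bundled study-input config."""
    return str(resources.files("txcost.fixtures") / _FIXTURE_NAME)


def paper_fixture() -> PaperFixture:
    """The bundled study inputs: a 2,200-patient incident cohort, the
    650 x 60,000 IRR hospitalization tariff, four maintenance lines, eight
    adverse-event profiles, five miscellaneous lines, and the hemodialysis
    comparator arm, at 12,260 IRR/USD."""
    from .io import read_dialysis_arm, read_rate, read_strategy

    path = fixture_path()
    return PaperFixture(
        strategy=read_strategy(path),
        dialysis=read_dialysis_arm(path),
        rate=read_rate(path),
    )
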