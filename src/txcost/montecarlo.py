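"""Patient-level Monte Carlo validation of the expected adverse-event cost.

Each patient's first-year adverse-event cost is a sum of independent
Bernoulli draws — one per event profile — times that event's fixed bundle
cost.  Repeating the cohort draw many times yields a distribution of
cohort-mean costs whose center must agree with the analytic expectation
sum(p_e * c_e); the convergence check quantifies that agreement in standard
errors of the replicate mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import sqrt
from statistics import pstdev
from typing import List, Sequence, Tuple

import numpy as np

from .core import AdverseEventProfile, ae_unit_cost_per_patient
from .money import ValidationError

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "ConvergenceReport",
    "simulate_patient",
    "simulate_cohort",
    "convergence_check",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    n_replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Replicate-level summary of simulated per-patient adverse-event cost."""

    config: SimulationConfig
    replicate_means: Tuple[Fraction, ...]
    analytic_expectation: Fraction

    @property
    def grand_mean(self) -> Fraction:
        return sum(self.replicate_means, start=Fraction(0)) / len(self.replicate_means)

    @property
    def min_mean(self) -> Fraction:
        return min(self.replicate_means)

    @property
    def max_mean(self) -> Fraction:
        return max(self.replicate_means)

    @property
    def sd_of_means(self) -> float:
        """Population SD of the replicate means (0.0 for a single replicate)."""
        if len(self.replicate_means) < 2:
            return 0.0
        return pstdev(float(m) for m in self.replicate_means)


@dataclass(frozen=True)
class ConvergenceReport:
    passed: bool
    standardized_deviation: float
    tolerance: float
    diagnostic: str

    def __bool__(self) -> bool:
        return self.passed


def _event_arrays(aes: Sequence[AdverseEventProfile]) -> Tuple[np.ndarray, np.ndarray]:
    probs = np.array([float(ae.probability) for ae in aes], dtype=float)
    costs = np.array([ae_unit_cost_per_patient(ae) for ae in aes], dtype=np.int64)
    return probs, costs


def simulate_patient(aes: Sequence[AdverseEventProfile], rng: np.random.Generator) -> int:
    """Draw one patient: Bernoulli per event, sum the bundle costs of the
    events that occurred."""
    total = 0
    for ae in aes:
        if rng.random() < float(ae.probability):
            total += ae_unit_cost_per_patient(ae)
    return total


def simulate_cohort(
    cfg: SimulationConfig, aes: Sequence[AdverseEventProfile]
) -> SimulationResult:
    """Simulate ``n_replicates`` independent cohorts of ``n_patients``.

    Deterministic given the seed: the replicate r, event e occurrence matrix
    is drawn as uniform(n_events, n_patients) < p from a single
    ``numpy.random.default_rng(seed)`` stream.  Replicate means are kept as
    exact rationals (integer cohort cost / cohort size).
    """
    probs, costs = _event_arrays(aes)
    rng = np.random.default_rng(cfg.seed)
    means: List[Fraction] = []
    for _ in range(cfg.n_replicates):
        if len(aes) == 0:
            cohort_cost = 0
        else:
            occurred = rng.random((len(aes), cfg.n_patients)) < probs[:, None]
            cohort_cost = int(occurred.sum(axis=1) @ costs)
        means.append(Fraction(cohort_cost, cfg.n_patients))
    analytic = sum(
        (ae.probability * ae_unit_cost_per_patient(ae) for ae in aes),
        start=Fraction(0),
    )
    return SimulationResult(
        config=cfg, replicate_means=tuple(means), analytic_expectation=analytic
    )


def convergence_check(
    result: SimulationResult, tol_se_multiples: float = 4.0
) -> ConvergenceReport:
    """Does the simulated grand mean agree with the analytic expectation?

    Passes iff |grand mean - analytic| <= tol * sd(replicate means)/sqrt(R).
    A degenerate simulation (zero spread) passes only on exact agreement.
    """
    deviation = float(result.grand_mean - result.analytic_expectation)
    se = result.sd_of_means / sqrt(len(result.replicate_means))
    if se == 0.0:
        passed = deviation == 0.0
        z = 0.0 if passed else float("inf")
        verdict = "exact agreement" if passed else "zero spread with nonzero deviation"
        diagnostic = (
            f"degenerate simulation ({verdict}): grand mean {float(result.grand_mean):,.1f} "
            f"vs analytic {float(result.analytic_expectation):,.1f}"
        )
        return ConvergenceReport(passed, z, tol_se_multiples, diagnostic)
    z = deviation / se
    passed = abs(z) <= tol_se_multiples
    diagnostic = (
        f"grand mean {float(result.grand_mean):,.1f} IRR vs analytic "
        f"{float(result.analytic_expectation):,.1f} IRR: deviation {deviation:,.1f} "
        f"= {z:+.2f} SE (tolerance {tol_se_multiples:g} SE, "
        f"{len(result.replicate_means)} replicates of {result.config.n_patients} patients)"
    )
    return ConvergenceReport(passed, z, tol_se_multiples, diagnostic)
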