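"""Evaluation metrics: folding efficiency, chaperone cost, protein coverage.

* Folding efficiency: folded protein at the end of the run divided by all
  protein that ever entered the unfolded pool (initial pool + influx).
* Chaperone cost: time average of (bound BiP on non-native protein) /
  (non-native protein monomers), trapezoid rule on the trajectory grid.
  This is the dimensionally coherent reading of "average number of bound
  chaperones per unfolded protein per unit time"; an end-state estimator
  is available behind a flag for comparison.
* Coverage: fraction of non-native monomers residing in a complex with at
  least one bound BiP.

Chaperones lost to the inert pool are not "bound per unfolded protein"
and are excluded from the cost numerator; inert monomers are terminally
lost and excluded from all denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory
from .network import Form, SpeciesState


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is zero."""


def _vectors(species: tuple[SpeciesState, ...]):
    non_native = np.array(
        [s.monomer_content if s.is_non_native else 0 for s in species], float
    )
    bound_bip = np.array(
        [s.n_bip if s.is_non_native else 0 for s in species], float
    )
    covered = np.array(
        [
            s.monomer_content if (s.is_non_native and s.n_bip >= 1) else 0
            for s in species
        ],
        float,
    )
    folded = np.array([1.0 if s.form is Form.FOLDED else 0.0 for s in species])
    return non_native, bound_bip, covered, folded


def folding_efficiency(
    trajectory: Trajectory,
    initial_unfolded_total: float,
    influx_total: float | None = None,
) -> float:
    """Final folded count over (initial unfolded + translocated influx)."""
    if influx_total is None:
        influx_total = trajectory.influx_total
    denom = initial_unfolded_total + influx_total
    if denom <= 0.0:
        raise UndefinedMetricError("no protein ever entered the unfolded pool")
    _, _, _, folded = _vectors(trajectory.species)
    return float(trajectory.final_state @ folded) / denom


def chaperone_cost(trajectory: Trajectory, end_state: bool = False) -> float:
    """Time-averaged bound BiP per non-native protein monomer.

    ``end_state=True`` instead evaluates the ratio at the final time point
    only (the alternative, non-time-resolved estimator).
    """
    non_native, bound_bip, _, _ = _vectors(trajectory.species)
    proteins = trajectory.states @ non_native
    bips = trajectory.states @ bound_bip
    ratio = np.divide(
        bips, proteins, out=np.zeros_like(bips), where=proteins > 0.5
    )
    if end_state:
        return float(ratio[-1])
    t = trajectory.times
    if len(t) < 2:
        raise UndefinedMetricError("cost needs at least two time points")
    span = t[-1] - t[0]
    if span <= 0.0:
        raise UndefinedMetricError("degenerate time grid")
    return float(np.trapezoid(ratio, t) / span)


def coverage(state: np.ndarray, species: tuple[SpeciesState, ...]) -> float:
    """Fraction of non-native monomers protected by >= 1 bound BiP."""
    non_native, _, covered, _ = _vectors(species)
    total = float(state @ non_native)
    if total <= 0.0:
        return 0.0
    return float(state @ covered) / total


@dataclass(frozen=True)
class MetricsResult:
    folding_efficiency: float
    chaperone_cost: float
    coverage: float

    def to_dict(self) -> dict:
        return {
            "folding_efficiency": self.folding_efficiency,
            "chaperone_cost": self.chaperone_cost,
            "coverage": self.coverage,
        }


def evaluate(
    trajectory: Trajectory,
    initial_unfolded_total: float,
    influx_total: float | None = None,
) -> MetricsResult:
    return MetricsResult(
        folding_efficiency=folding_efficiency(
            trajectory, initial_unfolded_total, influx_total
        ),
        chaperone_cost=chaperone_cost(trajectory),
        coverage=coverage(trajectory.final_state, trajectory.species),
    )
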