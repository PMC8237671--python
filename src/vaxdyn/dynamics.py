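"""Period-by-period coverage dynamics under voluntary and enforced plans.

Each period, citizens observe last period's total coverage ``f`` and the
policy regime.  Anyone unvaccinated who prefers being vaccinated gets the
vaccine first (the ratchet ``f -> max(f, p(f))``; coverage never declines).
Under an enforced plan, whenever voluntary uptake stalls at a rest point
below the target, unwilling citizens are vaccinated — up to the per-period
``enforcement_capacity`` — but only as far as needed: just past the nearest
tipping point (after which conformist growth resumes on its own) or, if no
tipping point helps, up to the target itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adoption import (
    AdoptionCurve,
    EquilibriumKind,
    EquilibriumSet,
    RegimeCurvePair,
    _fixed_points_cached,
    ratchet_limit,
)


def _growth_limit(
    curve: AdoptionCurve, f: float, tol: float, eq: EquilibriumSet
) -> float:
    """Where the ratchet will eventually end starting from ``f``.

    Unlike :func:`vaxdyn.adoption.ratchet_limit`, this treats slow growth just
    above a tipping point as growth (it looks past any non-stable fixed point
    within ``tol`` of ``f``), which matters when deciding whether voluntary
    uptake has genuinely stalled.
    """
    if curve(f) <= f:
        return float(f)
    for p in eq.points:
        if abs(p.f - f) <= tol and p.is_stable and p.f >= f - tol:
            return float(p.f)  # effectively at a stable point already
    above = [p.f for p in eq.points if p.f > f + tol]
    if above:
        return above[0]
    return 1.0 if curve(1.0) >= 1.0 - tol else float(f)

__all__ = [
    "PolicyPlan",
    "TrajectoryStep",
    "Trajectory",
    "step_voluntary",
    "step_enforced",
    "simulate",
    "minimal_enforcement",
]

DEFAULT_SIM_TOL = 1e-9
DEFAULT_HORIZON = 10_000

#: nudge applied when enforcing past a tipping point; kept well below the
#: convergence tolerance so enforcement totals match the analytic minimum
_TIP_NUDGE_FRACTION = 0.25


@dataclass(frozen=True)
class PolicyPlan:
    """Policy regime, coverage target fT, per-period enforcement capacity
    (1 = unlimited) and simulation horizon."""

    regime: str  # "voluntary" | "enforced"
    target: float
    enforcement_capacity: float = 1.0
    horizon: int = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        if self.regime not in ("voluntary", "enforced"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 < self.target <= 1.0:
            raise ValueError("target must lie in (0, 1]")
        if not 0.0 <= self.enforcement_capacity <= 1.0:
            raise ValueError("enforcement_capacity must lie in [0, 1]")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass(frozen=True)
class TrajectoryStep:
    t: int
    f: float
    pref: float  # preference share evaluated at last period's coverage
    regret: float  # max(0, f - p(f)): vaccinated who prefer not to have been
    enforced_added: float


@dataclass
class Trajectory:
    steps: list[TrajectoryStep] = field(default_factory=list)
    converged: bool = False
    rest_point: float = 0.0
    reached_target: bool = False

    @property
    def coverage(self) -> np.ndarray:
        return np.array([s.f for s in self.steps])

    @property
    def total_enforced(self) -> float:
        return float(sum(s.enforced_added for s in self.steps))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": [s.t for s in self.steps],
                "f": [s.f for s in self.steps],
                "pref": [s.pref for s in self.steps],
                "regret": [s.regret for s in self.steps],
                "enforced_added": [s.enforced_added for s in self.steps],
            }
        )


def step_voluntary(curve: AdoptionCurve, f: float) -> float:
    """Ratchet map: coverage rises to the preferring share if larger."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    return float(min(max(f, curve(f)), 1.0))


def _enforcement_goal(
    curve: AdoptionCurve,
    f: float,
    target: float,
    tol: float,
    eq: EquilibriumSet,
) -> float:
    """Coverage level enforcement should push toward from a stall at ``f``.

    Just past the nearest useful tipping point if one lies below the target;
    otherwise the target itself.  Repelling boundary points count as tipping.
    """
    nudge = _TIP_NUDGE_FRACTION * tol
    tips = [
        p.f
        for p in eq.points
        if p.f > f + tol
        and (
            p.kind == EquilibriumKind.TIPPING
            or (p.kind == EquilibriumKind.BOUNDARY and curve.derivative(p.f) > 1.0)
        )
    ]
    if tips and tips[0] < target:
        return min(tips[0] + nudge, 1.0)
    return float(target)


def step_enforced(
    curve: AdoptionCurve,
    f: float,
    plan: PolicyPlan,
    tol: float = DEFAULT_SIM_TOL,
    equilibria: EquilibriumSet | None = None,
) -> tuple[float, float]:
    """Willing-first step with capacity-limited enforcement at stalls.

    Returns ``(new_coverage, enforced_added)``.  Enforcement activates only
    when the willing-first ratchet is at a rest point below the target and
    voluntary growth cannot reach the target from there on its own.
    """
    eq = equilibria if equilibria is not None else _fixed_points_cached(curve, tol)
    f1 = step_voluntary(curve, f)
    added = 0.0
    # stalled = voluntary growth effectively exhausted at this coverage level
    stalled = curve(f1) - f1 <= 0.1 * tol
    if f1 < plan.target and stalled:
        if _growth_limit(curve, f1, tol, eq) < plan.target - tol:
            goal = _enforcement_goal(curve, f1, plan.target, tol, eq)
            f2 = min(f1 + plan.enforcement_capacity, goal, 1.0)
            added = max(f2 - f1, 0.0)
            f1 = f2
    return f1, added


def _converged(
    curve: AdoptionCurve, f_prev: float, f_new: float, added: float,
    tol: float, eq: EquilibriumSet, plan: PolicyPlan | None = None,
) -> bool:
    if added != 0.0 or f_new - f_prev > tol:
        return False
    if (
        plan is not None
        and plan.regime == "enforced"
        and plan.enforcement_capacity > 0.0
        and f_new < plan.target - tol
        and _growth_limit(curve, f_new, tol, eq) < plan.target - tol
    ):
        return False  # enforcement still owed once the stall tightens
    if curve(f_new) <= f_new:  # at or above the curve: ratchet cannot move
        return True
    if f_new >= 1.0 - tol:
        return True
    # growing toward a fixed point: converged only once within tol of a
    # stable one (guards against premature stops just past a tipping point)
    above = [p for p in eq.points if p.f >= f_new - tol]
    return bool(above) and above[0].is_stable and above[0].f - f_new <= tol


def simulate(
    curve_pair: RegimeCurvePair,
    plan: PolicyPlan,
    f0: float = 0.0,
    tol: float = DEFAULT_SIM_TOL,
) -> Trajectory:
    """Iterate the regime's step map from ``f0`` for at most ``plan.horizon``
    periods, recording coverage, preference share, regret, and enforced doses.

    ``converged`` is False with the horizon exhausted if the dynamics were
    still moving (or still being enforced) at the last period.
    """
    if not 0.0 <= f0 <= 1.0:
        raise ValueError("f0 must lie in [0, 1]")
    curve = curve_pair.curve(plan.regime)
    eq = _fixed_points_cached(curve, tol)

    traj = Trajectory()
    f = float(f0)
    traj.steps.append(
        TrajectoryStep(0, f, float(curve(f)), max(0.0, f - float(curve(f))), 0.0)
    )
    for t in range(1, plan.horizon + 1):
        pref = float(curve(f))
        if plan.regime == "voluntary":
            f_new, added = step_voluntary(curve, f), 0.0
        else:
            f_new, added = step_enforced(curve, f, plan, tol, eq)
        traj.steps.append(
            TrajectoryStep(t, f_new, pref, max(0.0, f_new - float(curve(f_new))), added)
        )
        if _converged(curve, f, f_new, added, tol, eq, plan):
            traj.converged = True
            f = f_new
            break
        f = f_new
    traj.rest_point = float(f)
    traj.reached_target = f >= plan.target - tol
    return traj


def minimal_enforcement(
    curve: AdoptionCurve, target: float, tol: float = DEFAULT_SIM_TOL
) -> float:
    """Smallest fraction that must be vaccinated against their preference for
    coverage to reach ``target`` under the given curve, starting from f = 0.

    Zero if the voluntary rest point already reaches the target.  With a
    tipping point on the way to a stable point at or above the target, the
    cost of each stall is the distance from the rest point to the next
    tipping point; with no tipping route, every dose from the rest point up
    to the target must be enforced.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError("target must lie in (0, 1]")
    eq = _fixed_points_cached(curve, tol)
    f = ratchet_limit(curve, 0.0, tol, eq)
    total = 0.0
    while f < target - tol:
        tips = [
            p.f
            for p in eq.points
            if p.f > f + tol
            and (
                p.kind == EquilibriumKind.TIPPING
                or (p.kind == EquilibriumKind.BOUNDARY and curve.derivative(p.f) > 1.0)
            )
        ]
        if not tips or tips[0] >= target:
            total += target - f
            break
        tp = tips[0]
        total += tp - f
        after = [x for x in eq.locations if x > tp + tol]
        f = after[0] if after else (1.0 if curve(1.0) >= 1.0 - tol else target)
    return float(total)


def simulate_enforcement_first(
    curve_pair: RegimeCurvePair,
    plan: PolicyPlan,
    f0: float = 0.0,
    tol: float = DEFAULT_SIM_TOL,
) -> Trajectory:
    """Variant stepping used for order-of-operations checks: the enforcer
    tops up toward the target *before* observing voluntary uptake, then the
    willing are vaccinated.  Burns more enforced doses than willing-first."""
    if plan.regime != "enforced":
        raise ValueError("enforcement-first stepping requires an enforced plan")
    curve = curve_pair.curve("enforced")
    eq = _fixed_points_cached(curve, tol)
    traj = Trajectory()
    f = float(f0)
    traj.steps.append(
        TrajectoryStep(0, f, float(curve(f)), max(0.0, f - float(curve(f))), 0.0)
    )
    for t in range(1, plan.horizon + 1):
        pref = float(curve(f))
        added = 0.0
        f_mid = f
        if f < plan.target:
            f_mid = min(f + plan.enforcement_capacity, plan.target, 1.0)
            added = f_mid - f
        f_new = step_voluntary(curve, f_mid)
        traj.steps.append(
            TrajectoryStep(t, f_new, pref, max(0.0, f_new - float(curve(f_new))), added)
        )
        if _converged(curve, f, f_new, added, tol, eq):
            traj.converged = True
            f = f_new
            break
        f = f_new
    traj.rest_point = float(f)
    traj.reached_target = f >= plan.target - tol
    return traj
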