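"""Regime-specific adoption curves and their equilibrium structure.

An adoption curve maps the fraction of the population already vaccinated,
``f`` in [0, 1], to the fraction that prefers being vaccinated under a given
policy regime.  Two families are supported:

``gaussian_threshold``
    S-shaped curve from a truncated-normal distribution of conformism
    thresholds, renormalized so that the anchors ``p(0) = p0`` and
    ``p(1) = p1`` hold exactly.

``linear``
    Straight line between the same anchors (uniform threshold distribution).

The module also locates fixed points of ``p(f) = f`` (intersections with the
45-degree line), classifies them as stable rest points or tipping points, and
classifies voluntary/enforced scenario pairs against a coverage target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import (
    DegenerateContinuumError,
    DegenerateCurveError,
    InvalidAnchorError,
    RegimeOrderingError,
)

__all__ = [
    "AdoptionCurve",
    "RegimeCurvePair",
    "EquilibriumKind",
    "FixedPoint",
    "EquilibriumSet",
    "ScenarioReport",
    "make_gaussian_curve",
    "make_linear_curve",
    "fixed_points",
    "ratchet_limit",
    "classify_scenario",
    "gap_from_survey_shares",
]

GAUSSIAN = "gaussian_threshold"
LINEAR = "linear"

#: default bisection tolerance for fixed-point location
DEFAULT_TOL = 1e-8
#: default scan grid for sign changes (power of two plus one)
SCAN_GRID = 4097


@dataclass(frozen=True)
class AdoptionCurve:
    """Nondecreasing map from prior coverage to the share preferring vaccination.

    Values are fractions in [0, 1]; evaluation is vectorized over numpy arrays.
    """

    family: str
    p0: float
    p1: float
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p1 <= 1.0):
            raise InvalidAnchorError(
                f"anchors must lie in [0, 1]; got p0={self.p0}, p1={self.p1}"
            )
        if self.p0 > self.p1:
            raise InvalidAnchorError(f"p0={self.p0} exceeds p1={self.p1}")
        if self.family == GAUSSIAN:
            if self.sigma is None or self.sigma <= 0:
                raise DegenerateCurveError(f"sigma must be positive, got {self.sigma}")
            if self.mu is None:
                raise DegenerateCurveError("gaussian_threshold family requires mu")
        elif self.family == LINEAR:
            pass
        else:
            raise DegenerateCurveError(f"unknown curve family {self.family!r}")

    # -- evaluation -------------------------------------------------------

    def __call__(self, f):
        f = np.asarray(f, dtype=float)
        if self.family == LINEAR:
            out = self.p0 + (self.p1 - self.p0) * f
        else:
            lo = norm.cdf((0.0 - self.mu) / self.sigma)
            hi = norm.cdf((1.0 - self.mu) / self.sigma)
            z = (norm.cdf((f - self.mu) / self.sigma) - lo) / (hi - lo)
            out = self.p0 + (self.p1 - self.p0) * z
        return float(out) if out.ndim == 0 else out

    def derivative(self, f):
        """Analytic slope dp/df."""
        f = np.asarray(f, dtype=float)
        if self.family == LINEAR:
            out = np.full_like(f, self.p1 - self.p0)
        else:
            lo = norm.cdf((0.0 - self.mu) / self.sigma)
            hi = norm.cdf((1.0 - self.mu) / self.sigma)
            out = (
                (self.p1 - self.p0)
                * norm.pdf((f - self.mu) / self.sigma)
                / (self.sigma * (hi - lo))
            )
        return float(out) if out.ndim == 0 else out

    def max_slope(self, grid_points: int = 1001) -> float:
        fs = np.linspace(0.0, 1.0, grid_points)
        return float(np.max(self.derivative(fs)))


def make_gaussian_curve(p0: float, p1: float, mu: float, sigma: float) -> AdoptionCurve:
    """S-shaped curve with truncated-normal threshold distribution.

    ``p(f) = p0 + (p1 - p0) * [Phi((f-mu)/sigma) - Phi(-mu/sigma)]
    / [Phi((1-mu)/sigma) - Phi(-mu/sigma)]`` so both anchors hold exactly.
    """
    return AdoptionCurve(GAUSSIAN, float(p0), float(p1), float(mu), float(sigma))


def make_linear_curve(p0: float, p1: float) -> AdoptionCurve:
    """Linear curve ``p(f) = p0 + (p1 - p0) * f``."""
    return AdoptionCurve(LINEAR, float(p0), float(p1))


@dataclass(frozen=True)
class RegimeCurvePair:
    """Voluntary and enforced curves for the same population.

    Construction rejects pairs where the voluntary curve dips below the
    enforced curve anywhere on a dense grid; a lower maximum slope for the
    voluntary curve only triggers a warning (crowding out is expected to
    flatten the enforced curve, but this is a soft modelling assumption).
    """

    voluntary: AdoptionCurve
    enforced: AdoptionCurve

    def __post_init__(self) -> None:
        fs = np.linspace(0.0, 1.0, 1001)
        diff = self.voluntary(fs) - self.enforced(fs)
        if np.any(diff < -1e-12):
            worst = fs[int(np.argmin(diff))]
            raise RegimeOrderingError(
                f"voluntary curve falls below enforced curve near f={worst:.4f}"
            )
        if self.voluntary.max_slope() < self.enforced.max_slope() - 1e-12:
            warnings.warn(
                "enforced curve has larger maximum slope than voluntary curve",
                UserWarning,
                stacklevel=2,
            )

    def curve(self, regime: str) -> AdoptionCurve:
        if regime not in ("voluntary", "enforced"):
            raise ValueError(f"unknown regime {regime!r}")
        return self.voluntary if regime == "voluntary" else self.enforced

    def gap(self, f) -> np.ndarray:
        """Vertical voluntary-minus-enforced distance at coverage f (fraction)."""
        return self.voluntary(f) - self.enforced(f)


class EquilibriumKind(str, Enum):
    STABLE_LOW = "stable_low"
    TIPPING = "tipping"
    STABLE_HIGH = "stable_high"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class FixedPoint:
    f: float
    kind: EquilibriumKind

    @property
    def is_stable(self) -> bool:
        return self.kind in (EquilibriumKind.STABLE_LOW, EquilibriumKind.STABLE_HIGH)


@dataclass(frozen=True)
class EquilibriumSet:
    """Sorted fixed points of p(f) = f with stability classification."""

    points: tuple[FixedPoint, ...]

    @property
    def locations(self) -> tuple[float, ...]:
        return tuple(p.f for p in self.points)

    def of_kind(self, *kinds: EquilibriumKind) -> tuple[FixedPoint, ...]:
        return tuple(p for p in self.points if p.kind in kinds)

    @property
    def tipping_points(self) -> tuple[float, ...]:
        return tuple(p.f for p in self.points if p.kind == EquilibriumKind.TIPPING)


def _bisect_root(curve: AdoptionCurve, lo: float, hi: float, xtol: float) -> float:
    g = lambda f: curve(f) - f
    return float(brentq(g, lo, hi, xtol=xtol))


def fixed_points(
    curve: AdoptionCurve,
    tol: float = DEFAULT_TOL,
    grid_points: int = SCAN_GRID,
) -> EquilibriumSet:
    """Locate all solutions of p(f) = f on [0, 1].

    A dense sign-change scan brackets each crossing, refined by bisection to
    well below ``tol``.  A crossing from below to above the 45-degree line is
    a tipping point; from above to below is stable.  Touching (tangent)
    contacts are conservatively classified as tipping.  The endpoint f=1 is
    included as ``stable_high`` when p(1) >= 1 - tol; a fixed point at f=0 is
    labelled ``boundary``.

    Raises
    ------
    DegenerateContinuumError
        If |p(f) - f| < tol on more than half of the scan grid.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    fs = np.linspace(0.0, 1.0, grid_points)
    g = curve(fs) - fs
    if np.mean(np.abs(g) < tol) > 0.5:
        raise DegenerateContinuumError(
            "curve coincides with the 45-degree line on most of [0, 1]"
        )
    xtol = max(tol * 1e-4, 1e-14)

    roots: list[tuple[float, EquilibriumKind]] = []

    # boundary fixed point at f = 0
    if abs(g[0]) <= tol:
        roots.append((0.0, EquilibriumKind.BOUNDARY))

    # interior sign changes
    for i in range(grid_points - 1):
        a, b = g[i], g[i + 1]
        if a == 0.0 and fs[i] > 0.0:
            lo_side = g[i - 1] if i > 0 else 0.0
            if lo_side > 0.0 > b:
                kind = EquilibriumKind.STABLE_LOW
            else:  # genuine upward crossing or tangency: treat as tipping
                kind = EquilibriumKind.TIPPING
            roots.append((float(fs[i]), kind))
        elif a * b < 0:
            root = _bisect_root(curve, float(fs[i]), float(fs[i + 1]), xtol)
            kind = EquilibriumKind.TIPPING if (a < 0 < b) else EquilibriumKind.STABLE_LOW
            roots.append((root, kind))

    # tangency sweep: near-zero local minima of |g| without a sign change
    absg = np.abs(g)
    near = absg < tol
    if np.any(near):
        known = np.array([r[0] for r in roots]) if roots else np.empty(0)
        h = fs[1] - fs[0]
        for i in np.flatnonzero(near):
            if i == 0 or i == grid_points - 1:
                continue  # endpoints handled separately
            fi = fs[i]
            if known.size and np.min(np.abs(known - fi)) < 2 * h:
                continue
            is_min = (i == 0 or absg[i] <= absg[i - 1]) and (
                i == grid_points - 1 or absg[i] <= absg[i + 1]
            )
            if is_min:
                roots.append((float(fi), EquilibriumKind.TIPPING))
                known = np.append(known, fi)

    # endpoint f = 1
    if curve(1.0) >= 1.0 - tol and all(abs(r[0] - 1.0) > tol for r in roots):
        roots.append((1.0, EquilibriumKind.STABLE_HIGH))

    roots.sort(key=lambda r: r[0])

    # relabel stable points: highest stable above a tipping point is stable_high
    tippings = [f for f, k in roots if k == EquilibriumKind.TIPPING]
    out: list[FixedPoint] = []
    stable_fs = [f for f, k in roots if k in (EquilibriumKind.STABLE_LOW, EquilibriumKind.STABLE_HIGH)]
    top_stable = max(stable_fs) if stable_fs else None
    for f, k in roots:
        if k in (EquilibriumKind.STABLE_LOW, EquilibriumKind.STABLE_HIGH):
            if f >= 1.0 - tol:
                k = EquilibriumKind.STABLE_HIGH
            elif f == top_stable and any(t < f for t in tippings):
                k = EquilibriumKind.STABLE_HIGH
            else:
                k = EquilibriumKind.STABLE_LOW
        out.append(FixedPoint(f, k))
    return EquilibriumSet(tuple(out))


@lru_cache(maxsize=256)
def _fixed_points_cached(curve: AdoptionCurve, tol: float) -> EquilibriumSet:
    return fixed_points(curve, tol)


def _is_repelling(curve: AdoptionCurve, f: float) -> bool:
    return curve.derivative(f) > 1.0


def ratchet_limit(
    curve: AdoptionCurve,
    f0: float,
    tol: float = DEFAULT_TOL,
    equilibria: EquilibriumSet | None = None,
) -> float:
    """Rest point of the ratchet map f -> max(f, p(f)) started at ``f0``.

    Coverage grows while the curve lies above the 45-degree line and stops at
    the first fixed point at or above ``f0``.  If ``f0`` is already at or
    above the curve, it is its own rest point.
    """
    if not 0.0 <= f0 <= 1.0:
        raise ValueError("f0 must lie in [0, 1]")
    if curve(f0) <= f0 + tol:
        return float(f0)
    eq = equilibria if equilibria is not None else _fixed_points_cached(curve, tol)
    above = [x for x in eq.locations if x > f0 + tol]
    if above:
        return above[0]
    return 1.0 if curve(1.0) >= 1.0 - tol else float(f0)


@dataclass(frozen=True)
class ScenarioReport:
    """Classification of a curve pair against a coverage target.

    ``enforcement_burden`` is the fraction that must be vaccinated against
    their preference to move enforced-regime coverage from its low rest point
    past the tipping point(s) needed to reach the target (0 if the target is
    reached voluntarily under enforcement).
    """

    classification: str  # "optimistic" | "pessimistic"
    target: float
    voluntary_limit: float
    enforced_limit: float
    enforcement_burden: float

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "target": self.target,
            "voluntary_limit": self.voluntary_limit,
            "enforced_limit": self.enforced_limit,
            "enforcement_burden": self.enforcement_burden,
        }


def classify_scenario(
    pair: RegimeCurvePair, target: float, tol: float = DEFAULT_TOL
) -> ScenarioReport:
    """Classify a scenario as optimistic (voluntary policy reaches the target
    from zero coverage) or pessimistic, and compute the enforcement burden."""
    if not 0.0 < target <= 1.0:
        raise ValueError("target must lie in (0, 1]")
    # local import: dynamics depends on this module for curve machinery
    from .dynamics import minimal_enforcement

    voluntary_limit = ratchet_limit(pair.voluntary, 0.0, tol)
    enforced_limit = ratchet_limit(pair.enforced, 0.0, tol)
    optimistic = voluntary_limit >= target - tol
    burden = minimal_enforcement(pair.enforced, target, tol)
    return ScenarioReport(
        classification="optimistic" if optimistic else "pessimistic",
        target=float(target),
        voluntary_limit=float(voluntary_limit),
        enforced_limit=float(enforced_limit),
        enforcement_burden=float(burden),
    )


def gap_from_survey_shares(voluntary_support: float, enforced_support: float) -> float:
    """Survey-implied vertical gap between the curves, in percentage points.

    Negative gaps are returned as-is; callers decide whether to warn.
    """
    for name, s in (("voluntary", voluntary_support), ("enforced", enforced_support)):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{name} support share must lie in [0, 1], got {s}")
    return 100.0 * (voluntary_support - enforced_support)
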