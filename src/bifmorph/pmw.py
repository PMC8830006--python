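"""Principle-of-minimum-work (PMW) optimality indices for one bifurcation.

Murray's analysis of an energetically optimal vascular tree predicts, for a
bifurcation with parent radius ``r0`` and branch radii ``r1 >= r2``:

* a *junction exponent* ``n`` solving ``r0**n = r1**n + r2**n`` (the
  energetic optimum is ``n = 3``, the cube law);
* *optimal branch angles* ``phi1_opt``, ``phi2_opt`` (and their sum) given by
  law-of-cosines-type expressions in the squared radii:

      cos(phi1_opt)            = (r0**4 + r1**4 - r2**4) / (2 r0**2 r1**2)
      cos(phi2_opt)            = (r0**4 + r2**4 - r1**4) / (2 r0**2 r2**2)
      cos(phi1_opt + phi2_opt) = (r0**4 - r1**4 - r2**4) / (2 r1**2 r2**2)

All three cosines lie in [-1, 1] exactly when the squared radii
``(r0**2, r1**2, r2**2)`` satisfy the triangle inequality; outside that
domain no real optimal angle exists and the result is flagged *undefined*
rather than silently clamped (clamping is available as an explicit opt-in).
Two shape descriptors complete the set: the asymmetry ratio ``r2**2/r1**2``
and the area ratio ``(r1**2 + r2**2)/r0**2``.

Deviations of the observed geometry from the PMW optimum are the signed
differences predicted minus observed: ``(phi1_opt+phi2_opt) - alpha``,
``phi1_opt - Phi1`` and ``phi2_opt - Phi2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from scipy.optimize import brentq

from .geometry import ObservedAngles, ValidationError

JUNCTION_EXPONENT_BRACKET = (0.05, 50.0)
JUNCTION_EXPONENT_RTOL = 1e-9
_MAX_BRACKET_EXPANSIONS = 3


class DomainStatus(str, Enum):
    """Whether the PMW predictions exist for a radius triple."""

    VALID = "valid"
    EXPONENT_UNDEFINED = "exponent_undefined"
    ANGLES_UNDEFINED = "angles_undefined"
    BOTH_UNDEFINED = "both_undefined"
    ANGLES_CLAMPED = "angles_clamped"


@dataclass(frozen=True)
class RadiiTriple:
    """Radii of parent (r0), larger branch (r1) and smaller branch (r2), mm."""

    r0: float
    r1: float
    r2: float

    def __post_init__(self) -> None:
        for name in ("r0", "r1", "r2"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"radius {name} must be positive, got {v}")
        if self.r1 < self.r2:
            raise ValidationError(
                f"r1 must be >= r2 (larger branch first), got r1={self.r1}, r2={self.r2}"
            )


@dataclass(frozen=True)
class PmwIndices:
    """PMW-derived indices; angle/exponent fields are None when undefined."""

    asymmetry_ratio: float
    area_ratio: float
    junction_exponent: Optional[float]
    phi1_opt_deg: Optional[float]
    phi2_opt_deg: Optional[float]
    total_opt_deg: Optional[float]
    domain_status: DomainStatus
    undefined_reason: Optional[str] = None


@dataclass(frozen=True)
class DeviationSet:
    """Signed predicted-minus-observed angle deviations, degrees."""

    dev_total_deg: Optional[float]
    dev_phi1_deg: Optional[float]
    dev_phi2_deg: Optional[float]


def asymmetry_ratio(r: RadiiTriple) -> float:
    """Branch size imbalance ``r2**2 / r1**2``; 1 means symmetric branches."""
    return (r.r2 / r.r1) ** 2


def area_ratio(r: RadiiTriple) -> float:
    """Combined branch cross-section relative to the parent,
    ``(r1**2 + r2**2) / r0**2``."""
    return (r.r1 ** 2 + r.r2 ** 2) / r.r0 ** 2


def junction_exponent(
    r: RadiiTriple,
    bracket: tuple[float, float] = JUNCTION_EXPONENT_BRACKET,
    tol: float = JUNCTION_EXPONENT_RTOL,
) -> tuple[Optional[float], Optional[str]]:
    """Solve ``r0**n = r1**n + r2**n`` for the junction exponent ``n > 0``.

    Works on ``f(n) = (r1/r0)**n + (r2/r0)**n - 1``, which for
    ``r0 > r1 >= r2`` is strictly decreasing from ``f(0) = 1`` towards -1,
    so a bracketed Brent search is globally convergent.  Returns
    ``(n, None)`` on success or ``(None, reason)`` when no unique positive
    root exists (``r0 <= r1``) or the root escapes the bracket even after
    adaptive expansion.
    """
    if r.r0 <= r.r1:
        return None, "no unique positive root (r0 <= r1)"
    a, b = bracket

    def f(n: float) -> float:
        return (r.r1 / r.r0) ** n + (r.r2 / r.r0) ** n - 1.0

    for _ in range(_MAX_BRACKET_EXPANSIONS + 1):
        if f(a) > 0.0 >= f(b):
            n = brentq(f, a, b, rtol=tol, xtol=1e-15)
            return float(n), None
        a, b = a / 10.0, b * 10.0
    return None, f"root not bracketed in {bracket} after expansion"


def _pmw_cosines(r: RadiiTriple) -> tuple[float, float, float]:
    r0sq, r1sq, r2sq = r.r0 ** 2, r.r1 ** 2, r.r2 ** 2
    c1 = (r0sq ** 2 + r1sq ** 2 - r2sq ** 2) / (2.0 * r0sq * r1sq)
    c2 = (r0sq ** 2 + r2sq ** 2 - r1sq ** 2) / (2.0 * r0sq * r2sq)
    c12 = (r0sq ** 2 - r1sq ** 2 - r2sq ** 2) / (2.0 * r1sq * r2sq)
    return c1, c2, c12


def optimal_angles(
    r: RadiiTriple, clamp_mode: bool = False
) -> tuple[Optional[float], Optional[float], Optional[float], bool]:
    """PMW-optimal branch angles (phi1, phi2, phi1+phi2) in degrees.

    Returns ``(phi1, phi2, total, clamped)``.  When any of the three cosines
    falls outside [-1, 1] the triple is geometrically unrealisable: the
    default returns ``(None, None, None, False)``; with ``clamp_mode`` the
    cosines are clamped to +/-1 and ``clamped=True`` marks the record.
    """
    c1, c2, c12 = _pmw_cosines(r)
    # overshoot within 1e-12 is floating-point noise at the domain boundary
    in_domain = all(abs(c) <= 1.0 + 1e-12 for c in (c1, c2, c12))
    if not in_domain and not clamp_mode:
        return None, None, None, False
    clamped = not in_domain
    c1, c2, c12 = (min(1.0, max(-1.0, c)) for c in (c1, c2, c12))
    phi1 = math.degrees(math.acos(c1))
    phi2 = math.degrees(math.acos(c2))
    total = math.degrees(math.acos(c12))
    return phi1, phi2, total, clamped


def pmw_indices(r: RadiiTriple, clamp_mode: bool = False) -> PmwIndices:
    """All PMW indices for one radius triple, with a joint domain status."""
    n, n_reason = junction_exponent(r)
    phi1, phi2, total, clamped = optimal_angles(r, clamp_mode=clamp_mode)
    angles_ok = phi1 is not None and not clamped
    reasons = []
    if n is None:
        reasons.append(f"junction exponent: {n_reason}")
    if phi1 is None:
        reasons.append("optimal angles: cosine outside [-1, 1] "
                       "(squared radii violate the triangle inequality)")
    elif clamped:
        reasons.append("optimal angles: cosine clamped to [-1, 1]")
    if n is not None and angles_ok:
        status = DomainStatus.VALID
    elif n is None and phi1 is None:
        status = DomainStatus.BOTH_UNDEFINED
    elif n is None:
        status = DomainStatus.EXPONENT_UNDEFINED
    elif phi1 is None:
        status = DomainStatus.ANGLES_UNDEFINED
    else:
        status = DomainStatus.ANGLES_CLAMPED
    return PmwIndices(
        asymmetry_ratio=asymmetry_ratio(r),
        area_ratio=area_ratio(r),
        junction_exponent=n,
        phi1_opt_deg=phi1,
        phi2_opt_deg=phi2,
        total_opt_deg=total,
        domain_status=status,
        undefined_reason="; ".join(reasons) or None,
    )


@dataclass(frozen=True)
class BifurcationMorphometry:
    """Complete morphometric description of one bifurcation:
    radii, observed angles, PMW indices and deviations."""

    radii: RadiiTriple
    observed: ObservedAngles
    indices: PmwIndices
    devs: "DeviationSet"


def measure_bifurcation(
    radii: RadiiTriple, obs: ObservedAngles, clamp_mode: bool = False
) -> BifurcationMorphometry:
    """Compute every PMW index and deviation for one measured bifurcation."""
    pred = pmw_indices(radii, clamp_mode=clamp_mode)
    return BifurcationMorphometry(
        radii=radii, observed=obs, indices=pred, devs=deviations(obs, pred)
    )


def deviations(obs: ObservedAngles, pred: PmwIndices) -> DeviationSet:
    """Signed predicted-minus-observed deviations; undefined propagates."""
    if pred.total_opt_deg is None:
        return DeviationSet(None, None, None)
    return DeviationSet(
        dev_total_deg=pred.total_opt_deg - obs.alpha_deg,
        dev_phi1_deg=pred.phi1_opt_deg - obs.phi1_obs_deg,
        dev_phi2_deg=pred.phi2_opt_deg - obs.phi2_obs_deg,
    )
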