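"""Bifurcation geometry: from 3D landmarks to observed angles and radii.

A bifurcation is described by four landmarks: ``A`` on the parent vessel,
``B`` on the larger branch, ``C`` on the smaller branch, and ``O``, the
intersection of the vessel centrelines, which is the apex of every angle
measured here.  Three observed angles are formed at ``O``:

* ``alpha`` — the total bifurcation angle, between arms ``OB`` and ``OC``;
* ``beta``  — between the parent arm ``OA`` and the larger branch ``OB``;
* ``gamma`` — between the parent arm ``OA`` and the smaller branch ``OC``.

The branch angles relative to the *extended* parent axis are then

    Phi1 = 180 - beta,    Phi2 = 180 - gamma,

and the vessel radii come from the best-fit diameters as ``r = d / 2``.
All angles are handled in degrees; radians appear only inside the
trigonometric calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("bifmorph")

#: landmarks closer to the apex than this are suspicious (upstream extraction
#: is supposed to place curvature points at least 5 mm from the bifurcation)
MIN_ARM_LENGTH_MM = 5.0

#: cosines may overshoot 1 by at most this much before we refuse to clamp
COS_CLAMP_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """A landmark coincides with the angle apex (zero-length arm)."""


class ValidationError(ValueError):
    """An input value violates a type invariant."""


@dataclass
class BifurcationLandmarks:
    """3D landmark set for one bifurcation, coordinates in millimetres.

    ``point_A``/``point_B``/``point_C`` are the largest-curvature points on
    the parent vessel, larger branch and smaller branch; ``point_O`` is the
    centreline intersection.  ``d0, d1, d2`` are the best-fit diameters (mm)
    of parent, larger branch and smaller branch.  If ``d1 < d2`` on input the
    two branches are swapped (points and diameters together) so that B always
    labels the larger branch; the swap is recorded in ``branches_swapped``
    and logged, never silent.
    """

    point_A: np.ndarray
    point_B: np.ndarray
    point_C: np.ndarray
    point_O: np.ndarray
    d0: float
    d1: float
    d2: float
    branches_swapped: bool = field(default=False)

    def __post_init__(self) -> None:
        for name in ("point_A", "point_B", "point_C", "point_O"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,):
                raise ValidationError(f"{name} must be a 3-vector, got shape {p.shape}")
            if not np.all(np.isfinite(p)):
                raise ValidationError(f"{name} contains non-finite coordinates")
            setattr(self, name, p)
        for name in ("d0", "d1", "d2"):
            d = float(getattr(self, name))
            if not math.isfinite(d) or d <= 0:
                raise ValidationError(f"diameter {name} must be positive, got {d}")
            setattr(self, name, d)
        for name in ("point_A", "point_B", "point_C"):
            if np.array_equal(getattr(self, name), self.point_O):
                raise DegenerateGeometryError(
                    f"{name} coincides with the apex point_O"
                )
        if self.d1 < self.d2:
            self.point_B, self.point_C = self.point_C, self.point_B
            self.d1, self.d2 = self.d2, self.d1
            self.branches_swapped = True
            logger.info("branches swapped so that B labels the larger branch "
                        "(input had d1 < d2)")
        for name in ("point_A", "point_B", "point_C"):
            arm = float(np.linalg.norm(getattr(self, name) - self.point_O))
            if arm < MIN_ARM_LENGTH_MM:
                logger.warning(
                    "arm O-%s is %.2f mm, below the %.0f mm curvature-point "
                    "distance rule", name[-1], arm, MIN_ARM_LENGTH_MM,
                )


@dataclass(frozen=True)
class ObservedAngles:
    """Observed bifurcation angles in degrees.

    ``phi1_obs_deg = 180 - beta_deg`` and ``phi2_obs_deg = 180 - gamma_deg``
    by construction (branch angles measured from the extended parent axis).
    """

    alpha_deg: float
    beta_deg: float
    gamma_deg: float
    phi1_obs_deg: float
    phi2_obs_deg: float

    def __post_init__(self) -> None:
        for name in ("alpha_deg", "beta_deg", "gamma_deg",
                     "phi1_obs_deg", "phi2_obs_deg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 180.0):
                raise ValidationError(f"{name}={v} outside [0, 180]")


def angle_between(apex: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Angle at ``apex`` between arms ``apex->p`` and ``apex->q``, in degrees.

    The cosine is clamped against floating-point overshoot of at most
    ``COS_CLAMP_TOL``; a larger overshoot indicates a real numerical problem
    and raises.
    """
    apex = np.asarray(apex, dtype=float)
    u = np.asarray(p, dtype=float) - apex
    v = np.asarray(q, dtype=float) - apex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0:
        raise DegenerateGeometryError(f"point {p!r} coincides with the apex")
    if nv == 0.0:
        raise DegenerateGeometryError(f"point {q!r} coincides with the apex")
    c = float(np.dot(u, v) / (nu * nv))
    if abs(c) > 1.0:
        if abs(c) > 1.0 + COS_CLAMP_TOL:
            raise ValidationError(f"cosine overshoot too large: {c!r}")
        c = math.copysign(1.0, c)
    return math.degrees(math.acos(c))


def compute_observed_angles(lm: BifurcationLandmarks) -> ObservedAngles:
    """Measure alpha, beta, gamma at the apex O and derive Phi1, Phi2."""
    alpha = angle_between(lm.point_O, lm.point_B, lm.point_C)
    beta = angle_between(lm.point_O, lm.point_A, lm.point_B)
    gamma = angle_between(lm.point_O, lm.point_A, lm.point_C)
    return ObservedAngles(
        alpha_deg=alpha,
        beta_deg=beta,
        gamma_deg=gamma,
        phi1_obs_deg=180.0 - beta,
        phi2_obs_deg=180.0 - gamma,
    )


def radius_from_diameter(d: float) -> float:
    """Vessel radius from best-fit diameter, ``r = d / 2`` (mm)."""
    d = float(d)
    if not math.isfinite(d) or d <= 0:
        raise ValidationError(f"diameter must be positive, got {d}")
    return d / 2.0
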