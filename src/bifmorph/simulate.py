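"""Synthetic case-control cohorts of cerebral arterial bifurcations.

Real bifurcation morphometry comes from CTA-derived 3D models, which are
not shippable; this module generates cohorts with the same statistical
skeleton so every downstream stage (geometry, PMW indices, group
comparisons, logistic/ROC analysis) can be exercised and parameter recovery
asserted against a known ground truth.

Per site-within-group block, radii ``(r0, r1, r2)`` are drawn from a
truncated trivariate normal with exchangeable correlation ``rho`` and the
anatomical ordering ``r0 > r1 >= r2`` enforced by resampling; angles
``(alpha, Phi1, Phi2)`` are drawn from truncated normals on (0, 180).  An
"aneurysm effect" — an additive widening of ``alpha`` and enlargement of
``r0`` — is applied to the sites designated as aneurysmal.  The default
calibration reproduces the group-by-site means and SDs of a published
three-group (MCA-aneurysm / BA-aneurysm / control), five-site case-control
cohort; aneurysmal-site blocks carry the printed aneurysmal means, so the
default effect shifts are zero.

Optionally each record is rendered as four 3D landmark points at a random
rigid pose whose measured angles reproduce the drawn ones, inverting the
angle construction used by :mod:`bifmorph.geometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .geometry import BifurcationLandmarks, ObservedAngles, ValidationError
from .pmw import RadiiTriple, measure_bifurcation, optimal_angles
from .stats import CohortRecord

MAX_RESAMPLE_ATTEMPTS = 1000


class SimulationError(RuntimeError):
    """Configuration constraints could not be satisfied while sampling."""


@dataclass(frozen=True)
class SiteBlock:
    """Sampling distribution for one site within one group."""

    site: str
    n: int
    r0_mean: float
    r0_sd: float
    r1_mean: float
    r1_sd: float
    r2_mean: float
    r2_sd: float
    alpha_mean: float
    alpha_sd: float
    phi1_mean: float
    phi1_sd: float
    phi2_mean: float
    phi2_sd: float
    aneurysmal: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"site {self.site!r}: n must be >= 1")
        for name in ("r0_sd", "r1_sd", "r2_sd", "alpha_sd", "phi1_sd", "phi2_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"site {self.site!r}: {name} must be > 0")


@dataclass(frozen=True)
class AneurysmEffect:
    """Additive shifts applied to aneurysmal sites (angle widening +
    parent-radius enlargement)."""

    alpha_shift_deg: float = 0.0
    r0_shift_mm: float = 0.0


@dataclass
class SimulationConfig:
    """Full cohort layout: per-group site blocks plus global knobs.

    ``rho`` is the exchangeable correlation of the radius triple;
    ``radius_min_mm`` and the (0, 180) angle band are the truncation limits;
    ``angle_mode`` is ``"independent"`` (angles drawn from their own
    truncated normals) or ``"pmw_coupled"`` (angles derived from the PMW
    optimum of the drawn radii plus truncated-normal noise with the block
    SDs).  ``output_mode`` selects whether 3D landmarks are rendered.
    """

    groups: dict = field(default_factory=dict)  # group -> list[SiteBlock]
    effect: AneurysmEffect = field(default_factory=AneurysmEffect)
    rho: float = 0.5
    radius_min_mm: float = 0.2
    seed: Optional[int] = None
    output_mode: str = "morphometry"  # or "landmarks"
    angle_mode: str = "independent"  # or "pmw_coupled"
    clamp_mode: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("simulation seed is mandatory")
        if not -0.99 < self.rho < 0.99:
            raise ValidationError(f"rho={self.rho} outside (-0.99, 0.99)")
        if self.output_mode not in ("morphometry", "landmarks"):
            raise ValidationError(f"unknown output_mode {self.output_mode!r}")
        if self.angle_mode not in ("independent", "pmw_coupled"):
            raise ValidationError(f"unknown angle_mode {self.angle_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        groups = {
            g: [SiteBlock(**blk) for blk in blocks]
            for g, blocks in d["groups"].items()
        }
        eff = AneurysmEffect(**d.get("aneurysm_effect", {}))
        return cls(
            groups=groups, effect=eff,
            rho=d.get("rho", 0.5),
            radius_min_mm=d.get("radius_min_mm", 0.2),
            seed=d["seed"],
            output_mode=d.get("output_mode", "morphometry"),
            angle_mode=d.get("angle_mode", "independent"),
            clamp_mode=d.get("clamp_mode", False),
        )

    def to_dict(self) -> dict:
        return {
            "groups": {g: [asdict(b) for b in blocks]
                       for g, blocks in self.groups.items()},
            "aneurysm_effect": asdict(self.effect),
            "rho": self.rho,
            "radius_min_mm": self.radius_min_mm,
            "seed": self.seed,
            "output_mode": self.output_mode,
            "angle_mode": self.angle_mode,
            "clamp_mode": self.clamp_mode,
        }


@dataclass
class SyntheticCohort:
    """Generated records plus the ground truth actually applied."""

    records: list  # list[CohortRecord]
    landmarks: Optional[list]  # parallel list[BifurcationLandmarks] or None
    ground_truth: dict


# ---------------------------------------------------------------------------
# calibration: group-by-site means +/- SD of the emulated cohort
# (alpha, phi1, phi2 in degrees; radii in mm)
# ---------------------------------------------------------------------------

def _blk(site, n, alpha, phi1, phi2, r0, r1, r2, aneurysmal=False):
    return SiteBlock(
        site=site, n=n,
        alpha_mean=alpha[0], alpha_sd=alpha[1],
        phi1_mean=phi1[0], phi1_sd=phi1[1],
        phi2_mean=phi2[0], phi2_sd=phi2[1],
        r0_mean=r0[0], r0_sd=r0[1],
        r1_mean=r1[0], r1_sd=r1[1],
        r2_mean=r2[0], r2_sd=r2[1],
        aneurysmal=aneurysmal,
    )


def default_config(seed: int, output_mode: str = "morphometry") -> SimulationConfig:
    """Three-group, five-site cohort calibrated to the emulated study.

    Aneurysmal-site blocks (MCA_an, BA_an) carry the aneurysmal means
    directly, so the configured effect shifts are zero.
    """
    groups = {
        "MCA_an": [
            _blk("MCA_an", 119, (128.2, 24.2), (59.6, 25.2), (81.5, 21.7),
                 (1.40, 0.18), (1.16, 0.17), (0.87, 0.20), aneurysmal=True),
            _blk("MCA_contra", 92, (105.9, 19.1), (47.3, 20.9), (68.2, 20.4),
                 (1.42, 0.18), (1.17, 0.19), (0.91, 0.19)),
            _blk("ICA_L", 108, (114.8, 15.4), (39.9, 30.3), (86.8, 27.4),
                 (1.85, 0.20), (1.48, 0.18), (1.13, 0.17)),
            _blk("ICA_R", 107, (116.4, 18.7), (44.9, 31.3), (88.2, 28.2),
                 (1.86, 0.24), (1.48, 0.21), (1.12, 0.22)),
            _blk("BA", 93, (107.37, 19.27), (54.60, 20.23), (60.51, 17.87),
                 (1.57, 0.22), (1.17, 0.21), (0.96, 0.24)),
        ],
        "BA_an": [
            _blk("BA", 32, (136.68, 22.98), (71.70, 18.95), (77.07, 24.00),
                 (1.76, 0.36), (1.31, 0.25), (1.01, 0.23), aneurysmal=True),
            _blk("MCA_L", 23, (93.3, 18.0), (49.9, 27.0), (57.8, 25.2),
                 (1.49, 0.25), (1.21, 0.23), (0.94, 0.18)),
            _blk("MCA_R", 23, (103.4, 25.8), (47.7, 23.0), (66.4, 20.5),
                 (1.54, 0.21), (1.24, 0.23), (0.95, 0.22)),
            _blk("ICA_L", 29, (120.7, 26.4), (45.6, 19.2), (93.2, 15.6),
                 (1.91, 0.23), (1.48, 0.23), (1.17, 0.24)),
            _blk("ICA_R", 28, (119.4, 18.4), (35.6, 16.8), (96.0, 13.8),
                 (1.92, 0.23), (1.53, 0.19), (1.16, 0.21)),
        ],
        "control": [
            _blk("MCA_L", 91, (93.2, 19.6), (42.4, 23.0), (65.3, 18.2),
                 (1.31, 0.20), (1.11, 0.21), (0.84, 0.18)),
            _blk("MCA_R", 91, (97.1, 20.5), (46.8, 23.1), (61.0, 19.4),
                 (1.35, 0.16), (1.15, 0.18), (0.86, 0.17)),
            _blk("ICA_L", 100, (119.1, 14.7), (40.4, 20.6), (92.5, 19.1),
                 (1.82, 0.22), (1.46, 0.23), (1.13, 0.26)),
            _blk("ICA_R", 99, (120.2, 14.8), (41.7, 20.4), (95.0, 17.4),
                 (1.85, 0.23), (1.49, 0.22), (1.15, 0.25)),
            _blk("BA", 91, (107.02, 23.55), (55.73, 19.19), (58.23, 20.82),
                 (1.58, 0.25), (1.12, 0.22), (0.92, 0.27)),
        ],
    }
    return SimulationConfig(groups=groups, seed=seed, output_mode=output_mode)


def recovery_config(
    seed: int,
    n_per_arm: int = 120,
    alpha_shift_deg: float = 25.0,
    r0_shift_mm: float = 0.15,
    output_mode: str = "morphometry",
) -> SimulationConfig:
    """Two-arm effect-recovery design: MCA-calibrated control baseline in
    both arms, with a configurable aneurysm effect (angle widening +
    parent-radius enlargement) on the case arm only."""
    base = dict(alpha=(95.1, 20.0), phi1=(44.6, 23.0), phi2=(63.1, 18.8),
                r0=(1.33, 0.18), r1=(1.13, 0.20), r2=(0.85, 0.18))
    groups = {
        "case": [_blk("MCA_an", n_per_arm, base["alpha"], base["phi1"],
                      base["phi2"], base["r0"], base["r1"], base["r2"],
                      aneurysmal=True)],
        "control": [_blk("MCA", n_per_arm, base["alpha"], base["phi1"],
                         base["phi2"], base["r0"], base["r1"], base["r2"])],
    }
    return SimulationConfig(
        groups=groups,
        effect=AneurysmEffect(alpha_shift_deg=alpha_shift_deg,
                              r0_shift_mm=r0_shift_mm),
        seed=seed,
        output_mode=output_mode,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_radii(rng: np.random.Generator, blk: SiteBlock, rho: float,
                  r0_shift: float, radius_min: float) -> RadiiTriple:
    mean = np.array([blk.r0_mean + r0_shift, blk.r1_mean, blk.r2_mean])
    sd = np.array([blk.r0_sd, blk.r1_sd, blk.r2_sd])
    cov = np.outer(sd, sd) * (np.full((3, 3), rho) + (1 - rho) * np.eye(3))
    for _ in range(MAX_RESAMPLE_ATTEMPTS):
        r0, r1, r2 = rng.multivariate_normal(mean, cov)
        if r0 > r1 >= r2 > radius_min:
            return RadiiTriple(float(r0), float(r1), float(r2))
    raise SimulationError(
        f"site {blk.site!r}: could not draw radii with r0 > r1 >= r2 > "
        f"{radius_min} in {MAX_RESAMPLE_ATTEMPTS} attempts — check that the "
        f"configured means respect the ordering"
    )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, what: str) -> float:
    for _ in range(MAX_RESAMPLE_ATTEMPTS):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    raise SimulationError(
        f"could not draw {what} in ({lo}, {hi}) around {mean} +/- {sd}")


def _sample_angles(rng: np.random.Generator, blk: SiteBlock, radii: RadiiTriple,
                   alpha_shift: float, angle_mode: str,
                   require_3d_feasible: bool) -> tuple[float, float, float]:
    if angle_mode == "pmw_coupled":
        p1, p2, tot, _ = optimal_angles(radii, clamp_mode=True)
        mu_a, mu_1, mu_2 = tot + alpha_shift, p1, p2
    else:
        mu_a = blk.alpha_mean + alpha_shift
        mu_1, mu_2 = blk.phi1_mean, blk.phi2_mean
    for _ in range(MAX_RESAMPLE_ATTEMPTS):
        alpha = _trunc_normal(rng, mu_a, blk.alpha_sd, 0.0, 180.0, "alpha")
        phi1 = _trunc_normal(rng, mu_1, blk.phi1_sd, 0.0, 180.0, "phi1")
        phi2 = _trunc_normal(rng, mu_2, blk.phi2_sd, 0.0, 180.0, "phi2")
        if not require_3d_feasible:
            return alpha, phi1, phi2
        if abs(phi1 - phi2) <= alpha <= phi1 + phi2:
            return alpha, phi1, phi2
    raise SimulationError(
        f"site {blk.site!r}: no 3D-realisable angle triple in "
        f"{MAX_RESAMPLE_ATTEMPTS} attempts")


def generate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Draw the full cohort specified by ``cfg``; deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    records: list[CohortRecord] = []
    landmarks: Optional[list] = [] if cfg.output_mode == "landmarks" else None
    counter = 0
    for group in sorted(cfg.groups):
        for blk in cfg.groups[group]:
            a_shift = cfg.effect.alpha_shift_deg if blk.aneurysmal else 0.0
            r_shift = cfg.effect.r0_shift_mm if blk.aneurysmal else 0.0
            for _ in range(blk.n):
                counter += 1
                radii = _sample_radii(rng, blk, cfg.rho, r_shift,
                                      cfg.radius_min_mm)
                alpha, phi1, phi2 = _sample_angles(
                    rng, blk, radii, a_shift, cfg.angle_mode,
                    require_3d_feasible=cfg.output_mode == "landmarks")
                obs = ObservedAngles(
                    alpha_deg=alpha, beta_deg=180.0 - phi1,
                    gamma_deg=180.0 - phi2,
                    phi1_obs_deg=phi1, phi2_obs_deg=phi2,
                )
                morph = measure_bifurcation(radii, obs,
                                            clamp_mode=cfg.clamp_mode)
                rec = CohortRecord(
                    subject_id=f"S{counter:05d}",
                    site=blk.site,
                    group=group,
                    aneurysm=int(blk.aneurysmal),
                    morphometry=morph,
                )
                records.append(rec)
                if landmarks is not None:
                    landmarks.append(generate_landmarks(obs, radii, rng=rng))
    ground_truth = {
        "config": cfg.to_dict(),
        "applied_effects": {
            "alpha_shift_deg": cfg.effect.alpha_shift_deg,
            "r0_shift_mm": cfg.effect.r0_shift_mm,
            "aneurysmal_sites": sorted({
                f"{g}/{b.site}" for g, bs in cfg.groups.items()
                for b in bs if b.aneurysmal}),
        },
        "seed": cfg.seed,
        "n_records": len(records),
        "assumptions": (
            "truncated-normal marginals and exchangeable radius correlation "
            "are modelling assumptions, not published properties of the "
            "emulated cohort"
        ),
    }
    return SyntheticCohort(records=records, landmarks=landmarks,
                           ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# landmark synthesis (inverse of the geometry construction)
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-uniform orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_landmarks(
    target: ObservedAngles,
    radii: RadiiTriple,
    rng: Optional[np.random.Generator] = None,
    arm_length_mm: float = 10.0,
) -> BifurcationLandmarks:
    """Four 3D landmark points at a random rigid pose whose measured angles
    reproduce ``target`` to ~1e-6 degrees.

    The construction places the extended parent axis along +x, puts the
    larger branch at ``phi1_obs`` from it in the xz-plane, and rotates the
    smaller branch about the axis by the dihedral angle ``theta`` solving
    ``cos(alpha) = cos(phi1)cos(phi2) + sin(phi1)sin(phi2)cos(theta)``; a
    solution exists iff ``|phi1 - phi2| <= alpha <= phi1 + phi2``.  Arm
    lengths honour the >= 5 mm curvature-point distance rule.
    """
    if rng is None:
        rng = np.random.default_rng()
    a, p1, p2 = target.alpha_deg, target.phi1_obs_deg, target.phi2_obs_deg
    for name, v in (("alpha", a), ("phi1", p1), ("phi2", p2)):
        if not 0.0 < v < 180.0:
            raise ValidationError(f"target {name}={v} outside (0, 180)")
    if arm_length_mm < 5.0:
        raise ValidationError("arm length below the 5 mm distance rule")
    ar, p1r, p2r = (math.radians(v) for v in (a, p1, p2))
    denom = math.sin(p1r) * math.sin(p2r)
    cos_theta = (math.cos(ar) - math.cos(p1r) * math.cos(p2r)) / denom
    if cos_theta < -1.0 - 1e-12 or cos_theta > 1.0 + 1e-12:
        raise ValidationError(
            f"angle triple infeasible in 3D: need |phi1 - phi2| <= alpha <= "
            f"phi1 + phi2, got alpha={a}, phi1={p1}, phi2={p2}")
    theta = math.acos(min(1.0, max(-1.0, cos_theta)))

    e = np.array([1.0, 0.0, 0.0])  # extended parent axis
    b_dir = np.array([math.cos(p1r), math.sin(p1r), 0.0])
    c_dir = np.array([
        math.cos(p2r),
        math.sin(p2r) * math.cos(theta),
        math.sin(p2r) * math.sin(theta),
    ])
    O = np.zeros(3)
    A = O - arm_length_mm * e
    B = O + arm_length_mm * b_dir
    C = O + arm_length_mm * c_dir

    R = _random_rotation(rng)
    t = rng.uniform(-50.0, 50.0, size=3)
    return BifurcationLandmarks(
        point_A=R @ A + t, point_B=R @ B + t, point_C=R @ C + t,
        point_O=R @ O + t,
        d0=2.0 * radii.r0, d1=2.0 * radii.r1, d2=2.0 * radii.r2,
    )
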