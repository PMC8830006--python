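"""Minimum-work indices: ratio examples, the junction-exponent solver
against an independent oracle, optimal-angle domain handling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bifmorph import (
    DomainStatus,
    ObservedAngles,
    RadiiTriple,
    ValidationError,
    area_ratio,
    asymmetry_ratio,
    deviations,
    junction_exponent,
    optimal_angles,
    pmw_indices,
)


def exponent_oracle(r0, r1, r2, iters=200):
    """Fine grid to bracket the root of (r1/r0)^n + (r2/r0)^n - 1, then
    plain bisection; independent of the scipy-based solver."""

    def f(n):
        return (r1 / r0) ** n + (r2 / r0) ** n - 1.0

    grid = np.linspace(1e-4, 60.0, 4000)
    lo = hi = None
    for a, b in zip(grid[:-1], grid[1:]):
        if f(a) > 0.0 >= f(b):
            lo, hi = a, b
            break
    assert lo is not None, "oracle failed to bracket"
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


valid_radii = st.builds(
    lambda r0_extra, r1, frac: (r1 + r0_extra, r1, r1 * frac),
    r0_extra=st.floats(0.01, 2.0),
    r1=st.floats(0.3, 2.5),
    frac=st.floats(0.2, 1.0),
)


@pytest.mark.parametrize(
    "r0, r1, r2, expected",
    [
        (1.259921, 1.0, 1.0, 3.0),          # cube-law optimum
        (2.0, 1.0, 1.0, 1.0),               # 2 = 1 + 1
        (1.76, 1.31, 1.01, 1.6857),         # Table-style mean radii
    ],
)
def test_junction_exponent_examples(r0, r1, r2, expected):
    n, reason = junction_exponent(RadiiTriple(r0, r1, r2))
    assert reason is None
    assert n == pytest.approx(expected, abs=5e-4)


def test_junction_exponent_undefined_when_branch_exceeds_parent():
    n, reason = junction_exponent(RadiiTriple(1.0, 1.2, 0.8))
    assert n is None
    assert "no unique positive root" in reason


@given(valid_radii)
def test_solver_matches_oracle_and_residual(radii):
    r0, r1, r2 = radii
    r = RadiiTriple(r0, r1, r2)
    n, reason = junction_exponent(r)
    assert reason is None
    residual = abs((r1 / r0) ** n + (r2 / r0) ** n - 1.0)
    assert residual < 1e-9
    assert n == pytest.approx(exponent_oracle(r0, r1, r2), abs=1e-6)


@given(valid_radii, st.floats(0.01, 0.5))
def test_exponent_monotone_decreasing_in_r0(radii, bump):
    r0, r1, r2 = radii
    n1, _ = junction_exponent(RadiiTriple(r0, r1, r2))
    n2, _ = junction_exponent(RadiiTriple(r0 + bump, r1, r2))
    assert n2 < n1


@given(valid_radii, st.floats(0.1, 10.0))
def test_scale_invariance_of_all_indices(radii, scale):
    r = RadiiTriple(*radii)
    rs = RadiiTriple(*(scale * v for v in radii))
    assert asymmetry_ratio(rs) == pytest.approx(asymmetry_ratio(r), rel=1e-9)
    assert area_ratio(rs) == pytest.approx(area_ratio(r), rel=1e-9)
    n_a, _ = junction_exponent(r)
    n_b, _ = junction_exponent(rs)
    assert n_b == pytest.approx(n_a, rel=1e-6)
    ang_a = optimal_angles(r)
    ang_b = optimal_angles(rs)
    assert (ang_a[0] is None) == (ang_b[0] is None)
    if ang_a[0] is not None:
        for a, b in zip(ang_a[:3], ang_b[:3]):
            assert b == pytest.approx(a, abs=1e-6)


@pytest.mark.parametrize(
    "r0, r1, r2, expected",
    [
        (2.5, 2.0, 1.0, 0.25),
        (2.0, 2.0, 2.0, 1.0),
        (2.0, 1.31, 1.01, (1.01 / 1.31) ** 2),
    ],
)
def test_asymmetry_ratio(r0, r1, r2, expected):
    assert asymmetry_ratio(RadiiTriple(r0, r1, r2)) == pytest.approx(expected)


def test_asymmetry_ratio_table_radii_differ_from_per_subject_mean():
    # ratio of the group-mean radii need not equal the mean per-subject ratio
    assert asymmetry_ratio(RadiiTriple(1.76, 1.31, 1.01)) == pytest.approx(
        0.5944, abs=1e-4)


@pytest.mark.parametrize(
    "r0, r1, r2, expected",
    [
        (math.sqrt(2.0), 1.0, 1.0, 1.0),
        (2.0 ** (1.0 / 3.0), 1.0, 1.0, 2.0 ** (1.0 / 3.0)),
        (1.58, 1.12, 0.92, 0.8416),
    ],
)
def test_area_ratio(r0, r1, r2, expected):
    assert area_ratio(RadiiTriple(r0, r1, r2)) == pytest.approx(expected, abs=1e-4)


def test_optimal_angles_symmetric_cube_law():
    phi1, phi2, total, clamped = optimal_angles(
        RadiiTriple(2.0 ** (1.0 / 3.0), 1.0, 1.0))
    assert not clamped
    assert phi1 == pytest.approx(37.467, abs=1e-3)
    assert phi2 == pytest.approx(37.467, abs=1e-3)
    assert total == pytest.approx(74.934, abs=1e-3)


def test_optimal_angles_boundary_case_all_zero():
    phi1, phi2, total, clamped = optimal_angles(RadiiTriple(math.sqrt(2), 1, 1))
    assert (phi1, phi2, total) == (0.0, 0.0, 0.0)
    assert not clamped


def test_optimal_angles_out_of_domain_flagged_not_guessed():
    # control-BA-style mean radii: cos(phi1) = 1.132 > 1
    r = RadiiTriple(1.58, 1.12, 0.92)
    assert optimal_angles(r) == (None, None, None, False)
    phi1, phi2, total, clamped = optimal_angles(r, clamp_mode=True)
    assert clamped
    assert phi1 == 0.0  # cos clamped to +1
    idx = pmw_indices(r)
    assert idx.domain_status is DomainStatus.ANGLES_UNDEFINED
    assert idx.junction_exponent is not None


@given(valid_radii)
def test_triangle_identity_and_domain_equivalence(radii):
    r = RadiiTriple(*radii)
    phi1, phi2, total, _ = optimal_angles(r)
    sq = sorted(v * v for v in radii)
    strict_triangle = sq[2] < sq[0] + sq[1]
    if phi1 is None:
        assert not strict_triangle or math.isclose(
            sq[2], sq[0] + sq[1], rel_tol=1e-12)
    else:
        assert phi1 + phi2 == pytest.approx(total, abs=1e-8)
        # domain holds up to boundary ties
        assert sq[2] <= sq[0] + sq[1] * (1 + 1e-12)


def test_deviations_signed_and_propagating():
    obs = ObservedAngles(128.2, 120.4, 98.5, 59.6, 81.5)
    idx = pmw_indices(RadiiTriple(1.40, 1.16, 0.87))
    dev = deviations(obs, idx)
    assert dev.dev_total_deg == pytest.approx(idx.total_opt_deg - 128.2)
    assert dev.dev_phi1_deg == pytest.approx(idx.phi1_opt_deg - 59.6)
    assert dev.dev_phi2_deg == pytest.approx(idx.phi2_opt_deg - 81.5)

    undef = pmw_indices(RadiiTriple(1.58, 1.12, 0.92))
    dev2 = deviations(obs, undef)
    assert dev2.dev_total_deg is None
    assert dev2.dev_phi1_deg is None
    assert dev2.dev_phi2_deg is None


def test_radii_triple_validation():
    with pytest.raises(ValidationError):
        RadiiTriple(1.0, 0.8, 0.9)  # r1 < r2
    with pytest.raises(ValidationError):
        RadiiTriple(-1.0, 0.8, 0.7)
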