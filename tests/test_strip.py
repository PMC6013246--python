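"""Strip-model analytics: stability, pitchfork, shape forces, kappa fit."""

import math

import numpy as np
import pytest

from myopos import (
    CellGeometry,
    StripParams,
    aspect_ratio_predicted,
    bifurcation_table,
    df_equilibrium,
    fit_kappa,
    make_model,
    sf_is_stable,
    shape_forces,
    strip_rhs,
)


def m1(MS=2.0):
    return make_model(1, -1, -1, 1, M_S=MS)


def m2(MS=2.0):
    return make_model(1, -1, 1, -1, M_S=MS)


# ---------------------------------------------------------------------------
# strip ODE right-hand side
# ---------------------------------------------------------------------------

def test_single_file_is_always_a_steady_state():
    for model in (m1(), m2(), make_model(1, 0, 1, 1, M_S=3.0)):
        p = StripParams(40.0, 60.0, model)
        assert strip_rhs(0.0, p) == 0.0


def test_strip_rhs_is_odd(rng):
    p = StripParams(40.0, 60.0, m2())
    xs = rng.uniform(0.1, 55.0, 40)
    np.testing.assert_allclose(strip_rhs(-xs, p), -strip_rhs(xs, p), atol=1e-12)


def test_m2_worked_root():
    # 160 x/(4x^2 + lam^2) = 160 x/(b^2 - x^2) at x = 20 for MS=2, lam=40, b=60
    p = StripParams(40.0, 60.0, m2())
    assert strip_rhs(20.0, p) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# single-file stability
# ---------------------------------------------------------------------------

def test_m2_stability_threshold():
    # SF stable iff b < sqrt(MS/2) * lambda = 40 for MS=2, lam=40
    assert sf_is_stable(StripParams(40.0, 39.9, m2())).stable
    assert not sf_is_stable(StripParams(40.0, 40.1, m2())).stable
    assert sf_is_stable(StripParams(40.0, 39.9, m2())).critical_ratio == pytest.approx(1.0)


def test_m1_stability_threshold_is_width_independent():
    # lambda* = d_ref sqrt(2/MS) = 40 for MS=2; SF stable iff lambda > 40
    for b in (30.0, 60.0, 120.0):
        assert sf_is_stable(StripParams(40.5, b, m1())).stable
        assert not sf_is_stable(StripParams(39.5, b, m1())).stable
    assert sf_is_stable(StripParams(40.5, 60.0, m1())).critical_spacing == pytest.approx(40.0)


@pytest.mark.parametrize("alpha_N", [-1, 0, 1])
@pytest.mark.parametrize("sign_S, alpha_S", [(-1, 1), (1, -1), (1, 0), (1, 1), (-1, -1)])
def test_stability_matches_finite_difference_slope(alpha_N, sign_S, alpha_S):
    """The analytic criterion agrees with the sign of d(rhs)/dx at 0."""
    model = make_model(1, alpha_N, sign_S, alpha_S, M_S=1.7)
    p = StripParams(35.0, 35.0, model)
    res = sf_is_stable(p)
    h = 1e-6
    slope = (strip_rhs(h, p) - strip_rhs(-h, p)) / (2 * h)
    if abs(slope) > 1e-9:
        assert res.stable == (slope < 0)


def test_general_inequality_form(rng):
    """b^(1-aS) lam^(aN-1) < -sS aS MS d_ref^(aN-aS)/2 reproduces the criterion."""
    for _ in range(40):
        aN = rng.choice([-1, 0, 1])
        sS, aS = [(-1, 1), (1, -1), (1, 0), (1, 1)][rng.integers(4)]
        MS = float(rng.uniform(0.2, 8.0))
        lam = float(rng.uniform(15.0, 80.0))
        b = float(rng.uniform(10.0, 90.0))
        model = make_model(1, aN, sS, aS, M_S=MS)
        res = sf_is_stable(StripParams(lam, b, model))
        lhs = b ** (1 - aS) * lam ** (aN - 1)
        rhs = -sS * aS * MS * 40.0 ** (aN - aS) / 2.0
        if not math.isclose(lhs, rhs, rel_tol=1e-9):
            assert res.stable == (lhs < rhs)


def test_cutoff_within_reach_is_an_error():
    model = make_model(1, -1, 1, -1, M_S=2.0, c_S=30.0)
    with pytest.raises(ValueError, match="differentiable"):
        sf_is_stable(StripParams(40.0, 50.0, model))


# ---------------------------------------------------------------------------
# pitchfork equilibria
# ---------------------------------------------------------------------------

def test_worked_pitchfork_offsets():
    assert df_equilibrium(StripParams(30.0, 100.0, m1())) == pytest.approx(
        0.5 * math.sqrt(1600 - 900), abs=1e-9
    )  # 13.2288
    assert df_equilibrium(StripParams(40.0, 60.0, m2())) == pytest.approx(20.0, abs=1e-9)


def test_offset_vanishes_at_the_bifurcation_point():
    assert df_equilibrium(StripParams(40.0, 39.999, m2())) == 0.0
    assert df_equilibrium(StripParams(40.001, 60.0, m1())) == 0.0


@pytest.mark.parametrize("family", ["M1", "M2"])
def test_closed_form_matches_numeric_root(family, rng):
    """20 random parameter draws: closed form vs root of the strip ODE."""
    from myopos.strip import _numeric_root

    n_checked = 0
    while n_checked < 20:
        MS = float(rng.uniform(0.3, 6.0))
        lam = float(rng.uniform(20.0, 70.0))
        b = float(rng.uniform(20.0, 90.0))
        model = m1(MS) if family == "M1" else m2(MS)
        p = StripParams(lam, b, model)
        if sf_is_stable(p).stable:
            continue
        xbar = df_equilibrium(p)
        if family == "M1" and xbar >= b:
            continue  # strip fork lies outside this width
        root = _numeric_root(p)
        assert abs(xbar - root) / root < 1e-6
        n_checked += 1


def test_stability_exchange_across_the_fork():
    p = StripParams(40.0, 60.0, m2())  # unstable SF, fork at 20
    h = 1e-5
    assert (strip_rhs(h, p) - strip_rhs(-h, p)) / (2 * h) > 0
    xb = df_equilibrium(p)
    assert (strip_rhs(xb + h, p) - strip_rhs(xb - h, p)) / (2 * h) < 0


def test_bifurcation_table_contract():
    df = bifurcation_table("M2", 2.0, [30, 40, 50], [20, 45, 60])
    assert len(df) == 9
    stable = df[df.sf_stable]
    assert (stable.x_bar == 0).all()
    assert (df[~df.sf_stable].x_bar > 0).all()


# ---------------------------------------------------------------------------
# shape model
# ---------------------------------------------------------------------------

def test_sf_shape_forces_worked_example():
    fx, fy = shape_forces(StripParams(50.0, 30.0, m2()), "SF")
    assert fx == pytest.approx(16.0 / 3.0, abs=1e-9)
    assert fy == pytest.approx(1.6, abs=1e-9)


def test_m1_side_pull_is_negative():
    fx, fy = shape_forces(StripParams(60.0, 30.0, m1(1.0)), "SF")
    assert fx < 0 < fy


def test_long_range_variant_adds_second_neighbours():
    p = StripParams(40.0, 60.0, m2())
    _, fy_short = shape_forces(p, "DF", "short")
    _, fy_long = shape_forces(p, "DF", "long")
    assert fy_long >= fy_short
    assert fy_long - fy_short == pytest.approx(2.0 * (80.0 / 40.0) ** -1)


def test_pattern_parameter_mismatch_raises():
    p = StripParams(40.0, 60.0, m2())  # SF unstable here
    with pytest.raises(ValueError):
        shape_forces(p, "SF")
    p2 = StripParams(40.0, 30.0, m2())  # SF stable here
    with pytest.raises(ValueError):
        shape_forces(p2, "DF")


def test_aspect_ratio_prediction():
    assert aspect_ratio_predicted(5.0, 5.0, 30.0) == 1.0
    assert aspect_ratio_predicted(16.0 / 3.0, 1.6, 35.0) == pytest.approx(1.2675, abs=1e-3)
    # compressing more from the sides elongates along the cell axis
    assert aspect_ratio_predicted(8.0, 1.6, 35.0) > aspect_ratio_predicted(5.0, 1.6, 35.0)
    with pytest.raises(ValueError):
        aspect_ratio_predicted(40.0, 1.0, 35.0)


def _shape_cells(model, kappa, n=12, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n):
        n_nuc = int(rng.integers(7, 20))
        b = float(rng.uniform(21.0, 58.0))
        geom = CellGeometry(b, 250.0, n_nuc)
        p = StripParams.from_geometry(geom, model)
        pattern = "SF" if sf_is_stable(p).stable else "DF"
        fx, fy = shape_forces(p, pattern, "long")
        ar = aspect_ratio_predicted(fx, fy, kappa)
        if noise > 0:
            ar *= math.exp(rng.normal(0.0, noise))
        cells.append((geom, ar))
    return cells


def test_kappa_recovery_noiseless_is_exact():
    cells = _shape_cells(m2(2.2), kappa=35.0)
    fit = fit_kappa(cells, m2(2.2), "long")
    assert fit.kappa == pytest.approx(35.0, abs=1e-3)
    assert fit.error < 1e-6
    assert not fit.degenerate


def test_kappa_recovery_under_noise():
    cells = _shape_cells(m2(2.2), kappa=35.0, noise=0.05, seed=7)
    fit = fit_kappa(cells, m2(2.2), "long")
    assert abs(fit.kappa - 35.0) / 35.0 < 0.10
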