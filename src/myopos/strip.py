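"""Closed-form analysis of the single-file / double-file transition.

The 2D many-body problem reduces to one scalar offset x when the cell is
viewed as an infinite strip of half-width ``b`` with nuclei evenly spaced
along y at ``lambda = 2l/(N+1)`` in a zigzag (a nucleus at offset x has
neighbours above and below at -x).  The offset then obeys the autonomous
ODE::

    dx/dt = 4 f(d(x)) x / d(x) + g_S(b + x) - g_S(b - x),
    d(x) = sqrt(4 x^2 + lambda^2)

Cut-offs are ignored here (infinite reach, as in the calibration laws).
x = 0 (the single file) is always an equilibrium; it is stable iff
``2 f(lambda)/lambda < -g_S'(b)``.  When it loses stability a pitchfork
bifurcation produces the double file at +-x_bar:

* Model 1 (repulsive decreasing internuclear, attractive increasing side):
  SF stable iff lambda > lambda* = d_ref sqrt(2/M_S);
  x_bar = sqrt(lambda*^2 - lambda^2)/2.
* Model 2 (repulsive decreasing internuclear, repulsive decreasing side):
  SF stable iff b < r* lambda with r* = sqrt(M_S/2);
  x_bar = sqrt((b^2 - (r* lambda)^2) / (2 M_S + 1)).

All closed forms are re-derived from the stability inequality and verified
against numerical root-finding on the strip ODE (the tests carry the
finite-difference and root oracles).

The same reduction predicts nuclear shapes: the net compressive forces
f_x, f_y on a nucleus deform it (area-preserving, linear in force/stiffness
kappa) into an ellipse of oriented aspect ratio
``N_AR = (kappa - f_y)^2 / (kappa - f_x)^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .forces import ModelSpec
from .dynamics import CellGeometry

Pattern = Literal["SF", "DF"]
RangeVariant = Literal["short", "long"]


@dataclass(frozen=True)
class StripParams:
    """Strip reduction parameters: y-spacing, half-width and the model."""

    spacing: float
    half_width: float
    model: ModelSpec

    def __post_init__(self) -> None:
        if not (self.spacing > 0 and self.half_width > 0):
            raise ValueError("spacing and half_width must be positive")

    @classmethod
    def from_geometry(cls, geom: CellGeometry, model: ModelSpec) -> "StripParams":
        return cls(spacing=geom.spacing, half_width=geom.half_width, model=model)


@dataclass
class StabilityResult:
    stable: bool
    lhs: float
    rhs: float
    critical_spacing: float | None = None   # lambda* (Model-1 family)
    critical_ratio: float | None = None     # r* (Model-2 family)


def _laws(p: StripParams):
    return p.model.internuclear.without_cutoff(), p.model.side.without_cutoff()


def _family(p: StripParams) -> str | None:
    key = p.model.class_key()
    if key == (1, -1, -1, 1):
        return "M1"
    if key == (1, -1, 1, -1):
        return "M2"
    return None


def strip_rhs(x, p: StripParams):
    """Velocity of the reference nucleus's offset; odd in x, 0 at x = 0."""
    f, g = _laws(p)
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) >= p.half_width):
        raise ValueError("offset must satisfy |x| < b")
    d = np.sqrt(4.0 * x**2 + p.spacing**2)
    out = 4.0 * f(d) * x / d + g(p.half_width + x) - g(p.half_width - x)
    return float(out) if out.ndim == 0 else out


def sf_is_stable(p: StripParams) -> StabilityResult:
    """Linear stability of the single file: 2 f(lambda)/lambda < -g_S'(b).

    For the Model-1 / Model-2 families the closed-form threshold
    (lambda* resp. r*) is reported as well.
    """
    f, g = _laws(p)
    if p.model.side.cutoff <= p.half_width:
        raise ValueError("side law is not differentiable at b (cutoff within reach)")
    lhs = 2.0 * f(p.spacing) / p.spacing
    rhs = -g.derivative(p.half_width)
    res = StabilityResult(stable=bool(lhs < rhs), lhs=lhs, rhs=rhs)
    MS = p.model.side.magnitude
    d_ref = p.model.internuclear.ref_distance
    fam = _family(p)
    if fam == "M1":
        res.critical_spacing = d_ref * math.sqrt(2.0 / MS)
    elif fam == "M2":
        res.critical_ratio = math.sqrt(MS / 2.0)
    return res


def _numeric_root(p: StripParams) -> float:
    """Positive root of the strip ODE, bracketed by a sign scan."""
    b = p.half_width
    xs = np.linspace(1e-9, b * (1 - 1e-9), 2001)
    vals = strip_rhs(xs, p)
    sign = np.sign(vals)
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if len(flips) == 0:
        raise ValueError("no double-file equilibrium found in (0, b)")
    i = flips[-1]
    return float(optimize.brentq(lambda x: strip_rhs(x, p), xs[i], xs[i + 1], xtol=1e-12))


def df_equilibrium(p: StripParams) -> float:
    """Stable double-file offset x_bar >= 0; 0 while the single file is stable."""
    if sf_is_stable(p).stable:
        return 0.0
    MS = p.model.side.magnitude
    lam, b = p.spacing, p.half_width
    fam = _family(p)
    if fam == "M1":
        lam_star = sf_is_stable(p).critical_spacing
        return 0.5 * math.sqrt(lam_star**2 - lam**2)
    if fam == "M2":
        r_star = math.sqrt(MS / 2.0)
        return math.sqrt((b**2 - (r_star * lam) ** 2) / (2.0 * MS + 1.0))
    return _numeric_root(p)


def shape_forces(
    p: StripParams, pattern: Pattern, variant: RangeVariant = "short"
) -> tuple[float, float]:
    """Net compressive forces (f_x, f_y) on a nucleus in the strip lattice.

    SF: f_x = 2 g_S(b), f_y = 2 f(lambda).  DF (at the offset x_bar):
    f_x = g_S(b - x_bar) + g_S(b + x_bar) + 4 f(d) x_bar/d,
    f_y = 2 f(d) lambda/d, plus 2 f(2 lambda) from the second neighbours in
    the long-range variant.  Positive values push (compress), negative pull.
    """
    f, g = _laws(p)
    lam, b = p.spacing, p.half_width
    stable = sf_is_stable(p).stable
    if pattern == "SF":
        if not stable:
            raise ValueError("single file is unstable at these parameters")
        return 2.0 * g(b), 2.0 * f(lam)
    if pattern == "DF":
        if stable:
            raise ValueError("double file requires the single file to be unstable")
        xb = df_equilibrium(p)
        d = math.sqrt(4.0 * xb**2 + lam**2)
        fx = g(b - xb) + g(b + xb) + 4.0 * f(d) * xb / d
        fy = 2.0 * f(d) * lam / d
        if variant == "long":
            fy += 2.0 * f(2.0 * lam)
        return float(fx), float(fy)
    raise ValueError(f"unknown pattern {pattern!r}")


def aspect_ratio_predicted(f_x: float, f_y: float, kappa: float) -> float:
    """Nuclear aspect ratio from anisotropic stress: (k - f_y)^2/(k - f_x)^2.

    ``kappa`` is the nucleus's resistance to deformation (force units,
    proportional to its Young modulus) and must exceed both forces.
    """
    if kappa <= max(f_x, f_y):
        raise ValueError("kappa must exceed both f_x and f_y (model validity)")
    return (kappa - f_y) ** 2 / (kappa - f_x) ** 2


@dataclass
class KappaFit:
    kappa: float
    error: float
    kappa_grid: np.ndarray
    errors: np.ndarray
    degenerate: bool


def fit_kappa(
    cells: Sequence[tuple],
    model: ModelSpec,
    variant: RangeVariant = "long",
    kappa_max: float = 500.0,
) -> KappaFit:
    """Fit the nuclear stiffness kappa to observed aspect ratios.

    ``cells`` is a sequence of (CellGeometry, observed_aspect_ratio).  Each
    cell's pattern (SF or DF) follows from the stability condition at its
    (lambda, b); kappa minimises the mean absolute error between predicted
    and observed aspect ratios.  The error curve is returned alongside the
    minimiser; a flat prediction (all cells identical) is flagged.
    """
    forces = []
    obs = []
    for geom, ar in cells:
        p = StripParams.from_geometry(geom, model)
        pattern = "SF" if sf_is_stable(p).stable else "DF"
        forces.append(shape_forces(p, pattern, variant))
        obs.append(float(ar))
    forces_arr = np.asarray(forces)
    obs_arr = np.asarray(obs)
    lower = float(forces_arr.max()) + 1e-9
    if lower >= kappa_max:
        raise ValueError("kappa_max does not exceed the largest force")

    def err(k: float) -> float:
        pred = (k - forces_arr[:, 1]) ** 2 / (k - forces_arr[:, 0]) ** 2
        return float(np.abs(pred - obs_arr).mean())

    grid = np.linspace(lower, kappa_max, 512)
    errors = np.array([err(k) for k in grid])
    k0 = grid[int(np.argmin(errors))]
    span = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        err, bounds=(max(lower, k0 - 2 * span), min(kappa_max, k0 + 2 * span)),
        method="bounded", options={"xatol": 1e-8},
    )
    degenerate = bool(np.allclose(forces_arr, forces_arr[0]))
    return KappaFit(float(res.x), float(res.fun), grid, errors, degenerate)


def bifurcation_table(
    model_class: Literal["M1", "M2"],
    M_S: float,
    spacings: Sequence[float],
    half_widths: Sequence[float],
) -> "pd.DataFrame":
    """SF/DF phase diagram data over a (lambda, b) grid."""
    import pandas as pd
    from .forces import make_model

    if model_class == "M1":
        model = make_model(1, -1, -1, 1, M_S=M_S)
    elif model_class == "M2":
        model = make_model(1, -1, 1, -1, M_S=M_S)
    else:
        raise ValueError("model_class must be 'M1' or 'M2'")
    rows = []
    for lam in spacings:
        for b in half_widths:
            p = StripParams(lam, b, model)
            stable = sf_is_stable(p).stable
            rows.append({
                "spacing": lam, "half_width": b,
                "sf_stable": stable, "x_bar": df_equilibrium(p),
            })
    return pd.DataFrame(rows)
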