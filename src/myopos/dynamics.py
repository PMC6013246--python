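"""Overdamped motion of N nuclei in a rectangular cell.

The cell is the rectangle ``[-b, b] x [-l, l]`` (x across the short axis,
y along the long axis, um).  Each nucleus moves with velocity equal to the
sum of the forces acting on it: pairwise internuclear forces, forces from
the normal projections onto the two sides (L/R) and two poles (U/D), and
short-range size exclusion against both nuclei and boundary.  Drag is
normalised to 1, so time is measured in model units of um per force unit.

Equilibria are found by integrating the flow until every nucleus's velocity
2-norm falls below a tolerance (default 1e-4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.spatial.distance import pdist

from . import _kernels
from .forces import ForceLaw, ModelSpec, _pack, evaluate_force, evaluate_size_exclusion

InitMode = Literal["random", "equally_spaced_axis", "provided"]


def _dynamic_force(d, law: ForceLaw):
    """Force law as seen by the dynamics: cut-off smoothed by a short ramp.

    Identical to ``evaluate_force`` except within ``_kernels.CUTOFF_RAMP``
    um of a finite cut-off, where the force falls linearly to zero so the
    velocity field is continuous (see the kernel module).
    """
    F = evaluate_force(d, law)
    if math.isinf(law.cutoff):
        return F
    u = np.clip((law.cutoff - np.asarray(d, dtype=float)) / _kernels.CUTOFF_RAMP, 0.0, 1.0)
    out = F * u * u * (3.0 - 2.0 * u)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class CellGeometry:
    """Rectangular cell: half-width ``b``, half-length ``l`` (um), N nuclei."""

    half_width: float
    half_length: float
    n_nuclei: int
    nuclear_radius: float = 7.0

    def __post_init__(self) -> None:
        if not (self.half_width > 0 and self.half_length > 0):
            raise ValueError("half_width and half_length must be positive")
        if self.half_width >= self.half_length:
            raise ValueError("the long axis is y: require half_width < half_length")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if not self.nuclear_radius > 0:
            raise ValueError("nuclear_radius must be positive")

    @property
    def spacing(self) -> float:
        """Even y-spacing lambda = 2l/(N+1)."""
        return 2.0 * self.half_length / (self.n_nuclei + 1)


@dataclass
class EquilibriumResult:
    """Outcome of relaxing a configuration to its force balance.

    ``method`` records how the equilibrium was reached: ``"flow"`` if the
    integrator's residual dropped below tolerance on its own, ``"polish"``
    if a Newton root-finding step finished the job from the integrator's
    quasi-stationary state, ``"none"`` if the run did not converge.
    """

    final: np.ndarray
    converged: bool
    max_residual: float
    elapsed_model_time: float
    n_steps: int
    method: str = "flow"
    trajectory: Optional[np.ndarray] = None
    trajectory_times: Optional[np.ndarray] = None


def boundary_projections(p, geom: CellGeometry):
    """Normal projections of a point onto the four boundary segments.

    Returns ``(points, distances, inside)`` with rows ordered L, R, U, D.
    For points outside the rectangle the corresponding distances are clamped
    at 0 and ``inside`` is False.
    """
    x, y = float(p[0]), float(p[1])
    b, l = geom.half_width, geom.half_length
    points = np.array([[-b, y], [b, y], [x, l], [x, -l]])
    distances = np.array([b + x, b - x, l - y, l + y])
    inside = bool(np.all(distances >= 0))
    return points, np.maximum(distances, 0.0), inside


def _check_config(positions: np.ndarray, geom: CellGeometry) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must have shape (N, 2)")
    if pos.shape[0] != geom.n_nuclei:
        raise ValueError(
            f"configuration has {pos.shape[0]} nuclei, geometry expects {geom.n_nuclei}"
        )
    if np.any(np.abs(pos[:, 0]) > geom.half_width) or np.any(
        np.abs(pos[:, 1]) > geom.half_length
    ):
        raise ValueError("positions must lie inside the cell rectangle")
    if pos.shape[0] > 1 and np.min(pdist(pos)) == 0.0:
        raise ValueError("coincident nuclei (size exclusion diverges)")
    return pos


def net_velocities(positions, model: ModelSpec, geom: CellGeometry) -> np.ndarray:
    """Velocity of every nucleus under the model's force balance.

    Reference (pure numpy) implementation; the integrator uses a compiled
    kernel with identical physics.  Unit vectors point from the force source
    toward the nucleus, so positive (repulsive) laws push away from it.
    """
    pos = _check_config(positions, geom)
    n = pos.shape[0]
    r = model.nuclear_radius
    Q = model.exclusion_strength
    vel = np.zeros_like(pos)

    # pairwise internuclear + exclusion
    for i in range(n):
        diff = pos[i] - np.delete(pos, i, axis=0)
        if len(diff) == 0:
            continue
        d = np.linalg.norm(diff, axis=1)
        F = _dynamic_force(d, model.internuclear) + evaluate_size_exclusion(d, 2 * r, Q)
        vel[i] += (F / d) @ diff if diff.ndim == 2 else 0.0

    # boundary forces along the inward normals
    b, l = geom.half_width, geom.half_length
    dL, dR = b + pos[:, 0], b - pos[:, 0]
    dD, dU = l + pos[:, 1], l - pos[:, 1]
    side, pole = model.side, model.pole
    vel[:, 0] += _dynamic_force(dL, side) + evaluate_size_exclusion(dL, r, Q)
    vel[:, 0] -= _dynamic_force(dR, side) + evaluate_size_exclusion(dR, r, Q)
    vel[:, 1] += _dynamic_force(dD, pole) + evaluate_size_exclusion(dD, r, Q)
    vel[:, 1] -= _dynamic_force(dU, pole) + evaluate_size_exclusion(dU, r, Q)
    return vel


def relax_to_equilibrium(
    positions,
    model: ModelSpec,
    geom: CellGeometry,
    tol: float = 1e-4,
    max_time: float = 1e6,
    max_iters: int = 2_000_000,
    step_tol: float = 1e-4,
    record_every: float = 0.0,
    max_records: int = 2000,
    check_every: int = 20_000,
    min_move: float = 1e-2,
    polish: bool = True,
    polish_max_move: float = 10.0,
    solver: str = "explicit",
) -> EquilibriumResult:
    """Relax the overdamped dynamics until the force balance is reached.

    Converged means every nucleus's velocity 2-norm is below ``tol``.
    The integrator runs until the residual drops below ``tol``, the
    time/iteration budget runs out, or the configuration stops moving
    (largest displacement below ``min_move`` um over ``check_every``
    iterations).  In the latter two cases, if ``polish`` is set the
    quasi-stationary state is handed to a Newton root-finder on the
    velocity field; the root is accepted only if it satisfies ``tol``,
    stays inside the cell, and lies within ``polish_max_move`` um of the
    integrator's end state (so the flow, not the root-finder, selects the
    equilibrium).  Slow collective modes of long nuclear chains otherwise
    take millions of explicit steps to satisfy the residual rule.
    Non-convergence is reported, never silent.

    ``step_tol`` bounds the local step error (um) of the adaptive embedded
    Euler/Heun pair; equilibrium accuracy is set by ``tol``.  Set
    ``record_every`` to a positive model-time interval to also return
    trajectory snapshots.

    ``solver="stiff"`` integrates with LSODA instead (tolerances 1e-5):
    required when boundary forces are orders of magnitude stronger than the
    internuclear unit (equilibria on a steep cut-off ramp pin an explicit
    step size while the chain's soft modes still evolve).  The explicit
    scheme remains the default; trajectory recording is explicit-only.
    """
    pos = _check_config(positions, geom)
    P = _pack(model)
    if solver == "stiff":
        return _relax_stiff(pos, model, geom, P, tol, max_time, polish, polish_max_move)
    if solver != "explicit":
        raise ValueError(f"unknown solver {solver!r}")
    if record_every > 0:
        rec_pos = np.empty((max_records, pos.shape[0], 2))
        rec_t = np.empty(max_records)
    else:
        rec_pos = np.empty((0, pos.shape[0], 2))
        rec_t = np.empty(0)
    final, converged, res, t, steps, n_rec = _kernels.relax_kernel(
        pos, geom.half_width, geom.half_length, P,
        tol, max_time, max_iters, step_tol,
        1e-3, 1e-12, 1e3, record_every, rec_pos, rec_t,
        check_every, min_move,
    )
    method = "flow" if converged else "none"
    if not converged and polish:
        polished, pres = _polish_root(final, geom, P, tol)
        if polished is not None and np.abs(polished - final).max() <= polish_max_move:
            final, res, converged, method = polished, pres, True, "polish"
    result = EquilibriumResult(
        final=final, converged=bool(converged), max_residual=float(res),
        elapsed_model_time=float(t), n_steps=int(steps), method=method,
    )
    if record_every > 0:
        result.trajectory = rec_pos[:n_rec].copy()
        result.trajectory_times = rec_t[:n_rec].copy()
    return result


def _relax_stiff(
    pos: np.ndarray,
    model: ModelSpec,
    geom: CellGeometry,
    P: np.ndarray,
    tol: float,
    max_time: float,
    polish: bool,
    polish_max_move: float,
) -> EquilibriumResult:
    """LSODA relaxation in growing time chunks until the residual settles."""
    from scipy.integrate import odeint

    n = pos.shape[0]
    b, l = geom.half_width, geom.half_length
    buf = np.empty(2 * n)
    eps = 1e-9

    def fun(y, t):
        try:
            _kernels.rhs_flat(y, b, l, P, buf)
        except ZeroDivisionError:  # coincident trial positions
            return np.full(2 * n, 1e6)
        return buf

    def residual(y):
        v = fun(y, 0.0).reshape(n, 2)
        return float(np.sqrt((v**2).sum(axis=1)).max())

    y = pos.ravel().copy()
    t_done = 0.0
    chunk = 200.0
    res = residual(y)
    while res >= tol and t_done < max_time:
        span = min(chunk, max_time - t_done)
        ys = odeint(fun, y, [0.0, span], rtol=1e-5, atol=1e-5, mxstep=100_000)
        y = ys[-1]
        t_done += span
        chunk *= 3.0
        res = residual(y)
    final = y.reshape(n, 2)
    final[:, 0] = np.clip(final[:, 0], -b + eps, b - eps)
    final[:, 1] = np.clip(final[:, 1], -l + eps, l - eps)
    converged = bool(res < tol)
    method = "stiff" if converged else "none"
    if not converged and polish:
        polished, pres = _polish_root(final, geom, P, tol)
        if polished is not None and np.abs(polished - final).max() <= polish_max_move:
            final, res, converged, method = polished, pres, True, "polish"
    return EquilibriumResult(
        final=final, converged=converged, max_residual=res,
        elapsed_model_time=t_done, n_steps=0, method=method,
    )


def _polish_root(pos: np.ndarray, geom: CellGeometry, P: np.ndarray, tol: float):
    """Newton-refine a quasi-stationary state to an exact force balance.

    Returns (positions, residual) or (None, None) if no acceptable root is
    found (outside the cell, non-finite, or residual above tolerance).
    """
    from scipy import optimize

    n = pos.shape[0]
    b, l = geom.half_width, geom.half_length
    out = np.empty((n, 2))

    def fun(x):
        p = x.reshape(n, 2)
        if not np.all(np.isfinite(p)):
            return np.full(2 * n, 1e6)
        if np.any(np.abs(p[:, 0]) >= b) or np.any(np.abs(p[:, 1]) >= l):
            return np.full(2 * n, 1e6)
        try:
            _kernels.net_velocities_kernel(p, b, l, P, out)
        except ZeroDivisionError:
            return np.full(2 * n, 1e6)
        v = out.ravel()
        return np.where(np.isfinite(v), v, 1e6)

    best = None
    for method, options in (("hybr", {"xtol": 1e-12}), ("lm", {"xtol": 1e-12})):
        try:
            sol = optimize.root(fun, pos.ravel(), method=method, options=options)
        except Exception:
            continue
        cand = sol.x.reshape(n, 2)
        if np.all(np.isfinite(cand)):
            r = float(np.max(np.abs(fun(sol.x))))
            if best is None or r < best[1]:
                best = (cand, r)
            if r < tol:
                break
    if best is None:
        return None, None
    p = best[0]
    if not np.all(np.isfinite(p)):
        return None, None
    if np.any(np.abs(p[:, 0]) >= b) or np.any(np.abs(p[:, 1]) >= l):
        return None, None
    _kernels.net_velocities_kernel(p, b, l, P, out)
    res = float(np.sqrt((out**2).sum(axis=1)).max())
    if not math.isfinite(res) or res >= tol:
        return None, None
    return p, res


def initial_conditions(
    geom: CellGeometry,
    mode: InitMode = "random",
    seed=0,
    positions=None,
    axis_jitter: float = 0.5,
) -> np.ndarray:
    """Build an initial configuration.

    random
        x, y i.i.d. uniform in the rectangle shrunk by the nuclear radius.
    equally_spaced_axis
        Nuclei along the long axis at y-spacing 2l/(N+1), with a small
        alternating x-offset (``axis_jitter``, default 0.5 um).  The exact
        x = 0 line is invariant under the dynamics, so starting exactly on
        it would freeze even unstable single files; the offset seeds the
        zigzag mode and lets stability decide the outcome.
    provided
        Echo the given measured positions unchanged (after validation).
    """
    if mode == "provided":
        if positions is None:
            raise ValueError("mode 'provided' requires positions")
        return _check_config(positions, geom).copy()
    n = geom.n_nuclei
    if mode == "equally_spaced_axis":
        lam = geom.spacing
        y = -geom.half_length + lam * np.arange(1, n + 1)
        x = axis_jitter * (-1.0) ** np.arange(n)
        return np.column_stack([x, y])
    if mode == "random":
        rng = np.random.default_rng(seed)
        r = geom.nuclear_radius
        x = rng.uniform(-geom.half_width + r, geom.half_width - r, n)
        y = rng.uniform(-geom.half_length + r, geom.half_length - r, n)
        return np.column_stack([x, y])
    raise ValueError(f"unknown mode {mode!r}")
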