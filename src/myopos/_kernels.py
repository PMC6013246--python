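"""Numba-compiled inner loops for the overdamped particle dynamics.

The model parameter vector ``P`` (see ``forces._pack``) is laid out as::

    0 sign_N  1 alpha_N  2 c_N
    3 sign_S  4 alpha_S  5 M_S  6 c_S
    7 sign_P  8 alpha_P  9 M_P  10 c_P
    11 d_ref  12 Q_SE    13 r

Velocities equal forces (drag normalised to 1); distances in um.
"""

from __future__ import annotations

import numpy as np
from numba import njit


#: Width (um) of the linear ramp smoothing each force cut-off inside the
#: dynamics.  The hard Heaviside makes the velocity field discontinuous, so
#: equilibria can sit *on* a cut-off surface (sliding states) where a
#: pointwise residual never settles; the ramp turns them into ordinary
#: smooth equilibria displaced by less than the ramp width.
CUTOFF_RAMP = 0.5


@njit(cache=True, inline="always")
def _plaw(d, sign, alpha, M, c, d_ref):
    if d >= c:
        return 0.0
    # fast paths for the screen exponents; generic pow otherwise
    if alpha == -1.0:
        F = sign * M * d_ref / d
    elif alpha == 0.0:
        F = sign * M
    elif alpha == 1.0:
        F = sign * M * d / d_ref
    else:
        F = sign * M * (d / d_ref) ** alpha
    if d > c - CUTOFF_RAMP:
        u = (c - d) / CUTOFF_RAMP
        F *= u * u * (3.0 - 2.0 * u)  # C1 smoothstep: kink-free at both edges
    return F


@njit(cache=True, inline="always")
def _sizex(d, diam, Q):
    if d >= diam:
        return 0.0
    return Q * (1.0 / (d * d) - 1.0 / (diam * diam))


@njit(cache=True)
def net_velocities_kernel(pos, b, l, P, out):
    """Sum of pairwise, side, pole and size-exclusion forces per nucleus."""
    n = pos.shape[0]
    d_ref = P[11]
    Q = P[12]
    r = P[13]
    diam = 2.0 * r
    for i in range(n):
        out[i, 0] = 0.0
        out[i, 1] = 0.0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            d = np.sqrt(dx * dx + dy * dy)
            F = _plaw(d, P[0], P[1], 1.0, P[2], d_ref) + _sizex(d, diam, Q)
            fx = F * dx / d
            fy = F * dy / d
            out[i, 0] += fx
            out[i, 1] += fy
            out[j, 0] -= fx
            out[j, 1] -= fy
        # sides: left wall at x=-b (distance b+x, inward normal +x),
        # right wall at x=+b (distance b-x, inward normal -x)
        dL = b + xi
        dR = b - xi
        out[i, 0] += _plaw(dL, P[3], P[4], P[5], P[6], d_ref) + _sizex(dL, r, Q)
        out[i, 0] -= _plaw(dR, P[3], P[4], P[5], P[6], d_ref) + _sizex(dR, r, Q)
        # poles: down wall at y=-l, up wall at y=+l
        dD = l + yi
        dU = l - yi
        out[i, 1] += _plaw(dD, P[7], P[8], P[9], P[10], d_ref) + _sizex(dD, r, Q)
        out[i, 1] -= _plaw(dU, P[7], P[8], P[9], P[10], d_ref) + _sizex(dU, r, Q)


@njit(cache=True, inline="always")
def _max_speed(v):
    m = 0.0
    for i in range(v.shape[0]):
        s = np.sqrt(v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1])
        if s > m:
            m = s
    return m


@njit(cache=True, inline="always")
def _inside(pos, b, l):
    for i in range(pos.shape[0]):
        x = pos[i, 0]
        y = pos[i, 1]
        if not (-b < x < b and -l < y < l) or np.isnan(x) or np.isnan(y):
            return False
    return True


@njit(cache=True)
def relax_kernel(
    pos0, b, l, P, tol, max_time, max_iters, step_tol,
    dt0, dt_min, dt_max, record_every, rec_pos, rec_t,
    check_every, min_move,
):
    """Adaptive embedded Euler/Heun relaxation of the force balance.

    Steps are rejected (and dt halved) when the per-step error estimate
    ``dt/2 * max_i |v2_i - v1_i|`` exceeds ``step_tol`` or when a trial
    position leaves the open rectangle; positions are never clamped.
    Integration stops when every nucleus's speed 2-norm drops below ``tol``
    (converged) or when the time/iteration budget is exhausted.

    Force laws with finite cut-offs make the velocity field discontinuous;
    trajectories can chatter on a cut-off surface without the residual ever
    dropping below ``tol``.  Every ``check_every`` iterations the maximal
    nuclear displacement since the previous check is inspected; if it falls
    below ``min_move`` while the residual is still above ``tol``, the run is
    declared stalled (returned as not converged).

    Optionally records snapshots every ``record_every`` model-time units into
    ``rec_pos``/``rec_t`` (pass record_every <= 0 to disable).  Returns
    (positions, converged, max_residual, elapsed_time, n_accepted, n_recorded).
    """
    n = pos0.shape[0]
    pos = pos0.copy()
    v1 = np.empty((n, 2))
    v2 = np.empty((n, 2))
    xe = np.empty((n, 2))
    xn = np.empty((n, 2))

    net_velocities_kernel(pos, b, l, P, v1)
    res = _max_speed(v1)
    t = 0.0
    dt = dt0
    accepted = 0
    n_rec = 0
    if record_every > 0.0 and rec_pos.shape[0] > 0:
        rec_pos[0] = pos
        rec_t[0] = 0.0
        n_rec = 1
    next_rec = record_every
    snap = pos.copy()
    it = 0
    stiff_run = 0  # consecutive accepted steps with a stiffness-pinned dt

    while it < max_iters:
        it += 1
        if res < tol:
            return pos, True, res, t, accepted, n_rec
        if t >= max_time:
            break
        if check_every > 0:
            if it % check_every == 0:
                moved = 0.0
                for i in range(n):
                    dx = pos[i, 0] - snap[i, 0]
                    dy = pos[i, 1] - snap[i, 1]
                    m = np.sqrt(dx * dx + dy * dy)
                    if m > moved:
                        moved = m
                if moved < min_move:
                    break  # stalled: configuration has stopped moving
                snap = pos.copy()
            # a dt pinned well below the smooth scale for thousands of
            # consecutive steps means contact/ramp stiffness dominates;
            # hand over to the polish stage instead of grinding on
            if it > 8000 and stiff_run > 3000:
                break
        # forward Euler trial
        err = 0.0
        ok = True
        for i in range(n):
            xe[i, 0] = pos[i, 0] + dt * v1[i, 0]
            xe[i, 1] = pos[i, 1] + dt * v1[i, 1]
        if not _inside(xe, b, l):
            ok = False
        if ok:
            net_velocities_kernel(xe, b, l, P, v2)
            err = 0.0
            for i in range(n):
                ex = v2[i, 0] - v1[i, 0]
                ey = v2[i, 1] - v1[i, 1]
                e = 0.5 * dt * np.sqrt(ex * ex + ey * ey)
                if e > err:
                    err = e
                xn[i, 0] = pos[i, 0] + 0.5 * dt * (v1[i, 0] + v2[i, 0])
                xn[i, 1] = pos[i, 1] + 0.5 * dt * (v1[i, 1] + v2[i, 1])
            if np.isnan(err) or (err > step_tol and dt > dt_min):
                ok = False
            elif not _inside(xn, b, l):
                ok = False
        if not ok:
            dt = dt * 0.5
            if dt < dt_min:
                dt = dt_min
            continue
        # accept the Heun step
        for i in range(n):
            pos[i, 0] = xn[i, 0]
            pos[i, 1] = xn[i, 1]
        t += dt
        accepted += 1
        if dt < 0.5:
            stiff_run += 1
        else:
            stiff_run = 0
        if record_every > 0.0 and t >= next_rec and n_rec < rec_pos.shape[0]:
            rec_pos[n_rec] = pos
            rec_t[n_rec] = t
            n_rec += 1
            next_rec += record_every
        net_velocities_kernel(pos, b, l, P, v1)
        res = _max_speed(v1)
        if err > 1e-300:
            fac = 0.9 * np.sqrt(step_tol / err)
            if fac > 2.0:
                fac = 2.0
            dt = dt * fac
        else:
            dt = dt * 2.0
        if dt > dt_max:
            dt = dt_max
        if dt < dt_min:
            dt = dt_min

    return pos, res < tol, res, t, accepted, n_rec


@njit(cache=True)
def rhs_flat(y, b, l, P, out):
    """Flat-vector RHS for the stiff (LSODA) path.

    Positions evaluated slightly outside the rectangle (solver trial steps)
    are mapped back to the open interior, where the boundary exclusion
    provides the restoring force; non-finite velocities are capped.
    """
    n = y.shape[0] // 2
    eps = 1e-9
    pos = np.empty((n, 2))
    for i in range(n):
        x = y[2 * i]
        yy = y[2 * i + 1]
        if x < -b + eps:
            x = -b + eps
        elif x > b - eps:
            x = b - eps
        if yy < -l + eps:
            yy = -l + eps
        elif yy > l - eps:
            yy = l - eps
        pos[i, 0] = x
        pos[i, 1] = yy
    vel = np.empty((n, 2))
    net_velocities_kernel(pos, b, l, P, vel)
    for i in range(n):
        v0 = vel[i, 0]
        v1 = vel[i, 1]
        out[2 * i] = v0 if np.isfinite(v0) else 1e6
        out[2 * i + 1] = v1 if np.isfinite(v1) else 1e6
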