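"""Numerical kernels (numba-compiled) shared by the potential and the
trajectory integrator.

The probe state is the 6-vector (x, y, z, vx, vy, vz) of the drift-gas
molecule's center of mass; the ion is rigid and fixed at the origin frame,
and the gas orientation axis is frozen during a trajectory.  Units follow
the package contract: Angstrom, Da, meV, e, ps.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import MEV_TO_DA_A2_PS2

# propagate() status codes
STATUS_OK = 0
STATUS_TRAPPED = 2
STATUS_GUARD = 3


@njit(cache=True)
def eval_potential_force(
    rc,
    axis,
    apos,
    aq,
    aeps,
    asig,
    site_off,
    site_lj,
    site_q,
    alpha,
    coul,
    rmin_guard,
):
    """Potential (meV), force and torque (meV/A, meV) on the gas probe.

    Terms: pairwise 12-6 Lennard-Jones between ion atoms and the gas LJ
    sites; Coulomb between ion partial charges and the gas point charges
    (the ion-quadrupole term for N2); and the charge-induced-dipole term
    -(alpha/2)|E|^2 evaluated at the gas center.

    Returns ``(V, F, tau, ok)``; ``ok`` is False when any atom-site
    distance fell below *rmin_guard*.
    """
    n = apos.shape[0]
    ns = site_off.shape[0]
    V = 0.0
    F = np.zeros(3)
    tau = np.zeros(3)
    ok = True
    for s in range(ns):
        sx = rc[0] + site_off[s] * axis[0]
        sy = rc[1] + site_off[s] * axis[1]
        sz = rc[2] + site_off[s] * axis[2]
        fx = 0.0
        fy = 0.0
        fz = 0.0
        for i in range(n):
            dx = sx - apos[i, 0]
            dy = sy - apos[i, 1]
            dz = sz - apos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r < rmin_guard:
                ok = False
            if site_lj[s] != 0:
                s2 = asig[i] * asig[i] / r2
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                V += 4.0 * aeps[i] * (s12 - s6)
                fmag = 4.0 * aeps[i] * (12.0 * s12 - 6.0 * s6) / r2
                fx += fmag * dx
                fy += fmag * dy
                fz += fmag * dz
            if site_q[s] != 0.0:
                c = coul * site_q[s] * aq[i]
                V += c / r
                cf = c / (r2 * r)
                fx += cf * dx
                fy += cf * dy
                fz += cf * dz
        F[0] += fx
        F[1] += fy
        F[2] += fz
        # torque about the gas center (informative; orientation is frozen)
        ox = site_off[s] * axis[0]
        oy = site_off[s] * axis[1]
        oz = site_off[s] * axis[2]
        tau[0] += oy * fz - oz * fy
        tau[1] += oz * fx - ox * fz
        tau[2] += ox * fy - oy * fx

    if alpha > 0.0:
        ex = 0.0
        ey = 0.0
        ez = 0.0
        jxx = 0.0
        jxy = 0.0
        jxz = 0.0
        jyy = 0.0
        jyz = 0.0
        jzz = 0.0
        for i in range(n):
            dx = rc[0] - apos[i, 0]
            dy = rc[1] - apos[i, 1]
            dz = rc[2] - apos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r < rmin_guard:
                ok = False
            r3 = r2 * r
            r5 = r3 * r2
            q = aq[i]
            ex += q * dx / r3
            ey += q * dy / r3
            ez += q * dz / r3
            jxx += q * (1.0 / r3 - 3.0 * dx * dx / r5)
            jyy += q * (1.0 / r3 - 3.0 * dy * dy / r5)
            jzz += q * (1.0 / r3 - 3.0 * dz * dz / r5)
            jxy += q * (-3.0 * dx * dy / r5)
            jxz += q * (-3.0 * dx * dz / r5)
            jyz += q * (-3.0 * dy * dz / r5)
        e2 = ex * ex + ey * ey + ez * ez
        V += -0.5 * alpha * coul * e2
        # F = -grad V = alpha * coul * J @ E  (J symmetric field gradient)
        F[0] += alpha * coul * (jxx * ex + jxy * ey + jxz * ez)
        F[1] += alpha * coul * (jxy * ex + jyy * ey + jyz * ez)
        F[2] += alpha * coul * (jxz * ex + jyz * ey + jzz * ez)
    return V, F, tau, ok


# Cash-Karp RK45 tableau
_CK_B = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0],
        [1.0 / 5.0, 0.0, 0.0, 0.0, 0.0],
        [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0],
        [3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0, 0.0, 0.0],
        [-11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0, 0.0],
        [
            1631.0 / 55296.0,
            175.0 / 512.0,
            575.0 / 13824.0,
            44275.0 / 110592.0,
            253.0 / 4096.0,
        ],
    ]
)
_CK_C5 = np.array(
    [37.0 / 378.0, 0.0, 250.0 / 621.0, 125.0 / 594.0, 0.0, 512.0 / 1771.0]
)
_CK_C4 = np.array(
    [
        2825.0 / 27648.0,
        0.0,
        18575.0 / 48384.0,
        13525.0 / 55296.0,
        277.0 / 14336.0,
        1.0 / 4.0,
    ]
)


@njit(cache=True)
def _deriv(
    y, mu, axis, apos, aq, aeps, asig, site_off, site_lj, site_q, alpha, coul, guard
):
    V, F, tau, ok = eval_potential_force(
        y[:3], axis, apos, aq, aeps, asig, site_off, site_lj, site_q, alpha, coul, guard
    )
    dy = np.empty(6)
    dy[0] = y[3]
    dy[1] = y[4]
    dy[2] = y[5]
    acc = MEV_TO_DA_A2_PS2 / mu
    dy[3] = F[0] * acc
    dy[4] = F[1] * acc
    dy[5] = F[2] * acc
    return dy, ok


@njit(cache=True)
def propagate(
    y0,
    mu,
    axis,
    apos,
    aq,
    aeps,
    asig,
    site_off,
    site_lj,
    site_q,
    alpha,
    coul,
    guard,
    rtol,
    r_exit2,
    max_steps,
):
    """Integrate the probe through the collision with adaptive Cash-Karp RK45.

    Terminates when the probe is outside the exit radius and moving outward.
    Returns ``(y_final, status, n_steps)``.
    """
    y = y0.copy()
    g = np.sqrt(y[3] * y[3] + y[4] * y[4] + y[5] * y[5])
    h = 0.05 / g  # first step ~0.05 A of path
    atol = 1e-12
    k = np.empty((6, 6))
    n_steps = 0
    status = STATUS_TRAPPED
    y_prev = y.copy()
    h_used = h
    while n_steps < max_steps:
        y_prev[:] = y
        dy0, ok = _deriv(
            y, mu, axis, apos, aq, aeps, asig, site_off, site_lj, site_q, alpha,
            coul, guard,
        )
        if not ok:
            return y, STATUS_GUARD, n_steps
        # attempt steps until the local error test passes
        for _attempt in range(60):
            for stage in range(6):
                yt = y.copy()
                for j in range(stage):
                    if _CK_B[stage, j] != 0.0:
                        yt += h * _CK_B[stage, j] * k[j]
                if stage == 0:
                    k[0] = dy0
                else:
                    k[stage], ok = _deriv(
                        yt, mu, axis, apos, aq, aeps, asig, site_off, site_lj,
                        site_q, alpha, coul, guard,
                    )
                    if not ok:
                        break
            if not ok:
                h *= 0.25
                continue
            y5 = y.copy()
            y4 = y.copy()
            for j in range(6):
                y5 += h * _CK_C5[j] * k[j]
                y4 += h * _CK_C4[j] * k[j]
            # scaled max-norm error
            err = 0.0
            for j in range(6):
                sc = atol + rtol * (abs(y[j]) + abs(h * k[0][j]))
                e = abs(y5[j] - y4[j]) / sc
                if e > err:
                    err = e
            if err <= 1.0 or h < 1e-12:
                y = y5
                h_used = h
                if err > 0.0:
                    fac = 0.9 * err ** (-0.2)
                    if fac > 5.0:
                        fac = 5.0
                    h *= fac
                else:
                    h *= 5.0
                break
            fac = 0.9 * err ** (-0.25)
            if fac < 0.1:
                fac = 0.1
            h *= fac
        n_steps += 1
        r2 = y[0] * y[0] + y[1] * y[1] + y[2] * y[2]
        rv = y[0] * y[3] + y[1] * y[4] + y[2] * y[5]
        if r2 > r_exit2 and rv > 0.0:
            # land exactly on the exit sphere so the reported state does not
            # depend on how far the last adaptive step overshot it
            rv_prev = (
                y_prev[0] * y_prev[3]
                + y_prev[1] * y_prev[4]
                + y_prev[2] * y_prev[5]
            )
            if rv_prev > 0.0:
                lo = 0.0
                hi = h_used
                for _bisect in range(40):
                    hm = 0.5 * (lo + hi)
                    ym = _ck_step(
                        y_prev, hm, mu, axis, apos, aq, aeps, asig, site_off,
                        site_lj, site_q, alpha, coul, guard,
                    )
                    r2m = ym[0] * ym[0] + ym[1] * ym[1] + ym[2] * ym[2]
                    if r2m > r_exit2:
                        hi = hm
                    else:
                        lo = hm
                y = _ck_step(
                    y_prev, hi, mu, axis, apos, aq, aeps, asig, site_off,
                    site_lj, site_q, alpha, coul, guard,
                )
            status = STATUS_OK
            break
    return y, status, n_steps


@njit(cache=True)
def _ck_step(
    y0, h, mu, axis, apos, aq, aeps, asig, site_off, site_lj, site_q, alpha,
    coul, guard,
):
    """One fixed Cash-Karp step of size h (5th-order solution)."""
    k = np.empty((6, 6))
    for stage in range(6):
        yt = y0.copy()
        for j in range(stage):
            if _CK_B[stage, j] != 0.0:
                yt += h * _CK_B[stage, j] * k[j]
        k[stage], _ok = _deriv(
            yt, mu, axis, apos, aq, aeps, asig, site_off, site_lj, site_q,
            alpha, coul, guard,
        )
    y = y0.copy()
    for j in range(6):
        y += h * _CK_C5[j] * k[j]
    return y
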