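"""Numba kernels for the D3Q19 solver hot loops.

All kernels operate on flat site lists: populations are ``(n_sites, 19)``
arrays over the *valid* sites of a domain (fluid, inlet, outlet and — in
elastic mode — wall sites).  ``nbr[k, i]`` is the valid-site index of the
pull-streaming source ``x_k - c_i``, or -1 when the source is not a valid
population carrier (then halfway bounceback applies).

State convention: arrays hold *post-collision* populations.  One step pulls
post-collision values from the neighbours (streaming), takes moments
(pre-collision state at the new time) and relaxes them (BGK), writing new
post-collision values.  Boundary kernels re-gather their designated
neighbour's pre-collision populations and write constructed post-collision
populations, so wall/inlet/outlet sites participate in the next streaming
step exactly like interior sites.
"""

import numpy as np
from numba import njit

# collision constants for Cs^2 = 1/3 baked into the kernels: 3 = 1/Cs^2,
# 4.5 = 1/(2 Cs^4), 1.5 = 1/(2 Cs^2)


@njit(cache=True, fastmath=True, error_model="numpy")
def stream_collide(f_old, f_new, nbr, ids, opp, cx, cy, cz, w, omega, rho, ux, uy, uz):
    """Fused pull-stream + BGK collide over the sites listed in ``ids``.

    Writes post-collision populations into ``f_new`` and the post-stream
    macroscopic moments into ``rho``/``ux``/``uy``/``uz``.  Returns
    ``(umax2, mass)``: the maximum squared velocity and the total mass of the
    streamed state (NaN propagates into ``mass``, which the driver checks).
    """
    umax2 = 0.0
    mass = 0.0
    fl = np.empty(19)
    for s in range(ids.shape[0]):
        k = ids[s]
        for i in range(19):
            j = nbr[k, i]
            if j >= 0:
                fl[i] = f_old[j, i]
            else:
                fl[i] = f_old[k, opp[i]]
        r = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for i in range(19):
            fi = fl[i]
            r += fi
            mx += fi * cx[i]
            my += fi * cy[i]
            mz += fi * cz[i]
        vx = mx / r
        vy = my / r
        vz = mz / r
        u2 = vx * vx + vy * vy + vz * vz
        if u2 > umax2:
            umax2 = u2
        mass += r
        rho[k] = r
        ux[k] = vx
        uy[k] = vy
        uz[k] = vz
        for i in range(19):
            cu = cx[i] * vx + cy[i] * vy + cz[i] * vz
            feq = w[i] * r * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * u2)
            f_new[k, i] = fl[i] - omega * (fl[i] - feq)
    return umax2, mass


@njit(cache=True, fastmath=True, error_model="numpy")
def wall_construct(f_old, f_new, nbr, wall_ids, wall_nbr_ids, opp, cx, cy, cz, w, tau, coef):
    """Elastic-wall construction of wall-site post-collision populations.

    Per wall site: read the designated fluid neighbour's post-stream state
    (rho_f, U_f), set the wall velocity U_w = coef * U_f (the slip formula
    coefficient, per site), and assemble

        f_i(x_w) = f_i^eq(rho_f, U_w) + (1 - 1/tau) f_i^neq(x_f)

    with the non-equilibrium part copied per direction from the neighbour.
    """
    fac = 1.0 - 1.0 / tau
    fl = np.empty(19)
    for s in range(wall_ids.shape[0]):
        k = wall_ids[s]
        n = wall_nbr_ids[s]
        for i in range(19):
            j = nbr[n, i]
            if j >= 0:
                fl[i] = f_old[j, i]
            else:
                fl[i] = f_old[n, opp[i]]
        r = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for i in range(19):
            fi = fl[i]
            r += fi
            mx += fi * cx[i]
            my += fi * cy[i]
            mz += fi * cz[i]
        vx = mx / r
        vy = my / r
        vz = mz / r
        u2f = vx * vx + vy * vy + vz * vz
        cf = coef[s]
        u2w = cf * cf * u2f
        for i in range(19):
            cuf = cx[i] * vx + cy[i] * vy + cz[i] * vz
            cuw = cf * cuf
            feqf = w[i] * r * (1.0 + 3.0 * cuf + 4.5 * cuf * cuf - 1.5 * u2f)
            feqw = w[i] * r * (1.0 + 3.0 * cuw + 4.5 * cuw * cuw - 1.5 * u2w)
            f_new[k, i] = feqw + fac * (fl[i] - feqf)


@njit(cache=True, fastmath=True, error_model="numpy")
def impose_pressure(f_old, f_new, nbr, ids, nbr_ids, opp, cx, cy, cz, w, tau, rho_target):
    """Fixed-pressure plane: equilibrium at the target density with the
    neighbour's (extrapolated) velocity, plus the neighbour's non-equilibrium
    part, collided."""
    fac = 1.0 - 1.0 / tau
    fl = np.empty(19)
    for s in range(ids.shape[0]):
        k = ids[s]
        n = nbr_ids[s]
        for i in range(19):
            j = nbr[n, i]
            if j >= 0:
                fl[i] = f_old[j, i]
            else:
                fl[i] = f_old[n, opp[i]]
        r = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for i in range(19):
            fi = fl[i]
            r += fi
            mx += fi * cx[i]
            my += fi * cy[i]
            mz += fi * cz[i]
        vx = mx / r
        vy = my / r
        vz = mz / r
        u2 = vx * vx + vy * vy + vz * vz
        for i in range(19):
            cu = cx[i] * vx + cy[i] * vy + cz[i] * vz
            q = 1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * u2
            feq_n = w[i] * r * q
            feq_t = w[i] * rho_target * q
            f_new[k, i] = feq_t + fac * (fl[i] - feq_n)


@njit(cache=True, fastmath=True, error_model="numpy")
def impose_velocity(f_old, f_new, nbr, ids, nbr_ids, opp, cx, cy, cz, w, tau, utx, uty, utz):
    """Prescribed-velocity plane: equilibrium at the neighbour's density with
    the target velocity, plus the neighbour's non-equilibrium part, collided."""
    fac = 1.0 - 1.0 / tau
    fl = np.empty(19)
    for s in range(ids.shape[0]):
        k = ids[s]
        n = nbr_ids[s]
        for i in range(19):
            j = nbr[n, i]
            if j >= 0:
                fl[i] = f_old[j, i]
            else:
                fl[i] = f_old[n, opp[i]]
        r = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for i in range(19):
            fi = fl[i]
            r += fi
            mx += fi * cx[i]
            my += fi * cy[i]
            mz += fi * cz[i]
        vx = mx / r
        vy = my / r
        vz = mz / r
        u2n = vx * vx + vy * vy + vz * vz
        tx = utx[s]
        ty = uty[s]
        tz = utz[s]
        u2t = tx * tx + ty * ty + tz * tz
        for i in range(19):
            cun = cx[i] * vx + cy[i] * vy + cz[i] * vz
            cut = cx[i] * tx + cy[i] * ty + cz[i] * tz
            feq_n = w[i] * r * (1.0 + 3.0 * cun + 4.5 * cun * cun - 1.5 * u2n)
            feq_t = w[i] * r * (1.0 + 3.0 * cut + 4.5 * cut * cut - 1.5 * u2t)
            f_new[k, i] = feq_t + fac * (fl[i] - feq_n)
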