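"""Compiled photon-transport core.

Every stochastic primitive (Fresnel draw, step sampling, Henyey-Greenstein
deflection, direction rotation, roulette) lives here as a scalar ``@njit``
function, and the full hop-drop-spin tracing loop is built from those same
primitives.  The Python-level API in :mod:`drupemc.transport` wraps these
functions one-to-one, so there is a single implementation of each formula.

The kernel consumes a ``numpy.random.Generator`` passed in from Python; one
seeded generator drives an entire simulation, which makes runs bit-for-bit
reproducible for a given (seed, config) pair.  Tracing is single-threaded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Escape codes returned by _trace_one.
ESCAPED_ABOVE = 0
ESCAPED_BELOW = 1
TERMINATED = 2  # killed by roulette
RUNAWAY = 3  # event cap exceeded

_COS_NORMAL = 1.0 - 1e-9  # treat as exactly normal incidence
_COS_GRAZING = 1e-6  # treat as grazing: total reflection
_VERTICAL = 1.0 - 1e-5  # near-vertical branch of the spin update


@njit(cache=False)
def _fresnel(n_i, n_t, ca_i):
    """Unpolarized Fresnel reflectance for incidence cosine ``ca_i``.

    The 0/0 singularities of the sine/tangent form are replaced by their
    analytic limits: ((n_i-n_t)/(n_i+n_t))**2 at normal incidence and 1 at
    grazing incidence; beyond the critical angle the return is exactly 1.
    """
    if n_i == n_t:
        return 0.0
    if ca_i > _COS_NORMAL:
        rn = (n_i - n_t) / (n_i + n_t)
        return rn * rn
    if ca_i < _COS_GRAZING:
        return 1.0
    sa_i = np.sqrt(1.0 - ca_i * ca_i)
    sa_t = n_i * sa_i / n_t
    if sa_t >= 1.0:
        return 1.0  # total internal reflection
    ca_t = np.sqrt(1.0 - sa_t * sa_t)
    # sin/cos of (a_i +/- a_t) by the addition identities
    sap = sa_i * ca_t + ca_i * sa_t
    sam = sa_i * ca_t - ca_i * sa_t
    cap = ca_i * ca_t - sa_i * sa_t
    cam = ca_i * ca_t + sa_i * sa_t
    return 0.5 * sam * sam * (cap * cap + cam * cam) / (sap * sap * cam * cam)


@njit(cache=False)
def _sample_step(mu_t, xi):
    """Free-path length s = -ln(xi)/mu_t for xi in (0, 1]."""
    if xi <= 0.0:
        xi = 1e-12
    return -np.log(xi) / mu_t


@njit(cache=False)
def _hg_cos(g, xi):
    """Deflection cosine sampled from the Henyey-Greenstein phase function."""
    if g == 0.0:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - t * t) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=False)
def _spin(ux, uy, uz, ct, psi):
    """Rotate a unit direction by deflection cosine ct and azimuth psi."""
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(psi)
    sp = np.sin(psi)
    if abs(uz) > _VERTICAL:
        nux = st * cp
        nuy = st * sp
        nuz = ct if uz >= 0.0 else -ct
    else:
        tmp = np.sqrt(1.0 - uz * uz)
        nux = st * (ux * uz * cp - uy * sp) / tmp + ux * ct
        nuy = st * (uy * uz * cp + ux * sp) / tmp + uy * ct
        nuz = -st * cp * tmp + uz * ct
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=False)
def _trace_one(
    n_above,
    n_below,
    n_l,
    mua_l,
    mus_l,
    g_l,
    zb,
    flesh_idx,
    w_th,
    r_m,
    max_events,
    rng,
    dr,
    dz,
    nr,
    nz,
    na,
    refl_ra,
    absorb_rz,
    below_r,
    eff_w,
    tot_w,
    eff_n,
    tot_n,
    fpath,
    tpath,
    ovf_refl_a,
    ovf_below,
    path_buf,
    a_buf,
):
    """Trace one photon through the stack, scoring into the shared grids.

    Returns (code, exit_weight, exit_r, exit_alpha, n_events, flesh_flag).
    ``path_buf`` and ``a_buf`` are per-layer scratch accumulators the caller
    must zero beforehand; on return they hold the photon's geometric
    pathlength and absorbed weight per layer.
    """
    n_layers = n_l.shape[0]
    w = 1.0 - _fresnel(n_above, n_l[0], 1.0)  # specular decrement at launch
    x = 0.0
    y = 0.0
    z = 0.0
    ux = 0.0
    uy = 0.0
    uz = 1.0
    lay = 0
    flesh = False
    sl = 0.0  # dimensionless residual path, carried across boundaries
    events = 0
    code = TERMINATED
    exit_w = 0.0
    exit_r = 0.0
    exit_a = 0.0
    d_alpha = (np.pi / 2.0) / na

    while True:
        events += 1
        if events > max_events:
            code = RUNAWAY
            break
        if sl <= 0.0:
            xi = rng.random()
            if xi <= 0.0:
                xi = 1e-12
            sl = -np.log(xi)
        mu_t = mua_l[lay] + mus_l[lay]
        if uz > 0.0:
            db = (zb[lay + 1] - z) / uz
        elif uz < 0.0:
            db = (zb[lay] - z) / uz
        else:
            db = 1e30  # parallel to the planes: no boundary this step

        if db * mu_t <= sl:
            # -- hop to the boundary; residual dimensionless path is kept and
            #    re-scaled implicitly by the next layer's mu_t
            x += ux * db
            y += uy * db
            going_down = uz > 0.0
            z = zb[lay + 1] if going_down else zb[lay]
            path_buf[lay] += db
            sl -= db * mu_t
            n_i = n_l[lay]
            if going_down:
                n_t = n_below if lay == n_layers - 1 else n_l[lay + 1]
            else:
                n_t = n_above if lay == 0 else n_l[lay - 1]
            ca_i = uz if going_down else -uz
            if rng.random() <= _fresnel(n_i, n_t, ca_i):
                uz = -uz  # internally reflected
                continue
            # transmitted: refract by Snell's law
            sa_i = np.sqrt(max(0.0, 1.0 - ca_i * ca_i))
            sa_t = n_i * sa_i / n_t
            if sa_t > 1.0:
                sa_t = 1.0
            ca_t = np.sqrt(max(0.0, 1.0 - sa_t * sa_t))
            if going_down and lay == n_layers - 1:
                # escape below: core-absorbed, never returns
                r = np.sqrt(x * x + y * y)
                ir = int(r / dr)
                if ir >= nr:
                    ir = nr - 1
                    ovf_below[0] += w
                below_r[ir] += w
                code = ESCAPED_BELOW
                exit_w = w
                exit_r = r
                exit_a = np.arccos(ca_t)
                break
            if (not going_down) and lay == 0:
                # escape above: diffuse reflectance
                r = np.sqrt(x * x + y * y)
                alpha = np.arccos(ca_t)  # from the outward surface normal
                ia = int(alpha / d_alpha)
                if ia >= na:
                    ia = na - 1
                ir = int(r / dr)
                overflow = False
                if ir >= nr:
                    ir = nr - 1
                    overflow = True
                refl_ra[ir, ia] += w
                if overflow:
                    ovf_refl_a[ia] += w
                tot_w[ir] += w
                tot_n[ir] += 1.0
                if flesh:
                    eff_w[ir] += w
                    eff_n[ir] += 1.0
                l_tot = 0.0
                for k in range(n_layers):
                    l_tot += path_buf[k]
                l_flesh = 0.0
                if 0 <= flesh_idx < n_layers:
                    l_flesh = path_buf[flesh_idx]
                tpath[ir] += w * l_tot
                fpath[ir] += w * l_flesh
                code = ESCAPED_ABOVE
                exit_w = w
                exit_r = r
                exit_a = alpha
                break
            # internal crossing into an adjacent layer
            scale = n_i / n_t
            ux *= scale
            uy *= scale
            uz = ca_t if going_down else -ca_t
            lay += 1 if going_down else -1
            continue

        # -- hop to the interaction site
        s = sl / mu_t
        x += ux * s
        y += uy * s
        z += uz * s
        path_buf[lay] += s
        sl = 0.0
        # drop
        dw = w * mua_l[lay] / mu_t
        w -= dw
        a_buf[lay] += dw
        rr = np.sqrt(x * x + y * y)
        ir = int(rr / dr)
        iz = int(z / dz)
        if ir >= nr:
            ir = nr - 1
        if iz >= nz:
            iz = nz - 1
        elif iz < 0:
            iz = 0
        absorb_rz[ir, iz] += dw
        if lay == flesh_idx:
            flesh = True
        if w <= 0.0:  # fully absorbed (pure absorber): nothing left to trace
            code = TERMINATED
            break
        # spin
        ct = _hg_cos(g_l[lay], rng.random())
        psi = 2.0 * np.pi * rng.random()
        ux, uy, uz = _spin(ux, uy, uz, ct, psi)
        # roulette
        if w < w_th:
            if rng.random() < 1.0 / r_m:
                w *= r_m
            else:
                code = TERMINATED
                break

    return code, exit_w, exit_r, exit_a, events, 1 if flesh else 0


@njit(cache=False)
def _run_kernel(
    n_photons,
    n_above,
    n_below,
    n_l,
    mua_l,
    mus_l,
    g_l,
    zb,
    flesh_idx,
    w_th,
    r_m,
    max_events,
    rng,
    dr,
    dz,
    nr,
    nz,
    na,
    refl_ra,
    absorb_rz,
    below_r,
    eff_w,
    tot_w,
    eff_n,
    tot_n,
    fpath,
    tpath,
    ovf_refl_a,
    ovf_below,
):
    """Trace ``n_photons`` photons; return per-photon moment accumulators.

    Returns (rd_sum, rd_sumsq, tb_sum, tb_sumsq, a_sum, a_sumsq, n_runaway)
    where the a_* arrays are per-layer.  Sums of squares are over per-photon
    contributions and feed the Monte Carlo standard errors of the totals.
    """
    n_layers = n_l.shape[0]
    path_buf = np.zeros(n_layers)
    a_buf = np.zeros(n_layers)
    rd_sum = 0.0
    rd_sq = 0.0
    tb_sum = 0.0
    tb_sq = 0.0
    a_sum = np.zeros(n_layers)
    a_sq = np.zeros(n_layers)
    n_runaway = 0
    for _ in range(n_photons):
        for k in range(n_layers):
            path_buf[k] = 0.0
            a_buf[k] = 0.0
        code, exit_w, _, _, _, _ = _trace_one(
            n_above, n_below, n_l, mua_l, mus_l, g_l, zb, flesh_idx,
            w_th, r_m, max_events, rng, dr, dz, nr, nz, na,
            refl_ra, absorb_rz, below_r, eff_w, tot_w, eff_n, tot_n,
            fpath, tpath, ovf_refl_a, ovf_below, path_buf, a_buf,
        )
        if code == RUNAWAY:
            n_runaway += 1
        rd = exit_w if code == ESCAPED_ABOVE else 0.0
        tb = exit_w if code == ESCAPED_BELOW else 0.0
        rd_sum += rd
        rd_sq += rd * rd
        tb_sum += tb
        tb_sq += tb * tb
        for k in range(n_layers):
            a_sum[k] += a_buf[k]
            a_sq[k] += a_buf[k] * a_buf[k]
    return rd_sum, rd_sq, tb_sum, tb_sq, a_sum, a_sq, n_runaway
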