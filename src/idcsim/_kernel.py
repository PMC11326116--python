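"""Compiled right-hand side and fixed-step day integrator.

The RHS is written once in scalar NumPy-free Python and compiled with numba
when available (a pure-Python fallback keeps the package importable without
it, at reduced speed).  The RK4 day integrator is the screening path used by
the Latin-hypercube fitting loops and sweeps; the adaptive LSODA path in
``model.integrate_day`` is the reference integrator, and the two are
cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco

# Indices duplicated from params.py (numba cannot take module constants from
# closures at compile time as cheaply; keep literal offsets in sync).
# pp: 0 mu(3) | 3 d(3) | 6 K(3x5) | 21 u(3x5) | 36 req(3x5) | 51 secLY
#     52 secLT | 53 secWB | 54 P | 55 tau | 56 ka | 57 kd | 58 g | 59 gc
#     60 mode | 61 vol
# y: Bf Bc Yf Yc Tf Tc nLeu nTrp nUra nHis nGlc Ccum


@njit(cache=True)
def _collision(d, r, bystanders, gamma, mode, vol):
    if d <= 0.0 or r <= 0.0 or gamma == 0.0:
        return 0.0
    if mode < 0.5:  # per_total_cell
        n = d + r + bystanders
        if n <= 0.0:
            return 0.0
        return gamma * d * r / n
    # Levin-style mass action on densities; gamma carries µL/(cell·h)
    return gamma * d * r / vol


@njit(cache=True)
def _rhs(t, y, pp):
    out = np.zeros(12)
    bf = y[0] if y[0] > 0.0 else 0.0
    bc = y[1] if y[1] > 0.0 else 0.0
    yf = y[2] if y[2] > 0.0 else 0.0
    yc = y[3] if y[3] > 0.0 else 0.0
    tf = y[4] if y[4] > 0.0 else 0.0
    tc = y[5] if y[5] > 0.0 else 0.0

    n = np.empty(5)
    for a in range(5):
        v = y[6 + a]
        n[a] = v if v > 0.0 else 0.0

    # clump-local leucine perceived by clumped bacteria: bulk plus the
    # proximity-scaled standing pool secreted by clumped yeast partners
    local_leu = n[0] + pp[54] * (pp[51] * yc + pp[52] * tc) * pp[55]

    # growth factors (multiplicative Monod over required nutrients)
    g_bf = pp[0]
    g_bc = pp[0]
    for a in range(5):
        if pp[36 + a] > 0.0:
            k = pp[6 + a]
            g_bf *= n[a] / (k + n[a])
            ca = local_leu if a == 0 else n[a]
            g_bc *= ca / (k + ca)
    g_y = pp[1]
    for a in range(5):
        if pp[41 + a] > 0.0:
            g_y *= n[a] / (pp[11 + a] + n[a])
    g_t = pp[2]
    for a in range(5):
        if pp[46 + a] > 0.0:
            g_t *= n[a] / (pp[16 + a] + n[a])

    # clump exchange: 1:1 bacterium-partner pairs, partner drawn from free
    # yeast vs transconjugants by relative abundance
    ytf = yf + tf
    assoc = pp[56] * bf * ytf
    if ytf > 0.0:
        a_y = assoc * yf / ytf
        a_t = assoc * tf / ytf
    else:
        a_y = 0.0
        a_t = 0.0
    kd = pp[57]

    conj_f = _collision(bf, yf, tf, pp[58], pp[60], pp[61])
    conj_c = _collision(bc, yc, tc, pp[59], pp[60], pp[61])

    out[0] = (g_bf - pp[3]) * bf - assoc + kd * bc
    out[1] = (g_bc - pp[3]) * bc + assoc - kd * bc
    out[2] = (g_y - pp[4]) * yf - a_y + kd * yc - conj_f
    out[3] = (g_y - pp[4]) * yc + a_y - kd * yc - conj_c
    out[4] = (g_t - pp[5]) * tf - a_t + kd * tc + conj_f
    out[5] = (g_t - pp[5]) * tc + a_t - kd * tc + conj_c

    # secretion (constant per cell) and growth-coupled consumption
    out[6] = pp[51] * (yf + yc) + pp[52] * (tf + tc)
    out[7] = pp[53] * (bf + bc)
    b_growth_f = g_bf * bf
    b_growth_c = g_bc * bc
    y_growth = g_y * (yf + yc)
    t_growth = g_t * (tf + tc)
    for a in range(5):
        out[6 + a] -= (pp[21 + a] * (b_growth_f + b_growth_c)
                       + pp[26 + a] * y_growth
                       + pp[31 + a] * t_growth)

    out[11] = conj_f + conj_c
    return out


@njit(cache=True)
def _rk4_day(y0, pp, duration, n_steps, record_every):
    """Fixed-step RK4 over one day; returns states at recorded steps.

    Output has ``n_steps // record_every + 1`` rows (t=0 included).
    Components are clipped at zero after every step.
    """
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, 12))
    y = y0.copy()
    for i in range(12):
        if y[i] < 0.0:
            y[i] = 0.0
    out[0] = y
    h = duration / n_steps
    r = 1
    for s in range(n_steps):
        t = s * h
        k1 = _rhs(t, y, pp)
        k2 = _rhs(t + 0.5 * h, y + 0.5 * h * k1, pp)
        k3 = _rhs(t + 0.5 * h, y + 0.5 * h * k2, pp)
        k4 = _rhs(t + h, y + h * k3, pp)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for i in range(12):
            if y[i] < 0.0:
                y[i] = 0.0
        if (s + 1) % record_every == 0:
            out[r] = y
            r += 1
    return out
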