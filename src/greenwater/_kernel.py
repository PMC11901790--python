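"""Compiled inner loop of the Richards integration.

The modified-Picard substep (nodal hydraulics, tridiagonal assembly,
Thomas solve, boundary-mode switching) runs thousands of times per
simulated season, so it is JIT-compiled with numba.  The logic mirrors
the documentation in :mod:`greenwater.richards`; scalars and flat float
arrays only.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# boundary-mode codes
MODE_FLUX = 0
MODE_POND = 1
MODE_DRY = 2


@njit(cache=True)
def _hydraulics_fill(h, tr, ts, a, n, m, Ks, l, theta, cap, K):
    for i in range(h.size):
        hv = h[i]
        if hv < 0.0:
            ahn = abs(a[i] * hv) ** n[i]
            base = 1.0 + ahn
            se = base ** (-m[i])
            theta[i] = tr[i] + (ts[i] - tr[i]) * se
            c = (ts[i] - tr[i]) * n[i] * m[i] * (ahn / abs(hv)) / base * se
            cap[i] = c if c > 1e-12 else 1e-12
            sec = se if se < 1.0 else 1.0
            K[i] = Ks[i] * sec ** l[i] * (1.0 - (1.0 - sec ** (1.0 / m[i])) ** m[i]) ** 2
        else:
            theta[i] = ts[i]
            cap[i] = 1e-12
            K[i] = Ks[i]


@njit(cache=True)
def _thomas(lower, diag, upper, rhs, x, cp, dp):
    """Solve a tridiagonal system in place (Thomas algorithm)."""
    nn = diag.size
    cp[0] = upper[0] / diag[0]
    dp[0] = rhs[0] / diag[0]
    for i in range(1, nn):
        denom = diag[i] - lower[i - 1] * cp[i - 1]
        cp[i] = upper[i] / denom if i < nn - 1 else 0.0
        dp[i] = (rhs[i] - lower[i - 1] * dp[i - 1]) / denom
    x[nn - 1] = dp[nn - 1]
    for i in range(nn - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]


@njit(cache=True)
def picard_substep(h_in, theta_old, dt, q_target, sink,
                   tr, ts, a, n, m, Ks, l,
                   K_pond, K_dry, dz, tol, max_iter,
                   h_pond, h_dry, free_drain):
    """One implicit substep; returns (h_new, theta_new, q_top, q_bot, iters, ok)."""
    nn = h_in.size
    h = h_in.copy()
    theta = np.empty(nn)
    cap = np.empty(nn)
    K = np.empty(nn)
    lower = np.empty(nn - 1)
    upper = np.empty(nn - 1)
    diag = np.empty(nn)
    rhs = np.empty(nn)
    h_new = np.empty(nn)
    cp = np.empty(nn)
    dp = np.empty(nn)

    mode = MODE_FLUX
    switches = 0
    dz2 = dz * dz
    for it in range(1, max_iter + 1):
        _hydraulics_fill(h, tr, ts, a, n, m, Ks, l, theta, cap, K)
        for i in range(nn):
            diag[i] = cap[i] / dt
            rhs[i] = diag[i] * h[i] - (theta[i] - theta_old[i]) / dt - sink[i]
        for i in range(nn - 1):
            kint = 0.5 * (K[i] + K[i + 1])
            off = -kint / dz2
            lower[i] = off
            upper[i] = off
            diag[i] += kint / dz2
            diag[i + 1] += kint / dz2
            rhs[i] -= kint / dz
            rhs[i + 1] += kint / dz

        if mode == MODE_FLUX:
            rhs[0] += q_target / dz
        else:
            h_surf = h_pond if mode == MODE_POND else h_dry
            K_s = 0.5 * ((K_pond if mode == MODE_POND else K_dry) + K[0])
            diag[0] += 2.0 * K_s / dz2
            rhs[0] += K_s / dz + 2.0 * K_s * h_surf / dz2

        if free_drain:
            rhs[nn - 1] -= K[nn - 1] / dz

        _thomas(lower, diag, upper, rhs, h_new, cp, dp)

        if switches < 4:
            if mode == MODE_FLUX and q_target > 0.0 and h_new[0] > h_pond:
                mode = MODE_POND
                switches += 1
                h[:] = h_new
                continue
            if mode == MODE_FLUX and q_target < 0.0 and h_new[0] < h_dry:
                mode = MODE_DRY
                switches += 1
                h[:] = h_new
                continue
            if mode != MODE_FLUX:
                h_surf = h_pond if mode == MODE_POND else h_dry
                K_s = 0.5 * ((K_pond if mode == MODE_POND else K_dry) + K[0])
                q_try = K_s * (1.0 + 2.0 * (h_surf - h_new[0]) / dz)
                if (mode == MODE_POND and q_try > q_target) or (
                        mode == MODE_DRY and q_try < q_target):
                    mode = MODE_FLUX
                    switches += 1
                    h[:] = h_new
                    continue

        dh = 0.0
        for i in range(nn):
            d = abs(h_new[i] - h[i])
            if d > dh:
                dh = d
        h[:] = h_new
        if dh < tol:
            _hydraulics_fill(h, tr, ts, a, n, m, Ks, l, theta, cap, K)
            if mode == MODE_FLUX:
                q_top = q_target
            else:
                h_surf = h_pond if mode == MODE_POND else h_dry
                K_s = 0.5 * ((K_pond if mode == MODE_POND else K_dry) + K[0])
                q_top = K_s * (1.0 + 2.0 * (h_surf - h[0]) / dz)
            q_bot = K[nn - 1] if free_drain else 0.0
            return h, theta, q_top, q_bot, it, True
    return h, theta, 0.0, 0.0, max_iter, False
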