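"""Compiled inner loops for steady-state computation.

The bound-enzyme states have an exact closed form at steady state
(E1_i = E_i * S_d / (S_d + S_a) with S_d = sum_j k_ij X_dj and
S_a = sum_j (k_ij/q_ij) X_aj), so the fixed point of the full cell ODE
is found by solving the reduced 2**n_groups-dimensional metabolite
system.  A damped Newton iteration with an analytic Jacobian does the
work; a pseudo-transient continuation (adaptive implicit Euler) handles
cold starts and the rare step where Newton stalls.

Metabolites outside the `free` mask (unreachable from the medium) are
pinned to zero exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=True)
def rhs(X, enz_d, enz_a, K, Q, Edos, ttot, ext, bm, kBM, denom, free):
    """Reduced steady-state residual F(X); returns (F, W, v_BM)."""
    M = X.shape[0]
    nE = K.shape[0]
    S = K.shape[1]
    F = np.zeros(M)

    vbm = kBM
    for ib in range(bm.shape[0]):
        vbm *= X[bm[ib]]
    W = vbm / denom

    for i in range(nE):
        Sd = 0.0
        Sa = 0.0
        for j in range(S):
            kd = K[i, j]
            if kd > 0.0:
                Sd += kd * X[enz_d[i, j]]
                Sa += (kd / Q[i, j]) * X[enz_a[i, j]]
        Ssum = Sd + Sa
        if Ssum <= _TINY:
            continue
        E1 = Edos[i] * Sd / Ssum
        E0 = Edos[i] - E1
        for j in range(S):
            kd = K[i, j]
            if kd <= 0.0:
                continue
            dj = enz_d[i, j]
            aj = enz_a[i, j]
            v = kd * (E0 * X[dj] - E1 * X[aj] / Q[i, j])
            F[dj] -= v
            F[aj] += v

    for j in range(M):
        if ttot[j] > 0.0:
            F[j] -= ttot[j] * (X[j] - ext[j])

    for ib in range(bm.shape[0]):
        F[bm[ib]] -= vbm

    for j in range(M):
        F[j] -= W * X[j]

    for j in range(M):
        if not free[j]:
            F[j] = 0.0
    return F, W, vbm


@njit(cache=True)
def rhs_jac(X, enz_d, enz_a, K, Q, Edos, ttot, ext, bm, kBM, denom, free):
    """Residual plus analytic Jacobian; returns (F, J, W, v_BM)."""
    M = X.shape[0]
    nE = K.shape[0]
    S = K.shape[1]
    nb = bm.shape[0]
    F = np.zeros(M)
    J = np.zeros((M, M))

    vbm = kBM
    for ib in range(nb):
        vbm *= X[bm[ib]]
    W = vbm / denom

    # d v_BM / d X_b = kBM * prod of the other biomass concentrations
    g = np.zeros(nb)
    for ib in range(nb):
        p = kBM
        for jb in range(nb):
            if jb != ib:
                p *= X[bm[jb]]
        g[ib] = p

    for i in range(nE):
        Sd = 0.0
        Sa = 0.0
        for j in range(S):
            kd = K[i, j]
            if kd > 0.0:
                Sd += kd * X[enz_d[i, j]]
                Sa += (kd / Q[i, j]) * X[enz_a[i, j]]
        Ssum = Sd + Sa
        if Ssum <= _TINY:
            continue
        E = Edos[i]
        E1 = E * Sd / Ssum
        E0 = E - E1
        cd = E * Sa / (Ssum * Ssum)  # dE1/dX_dl = cd * k_l ; dE0 = -that
        ca = E * Sd / (Ssum * Ssum)  # dE0/dX_al = ca * c_l ; dE1 = -that
        for j in range(S):
            kd = K[i, j]
            if kd <= 0.0:
                continue
            dj = enz_d[i, j]
            aj = enz_a[i, j]
            c = kd / Q[i, j]
            A = kd * X[dj]
            B = c * X[aj]
            v = E0 * A - E1 * B
            F[dj] -= v
            F[aj] += v
            AB = A + B
            for l in range(S):
                kl = K[i, l]
                if kl <= 0.0:
                    continue
                dl = enz_d[i, l]
                al = enz_a[i, l]
                cl = kl / Q[i, l]
                dv_d = -AB * cd * kl
                if l == j:
                    dv_d += E0 * kd
                J[dj, dl] -= dv_d
                J[aj, dl] += dv_d
                dv_a = AB * ca * cl
                if l == j:
                    dv_a -= E1 * c
                J[dj, al] -= dv_a
                J[aj, al] += dv_a

    for j in range(M):
        if ttot[j] > 0.0:
            F[j] -= ttot[j] * (X[j] - ext[j])
            J[j, j] -= ttot[j]

    for ib in range(nb):
        b = bm[ib]
        F[b] -= vbm
        for jb in range(nb):
            J[b, bm[jb]] -= g[jb]

    for j in range(M):
        F[j] -= W * X[j]
        J[j, j] -= W
    for ib in range(nb):
        col = bm[ib]
        gw = g[ib] / denom
        if gw != 0.0:
            for j in range(M):
                J[j, col] -= X[j] * gw

    for j in range(M):
        if not free[j]:
            F[j] = 0.0
            for l in range(M):
                J[j, l] = 0.0
            J[j, j] = 1.0
    return F, J, W, vbm


@njit(cache=True)
def reachable(enz_d, enz_a, K, ttot, ext):
    """Metabolites that can carry nonzero concentration at steady state.

    Sources are importable nutrients; a donor->acceptor edge needs only an
    active rate constant, the reverse additionally needs the enzyme to be
    loadable (some active slot with a reachable donor).
    """
    M = ttot.shape[0]
    nE, S = K.shape
    reach = np.zeros(M, np.bool_)
    for j in range(M):
        if ttot[j] > 0.0 and ext[j] > 0.0:
            reach[j] = True
    changed = True
    while changed:
        changed = False
        for i in range(nE):
            loaded = False
            for j in range(S):
                if K[i, j] > 0.0 and reach[enz_d[i, j]]:
                    loaded = True
                    break
            for j in range(S):
                if K[i, j] <= 0.0:
                    continue
                d = enz_d[i, j]
                a = enz_a[i, j]
                if reach[d] and not reach[a]:
                    reach[a] = True
                    changed = True
                if loaded and reach[a] and not reach[d]:
                    reach[d] = True
                    changed = True
    return reach


@njit(cache=True)
def _max_abs(F, free):
    r = 0.0
    for j in range(F.shape[0]):
        if free[j]:
            a = abs(F[j])
            if a > r:
                r = a
    return r


@njit(cache=True)
def newton(X0, enz_d, enz_a, K, Q, Edos, ttot, ext, bm, kBM, denom, free,
           tol_accept, max_iter):
    """Damped Newton with nonnegativity projection.

    Iterates until the residual reaches the numerical floor (well below
    `tol_accept`) or progress stops; `converged` reports residual < tol_accept.
    Returns (X, converged, residual).
    """
    M = X0.shape[0]
    X = X0.copy()
    for j in range(M):
        if not free[j] or X[j] < 0.0:
            X[j] = 0.0

    res = 1e300
    for _ in range(max_iter):
        F, J, W, vbm = rhs_jac(X, enz_d, enz_a, K, Q, Edos, ttot, ext, bm,
                               kBM, denom, free)
        res = _max_abs(F, free)
        if res < 1e-14:
            return X, True, res
        for j in range(M):
            if free[j]:
                J[j, j] -= 1e-13
        dx = np.linalg.solve(J, -F)
        lam = 1.0
        accepted = False
        for _bt in range(10):
            Xn = X + lam * dx
            for j in range(M):
                if Xn[j] < 0.0:
                    Xn[j] = 0.0
            Fn, Wn, vn = rhs(Xn, enz_d, enz_a, K, Q, Edos, ttot, ext, bm,
                             kBM, denom, free)
            resn = _max_abs(Fn, free)
            if resn < res * 0.9999 or resn < 1e-14:
                X = Xn
                res = resn
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            # no further progress possible at this precision
            return X, res < tol_accept, res
        if res < 1e-14:
            return X, True, res
    return X, res < tol_accept, res


@njit(cache=True)
def ptc(X0, enz_d, enz_a, K, Q, Edos, ttot, ext, bm, kBM, denom, free,
        tol, dt0, max_steps):
    """Pseudo-transient continuation: adaptive implicit-Euler march toward the
    fixed point.  Used to bring cold or difficult starts into Newton's basin.
    """
    M = X0.shape[0]
    X = X0.copy()
    for j in range(M):
        if not free[j] or X[j] < 0.0:
            X[j] = 0.0
    dt = dt0
    res_prev = 1e300
    for _ in range(max_steps):
        F, J, W, vbm = rhs_jac(X, enz_d, enz_a, K, Q, Edos, ttot, ext, bm,
                               kBM, denom, free)
        res = _max_abs(F, free)
        if res < tol:
            return X, True, res
        # (I/dt - J) dx = F
        A = -J
        for j in range(M):
            if free[j]:
                A[j, j] += 1.0 / dt
            else:
                for l in range(M):
                    A[j, l] = 0.0
                A[j, j] = 1.0
        dx = np.linalg.solve(A, F)
        Xn = X + dx
        bad = False
        for j in range(M):
            if not np.isfinite(Xn[j]):
                bad = True
                break
            if Xn[j] < 0.0:
                Xn[j] = 0.0
        if bad:
            dt *= 0.25
            if dt < 1e-12:
                return X, False, res
            continue
        X = Xn
        if res < res_prev:
            dt = min(dt * 2.0, 1e8)
        else:
            dt = max(dt * 0.5, 1e-9)
        res_prev = res
    F, W, vbm = rhs(X, enz_d, enz_a, K, Q, Edos, ttot, ext, bm, kBM, denom, free)
    res = _max_abs(F, free)
    return X, res < tol, res
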