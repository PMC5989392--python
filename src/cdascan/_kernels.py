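"""Numba kernels for the pseudo-likelihood objective and its maximizer.

For small SNP sets (the regime of simulation protocols and per-pathway fits
after pruning) the vectorized numpy objective is dominated by per-call
overhead, so the objective/gradient, the Bayes predictor and a standard
L-BFGS loop (two-loop recursion, Armijo backtracking, curvature-guarded
history updates) are compiled with numba.  Large SNP sets go through the
BLAS-based numpy path instead, where matrix products dominate and numpy is
the right tool.

The kernels exploit the zero-reference convention: fields and couplings at
genotype level 0 are identically zero, so level-0 terms and couplings to
reference-genotype neighbors are skipped outright.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pl_negobj_grad", "pl_predict", "pl_lbfgs"]


@njit(cache=True, fastmath=True)
def _unpack_tensors(x, m, L, idx_h, fi, fj, fa, fb, use_J):
    nh = idx_h.shape[0]
    nJ = fi.shape[0]
    h0 = np.zeros((m, L))
    h1 = np.zeros((m, L))
    for t in range(nh):
        i = idx_h[t] // L
        a = idx_h[t] - i * L
        h0[i, a] = x[t]
        h1[i, a] = x[nh + t]
    if use_J and nJ > 0:
        J0 = np.zeros((m, m, L, L))
        J1 = np.zeros((m, m, L, L))
        for t in range(nJ):
            i, j, a, b = fi[t], fj[t], fa[t], fb[t]
            J0[i, j, a, b] = x[2 * nh + t]
            J0[j, i, b, a] = x[2 * nh + t]
            J1[i, j, a, b] = x[2 * nh + nJ + t]
            J1[j, i, b, a] = x[2 * nh + nJ + t]
    else:
        J0 = np.zeros((1, 1, 1, 1))
        J1 = np.zeros((1, 1, 1, 1))
    return h0, h1, J0, J1


@njit(cache=True, fastmath=True)
def _negobj_grad_L2(x, G, y, fi, fj, lam1, lam2, use_J):
    """Two-level (dominant) specialization: one free level per site, so the
    couplings collapse to symmetric m x m matrices and each site conditional
    is a sigmoid."""
    n, m = G.shape
    nJ = fi.shape[0]
    interacting = use_J and nJ > 0
    h0v = x[:m]
    h1v = x[m:2 * m]
    J0m = np.zeros((m, m))
    J1m = np.zeros((m, m))
    if interacting:
        for t in range(nJ):
            i, j = fi[t], fj[t]
            J0m[i, j] = x[2 * m + t]
            J0m[j, i] = x[2 * m + t]
            J1m[i, j] = x[2 * m + nJ + t]
            J1m[j, i] = x[2 * m + nJ + t]
    gh0 = np.zeros(m)
    gh1 = np.zeros(m)
    gJ0 = np.zeros((m, m))
    gJ1 = np.zeros((m, m))
    act = np.empty(m, np.int64)
    ll = 0.0
    for k in range(n):
        yk = y[k]
        na = 0
        for j in range(m):
            if G[k, j] > 0:
                act[na] = j
                na += 1
        for i in range(m):
            f0 = h0v[i]
            f1 = h1v[i]
            if interacting:
                for t in range(na):
                    j = act[t]
                    f0 += J0m[i, j]  # diagonal is zero, no i==j guard needed
                    f1 += J1m[i, j]
            v = f0 + yk * f1
            if v > 0.0:
                e = np.exp(-v)
                p1 = 1.0 / (1.0 + e)
                sp = v + np.log1p(e)
            else:
                e = np.exp(v)
                p1 = e / (1.0 + e)
                sp = np.log1p(e)
            if G[k, i] > 0:
                ll += v
                d = 1.0 - p1
            else:
                d = -p1
            ll -= sp
            gh0[i] += d
            gh1[i] += yk * d
            if interacting:
                for t in range(na):
                    j = act[t]
                    gJ0[i, j] += d
                    gJ1[i, j] += yk * d
    grad = np.empty(x.shape[0])
    pen = 0.0
    for i in range(m):
        grad[i] = gh0[i] / n - lam1 * x[i]
        grad[m + i] = gh1[i] / n - lam1 * x[m + i]
        pen += 0.5 * lam1 * (x[i] * x[i] + x[m + i] * x[m + i])
    if interacting:
        for t in range(nJ):
            i, j = fi[t], fj[t]
            v0 = x[2 * m + t]
            v1 = x[2 * m + nJ + t]
            grad[2 * m + t] = (gJ0[i, j] + gJ0[j, i]) / n - lam2 * v0
            grad[2 * m + nJ + t] = (gJ1[i, j] + gJ1[j, i]) / n - lam2 * v1
            pen += 0.5 * lam2 * (v0 * v0 + v1 * v1)
    return -(ll / n - pen), -grad


@njit(cache=True, fastmath=True)
def _predict_L2(x, G, fi, fj, use_J, ygrid, logprior):
    n, m = G.shape
    nJ = fi.shape[0]
    interacting = use_J and nJ > 0
    Gn = ygrid.shape[0]
    h0v = x[:m]
    h1v = x[m:2 * m]
    J0m = np.zeros((m, m))
    J1m = np.zeros((m, m))
    if interacting:
        for t in range(nJ):
            i, j = fi[t], fj[t]
            J0m[i, j] = x[2 * m + t]
            J0m[j, i] = x[2 * m + t]
            J1m[i, j] = x[2 * m + nJ + t]
            J1m[j, i] = x[2 * m + nJ + t]
    preds = np.empty(n)
    a0 = np.empty(m)
    a1 = np.empty(m)
    act = np.empty(m, np.int64)
    lw = np.empty(Gn)
    for k in range(n):
        na = 0
        for j in range(m):
            if G[k, j] > 0:
                act[na] = j
                na += 1
        num0 = 0.0
        num1 = 0.0
        for i in range(m):
            f0 = h0v[i]
            f1 = h1v[i]
            if interacting:
                for t in range(na):
                    j = act[t]
                    f0 += J0m[i, j]
                    f1 += J1m[i, j]
            a0[i] = f0
            a1[i] = f1
            if G[k, i] > 0:
                num0 += f0
                num1 += f1
        for gi in range(Gn):
            yv = ygrid[gi]
            ll = num0 + yv * num1
            for i in range(m):
                v = a0[i] + yv * a1[i]
                if v > 30.0:
                    ll -= v
                else:
                    ll -= np.log1p(np.exp(v))
            lw[gi] = ll + logprior[gi]
        mxw = lw[0]
        for gi in range(1, Gn):
            if lw[gi] > mxw:
                mxw = lw[gi]
        num = 0.0
        den = 0.0
        for gi in range(Gn):
            w = np.exp(lw[gi] - mxw)
            num += w * ygrid[gi]
            den += w
        preds[k] = num / den
    return preds


@njit(cache=True, fastmath=True)
def pl_negobj_grad(x, G, y, L, idx_h, fi, fj, fa, fb, lam1, lam2, use_J):
    """Negated penalized pseudo-log-likelihood per sample, with gradient.

    ``x`` is the free-parameter vector: [h0, h1, J0, J1] blocks with the
    level-0 reference entries excluded; ``fi/fj/fa/fb`` index the free
    couplings (i < j, levels >= 1).  Two-level encodings take the
    specialized sigmoid path.
    """
    if L == 2:
        return _negobj_grad_L2(x, G, y, fi, fj, lam1, lam2, use_J)
    n, m = G.shape
    nh = idx_h.shape[0]
    nJ = fi.shape[0]
    interacting = use_J and nJ > 0
    h0, h1, J0, J1 = _unpack_tensors(x, m, L, idx_h, fi, fj, fa, fb, use_J)

    gh0 = np.zeros((m, L))
    gh1 = np.zeros((m, L))
    if interacting:
        gJ0 = np.zeros((m, m, L, L))
        gJ1 = np.zeros((m, m, L, L))
    else:
        gJ0 = np.zeros((1, 1, 1, 1))
        gJ1 = np.zeros((1, 1, 1, 1))

    Hs = np.empty(L)
    P = np.empty(L)
    act = np.empty(m, np.int64)
    ll = 0.0
    for k in range(n):
        yk = y[k]
        na = 0
        for j in range(m):
            if G[k, j] > 0:
                act[na] = j
                na += 1
        for i in range(m):
            ai = G[k, i]
            for a in range(1, L):
                f0 = h0[i, a]
                f1 = h1[i, a]
                if interacting:
                    for t in range(na):
                        j = act[t]
                        if j != i:
                            gj = G[k, j]
                            f0 += J0[i, j, a, gj]
                            f1 += J1[i, j, a, gj]
                Hs[a] = f0 + yk * f1
            mx = 0.0
            for a in range(1, L):
                if Hs[a] > mx:
                    mx = Hs[a]
            if mx < 30.0:
                Z = 1.0
                for a in range(1, L):
                    P[a] = np.exp(Hs[a])
                    Z += P[a]
                if ai > 0:
                    ll += Hs[ai]
                ll -= np.log(Z)
            else:
                Z = np.exp(-mx)
                for a in range(1, L):
                    P[a] = np.exp(Hs[a] - mx)
                    Z += P[a]
                if ai > 0:
                    ll += Hs[ai]
                ll -= np.log(Z) + mx
            for a in range(1, L):
                P[a] /= Z
                d = -P[a]
                if a == ai:
                    d += 1.0
                gh0[i, a] += d
                gh1[i, a] += yk * d
                if interacting:
                    for t in range(na):
                        j = act[t]
                        if j != i:
                            gj = G[k, j]
                            gJ0[i, j, a, gj] += d
                            gJ1[i, j, a, gj] += yk * d

    grad = np.empty(x.shape[0])
    pen = 0.0
    for t in range(nh):
        i = idx_h[t] // L
        a = idx_h[t] - i * L
        grad[t] = gh0[i, a] / n - lam1 * x[t]
        grad[nh + t] = gh1[i, a] / n - lam1 * x[nh + t]
        pen += 0.5 * lam1 * (x[t] * x[t] + x[nh + t] * x[nh + t])
    if interacting:
        for t in range(nJ):
            i, j, a, b = fi[t], fj[t], fa[t], fb[t]
            v0 = x[2 * nh + t]
            v1 = x[2 * nh + nJ + t]
            grad[2 * nh + t] = (gJ0[i, j, a, b] + gJ0[j, i, b, a]) / n \
                - lam2 * v0
            grad[2 * nh + nJ + t] = (gJ1[i, j, a, b] + gJ1[j, i, b, a]) / n \
                - lam2 * v1
            pen += 0.5 * lam2 * (v0 * v0 + v1 * v1)
    return -(ll / n - pen), -grad


@njit(cache=True, fastmath=True)
def pl_predict(x, G, L, idx_h, fi, fj, fa, fb, use_J, ygrid, logprior):
    """Bayes phenotype estimates under the PL factorization.

    ``logprior[g]`` holds the log normal density of the marginal phenotype
    model plus the log trapezoidal weight at grid point g.
    """
    if L == 2:
        return _predict_L2(x, G, fi, fj, use_J, ygrid, logprior)
    n, m = G.shape
    nJ = fi.shape[0]
    interacting = use_J and nJ > 0
    Gn = ygrid.shape[0]
    h0, h1, J0, J1 = _unpack_tensors(x, m, L, idx_h, fi, fj, fa, fb, use_J)

    preds = np.empty(n)
    A0 = np.empty((m, L))
    A1 = np.empty((m, L))
    act = np.empty(m, np.int64)
    lw = np.empty(Gn)
    for k in range(n):
        num0 = 0.0
        num1 = 0.0
        na = 0
        for j in range(m):
            if G[k, j] > 0:
                act[na] = j
                na += 1
        for i in range(m):
            for a in range(1, L):
                f0 = h0[i, a]
                f1 = h1[i, a]
                if interacting:
                    for t in range(na):
                        j = act[t]
                        if j != i:
                            gj = G[k, j]
                            f0 += J0[i, j, a, gj]
                            f1 += J1[i, j, a, gj]
                A0[i, a] = f0
                A1[i, a] = f1
            ai = G[k, i]
            if ai > 0:
                num0 += A0[i, ai]
                num1 += A1[i, ai]
        for gi in range(Gn):
            yv = ygrid[gi]
            ll = num0 + yv * num1
            for i in range(m):
                mx = 0.0
                for a in range(1, L):
                    v = A0[i, a] + yv * A1[i, a]
                    if v > mx:
                        mx = v
                if mx < 30.0:
                    Z = 1.0
                    for a in range(1, L):
                        Z += np.exp(A0[i, a] + yv * A1[i, a])
                    ll -= np.log(Z)
                else:
                    Z = np.exp(-mx)
                    for a in range(1, L):
                        Z += np.exp(A0[i, a] + yv * A1[i, a] - mx)
                    ll -= np.log(Z) + mx
            lw[gi] = ll + logprior[gi]
        mxw = lw[0]
        for gi in range(1, Gn):
            if lw[gi] > mxw:
                mxw = lw[gi]
        num = 0.0
        den = 0.0
        for gi in range(Gn):
            w = np.exp(lw[gi] - mxw)
            num += w * ygrid[gi]
            den += w
        preds[k] = num / den
    return preds


@njit(cache=True, fastmath=True)
def pl_lbfgs(x0, G, y, L, idx_h, fi, fj, fa, fb, lam1, lam2, use_J,
             tol, max_iter):
    """Minimize the negated penalized pseudo-likelihood by L-BFGS.

    History size 8, Armijo backtracking line search, history pairs skipped
    when the curvature condition fails.  Terminates when the gradient
    max-norm drops to ``tol`` or after ``max_iter`` iterations.  Returns
    ``(x, converged, iterations)``.
    """
    hist = 8
    d = x0.shape[0]
    x = x0.copy()
    f, g = pl_negobj_grad(x, G, y, L, idx_h, fi, fj, fa, fb, lam1, lam2, use_J)
    S = np.zeros((hist, d))
    Y = np.zeros((hist, d))
    rho = np.zeros(hist)
    alpha = np.zeros(hist)
    n_pairs = 0
    head = 0  # next slot to write
    it = 0
    while it < max_iter:
        gmax = 0.0
        for t in range(d):
            av = abs(g[t])
            if av > gmax:
                gmax = av
        if gmax <= tol:
            return x, True, it
        # two-loop recursion
        q = -g.copy()
        for c in range(n_pairs):
            idx = (head - 1 - c) % hist
            alpha[idx] = rho[idx] * np.dot(S[idx], q)
            q -= alpha[idx] * Y[idx]
        if n_pairs > 0:
            last = (head - 1) % hist
            gamma = np.dot(S[last], Y[last]) / np.dot(Y[last], Y[last])
            q *= gamma
        for c in range(n_pairs - 1, -1, -1):
            idx = (head - 1 - c) % hist
            beta = rho[idx] * np.dot(Y[idx], q)
            q += (alpha[idx] - beta) * S[idx]
        # descent check
        dg = np.dot(q, g)
        if dg >= 0.0:
            q = -g.copy()
            dg = -np.dot(g, g)
        # Armijo backtracking
        step = 1.0
        accepted = False
        fn = f
        gn = g
        for _ in range(40):
            xn = x + step * q
            fn, gn = pl_negobj_grad(xn, G, y, L, idx_h, fi, fj, fa, fb,
                                    lam1, lam2, use_J)
            if fn <= f + 1e-4 * step * dg:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return x, False, it
        s = xn - x
        yv = gn - g
        sy = np.dot(s, yv)
        if sy > 1e-12:
            S[head] = s
            Y[head] = yv
            rho[head] = 1.0 / sy
            head = (head + 1) % hist
            if n_pairs < hist:
                n_pairs += 1
        x, f, g = xn, fn, gn
        it += 1
    gmax = 0.0
    for t in range(d):
        av = abs(g[t])
        if av > gmax:
            gmax = av
    return x, gmax <= tol, it
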