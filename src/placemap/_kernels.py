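"""Low-level training kernels.

The online learning loop (thresholded Euler dynamics followed by an
outer-product dictionary update, once per presented location) is written as
explicit loops and JIT-compiled with numba.  If numba is unavailable the
same functions run as plain Python, bit-for-bit the same algorithm, only
slower.  Vectorized reference implementations of the individual operations
live in :mod:`placemap.network`; agreement between the two is covered by
tests.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


U_GUARD = 1.0e6  # membrane potential magnitude signalling divergence


@njit(cache=False)
def lca_loop(b, W, beta, alpha, n_steps):
    """Euler-integrate the thresholded competitive dynamics for one input.

    b is the feedforward drive A^T s_e; each step computes the rates
    s = max(u - beta, 0) from the current potentials and then updates
    u += alpha * (b - u - W s).  Returns (rates, potentials) after exactly
    ``n_steps`` steps, plus a status flag (1 = diverged).
    """
    n = b.shape[0]
    u = np.zeros(n)
    s = np.zeros(n)
    y = np.zeros(n)
    act = np.empty(n, np.int64)
    for _ in range(n_steps):
        nact = 0
        for j in range(n):
            sj = u[j] - beta
            if sj > 0.0:
                s[j] = sj
                act[nact] = j
                nact += 1
            else:
                s[j] = 0.0
        for j in range(n):
            y[j] = 0.0
        for a in range(nact):
            jj = act[a]
            sj = s[jj]
            for j in range(n):
                y[j] += W[j, jj] * sj
        for j in range(n):
            u[j] += alpha * (b[j] - u[j] - y[j])
    status = 0
    for j in range(n):
        if not (-U_GUARD < u[j] < U_GUARD):
            status = 1
        sj = u[j] - beta
        s[j] = sj if sj > 0.0 else 0.0
    return s, u, status


@njit(cache=False)
def train_chunk(
    E,
    A,
    W,
    locs,
    noise,
    use_noise,
    beta,
    alpha,
    n_steps,
    eta,
    respawn,
    cost_log,
    act_log,
):
    """Run one chunk of training epochs in place.

    Per epoch: read the entorhinal response row (optionally plus
    pre-drawn Gaussian noise), run the competitive dynamics, then apply the
    outer-product update to the active dictionary columns, clip negatives,
    renormalize the touched columns to unit length and refresh the affected
    rows/columns of the recurrent matrix W = A^T A - I.

    ``cost_log``/``act_log`` receive the pre-update sparse-coding cost and
    the active fraction for every epoch of the chunk.  Columns whose norm
    collapses to zero after clipping are re-seeded from the ``respawn``
    pool.  Returns (status, n_dead) with status 1 on numerical divergence.
    """
    n_epochs = locs.shape[0]
    Ne = E.shape[1]
    Nh = A.shape[1]
    u = np.zeros(Nh)
    s = np.zeros(Nh)
    y = np.zeros(Nh)
    b = np.zeros(Nh)
    s_e = np.zeros(Ne)
    recon = np.zeros(Ne)
    act = np.empty(Nh, np.int64)
    n_dead = 0
    respawn_i = 0
    for t in range(n_epochs):
        loc = locs[t]
        for i in range(Ne):
            s_e[i] = E[loc, i]
        if use_noise:
            for i in range(Ne):
                s_e[i] += noise[t, i]
        for j in range(Nh):
            b[j] = 0.0
            u[j] = 0.0
        for i in range(Ne):
            sei = s_e[i]
            if sei != 0.0:
                for j in range(Nh):
                    b[j] += A[i, j] * sei
        for _ in range(n_steps):
            nact = 0
            for j in range(Nh):
                sj = u[j] - beta
                if sj > 0.0:
                    s[j] = sj
                    act[nact] = j
                    nact += 1
                else:
                    s[j] = 0.0
            for j in range(Nh):
                y[j] = 0.0
            for a in range(nact):
                jj = act[a]
                sj = s[jj]
                for j in range(Nh):
                    y[j] += W[j, jj] * sj
            for j in range(Nh):
                u[j] += alpha * (b[j] - u[j] - y[j])
        nact = 0
        for j in range(Nh):
            if not (-U_GUARD < u[j] < U_GUARD):
                return 1, n_dead
            sj = u[j] - beta
            if sj > 0.0:
                s[j] = sj
                act[nact] = j
                nact += 1
            else:
                s[j] = 0.0
        for i in range(Ne):
            recon[i] = 0.0
        for a in range(nact):
            j = act[a]
            sj = s[j]
            for i in range(Ne):
                recon[i] += A[i, j] * sj
        err = 0.0
        for i in range(Ne):
            d = s_e[i] - recon[i]
            err += d * d
        ssum = 0.0
        for a in range(nact):
            ssum += s[act[a]]
        cost_log[t] = 0.5 * err + beta * ssum
        act_log[t] = nact / Nh
        if nact == 0:
            continue
        for a in range(nact):
            j = act[a]
            sj = s[j]
            norm2 = 0.0
            for i in range(Ne):
                aij = A[i, j] + eta * (s_e[i] - recon[i]) * sj
                if aij < 0.0:
                    aij = 0.0
                A[i, j] = aij
                norm2 += aij * aij
            if norm2 == 0.0:
                # dead unit: re-seed from the pre-drawn random pool
                n_dead += 1
                for i in range(Ne):
                    aij = respawn[respawn_i % respawn.shape[0], i]
                    A[i, j] = aij
                    norm2 += aij * aij
                respawn_i += 1
            inv = 1.0 / np.sqrt(norm2)
            for i in range(Ne):
                A[i, j] *= inv
        for a in range(nact):
            j = act[a]
            for q in range(Nh):
                d = 0.0
                for i in range(Ne):
                    d += A[i, q] * A[i, j]
                if q == j:
                    d -= 1.0
                W[q, j] = d
                W[j, q] = d
    return 0, n_dead
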