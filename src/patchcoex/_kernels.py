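"""Hot inner loop of the explicit competition-diffusion integrator.

The update is carried out on the packed interior-cell representation:
``u`` has shape (S, n_interior) and the discrete Laplacian is a CSR matrix
over interior cells with Dirichlet (zero) exterior. Compiled with numba
when available; an equivalent vectorized numpy fallback keeps the package
functional without it.

Status codes returned by the evolvers: 0 = step cap reached without
convergence, 1 = converged (last total absolute change < tol),
2 = numerical instability (non-finite value or undershoot below -clamp_eps;
the offending step/cell/species indices are reported).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - environment detail
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def _evolve_csr(indptr, indices, data, u, rvec, dvec, amat, dt, tol, max_steps,
                clamp_eps, hist_every, hist):
    S, n = u.shape
    du = np.empty_like(u)
    clamp_count = 0
    hist_len = 0
    step = 0
    while step < max_steps:
        for i in range(S):
            Di = dvec[i]
            ri = rvec[i]
            for c in range(n):
                lap = 0.0
                for k in range(indptr[c], indptr[c + 1]):
                    lap += data[k] * u[i, indices[k]]
                inter = 0.0
                for j in range(S):
                    inter += amat[i, j] * u[j, c]
                du[i, c] = dt * (Di * lap + u[i, c] * (ri - inter))
        total_change = 0.0
        for i in range(S):
            for c in range(n):
                new = u[i, c] + du[i, c]
                if not np.isfinite(new) or new <= -clamp_eps:
                    return step, 2, clamp_count, hist_len, step, c, i
                if new < 0.0:
                    clamp_count += 1
                    new = 0.0
                total_change += abs(new - u[i, c])
                u[i, c] = new
        step += 1
        if hist_every > 0 and step % hist_every == 0 and hist_len < hist.shape[0]:
            hist[hist_len] = total_change
            hist_len += 1
        if total_change < tol:
            return step, 1, clamp_count, hist_len, -1, -1, -1
    return step, 0, clamp_count, hist_len, -1, -1, -1


def _evolve_numpy(lap_csr, u, rvec, dvec, amat, dt, tol, max_steps,
                  clamp_eps, hist_every, hist):
    """Vectorized fallback with identical semantics to :func:`_evolve_csr`."""
    clamp_count = 0
    hist_len = 0
    step = 0
    while step < max_steps:
        lap = lap_csr.dot(u.T).T
        du = dt * (dvec[:, None] * lap + u * (rvec[:, None] - amat @ u))
        new = u + du
        bad = ~np.isfinite(new) | (new <= -clamp_eps)
        if bad.any():
            i, c = np.argwhere(bad)[0]
            return step, 2, clamp_count, hist_len, step, int(c), int(i)
        neg = new < 0.0
        clamp_count += int(neg.sum())
        new[neg] = 0.0
        total_change = float(np.abs(new - u).sum())
        u[...] = new
        step += 1
        if hist_every > 0 and step % hist_every == 0 and hist_len < hist.shape[0]:
            hist[hist_len] = total_change
            hist_len += 1
        if total_change < tol:
            return step, 1, clamp_count, hist_len, -1, -1, -1
    return step, 0, clamp_count, hist_len, -1, -1, -1


def evolve(lap_csr, u, rvec, dvec, amat, dt, tol, max_steps, clamp_eps,
           hist_every=100, use_numba=True):
    """Run the explicit scheme in place on packed ``u``; see module docstring."""
    hist = np.empty(max(max_steps // hist_every + 1, 1) if hist_every > 0 else 1)
    if HAVE_NUMBA and use_numba:
        out = _evolve_csr(
            lap_csr.indptr, lap_csr.indices, lap_csr.data, u,
            rvec, dvec, amat, dt, tol, max_steps, clamp_eps, hist_every, hist,
        )
    else:
        out = _evolve_numpy(
            lap_csr, u, rvec, dvec, amat, dt, tol, max_steps, clamp_eps,
            hist_every, hist,
        )
    steps, status, clamp_count, hist_len, bad_step, bad_cell, bad_species = out
    return {
        "steps": int(steps),
        "status": int(status),
        "clamp_count": int(clamp_count),
        "history": hist[:hist_len].copy(),
        "bad": (int(bad_step), int(bad_cell), int(bad_species)),
    }
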