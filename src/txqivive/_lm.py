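"""Batched bounded Levenberg-Marquardt for the dose-response families.

The BMC engine fits four small nonlinear models to thousands of genes and
to hundreds of bootstrap replicates per gene. Generic solvers spend most
of that time in per-call overhead, so this module implements a vectorized
LM iteration that advances a whole batch of problems (multi-starts or
bootstrap replicates) simultaneously: parameters (B, p), residuals (B, n),
analytic Jacobians (B, n, p), one batched normal-equation solve per step.
Bounds are enforced by projection, which is adequate here because starts
are data-informed and the families are monotone in their parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lm_fit_batch"]


def lm_fit_batch(
    fun,
    jac,
    y: np.ndarray,
    p0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    max_iter: int = 60,
    xtol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize ||fun(P) - y||² row-wise over a batch.

    Parameters
    ----------
    fun, jac : callables
        ``fun(P) -> (B, n)`` model values and ``jac(P) -> (B, n, p)``.
    y : (B, n) targets; p0 : (B, p) starts; lo, hi : (p,) bounds.

    Returns ``(P, sse)`` with the best parameters found per row.
    """
    p = np.clip(np.asarray(p0, dtype=float), lo, hi)
    b, npar = p.shape
    lam = np.full(b, 1e-3)
    r = fun(p) - y
    sse = np.einsum("bn,bn->b", r, r)
    active = np.ones(b, dtype=bool)
    eye = np.eye(npar)
    for _ in range(max_iter):
        if not active.any():
            break
        pa = p[active]
        ya = y[active]
        ra = fun(pa) - ya
        ja = jac(pa)
        jtj = np.einsum("bnp,bnq->bpq", ja, ja)
        jtr = np.einsum("bnp,bn->bp", ja, ra)
        diag = np.einsum("bpp->bp", jtj)
        damp = np.maximum(diag, 1e-12) * lam[active][:, None]
        a_mat = jtj + damp[:, :, None] * eye
        try:
            step = -np.linalg.solve(a_mat, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            a_mat = a_mat + 1e-8 * eye
            step = -np.linalg.solve(a_mat, jtr[..., None])[..., 0]
        trial = np.clip(pa + step, lo, hi)
        rt = fun(trial) - ya
        sse_t = np.einsum("bn,bn->b", rt, rt)
        improved = sse_t < sse[active] * (1 - 1e-15)
        idx = np.flatnonzero(active)
        good = idx[improved]
        p[good] = trial[improved]
        sse[good] = sse_t[improved]
        lam[good] = np.maximum(lam[good] / 3.0, 1e-12)
        bad = idx[~improved]
        lam[bad] = np.minimum(lam[bad] * 5.0, 1e10)
        # stop rows whose accepted relative step is tiny
        rel = np.max(
            np.abs(trial[improved] - pa[improved])
            / np.maximum(np.abs(pa[improved]), 1e-12),
            axis=1,
        ) if improved.any() else np.empty(0)
        done = good[rel < xtol] if len(rel) else np.empty(0, dtype=int)
        active[done] = False
        # rows with very large lambda cannot move: stop them too
        active[idx[lam[idx] >= 1e10]] = False
    return p, sse
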