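"""Non-negativity-constrained trilinear tensor decomposition.

Alternating least squares over the three factor matrices of a CP/PARAFAC
model ``X[i,j,k] = sum_r A[i,r] B[j,r] C[k,r]`` with every factor entry
constrained >= 0.  Each block update is an *exact* non-negative
least-squares solve, so the squared residual is non-increasing across
iterations — a property the test suite asserts on the iteration trace.

The block solves work on the normal equations: the Gram matrix of the
Khatri-Rao design factorises into a Hadamard product of the small per-mode
Grams, and the right-hand side is a matricised-tensor-times-Khatri-Rao
product, so no tall design matrix is ever formed.  For the ranks used here
(2-4 chemical species) the NNLS is solved exactly by enumerating active
sets and checking the KKT conditions, vectorised over all rows at once;
larger ranks fall back to scipy's NNLS.

Under Kruskal's condition (factors of full column rank in at least two
modes — distinct spectra, lifetimes and concentration profiles) the
decomposition is unique up to permutation and scaling; resolving that
indeterminacy is the caller's job (see :mod:`lanthafit.trlfs`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .errors import InputError

__all__ = ["CPDecomposition", "nn_parafac", "khatri_rao", "factor_congruence"]

_ENUM_MAX_RANK = 6


def khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product of (I,R) and (J,R) -> (I*J, R)."""
    i, r = a.shape
    j, r2 = b.shape
    if r != r2:
        raise InputError("Khatri-Rao factors must share the column count")
    return (a[:, None, :] * b[None, :, :]).reshape(i * j, r)


def nnls_gram(gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Exact NNLS from normal equations, for many right-hand sides.

    Minimises ``0.5 x' G x - x' h`` subject to ``x >= 0`` for every column
    ``h`` of ``rhs`` (shape (R, N)); returns (N, R).  For small R every
    active set is enumerated and the KKT-optimal solution selected, all
    rows in one vectorised pass per subset.
    """
    r, n = rhs.shape
    out = np.zeros((n, r))
    # fast path: the unconstrained minimiser is the NNLS solution wherever it
    # is feasible — the common case once the iterates are interior
    try:
        x_free = np.linalg.solve(gram, rhs)
        interior = np.all(x_free >= 0.0, axis=0)
    except np.linalg.LinAlgError:
        x_free, interior = None, np.zeros(n, dtype=bool)
    if x_free is not None:
        out[interior] = x_free[:, interior].T
    rest = np.flatnonzero(~interior)
    if rest.size == 0:
        return out
    rhs_rest = rhs[:, rest]

    if r > _ENUM_MAX_RANK:
        # rare path: rebuild a design from the Gram via Cholesky
        chol = np.linalg.cholesky(gram + 1e-12 * np.eye(r) * np.trace(gram) / r)
        for pos, col in enumerate(rest):
            y = np.linalg.solve(chol, rhs_rest[:, pos])
            out[col], _ = _scipy_nnls(chol.T, y)
        return out

    m = rest.size
    tol = 1e-12 * max(float(np.trace(gram)) / r, 1e-300)
    dual_tol = 1e-9 * max(float(np.trace(gram)) / r, 1e-300)
    best_x = np.zeros((m, r))
    best_obj = np.zeros(m)                           # objective of x = 0
    solved = np.all(rhs_rest <= dual_tol, axis=0)    # KKT at zero: gradient -h >= 0

    for size in range(1, r + 1):
        for subset in combinations(range(r), size):
            idx = np.asarray(subset)
            g_ss = gram[np.ix_(idx, idx)]
            try:
                x_s = np.linalg.solve(g_ss, rhs_rest[idx, :])    # (size, m)
            except np.linalg.LinAlgError:
                continue
            # primal feasibility on the support
            feas = np.all(x_s >= -tol, axis=0)
            # dual feasibility off the support: grad = G x - h >= 0
            off = np.setdiff1d(np.arange(r), idx)
            if off.size:
                grad_off = gram[np.ix_(off, idx)] @ x_s - rhs_rest[off, :]
                feas &= np.all(grad_off >= -dual_tol, axis=0)
            obj = -0.5 * np.sum(x_s * rhs_rest[idx, :], axis=0)  # 0.5 x'Gx - x'h at solution
            take = feas & (~solved | (obj < best_obj - tol))
            if np.any(take):
                cols = np.flatnonzero(take)
                best_x[cols, :] = 0.0
                best_x[np.ix_(cols, idx)] = np.clip(x_s[:, cols].T, 0.0, None)
                best_obj[cols] = obj[cols]
                solved[cols] = True

    if not np.all(solved):
        # numerically degenerate columns: scipy fallback on a Cholesky design
        chol = np.linalg.cholesky(
            gram + 1e-10 * np.eye(r) * max(np.trace(gram) / r, 1e-300))
        for pos in np.flatnonzero(~solved):
            y = np.linalg.solve(chol, rhs_rest[:, pos])
            best_x[pos], _ = _scipy_nnls(chol.T, y)
    out[rest] = best_x
    return out


@dataclass
class CPDecomposition:
    """Result of one non-negative trilinear decomposition."""

    factors: tuple[np.ndarray, np.ndarray, np.ndarray]
    residual_norm: float
    explained_variance: float
    n_iter: int
    converged: bool
    residual_trace: np.ndarray

    @property
    def rank(self) -> int:
        return self.factors[0].shape[1]

    def reconstruct(self) -> np.ndarray:
        a, b, c = self.factors
        return np.einsum("ir,jr,kr->ijk", a, b, c)


def _als_run(x: np.ndarray, rank: int, rng: np.random.Generator,
             max_iter: int, rel_tol: float,
             init: tuple[np.ndarray, ...] | None = None) -> CPDecomposition:
    i, j, k = x.shape
    if init is not None:
        a, b, c = (np.ascontiguousarray(f, dtype=float).copy() for f in init)
    else:
        scale = (x.mean() / rank) ** (1.0 / 3.0) if x.mean() > 0 else 1.0
        a = rng.uniform(0.1, 1.0, (i, rank)) * scale
        b = rng.uniform(0.1, 1.0, (j, rank)) * scale
        c = rng.uniform(0.1, 1.0, (k, rank)) * scale

    x_norm2 = float(np.sum(x * x))

    def resid2_of(fa: np.ndarray, fb: np.ndarray, fc: np.ndarray) -> float:
        rhs = np.einsum("ijk,ir,jr->rk", x, fa, fb)
        gram = (fa.T @ fa) * (fb.T @ fb)
        return max(x_norm2 - 2.0 * float(np.sum(fc * rhs.T))
                   + float(np.sum(gram * (fc.T @ fc))), 0.0)

    trace = []
    prev = np.inf
    converged = False
    n_done = 0
    beta = 0.5   # extrapolation step; adapted multiplicatively on accept/reject
    a_old, b_old, c_old = a, b, c
    for it in range(max_iter):
        a = nnls_gram((b.T @ b) * (c.T @ c), np.einsum("ijk,jr,kr->ri", x, b, c))
        b = nnls_gram((a.T @ a) * (c.T @ c), np.einsum("ijk,ir,kr->rj", x, a, c))
        rhs_c = np.einsum("ijk,ir,jr->rk", x, a, b)
        gram_c = (a.T @ a) * (b.T @ b)
        c = nnls_gram(gram_c, rhs_c)
        # exact residual from the normal-equation pieces of the last update
        resid2 = max(
            x_norm2 - 2.0 * float(np.sum(c * rhs_c.T))
            + float(np.sum(gram_c * (c.T @ c))),
            0.0,
        )
        # line-search extrapolation along the sweep direction; accepted only
        # when it lowers the residual, so the trace stays monotone
        if it > 0 and beta > 0:
            ae = np.clip(a + beta * (a - a_old), 0.0, None)
            be = np.clip(b + beta * (b - b_old), 0.0, None)
            ce = np.clip(c + beta * (c - c_old), 0.0, None)
            resid2_e = resid2_of(ae, be, ce)
            if resid2_e < resid2:
                a_old, b_old, c_old = a, b, c
                a, b, c = ae, be, ce
                resid2 = resid2_e
                beta = min(beta * 1.2, 4.0)
            else:
                a_old, b_old, c_old = a, b, c
                beta = max(beta * 0.6, 0.1)
        else:
            a_old, b_old, c_old = a, b, c
        trace.append(np.sqrt(resid2))
        n_done = it + 1
        if prev - resid2 <= rel_tol * max(resid2, x_norm2 * 1e-16):
            converged = True
            break
        prev = resid2
    resid = trace[-1]
    ev = 1.0 - resid**2 / x_norm2 if x_norm2 > 0 else 0.0
    return CPDecomposition(
        factors=(a, b, c), residual_norm=resid,
        explained_variance=max(0.0, min(1.0, ev)),
        n_iter=n_done, converged=converged,
        residual_trace=np.asarray(trace),
    )


def nn_parafac(x: np.ndarray, rank: int, n_restarts: int = 20,
               max_iter: int = 6000, rel_tol: float = 1e-13,
               seed: int | None = 0,
               init: tuple[np.ndarray, ...] | None = None) -> CPDecomposition:
    """Best-of-N restarts non-negative trilinear decomposition.

    Parameters
    ----------
    x
        Non-negative 3-way array.
    rank
        Number of trilinear components (must not exceed any dimension).
    n_restarts
        Random initialisations; the lowest-residual run wins.  Ignored when
        ``init`` is given (single warm-started run, used by the Monte-Carlo
        refits).
    rel_tol
        Stop when the per-iteration decrease of the squared residual falls
        below this fraction of its value (ALS decreases monotonically, so
        this is a plateau criterion).
    seed
        Seeds the initialisations; identical seeds give identical results.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise InputError(f"expected a 3-way array, got ndim={x.ndim}")
    if not np.all(np.isfinite(x)):
        raise InputError("tensor contains non-finite values")
    if np.all(x == 0):
        raise InputError("tensor is identically zero")
    if not 1 <= rank <= min(x.shape):
        raise InputError(f"rank {rank} incompatible with tensor shape {x.shape}")

    rng = np.random.default_rng(seed)
    if init is not None:
        return _als_run(x, rank, rng, max_iter, rel_tol, init=init)
    best: CPDecomposition | None = None
    for _ in range(max(1, n_restarts)):
        run = _als_run(x, rank, rng, max_iter, rel_tol)
        if best is None or run.residual_norm < best.residual_norm:
            best = run
    assert best is not None
    return best


def factor_congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity (Tucker congruence) between two loading vectors."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def match_components(true_factors: tuple[np.ndarray, ...],
                     est_factors: tuple[np.ndarray, ...]) -> np.ndarray:
    """Greedy permutation matching estimated components to reference ones.

    Components are matched by the product of per-mode congruences; returns
    the column permutation to apply to the estimated factors.
    """
    r = true_factors[0].shape[1]
    score = np.ones((r, r))
    for t, e in zip(true_factors, est_factors):
        for p in range(r):
            for q in range(r):
                score[p, q] *= abs(factor_congruence(t[:, p], e[:, q]))
    perm = np.full(r, -1)
    used: set[int] = set()
    for p in np.argsort(-score.max(axis=1)):
        q = int(np.argmax([score[p, q] if q not in used else -1 for q in range(r)]))
        perm[p] = q
        used.add(q)
    return perm
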