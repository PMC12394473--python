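"""Partial Least Squares Correlation between two variable blocks.

PLSC decomposes the cross-block correlation matrix
R = X'Y / (n - 1) (columns z-scored) by SVD, R = U D V'.  Each latent
dimension i carries a singular value d_i (variance explained
d_i^2 / sum d^2), block saliences (columns of U and V), latent scores
(projections of the standardized blocks onto their saliences) and the
correlation between the paired latent scores.  Dimension significance
comes from a permutation test (rows of X permuted against Y);
salience reliability from bootstrap ratios (salience / bootstrap SE),
with |ratio| > 2 conventionally read as significant.

Contributions are squared saliences; because salience vectors are unit
norm they sum to one within each block and dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import _substream


@dataclass
class PLSCResult:
    singular_values: np.ndarray       # (k,), descending
    variance_explained: np.ndarray    # (k,), sums to 1
    saliences_x: np.ndarray           # (p, k)
    saliences_y: np.ndarray           # (q, k)
    contributions_x: np.ndarray       # (p, k), squared saliences
    contributions_y: np.ndarray       # (q, k)
    latent_x: np.ndarray              # (n, k)
    latent_y: np.ndarray              # (n, k)
    latent_correlation: np.ndarray    # (k,)
    dim_p_values: np.ndarray | None = None
    bootstrap_ratios_x: np.ndarray | None = None
    bootstrap_ratios_y: np.ndarray | None = None


def _standardize(M: np.ndarray, name: str) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        cols = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-variance column(s) {cols} in {name}")
    return (M - M.mean(axis=0)) / sd


def _cross_svd(Xs: np.ndarray, Ys: np.ndarray):
    R = Xs.T @ Ys / (Xs.shape[0] - 1)
    U, d, Vt = np.linalg.svd(R, full_matrices=False)
    return U, d, Vt.T


def _orient(U: np.ndarray, V: np.ndarray):
    """Sign convention: largest-|.| X-salience positive per dimension."""
    for k in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return U, V


def plsc_fit(X: np.ndarray, Y: np.ndarray, standardize: bool = True) -> PLSCResult:
    """Point estimates of the PLSC decomposition.

    ``X`` (n x p) and ``Y`` (n x q) must share rows (subjects) and have
    no missing values; columns are z-scored by default so R is a
    correlation matrix.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with equal row counts")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not supported")
    Xs = _standardize(X, "X") if standardize else X - X.mean(axis=0)
    Ys = _standardize(Y, "Y") if standardize else Y - Y.mean(axis=0)
    U, d, V = _cross_svd(Xs, Ys)
    U, V = _orient(U, V)
    Lx, Ly = Xs @ U, Ys @ V
    k = d.size
    corr = np.empty(k)
    for i in range(k):
        sx, sy = Lx[:, i].std(), Ly[:, i].std()
        corr[i] = (np.corrcoef(Lx[:, i], Ly[:, i])[0, 1]
                   if sx > 0 and sy > 0 else 0.0)
    total = (d ** 2).sum()
    return PLSCResult(
        singular_values=d,
        variance_explained=d ** 2 / total if total > 0 else np.zeros(k),
        saliences_x=U, saliences_y=V,
        contributions_x=U ** 2, contributions_y=V ** 2,
        latent_x=Lx, latent_y=Ly, latent_correlation=corr)


def plsc_permutation(X: np.ndarray, Y: np.ndarray, n_perm: int = 1000,
                     seed: int = 0, standardize: bool = True) -> np.ndarray:
    """Permutation p-value per dimension: rows of X permuted against Y.

    p_i = (1 + #{d_i_perm >= d_i_obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    rng = _substream(seed, "plsc-perm")
    n = X.shape[0]
    Xs = _standardize(X, "X") if standardize else X - X.mean(axis=0)
    Ys = _standardize(Y, "Y") if standardize else Y - Y.mean(axis=0)
    _, d_obs, _ = _cross_svd(Xs, Ys)
    perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Xp = Xs[perm_idx]                               # (B, n, p)
    Rb = np.einsum("bnp,nq->bpq", Xp, Ys) / (n - 1)
    d_perm = np.linalg.svd(Rb, compute_uv=False)    # (B, k) descending
    exceed = (d_perm >= d_obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + n_perm)


def plsc_bootstrap(X: np.ndarray, Y: np.ndarray, n_boot: int = 1000,
                   seed: int = 0, standardize: bool = True):
    """Bootstrap ratios for X and Y saliences.

    Rows are resampled with replacement jointly across the blocks; each
    replicate's saliences are sign-aligned to the original solution
    (dot-product matching per dimension) before the elementwise SE is
    taken.  Replicates drawing a zero-variance column are redrawn (the
    count is returned).  Returns ``(ratios_x, ratios_y, n_redrawn)``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    rng = _substream(seed, "plsc-boot")
    n = X.shape[0]
    fit = plsc_fit(X, Y, standardize=standardize)
    U0, V0 = fit.saliences_x, fit.saliences_y
    k = U0.shape[1]
    Ub = np.empty((n_boot,) + U0.shape)
    Vb = np.empty((n_boot,) + V0.shape)
    redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb, Yb = X[idx], Y[idx]
        if standardize and (np.any(Xb.std(axis=0, ddof=1) == 0)
                            or np.any(Yb.std(axis=0, ddof=1) == 0)):
            redrawn += 1
            continue
        Xs = _standardize(Xb, "X") if standardize else Xb - Xb.mean(axis=0)
        Ys = _standardize(Yb, "Y") if standardize else Yb - Yb.mean(axis=0)
        U, d, V = _cross_svd(Xs, Ys)
        # align to the original solution dimension by dimension
        for j in range(k):
            if U0[:, j] @ U[:, j] + V0[:, j] @ V[:, j] < 0:
                U[:, j] = -U[:, j]
                V[:, j] = -V[:, j]
        Ub[b], Vb[b] = U, V
        b += 1
    se_u = Ub.std(axis=0, ddof=1)
    se_v = Vb.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rx = np.where(se_u > 0, U0 / se_u, np.inf * np.sign(U0))
        ry = np.where(se_v > 0, V0 / se_v, np.inf * np.sign(V0))
    return rx, ry, redrawn


def plsc_analysis(X: np.ndarray, Y: np.ndarray, n_perm: int = 1000,
                  n_boot: int = 1000, seed: int = 0) -> PLSCResult:
    """Full PLSC: fit + dimension permutation test + bootstrap ratios."""
    fit = plsc_fit(X, Y)
    fit.dim_p_values = plsc_permutation(X, Y, n_perm=n_perm, seed=seed)
    rx, ry, _ = plsc_bootstrap(X, Y, n_boot=n_boot, seed=seed)
    fit.bootstrap_ratios_x = rx
    fit.bootstrap_ratios_y = ry
    return fit


def contributions_table(result: PLSCResult, x_names: list[str],
                        y_names: list[str]):
    """Long-format table of contributions and bootstrap ratios per variable."""
    import pandas as pd

    rows = []
    k = result.singular_values.size
    for names, contrib, ratios, block in (
            (x_names, result.contributions_x, result.bootstrap_ratios_x, "X"),
            (y_names, result.contributions_y, result.bootstrap_ratios_y, "Y")):
        for i, name in enumerate(names):
            for dim in range(k):
                t = float(ratios[i, dim]) if ratios is not None else np.nan
                rows.append({"set": block, "item": name, "dimension": dim + 1,
                             "contribution": float(contrib[i, dim]),
                             "bootstrap_ratio": t,
                             "significant": abs(t) > 2 if ratios is not None else False})
    return pd.DataFrame(rows)
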