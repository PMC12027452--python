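"""Classical genomic-prediction baselines: GRM, GBLUP, ridge, REML h2.

The genomic relationship matrix follows VanRaden's first method:
G = Z Z' / (2 * sum_j p_j (1 - p_j)) with Z the dosage matrix centered
by twice the allele frequency of each locus (centered, not
variance-scaled — the printed scaling constant is exactly VanRaden's).
Allele frequencies come from the full panel (training + test jointly),
matching GBLUP's transductive character.

Heritability is estimated by single-component REML: after an
eigendecomposition of G the restricted likelihood is a one-dimensional
function of h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2), maximized by a
grid pass plus golden-section refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "GRM",
    "VarianceComponents",
    "compute_grm",
    "reml_h2",
    "gblup_fit_predict",
    "ridge_fit",
    "GBLUP",
    "GBLUPResults",
    "write_grm",
]


@dataclass
class GRM:
    """Genomic relationship matrix with its construction constants."""

    matrix: np.ndarray
    samples: list
    allele_freq: np.ndarray
    scale: float                    # 2 * sum p_j (1 - p_j)

    def __post_init__(self):
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    loglik: float = np.nan

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def compute_grm(g) -> GRM:
    """VanRaden-method-1 GRM from imputed dosages."""
    if g.signed:
        raise ValueError("compute the GRM from dosages, not signed coding")
    if g.missing.any():
        raise ValueError("impute before computing the GRM")
    if g.n_markers < 1:
        raise ValueError("need at least 1 marker")
    p = g.allele_freq()
    scale = 2.0 * float(np.sum(p * (1.0 - p)))
    if scale == 0.0:
        raise ValueError("all markers monomorphic: GRM scaling constant is zero")
    Z = g.dosages - 2.0 * p[None, :]
    G = (Z @ Z.T) / scale
    G = 0.5 * (G + G.T)
    return GRM(matrix=G, samples=list(g.samples), allele_freq=p, scale=scale)


def _grm_array(G) -> np.ndarray:
    return G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)


def reml_h2(G, y, grid: int = 50, tol: float = 1e-8) -> VarianceComponents:
    """Single-component REML for y = mu + g + e, g ~ N(0, G sigma_g^2).

    Exact via one eigendecomposition of G; the restricted likelihood is
    profiled over the total scale, leaving a 1-D maximization in h2.
    """
    K = _grm_array(G)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 20:
        raise ValueError("REML needs at least 20 samples")
    if K.shape != (n, n):
        raise ValueError(f"GRM shape {K.shape} does not match n={n}")
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-6 * max(1.0, lam.max()):
        raise ValueError("GRM is not positive semidefinite")
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_restricted_ll(h: float) -> float:
        v = h * lam + (1.0 - h)             # variances up to the profiled scale
        v = np.maximum(v, 1e-12)
        w = 1.0 / v
        xwx = np.sum(w * xt * xt)
        beta = np.sum(w * xt * yt) / xwx
        r = yt - beta * xt
        rss = np.sum(w * r * r)
        sigma2 = rss / (n - 1)
        ll = -0.5 * ((n - 1) * np.log(sigma2) + np.sum(np.log(v)) + np.log(xwx) + (n - 1))
        return -ll

    hs = np.linspace(1e-6, 1.0 - 1e-6, grid)
    vals = [neg_restricted_ll(h) for h in hs]
    i = int(np.argmin(vals))
    lo, hi = hs[max(i - 1, 0)], hs[min(i + 1, grid - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res.message}; trace min {min(vals):.4f}")
    h = float(res.x)
    # recover the profiled scale to report absolute components
    v = np.maximum(h * lam + (1.0 - h), 1e-12)
    w = 1.0 / v
    beta = np.sum(w * xt * yt) / np.sum(w * xt * xt)
    sigma2 = float(np.sum(w * (yt - beta * xt) ** 2) / (n - 1))
    return VarianceComponents(sigma2_g=h * sigma2, sigma2_e=(1.0 - h) * sigma2,
                              loglik=-float(res.fun))


def gblup_fit_predict(G, y_train, train_idx, test_idx, vc: VarianceComponents = None) -> np.ndarray:
    """BLUP of test genetic values from the train/test blocks of G.

    yhat_test = mu + sigma_g^2 * G[test, train] V^{-1} (y_train - mu),
    V = sigma_g^2 G[train, train] + sigma_e^2 I, mu the GLS mean.
    Variance components are REML-estimated on the training block when
    not supplied.
    """
    K = _grm_array(G)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if y_train.size != train_idx.size:
        raise ValueError("y_train length must match train_idx")
    if vc is None:
        vc = reml_h2(K[np.ix_(train_idx, train_idx)], y_train)
    Ktt = K[np.ix_(train_idx, train_idx)]
    Kxt = K[np.ix_(test_idx, train_idx)]
    V = vc.sigma2_g * Ktt + vc.sigma2_e * np.eye(train_idx.size)
    try:
        c, low = _chol(V)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular mixed-model system; add a small ridge to the GRM diagonal"
        ) from err
    ones = np.ones(train_idx.size)
    Vi_y = _chol_solve(c, low, y_train)
    Vi_1 = _chol_solve(c, low, ones)
    mu = float(ones @ Vi_y) / float(ones @ Vi_1)
    alpha = _chol_solve(c, low, y_train - mu)
    return mu + vc.sigma2_g * (Kxt @ alpha)


def _chol(V):
    from scipy.linalg import cho_factor

    return cho_factor(V, lower=True), True


def _chol_solve(c, low, b):
    from scipy.linalg import cho_solve

    return cho_solve(c, b)


def ridge_fit(X, y, lam: float, fit_intercept: bool = True):
    """Closed-form ridge: argmin ||y - Xb||^2 + lam ||b||^2.

    Returns ``(beta, intercept, flagged)`` where ``flagged`` is True for
    the minimum-norm fallback (lam = 0 with rank-deficient X).
    """
    if lam < 0:
        raise ValueError("ridge parameter must be nonnegative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if fit_intercept:
        xm, ym = X.mean(axis=0), y.mean()
        Xc, yc = X - xm, y - ym
    else:
        xm, ym = np.zeros(X.shape[1]), 0.0
        Xc, yc = X, y
    n, p = Xc.shape
    flagged = False
    if lam == 0.0:
        if np.linalg.matrix_rank(Xc) < p:
            beta = np.linalg.pinv(Xc) @ yc
            flagged = True
        else:
            beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    else:
        A = Xc.T @ Xc + lam * np.eye(p)
        beta = np.linalg.solve(A, Xc.T @ yc)
    intercept = ym - xm @ beta if fit_intercept else 0.0
    return beta, float(intercept), flagged


def ridge_gcv_lambda(X, y, grid=None):
    """Pick lambda by SVD-based generalized cross-validation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    uy = U.T @ yc
    n = y.size
    if grid is None:
        base = float(np.mean(s**2)) if s.size else 1.0
        grid = base * np.logspace(-4, 4, 25)
    best, best_lam = np.inf, grid[0]
    yc2 = float(yc @ yc)
    for lam in grid:
        d = s**2 / (s**2 + lam)
        rss = yc2 - float((uy * d * (2 - d)) @ uy)
        edf = float(d.sum())
        gcv = rss / (n * (1 - edf / n) ** 2)
        if gcv < best:
            best, best_lam = gcv, float(lam)
    return best_lam


# ---------------------------------------------------------------------------
# model-object veneer


class GBLUP:
    """GBLUP as a model object: built from a panel and phenotypes.

    Transductive: the GRM spans training *and* prediction samples, so
    all genotypes must be present at construction time.
    """

    def __init__(self, genotypes, phenotypes, trait=None):
        import pandas as pd

        self.grm = compute_grm(genotypes)
        if isinstance(phenotypes, pd.DataFrame):
            col = trait if trait is not None else phenotypes.columns[0]
            self.y = phenotypes[col].reindex(genotypes.samples).to_numpy(dtype=float)
        else:
            self.y = np.asarray(phenotypes, dtype=float)
        self.samples = list(genotypes.samples)

    def fit(self, train_idx=None) -> "GBLUPResults":
        n = len(self.samples)
        train_idx = np.arange(n) if train_idx is None else np.asarray(train_idx, dtype=int)
        vc = reml_h2(self.grm.matrix[np.ix_(train_idx, train_idx)], self.y[train_idx])
        return GBLUPResults(model=self, train_idx=train_idx, vc=vc)


@dataclass
class GBLUPResults:
    model: GBLUP
    train_idx: np.ndarray
    vc: VarianceComponents

    def predict(self, test_idx) -> np.ndarray:
        return gblup_fit_predict(self.model.grm, self.model.y[self.train_idx],
                                 self.train_idx, np.asarray(test_idx, dtype=int), vc=self.vc)

    def summary(self) -> str:
        return (
            "GBLUP results\n"
            "=============\n"
            f"training samples   {self.train_idx.size}\n"
            f"sigma2_g           {self.vc.sigma2_g:.5f}\n"
            f"sigma2_e           {self.vc.sigma2_e:.5f}\n"
            f"h2                 {self.vc.h2:.4f}\n"
            f"restricted loglik  {self.vc.loglik:.3f}"
        )


def write_grm(G: GRM, path) -> None:
    """Delimited symmetric matrix with a sample-id header."""
    import pandas as pd

    pd.DataFrame(G.matrix, index=G.samples, columns=G.samples).to_csv(path)
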