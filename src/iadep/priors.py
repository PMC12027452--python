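"""Per-marker association priors: the two p-value channels of the SNP embedding.

Two scans are provided, both restricted to an explicit sample subset so
cross-validation can keep test phenotypes out of the priors:

* :func:`gwas_scan` — single-marker additive association.  Default is
  ordinary least squares (two-sided t-test on the slope of phenotype on
  signed dosage).  ``method="mixed"`` first estimates a single genetic
  variance component on a genomic relationship matrix by REML, rotates
  phenotype and genotypes into the GRM eigenbasis and runs the same
  per-marker test under the implied generalized-least-squares weights.

* :func:`lit_scan` — a latent-interaction (variance-heterogeneity)
  scan.  Unmodelled interactions involving a marker inflate the
  residual variance of some genotype classes relative to others; the
  scan fits the marker's own additive effect, squares the residuals and
  runs a one-way ANOVA of the squared residuals across genotype
  classes.  This is a desk-scale vQTL test standing in for external
  kernel-based latent-interaction software; externally computed tables
  can be imported instead via :func:`import_priors`.

p-values are floored at 1e-300 (so -log10 p is capped at 300).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PriorTable",
    "P_FLOOR",
    "gwas_scan",
    "lit_scan",
    "import_priors",
    "priors_for_fold",
    "write_priors",
    "read_priors",
]

P_FLOOR = 1e-300


@dataclass
class PriorTable:
    """Per-marker GWAS and latent-interaction p-values with provenance.

    ``provenance`` records which samples the scans saw, so that
    cross-validation can assert the absence of test-phenotype leakage.
    """

    markers: list
    gwas_p: np.ndarray
    lit_p: np.ndarray
    gwas_degenerate: np.ndarray = None
    lit_degenerate: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gwas_p = np.asarray(self.gwas_p, dtype=float)
        self.lit_p = np.asarray(self.lit_p, dtype=float)
        m = len(self.markers)
        if self.gwas_p.shape != (m,) or self.lit_p.shape != (m,):
            raise ValueError("p-value arrays must be one value per marker")
        for arr, name in ((self.gwas_p, "gwas_p"), (self.lit_p, "lit_p")):
            if np.any((arr <= 0) | (arr > 1) | ~np.isfinite(arr)):
                raise ValueError(f"{name} values must lie in (0, 1]")
        if self.gwas_degenerate is None:
            self.gwas_degenerate = np.zeros(m, dtype=bool)
        if self.lit_degenerate is None:
            self.lit_degenerate = np.zeros(m, dtype=bool)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_indices(self) -> np.ndarray:
        return np.asarray(self.provenance.get("sample_indices", []), dtype=int)

    def assert_no_leakage(self, test_indices) -> None:
        """Raise if any scan sample is also a test sample."""
        used = set(self.sample_indices().tolist())
        overlap = used & set(np.asarray(test_indices, dtype=int).tolist())
        if overlap:
            raise AssertionError(
                f"prior table leaks {len(overlap)} test sample(s): {sorted(overlap)[:5]}..."
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.markers, "gwas_p": self.gwas_p, "lit_p": self.lit_p}
        )


def _signed_matrix(g) -> np.ndarray:
    if g.missing.any():
        raise ValueError("impute genotypes before scanning")
    return g.dosages - 1.0 if not g.signed else g.dosages


def _trait_vector(g, y, trait=None) -> np.ndarray:
    if isinstance(y, pd.DataFrame):
        col = trait if trait is not None else y.columns[0]
        y = y[col].reindex(g.samples)
        if y.isna().any():
            raise ValueError("phenotype missing for some genotype samples")
        return y.to_numpy(dtype=float)
    return np.asarray(y, dtype=float)


def _ols_slope_p(X: np.ndarray, yv: np.ndarray):
    """Two-sided slope t-test p per column of X (vectorized OLS)."""
    n = yv.shape[0]
    xc = X - X.mean(axis=0)
    yc = yv - yv.mean()
    sx = xc.std(axis=0)
    sy = yc.std()
    degenerate = (sx == 0) | (sy == 0)
    sx_safe = np.where(degenerate, 1.0, sx)
    r = (xc * yc[:, None]).mean(axis=0) / (sx_safe * (sy if sy > 0 else 1.0))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(degenerate, 1.0, p)
    return np.clip(p, P_FLOOR, 1.0), degenerate


def gwas_scan(g, y, sample_subset=None, trait=None, method="ols", grm=None) -> PriorTable:
    """Single-marker additive association scan on a sample subset.

    Returns a :class:`PriorTable` whose ``lit_p`` channel is all ones
    (fill in with :func:`lit_scan` or use :func:`priors_for_fold`).
    """
    signed = _signed_matrix(g)
    yv = _trait_vector(g, y, trait)
    idx = np.arange(g.n_samples) if sample_subset is None else np.asarray(sample_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("empty sample subset")
    Xs, ys = signed[idx], yv[idx]

    if method == "mixed":
        Xs, ys = _grm_rotate(g, Xs, ys, idx, grm)
    elif method != "ols":
        raise ValueError(f"unknown gwas method {method!r}")

    p, degen = _ols_slope_p(Xs, ys)
    return PriorTable(
        markers=list(g.markers),
        gwas_p=p,
        lit_p=np.ones(g.n_markers),
        gwas_degenerate=degen,
        provenance=_provenance(idx, f"gwas_{method}", trait),
    )


def _grm_rotate(g, Xs, ys, idx, grm):
    """EMMA-style whitening: rotate into the GRM eigenbasis and reweight."""
    from .baselines import compute_grm, reml_h2

    if grm is None:
        grm = compute_grm(g)
    K = grm.matrix[np.ix_(idx, idx)]
    vc = reml_h2(K, ys)
    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    w = vc.h2 * lam + (1.0 - vc.h2)          # variance of each rotated residual
    scale = 1.0 / np.sqrt(np.maximum(w, 1e-12))
    Xw = (U.T @ Xs) * scale[:, None]
    yw = (U.T @ ys) * scale
    # the whitened intercept is no longer constant: project it out of both
    x0 = (U.T @ np.ones(idx.size)) * scale
    x0 /= np.linalg.norm(x0)
    Xw -= x0[:, None] * (x0 @ Xw)[None, :]
    yw -= x0 * (x0 @ yw)
    return Xw, yw


def lit_scan(g, y, sample_subset=None, trait=None) -> PriorTable:
    """Variance-heterogeneity scan: ANOVA of squared residuals across
    genotype classes (latent-interaction stand-in).

    Per marker the additive effect is removed by OLS on the signed
    dosage; squared residuals are then compared across the genotype
    classes present (an F-test with classes-1 numerator df).  Markers
    with a single class present get p = 1 and a degenerate flag.
    """
    signed = _signed_matrix(g)
    yv = _trait_vector(g, y, trait)
    idx = np.arange(g.n_samples) if sample_subset is None else np.asarray(sample_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("empty sample subset")
    X, ys = signed[idx], yv[idx]
    n, m = X.shape

    # residuals from the marker's own additive fit (vectorized per marker)
    xc = X - X.mean(axis=0)
    yc = ys - ys.mean()
    denom = (xc**2).sum(axis=0)
    beta = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / np.maximum(denom, 1e-300), 0.0)
    resid = yc[:, None] - xc * beta[None, :]
    z = resid**2

    # one-way ANOVA of z across genotype classes {-1, 0, +1}, per marker
    p = np.ones(m)
    degen = np.zeros(m, dtype=bool)
    counts = np.stack([(X == v).sum(axis=0) for v in (-1.0, 0.0, 1.0)])      # 3 x m
    sums = np.stack([np.where(X == v, z, 0.0).sum(axis=0) for v in (-1.0, 0.0, 1.0)])
    k = (counts > 0).sum(axis=0)
    degen = k < 2
    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        grand = z.mean(axis=0)
        ss_between = (counts * (means - grand[None, :]) ** 2).sum(axis=0)
        ss_total = ((z - grand[None, :]) ** 2).sum(axis=0)
        ss_within = np.maximum(ss_total - ss_between, 0.0)
        df1 = np.maximum(k - 1, 1)
        df2 = np.maximum(n - k, 1)
        F = (ss_between / df1) / np.maximum(ss_within / df2, 1e-300)
    valid = (~degen) & (ss_within > 0)
    p_valid = stats.f.sf(F[valid], df1[valid], df2[valid])
    p[valid] = p_valid
    p = np.clip(p, P_FLOOR, 1.0)
    p[degen] = 1.0
    return PriorTable(
        markers=list(g.markers),
        gwas_p=np.ones(m),
        lit_p=p,
        lit_degenerate=degen,
        provenance=_provenance(idx, "lit_vqtl", trait),
    )


def compute_priors(g, y, sample_subset=None, trait=None, gwas_method="ols") -> PriorTable:
    """Run both scans on the same subset and merge into one table."""
    gw = gwas_scan(g, y, sample_subset, trait=trait, method=gwas_method)
    li = lit_scan(g, y, sample_subset, trait=trait)
    prov = dict(gw.provenance)
    prov["methods"] = [gw.provenance["method"], li.provenance["method"]]
    return PriorTable(
        markers=gw.markers,
        gwas_p=gw.gwas_p,
        lit_p=li.lit_p,
        gwas_degenerate=gw.gwas_degenerate,
        lit_degenerate=li.lit_degenerate,
        provenance=prov,
    )


def priors_for_fold(g, y, fold_plan, fold_index: int, trait=None, gwas_method="ols") -> PriorTable:
    """Both scans restricted to the training samples of one CV fold."""
    train_idx = fold_plan.train_indices(fold_index)
    tab = compute_priors(g, y, train_idx, trait=trait, gwas_method=gwas_method)
    tab.provenance["fold_index"] = int(fold_index)
    tab.provenance["k"] = int(fold_plan.k)
    tab.assert_no_leakage(fold_plan.test_indices(fold_index))
    return tab


def import_priors(path, markers) -> PriorTable:
    """Ingest an externally computed prior table (marker, gwas_p, lit_p).

    All requested markers must be present; p-values must lie in (0, 1]
    (exact zeros are rejected — clip to the 1e-300 floor upstream).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"marker", "gwas_p", "lit_p"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    df = df.set_index(df["marker"].astype(str))
    missing = [m for m in markers if str(m) not in df.index]
    if missing:
        raise ValueError(f"{path}: prior table missing markers: {missing}")
    sub = df.loc[[str(m) for m in markers]]
    for col in ("gwas_p", "lit_p"):
        vals = sub[col].to_numpy(dtype=float)
        if np.any((vals <= 0) | (vals > 1)):
            raise ValueError(
                f"{path}: {col} outside (0, 1]; p=0 must be clipped to the "
                f"{P_FLOOR:g} floor before import"
            )
    return PriorTable(
        markers=list(markers),
        gwas_p=sub["gwas_p"].to_numpy(dtype=float),
        lit_p=sub["lit_p"].to_numpy(dtype=float),
        provenance={"method": "external", "source": str(path), "sample_indices": []},
    )


def write_priors(tab: PriorTable, path) -> None:
    tab.to_frame().to_csv(path, index=False)
    sidecar = str(path) + ".provenance.json"
    prov = dict(tab.provenance)
    prov["sample_indices"] = [int(i) for i in tab.sample_indices()]
    with open(sidecar, "w") as fh:
        json.dump(prov, fh, indent=1)


def read_priors(path, markers) -> PriorTable:
    tab = import_priors(path, markers)
    try:
        with open(str(path) + ".provenance.json") as fh:
            tab.provenance = json.load(fh)
    except FileNotFoundError:
        pass
    return tab


def _provenance(idx: np.ndarray, method: str, trait) -> dict:
    idx = np.asarray(idx, dtype=int)
    digest = hashlib.sha256(idx.tobytes()).hexdigest()[:16]
    return {
        "sample_indices": idx.tolist(),
        "indices_sha256": digest,
        "method": method,
        "trait": trait,
        "n_samples": int(idx.size),
    }
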