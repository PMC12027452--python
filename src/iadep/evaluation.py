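"""Cross-validation machinery, accuracy metrics and the comparison
experiments (ablation encodings, prior-based feature selection, CV
granularity).

Two accuracy summaries are reported for every cross-validation run:

* scheme 1 — the Pearson correlation between observed and predicted
  phenotype on each test fold; mean and standard error (sd of the fold
  values divided by sqrt(k)) over folds;
* scheme 2 — a single pooled correlation over the concatenated
  out-of-fold predictions of all samples.

For the deep model, association priors are recomputed inside every fold
from the training samples only, and the prior table's provenance is
asserted against the test fold — leakage of test phenotypes into the
embedding is a hard error, never a silent degradation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import GRM, compute_grm, gblup_fit_predict, reml_h2, ridge_fit, ridge_gcv_lambda
from .embedding import embed_matrix
from .network import IADEP, ModelConfig
from .priors import PriorTable, priors_for_fold

__all__ = [
    "FoldPlan",
    "CVResult",
    "make_folds",
    "pcc",
    "cross_validate",
    "select_features",
    "run_ablation",
    "compare_cv_granularity",
    "UndefinedCorrelationError",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested on a constant vector."""


@dataclass
class FoldPlan:
    """Deterministic k-fold partition of n samples."""

    n_samples: int
    k: int
    seed: int
    assignment: np.ndarray  # fold id per sample

    def test_indices(self, fold_index: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold_index)

    def train_indices(self, fold_index: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold_index)

    def folds(self):
        for f in range(self.k):
            yield f, self.train_indices(f), self.test_indices(f)


def make_folds(n: int, k: int, seed: int = 0) -> FoldPlan:
    """Random k-fold partition; fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = f
    return FoldPlan(n_samples=n, k=k, seed=seed, assignment=assignment)


def pcc(x, y) -> float:
    """Pearson correlation; errors on constant input instead of NaN."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CVResult:
    method: str
    fold_pccs: list
    scheme1_mean: float
    scheme1_se: float
    scheme1_sd: float
    scheme2_pcc: float
    predictions: pd.DataFrame    # sample, fold, observed, predicted
    encoding: str = None

    def summary(self) -> str:
        return (
            f"{self.method}"
            + (f" [{self.encoding}]" if self.encoding else "")
            + f": scheme-1 PCC {self.scheme1_mean:.4f} +/- {self.scheme1_se:.4f} (SE)"
            f" / {self.scheme1_sd:.4f} (SD); scheme-2 pooled PCC {self.scheme2_pcc:.4f}"
        )


def _trait_vector(genotypes, phenotypes, trait):
    if isinstance(phenotypes, pd.DataFrame):
        col = trait if trait is not None else phenotypes.columns[0]
        y = phenotypes[col].reindex(genotypes.samples)
        if y.isna().any():
            raise ValueError("phenotype missing for some genotype samples")
        return y.to_numpy(dtype=float)
    return np.asarray(phenotypes, dtype=float)


def cross_validate(
    method: str,
    genotypes,
    phenotypes,
    fold_plan: FoldPlan,
    trait: str = None,
    model_config: ModelConfig = None,
    encoding: str = "embedding",
    omics=None,
    ridge_lambda=None,
    gwas_method: str = "ols",
) -> CVResult:
    """Leakage-safe k-fold cross-validation of one method.

    ``method`` is one of ``iadep``, ``gblup``, ``ridge``.  For iadep the
    GWAS/LIT priors are recomputed per fold on the training samples only.
    """
    if method not in ("iadep", "gblup", "ridge"):
        raise ValueError(f"unknown method {method!r}")
    y = _trait_vector(genotypes, phenotypes, trait)
    n = genotypes.n_samples
    if fold_plan.n_samples != n:
        raise ValueError("fold plan size does not match panel")
    signed = genotypes.dosages - 1.0 if not genotypes.signed else genotypes.dosages
    om = None
    if omics is not None:
        om = omics.reindex(genotypes.samples).to_numpy(dtype=float) if isinstance(
            omics, pd.DataFrame) else np.asarray(omics, dtype=float)

    grm = compute_grm(genotypes) if method == "gblup" else None
    preds = np.full(n, np.nan)
    fold_ids = np.full(n, -1)
    fold_pccs = []
    for f, train_idx, test_idx in fold_plan.folds():
        if method == "gblup":
            vc = reml_h2(grm.matrix[np.ix_(train_idx, train_idx)], y[train_idx])
            yhat = gblup_fit_predict(grm, y[train_idx], train_idx, test_idx, vc=vc)
        elif method == "ridge":
            lam = ridge_lambda
            if lam is None:
                lam = ridge_gcv_lambda(signed[train_idx], y[train_idx])
            beta, icept, _ = ridge_fit(signed[train_idx], y[train_idx], lam)
            yhat = signed[test_idx] @ beta + icept
        else:
            priors = priors_for_fold(genotypes, y, fold_plan, f, gwas_method=gwas_method)
            priors.assert_no_leakage(test_idx)
            emb = embed_matrix(genotypes, priors, encoding=encoding)
            emb_train = _subset_embedded(emb, train_idx)
            cfg = model_config if model_config is not None else ModelConfig()
            model = IADEP(
                y[train_idx], emb_train, signed[train_idx],
                omics=None if om is None else om[train_idx],
                priors=priors, config=cfg,
            )
            res = model.fit()
            emb_test = _subset_embedded(emb, test_idx)
            yhat = res.predict(embedded=emb_test, raw_signed=signed[test_idx],
                               omics=None if om is None else om[test_idx])
        preds[test_idx] = yhat
        fold_ids[test_idx] = f
        fold_pccs.append(pcc(y[test_idx], yhat))

    assert not np.isnan(preds).any(), "every sample must be predicted exactly once"
    fold_pccs = [float(v) for v in fold_pccs]
    sd = float(np.std(fold_pccs, ddof=1)) if len(fold_pccs) > 1 else 0.0
    table = pd.DataFrame({
        "sample": genotypes.samples,
        "fold": fold_ids,
        "observed": y,
        "predicted": preds,
    })
    return CVResult(
        method=method,
        fold_pccs=fold_pccs,
        scheme1_mean=float(np.mean(fold_pccs)),
        scheme1_se=sd / math.sqrt(len(fold_pccs)),
        scheme1_sd=sd,
        scheme2_pcc=pcc(y, preds),
        predictions=table,
        encoding=encoding if method == "iadep" else None,
    )


def _subset_embedded(emb, idx):
    from .embedding import EmbeddedGenotypes

    return EmbeddedGenotypes(
        values=emb.values[idx],
        encoding=emb.encoding,
        markers=list(emb.markers),
        samples=[emb.samples[i] for i in idx],
    )


def select_features(priors: PriorTable, pct: float) -> list:
    """Union of the top ``pct`` % markers by GWAS p and by LIT p.

    Ranking is by ascending p-value with ties broken by marker order
    (stable sort), so selections are deterministic and monotone in pct.
    """
    if not 0.0 < pct <= 100.0:
        raise ValueError("pct must be in (0, 100]")
    m = priors.n_markers
    n_top = max(1, math.ceil(pct / 100.0 * m))
    top_g = np.argsort(priors.gwas_p, kind="stable")[:n_top]
    top_l = np.argsort(priors.lit_p, kind="stable")[:n_top]
    keep = sorted(set(top_g.tolist()) | set(top_l.tolist()))
    return [priors.markers[i] for i in keep]


def run_ablation(
    genotypes,
    phenotypes,
    fold_plan: FoldPlan,
    trait: str = None,
    model_config: ModelConfig = None,
    encodings=("embedding", "one_hot", "raw"),
) -> dict:
    """Cross-validate the network under each SNP encoding on identical
    folds and seeds; returns ``{encoding: CVResult}``."""
    results = {}
    for enc in encodings:
        results[enc] = cross_validate(
            "iadep", genotypes, phenotypes, fold_plan, trait=trait,
            model_config=model_config, encoding=enc,
        )
        assert np.array_equal(results[enc].predictions["fold"].to_numpy(),
                              fold_plan.assignment), "all encodings must share one fold plan"
    return results


def ablation_table(results: dict) -> pd.DataFrame:
    rows = [
        {
            "encoding": enc,
            "scheme1_mean": r.scheme1_mean,
            "scheme1_se": r.scheme1_se,
            "scheme1_sd": r.scheme1_sd,
            "scheme2_pcc": r.scheme2_pcc,
        }
        for enc, r in results.items()
    ]
    return pd.DataFrame(rows).set_index("encoding")


def compare_cv_granularity(
    genotypes,
    phenotypes,
    k_small: int,
    k_large: int,
    seed: int = 0,
    trait: str = None,
    model_config: ModelConfig = None,
    methods=("gblup", "iadep"),
) -> dict:
    """Pooled (scheme-2) PCC of each method at both fold counts.

    A transductive method (GBLUP sees all genotypes through the GRM)
    should move little between fold counts; an inductive learner gains
    from the larger training fraction at high k.
    """
    n = genotypes.n_samples
    if k_large > n:
        raise ValueError(f"k_large={k_large} exceeds n={n}")
    report = {"k_small": k_small, "k_large": k_large, "methods": {}}
    for method in methods:
        per_k = {}
        for k in (k_small, k_large):
            plan = make_folds(n, k, seed)
            res = cross_validate(method, genotypes, phenotypes, plan, trait=trait,
                                 model_config=model_config)
            assert len(res.predictions) == n
            per_k[k] = res.scheme2_pcc
        report["methods"][method] = {
            "pcc_small": per_k[k_small],
            "pcc_large": per_k[k_large],
            "delta": per_k[k_large] - per_k[k_small],
        }
    return report
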