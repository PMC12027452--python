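"""Synthetic genotype panels, quantitative traits and a correlated omics layer.

The trait generator follows the classical decomposition of the genotypic
value G = A + D + I: a sum of per-locus additive effects, within-locus
dominance deviations, and between-locus (epistatic) interaction
deviations.  Phenotype is y = G + e with Gaussian noise scaled so that
var(G)/var(y) hits the target heritability in expectation.

Linkage disequilibrium is emulated with a copy-with-mutation scheme:
within a block, each haplotype allele copies the previous marker's
allele and mutates to an independent draw with a small probability,
giving tunable adjacent-marker correlation; blocks are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix

__all__ = [
    "TraitConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_omics",
    "write_truth",
]


@dataclass
class TraitConfig:
    """Genetic architecture of a simulated trait.

    Parameters
    ----------
    n_qtl_additive, n_qtl_dominance, n_epistatic_pairs
        Number of causal loci per effect class.
    h2_target
        Target fraction of phenotypic variance that is genetic (broad
        sense: all of A, D, I count), in [0, 1].
    seed
        Seed for effect draws and noise.
    """

    n_qtl_additive: int = 50
    n_qtl_dominance: int = 0
    n_epistatic_pairs: int = 0
    h2_target: float = 0.5
    seed: int = 0

    def validate(self, n_markers: int) -> None:
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")
        for name in ("n_qtl_additive", "n_qtl_dominance"):
            if getattr(self, name) > n_markers:
                raise ValueError(f"{name} exceeds marker count {n_markers}")
        if 2 * self.n_epistatic_pairs > n_markers:
            raise ValueError("not enough markers for the requested epistatic pairs")
        total = self.n_qtl_additive + self.n_qtl_dominance + self.n_epistatic_pairs
        if total == 0 and self.h2_target > 0:
            raise ValueError("h2_target > 0 requires at least one causal locus")


@dataclass
class SimTruth:
    """Ground truth of one simulated trait."""

    genetic_value: np.ndarray       # G per sample
    additive: np.ndarray            # A
    dominance: np.ndarray           # D
    epistatic: np.ndarray           # I
    additive_qtl: list              # (marker index, effect)
    dominance_qtl: list
    epistatic_pairs: list           # (i, j, effect)
    realized_h2: float              # var(G)/var(y) on this sample
    config: TraitConfig = None

    @property
    def n_samples(self) -> int:
        return self.genetic_value.shape[0]


def simulate_genotypes(
    n_samples: int,
    n_markers: int,
    maf_range=(0.05, 0.5),
    ld_block_size: int = 1,
    seed: int = 0,
    mutation_rate: float = 0.1,
) -> GenotypeMatrix:
    """Draw a biallelic SNP panel with block-local LD.

    Each marker's population allele frequency is uniform on
    ``maf_range``.  Two haplotypes per sample; within an LD block each
    haplotype copies its left neighbour and re-draws with probability
    ``mutation_rate``, so adjacent-marker r^2 decays with the rate.
    """
    if n_samples < 2 or n_markers < 2:
        raise ValueError("need at least 2 samples and 2 markers")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=n_markers)
    hap = np.empty((2, n_samples, n_markers), dtype=np.int8)
    for m in range(n_markers):
        fresh = rng.random((2, n_samples)) < freqs[m]
        if m % ld_block_size == 0:
            hap[:, :, m] = fresh
        else:
            mutate = rng.random((2, n_samples)) < mutation_rate
            hap[:, :, m] = np.where(mutate, fresh, hap[:, :, m - 1])
    dosages = hap.sum(axis=0).astype(float)
    return GenotypeMatrix(
        samples=[f"S{i:05d}" for i in range(n_samples)],
        markers=[f"M{j:05d}" for j in range(n_markers)],
        dosages=dosages,
    )


def _components(signed: np.ndarray, cfg: TraitConfig, rng: np.random.Generator):
    """Pick causal loci and raw (unscaled-noise) genetic components."""
    n, m = signed.shape
    het = (signed == 0).astype(float)

    add_idx = rng.choice(m, size=cfg.n_qtl_additive, replace=False)
    dom_idx = rng.choice(m, size=cfg.n_qtl_dominance, replace=False)
    pair_flat = rng.choice(m, size=2 * cfg.n_epistatic_pairs, replace=False)
    pairs = pair_flat.reshape(-1, 2)

    a_eff = rng.standard_normal(cfg.n_qtl_additive)
    d_eff = rng.standard_normal(cfg.n_qtl_dominance)
    i_eff = rng.standard_normal(cfg.n_epistatic_pairs)

    A = signed[:, add_idx] @ a_eff if cfg.n_qtl_additive else np.zeros(n)
    D = het[:, dom_idx] @ d_eff if cfg.n_qtl_dominance else np.zeros(n)
    if cfg.n_epistatic_pairs:
        I = (signed[:, pairs[:, 0]] * signed[:, pairs[:, 1]]) @ i_eff
    else:
        I = np.zeros(n)
    return A, D, I, add_idx, a_eff, dom_idx, d_eff, pairs, i_eff


def simulate_trait(g: GenotypeMatrix, cfg: TraitConfig):
    """Simulate a phenotype on ``g`` under ``cfg``.

    Returns ``(phenotypes, truth)`` where phenotypes is a one-column
    DataFrame (trait name ``y``) indexed by sample id.
    """
    cfg.validate(g.n_markers)
    if g.missing.any():
        raise ValueError("impute genotypes before simulating a trait")
    signed = g.dosages - 1.0 if not g.signed else g.dosages
    rng = np.random.default_rng(cfg.seed)

    A, D, I, add_idx, a_eff, dom_idx, d_eff, pairs, i_eff = _components(signed, cfg, rng)
    G = A + D + I
    var_g = float(np.var(G))
    if cfg.h2_target > 0 and var_g == 0.0:
        raise ValueError("zero genetic variance: cannot hit a positive h2_target")

    if cfg.h2_target >= 1.0:
        noise = np.zeros(g.n_samples)
    elif cfg.h2_target == 0.0:
        # no genetic signal: phenotype is pure noise
        G = np.zeros_like(G)
        A = D = I = np.zeros_like(G)
        var_g = 0.0
        noise = rng.standard_normal(g.n_samples)
    else:
        sd_e = np.sqrt(var_g * (1.0 - cfg.h2_target) / cfg.h2_target)
        noise = rng.standard_normal(g.n_samples) * sd_e
    y = G + noise
    var_y = float(np.var(y))
    realized = var_g / var_y if var_y > 0 else 0.0

    pheno = pd.DataFrame({"y": y}, index=pd.Index(g.samples, name="sample"))
    truth = SimTruth(
        genetic_value=G,
        additive=A,
        dominance=D,
        epistatic=I,
        additive_qtl=[(int(i), float(e)) for i, e in zip(add_idx, a_eff)],
        dominance_qtl=[(int(i), float(e)) for i, e in zip(dom_idx, d_eff)],
        epistatic_pairs=[(int(i), int(j), float(e)) for (i, j), e in zip(pairs, i_eff)],
        realized_h2=float(realized),
        config=cfg,
    )
    return pheno, truth


def simulate_omics(
    truth: SimTruth,
    n_features: int = 100,
    signal_fraction: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    sample_ids=None,
) -> pd.DataFrame:
    """A secondary omics layer (e.g. metabolite intensities).

    A ``signal_fraction`` of features are affine functions of the
    genetic value G plus Gaussian noise of sd ``noise_sd``; the rest are
    pure noise.  Mimics an intermediate molecular layer sitting between
    genome and phenotype.
    """
    if not 0.0 <= signal_fraction <= 1.0:
        raise ValueError("signal_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = truth.n_samples
    n_signal = int(round(signal_fraction * n_features))
    G = truth.genetic_value
    sd_g = G.std() if G.std() > 0 else 1.0
    feats = np.empty((n, n_features))
    slopes = rng.uniform(0.5, 1.5, size=n_signal) * rng.choice([-1.0, 1.0], size=n_signal)
    feats[:, :n_signal] = (G[:, None] / sd_g) * slopes[None, :]
    feats[:, :n_signal] += rng.standard_normal((n, n_signal)) * noise_sd
    feats[:, n_signal:] = rng.standard_normal((n, n_features - n_signal))
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n)]
    return pd.DataFrame(
        feats,
        index=pd.Index(sample_ids, name="sample"),
        columns=[f"F{k:05d}" for k in range(n_features)],
    )


def write_truth(truth: SimTruth, markers: list, path) -> None:
    """Write causal loci, effects and per-sample components to a TSV."""
    rows = []
    for i, e in truth.additive_qtl:
        rows.append(("additive", markers[i], "", e))
    for i, e in truth.dominance_qtl:
        rows.append(("dominance", markers[i], "", e))
    for i, j, e in truth.epistatic_pairs:
        rows.append(("epistatic", markers[i], markers[j], e))
    with open(path, "w") as fh:
        fh.write(f"# realized_h2\t{truth.realized_h2:.6f}\n")
        fh.write("kind\tmarker\tmarker2\teffect\n")
        for kind, m1, m2, e in rows:
            fh.write(f"{kind}\t{m1}\t{m2}\t{e:.8g}\n")
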