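"""Genotype, phenotype, omics and prior-table I/O plus basic QC.

Genotypes are held as allele dosages (count of the alternate allele,
``{0, 1, 2}``) with an explicit missingness mask.  Downstream code works
on the *signed* coding ``{-1, 0, +1}`` (dosage minus one), in which the
heterozygote occupies state 0 — the state whose three-channel embedding
carries the dominance indicator.

Supported on-disk formats
-------------------------
``matrix``
    Delimited sample x marker table; first row marker ids, first column
    sample ids; cells in ``{0, 1, 2}`` or ``NA`` for missing.  Comma or
    tab, autodetected.
``raw``
    PLINK ``--recode A``-style dosage table: header ``FID IID PAT MAT
    SEX PHENOTYPE <marker> ...``, whitespace-delimited, ``NA`` missing.
``vcf``
    VCF with GT genotypes; biallelic SNP records only (multi-allelic
    records are skipped with a warning and counted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_omics",
    "write_omics",
    "impute_missing",
    "filter_maf",
    "to_signed",
    "align_samples",
    "read_config",
    "GenotypeParseError",
]

MISSING_TOKEN = "NA"


class GenotypeParseError(ValueError):
    """Raised when a genotype file does not parse as the declared format."""


@dataclass
class GenotypeMatrix:
    """Sample x marker dosage matrix with marker metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers.
    markers : list of str
        Ordered marker identifiers.
    dosages : ndarray of shape (n_samples, n_markers)
        Alternate-allele dosages in {0, 1, 2}; undefined where missing.
    missing : ndarray of bool, same shape
        True where the call is missing.
    signed : bool
        Whether :func:`to_signed` has been applied (values in {-1,0,+1}).
    chrom, pos : optional per-marker metadata (parallel to ``markers``).
    """

    samples: list
    markers: list
    dosages: np.ndarray
    missing: np.ndarray = None
    signed: bool = False
    chrom: list = None
    pos: list = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        if self.missing is None:
            self.missing = np.zeros(self.dosages.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.dosages.shape:
            raise ValueError("missing mask shape mismatch")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample count mismatch")
        if len(self.markers) != self.dosages.shape[1]:
            raise ValueError("marker count mismatch")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=list(self.markers),
            dosages=self.dosages.copy(),
            missing=self.missing.copy(),
            signed=self.signed,
            chrom=list(self.chrom) if self.chrom is not None else None,
            pos=list(self.pos) if self.pos is not None else None,
        )

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, over non-missing calls."""
        if self.signed:
            raise ValueError("allele frequencies are defined on dosages, not signed values")
        d = np.ma.masked_array(self.dosages, mask=self.missing)
        return np.asarray(d.mean(axis=0)) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# readers / writers


def _detect_delim(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def _read_matrix(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise GenotypeParseError(f"{path}: empty file (line 1)")
    delim = _detect_delim(header)
    df = pd.read_csv(path, sep=delim, index_col=0, na_values=[MISSING_TOKEN])
    vals = df.to_numpy(dtype=float)
    missing = np.isnan(vals)
    ok = missing | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise GenotypeParseError(
            f"{path}: line {i + 2}: dosage {vals[i, j]!r} not in {{0,1,2,NA}}"
        )
    vals = np.where(missing, 0.0, vals)
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        markers=[str(m) for m in df.columns],
        dosages=vals,
        missing=missing,
    )


_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _read_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=[MISSING_TOKEN])
    if list(df.columns[: len(_RAW_META)]) != _RAW_META:
        raise GenotypeParseError(
            f"{path}: line 1: expected PLINK-raw header starting {' '.join(_RAW_META)}"
        )
    markers = [str(c) for c in df.columns[len(_RAW_META):]]
    vals = df[df.columns[len(_RAW_META):]].to_numpy(dtype=float)
    missing = np.isnan(vals)
    ok = missing | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise GenotypeParseError(f"{path}: line {i + 2}: bad dosage {vals[i, j]!r}")
    return GenotypeMatrix(
        samples=[str(s) for s in df["IID"]],
        markers=markers,
        dosages=np.where(missing, 0.0, vals),
        missing=missing,
    )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0,1,2 dosages; 3 = missing
    samples = list(vcf.samples)
    markers, chroms, poss, rows = [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(rec.gt_types, dtype=float)
        rows.append(gt)
        markers.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} multi-allelic record(s)")
    if not rows:
        raise GenotypeParseError(f"{path}: no biallelic SNP records")
    dos = np.stack(rows, axis=1)  # samples x markers
    missing = dos == 3.0
    return GenotypeMatrix(
        samples=samples,
        markers=markers,
        dosages=np.where(missing, 0.0, dos),
        missing=missing,
        chrom=chroms,
        pos=poss,
    )


def read_genotypes(path, format: str = "matrix") -> GenotypeMatrix:
    """Read genotypes from ``path`` in the given format (vcf|raw|matrix)."""
    readers = {"matrix": _read_matrix, "raw": _read_raw, "vcf": _read_vcf}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}; expected vcf, raw or matrix")
    return readers[format](path)


def write_genotypes(g: GenotypeMatrix, path, format: str = "matrix") -> None:
    """Write a (dosage-coded) genotype matrix; ``matrix`` and ``raw`` only."""
    if g.signed:
        raise ValueError("write_genotypes expects dosage coding; got signed")
    vals = g.dosages.astype(object)
    vals[g.missing] = np.nan
    if format == "matrix":
        df = pd.DataFrame(vals, index=g.samples, columns=g.markers)
        df.to_csv(path, na_rep=MISSING_TOKEN, float_format="%.0f")
    elif format == "raw":
        df = pd.DataFrame(vals, columns=g.markers)
        for col, fill in zip(reversed(_RAW_META), [0, -9, 0, 0, 0, 0]):
            df.insert(0, col, g.samples if col in ("FID", "IID") else fill)
        df.to_csv(path, sep=" ", index=False, na_rep=MISSING_TOKEN, float_format="%.0f")
    else:
        raise ValueError(f"unsupported write format {format!r}")


def read_phenotypes(path, trait: str = None) -> pd.DataFrame:
    """Read a delimited phenotype table (first column sample id).

    Rows with a missing value for ``trait`` (or for any trait when
    ``trait`` is None) are dropped.
    """
    with open(path) as fh:
        delim = _detect_delim(fh.readline())
    df = pd.read_csv(path, sep=delim, index_col=0, na_values=[MISSING_TOKEN])
    df.index = df.index.astype(str)
    if trait is not None:
        if trait not in df.columns:
            raise KeyError(f"trait {trait!r} not in {list(df.columns)}")
        df = df[[trait]]
    return df.dropna()


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample")


def read_omics(path) -> pd.DataFrame:
    """Read a delimited sample x feature omics matrix; values must be finite."""
    with open(path) as fh:
        delim = _detect_delim(fh.readline())
    df = pd.read_csv(path, sep=delim, index_col=0)
    df.index = df.index.astype(str)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: omics matrix contains non-finite values")
    return df


def write_omics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample")


# ---------------------------------------------------------------------------
# QC operations


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker mean dosage, rounded to {0,1,2}.

    Rounding is round-half-to-even (numpy convention) with a final clip
    to the valid dosage range.  Non-missing cells are untouched.
    """
    if g.signed:
        raise ValueError("impute before signing")
    if not g.missing.any():
        return g
    n_obs = (~g.missing).sum(axis=0)
    dead = np.flatnonzero(n_obs == 0)
    if dead.size:
        ids = [g.markers[i] for i in dead]
        raise ValueError(f"markers with all calls missing: {ids}")
    out = g.copy()
    means = np.where(g.missing, 0.0, g.dosages).sum(axis=0) / n_obs
    fill = np.clip(np.round(means), 0, 2)
    out.dosages = np.where(g.missing, fill[None, :], g.dosages)
    out.missing = np.zeros_like(g.missing)
    return out


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05):
    """Drop markers with minor-allele frequency below ``threshold``.

    Returns ``(filtered, n_removed)``.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    if g.missing.any():
        raise ValueError("impute before MAF filtering")
    keep = g.maf() >= threshold
    idx = np.flatnonzero(keep)
    out = GenotypeMatrix(
        samples=list(g.samples),
        markers=[g.markers[i] for i in idx],
        dosages=g.dosages[:, idx],
        missing=g.missing[:, idx],
        signed=g.signed,
        chrom=[g.chrom[i] for i in idx] if g.chrom is not None else None,
        pos=[g.pos[i] for i in idx] if g.pos is not None else None,
    )
    return out, int((~keep).sum())


def to_signed(g: GenotypeMatrix) -> GenotypeMatrix:
    """Recode dosages {0,1,2} to signed {-1,0,+1} (dosage minus one)."""
    if g.signed:
        raise ValueError("genotypes are already signed")
    if g.missing.any():
        raise ValueError("impute before signing")
    out = g.copy()
    out.dosages = g.dosages - 1.0
    out.signed = True
    return out


def align_samples(g: GenotypeMatrix, pheno: pd.DataFrame, omics: pd.DataFrame = None):
    """Restrict genotype/phenotype(/omics) to their common samples, in
    genotype order.  Returns aligned copies."""
    common = [s for s in g.samples if s in pheno.index]
    if omics is not None:
        common = [s for s in common if s in omics.index]
    if not common:
        raise ValueError("no samples shared between inputs")
    idx = [g.samples.index(s) for s in common]
    g2 = GenotypeMatrix(
        samples=common,
        markers=list(g.markers),
        dosages=g.dosages[idx],
        missing=g.missing[idx],
        signed=g.signed,
        chrom=g.chrom,
        pos=g.pos,
    )
    p2 = pheno.loc[common]
    if omics is None:
        return g2, p2
    return g2, p2, omics.loc[common]


def read_config(path) -> dict:
    """Read a YAML key-value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
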