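"""Three-channel SNP embedding built from association priors.

Each SNP in signed coding s in {-1, 0, +1} is mapped to a 3-vector
whose channels carry the three classical components of genetic value:

* channel 1 (additive):  sign(s) * (-log10 gwas_p) for homozygotes, 0
  for the heterozygote;
* channel 2 (dominance):  the heterozygote indicator;
* channel 3 (interaction): -log10 lit_p for every state.

So a marker with no association evidence (both p = 1) embeds near the
zero vector for homozygotes and (0, 1, 0) for heterozygotes.  Two
ablation encodings are provided: ``one_hot`` ([1,0,0]/[0,1,0]/[0,0,1]
for +1/0/-1) and ``raw`` (the single-channel signed value itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .priors import P_FLOOR, PriorTable

__all__ = ["EmbeddedGenotypes", "embed_snp", "embed_matrix", "NEG_LOG10_CAP", "ENCODINGS"]

NEG_LOG10_CAP = 300.0
ENCODINGS = ("embedding", "one_hot", "raw")


@dataclass
class EmbeddedGenotypes:
    """n_samples x n_markers x channels tensor plus bookkeeping."""

    values: np.ndarray
    encoding: str
    markers: list
    samples: list

    def __post_init__(self):
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        expected = 1 if self.encoding == "raw" else 3
        if self.values.ndim != 3 or self.values.shape[2] != expected:
            raise ValueError(
                f"{self.encoding} encoding requires {expected} channel(s), "
                f"got shape {self.values.shape}"
            )

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


def _neg_log10(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(-np.log10(np.maximum(p, P_FLOOR)), NEG_LOG10_CAP)


def embed_snp(state, gwas_p, lit_p) -> np.ndarray:
    """Embed one SNP state with its two prior p-values.

    state=+1 -> (-log10 p_G, 0, -log10 p_L)
    state= 0 -> (0, 1, -log10 p_L)
    state=-1 -> (+log10 p_G, 0, -log10 p_L)
    """
    if state not in (-1, 0, 1):
        raise ValueError(f"SNP state must be -1, 0 or +1, got {state!r}")
    lg = float(_neg_log10(gwas_p))
    ll = float(_neg_log10(lit_p))
    if state == 0:
        return np.array([0.0, 1.0, ll])
    return np.array([state * lg, 0.0, ll])


def embed_matrix(g, priors: PriorTable = None, encoding: str = "embedding") -> EmbeddedGenotypes:
    """Vectorized embedding of a whole signed genotype matrix."""
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")
    signed = g.dosages if g.signed else g.dosages - 1.0
    n, m = signed.shape

    if encoding == "raw":
        vals = signed[:, :, None].astype(float)
    elif encoding == "one_hot":
        vals = np.zeros((n, m, 3))
        vals[:, :, 0] = signed == 1
        vals[:, :, 1] = signed == 0
        vals[:, :, 2] = signed == -1
    else:
        if priors is None:
            raise ValueError("encoding='embedding' requires a PriorTable")
        pm = {str(mk): i for i, mk in enumerate(priors.markers)}
        missing = [mk for mk in g.markers if str(mk) not in pm]
        if missing:
            raise ValueError(f"markers missing from prior table: {missing}")
        order = [pm[str(mk)] for mk in g.markers]
        lg = _neg_log10(priors.gwas_p[order])
        ll = _neg_log10(priors.lit_p[order])
        het = signed == 0
        vals = np.zeros((n, m, 3))
        vals[:, :, 0] = np.where(het, 0.0, signed * lg[None, :])
        vals[:, :, 1] = het
        vals[:, :, 2] = ll[None, :]
    return EmbeddedGenotypes(values=vals, encoding=encoding, markers=list(g.markers), samples=list(g.samples))
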