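"""The iADEP prediction network: model and results objects.

Architecture
------------
* **Local encoder** — a 1-D residual convolution stack over the marker
  axis (channels = embedding channels) compresses the panel to a short
  token sequence; multi-head self-attention plus layer normalization
  then mixes interaction information between the local features.
* **Global decoder** — the raw signed genotype row is compressed by a
  two-layer linear map with LeakyReLU (divisor form: x/a on the
  negative side, a = 100 by default) into a few global tokens; these
  query the local tokens through multi-head cross-attention and the
  attention output is added back to the global tokens (residual), then
  flattened to a fused vector.
* **Omics fusion (optional)** — a second omics layer is compressed the
  same way and fused as ``out_omics + sigmoid(max(out_snp, out_omics))``
  elementwise.
* **Head** — a three-layer MLP with LeakyReLU and dropout regresses the
  (training-fold standardized) phenotype; training minimizes
  MSE + lambda * ||theta||^2 with Adam.

Usage follows the statsmodels convention::

    model = IADEP.from_data(genotypes, phenotypes, priors, config=cfg)
    res = model.fit()
    print(res.summary())
    yhat = res.predict(genotypes=new_genotypes)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddedGenotypes, embed_matrix
from .nn.autograd import Tensor, leaky_relu as _t_leaky, maximum as _t_max, sigmoid as _t_sigmoid
from .nn.layers import (
    Adam,
    Conv1d,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    ResidualBlock1d,
    dropout,
)

__all__ = ["ModelConfig", "IADEP", "IADEPResults", "attention", "leaky_relu", "fuse_omics"]


# ---------------------------------------------------------------------------
# formula-level free functions (pure numpy; the network uses autograd twins)


def leaky_relu(x, a: float = 100.0):
    """LeakyReLU in divisor form: x if x >= 0 else x / a."""
    if a <= 0:
        raise ValueError("divisor a must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, x, x / a)
    return out if out.ndim else float(out)


def attention(Q, K, V, n_heads: int = 1):
    """Scaled dot-product attention softmax(QK^T/sqrt(d_k))V.

    Plain (projection-free) form; with ``n_heads > 1`` the width is
    split into heads, attended independently, and concatenated.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have the same number of tokens")
    d = Q.shape[-1]
    if d % n_heads != 0:
        raise ValueError(f"width {d} not divisible by {n_heads} heads")
    dk = d // n_heads
    outs = []
    for h in range(n_heads):
        sl = slice(h * dk, (h + 1) * dk)
        scores = Q[:, sl] @ K[:, sl].T / np.sqrt(dk)
        scores -= scores.max(axis=-1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=-1, keepdims=True)
        outs.append(w @ V[:, sl])
    return np.concatenate(outs, axis=-1)


def fuse_omics(out_snp, out_omics):
    """Omics fusion rule: out_omics + sigmoid(max(out_snp, out_omics))."""
    out_snp = np.asarray(out_snp, dtype=float)
    out_omics = np.asarray(out_omics, dtype=float)
    if out_snp.shape != out_omics.shape:
        raise ValueError(f"width mismatch: {out_snp.shape} vs {out_omics.shape}")
    m = np.maximum(out_snp, out_omics)
    return out_omics + 1.0 / (1.0 + np.exp(-m))


# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Hyperparameters of the network, sized for desk-scale panels."""

    conv_width: int = 16
    stem_kernel: int = 7
    stem_stride: int = 4
    block_kernels: tuple = (7, 3)
    block_strides: tuple = (4, 2)
    n_heads: int = 4
    global_hidden: int = 32
    n_global_tokens: int = 2
    omics_hidden: int = 32
    leaky_a: float = 100.0
    mlp_hidden: tuple = (32, 16)
    dropout: float = 0.1
    lr: float = 3e-3
    weight_decay: float = 1e-4
    epochs: int = 60
    batch_size: int = 128
    seed: int = 0
    trainable_embedding: bool = False

    def validate(self):
        if self.conv_width % self.n_heads != 0:
            raise ValueError(
                f"conv_width {self.conv_width} must be divisible by n_heads {self.n_heads}"
            )
        if self.leaky_a <= 0:
            raise ValueError("leaky_a must be positive")
        if len(self.block_kernels) != len(self.block_strides):
            raise ValueError("block_kernels and block_strides must have equal length")
        for w in (self.conv_width, self.global_hidden, self.n_global_tokens, *self.mlp_hidden):
            if w < 1:
                raise ValueError("all widths must be >= 1")

    def n_tokens(self, n_markers: int) -> int:
        """Token count left after the conv stack for a panel of this size."""
        def out_len(L, k, s):
            return (L + 2 * (k // 2) - k) // s + 1

        L = out_len(n_markers, self.stem_kernel, self.stem_stride)
        for k, s in zip(self.block_kernels, self.block_strides):
            L = out_len(L, k, s)
        if L < 1:
            raise ValueError(
                f"conv schedule reduces {n_markers} markers to {L} tokens; "
                "reduce stem_stride/block_strides or kernel sizes"
            )
        return L


class _EmbeddingTable(Module):
    """Optional trainable per-(marker, state) table, initialized at the fixed embedding."""

    def __init__(self, init: np.ndarray):
        self.table = Tensor(init.copy(), requires_grad=True)  # (m, 3 states, C)

    def __call__(self, onehot: np.ndarray) -> Tensor:
        tab = self.table
        out_data = np.einsum("bms,msc->bmc", onehot, tab.data, optimize=True)

        def backward(g):
            tab._accum(np.einsum("bms,bmc->msc", onehot, g, optimize=True))

        return tab._make(out_data, (tab,), backward)


class _Network(Module):
    def __init__(self, n_markers: int, n_channels: int, n_omics, cfg: ModelConfig,
                 rng: np.random.Generator, embed_init: np.ndarray = None):
        cfg.validate()
        W = cfg.conv_width
        self.cfg = cfg
        self.n_tokens = cfg.n_tokens(n_markers)
        self.stem = Conv1d(n_channels, W, cfg.stem_kernel, cfg.stem_stride, rng)
        self.blocks = [
            ResidualBlock1d(W, k, s, cfg.leaky_a, rng)
            for k, s in zip(cfg.block_kernels, cfg.block_strides)
        ]
        self.self_attn = MultiHeadAttention(W, cfg.n_heads, rng)
        self.ln = LayerNorm(W)
        fused = cfg.n_global_tokens * W
        self.glob1 = Linear(n_markers, cfg.global_hidden, rng)
        self.glob2 = Linear(cfg.global_hidden, fused, rng)
        self.cross_attn = MultiHeadAttention(W, cfg.n_heads, rng)
        if n_omics:
            self.om1 = Linear(n_omics, cfg.omics_hidden, rng)
            self.om2 = Linear(cfg.omics_hidden, fused, rng)
        h1, h2 = cfg.mlp_hidden
        self.mlp1 = Linear(fused, h1, rng)
        self.mlp2 = Linear(h1, h2, rng)
        self.mlp3 = Linear(h2, 1, rng)
        self.embed_table = _EmbeddingTable(embed_init) if embed_init is not None else None

    # -- blocks exposed for inspection/testing ------------------------------
    def local_encode(self, e: Tensor) -> Tensor:
        """Embedded batch (B, m, C) -> token matrix (B, T, W)."""
        x = e.swapaxes(1, 2)                     # (B, C, m)
        x = _t_leaky(self.stem(x), self.cfg.leaky_a)
        for blk in self.blocks:
            x = blk(x)
        tokens = x.swapaxes(1, 2)                # (B, T, W)
        return self.ln(tokens + self.self_attn(tokens))

    def global_decode(self, raw: Tensor, local_tokens: Tensor) -> Tensor:
        """Raw signed rows (B, m) + local tokens -> fused vector (B, Tg*W)."""
        z = self.glob2(_t_leaky(self.glob1(raw), self.cfg.leaky_a))
        B = z.shape[0]
        zt = z.reshape(B, self.cfg.n_global_tokens, self.cfg.conv_width)
        att = self.cross_attn(zt, local_tokens, local_tokens)
        out = att + zt                           # residual: keep global information
        return out.reshape(B, self.cfg.n_global_tokens * self.cfg.conv_width)

    def omics_encode(self, omics: Tensor) -> Tensor:
        return self.om2(_t_leaky(self.om1(omics), self.cfg.leaky_a))

    def forward(self, embedded, raw, omics, rng, training: bool) -> Tensor:
        cfg = self.cfg
        if self.embed_table is not None:
            states = np.stack([raw == -1.0, raw == 0.0, raw == 1.0], axis=-1).astype(float)
            e = self.embed_table(states)
        else:
            e = Tensor(embedded)
        tokens = self.local_encode(e)
        out_snp = self.global_decode(Tensor(raw), tokens)
        if omics is not None:
            out_om = self.omics_encode(Tensor(omics))
            h = out_om + _t_sigmoid(_t_max(out_snp, out_om))
        else:
            h = out_snp
        h = dropout(_t_leaky(self.mlp1(h), cfg.leaky_a), cfg.dropout, rng, training)
        h = dropout(_t_leaky(self.mlp2(h), cfg.leaky_a), cfg.dropout, rng, training)
        B = h.shape[0]
        return self.mlp3(h).reshape(B)


# ---------------------------------------------------------------------------


class IADEP:
    """Prior-knowledge-embedded deep genomic prediction model.

    Parameters
    ----------
    y : array-like, training phenotypes (one per sample).
    embedded : EmbeddedGenotypes for the training samples.
    raw_signed : (n, m) signed genotypes {-1, 0, +1} for the same samples.
    omics : optional (n, F) second-omics matrix.
    priors : the PriorTable used to build ``embedded`` (kept so new
        samples can be embedded identically at prediction time).
    config : ModelConfig.
    """

    def __init__(self, y, embedded: EmbeddedGenotypes, raw_signed, omics=None,
                 priors=None, config: ModelConfig = None):
        self.y = np.asarray(y, dtype=float).ravel()
        if self.y.size < 2:
            raise ValueError("need at least 2 training samples")
        if not np.isfinite(self.y).all():
            raise ValueError("phenotypes must be finite")
        self.embedded = embedded
        self.raw_signed = np.asarray(raw_signed, dtype=float)
        self.omics = None if omics is None else np.asarray(omics, dtype=float)
        self.priors = priors
        self.config = config if config is not None else ModelConfig()
        if embedded.values.shape[0] != self.y.size:
            raise ValueError("embedded sample count != phenotype count")
        if self.raw_signed.shape != embedded.values.shape[:2]:
            raise ValueError("raw_signed shape mismatch with embedding")

    @classmethod
    def from_data(cls, genotypes, phenotypes, priors=None, trait=None,
                  encoding: str = "embedding", omics=None, config: ModelConfig = None):
        """Build the model from package-native containers."""
        import pandas as pd

        emb = embed_matrix(genotypes, priors, encoding=encoding)
        signed = genotypes.dosages if genotypes.signed else genotypes.dosages - 1.0
        if isinstance(phenotypes, pd.DataFrame):
            col = trait if trait is not None else phenotypes.columns[0]
            y = phenotypes[col].reindex(genotypes.samples).to_numpy(dtype=float)
        else:
            y = np.asarray(phenotypes, dtype=float)
        om = None
        if omics is not None:
            om = omics.reindex(genotypes.samples).to_numpy(dtype=float) if isinstance(
                omics, pd.DataFrame) else np.asarray(omics, dtype=float)
        return cls(y, emb, signed, omics=om, priors=priors, config=config)

    # -- fitting ------------------------------------------------------------

    def fit(self, verbose: bool = False) -> "IADEPResults":
        cfg = self.config
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        n, m, C = self.embedded.values.shape

        # preprocessing state: z-scored phenotype, per-channel input scale
        y_mean, y_std = float(self.y.mean()), float(self.y.std())
        y_std = y_std if y_std > 0 else 1.0
        yz = (self.y - y_mean) / y_std
        ch_scale = self.embedded.values.reshape(-1, C).std(axis=0)
        ch_scale = np.where(ch_scale > 1e-8, ch_scale, 1.0)
        X = self.embedded.values / ch_scale[None, None, :]
        om_mean = om_std = None
        OM = None
        if self.omics is not None:
            om_mean = self.omics.mean(axis=0)
            om_std = self.omics.std(axis=0)
            om_std = np.where(om_std > 1e-8, om_std, 1.0)
            OM = (self.omics - om_mean) / om_std

        embed_init = None
        if cfg.trainable_embedding:
            embed_init = self._embedding_init(ch_scale)
        net = _Network(m, C, 0 if OM is None else OM.shape[1], cfg, rng, embed_init)
        params = net.parameters()
        opt = Adam(params, lr=cfg.lr)
        trace = []
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                if idx.size < 2:
                    continue
                pred = net.forward(X[idx], self.raw_signed[idx],
                                   None if OM is None else OM[idx], rng, training=True)
                err = pred - Tensor(yz[idx])
                loss = (err * err).mean()
                if cfg.weight_decay > 0:
                    l2 = None
                    for p in params:
                        term = (p * p).sum()
                        l2 = term if l2 is None else l2 + term
                    loss = loss + cfg.weight_decay * l2
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch} (lr={cfg.lr}); lower the "
                        "learning rate or weight decay"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            trace.append(float(np.mean(losses)))
            if verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
                print(f"epoch {epoch:4d}  loss {trace[-1]:.5f}")
        return IADEPResults(
            model=self, network=net, loss_trace=np.asarray(trace),
            y_mean=y_mean, y_std=y_std, channel_scale=ch_scale,
            omics_mean=om_mean, omics_std=om_std,
        )

    def _embedding_init(self, ch_scale) -> np.ndarray:
        """Per-(marker, state) table initialized from the fixed embedding."""
        if self.priors is None:
            raise ValueError("trainable_embedding requires the PriorTable")
        from .embedding import _neg_log10

        m, C = self.embedded.values.shape[1], self.embedded.values.shape[2]
        if C != 3:
            raise ValueError("trainable_embedding only applies to the 3-channel encoding")
        lg = _neg_log10(self.priors.gwas_p)
        ll = _neg_log10(self.priors.lit_p)
        tab = np.zeros((m, 3, 3))
        tab[:, 0, 0] = -lg          # state -1
        tab[:, 0, 2] = ll
        tab[:, 1, 1] = 1.0          # state 0
        tab[:, 1, 2] = ll
        tab[:, 2, 0] = lg           # state +1
        tab[:, 2, 2] = ll
        return tab / ch_scale[None, None, :]


@dataclass
class IADEPResults:
    """Fitted network plus the preprocessing state needed to embed and
    predict new samples."""

    model: IADEP
    network: _Network
    loss_trace: np.ndarray
    y_mean: float
    y_std: float
    channel_scale: np.ndarray
    omics_mean: np.ndarray = None
    omics_std: np.ndarray = None

    def predict(self, embedded: EmbeddedGenotypes = None, raw_signed=None,
                genotypes=None, omics=None, batch_size: int = 256) -> np.ndarray:
        """Pure forward pass (dropout off), destandardized outputs."""
        if genotypes is not None:
            embedded = embed_matrix(genotypes, self.model.priors,
                                    encoding=self.model.embedded.encoding)
            raw_signed = genotypes.dosages if genotypes.signed else genotypes.dosages - 1.0
        if embedded is None or raw_signed is None:
            raise ValueError("provide either genotypes or (embedded, raw_signed)")
        if list(embedded.markers) != list(self.model.embedded.markers):
            raise ValueError("marker set differs from the training panel")
        X = embedded.values / self.channel_scale[None, None, :]
        raw = np.asarray(raw_signed, dtype=float)
        OM = None
        if self.model.omics is not None:
            if omics is None:
                raise ValueError("model was fitted with omics; supply omics for prediction")
            import pandas as pd

            om = omics.reindex(embedded.samples).to_numpy(dtype=float) if isinstance(
                omics, pd.DataFrame) else np.asarray(omics, dtype=float)
            OM = (om - self.omics_mean) / self.omics_std
        rng = np.random.default_rng(0)  # unused: dropout is off in eval mode
        preds = []
        for s in range(0, X.shape[0], batch_size):
            sl = slice(s, s + batch_size)
            out = self.network.forward(X[sl], raw[sl], None if OM is None else OM[sl],
                                       rng, training=False)
            preds.append(out.data)
        return np.concatenate(preds) * self.y_std + self.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(embedded=self.model.embedded, raw_signed=self.model.raw_signed,
                            omics=self.model.omics)

    def summary(self) -> str:
        cfg = self.model.config
        n, m, C = self.model.embedded.values.shape
        n_par = sum(p.data.size for p in self.network.parameters())
        corr = np.corrcoef(self.fittedvalues, self.model.y)[0, 1]
        lines = [
            "iADEP regression results",
            "=" * 44,
            f"{'encoding':<28}{self.model.embedded.encoding:>16}",
            f"{'training samples':<28}{n:>16d}",
            f"{'markers':<28}{m:>16d}",
            f"{'input channels':<28}{C:>16d}",
            f"{'omics features':<28}{0 if self.model.omics is None else self.model.omics.shape[1]:>16d}",
            f"{'local tokens':<28}{self.network.n_tokens:>16d}",
            f"{'parameters':<28}{n_par:>16d}",
            f"{'epochs':<28}{cfg.epochs:>16d}",
            f"{'final training loss':<28}{self.loss_trace[-1]:>16.5f}",
            f"{'training-fit PCC':<28}{corr:>16.4f}",
            "=" * 44,
        ]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Training-loss trace plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.loss_trace)), self.loss_trace)
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE + L2 loss")
        return ax
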