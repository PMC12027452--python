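"""Save/load fitted networks as a single-file checkpoint.

The checkpoint bundles the network parameters, the model configuration,
the preprocessing state (phenotype standardization, channel scales) and
the prior table used at fit time, so new samples can be embedded and
predicted without the training data.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .embedding import embed_matrix
from .network import IADEPResults, ModelConfig, _Network
from .priors import PriorTable

__all__ = ["save_results", "load_predictor", "CheckpointPredictor"]


def save_results(res: IADEPResults, path) -> None:
    model = res.model
    cfg = asdict(model.config)
    for key in ("block_kernels", "block_strides", "mlp_hidden"):
        cfg[key] = list(cfg[key])
    params = res.network.parameters()
    arrays = {f"param_{i}": p.data for i, p in enumerate(params)}
    arrays["channel_scale"] = res.channel_scale
    arrays["loss_trace"] = res.loss_trace
    if res.omics_mean is not None:
        arrays["omics_mean"] = res.omics_mean
        arrays["omics_std"] = res.omics_std
    meta = {
        "config": cfg,
        "y_mean": res.y_mean,
        "y_std": res.y_std,
        "encoding": model.embedded.encoding,
        "markers": [str(m) for m in model.embedded.markers],
        "n_channels": int(model.embedded.values.shape[2]),
        "n_omics": 0 if model.omics is None else int(model.omics.shape[1]),
        "n_params": len(params),
    }
    if model.priors is not None:
        arrays["priors_gwas_p"] = model.priors.gwas_p
        arrays["priors_lit_p"] = model.priors.lit_p
        meta["priors_provenance"] = {
            k: v for k, v in model.priors.provenance.items() if k != "sample_indices"
        }
    np.savez(path, meta=json.dumps(meta), **arrays)


class CheckpointPredictor:
    """Loaded model: embeds new samples with the stored priors and runs
    the frozen network forward."""

    def __init__(self, network, meta, channel_scale, y_mean, y_std,
                 priors, omics_mean=None, omics_std=None, loss_trace=None):
        self.network = network
        self.meta = meta
        self.channel_scale = channel_scale
        self.y_mean = y_mean
        self.y_std = y_std
        self.priors = priors
        self.omics_mean = omics_mean
        self.omics_std = omics_std
        self.loss_trace = loss_trace

    def predict(self, genotypes, omics=None, batch_size: int = 256) -> np.ndarray:
        if [str(m) for m in genotypes.markers] != self.meta["markers"]:
            raise ValueError("marker set differs from the training panel")
        emb = embed_matrix(genotypes, self.priors, encoding=self.meta["encoding"])
        X = emb.values / self.channel_scale[None, None, :]
        raw = genotypes.dosages if genotypes.signed else genotypes.dosages - 1.0
        OM = None
        if self.meta["n_omics"]:
            if omics is None:
                raise ValueError("model was fitted with omics; supply omics")
            import pandas as pd

            om = omics.reindex(genotypes.samples).to_numpy(dtype=float) if isinstance(
                omics, pd.DataFrame) else np.asarray(omics, dtype=float)
            OM = (om - self.omics_mean) / self.omics_std
        rng = np.random.default_rng(0)
        out = []
        for s in range(0, X.shape[0], batch_size):
            sl = slice(s, s + batch_size)
            res = self.network.forward(X[sl], raw[sl], None if OM is None else OM[sl],
                                       rng, training=False)
            out.append(res.data)
        return np.concatenate(out) * self.y_std + self.y_mean


def load_predictor(path) -> CheckpointPredictor:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        cfg_d = dict(meta["config"])
        for key in ("block_kernels", "block_strides", "mlp_hidden"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = ModelConfig(**cfg_d)
        rng = np.random.default_rng(cfg.seed)
        embed_init = None
        if cfg.trainable_embedding:
            embed_init = np.zeros((len(meta["markers"]), 3, meta["n_channels"]))
        net = _Network(len(meta["markers"]), meta["n_channels"], meta["n_omics"], cfg, rng,
                       embed_init)
        params = net.parameters()
        if len(params) != meta["n_params"]:
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            p.data = np.array(z[f"param_{i}"])
        priors = None
        if "priors_gwas_p" in z:
            priors = PriorTable(
                markers=meta["markers"],
                gwas_p=np.array(z["priors_gwas_p"]),
                lit_p=np.array(z["priors_lit_p"]),
                provenance=meta.get("priors_provenance", {}),
            )
        return CheckpointPredictor(
            network=net,
            meta=meta,
            channel_scale=np.array(z["channel_scale"]),
            y_mean=float(meta["y_mean"]),
            y_std=float(meta["y_std"]),
            priors=priors,
            omics_mean=np.array(z["omics_mean"]) if "omics_mean" in z else None,
            omics_std=np.array(z["omics_std"]) if "omics_std" in z else None,
            loss_trace=np.array(z["loss_trace"]),
        )
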