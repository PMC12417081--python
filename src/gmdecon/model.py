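"""Gaussian-mixture graph convolutional encoder with proportion and domain heads.

The encoder is two graph-convolution layers (symmetric-normalized propagation
with self-loops, ELU activations) whose shared hidden state feeds three heads:
per-component means, per-component log-variances, and component-responsibility
logits.  A node embedding z_i is the responsibility-weighted mixture
z_i = sum_k r_ik (mu_ik + sigma_ik * eps_k) during training (eps ~ N(0, I)) and
sum_k r_ik mu_ik at inference, so inference is deterministic.

Proportions come from a two-layer MLP with a softmax output.  The domain
discriminator sits behind a gradient-reversal layer: identity forward, gradient
scaled by -alpha backward, so minimizing the discriminator's cross-entropy
trains the encoder adversarially toward platform-invariant embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graphs import SpotGraph


@dataclass
class ModelConfig:
    n_genes: int
    n_types: int
    n_components: int = 8
    hidden: int = 512
    embed: int = 512
    head_hidden: int = 256
    disc_hidden: int = 256
    alpha: float = 1.0          # gradient-reversal coefficient
    hard_assignment: bool = False
    logvar_clip: float = 10.0
    logvar_init: float = -4.0   # initial log-variance bias (sigma ~ 0.14)
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class MixtureLatent:
    """Per-node Gaussian-mixture parameters from the encoder."""

    mu: Tensor        # (n, K, embed)
    logvar: Tensor    # (n, K, embed), clamped
    resp: Tensor      # (n, K), rows on the simplex

    @property
    def sigma(self) -> Tensor:
        return ad.exp(ad.mul(self.logvar, 0.5))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(dtype)


def normalize_adjacency(A: np.ndarray, dtype=np.float32) -> np.ndarray:
    """Symmetric normalization with self-loops: D^{-1/2} (A + I) D^{-1/2}."""
    A_hat = np.asarray(A, dtype=np.float64) + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return (A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]).astype(dtype)


class GMGCN:
    """The full model: encoder, reparameterization, proportion head, discriminator."""

    ENCODER_KEYS = ("W_gc1", "b_gc1", "W_gc2", "b_gc2",
                    "W_mu", "b_mu", "W_lv", "b_lv", "W_r", "b_r")
    HEAD_KEYS = ("W_h1", "b_h1", "W_h2", "b_h2")
    DISC_KEYS = ("W_d1", "b_d1", "W_d2", "b_d2")

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dt = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        g, H, E, K = cfg.n_genes, cfg.hidden, cfg.embed, cfg.n_components
        p: Dict[str, Tensor] = {}
        p["W_gc1"] = Tensor(_glorot(rng, g, H, dt), requires_grad=True)
        p["b_gc1"] = Tensor(np.zeros(H, dt), requires_grad=True)
        p["W_gc2"] = Tensor(_glorot(rng, H, H, dt), requires_grad=True)
        p["b_gc2"] = Tensor(np.zeros(H, dt), requires_grad=True)
        p["W_mu"] = Tensor(_glorot(rng, H, K * E, dt), requires_grad=True)
        p["b_mu"] = Tensor(np.zeros(K * E, dt), requires_grad=True)
        # log-variance head starts at a negative bias so the initial latent
        # noise is small relative to the mixture means; unit-scale noise at
        # initialization swamps the supervised signal in early epochs
        p["W_lv"] = Tensor(_glorot(rng, H, K * E, dt), requires_grad=True)
        p["b_lv"] = Tensor(np.full(K * E, cfg.logvar_init, dt), requires_grad=True)
        p["W_r"] = Tensor(_glorot(rng, H, K, dt), requires_grad=True)
        p["b_r"] = Tensor(np.zeros(K, dt), requires_grad=True)
        p["W_h1"] = Tensor(_glorot(rng, E, cfg.head_hidden, dt), requires_grad=True)
        p["b_h1"] = Tensor(np.zeros(cfg.head_hidden, dt), requires_grad=True)
        p["W_h2"] = Tensor(_glorot(rng, cfg.head_hidden, cfg.n_types, dt), requires_grad=True)
        p["b_h2"] = Tensor(np.zeros(cfg.n_types, dt), requires_grad=True)
        p["W_d1"] = Tensor(_glorot(rng, E, cfg.disc_hidden, dt), requires_grad=True)
        p["b_d1"] = Tensor(np.zeros(cfg.disc_hidden, dt), requires_grad=True)
        p["W_d2"] = Tensor(_glorot(rng, cfg.disc_hidden, 1, dt), requires_grad=True)
        p["b_d2"] = Tensor(np.zeros(1, dt), requires_grad=True)
        self.params = p

    # ------------------------------------------------------------- parameters
    def parameters(self, group: Optional[str] = None) -> List[Tensor]:
        if group == "encoder":
            keys = self.ENCODER_KEYS
        elif group == "head":
            keys = self.HEAD_KEYS
        elif group == "discriminator":
            keys = self.DISC_KEYS
        else:
            keys = tuple(self.params)
        return [self.params[k] for k in keys]

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # ----------------------------------------------------------------- layers
    def encode(self, graph: SpotGraph) -> MixtureLatent:
        cfg = self.cfg
        if graph.X.shape[1] != cfg.n_genes:
            raise ValueError(
                f"feature width {graph.X.shape[1]} does not match model input {cfg.n_genes}"
            )
        dt = np.dtype(cfg.dtype)
        A_hat = ad.constant(normalize_adjacency(graph.A, dt))
        X = ad.constant(np.asarray(graph.X, dtype=dt))
        p = self.params
        h = ad.elu(ad.add(ad.matmul(A_hat, ad.matmul(X, p["W_gc1"])), p["b_gc1"]))
        h = ad.elu(ad.add(ad.matmul(A_hat, ad.matmul(h, p["W_gc2"])), p["b_gc2"]))
        n = graph.n
        K, E = cfg.n_components, cfg.embed
        mu = ad.reshape(ad.add(ad.matmul(h, p["W_mu"]), p["b_mu"]), (n, K, E))
        logvar = ad.clip(ad.reshape(ad.add(ad.matmul(h, p["W_lv"]), p["b_lv"]), (n, K, E)),
                         -cfg.logvar_clip, cfg.logvar_clip)
        resp = ad.softmax(ad.add(ad.matmul(h, p["W_r"]), p["b_r"]), axis=1)
        return MixtureLatent(mu=mu, logvar=logvar, resp=resp)

    def reparameterize(
        self,
        lat: MixtureLatent,
        rng: Optional[np.random.Generator] = None,
        training: bool = True,
    ) -> Tensor:
        """Mixture embedding: responsibility-weighted means, plus noise in training."""
        resp = lat.resp
        if self.cfg.hard_assignment:
            # straight-through: forward uses the argmax one-hot, gradient uses soft resp
            hard = np.zeros_like(resp.data)
            hard[np.arange(resp.shape[0]), resp.data.argmax(axis=1)] = 1.0
            resp = ad.add(resp, ad.constant(hard - resp.data))
        r3 = ad.expand_dims(resp, 2)  # (n, K, 1)
        if training:
            if rng is None:
                rng = np.random.default_rng(0)
            eps = ad.constant(rng.standard_normal(lat.mu.shape).astype(lat.mu.dtype))
            comp = ad.add(lat.mu, ad.mul(lat.sigma, eps))
        else:
            comp = lat.mu
        return ad.tsum(ad.mul(r3, comp), axis=1)  # (n, embed)

    def predict_proportions(self, Z: Tensor) -> Tensor:
        p = self.params
        h = ad.elu(ad.add(ad.matmul(Z, p["W_h1"]), p["b_h1"]))
        return ad.softmax(ad.add(ad.matmul(h, p["W_h2"]), p["b_h2"]), axis=1)

    def discriminate_domain(self, Z: Tensor, alpha: Optional[float] = None) -> Tensor:
        p = self.params
        a = self.cfg.alpha if alpha is None else alpha
        h = ad.elu(ad.add(ad.matmul(ad.grl(Z, a), p["W_d1"]), p["b_d1"]))
        return ad.sigmoid(ad.add(ad.matmul(h, p["W_d2"]), p["b_d2"]))

    def forward(
        self,
        graph: SpotGraph,
        rng: Optional[np.random.Generator] = None,
        training: bool = True,
    ) -> Dict[str, Tensor]:
        lat = self.encode(graph)
        Z = self.reparameterize(lat, rng=rng, training=training)
        return {
            "latent": lat,
            "Z": Z,
            "proportions": self.predict_proportions(Z),
            "domain": self.discriminate_domain(Z),
        }

    # ------------------------------------------------------------- checkpoint
    def save(self, path: Union[str, Path]) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(path, __version__=np.array([1]),
                 __config__=np.array([repr(asdict(self.cfg))]), **arrays)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "GMGCN":
        with np.load(path, allow_pickle=False) as z:
            cfg = ModelConfig(**eval(str(z["__config__"][0])))  # noqa: S307 - own header
            model = cls(cfg)
            for k in model.params:
                model.params[k].data = z[k]
        return model
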