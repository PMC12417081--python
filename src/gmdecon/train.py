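"""Training schedule and dual-graph inference.

Each epoch visits the graphs in a fixed order: all pseudo-spot expression
graphs (one Adam step per graph, full five-term loss), then the SRT expression
graph and the SRT spatial graph (reconstruction + domain cross-entropy only —
SRT proportions are never supervised).  No validation split or early stopping
is used.  At inference the deterministic forward pass (mixture means, no
latent sampling) is run on both SRT graphs and the two proportion matrices are
averaged elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import losses as L
from .autodiff import Adam
from .graphs import SpotGraph
from .model import GMGCN


@dataclass
class TrainConfig:
    epochs: int = 20
    lr: float = 0.001
    seed: int = 0
    w_mse: float = L.DEFAULT_W_MSE
    w_sample: float = L.DEFAULT_W_SAMPLE
    w_entropy: float = L.DEFAULT_W_ENTROPY
    entropy_sign: int = 1
    disable_recon: bool = False
    disable_domain: bool = False
    disable_sample: bool = False
    disable_entropy: bool = False
    shuffle_graphs: bool = False   # reshuffle pseudo-graph order each epoch
    # adaptive gradient clipping: clip the global gradient norm to
    # clip_factor x its running average (None disables). Tames the occasional
    # late-training spike of the n^2-scale reconstruction term.
    clip_factor: Optional[float] = 3.0
    clip_ema_decay: float = 0.9

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class LogRecord:
    epoch: int
    graph: str
    domain: str
    breakdown: L.LossBreakdown


def _check_finite(parts: L.LossBreakdown, graph_name: str) -> None:
    bad = [name for name in ("recon", "mse", "domain_ce", "sample", "entropy", "total")
           if not (np.isnan(getattr(parts, name)) or np.isfinite(getattr(parts, name)))]
    if bad or not np.isfinite(parts.total):
        raise FloatingPointError(
            f"non-finite loss on graph {graph_name}: "
            + ", ".join(f"{name}={getattr(parts, name)}" for name in
                        ("recon", "mse", "domain_ce", "sample", "entropy", "total"))
        )


class _GradClipper:
    """Global-norm clipping against an exponential moving average of the norm."""

    def __init__(self, factor: Optional[float], decay: float):
        self.factor = factor
        self.decay = decay
        self.ema: Optional[float] = None

    def __call__(self, params: Sequence) -> None:
        if self.factor is None:
            return
        norm = float(np.sqrt(sum(float((p.grad ** 2).sum())
                                 for p in params if p.grad is not None)))
        if norm == 0.0:
            return
        if self.ema is None:
            self.ema = norm
        limit = self.factor * self.ema
        if norm > limit:
            scale = limit / norm
            for p in params:
                if p.grad is not None:
                    p.grad *= scale
            norm = limit
        self.ema = self.decay * self.ema + (1.0 - self.decay) * norm


def _graph_step(
    model: GMGCN,
    graph: SpotGraph,
    cfg: TrainConfig,
    opt: Adam,
    rng: np.random.Generator,
    clipper: Optional[_GradClipper] = None,
) -> L.LossBreakdown:
    """One forward/backward/update on a single graph."""
    domain = "pseudo" if graph.domain == 0 else "srt"
    out = model.forward(graph, rng=rng, training=True)
    parts = L.LossBreakdown(w_mse=cfg.w_mse, w_sample=cfg.w_sample, w_entropy=cfg.w_entropy)

    recon_t = None
    if not cfg.disable_recon:
        recon_t = L.reconstruction_loss(graph.A, out["Z"])
        parts.recon = recon_t.item()
    ce_t = None
    if not cfg.disable_domain:
        m_true = np.full(graph.n, float(graph.domain))
        ce_t = L.domain_ce_loss(out["domain"], m_true)
        parts.domain_ce = ce_t.item()
    mse_t = sample_t = entropy_t = None
    if domain == "pseudo":
        mse_t = L.mse_loss(out["proportions"], graph.y)
        parts.mse = mse_t.item()
        if not cfg.disable_sample:
            sample_t = L.sample_loss(out["proportions"], graph.y)
            parts.sample = sample_t.item()
        if not cfg.disable_entropy:
            entropy_t = L.entropy_loss(out["proportions"], sign=cfg.entropy_sign)
            parts.entropy = entropy_t.item()

    total_t = L.total_loss(recon_t, ce_t, domain, mse=mse_t, sample=sample_t,
                           entropy=entropy_t, w_mse=cfg.w_mse,
                           w_sample=cfg.w_sample, w_entropy=cfg.w_entropy)
    parts.total = total_t.item()
    _check_finite(parts, f"{domain}:{graph.node_ids[0]}")

    opt.zero_grad()
    total_t.backward()
    if clipper is not None:
        clipper(opt.params)
    opt.step()
    return parts


def train(
    model: GMGCN,
    pseudo_graphs: Sequence[SpotGraph],
    srt_expr_graph: Optional[SpotGraph],
    srt_spatial_graph: Optional[SpotGraph],
    cfg: TrainConfig,
) -> List[LogRecord]:
    """Run the full schedule; returns the per-step loss log."""
    widths = {g.X.shape[1] for g in pseudo_graphs}
    for g in (srt_expr_graph, srt_spatial_graph):
        if g is not None:
            widths.add(g.X.shape[1])
    if len(widths) != 1:
        raise ValueError(f"graphs disagree on feature width: {sorted(widths)}")
    for g in pseudo_graphs:
        if g.y is None:
            raise ValueError("pseudo-spot graphs must carry true proportions")

    params = model.parameters()
    if cfg.disable_domain:
        # discriminator is unused: exclude its parameters so they receive no updates
        disc = set(id(t) for t in model.parameters("discriminator"))
        params = [t for t in params if id(t) not in disc]
    opt = Adam(params, lr=cfg.lr)
    clipper = _GradClipper(cfg.clip_factor, cfg.clip_ema_decay)
    rng = np.random.default_rng(cfg.seed)
    order_rng = np.random.default_rng(cfg.seed + 1)

    log: List[LogRecord] = []
    for epoch in range(cfg.epochs):
        order = list(range(len(pseudo_graphs)))
        if cfg.shuffle_graphs:
            order_rng.shuffle(order)
        for gi in order:
            parts = _graph_step(model, pseudo_graphs[gi], cfg, opt, rng, clipper)
            log.append(LogRecord(epoch, f"pseudo_{gi}", "pseudo", parts))
        for name, g in (("srt_expression", srt_expr_graph), ("srt_spatial", srt_spatial_graph)):
            if g is None:
                continue
            if cfg.disable_recon and cfg.disable_domain:
                continue  # SRT graphs carry no active loss terms under this ablation
            parts = _graph_step(model, g, cfg, opt, rng, clipper)
            log.append(LogRecord(epoch, name, "srt", parts))
    return log


def infer(
    model: GMGCN,
    srt_spatial_graph: SpotGraph,
    srt_expr_graph: SpotGraph,
) -> np.ndarray:
    """Average the deterministic predictions from the spatial and expression graphs."""
    if srt_spatial_graph.node_ids != srt_expr_graph.node_ids:
        raise ValueError("spatial and expression graphs must cover the same spots in order")
    y_spatial = model.forward(srt_spatial_graph, training=False)["proportions"].data
    y_expr = model.forward(srt_expr_graph, training=False)["proportions"].data
    return ((y_spatial + y_expr) / 2.0).astype(np.float64)


def log_to_rows(log: Sequence[LogRecord]) -> List[dict]:
    """Flatten the training log for TSV export."""
    rows = []
    for rec in log:
        b = rec.breakdown
        rows.append({
            "epoch": rec.epoch, "graph": rec.graph, "domain": rec.domain,
            "recon": b.recon, "mse": b.mse, "domain_ce": b.domain_ce,
            "sample": b.sample, "entropy": b.entropy, "total": b.total,
        })
    return rows
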