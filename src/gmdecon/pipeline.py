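"""End-to-end deconvolution pipeline tying the stages together.

preprocess (shared HVGs, normalize/log1p/zscore per dataset) -> pseudo-spot
sampling -> graph construction -> training -> dual-graph inference ->
(optional) evaluation.  Every run directory is stamped with the resolved
config and its hash so outputs can be reproduced bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import data as dio
from .config import RunConfig, stage_seed
from .graphs import batch_pseudo_graphs, build_srt_graphs
from .model import GMGCN, ModelConfig
from .pseudo import generate_pseudo_spots
from .train import TrainConfig, infer, log_to_rows, train

logger = logging.getLogger("gmdecon")


@dataclass
class PipelineResult:
    proportions: pd.DataFrame      # spots x cell types
    type_names: List[str]
    hvgs: List[str]
    model: GMGCN
    training_log: pd.DataFrame
    embeddings_srt: np.ndarray
    embeddings_pseudo: np.ndarray


def run_pipeline(
    cfg: RunConfig,
    ref: dio.CountMatrix,
    labels: dio.CellAnnotation,
    srt: dio.CountMatrix,
    coords: dio.SpotCoordinates,
    out_dir: Optional[Path] = None,
) -> PipelineResult:
    if ref.unit_ids != labels.unit_ids:
        raise ValueError("stage=preprocess: reference and labels disagree on unit ids")
    if srt.unit_ids != coords.unit_ids:
        raise ValueError("stage=preprocess: SRT matrix and coordinates disagree on unit ids")

    logger.info("stage=preprocess selecting shared HVGs")
    hvgs = dio.select_shared_hvgs(ref, srt, min_genes=cfg.min_genes)
    ref_h = ref.subset_genes(hvgs)
    srt_h = srt.subset_genes(hvgs)

    logger.info("stage=pseudo sampling %d pseudo-spots", cfg.n_pseudo)
    batch = generate_pseudo_spots(
        ref_h, labels, n_spots=cfg.n_pseudo, lam=cfg.lam, NK=cfg.NK,
        seed=stage_seed(cfg.seed, "pseudo"), size_sampler=cfg.size_sampler,
    )

    logger.info("stage=preprocess normalizing features")
    # each dataset standardized on its own statistics; residual shift is left
    # to the domain-adaptation loss
    X_pseudo = dio.preprocess(batch.counts, cfg.library_target).values
    X_srt = dio.preprocess(srt_h, cfg.library_target).values

    logger.info("stage=graphs building %d pseudo graphs + 2 SRT graphs", cfg.n_graphs)
    pseudo_graphs = batch_pseudo_graphs(
        X_pseudo, batch.proportions, batch.counts.unit_ids,
        graph_size=cfg.graph_size, n_graphs=cfg.n_graphs, k=cfg.k,
        seed=stage_seed(cfg.seed, "partition"),
    )
    srt_spatial, srt_expr = build_srt_graphs(X_srt, coords, srt_h.unit_ids, k=cfg.k)

    logger.info("stage=train %d epochs over %d graphs", cfg.epochs, len(pseudo_graphs) + 2)
    model = GMGCN(ModelConfig(
        n_genes=len(hvgs), n_types=labels.CT, n_components=cfg.n_components,
        hidden=cfg.hidden, embed=cfg.embed, head_hidden=cfg.head_hidden,
        disc_hidden=cfg.disc_hidden, alpha=cfg.alpha,
        hard_assignment=cfg.hard_assignment, seed=stage_seed(cfg.seed, "init"),
    ))
    tcfg = TrainConfig(
        epochs=cfg.epochs, lr=cfg.lr, seed=stage_seed(cfg.seed, "train"),
        w_mse=cfg.w_mse, w_sample=cfg.w_sample, w_entropy=cfg.w_entropy,
        entropy_sign=cfg.entropy_sign, disable_recon=cfg.disable_recon,
        disable_domain=cfg.disable_domain, disable_sample=cfg.disable_sample,
        disable_entropy=cfg.disable_entropy, shuffle_graphs=cfg.shuffle_graphs,
        clip_factor=cfg.clip_factor,
    )
    log = train(model, pseudo_graphs, srt_expr, srt_spatial, tcfg)

    logger.info("stage=infer predicting %d spots", srt_h.n_units)
    pred = infer(model, srt_spatial, srt_expr)
    proportions = pd.DataFrame(pred, index=srt_h.unit_ids, columns=labels.types)

    # deterministic embeddings for platform-mixing diagnostics; use enough
    # pseudo graphs to balance the two platform groups
    z_srt = model.forward(srt_expr, training=False)["Z"].data.astype(np.float64)
    n_needed = int(np.ceil(srt_h.n_units / cfg.graph_size))
    z_pseudo = np.vstack([
        model.forward(g, training=False)["Z"].data.astype(np.float64)
        for g in pseudo_graphs[:n_needed]
    ])[:srt_h.n_units]

    result = PipelineResult(
        proportions=proportions,
        type_names=list(labels.types),
        hvgs=hvgs,
        model=model,
        training_log=pd.DataFrame(log_to_rows(log)),
        embeddings_srt=z_srt,
        embeddings_pseudo=z_pseudo,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        proportions.to_csv(out_dir / "proportions.tsv", sep="\t")
        result.training_log.to_csv(out_dir / "training_log.tsv", sep="\t", index=False)
        model.save(out_dir / "checkpoint.npz")
        cfg.to_yaml(out_dir / "run_config.yaml")
        (out_dir / "config_hash.txt").write_text(cfg.config_hash() + "\n")
    return result
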