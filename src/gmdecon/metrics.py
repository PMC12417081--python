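"""Benchmark metrics for deconvolution output.

Per-spot agreement between predicted and true proportion rows is scored with
PCC, SSIM, RMSE and base-2 JSD; methods are compared with a rank-based
accuracy score (AS) aggregating the four.  Sample-level fractions are the
column means of a proportion matrix; their agreement is scored by ordinary
least squares r^2 and RMSE.  Spatial domains are recovered by K-means over
predicted proportions and scored with ARI and purity.  Platform mixing between
SRT and pseudo-spot embeddings is the mean silhouette with the platform as the
cluster label (lower = better mixed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

SSIM_C1 = 0.01 ** 2
SSIM_C2 = 0.03 ** 2


@dataclass
class SampleLevelResult:
    pred_fractions: np.ndarray
    true_fractions: np.ndarray
    r2: float
    rmse: float


@dataclass
class ClusterResult:
    labels: np.ndarray
    ari: Optional[float] = None
    purity: Optional[float] = None


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    return pred, truth


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def per_spot_metrics(pred: np.ndarray, truth: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-spot PCC, SSIM, RMSE and base-2 JSD between proportion rows.

    PCC of a constant vector is defined as 0.  SSIM is computed per spot over
    cell types after min-max scaling each whole matrix to [0, 1], with the
    standard constants C1 = 0.01^2, C2 = 0.03^2 and population moments.
    """
    pred, truth = _check_pair(pred, truth)
    n, ct = pred.shape

    pcc = np.zeros(n)
    for i in range(n):
        if np.std(pred[i]) == 0 or np.std(truth[i]) == 0:
            pcc[i] = 0.0
        else:
            pcc[i] = np.corrcoef(pred[i], truth[i])[0, 1]

    rmse = np.sqrt(np.mean((pred - truth) ** 2, axis=1))

    ps = _minmax(pred)
    ts = _minmax(truth)
    ssim = np.zeros(n)
    for i in range(n):
        mx, my = ps[i].mean(), ts[i].mean()
        vx, vy = ps[i].var(), ts[i].var()
        cov = np.mean((ps[i] - mx) * (ts[i] - my))
        ssim[i] = ((2 * mx * my + SSIM_C1) * (2 * cov + SSIM_C2)) / (
            (mx ** 2 + my ** 2 + SSIM_C1) * (vx + vy + SSIM_C2)
        )

    jsd = np.array([jensen_shannon_divergence(pred[i], truth[i]) for i in range(n)])
    return {"pcc": pcc, "ssim": ssim, "rmse": rmse, "jsd": jsd}


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence between two proportion vectors (range [0, 1])."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum() if p.sum() > 0 else np.full_like(p, 1.0 / p.size)
    q = q / q.sum() if q.sum() > 0 else np.full_like(q, 1.0 / q.size)
    m = 0.5 * (p + q)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def spot_entropy(pred: np.ndarray) -> np.ndarray:
    """Shannon entropy (natural log) of each proportion row; 0 log 0 := 0."""
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("negative entry in proportion matrix")
    out = np.zeros(pred.shape[0])
    for i, row in enumerate(pred):
        mask = row > 0
        out[i] = -np.sum(row[mask] * np.log(row[mask]))
    return out


def accuracy_score(table: pd.DataFrame) -> pd.Series:
    """Rank-based accuracy score per method.

    ``table`` holds one summary value per method (rows) and metric (columns
    among PCC, SSIM, RMSE, JSD).  Within each metric, methods are ranked (PCC
    and SSIM: higher is better; RMSE and JSD: lower is better; ties share the
    average rank), each rank r among M methods maps to (M - r + 1) / M, and AS
    is the mean of the four normalized scores.
    """
    higher_better = {"PCC": True, "SSIM": True, "RMSE": False, "JSD": False}
    required = list(higher_better)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing metric columns: {missing}")
    if table[required].isna().any().any():
        raise ValueError("missing cell in metric table")
    if len(table) < 2:
        raise ValueError("AS needs at least two methods")
    M = len(table)
    scores = pd.DataFrame(index=table.index, columns=required, dtype=float)
    for metric in required:
        vals = table[metric].to_numpy(dtype=float)
        # rank 1 = best
        r = stats.rankdata(-vals if higher_better[metric] else vals, method="average")
        scores[metric] = (M - r + 1) / M
    return scores.mean(axis=1)


def sample_level_eval(pred: np.ndarray, truth: np.ndarray) -> SampleLevelResult:
    """Sample-level fractions (column means) compared by OLS r^2 and RMSE."""
    pred, truth = _check_pair(pred, truth)
    if pred.shape[1] < 2:
        raise ValueError("r^2 undefined with a single cell type")
    f_pred = pred.mean(axis=0)
    f_true = truth.mean(axis=0)
    reg = stats.linregress(f_pred, f_true)
    rmse = float(np.sqrt(np.mean((f_pred - f_true) ** 2)))
    return SampleLevelResult(f_pred, f_true, float(reg.rvalue ** 2), rmse)


def purity_score(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Sum over predicted clusters of their largest true-label overlap, over n."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    total = 0
    for c in np.unique(pred_labels):
        members = true_labels[pred_labels == c]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return float(total / len(pred_labels))


def cluster_domains(
    pred: np.ndarray,
    K: int,
    true_labels: Optional[Sequence] = None,
    seed: int = 0,
) -> ClusterResult:
    """K-means over predicted proportion rows; ARI/purity when truth is given."""
    pred = np.asarray(pred, dtype=float)
    if K < 2 or K > pred.shape[0]:
        raise ValueError("K must satisfy 2 <= K <= n_spots")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    labels = km.fit_predict(pred)
    res = ClusterResult(labels=labels)
    if true_labels is not None:
        true_arr = np.asarray(true_labels)
        res.ari = float(adjusted_rand_score(true_arr, labels))
        res.purity = purity_score(labels, true_arr)
    return res


def platform_mixing_score(z_srt: np.ndarray, z_pseudo: np.ndarray) -> float:
    """Mean silhouette between the two platforms' embeddings (lower = better mixed)."""
    z_srt = np.atleast_2d(np.asarray(z_srt, dtype=float))
    z_pseudo = np.atleast_2d(np.asarray(z_pseudo, dtype=float))
    if z_srt.shape[0] < 2 or z_pseudo.shape[0] < 2:
        raise ValueError("each platform needs at least two embeddings")
    X = np.vstack([z_srt, z_pseudo])
    labels = np.array([0] * z_srt.shape[0] + [1] * z_pseudo.shape[0])
    return float(silhouette_score(X, labels, metric="euclidean"))


def drop_excluded_types(
    pred: np.ndarray,
    truth: np.ndarray,
    type_names: Sequence[str],
    exclude: Sequence[str],
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Drop excluded proportion columns from both matrices and renormalize rows.

    Spots whose remaining truth mass is zero are removed from both matrices.
    """
    keep = [i for i, t in enumerate(type_names) if t not in set(exclude)]
    if not keep:
        raise ValueError("all cell types excluded")
    p = np.asarray(pred, dtype=float)[:, keep]
    t = np.asarray(truth, dtype=float)[:, keep]
    rows = t.sum(axis=1) > 0
    p, t = p[rows], t[rows]
    p_sums = p.sum(axis=1)
    p[p_sums > 0] /= p_sums[p_sums > 0, None]
    t /= t.sum(axis=1, keepdims=True)
    return p, t, [type_names[i] for i in keep]
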