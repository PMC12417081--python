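"""The five training losses and their weighted combination.

Pseudo-spot graphs carry known proportions, so they are trained with all five
terms: graph reconstruction, proportion MSE (weight 1000), domain
cross-entropy, sample-level fraction loss (weight 1000), and an entropy loss
(weight 10) that penalizes overbalanced per-spot proportions.  SRT graphs have
no proportion labels, so only reconstruction and domain cross-entropy apply.

Every loss is written against the autodiff :class:`~gmdecon.autodiff.Tensor`
so it can sit on the training tape, but plain ndarrays are accepted too (they
are wrapped as constants), which is how the unit tests compare each loss to an
independent scalar-loop oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-7  # probabilities are clamped to [EPS, 1 - EPS] before any log

DEFAULT_W_MSE = 1000.0
DEFAULT_W_SAMPLE = 1000.0
DEFAULT_W_ENTROPY = 10.0

TensorLike = Union[Tensor, np.ndarray]


@dataclass
class LossBreakdown:
    """Scalar loss components and their weighted total for one graph step."""

    recon: float = float("nan")
    mse: float = float("nan")
    domain_ce: float = float("nan")
    sample: float = float("nan")
    entropy: float = float("nan")
    total: float = float("nan")
    w_mse: float = DEFAULT_W_MSE
    w_sample: float = DEFAULT_W_SAMPLE
    w_entropy: float = DEFAULT_W_ENTROPY


def _clip_prob(p: Tensor) -> Tensor:
    return ad.clip(p, EPS, 1.0 - EPS)


def reconstruction_loss(A: TensorLike, Z: TensorLike,
                        include_diagonal: bool = False) -> Tensor:
    """Edge-wise binary cross-entropy of sigmoid(z_i . z_j) against the adjacency.

    The sum runs over ordered pairs i != j by default (self inner products are
    uninformative); ``include_diagonal`` restores the literal all-pairs sum.
    """
    Z = ad.as_tensor(Z)
    A_arr = A.data if isinstance(A, Tensor) else np.asarray(A)
    n = Z.shape[0]
    if A_arr.shape != (n, n):
        raise ValueError(f"adjacency shape {A_arr.shape} does not match {n} embeddings")
    A_c = ad.constant(A_arr.astype(Z.dtype))
    logits = ad.matmul(Z, ad.transpose(Z))
    p = _clip_prob(ad.sigmoid(logits))
    ll = ad.add(ad.mul(A_c, ad.log(p)),
                ad.mul(ad.add(ad.mul(A_c, -1.0), 1.0), ad.log(ad.add(ad.mul(p, -1.0), 1.0))))
    if not include_diagonal:
        mask = ad.constant((1.0 - np.eye(n)).astype(Z.dtype))
        ll = ad.mul(ll, mask)
    return ad.mul(ad.tsum(ll), -1.0)


def mse_loss(y_pred: TensorLike, y_true: TensorLike) -> Tensor:
    """Mean over spots of the squared Euclidean distance between proportion rows."""
    y_pred = ad.as_tensor(y_pred)
    y_true_arr = y_true.data if isinstance(y_true, Tensor) else np.asarray(y_true)
    if y_pred.shape != y_true_arr.shape:
        raise ValueError("prediction and truth shapes differ")
    diff = ad.add(y_pred, ad.constant((-y_true_arr).astype(y_pred.dtype)))
    per_spot = ad.tsum(ad.mul(diff, diff), axis=1)
    return ad.tmean(per_spot)


def domain_ce_loss(m_pred: TensorLike, m_true: TensorLike) -> Tensor:
    """Mean binary cross-entropy of the domain discriminator (1 = SRT spot)."""
    m_pred = ad.as_tensor(m_pred)
    m_arr = np.asarray(m_true.data if isinstance(m_true, Tensor) else m_true,
                       dtype=float).reshape(-1)
    p = _clip_prob(ad.reshape(m_pred, (-1,)))
    if p.shape[0] != m_arr.shape[0]:
        raise ValueError("prediction and label lengths differ")
    m_c = ad.constant(m_arr.astype(p.dtype))
    one_minus_m = ad.constant((1.0 - m_arr).astype(p.dtype))
    ll = ad.add(ad.mul(m_c, ad.log(p)),
                ad.mul(one_minus_m, ad.log(ad.add(ad.mul(p, -1.0), 1.0))))
    return ad.mul(ad.tmean(ll), -1.0)


def sample_loss(y_pred: TensorLike, y_true: TensorLike) -> Tensor:
    """Squared distance between mean predicted and mean true proportion vectors.

    Algebraically equal to (1/n^2) || sum_i y~_i - sum_i y_i ||^2.
    """
    y_pred = ad.as_tensor(y_pred)
    y_true_arr = y_true.data if isinstance(y_true, Tensor) else np.asarray(y_true)
    if y_pred.shape != y_true_arr.shape:
        raise ValueError("prediction and truth shapes differ")
    mean_pred = ad.tmean(y_pred, axis=0)
    diff = ad.add(mean_pred, ad.constant((-y_true_arr.mean(axis=0)).astype(y_pred.dtype)))
    return ad.tsum(ad.mul(diff, diff))


def _entropy_rows(p: Tensor) -> Tensor:
    """Shannon entropy per row, natural log, with 0 log 0 := 0 via clamping.

    Only the lower bound is clamped so that an exact 1 contributes exactly 0.
    """
    pc = ad.clip(p, EPS, 1.0)
    return ad.mul(ad.tsum(ad.mul(p, ad.log(pc)), axis=1), -1.0)


def entropy_loss(y_pred: TensorLike, sign: int = 1) -> Tensor:
    """Mean per-spot entropy plus (sign) the entropy of the batch-mean proportions.

    With ``sign=+1`` both terms are penalties, as printed; ``sign=-1`` instead
    rewards a spread-out batch mean (documented alternative).
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    y_pred = ad.as_tensor(y_pred)
    if np.any(y_pred.data < 0):
        raise ValueError("negative entry in proportion matrix")
    term1 = ad.tmean(_entropy_rows(y_pred))
    mean_row = ad.reshape(ad.tmean(y_pred, axis=0), (1, -1))
    term2 = ad.reshape(_entropy_rows(mean_row), ())
    return ad.add(term1, ad.mul(term2, float(sign)))


def total_loss(
    recon: Optional[Tensor],
    domain_ce: Optional[Tensor],
    domain: str,
    mse: Optional[Tensor] = None,
    sample: Optional[Tensor] = None,
    entropy: Optional[Tensor] = None,
    w_mse: float = DEFAULT_W_MSE,
    w_sample: float = DEFAULT_W_SAMPLE,
    w_entropy: float = DEFAULT_W_ENTROPY,
) -> Tensor:
    """Weighted combination for one graph.

    Pseudo-spot graphs: recon + w_mse*mse + ce + w_sample*sample + w_entropy*entropy.
    SRT graphs: recon + ce.  A ``None`` component is treated as disabled
    (ablation) except that pseudo graphs require the supervised MSE term.
    """
    if domain not in ("pseudo", "srt"):
        raise ValueError(f"unknown domain: {domain!r}")
    terms = []
    if recon is not None:
        terms.append(recon)
    if domain_ce is not None:
        terms.append(domain_ce)
    if domain == "pseudo":
        if mse is None:
            raise ValueError("pseudo-spot graphs require the supervised MSE component")
        terms.append(ad.mul(mse, w_mse))
        if sample is not None:
            terms.append(ad.mul(sample, w_sample))
        if entropy is not None:
            terms.append(ad.mul(entropy, w_entropy))
    if not terms:
        raise ValueError("no loss components enabled")
    out = terms[0]
    for t in terms[1:]:
        out = ad.add(out, t)
    return out
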