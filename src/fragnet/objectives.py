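"""Loss functions: NT-Xent contrastive loss and masked reconstruction.

The contrastive batch holds 2N projection vectors ordered so that
(2k, 2k+1) are the two augmented views of molecule k.  For anchor i
with partner j the per-anchor loss is

    l(i, j) = -log[ exp(sim(z_i, z_j)/tau) / sum_{k != i} exp(sim(z_i, z_k)/tau) ]

with sim() the cosine similarity and tau the temperature; the reported
value is the mean over all 2N anchors.  Numerics are stabilized by
max-subtraction before exponentiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .smiles_data import EncodedSequence

logger = logging.getLogger(__name__)


def cosine_sim(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 for a zero vector."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.warning("cosine_sim: zero vector encountered, returning 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


@dataclass(frozen=True)
class ContrastiveBatch:
    """2N projection vectors with interleaved positive pairs."""

    vectors: np.ndarray     # (2N, d)
    temperature: float

    def __post_init__(self):
        n = self.vectors.shape[0]
        if n < 4 or n % 2:
            raise ValueError("contrastive batch needs an even count >= 4")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _cosine_matrix(z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        logger.warning("nt_xent: %d zero vectors in batch", int(zero.sum()))
    safe = np.where(norms == 0, 1.0, norms)
    zn = z / safe
    sims = zn @ zn.T
    sims[zero, :] = 0.0
    sims[:, zero] = 0.0
    return sims

def nt_xent(batch: ContrastiveBatch) -> float:
    """Mean NT-Xent loss over all 2N anchors (numpy, evaluation path)."""
    z = np.asarray(batch.vectors, dtype=float)
    n2 = z.shape[0]
    sims = _cosine_matrix(z) / batch.temperature
    np.fill_diagonal(sims, -np.inf)
    partner = np.arange(n2) ^ 1
    m = sims.max(axis=1, keepdims=True)
    lse = np.log(np.exp(sims - m).sum(axis=1)) + m[:, 0]
    losses = lse - sims[np.arange(n2), partner]
    return float(losses.mean())


def nt_xent_graph(z: Tensor, temperature: float) -> Tensor:
    """Differentiable NT-Xent over a (2N, d) latent Tensor.

    Same definition as :func:`nt_xent` but built on the autodiff graph
    for training; zero vectors are guarded by a tiny norm floor.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    n2 = z.shape[0]
    sq = ad.sum_(z * z, axis=1, keepdims=True)
    norm = ad.power(sq + ad.constant(1e-12), 0.5)
    zn = z / norm
    sims = (zn @ ad.transpose(zn, (1, 0))) * ad.constant(1.0 / temperature)
    diag = np.where(np.eye(n2, dtype=bool), -1e9, 0.0)
    sims = sims + ad.constant(diag)
    # stabilized log-sum-exp per row; the subtracted max is a constant
    m = ad.constant(sims.data.max(axis=1, keepdims=True))
    lse = ad.log(ad.sum_(ad.exp(sims - m), axis=1)) + ad.reshape(m, (n2,))
    partner = np.arange(n2) ^ 1
    pick = np.zeros((n2, n2))
    pick[np.arange(n2), partner] = 1.0
    pos = ad.sum_(sims * ad.constant(pick), axis=1)
    return ad.mean_(lse - pos)


def reconstruction_loss(probs: np.ndarray, targets: EncodedSequence) -> float:
    """Mean -log p(true token) over non-pad positions (numpy path).

    probs holds normalized rows (max_len x vocab); pad positions are
    excluded, so their content never influences the loss.
    """
    probs = np.asarray(probs, dtype=float)
    ids = targets.token_ids
    if ids.max() >= probs.shape[1] or ids.min() < 0:
        raise ValueError("target token index outside vocabulary range")
    keep = ~targets.pad_mask
    p = probs[np.arange(len(ids)), ids][keep]
    return float(-np.log(np.clip(p, 1e-300, None)).mean())


def reconstruction_loss_graph(logits: Tensor, target_ids: np.ndarray,
                              weights: np.ndarray) -> Tensor:
    """Differentiable masked token cross-entropy from logits."""
    return ad.cross_entropy_tokens(logits, target_ids, weights)


def total_loss(contrastive: float, reconstruction: float, cfg) -> float:
    """Weighted sum contrastive_weight*L_c + recon_weight*L_r."""
    return (cfg.contrastive_weight * contrastive
            + cfg.recon_weight * reconstruction)
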