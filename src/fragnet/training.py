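"""Dataset splitting, batching and the joint training loop.

Each training step draws a fresh pair of enumerated SMILES views per
molecule (canonical strings never enter training), encodes the 2N views
through the weight-shared encoder, applies the NT-Xent loss to the 2N
projections, and reconstructs each view from its own latent through the
unprojection head and masked decoder.  One Adam update is taken on the
weighted sum of the two losses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .model import FragNet, ModelConfig
from .objectives import nt_xent_graph, reconstruction_loss_graph
from .smiles_data import (MoleculeRecord, TokenVocabulary, encode_sequence,
                          sample_positive_pair)


def split_dataset(records: list[MoleculeRecord], train_fraction: float,
                  rng: np.random.Generator):
    """Seeded shuffle then split; train gets floor(fraction * n) records."""
    if not records:
        raise ValueError("cannot split an empty dataset")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    order = rng.permutation(len(records))
    n_train = int(np.floor(train_fraction * len(records)))
    shuffled = [records[i] for i in order]
    return shuffled[:n_train], shuffled[n_train:]


def make_batches(records: list, batch_size: int, rng: np.random.Generator,
                 drop_last: bool = True) -> list[list]:
    """Seeded shuffle into batches; incomplete tail dropped by default."""
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2 (NT-Xent needs a negative)")
    order = rng.permutation(len(records))
    shuffled = [records[i] for i in order]
    batches = [shuffled[i:i + batch_size]
               for i in range(0, len(shuffled), batch_size)]
    if drop_last and batches and len(batches[-1]) < batch_size:
        batches.pop()
    return batches


@dataclass
class TrainingMetrics:
    """Per-batch loss log; every value is finite and nonnegative."""

    rows: list[dict] = field(default_factory=list)

    def append(self, epoch: int, batch: int, contrastive: float,
               reconstruction: float, total: float) -> None:
        for v in (contrastive, reconstruction, total):
            if not np.isfinite(v):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} batch {batch}: "
                    f"c={contrastive} r={reconstruction} t={total}")
        self.rows.append(dict(epoch=epoch, batch=batch,
                              contrastive=contrastive,
                              reconstruction=reconstruction, total=total))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=[
                "epoch", "batch", "contrastive", "reconstruction", "total"])
            w.writeheader()
            w.writerows(self.rows)


class Adam:
    """Adam optimizer over a FragNet parameter dict."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _encode_views(batch: list[MoleculeRecord], vocab: TokenVocabulary,
                  max_len: int, rng: np.random.Generator):
    """Draw a positive pair per record; returns interleaved encoded views.

    Only enumerated (augmented) strings are encoded here — the training
    path never touches record.canonical_smiles as a model input.
    """
    ids, masks = [], []
    for rec in batch:
        pair = sample_positive_pair(rec, rng)
        for view in (pair.x_i, pair.x_j):
            seq = encode_sequence(view, vocab, max_len)
            ids.append(seq.token_ids)
            masks.append(seq.pad_mask)
    return np.stack(ids), np.stack(masks)


def train_step(batch: list[MoleculeRecord], model: FragNet,
               vocab: TokenVocabulary, optimizer: Adam,
               rng: np.random.Generator) -> tuple[float, float, float]:
    """One joint contrastive + reconstruction update; returns the losses."""
    if len(batch) < 2:
        raise ValueError("training batch needs at least 2 molecules")
    cfg = model.cfg
    ids, masks = _encode_views(batch, vocab, cfg.max_len, rng)

    model.zero_grad()
    h = model.encode(ids, masks, train=True, rng=rng)
    z = model.project(h, masks)
    l_con = nt_xent_graph(z, cfg.temperature)

    memory = model.unproject(z)
    logits = model.decode(memory, ids, train=True, rng=rng)
    # teacher forcing: position t predicts the token at t+1
    targets = np.roll(ids, -1, axis=1)
    targets[:, -1] = vocab.pad
    weights = np.zeros_like(ids, dtype=float)
    lengths = (~masks).sum(axis=1)
    for r, ln in enumerate(lengths):
        weights[r, :ln - 1] = 1.0
    l_rec = reconstruction_loss_graph(logits, targets, weights)

    total = l_con * ad.constant(cfg.contrastive_weight) \
        + l_rec * ad.constant(cfg.recon_weight)
    total.backward()
    optimizer.step()
    return float(l_con.data), float(l_rec.data), float(total.data)


def train(corpus: list[MoleculeRecord], cfg: ModelConfig,
          vocab: TokenVocabulary | None = None,
          max_steps: int | None = None,
          checkpoint_path: str | Path | None = None):
    """Train on fresh augmentations of the corpus; returns (model, vocab, metrics).

    Runs cfg.epochs passes (default 1, the one-shot regime); a master
    seed fans out into separate weight-init, shuffling and augmentation
    streams so runs are reproducible end to end.
    """
    if not corpus:
        raise ValueError("empty corpus")
    from .smiles_data import build_vocabulary
    master = np.random.SeedSequence(cfg.seed)
    s_init, s_shuffle, s_augment = master.spawn(3)
    if vocab is None:
        vocab = build_vocabulary(corpus, seed=cfg.seed)
    if cfg.vocab_size == 0:
        cfg.vocab_size = vocab.size
    if cfg.vocab_size < vocab.size:
        raise ValueError("config vocab_size smaller than actual vocabulary")
    model = FragNet(cfg, rng=np.random.default_rng(s_init))
    optimizer = Adam(model.params, lr=cfg.learning_rate)
    metrics = TrainingMetrics()
    rng_shuffle = np.random.default_rng(s_shuffle)
    rng_augment = np.random.default_rng(s_augment)
    step = 0
    done = False
    for epoch in range(cfg.epochs):
        batches = make_batches(corpus, cfg.batch_size, rng_shuffle,
                               drop_last=True)
        for b, batch in enumerate(batches):
            l_con, l_rec, l_tot = train_step(batch, model, vocab, optimizer,
                                             rng_augment)
            metrics.append(epoch, b, l_con, l_rec, l_tot)
            step += 1
            if max_steps is not None and step >= max_steps:
                done = True
                break
        if done:
            break
    if checkpoint_path is not None:
        model.save(checkpoint_path, vocab)
    return model, vocab, metrics
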