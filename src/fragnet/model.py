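"""The contrastive transformer autoencoder.

Pipeline: token embedding + sinusoidal positional encoding -> stack of
transformer encoder blocks -> per-position representation h (L x d_model)
-> 4-layer ReLU projection head -> latent z (d_model) -> mirrored
unprojection head -> decoder memory (L x d_model) -> causally masked
transformer decoder with cross-attention -> token logits.

The projection head ends in a ReLU, so latent coordinates are
nonnegative and can be exactly zero; latent sparsity diagnostics rely
on this.  One weight-shared encoder serves both augmented views of a
molecule (SimCLR convention).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .smiles_data import EncodedSequence, TokenVocabulary


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    d_model is both the embedding width and the latent dimensionality.
    proj_hidden gives the three hidden widths of the 4-layer projection
    head (input flatten -> h1 -> h2 -> h3 -> d_model); None selects a
    geometric taper [4*d_model, 2*d_model, d_model].
    """

    d_model: int = 64
    n_blocks: int = 4
    n_heads: int = 4
    max_len: int = 64
    vocab_size: int = 0
    dropout: float = 0.20
    temperature: float = 0.05
    batch_size: int = 8
    learning_rate: float = 1e-5
    ff_dim: int | None = None
    proj_hidden: list[int] | None = None
    recon_weight: float = 1.0
    contrastive_weight: float = 1.0
    epochs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ff_dim is None:
            self.ff_dim = 4 * self.d_model
        if self.proj_hidden is None:
            self.proj_hidden = [4 * self.d_model, 2 * self.d_model,
                                self.d_model]
        if len(self.proj_hidden) != 3:
            raise ValueError("proj_hidden needs exactly 3 hidden widths")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def positional_encoding(max_len: int, d_model: int) -> np.ndarray:
    """Sinusoidal position table: sin on even columns, cos on odd."""
    if max_len <= 0 or d_model <= 0 or d_model % 2:
        raise ValueError("max_len, d_model must be positive and d_model even")
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((max_len, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class FragNet:
    """Weight container plus forward passes for every stage."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        if cfg.vocab_size < 5:
            raise ValueError("vocab_size must cover the 4 specials plus tokens")
        self.cfg = cfg
        rng = rng or np.random.default_rng(cfg.seed)
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)

    # ---------------------------------------------------------------- init
    def _add(self, name: str, arr: np.ndarray) -> None:
        self.params[name] = Tensor(arr, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.cfg
        D, F, V, L = c.d_model, c.ff_dim, c.vocab_size, c.max_len
        self._add("tok_emb", rng.normal(0, 0.02, size=(V, D)))
        for side, nb in (("enc", c.n_blocks), ("dec", c.n_blocks)):
            for b in range(nb):
                p = f"{side}{b}"
                attns = ("self", "cross") if side == "dec" else ("self",)
                for a in attns:
                    for w in ("q", "k", "v", "o"):
                        self._add(f"{p}.{a}.W{w}", _glorot(rng, D, D))
                        self._add(f"{p}.{a}.b{w}", np.zeros(D))
                self._add(f"{p}.ff.W1", _glorot(rng, D, F))
                self._add(f"{p}.ff.b1", np.zeros(F))
                self._add(f"{p}.ff.W2", _glorot(rng, F, D))
                self._add(f"{p}.ff.b2", np.zeros(D))
                n_ln = 3 if side == "dec" else 2
                for ln in range(1, n_ln + 1):
                    self._add(f"{p}.ln{ln}.g", np.ones(D))
                    self._add(f"{p}.ln{ln}.b", np.zeros(D))
        widths = [L * D] + list(c.proj_hidden) + [D]
        for i in range(4):
            self._add(f"proj.W{i}", _glorot(rng, widths[i], widths[i + 1]))
            self._add(f"proj.b{i}", np.zeros(widths[i + 1]))
        uwidths = [D] + list(reversed(c.proj_hidden)) + [L * D]
        for i in range(4):
            self._add(f"unproj.W{i}", _glorot(rng, uwidths[i], uwidths[i + 1]))
            self._add(f"unproj.b{i}", np.zeros(uwidths[i + 1]))
        self._add("out.W", _glorot(rng, D, V))
        self._add("out.b", np.zeros(V))

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    # ------------------------------------------------------------ building
    def _attention(self, prefix: str, x: Tensor, kv: Tensor,
                   mask: np.ndarray | None, train: bool,
                   rng: np.random.Generator | None) -> Tensor:
        """Multi-head attention; mask is additive over (.., Lq, Lk) scores."""
        c = self.cfg
        H = c.n_heads
        dh = c.d_model // H
        B, Lq, D = x.shape
        Lk = kv.shape[1]
        p = self.params

        def heads(t: Tensor, L: int) -> Tensor:
            return ad.transpose(ad.reshape(t, (B, L, H, dh)), (0, 2, 1, 3))

        q = heads(x @ p[f"{prefix}.Wq"] + p[f"{prefix}.bq"], Lq)
        k = heads(kv @ p[f"{prefix}.Wk"] + p[f"{prefix}.bk"], Lk)
        v = heads(kv @ p[f"{prefix}.Wv"] + p[f"{prefix}.bv"], Lk)
        scores = (q @ ad.transpose(k, (0, 1, 3, 2))) * ad.constant(1 / np.sqrt(dh))
        if mask is not None:
            scores = scores + ad.constant(mask)
        attn = ad.softmax(scores, axis=-1)
        if train:
            attn = ad.dropout_mask(attn, c.dropout, rng)
        ctx = ad.reshape(ad.transpose(attn @ v, (0, 2, 1, 3)), (B, Lq, D))
        return ctx @ p[f"{prefix}.Wo"] + p[f"{prefix}.bo"]

    def _ff(self, prefix: str, x: Tensor, train: bool,
            rng: np.random.Generator | None) -> Tensor:
        p = self.params
        h = ad.relu(x @ p[f"{prefix}.W1"] + p[f"{prefix}.b1"])
        if train:
            h = ad.dropout_mask(h, self.cfg.dropout, rng)
        return h @ p[f"{prefix}.W2"] + p[f"{prefix}.b2"]

    def _ln(self, prefix: str, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.params[f"{prefix}.g"],
                             self.params[f"{prefix}.b"])

    def _embed(self, ids: np.ndarray, train: bool,
               rng: np.random.Generator | None) -> Tensor:
        L = ids.shape[1]
        pe = positional_encoding(L, self.cfg.d_model)
        x = ad.embedding(self.params["tok_emb"], ids) + ad.constant(pe)
        if train:
            x = ad.dropout_mask(x, self.cfg.dropout, rng)
        return x

    # ------------------------------------------------------------- forward
    def encode(self, ids: np.ndarray, pad_mask: np.ndarray,
               train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Token ids (B, L) -> representation h (B, L, d_model).

        Padded key positions are excluded from attention, so appending
        pads leaves the non-pad rows unchanged.
        """
        ids = np.atleast_2d(ids)
        pad_mask = np.atleast_2d(pad_mask)
        key_mask = np.where(pad_mask[:, None, None, :], -1e9, 0.0)
        x = self._embed(ids, train, rng)
        for b in range(self.cfg.n_blocks):
            p = f"enc{b}"
            a = self._attention(f"{p}.self", x, x, key_mask, train, rng)
            if train:
                a = ad.dropout_mask(a, self.cfg.dropout, rng)
            x = self._ln(f"{p}.ln1", x + a)
            f = self._ff(f"{p}.ff", x, train, rng)
            if train:
                f = ad.dropout_mask(f, self.cfg.dropout, rng)
            x = self._ln(f"{p}.ln2", x + f)
        return x

    def project(self, h: Tensor, pad_mask: np.ndarray) -> Tensor:
        """Representation (B, L, D) -> latent z (B, D), entries >= 0.

        Pad rows are zeroed before flattening so the latent does not
        depend on padding content; all four affine layers are followed
        by ReLU, the last one included.
        """
        pad_mask = np.atleast_2d(pad_mask)
        B, L, D = h.shape
        keep = (~pad_mask).astype(float)[:, :, None]
        x = ad.reshape(h * ad.constant(keep), (B, L * D))
        p = self.params
        for i in range(4):
            x = ad.relu(x @ p[f"proj.W{i}"] + p[f"proj.b{i}"])
        return x

    def unproject(self, z: Tensor) -> Tensor:
        """Latent (B, D) -> decoder memory (B, L, D); final layer linear."""
        p = self.params
        x = z
        for i in range(3):
            x = ad.relu(x @ p[f"unproj.W{i}"] + p[f"unproj.b{i}"])
        x = x @ p["unproj.W3"] + p["unproj.b3"]
        B = z.shape[0]
        return ad.reshape(x, (B, self.cfg.max_len, self.cfg.d_model))

    def decode(self, memory: Tensor, shifted_ids: np.ndarray,
               train: bool = False,
               rng: np.random.Generator | None = None,
               return_probs: bool = False) -> Tensor:
        """Teacher-forced decoder: logits (B, L, vocab) per position.

        shifted_ids start with the start token; a causal mask restricts
        self-attention to previous positions; cross-attention takes K,V
        from the unprojection memory.
        """
        shifted_ids = np.atleast_2d(shifted_ids)
        L = shifted_ids.shape[1]
        causal = np.where(np.triu(np.ones((L, L), dtype=bool), k=1),
                          -1e9, 0.0)[None, None]
        x = self._embed(shifted_ids, train, rng)
        for b in range(self.cfg.n_blocks):
            p = f"dec{b}"
            a = self._attention(f"{p}.self", x, x, causal, train, rng)
            if train:
                a = ad.dropout_mask(a, self.cfg.dropout, rng)
            x = self._ln(f"{p}.ln1", x + a)
            a = self._attention(f"{p}.cross", x, memory, None, train, rng)
            if train:
                a = ad.dropout_mask(a, self.cfg.dropout, rng)
            x = self._ln(f"{p}.ln2", x + a)
            f = self._ff(f"{p}.ff", x, train, rng)
            if train:
                f = ad.dropout_mask(f, self.cfg.dropout, rng)
            x = self._ln(f"{p}.ln3", x + f)
        logits = x @ self.params["out.W"] + self.params["out.b"]
        if return_probs:
            return ad.softmax(logits, axis=-1)
        return logits

    # ------------------------------------------------------- inference API
    def embed_sequence(self, seq: EncodedSequence) -> np.ndarray:
        """Latent vector of a single encoded sequence (evaluation mode)."""
        h = self.encode(seq.token_ids[None], seq.pad_mask[None])
        z = self.project(h, seq.pad_mask[None])
        return z.data[0]

    def greedy_decode(self, z: np.ndarray, vocab: TokenVocabulary) -> str:
        """Autoregressive argmax decoding from a latent vector.

        Stops at the first end token or at max_len; returns the token
        concatenation without specials.  The result is a token string
        and may or may not be a valid SMILES.
        """
        c = self.cfg
        memory = self.unproject(Tensor(np.atleast_2d(z)))
        ids = np.full((1, c.max_len), vocab.pad, dtype=np.int64)
        ids[0, 0] = vocab.start
        inv = {i: t for t, i in vocab.token_to_index.items()}
        out_tokens: list[str] = []
        for t in range(1, c.max_len):
            logits = self.decode(memory, ids[:, :t])
            nxt = int(np.argmax(logits.data[0, t - 1]))
            if nxt == vocab.end:
                break
            ids[0, t] = nxt
            out_tokens.append(inv.get(nxt, ""))
        return "".join(tok for tok in out_tokens
                       if tok not in {"<pad>", "<start>", "<end>", "<unk>"})

    # ----------------------------------------------------------- persisting
    def save(self, path: str | Path, vocab: TokenVocabulary) -> None:
        """Single-file checkpoint: weights + config + vocabulary (+hash)."""
        meta = {
            "config": self.cfg.to_dict(),
            "vocab": vocab.token_to_index,
            "vocab_hash": vocab.content_hash(),
        }
        arrays = {k: v.data for k, v in self.params.items()}
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> tuple["FragNet", TokenVocabulary]:
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = ModelConfig.from_dict(meta["config"])
            model = cls(cfg)
            for k in model.params:
                model.params[k] = Tensor(data[k], requires_grad=True)
        vocab = TokenVocabulary(token_to_index=meta["vocab"])
        if vocab.content_hash() != meta["vocab_hash"]:
            raise ValueError("checkpoint vocabulary hash mismatch")
        return model, vocab
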