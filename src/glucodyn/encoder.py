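"""Transformer encoder for tokenized CGM days.

Default architecture: 4 pre-norm blocks x 8 heads, d_model 128, GELU
feed-forward (d_ff = 4 x d_model), learned token embeddings plus fixed
sinusoidal positional encodings, and a linear masked-token prediction
head. Day embeddings are the mean of the 289 final-layer token states;
sample embeddings average a subject's day embeddings.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    Dropout,
    LayerNorm,
    Linear,
    Tensor,
    TransformerBlock,
    embedding,
    no_grad,
    sinusoidal_positions,
    softmax,
    take,
)
from .nn.autograd import softmax_cross_entropy
from .tokenizer import SEQ_LEN, MaskPlan, TokenSequence, TokenVocabulary
from .types import DayEmbedding, DayProfile, SampleEmbedding

__all__ = [
    "EncoderConfig",
    "CGMEncoder",
    "masked_lm_loss_from_probs",
    "sample_embedding",
    "positional_encoding",
]


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int = 4
    n_heads: int = 8
    d_model: int = 128
    d_ff: int = 512
    vocab_size: int = 263
    max_positions: int = SEQ_LEN
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    def checkpoint_id(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def positional_encoding(max_positions: int, d_model: int) -> np.ndarray:
    """Sinusoidal position matrix; see :func:`glucodyn.nn.sinusoidal_positions`."""
    return sinusoidal_positions(max_positions, d_model)


class CGMEncoder:
    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        self.token_emb = Tensor(
            rng.normal(0, 0.02, (config.vocab_size, d)).astype(np.float32), requires_grad=True
        )
        self.pos_enc = Tensor(positional_encoding(config.max_positions, d))
        self.blocks = [
            TransformerBlock(rng, d, config.n_heads, config.d_ff, config.dropout,
                             prefix=f"block{i}.")
            for i in range(config.n_layers)
        ]
        self.final_ln = LayerNorm(d, prefix="final_ln.")
        self.lm_head = Linear(rng, d, config.vocab_size, prefix="lm_head.")
        self.drop = Dropout(config.dropout)
        self.params: dict[str, Tensor] = {"token_emb": self.token_emb}
        for b in self.blocks:
            self.params.update(b.names)
        self.params.update(self.final_ln.names)
        self.params.update(self.lm_head.names)

    # -- forward --------------------------------------------------------
    def hidden_states(self, ids: np.ndarray, train: bool = False,
                      rng: np.random.Generator | None = None,
                      collect_attention: bool = False):
        """ids: (batch, 289) int array -> final-layer states (batch, 289, d)."""
        ids = np.atleast_2d(np.asarray(ids))
        if ids.shape[1] != self.config.max_positions:
            raise ValueError(
                f"sequence length {ids.shape[1]} != {self.config.max_positions}"
            )
        x = embedding(self.token_emb, ids) + self.pos_enc
        x = self.drop(x, train, rng)
        attention = []
        for block in self.blocks:
            if collect_attention:
                x, att = block(x, train=train, rng=rng, return_attention=True)
                attention.append(att)
            else:
                x = block(x, train=train, rng=rng)
        x = self.final_ln(x)
        if collect_attention:
            return x, attention
        return x

    def forward(self, seqs: list[TokenSequence], plans: list[MaskPlan],
                train: bool = False, rng: np.random.Generator | None = None):
        """Run masked sequences; returns (loss Tensor, logits at masked positions)."""
        ids = np.stack([s.token_ids for s in seqs])
        h = self.hidden_states(ids, train=train, rng=rng)
        b_idx = np.concatenate(
            [np.full(len(p.masked_positions), i) for i, p in enumerate(plans)]
        ).astype(np.int64)
        s_idx = np.concatenate([p.masked_positions for p in plans]).astype(np.int64)
        targets = np.concatenate([p.target_ids for p in plans]).astype(np.int64)
        if targets.size == 0:
            raise ValueError("masked-LM loss requires a non-empty mask plan")
        states = take(h, b_idx, s_idx)          # (n_masked, d)
        logits = self.lm_head(states)           # (n_masked, vocab)
        loss = softmax_cross_entropy(logits, targets)
        return loss, logits

    def predict_masked(self, seq: TokenSequence, plan: MaskPlan) -> np.ndarray:
        """q(.) rows over the vocabulary at each masked position (eval mode)."""
        with no_grad():
            h = self.hidden_states(seq.token_ids[None, :])
            states = take(h, np.zeros(len(plan.masked_positions), dtype=np.int64),
                          plan.masked_positions)
            probs = softmax(self.lm_head(states), axis=-1)
        return probs.data

    def attention_maps(self, seq: TokenSequence) -> list[np.ndarray]:
        """Per-layer (heads, 289, 289) row-stochastic attention matrices."""
        with no_grad():
            _, attention = self.hidden_states(seq.token_ids[None, :], collect_attention=True)
        return [a[0] for a in attention]

    # -- embeddings -----------------------------------------------------
    def day_embedding(self, seq: TokenSequence) -> DayEmbedding:
        """Mean of the 289 final-layer token states (eval mode)."""
        with no_grad():
            h = self.hidden_states(seq.token_ids[None, :])
        vec = h.data[0].mean(axis=0).astype(float)
        return DayEmbedding(vec, seq.subject_id, seq.date, self.config.checkpoint_id())

    def day_embeddings(self, seqs: list[TokenSequence], batch_size: int = 32
                       ) -> list[DayEmbedding]:
        out = []
        for start in range(0, len(seqs), batch_size):
            chunk = seqs[start:start + batch_size]
            ids = np.stack([s.token_ids for s in chunk])
            with no_grad():
                h = self.hidden_states(ids)
            means = h.data.mean(axis=1)
            for s, v in zip(chunk, means):
                out.append(DayEmbedding(v.astype(float), s.subject_id, s.date,
                                        self.config.checkpoint_id()))
        return out

    # -- checkpointing --------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz",
                 **{k: v.data for k, v in self.params.items()})
        sidecar = {
            "config": asdict(self.config),
            "checkpoint_id": self.config.checkpoint_id(),
            "format": "glucodyn-encoder-v1",
        }
        (directory / "checkpoint.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "CGMEncoder":
        directory = Path(directory)
        sidecar = json.loads((directory / "checkpoint.json").read_text())
        model = cls(EncoderConfig(**sidecar["config"]))
        with np.load(directory / "weights.npz") as arrs:
            for k, v in model.params.items():
                v.data = arrs[k].copy()
        return model

    def clone(self) -> "CGMEncoder":
        other = CGMEncoder(self.config)
        for k, v in self.params.items():
            other.params[k].data = v.data.copy()
        return other


def masked_lm_loss_from_probs(probs: np.ndarray, plan: MaskPlan) -> float:
    """-(1/|T_mask|) sum log q(true token), from explicit probability rows."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if len(plan.masked_positions) == 0:
        raise ValueError("mask plan is empty")
    if probs.shape[0] != len(plan.masked_positions):
        raise ValueError("one probability row per masked position required")
    if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("q rows must be probability distributions")
    p_true = probs[np.arange(probs.shape[0]), plan.target_ids]
    return float(-np.mean(np.log(p_true)))


def sample_embedding(days: list[DayEmbedding]) -> SampleEmbedding:
    """Component-wise mean of one subject's day embeddings."""
    if not days:
        raise ValueError("need at least one day embedding")
    subjects = {d.subject_id for d in days}
    if len(subjects) > 1:
        raise ValueError(f"day embeddings from mixed subjects: {sorted(subjects)}")
    mat = np.stack([d.vector for d in days])
    return SampleEmbedding(mat.mean(axis=0), days[0].subject_id, len(days),
                           days[0].checkpoint_id)
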