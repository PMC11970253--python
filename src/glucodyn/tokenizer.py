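"""Glucose tokenization and TF-IDF-weighted mask planning.

The vocabulary has 260 glucose tokens covering the clipped [40, 300] mg/dL
range at 1 mg/dL resolution: token ``i`` is the bin [40+i, 41+i) for
``i < 259`` and the top token 259 covers [299, 300] (300 shares the top
bin, so the 261 clipped integer values map onto 260 levels). Three special
tokens (PAD, CLS, MASK) complete the 263-id vocabulary. A tokenized day is
a length-289 sequence: CLS followed by 288 glucose/PAD tokens.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .types import (
    GLUCOSE_MAX,
    GLUCOSE_MIN,
    GRID_SLOTS,
    HYPER_THRESHOLD,
    HYPO_THRESHOLD,
    DayProfile,
)

__all__ = [
    "TokenVocabulary",
    "TokenSequence",
    "MaskPlan",
    "TfidfWeights",
    "tokenize_day",
    "detokenize",
    "tfidf_token_weights",
    "apply_masking",
    "DEFAULT_FRACTION_RANGE",
]

N_GLUCOSE_TOKENS = 260
SEQ_LEN = GRID_SLOTS + 1  # 289: CLS + 288 slots
DEFAULT_FRACTION_RANGE = (0.45, 0.60)
DEFAULT_ABNORMAL_BOOST = 2.0


@dataclass(frozen=True)
class TokenVocabulary:
    n_glucose: int = N_GLUCOSE_TOKENS
    pad_id: int = N_GLUCOSE_TOKENS
    cls_id: int = N_GLUCOSE_TOKENS + 1
    mask_id: int = N_GLUCOSE_TOKENS + 2

    @property
    def size(self) -> int:
        return self.n_glucose + 3

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset({self.pad_id, self.cls_id, self.mask_id})

    def id_of(self, glucose: float) -> int:
        """Glucose (mg/dL, clipped) -> token id; 300 shares the top bin."""
        g = min(max(float(glucose), GLUCOSE_MIN), GLUCOSE_MAX)
        return min(int(math.floor(g)) - int(GLUCOSE_MIN), self.n_glucose - 1)

    def level_of(self, token_id: int) -> float:
        """Token id -> representative glucose level (bin lower edge)."""
        if not (0 <= token_id < self.n_glucose):
            raise ValueError(f"token id {token_id} is not a glucose token")
        return GLUCOSE_MIN + token_id

    def ids_of(self, glucose: np.ndarray) -> np.ndarray:
        g = np.clip(np.asarray(glucose, dtype=float), GLUCOSE_MIN, GLUCOSE_MAX)
        return np.minimum(np.floor(g).astype(int) - int(GLUCOSE_MIN), self.n_glucose - 1)

    def is_hyper(self, token_id: int) -> bool:
        return token_id < self.n_glucose and self.level_of(token_id) > HYPER_THRESHOLD

    def is_hypo(self, token_id: int) -> bool:
        return token_id < self.n_glucose and self.level_of(token_id) < HYPO_THRESHOLD

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_glucose": self.n_glucose,
                "levels": {i: GLUCOSE_MIN + i for i in range(self.n_glucose)},
                "special": {"PAD": self.pad_id, "CLS": self.cls_id, "MASK": self.mask_id},
            }
        )


@dataclass
class TokenSequence:
    token_ids: np.ndarray  # length 289, position 0 is CLS
    subject_id: str = "?"
    date: object = None

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)
        if self.token_ids.shape != (SEQ_LEN,):
            raise ValueError(f"token sequence must have length {SEQ_LEN}")

    def __len__(self) -> int:
        return SEQ_LEN


@dataclass
class MaskPlan:
    masked_positions: np.ndarray   # positions in 1..288, sorted
    target_ids: np.ndarray         # true tokens at those positions
    mask_fraction: float           # |masked| / n maskable (non-PAD, non-CLS)

    def __post_init__(self):
        self.masked_positions = np.asarray(self.masked_positions, dtype=np.int64)
        self.target_ids = np.asarray(self.target_ids, dtype=np.int64)


def tokenize_day(day: DayProfile, vocab: TokenVocabulary) -> TokenSequence:
    ids = np.full(SEQ_LEN, vocab.pad_id, dtype=np.int64)
    ids[0] = vocab.cls_id
    present = day.present_mask
    ids[1:][present] = vocab.ids_of(day.values[present])
    return TokenSequence(ids, day.subject_id, day.date)


def detokenize(seq: TokenSequence, vocab: TokenVocabulary) -> DayProfile:
    import datetime as dt

    ids = seq.token_ids
    if ids[0] != vocab.cls_id:
        raise ValueError("sequence must start with CLS")
    body = ids[1:]
    bad = (body >= vocab.size) | (body == vocab.cls_id) | (body == vocab.mask_id) | (body < 0)
    if bad.any():
        raise ValueError(f"unknown or non-decodable token id at position {int(bad.argmax()) + 1}")
    values = np.full(GRID_SLOTS, np.nan)
    glucose = body < vocab.n_glucose
    values[glucose] = GLUCOSE_MIN + body[glucose]
    date = seq.date if seq.date is not None else dt.date(1970, 1, 1)
    return DayProfile(seq.subject_id, date, values, glucose)


class TfidfWeights:
    """Per-token masking weights: tf(token, day) x smoothed idf, with an
    abnormal-glycemia boost for hyper (>180) and hypo (<70) tokens."""

    def __init__(self, idf: np.ndarray, vocab: TokenVocabulary,
                 abnormal_boost: float = DEFAULT_ABNORMAL_BOOST):
        self.idf = np.asarray(idf, dtype=float)
        self.vocab = vocab
        self.abnormal_boost = float(abnormal_boost)
        boost = np.ones(vocab.size)
        for tid in range(vocab.n_glucose):
            level = GLUCOSE_MIN + tid
            if level > HYPER_THRESHOLD or level < HYPO_THRESHOLD:
                boost[tid] = self.abnormal_boost
        self._boost = boost

    def position_weights(self, seq: TokenSequence) -> np.ndarray:
        """Weight per position (length 289); 0 at CLS and PAD positions."""
        ids = seq.token_ids
        tf = np.bincount(ids, minlength=self.vocab.size).astype(float)
        w = tf[ids] * self.idf[ids] * self._boost[ids]
        w[0] = 0.0
        w[ids == self.vocab.pad_id] = 0.0
        return w


def tfidf_token_weights(
    corpus: list[TokenSequence],
    vocab: TokenVocabulary,
    abnormal_boost: float = DEFAULT_ABNORMAL_BOOST,
) -> TfidfWeights:
    """idf(token) = ln((1 + N) / (1 + df)) + 1 over the day corpus."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    n = len(corpus)
    df = np.zeros(vocab.size)
    for seq in corpus:
        df[np.unique(seq.token_ids)] += 1
    idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    return TfidfWeights(idf, vocab, abnormal_boost)


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Efraimidis-Spirakis reservoir keys: top-k of u^(1/w), w > 0."""
    pos = np.flatnonzero(weights > 0)
    if k >= pos.size:
        return pos
    u = rng.random(pos.size)
    keys = np.power(u, 1.0 / weights[pos])
    return pos[np.argpartition(-keys, k)[:k]]


def apply_masking(
    seq: TokenSequence,
    weights: TfidfWeights | np.ndarray,
    rng: np.random.Generator,
    fraction_range: tuple[float, float] = DEFAULT_FRACTION_RANGE,
    vocab: TokenVocabulary | None = None,
) -> tuple[TokenSequence, MaskPlan]:
    """Mask a weighted sample of non-PAD positions; returns the masked copy
    and a plan recording the truth.

    The target fraction is drawn uniformly from ``fraction_range`` per
    sequence; positions are drawn without replacement with probability
    proportional to their weights. Masked tokens are replaced by MASK.
    """
    lo, hi = fraction_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("fraction_range must satisfy 0 <= lo <= hi <= 1")
    if isinstance(weights, TfidfWeights):
        vocab = weights.vocab
        w = weights.position_weights(seq)
    else:
        if vocab is None:
            raise ValueError("vocab required when weights is a raw array")
        w = np.asarray(weights, dtype=float).copy()
        w[0] = 0.0
        w[seq.token_ids == vocab.pad_id] = 0.0
    maskable = int((w > 0).sum())
    if maskable == 0:
        raise ValueError("no maskable (non-PAD) positions")

    frac = rng.uniform(lo, hi)
    k = int(round(frac * maskable))
    if k == 0:
        plan = MaskPlan(np.array([], dtype=np.int64), np.array([], dtype=np.int64), 0.0)
        return TokenSequence(seq.token_ids.copy(), seq.subject_id, seq.date), plan

    chosen = np.sort(_weighted_sample_without_replacement(w, k, rng))
    masked_ids = seq.token_ids.copy()
    targets = masked_ids[chosen].copy()
    masked_ids[chosen] = vocab.mask_id
    plan = MaskPlan(chosen, targets, len(chosen) / maskable)
    return TokenSequence(masked_ids, seq.subject_id, seq.date), plan
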