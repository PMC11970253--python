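"""Self-supervised pretraining and masked-imputation evaluation.

The pretraining loop re-draws TF-IDF-weighted masks each epoch, tracks a
held-out validation loss under a fixed seeded masking, and retains the
best-validation weights. The imputation benchmark masks evaluation days
(random or contiguous-gap mode), decodes masked-token predictions back to
mg/dL, and reports MAE stratified by the true value's glycemic range
(hypo < 70, eu 70-180, hyper > 180) next to linear-interpolation and KNN
baselines.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoder import CGMEncoder, EncoderConfig
from .nn import Adam
from .tokenizer import (
    DEFAULT_FRACTION_RANGE,
    MaskPlan,
    TfidfWeights,
    TokenSequence,
    TokenVocabulary,
    apply_masking,
    tfidf_token_weights,
)
from .types import GRID_SLOTS, HYPER_THRESHOLD, HYPO_THRESHOLD, DayProfile

__all__ = [
    "PretrainRunConfig",
    "ImputationReport",
    "pretrain_loop",
    "baseline_impute_linear",
    "baseline_impute_knn",
    "evaluate_imputation",
    "mask_contiguous_gap",
]

log = logging.getLogger(__name__)

STRATA = ("hypo", "eu", "hyper")


@dataclass
class PretrainRunConfig:
    epochs: int = 5
    batch_size: int = 16
    learning_rate: float = 1e-3
    fraction_range: tuple[float, float] = DEFAULT_FRACTION_RANGE
    seed: int = 0
    val_fraction: float = 0.1
    warmup_steps: int = 20
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        lo, hi = self.fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("fraction_range must lie within (0, 1]")


def _epoch_batches(seqs, weights, rng, fraction_range, batch_size):
    order = rng.permutation(len(seqs))
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        batch, plans = [], []
        for i in idx:
            masked, plan = apply_masking(seqs[i], weights, rng, fraction_range)
            if len(plan.masked_positions) == 0:
                continue
            batch.append(masked)
            plans.append(plan)
        if batch:
            yield batch, plans


def _eval_loss(model, seqs, weights, fraction_range, seed, batch_size):
    rng = np.random.default_rng(seed)
    total, count = 0.0, 0
    from .nn import no_grad

    for batch, plans in _epoch_batches(seqs, weights, rng, fraction_range, batch_size):
        with no_grad():
            loss, _ = model.forward(batch, plans)
        n = sum(len(p.masked_positions) for p in plans)
        total += float(loss.data) * n
        count += n
    return total / max(count, 1)


def pretrain_loop(
    corpus: list[TokenSequence],
    config: PretrainRunConfig,
    encoder_config: EncoderConfig | None = None,
    vocab: TokenVocabulary | None = None,
) -> tuple[CGMEncoder, dict]:
    """Pretrain on a token corpus; returns (best model, history dict)."""
    if len(corpus) < config.batch_size:
        raise ValueError("corpus smaller than batch size")
    vocab = vocab or TokenVocabulary()
    encoder_config = encoder_config or EncoderConfig(seed=config.seed)
    model = CGMEncoder(encoder_config)
    weights = tfidf_token_weights(corpus, vocab)

    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * len(corpus))))
    order = rng.permutation(len(corpus))
    val = [corpus[i] for i in order[:n_val]]
    train = [corpus[i] for i in order[n_val:]]
    if not train:
        raise ValueError("no training sequences after validation split")

    opt = Adam(list(model.params.values()), lr=config.learning_rate,
               warmup_steps=config.warmup_steps)
    history = {"train_loss": [], "val_loss": [], "init_val_loss": None}
    history["init_val_loss"] = _eval_loss(
        model, val, weights, config.fraction_range, config.seed + 999, config.batch_size
    )

    best_val, best_state = np.inf, None
    for epoch in range(config.epochs):
        epoch_rng = np.random.default_rng(config.seed + 1 + epoch)
        losses = []
        for batch, plans in _epoch_batches(
            train, weights, epoch_rng, config.fraction_range, config.batch_size
        ):
            loss, _ = model.forward(batch, plans, train=True, rng=epoch_rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {float(loss.data)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss = _eval_loss(
            model, val, weights, config.fraction_range, config.seed + 999, config.batch_size
        )
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        log.info("epoch %d: train %.4f val %.4f", epoch, history["train_loss"][-1], val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = {k: v.data.copy() for k, v in model.params.items()}

    if best_state is not None:
        for k, v in model.params.items():
            v.data = best_state[k]
    history["best_val_loss"] = float(best_val)
    if config.checkpoint_dir is not None:
        model.save(config.checkpoint_dir)
        Path(config.checkpoint_dir, "history.json").write_text(json.dumps(history))
    return model, history


# -- baselines ----------------------------------------------------------

def baseline_impute_linear(values: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Linear interpolation between nearest present neighbours; boundary
    gaps take the nearest present value. Requires >= 2 anchors."""
    present = np.asarray(present, dtype=bool)
    if present.sum() < 2:
        raise ValueError("linear baseline needs at least 2 present anchor points")
    x = np.arange(len(values))
    return np.interp(x, x[present], np.asarray(values, dtype=float)[present])


def baseline_impute_knn(
    values: np.ndarray,
    present: np.ndarray,
    corpus: list[DayProfile],
    k: int = 5,
) -> np.ndarray:
    """Fill missing slots with the mean value of the k most similar corpus
    days (Euclidean distance on mutually present slots)."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    present = np.asarray(present, dtype=bool)
    values = np.asarray(values, dtype=float)
    out = values.copy()
    missing = ~present

    dists = []
    for day in corpus:
        both = present & day.present_mask
        if both.sum() == 0:
            dists.append(np.inf)
        else:
            d = values[both] - day.values[both]
            dists.append(float(np.sqrt(np.mean(d * d))))
    order = np.argsort(dists, kind="stable")[:k]

    for slot in np.flatnonzero(missing):
        donors = [corpus[i].values[slot] for i in order if corpus[i].present_mask[slot]]
        if donors:
            out[slot] = float(np.mean(donors))
        else:
            log.warning("KNN: no donor with slot %d present; falling back to linear", slot)
            out[slot] = baseline_impute_linear(values, present)[slot]
    return out


def mask_contiguous_gap(day: DayProfile, gap_slots: int, rng: np.random.Generator
                        ) -> np.ndarray:
    """Pick a contiguous run of `gap_slots` present slots to hide; returns
    the hidden slot indices."""
    present = day.present_mask
    starts = [
        s for s in range(GRID_SLOTS - gap_slots + 1)
        if present[s:s + gap_slots].all()
        and (s == 0 or present[s - 1]) and (s + gap_slots == GRID_SLOTS or present[s + gap_slots])
    ]
    if not starts:
        raise ValueError("no feasible contiguous gap placement")
    start = int(rng.choice(starts))
    return np.arange(start, start + gap_slots)


@dataclass
class ImputationReport:
    """Per-method, per-stratum mean absolute error in mg/dL."""

    mae: dict  # method -> {"hypo": float|nan, "eu": ..., "hyper": ..., "overall": float}
    n_values: dict  # stratum -> count of evaluated values
    mode: str = "random"
    per_day_mae: dict = field(default_factory=dict)  # method -> list of per-day MAE

    def to_json(self) -> str:
        def clean(x):
            return None if (isinstance(x, float) and not np.isfinite(x)) else x

        return json.dumps(
            {
                "mode": self.mode,
                "mae": {m: {k: clean(v) for k, v in d.items()} for m, d in self.mae.items()},
                "n_values": self.n_values,
            },
            indent=2,
        )


def _stratum(value: float) -> str:
    if value < HYPO_THRESHOLD:
        return "hypo"
    if value > HYPER_THRESHOLD:
        return "hyper"
    return "eu"


def model_impute(model: CGMEncoder, vocab: TokenVocabulary, day: DayProfile,
                 hidden_slots: np.ndarray, decoding: str = "argmax") -> np.ndarray:
    """Predict glucose at `hidden_slots` (0-based grid slots) from the rest."""
    from .tokenizer import tokenize_day

    seq = tokenize_day(day, vocab)
    ids = seq.token_ids.copy()
    positions = np.asarray(hidden_slots) + 1  # sequence positions
    targets = ids[positions].copy()
    ids[positions] = vocab.mask_id
    masked = TokenSequence(ids, seq.subject_id, seq.date)
    plan = MaskPlan(positions, targets, len(positions) / max(day.n_present, 1))
    probs = model.predict_masked(masked, plan)
    glucose_probs = probs[:, : vocab.n_glucose]
    if decoding == "argmax":
        pred_ids = glucose_probs.argmax(axis=1)
        return np.array([vocab.level_of(int(t)) for t in pred_ids])
    if decoding == "expectation":
        levels = np.arange(vocab.n_glucose) + 40.0
        p = glucose_probs / glucose_probs.sum(axis=1, keepdims=True)
        return p @ levels
    raise ValueError(f"unknown decoding {decoding!r}")


def evaluate_imputation(
    model: CGMEncoder,
    eval_days: list[DayProfile],
    vocab: TokenVocabulary | None = None,
    seed: int = 0,
    mode: str = "gap",
    gap_slots: int = 12,
    fraction_range: tuple[float, float] = DEFAULT_FRACTION_RANGE,
    knn_corpus: list[DayProfile] | None = None,
    knn_k: int = 5,
    decoding: str = "argmax",
) -> ImputationReport:
    """Hide values from fully observed regions of each day, impute with the
    model and both baselines, and report stratified MAE.

    ``mode='gap'`` hides one contiguous run of ``gap_slots`` present slots
    per day (device-dropout realism); ``mode='random'`` hides a random
    TF-IDF-style fraction drawn from ``fraction_range``.
    """
    if not eval_days:
        raise ValueError("need at least one evaluation day")
    vocab = vocab or TokenVocabulary()
    knn_corpus = knn_corpus if knn_corpus is not None else eval_days

    methods = ("model", "linear", "knn")
    errors = {m: {s: [] for s in STRATA} for m in methods}
    per_day = {m: [] for m in methods}

    for day in eval_days:
        # per-day stream keyed by day identity => report invariant to order
        key = zlib.crc32(f"{day.subject_id}|{day.date}".encode())
        rng = np.random.default_rng([seed, key])
        present_slots = np.flatnonzero(day.present_mask)
        if mode == "gap":
            hidden = mask_contiguous_gap(day, gap_slots, rng)
        elif mode == "random":
            frac = rng.uniform(*fraction_range)
            n_hide = max(1, int(round(frac * present_slots.size)))
            hidden = np.sort(rng.choice(present_slots, size=n_hide, replace=False))
        else:
            raise ValueError(f"unknown mode {mode!r}")

        truth = day.values[hidden]
        visible_mask = day.present_mask.copy()
        visible_mask[hidden] = False
        visible_values = np.where(visible_mask, day.values, np.nan)
        hidden_day = DayProfile(day.subject_id, day.date, visible_values, visible_mask)

        preds = {
            "model": model_impute(model, vocab, hidden_day, hidden, decoding=decoding),
            "linear": baseline_impute_linear(visible_values, visible_mask)[hidden],
            "knn": baseline_impute_knn(
                visible_values, visible_mask,
                [c for c in knn_corpus if c is not day], k=knn_k,
            )[hidden],
        }
        for m in methods:
            abs_err = np.abs(preds[m] - truth)
            per_day[m].append(float(abs_err.mean()))
            for e, t in zip(abs_err, truth):
                errors[m][_stratum(t)].append(float(e))

    mae, n_values = {}, {}
    for s in STRATA:
        n_values[s] = len(errors["model"][s])
    for m in methods:
        entry = {}
        allv = []
        for s in STRATA:
            entry[s] = float(np.mean(errors[m][s])) if errors[m][s] else float("nan")
            allv.extend(errors[m][s])
        entry["overall"] = float(np.mean(allv))
        mae[m] = entry
    return ImputationReport(mae, n_values, mode=mode, per_day_mae=per_day)
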