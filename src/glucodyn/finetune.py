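"""Supervised fine-tuning of the pretrained encoder.

A task-specific transformer block is appended after the pretrained stack
and a one-layer head maps the mean-pooled final states to label logits.
By default the first half of the pretrained blocks is frozen; the rest,
the task block, and the head are trained with cross-entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encoder import CGMEncoder
from .nn import Adam, Linear, Tensor, TransformerBlock, embedding, no_grad, softmax
from .nn.autograd import softmax_cross_entropy
from .tokenizer import TokenSequence

__all__ = [
    "TaskSpec",
    "FinetuneConfig",
    "ClassifierOutput",
    "SequenceClassifier",
    "finetune_classifier",
    "predict_labels",
    "evaluate_classifier",
]

log = logging.getLogger(__name__)


@dataclass
class TaskSpec:
    task_name: str
    label_set: tuple[str, ...]
    labels: dict[str, str]                       # subject_id -> label
    freeze_policy: tuple[int, ...] | None = None  # frozen pretrained block indices

    def __post_init__(self):
        if len(self.label_set) < 2:
            raise ValueError("need at least two labels")
        bad = set(self.labels.values()) - set(self.label_set)
        if bad:
            raise ValueError(f"labels outside label_set: {sorted(bad)}")

    def label_index(self, label: str) -> int:
        return self.label_set.index(label)


@dataclass
class FinetuneConfig:
    epochs: int = 8
    batch_size: int = 16
    learning_rate: float = 5e-4
    seed: int = 0
    class_weighting: bool = False


@dataclass
class ClassifierOutput:
    """Per-day predicted distributions plus subject-level aggregates."""

    day_probs: np.ndarray               # (n_days, n_classes)
    day_subjects: list[str]
    label_set: tuple[str, ...]
    subject_probs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        sums = self.day_probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("day distributions must sum to 1")
        if not self.subject_probs:
            for sid in sorted(set(self.day_subjects)):
                rows = self.day_probs[[i for i, s in enumerate(self.day_subjects) if s == sid]]
                self.subject_probs[sid] = rows.mean(axis=0)

    def day_labels(self) -> list[str]:
        return [self.label_set[i] for i in self.day_probs.argmax(axis=1)]

    def subject_labels(self) -> dict[str, str]:
        return {s: self.label_set[int(p.argmax())] for s, p in self.subject_probs.items()}


class SequenceClassifier:
    """Pretrained encoder + appended task block + linear head."""

    def __init__(self, encoder: CGMEncoder, n_classes: int, seed: int = 0,
                 freeze_blocks: tuple[int, ...] | None = None):
        self.encoder = encoder
        cfg = encoder.config
        if freeze_blocks is None:
            freeze_blocks = tuple(range(cfg.n_layers // 2))  # freeze blocks 0..n/2-1
        self.freeze_blocks = tuple(freeze_blocks)
        # mark frozen leaves so backprop stops below the first trainable layer;
        # the token embedding freezes with block 0 (it feeds only frozen blocks)
        for i in self.freeze_blocks:
            for t in self.encoder.blocks[i].names.values():
                t.requires_grad = False
        if 0 in self.freeze_blocks:
            self.encoder.params["token_emb"].requires_grad = False
        rng = np.random.default_rng(seed + 104729)
        self.task_block = TransformerBlock(
            rng, cfg.d_model, cfg.n_heads, cfg.d_ff, cfg.dropout, prefix="task_block."
        )
        self.head = Linear(rng, cfg.d_model, n_classes, prefix="head.")
        self.n_classes = n_classes

    def trainable_params(self) -> list[Tensor]:
        params = [t for t in self.encoder.params.values() if t.requires_grad]
        params += list(self.task_block.names.values()) + list(self.head.names.values())
        return params

    def logits(self, ids: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        h = self.encoder.hidden_states(ids, train=train, rng=rng)
        h = self.task_block(h, train=train, rng=rng)
        pooled = h.mean(axis=1)  # (batch, d)
        return self.head(pooled)

    def predict_probs(self, seqs: list[TokenSequence], batch_size: int = 32) -> np.ndarray:
        rows = []
        for start in range(0, len(seqs), batch_size):
            ids = np.stack([s.token_ids for s in seqs[start:start + batch_size]])
            with no_grad():
                p = softmax(self.logits(ids), axis=-1)
            rows.append(p.data)
        return np.concatenate(rows, axis=0)


def finetune_classifier(
    encoder: CGMEncoder,
    corpus: list[TokenSequence],
    task: TaskSpec,
    config: FinetuneConfig | None = None,
) -> tuple[SequenceClassifier, dict]:
    """Fine-tune on labeled days; every sequence's subject must be labeled."""
    config = config or FinetuneConfig()
    if not corpus:
        raise ValueError("labeled corpus is empty")
    unlabeled = sorted({s.subject_id for s in corpus} - set(task.labels))
    if unlabeled:
        raise ValueError(f"missing labels for subjects: {unlabeled[:5]}")

    model = SequenceClassifier(
        encoder.clone(), len(task.label_set), seed=config.seed,
        freeze_blocks=task.freeze_policy,
    )
    y = np.array([task.label_index(task.labels[s.subject_id]) for s in corpus])
    opt = Adam(model.trainable_params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": []}
    for epoch in range(config.epochs):
        order = rng.permutation(len(corpus))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            ids = np.stack([corpus[i].token_ids for i in idx])
            logits = model.logits(ids, train=True, rng=rng)
            loss = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite fine-tuning loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        log.info("finetune epoch %d: loss %.4f", epoch, history["train_loss"][-1])
    return model, history


def predict_labels(model: SequenceClassifier, seqs: list[TokenSequence],
                   label_set: tuple[str, ...]) -> ClassifierOutput:
    probs = model.predict_probs(seqs)
    return ClassifierOutput(probs, [s.subject_id for s in seqs], tuple(label_set))


def _binary_auroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-statistic AUROC with mid-ranked ties (Mann-Whitney)."""
    from scipy.stats import rankdata

    pos = truth.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """One-vs-rest ROC curve as (threshold, fpr, tpr) rows."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(np.asarray(truth, dtype=int), scores)
    return np.column_stack([thresholds, fpr, tpr])


def evaluate_classifier(output: ClassifierOutput, truth: dict[str, str],
                        level: str = "subject") -> dict:
    """Accuracy, per-class one-vs-rest AUROC, macro AUROC, precision/recall."""
    if level == "subject":
        subjects = sorted(output.subject_probs)
        probs = np.stack([output.subject_probs[s] for s in subjects])
        y_true = [truth[s] for s in subjects]
    else:
        probs = output.day_probs
        y_true = [truth[s] for s in output.day_subjects]

    labels = output.label_set
    y_idx = np.array([labels.index(t) for t in y_true])
    y_pred = probs.argmax(axis=1)
    accuracy = float((y_pred == y_idx).mean())

    auroc = {}
    for i, lab in enumerate(labels):
        is_lab = (y_idx == i).astype(int)
        if is_lab.sum() in (0, len(is_lab)):
            log.warning("AUROC undefined for class %s (single-class truth)", lab)
            auroc[lab] = None
            continue
        auroc[lab] = _binary_auroc(probs[:, i], is_lab)
    defined = [v for v in auroc.values() if v is not None]
    macro_auroc = float(np.mean(defined)) if defined else None

    precision, recall = {}, {}
    for i, lab in enumerate(labels):
        tp = int(((y_pred == i) & (y_idx == i)).sum())
        fp = int(((y_pred == i) & (y_idx != i)).sum())
        fn = int(((y_pred != i) & (y_idx == i)).sum())
        precision[lab] = tp / (tp + fp) if (tp + fp) else float("nan")
        recall[lab] = tp / (tp + fn) if (tp + fn) else float("nan")

    return {
        "accuracy": accuracy,
        "auroc_ovr": auroc,
        "macro_auroc": macro_auroc,
        "precision": precision,
        "recall": recall,
        "n": len(y_idx),
    }
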