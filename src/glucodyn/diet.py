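"""Postprandial glucose prediction from meal perturbations.

The model encodes a 128-d individual embedding into the recurrent state
of a gated (LSTM) cell, consumes one hour of pre-meal glucose together
with a pulse-encoded meal vector (teacher phase), then rolls forward
autoregressively for two hours feeding each predicted glucose value back
as the next input with zeroed meal rows. Trained by MSE against the
concatenation of pre-meal values 2..t and the observed postprandial
curve (length 3t - 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, LSTMCell, Linear, Tensor, concat, matmul, no_grad
from .types import GLUCOSE_MAX, GLUCOSE_MIN, MealDescriptor

__all__ = [
    "DietExample",
    "DietModelConfig",
    "DietModel",
    "encode_pulse",
    "build_input_matrix",
    "diet_loss",
    "train_diet",
    "perturb_in_silico",
    "postprandial_metrics",
    "DEFAULT_MEAL_SET",
]

log = logging.getLogger(__name__)

KCAL_PER_G = {"carb": 4.0, "protein": 4.0, "fat": 9.0}

# (name, carb/protein/fat energy ratios) — standard balanced meal first
DEFAULT_MEAL_SET = (
    ("standard", (0.50, 0.20, 0.30)),
    ("low_carb", (0.30, 0.30, 0.40)),
    ("high_protein", (0.40, 0.35, 0.25)),
    ("high_fat", (0.40, 0.15, 0.45)),
)


@dataclass
class DietExample:
    v_s: np.ndarray          # 128-d individual embedding
    pre_meal: np.ndarray     # G^B, t pre-meal glucose values (1 hour)
    meal: MealDescriptor
    target: np.ndarray       # Ĝ: concatenation of G^B[2..t] and postprandial G^P, length 3t-1

    def __post_init__(self):
        self.v_s = np.asarray(self.v_s, dtype=float)
        self.pre_meal = np.asarray(self.pre_meal, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        t = self.pre_meal.size
        if t < 2:
            raise ValueError("need t >= 2 pre-meal measurements")
        if self.target.size != 3 * t - 1:
            raise ValueError(f"target must have length 3t-1 = {3 * t - 1}")
        for arr in (self.pre_meal, self.target):
            if arr.min() < GLUCOSE_MIN or arr.max() > GLUCOSE_MAX:
                raise ValueError("glucose values must lie in [40, 300] mg/dL")

    @property
    def t(self) -> int:
        return self.pre_meal.size


@dataclass
class DietModelConfig:
    latent_dim: int = 32
    seed: int = 0
    # fixed reference scales for inputs (glucose stats set from training data)
    kcal_scale: float = 1000.0
    gram_scale: float = 100.0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


def encode_pulse(meal: MealDescriptor, t: int) -> np.ndarray:
    """Pulse matrix D-hat (5 x t): column t holds D, all others zero."""
    if t < 1:
        raise ValueError("t must be >= 1")
    d = meal.as_vector()
    out = np.zeros((5, t))
    out[:, t - 1] = d
    return out


def build_input_matrix(pre_meal: np.ndarray, pulse: np.ndarray) -> np.ndarray:
    """T (6 x t): row 1 is G^B, rows 2-6 the meal pulse."""
    pre_meal = np.asarray(pre_meal, dtype=float)
    pulse = np.asarray(pulse, dtype=float)
    if pulse.shape != (5, pre_meal.size):
        raise ValueError(f"pulse shape {pulse.shape} inconsistent with t={pre_meal.size}")
    return np.vstack([pre_meal[None, :], pulse])


class DietModel:
    """f_enc (128 -> l) + LSTM over 6-row input columns + f_dec (l -> 1)."""

    def __init__(self, config: DietModelConfig, embed_dim: int = 128):
        self.config = config
        rng = np.random.default_rng(config.seed)
        l = config.latent_dim
        self.f_enc = Linear(rng, embed_dim, l, std=0.1, prefix="f_enc.")
        self.cell = LSTMCell(rng, 6, l, prefix="lstm.")
        self.f_dec = Linear(rng, l, 1, std=0.1, prefix="f_dec.")
        self.params = {**self.f_enc.names, **self.cell.names, **self.f_dec.names}
        # glucose standardization constants (set by train_diet)
        self.g_mean = 120.0
        self.g_sd = 40.0

    def _scale_columns(self, T: np.ndarray) -> np.ndarray:
        s = T.copy().astype(float)
        s[0] = (s[0] - self.g_mean) / self.g_sd
        s[1] = s[1] / self.config.kcal_scale
        s[2:] = s[2:] / self.config.gram_scale
        return s

    def forward_batch(self, v_s: np.ndarray, T: np.ndarray):
        """Roll the cell through the t teacher columns then 2t autoregressive
        steps for a batch.

        v_s: (n, embed_dim); T: (n, 6, t). Returns g_pred Tensor (n, 3t-1)
        holding g_2..g_{3t} in mg/dL.
        """
        v_s = np.atleast_2d(np.asarray(v_s, dtype=np.float32))
        T = np.asarray(T, dtype=float)
        if T.ndim == 2:
            T = T[None, :, :]
        n, rows, t = T.shape
        if rows != 6:
            raise ValueError("input matrix must have 6 rows")
        Ts = np.stack([self._scale_columns(T[i]) for i in range(n)]).astype(np.float32)
        l = self.config.latent_dim

        h = self.f_enc(Tensor(v_s))  # v_1 (n, l)
        c = Tensor(np.zeros((n, l), dtype=np.float32))
        outputs = []  # o_2 .. o_{3t}
        for k in range(t):  # teacher phase: observed columns 1..t
            x = Tensor(Ts[:, :, k])
            h, c = self.cell(x, h, c)
            outputs.append(h)
        zeros = Tensor(np.zeros((n, 5), dtype=np.float32))
        for _ in range(t, 3 * t):  # autoregressive phase: feed back decoded glucose
            g_prev = self.f_dec(outputs[-1])  # (n, 1), standardized scale
            x = concat([g_prev, zeros], axis=1)
            h, c = self.cell(x, h, c)
            outputs.append(h)
        del outputs[-1]  # o_{3t+1} never decoded
        states = concat([o.reshape(n, 1, l) for o in outputs], axis=1)  # (n, 3t-1, l)
        # decoder works on the standardized scale; de-standardize to mg/dL
        g_pred = (self.f_dec(states).reshape(n, 3 * t - 1) * self.g_sd) + self.g_mean
        if not np.all(np.isfinite(g_pred.data)):
            bad = int(np.flatnonzero((~np.isfinite(g_pred.data)).any(axis=0))[0])
            raise FloatingPointError(f"non-finite rollout state at step {bad + 2}")
        return g_pred

    def forward(self, v_s: np.ndarray, T: np.ndarray):
        """Single-example rollout; returns g_pred Tensor of length 3t-1."""
        t = np.asarray(T).shape[-1]
        return self.forward_batch(v_s, T).reshape(3 * t - 1)

    def predict(self, v_s: np.ndarray, pre_meal: np.ndarray, meal: MealDescriptor,
                clip: bool = True) -> dict:
        """Predict; returns dict with 'g_pred' (3t-1) and 'postprandial' (2t)."""
        t = len(pre_meal)
        T = build_input_matrix(pre_meal, encode_pulse(meal, t))
        with no_grad():
            g_pred = self.forward(v_s, T).data.astype(float)
        post = g_pred[t - 1:]
        if clip:
            g_pred = np.clip(g_pred, GLUCOSE_MIN, GLUCOSE_MAX)
            post = np.clip(post, GLUCOSE_MIN, GLUCOSE_MAX)
        return {"g_pred": g_pred, "postprandial": post}


def diet_loss(predictions, example: DietExample):
    """MSE over all 3t-1 positions of Ĝ (teacher positions 2..t included)."""
    target = example.target
    if isinstance(predictions, Tensor):
        if predictions.data.size != target.size:
            raise ValueError("prediction/target length mismatch")
        diff = predictions - Tensor(target.astype(np.float32))
        return (diff * diff).mean()
    predictions = np.asarray(predictions, dtype=float)
    if predictions.size != target.size:
        raise ValueError("prediction/target length mismatch")
    return float(np.mean((predictions - target) ** 2))


def train_diet(
    examples: list[DietExample],
    config: DietModelConfig | None = None,
    epochs: int = 200,
    learning_rate: float = 1e-2,
    batch_size: int = 32,
    val_fraction: float = 0.2,
    min_examples: int = 10,
    seed: int | None = None,
) -> tuple[DietModel, dict]:
    """Train on meal examples; retains best-validation weights."""
    if len(examples) < min_examples:
        raise ValueError(f"need at least {min_examples} examples")
    config = config or DietModelConfig()
    if seed is not None:
        config = DietModelConfig(config.latent_dim, seed, config.kcal_scale, config.gram_scale)
    model = DietModel(config, embed_dim=examples[0].v_s.size)
    all_g = np.concatenate([ex.pre_meal for ex in examples])
    model.g_mean = float(all_g.mean())
    model.g_sd = float(max(all_g.std(ddof=0), 1.0))

    t = examples[0].t
    if any(ex.t != t for ex in examples):
        raise ValueError("all examples must share the same t")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(examples))
    n_val = int(round(val_fraction * len(examples)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = order, order[:0]

    V = np.stack([ex.v_s for ex in examples])
    T = np.stack([
        build_input_matrix(ex.pre_meal, encode_pulse(ex.meal, ex.t)) for ex in examples
    ])
    Y = np.stack([ex.target for ex in examples]).astype(np.float32)
    opt = Adam(list(model.params.values()), lr=learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state = np.inf, None
    for epoch in range(epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, perm.size, batch_size):
            idx = perm[start:start + batch_size]
            pred = model.forward_batch(V[idx], T[idx])
            diff = pred - Tensor(Y[idx])
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite diet loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if val_idx.size:
            with no_grad():
                vp = model.forward_batch(V[val_idx], T[val_idx])
                vloss = float(np.mean((vp.data - Y[val_idx]) ** 2))
        else:
            vloss = history["train_loss"][-1]
        history["val_loss"].append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_state = {k: v.data.copy() for k, v in model.params.items()}
    if best_state is not None:
        for k, v in model.params.items():
            v.data = best_state[k]
    history["best_val_loss"] = float(best_val)
    return model, history


def build_examples(
    days,
    meal_log,
    embeddings: dict,
    interval_minutes: float = 15.0,
) -> list[DietExample]:
    """Align meal events with (downsampled) day profiles into training examples.

    ``days``: DayProfile list on the 5-minute grid; ``meal_log``: MealEvent
    list; ``embeddings``: subject_id -> individual embedding vector. The
    pre-meal hour and 2-h postprandial window must be fully present at the
    device interval, else the meal is dropped (logged).
    """
    t = int(round(60 / interval_minutes))
    step = int(interval_minutes // 5)
    day_index = {(d.subject_id, d.date): d for d in days}
    examples = []
    for ev in meal_log:
        key = (ev.subject_id, ev.timestamp.date())
        if key not in day_index or ev.subject_id not in embeddings:
            continue
        day = day_index[key]
        meal_minute = ev.timestamp.hour * 60 + ev.timestamp.minute
        # snap the meal to the nearest device-grid point
        slot = int(round(meal_minute / interval_minutes)) * step
        pre_slots = np.arange(slot - (t - 1) * step, slot + 1, step)
        post_slots = np.arange(slot + step, slot + 2 * t * step + 1, step)
        if pre_slots.min() < 0 or post_slots.max() >= day.values.size:
            continue
        if not (day.present_mask[pre_slots].all() and day.present_mask[post_slots].all()):
            log.info("dropping meal at %s: observation window incomplete", ev.timestamp)
            continue
        pre = day.values[pre_slots]
        post = day.values[post_slots]
        examples.append(DietExample(
            np.asarray(embeddings[ev.subject_id], dtype=float), pre, ev.meal,
            np.concatenate([pre[1:], post]),
        ))
    return examples


def postprandial_metrics(curve: np.ndarray, interval_minutes: float) -> dict:
    """Mean, PG120 (last value of the 2-h window), Max, SD, and trapezoidal
    AUC of a postprandial curve."""
    curve = np.asarray(curve, dtype=float)
    minutes = (np.arange(curve.size) + 1) * interval_minutes
    return {
        "Mean": float(curve.mean()),
        "PG120": float(curve[-1]),
        "Max": float(curve.max()),
        "SD": float(curve.std(ddof=0)),
        "AUC": float(np.trapezoid(curve, minutes)),
    }


def meal_from_ratios(kcal: float, ratios: tuple[float, float, float],
                     fiber_g: float = 0.0) -> MealDescriptor:
    """Grams from energy ratios via 4/4/9 kcal per gram."""
    if abs(sum(ratios) - 1.0) > 1e-6:
        raise ValueError(f"energy ratios must sum to 1, got {sum(ratios)}")
    c, p, f = ratios
    return MealDescriptor(
        kcal,
        kcal * c / KCAL_PER_G["carb"],
        kcal * p / KCAL_PER_G["protein"],
        kcal * f / KCAL_PER_G["fat"],
        fiber_g,
    )


def perturb_in_silico(
    model: DietModel,
    v_s: np.ndarray,
    pre_meal: np.ndarray,
    kcal: float,
    meal_set=DEFAULT_MEAL_SET,
    interval_minutes: float = 15.0,
) -> dict:
    """Predict the postprandial curve for each simulated meal and the rate of
    change of each metric relative to the standard (first) meal."""
    names = [name for name, _ in meal_set]
    if not names:
        raise ValueError("meal_set is empty")
    results = {}
    for name, ratios in meal_set:
        meal = meal_from_ratios(kcal, ratios)
        out = model.predict(v_s, pre_meal, meal)
        results[name] = {
            "ratios": tuple(ratios),
            "curve": out["postprandial"],
            "metrics": postprandial_metrics(out["postprandial"], interval_minutes),
        }
    std = results[names[0]]["metrics"]
    for name in names:
        m = results[name]["metrics"]
        results[name]["rate_of_change"] = {
            k: (m[k] - std[k]) / std[k] if std[k] != 0 else float("nan") for k in m
        }
    return results
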