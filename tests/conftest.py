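import numpy as np
import pytest

from glucodyn.simulate import simulate_cohort
from glucodyn.tokenizer import TokenVocabulary, tokenize_day
from glucodyn.types import DayProfile, MealDescriptor


@pytest.fixture(scope="session")
def vocab():
    return TokenVocabulary()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(6, 2, seed=11)


@pytest.fixture(scope="session")
def small_corpus(small_cohort, vocab):
    return [tokenize_day(d, vocab) for d in small_cohort.days]


@pytest.fixture()
def constant_day():
    values = np.full(288, 100.0)
    return DayProfile.from_values("const", __import__("datetime").date(2024, 1, 1), values)


def make_planted_diet_cohort(n_subjects=30, meals_per_subject=12, seed=1,
                             alpha=0.6, peak_noise_sd=2.0, obs_noise_sd=2.0,
                             holdout_per_subject=2):
    """Synthetic diet examples with a planted carbohydrate effect:
    postprandial peak = alpha * carb_g + N(0, peak_noise_sd). Embeddings are
    shared per subject; the last meals of each subject are held out."""
    from glucodyn.diet import DietExample

    rng = np.random.default_rng(seed)
    train, held = [], []
    for _ in range(n_subjects):
        v = rng.normal(size=128) * 0.5
        base = rng.uniform(95, 135)
        for j in range(meals_per_subject):
            pre = np.clip(base + np.cumsum(rng.normal(0, 1.0, 4)), 60, 250)
            kcal = rng.uniform(400, 800)
            carb_ratio = rng.uniform(0.15, 0.75)
            meal = MealDescriptor(
                kcal,
                kcal * carb_ratio / 4.0,
                kcal * 0.2 / 4.0,
                kcal * max(0.85 - carb_ratio, 0.05) / 9.0,
                3.0,
            )
            peak = alpha * meal.carb_g + rng.normal(0, peak_noise_sd)
            tgrid = np.arange(1, 9) / 8.0
            shape = np.sin(np.pi * np.minimum(tgrid * 1.4, 1.0))
            post = np.clip(pre[-1] + peak * shape + rng.normal(0, obs_noise_sd, 8), 40, 300)
            target = np.clip(np.concatenate([pre[1:], post]), 40, 300)
            ex = DietExample(v, pre, meal, target)
            if j >= meals_per_subject - holdout_per_subject:
                held.append(ex)
            else:
                train.append(ex)
    return train, held


# ---------------------------------------------------------------------------
# Shared heavy fixture: one desk-scale pretraining run reused by the
# pretraining/fine-tuning acceptance tests and the embedding property tests.
# ---------------------------------------------------------------------------

PRETRAIN_COHORT_SEED = 42
PRETRAIN_SEED = 0


@pytest.fixture(scope="session")
def pretrain_cohort():
    # 3 archetypes x 125 subjects x 4 days = 1500 days
    return simulate_cohort(125, 4, seed=PRETRAIN_COHORT_SEED)


@pytest.fixture(scope="session")
def pretrained(pretrain_cohort, vocab):
    """(model, history, corpus). Desk-scale masked-token pretraining."""
    from glucodyn.pretrain import PretrainRunConfig, pretrain_loop

    corpus = [tokenize_day(d, vocab) for d in pretrain_cohort.days]
    # settings calibrated to the 1-CPU suite budget: 3 epochs at lr 3e-3
    # reach ~30% validation-loss reduction and a gap-imputation model that
    # beats linear interpolation on 3-hour dropout gaps
    config = PretrainRunConfig(epochs=3, batch_size=32, learning_rate=3e-3,
                               warmup_steps=30, seed=PRETRAIN_SEED)
    model, history = pretrain_loop(corpus, config, vocab=vocab)
    return model, history, corpus
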