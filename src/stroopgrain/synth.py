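"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates the empirical design: 151 participants in two
counterbalancing groups, four blocks of 48 standard Stroop trials and
four blocks of 48 emotional Stroop trials each (16 positive, 16
negative, 16 neutral words per block), a 2-second response window, and
trial RTs drawn from a gamma distribution whose mean follows the
identity-link fixed-effect structure of the reaction-time models
(congruency, brooding and counterbalancing interactions, sex, age, an
English-as-second-language offset) plus a participant random intercept.
Trait brooding is simulated as the sum of five 1-4 Likert items driven
by a participant-level latent trait, giving integer scores in 5-20.

It deliberately does not emulate sequential RT dynamics, practice or
block-position effects, or the subjective side of the rumination
induction; conclusions from synthetic cohorts are about the analysis
pipeline, not about participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .fitting import ModelVariant, ParameterBounds, ParameterVector, VARIANTS

__all__ = [
    "CohortConfig",
    "gen_cohort",
    "gen_wordbank",
    "gen_model_cohort",
    "RESPONSE_WINDOW_MS",
]

RESPONSE_WINDOW_MS = 2000.0


@dataclass
class CohortConfig:
    """Generative settings for a synthetic behavioural cohort.

    The default fixed effects are the reference effect sizes for a
    realistic standard-Stroop cohort: congruency 89.69 ms, congruency x
    brooding 7.47, counterbalancing x congruency x brooding -4.27, with
    the intercept placed so marginal condition means land near
    ~805 / ~960 ms.  The valence slope defaults to zero (emotional-task
    RTs typically show no reliable valence effect at this design size)
    and the English-as-second-language offset to -67.77 ms.
    """

    n_participants: int = 151
    blocks: int = 4
    trials_per_block: int = 48
    # fixed effects, ms (identity link)
    intercept: float = 800.0
    beta_cb: float = 0.0
    beta_congruency: float = 89.69
    beta_brooding: float = 2.0
    beta_cb_congruency: float = 0.0
    beta_cb_brooding: float = 0.0
    beta_congruency_brooding: float = 7.47
    beta_cb_congruency_brooding: float = -4.27
    beta_sex: float = 10.0
    beta_age: float = 0.5
    valence_slope: float = 0.0
    esl_offset: float = -67.77
    # random structure / noise
    random_intercept_sd: float = 70.0
    random_congruency_slope_sd: float = 0.0
    gamma_shape: float = 12.0
    # demographics
    p_male: float = 0.54
    p_esl: float = 0.6
    # accuracy rates by condition (used for filter testing only)
    p_correct: dict = field(
        default_factory=lambda: {
            "congruent": 0.95,
            "incongruent": 0.88,
            "emotional": 0.94,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.random_intercept_sd < 0 or self.random_congruency_slope_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


# ---------------------------------------------------------------------------
# Word bank
# ---------------------------------------------------------------------------

_NEGATIVE_WORDS = [
    "hostile", "greedy", "rude", "cruel", "selfish", "dishonest", "spiteful",
    "arrogant", "jealous", "deceitful", "vicious", "bitter", "callous",
    "petty", "hateful", "malicious",
]
_POSITIVE_WORDS = [
    "sincere", "honest", "kind", "loyal", "friendly", "generous", "warm",
    "cheerful", "gentle", "thoughtful", "helpful", "patient", "truthful",
    "trustworthy", "considerate", "goodnatured",
]
_NEUTRAL_WORDS = [
    "chair", "table", "window", "bottle", "spoon", "carpet", "pencil",
    "drawer", "kettle", "ladder", "curtain", "basket", "mirror", "candle",
    "hammer", "button",
]


def gen_wordbank(source=None) -> pd.DataFrame:
    """Word bank with per-word continuous valence scores in [-1, 1].

    With no ``source``, returns the built-in synthetic stand-in bank: 16
    negative and 16 positive personality-trait words and 16 neutral
    object words, with deterministic synthetic valence scores (negative
    words in [-0.8, -0.3], positive in [0.3, 0.8], neutral within
    [-0.1, 0.1]).  When a CSV path with columns word, category,
    valence_score is supplied, it is parsed and validated instead.
    """
    if source is not None:
        bank = pd.read_csv(source)
        required = {"word", "category", "valence_score"}
        if not required.issubset(bank.columns):
            raise ValueError(f"word bank file must have columns {sorted(required)}")
        counts = bank["category"].value_counts()
        for cat in ("negative", "neutral", "positive"):
            if counts.get(cat, 0) != 16:
                raise ValueError(
                    f"word bank must contain 16 {cat} words, got {counts.get(cat, 0)}"
                )
        bad = bank[(bank["valence_score"] < -1) | (bank["valence_score"] > 1)]
        if len(bad):
            raise ValueError("valence scores must lie in [-1, 1]")
        return bank.reset_index(drop=True)

    rng = np.random.default_rng(20240817)  # fixed: the bank is a constant
    rows = []
    for w in _NEGATIVE_WORDS:
        rows.append((w, "negative", round(float(rng.uniform(-0.8, -0.3)), 4)))
    for w in _NEUTRAL_WORDS:
        rows.append((w, "neutral", round(float(rng.uniform(-0.1, 0.1)), 4)))
    for w in _POSITIVE_WORDS:
        rows.append((w, "positive", round(float(rng.uniform(0.3, 0.8)), 4)))
    return pd.DataFrame(rows, columns=["word", "category", "valence_score"])


# ---------------------------------------------------------------------------
# Behavioural cohort
# ---------------------------------------------------------------------------


def _gen_participants(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    pid = np.arange(1, n + 1)
    cb = np.where(pid % 2 == 1, 1, 2)  # interleaved: 76/75 at n=151
    latent = rng.normal(size=n)
    p_item = expit(0.7 * latent - 0.2)
    items = rng.binomial(3, p_item[:, None], size=(n, 5))
    brooding = 5 + items.sum(axis=1)
    sex = rng.binomial(1, cfg.p_male, size=n)
    age = np.clip(18 + rng.gamma(2.0, 8.0, size=n), 18, 72).astype(int)
    esl = rng.binomial(1, cfg.p_esl, size=n)
    u = rng.normal(0.0, cfg.random_intercept_sd, size=n)
    slope_u = rng.normal(0.0, cfg.random_congruency_slope_sd, size=n)
    return pd.DataFrame(
        {
            "pid": pid,
            "cb": cb,
            "brooding": brooding,
            "sex": sex,
            "age": age,
            "esl": esl,
            "u": u,
            "slope_u": slope_u,
        }
    )


def gen_cohort(cfg: CohortConfig | None = None):
    """Generate ``(participants, trials)`` tables for one synthetic cohort.

    Trial RTs are gamma with fixed shape and mean equal to the
    identity-link linear predictor; draws beyond the 2-s response
    window become overtime outcomes (no RT), and correctness is
    simulated with condition-dependent rates.  Fully determined by
    ``cfg.seed``.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 11]))
    participants = _gen_participants(cfg, rng)
    bank = gen_wordbank()
    by_cat = {c: g["word"].tolist() for c, g in bank.groupby("category")}
    valence_of = dict(zip(bank["word"], bank["valence_score"]))

    n_per_val = cfg.trials_per_block // 3
    rows = []
    for p in participants.itertuples(index=False):
        cb2 = 1.0 if p.cb == 2 else 0.0
        base_mu = (
            cfg.intercept
            + cfg.beta_cb * cb2
            + cfg.beta_brooding * p.brooding
            + cfg.beta_cb_brooding * cb2 * p.brooding
            + cfg.beta_sex * p.sex
            + cfg.beta_age * p.age
            + cfg.esl_offset * p.esl
            + p.u
        )
        cong_delta = (
            cfg.beta_congruency
            + cfg.beta_cb_congruency * cb2
            + cfg.beta_congruency_brooding * p.brooding
            + cfg.beta_cb_congruency_brooding * cb2 * p.brooding
            + p.slope_u
        )
        # standard task
        for block in range(1, cfg.blocks + 1):
            half = cfg.trials_per_block // 2
            congs = np.array([1] * half + [0] * (cfg.trials_per_block - half))
            rng.shuffle(congs)
            for t, cong in enumerate(congs, start=1):
                mu = base_mu + cong_delta * cong
                if mu <= 0:
                    raise ValueError(
                        "linear predictor <= 0; rescale effects or intercept"
                    )
                rt = rng.gamma(cfg.gamma_shape, mu / cfg.gamma_shape)
                label = "incongruent" if cong else "congruent"
                if rt > RESPONSE_WINDOW_MS:
                    outcome, rt_ms = "overtime", np.nan
                else:
                    correct = rng.random() < cfg.p_correct[label]
                    outcome, rt_ms = ("correct" if correct else "incorrect"), rt
                rows.append(
                    (p.pid, p.cb, "standard", block, t, label, None, np.nan,
                     rt_ms, outcome, p.sex, p.age, p.esl, p.brooding)
                )
        # emotional task
        for block in range(1, cfg.blocks + 1):
            words = []
            for cat in ("positive", "negative", "neutral"):
                words.extend(rng.choice(by_cat[cat], size=n_per_val, replace=False))
            rng.shuffle(words)
            for t, word in enumerate(words, start=1):
                v = valence_of[word]
                mu = base_mu + cfg.valence_slope * v
                if mu <= 0:
                    raise ValueError(
                        "linear predictor <= 0; rescale effects or intercept"
                    )
                rt = rng.gamma(cfg.gamma_shape, mu / cfg.gamma_shape)
                if rt > RESPONSE_WINDOW_MS:
                    outcome, rt_ms = "overtime", np.nan
                else:
                    correct = rng.random() < cfg.p_correct["emotional"]
                    outcome, rt_ms = ("correct" if correct else "incorrect"), rt
                rows.append(
                    (p.pid, p.cb, "emotional", block, t, None, word, v,
                     rt_ms, outcome, p.sex, p.age, p.esl, p.brooding)
                )

    trials = pd.DataFrame(
        rows,
        columns=[
            "pid", "cb", "task", "block", "trial", "congruency", "word",
            "valence_score", "rt_ms", "outcome", "sex", "age", "esl", "brooding",
        ],
    )
    return participants.drop(columns=["u", "slope_u"]), trials


# ---------------------------------------------------------------------------
# Model-generated participants for recovery studies
# ---------------------------------------------------------------------------


def gen_model_cohort(
    base_spec,
    variant: ModelVariant | str,
    bounds: ParameterBounds | None = None,
    n: int = 20,
    noise_sd_ms: float = 0.0,
    seed: int = 0,
    context: str = "induction",
    max_retries: int = 200,
):
    """Ground-truth parameter vectors and their simulated condition means.

    Vectors are drawn uniformly within the fitting bounds and kept only
    when they produce behaviourally valid dynamics: both conditions
    respond before the deadline, the response is not an instant
    first-cycle crossing, and the congruency effect is positive (the
    regime the model is fitted in; large regions of the uniform box
    collapse to degenerate instant or condition-blind responses, which
    no participant the model is meant to describe would show).
    Rejected draws are redrawn up to ``max_retries`` per participant,
    then an error.  With ``noise_sd_ms`` > 0, independent Gaussian
    noise is added to each condition mean.
    """
    from .fitting import simulate_participant_means
    from .network import OVERTIME

    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if n < 1:
        raise ValueError("n must be >= 1")
    bounds = bounds or ParameterBounds()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    names = list(variant.free)
    lo, hi = bounds.arrays(names)
    truths, means = [], []
    for _ in range(n):
        for attempt in range(max_retries):
            x = rng.uniform(lo, hi)
            params = ParameterVector(dict(zip(names, x)))
            sim = simulate_participant_means(base_spec, params, context)
            if sim[0] is OVERTIME or sim[1] is OVERTIME:
                continue
            congruent_cycles = (sim[0] - params["I"]) / params["K"]
            if congruent_cycles >= 2 and sim[1] > sim[0]:
                break
        else:
            raise RuntimeError(
                f"no behaviourally valid parameter draw in {max_retries} attempts"
            )
        pair = (float(sim[0]), float(sim[1]))
        if noise_sd_ms > 0:
            pair = tuple(v + rng.normal(0.0, noise_sd_ms) for v in pair)
        truths.append(params)
        means.append(pair)
    return truths, means
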