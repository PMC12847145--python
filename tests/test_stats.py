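"""Behavioural statistics: filters, GLMMs, nonparametric tests, parameter LM."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from stroopgrain.stats import (
    DEFAULT_STOPLIST,
    fit_emotional_glmm,
    fit_param_lm,
    fit_standard_glmm,
    fits_to_frame,
    friedman_posthoc,
    friedman_statistic,
    power_simulation,
    prepare_trials,
)
from stroopgrain.synth import CohortConfig, gen_cohort


def _toy_emotional_table():
    rows = []
    words = ["GREEDY", "chair", "hostile", "GREEDY", "sincere",
             "rude", "table", "kind", "spoon", "loyal"]
    for i, w in enumerate(words):
        rows.append(
            dict(pid=1 + i % 2, cb=1, task="emotional", block=1, trial=i + 1,
                 congruency=None, word=w, valence_score=0.1, rt_ms=700.0 + i,
                 outcome="correct", sex=0, age=30, esl=0, brooding=10)
        )
    return pd.DataFrame(rows)


class TestPrepareTrials:
    def test_stoplist_hand_count(self):
        table = _toy_emotional_table()
        out = prepare_trials(table, task="emotional", stoplist=("GREEDY",))
        assert len(out) == 8  # 10 trials, 2 GREEDY removed

    def test_default_stoplist_also_removes_rude(self):
        table = _toy_emotional_table()
        out = prepare_trials(table, task="emotional", stoplist=DEFAULT_STOPLIST)
        assert len(out) == 7
        assert not out["word"].str.lower().isin(["greedy", "rude"]).any()

    def test_no_filters_is_identity_on_clean_table(self):
        table = _toy_emotional_table()
        out = prepare_trials(table, correct_only=False)
        pd.testing.assert_frame_equal(out, table)

    def test_all_overtime_raises_naming_filter(self):
        table = _toy_emotional_table()
        table["outcome"] = "overtime"
        table["rt_ms"] = np.nan
        with pytest.raises(ValueError, match="responded within window"):
            prepare_trials(table)

    def test_filters_commute(self, small_cohort):
        _, trials = small_cohort
        a = prepare_trials(
            prepare_trials(trials, correct_only=False), stoplist=DEFAULT_STOPLIST,
            correct_only=True,
        )
        b = prepare_trials(
            prepare_trials(trials, stoplist=DEFAULT_STOPLIST, correct_only=False),
            correct_only=True,
        )
        pd.testing.assert_frame_equal(
            a.sort_index(), b.sort_index(), check_like=True
        )

    def test_incorrect_trials_dropped_by_default(self, small_cohort):
        _, trials = small_cohort
        out = prepare_trials(trials, task="standard")
        assert (out["outcome"] == "correct").all()
        assert (out["rt_ms"] <= 2000).all()


class TestFriedmanStatistic:
    def test_all_identical_gives_zero(self):
        m = np.tile([700.0, 700.0, 700.0], (6, 1))
        stat, df, p = friedman_statistic(m)
        assert stat == 0.0
        assert p == 1.0

    def test_toy_table_matches_rank_oracle(self):
        # 4 participants x 3 conditions, no ties: explicit rank-sum formula
        m = np.array(
            [[650.0, 700.0, 720.0],
             [680.0, 660.0, 710.0],
             [600.0, 640.0, 630.0],
             [590.0, 620.0, 650.0]]
        )
        ranks = np.array([scipy.stats.rankdata(row) for row in m])
        rj = ranks.sum(axis=0)
        n, k = m.shape
        oracle = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
        stat, df, _ = friedman_statistic(m)
        assert stat == pytest.approx(oracle)
        assert df == 2

    def test_matches_scipy_for_three_conditions(self):
        rng = np.random.default_rng(0)
        m = rng.normal(700, 50, size=(12, 3))
        stat, _, p = friedman_statistic(m)
        s_stat, s_p = scipy.stats.friedmanchisquare(m[:, 0], m[:, 1], m[:, 2])
        assert stat == pytest.approx(s_stat)
        assert p == pytest.approx(s_p)

    def test_two_conditions_supported(self):
        rng = np.random.default_rng(1)
        m = np.column_stack([rng.normal(700, 30, 20), rng.normal(760, 30, 20)])
        stat, df, p = friedman_statistic(m)
        assert df == 1
        assert 0 <= p <= 1


@pytest.fixture(scope="module")
def valence_cohort():
    cfg = CohortConfig(n_participants=30, seed=21, valence_slope=120.0)
    _, trials = gen_cohort(cfg)
    return prepare_trials(trials, task="emotional")


class TestFriedmanPosthoc:
    def test_standard_two_condition_test(self, small_cohort):
        _, trials = small_cohort
        res = friedman_posthoc(prepare_trials(trials, task="standard"), "standard")
        assert res["df"] == 1
        assert res["conditions"] == ["congruent", "incongruent"]
        assert res["p"] < 0.05  # default generative congruency effect is large
        assert res["pairwise"] is not None

    def test_emotional_three_categories_and_bonferroni(self, valence_cohort):
        res = friedman_posthoc(valence_cohort, "emotional")
        assert res["df"] == 2
        assert res["p"] < 0.05
        pw = res["pairwise"]
        assert len(pw) == 3
        np.testing.assert_allclose(
            pw["p_bonferroni"], np.minimum(1.0, pw["p_raw"] * 3)
        )
        assert (pw["p_bonferroni"] >= pw["p_raw"] - 1e-15).all()

    def test_participant_missing_condition_excluded(self, valence_cohort):
        pid0 = valence_cohort["pid"].iloc[0]
        broken = valence_cohort[
            ~((valence_cohort["pid"] == pid0)
              & (valence_cohort["valence_score"] > 0.2))
        ]
        res = friedman_posthoc(broken, "emotional")
        assert res["n"] == valence_cohort["pid"].nunique() - 1


@pytest.fixture(scope="module")
def glmm_cohort():
    cfg = CohortConfig(n_participants=60, seed=2)
    _, trials = gen_cohort(cfg)
    return trials


@pytest.fixture(scope="module")
def standard_coef(glmm_cohort):
    return fit_standard_glmm(prepare_trials(glmm_cohort, task="standard"))


class TestStandardGLMM:
    EXPECTED_TERMS = {
        "(Intercept)", "cb", "congruency", "brooding", "sex", "age",
        "cb:congruency", "cb:brooding", "congruency:brooding",
        "cb:congruency:brooding",
    }

    def test_coefficient_table_contract(self, standard_coef):
        assert set(standard_coef.index) == self.EXPECTED_TERMS
        assert standard_coef["p"].between(0, 1).all()
        assert (standard_coef["ci_low"] <= standard_coef["estimate"]).all()
        assert (standard_coef["estimate"] <= standard_coef["ci_high"]).all()
        assert standard_coef.attrs["alpha"] == 0.025
        assert standard_coef.attrs["family"] == "Gamma"
        assert standard_coef.attrs["link"] == "identity"

    def test_congruency_recovered_within_own_ci(self, standard_coef):
        # generative congruency x brooding structure: the CI of each key
        # term must cover its generative value on this seeded cohort
        cfg = CohortConfig()
        rows = {
            "congruency": cfg.beta_congruency,
            "congruency:brooding": cfg.beta_congruency_brooding,
            "cb:congruency:brooding": cfg.beta_cb_congruency_brooding,
        }
        for term, truth in rows.items():
            lo = standard_coef.loc[term, "ci_low"]
            hi = standard_coef.loc[term, "ci_high"]
            assert lo <= truth <= hi, (term, lo, truth, hi)

    def test_random_slope_variant_runs(self, glmm_cohort):
        cfg = CohortConfig(n_participants=40, seed=31, random_congruency_slope_sd=30.0)
        _, trials = gen_cohort(cfg)
        coef = fit_standard_glmm(
            prepare_trials(trials, task="standard"), random_structure="slope"
        )
        assert "congruency" in coef.index
        assert coef.attrs["random"] == "(1 + congruency | pid)"

    def test_unknown_random_structure_rejected(self, glmm_cohort):
        with pytest.raises(ValueError):
            fit_standard_glmm(glmm_cohort, random_structure="banana")

    def test_agrees_with_gamma_glm_when_no_random_variance(self):
        """With zero participant variance the mixed model must collapse to
        an ordinary gamma GLM (statsmodels), the independent route."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        cfg = CohortConfig(n_participants=40, seed=13, random_intercept_sd=0.0,
                           esl_offset=0.0)
        _, trials = gen_cohort(cfg)
        prep = prepare_trials(trials, task="standard")
        mixed = fit_standard_glmm(prep)

        df = prep.copy()
        df["cbx"] = (df["cb"] == 2).astype(int)
        df["cong"] = (df["congruency"] == "incongruent").astype(int)
        glm = smf.glm(
            "rt_ms ~ cbx * cong * brooding + sex + age",
            data=df, family=sm.families.Gamma(link=sm.families.links.Identity()),
        ).fit()
        pairs = {
            "congruency": "cong",
            "congruency:brooding": "cong:brooding",
            "cb:congruency:brooding": "cbx:cong:brooding",
        }
        for mixed_term, glm_term in pairs.items():
            a = mixed.loc[mixed_term, "estimate"]
            b = glm.params[glm_term]
            assert a == pytest.approx(b, abs=max(1.0, 0.05 * abs(b)))


@pytest.fixture(scope="module")
def esl_cohort():
    cfg = CohortConfig(n_participants=50, seed=17, esl_offset=-70.0)
    _, trials = gen_cohort(cfg)
    return prepare_trials(trials, task="emotional")


class TestEmotionalGLMM:
    def test_esl_effect_recovered_and_lrt_positive(self, esl_cohort):
        coef = fit_emotional_glmm(esl_cohort, include_esl=True)
        assert coef.loc["esl", "ci_low"] <= -70.0 <= coef.loc["esl", "ci_high"]
        lrt = coef.attrs["lrt"]
        assert lrt["stat"] >= 0.0
        assert lrt["df"] == 1
        assert 0 <= lrt["p"] <= 1

    def test_null_valence_mostly_nonsignificant(self):
        """Cohorts generated with no valence effect should rarely produce a
        significant valence term at the corrected level."""
        from stroopgrain.stats import _glmm_columns, _run_glmm_batch

        frames = []
        for seed in range(10):
            cfg = CohortConfig(n_participants=40, seed=100 + seed)
            _, trials = gen_cohort(cfg)
            prep = prepare_trials(trials, task="emotional")
            frames.append(_glmm_columns(prep, valence=True))
        entries = _run_glmm_batch(
            frames, "rt_ms ~ cb * valence_score * brooding + sex + age + (1 | pid)"
        )
        nonsig = 0
        for e in entries:
            assert e["converged"]
            p = {c["term"]: c["p"] for c in e["coefficients"]}["valence_score"]
            nonsig += p >= 0.025
        assert nonsig >= 9


@pytest.fixture(scope="module")
def synthetic_fit_frame():
    rng = np.random.default_rng(77)
    n = 140
    params = {
        name: rng.uniform(0.5, 5.0, n)
        for name in ("emotion_task_w", "task_emotion_w", "task_bias",
                     "task_gain", "emotion_bias", "emotion_gain",
                     "task_intg", "emotion_intg")
    }
    df = pd.DataFrame(params)
    df["pid"] = np.arange(1, n + 1)
    z = (df["emotion_task_w"] - df["emotion_task_w"].mean()) / df[
        "emotion_task_w"
    ].std(ddof=0)
    brooding = 0.3 * z + rng.normal(0, 0.8, n)
    participants = pd.DataFrame(
        {
            "pid": df["pid"],
            "cb": np.where(df["pid"] % 2 == 1, 1, 2),
            "sex": rng.binomial(1, 0.5, n),
            "age": rng.integers(18, 60, n),
            "brooding": brooding,
        }
    )
    return df, participants


class TestParamLM:
    def test_generative_effect_recovered(self, synthetic_fit_frame):
        fits, participants = synthetic_fit_frame
        coef = fit_param_lm(fits, participants)
        lo = coef.loc["emotion_task_w", "ci_low"]
        hi = coef.loc["emotion_task_w", "ci_high"]
        # brooding was standardised inside the model, so the generative
        # standardised slope 0.3/sd(brooding) must fall in the CI
        target = 0.3 / participants["brooding"].std(ddof=0)
        assert lo <= target <= hi

    def test_three_way_term_present(self, synthetic_fit_frame):
        fits, participants = synthetic_fit_frame
        coef = fit_param_lm(fits, participants)
        assert "cb:task_intg:emotion_intg" in coef.index
        assert coef.attrs["alpha"] == 0.05

    def test_scale_invariance_of_standardised_estimates(self, synthetic_fit_frame):
        fits, participants = synthetic_fit_frame
        a = fit_param_lm(fits, participants)
        doubled = fits.copy()
        for col in ("emotion_task_w", "task_gain", "emotion_intg"):
            doubled[col] = 2.0 * doubled[col]
        b = fit_param_lm(doubled, participants)
        np.testing.assert_allclose(a["estimate"], b["estimate"], atol=1e-10)

    def test_cb_stratified_drops_cb_terms_and_tightens_alpha(self, synthetic_fit_frame):
        fits, participants = synthetic_fit_frame
        coef = fit_param_lm(fits, participants, cb_subset=1)
        assert coef.attrs["alpha"] == 0.025
        assert not any("cb" in t for t in coef.index)
        assert "task_intg:emotion_intg" in coef.index

    def test_zero_variance_regressor_rejected(self, synthetic_fit_frame):
        fits, participants = synthetic_fit_frame
        flat = fits.copy()
        flat["task_gain"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            fit_param_lm(flat, participants)

    def test_accepts_fit_results(self, default_spec, small_cohort):
        from stroopgrain.fitting import EAConfig, fit_cohort

        participants, trials = small_cohort
        fits = fit_cohort(
            trials, "full", ea=EAConfig(population_size=15, generations=8),
            base_spec=default_spec, master_seed=5,
        )
        frame = fits_to_frame(fits)
        assert len(frame) == len(participants)
        assert "emotion_task_w" in frame.columns


class TestPowerSimulation:
    def test_contract_and_monotonicity_for_large_effect(self):
        cfg = CohortConfig(beta_congruency=250.0, beta_congruency_brooding=0.0,
                           beta_cb_congruency_brooding=0.0)
        table = power_simulation(
            cfg, [10, 40], replicates=20, alpha=0.025, seed=5, term="congruency"
        )
        assert list(table["n"]) == [10, 40]
        assert table["power"].between(0, 1).all()
        assert (table["ci_low"] <= table["power"]).all()
        # a 250 ms effect is essentially always detected even at n=10
        assert table["power"].iloc[1] >= table["power"].iloc[0] - 0.15

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(CohortConfig(), [10], replicates=5)
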