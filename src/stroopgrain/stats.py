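"""Behavioural statistics: gamma GLMMs for RTs, nonparametric post hocs,
and the fitted-parameter -> brooding linear model.

Reaction times are right-skewed, so the mixed models assume
gamma-distributed responses with an *identity* link: effects stay on the
raw millisecond scale, avoiding the scale distortions of log or inverse
transforms.  The standard-task model is

    RT ~ cb * congruency * brooding + sex + age + (1 | pid)

and the emotional-task model replaces congruency with the continuous
word valence score.  Both task analyses are tested at a
Bonferroni-corrected alpha of 0.025.  The mixed models are fitted by
glmmTMB through an Rscript bridge (CSV in, JSON out); the bridge is the
backend, not part of the statistical contract — any gamma/identity
backend reporting Wald intervals would do.

The parameter model regresses z-scored brooding on the z-scored fitted
network parameters with ordinary least squares:

    brooding ~ emotion_task_w + task_emotion_w + task_bias + task_gain
             + emotion_bias + emotion_gain + cb*(task_intg*emotion_intg)
             + sex + age
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "ALPHA_TASKS",
    "ALPHA_PARAMS",
    "DEFAULT_STOPLIST",
    "prepare_trials",
    "fit_standard_glmm",
    "fit_emotional_glmm",
    "friedman_statistic",
    "friedman_posthoc",
    "fit_param_lm",
    "power_simulation",
    "fits_to_frame",
]

#: Bonferroni-corrected level for the two task-wise RT analyses.
ALPHA_TASKS = 0.025
#: level for the fitted-parameter linear model (0.025 when CB-stratified).
ALPHA_PARAMS = 0.05

#: Negative words sharing initial letters with the response colours,
#: introducing letter-level interference; removed in the post hoc filter.
DEFAULT_STOPLIST = ("greedy", "rude")


# ---------------------------------------------------------------------------
# Trial filtering
# ---------------------------------------------------------------------------


def prepare_trials(
    table: pd.DataFrame,
    task: str | None = None,
    correct_only: bool = True,
    stoplist: tuple[str, ...] | None = None,
    response_window_ms: float = 2000.0,
) -> pd.DataFrame:
    """Return the analysis subset of a trial table.

    Keeps responded trials inside the response window, drops incorrect
    responses when ``correct_only``, and optionally removes emotional
    trials whose word is on the stoplist.  Removal counts are logged;
    an empty result raises an error naming the responsible filter.
    """
    out = table
    applied = []
    if task is not None:
        out = out[out["task"] == task]
        applied.append(f"task == {task!r}")
        if out.empty:
            raise ValueError(f"no trials left after filter: task == {task!r}")
    n0 = len(out)
    out = out[(out["outcome"] != "overtime") & out["rt_ms"].notna()]
    out = out[(out["rt_ms"] > 0) & (out["rt_ms"] <= response_window_ms)]
    logger.info("responded/in-window filter removed %d of %d trials", n0 - len(out), n0)
    if out.empty:
        raise ValueError("no trials left after filter: responded within window")
    if correct_only:
        n0 = len(out)
        out = out[out["outcome"] == "correct"]
        logger.info("correct-only filter removed %d trials", n0 - len(out))
        if out.empty:
            raise ValueError("no trials left after filter: correct responses only")
    if stoplist:
        lowered = {w.lower() for w in stoplist}
        n0 = len(out)
        words = out["word"].astype(str).str.lower()
        out = out[(out["task"] != "emotional") | ~words.isin(lowered)]
        logger.info("stoplist filter removed %d trials", n0 - len(out))
        if out.empty:
            raise ValueError("no trials left after filter: stoplist")
    return out.copy()


# ---------------------------------------------------------------------------
# Gamma GLMM backend (glmmTMB via Rscript)
# ---------------------------------------------------------------------------

_R_BATCH_SCRIPT = r"""
suppressMessages({library(glmmTMB); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d_all <- read.csv(args[1])
f_main <- as.formula(args[2])
f_alt <- if (nchar(args[3]) > 0) as.formula(args[3]) else NULL
zq <- qnorm(0.975)

coef_list <- function(m) {
  s <- summary(m)$coefficients$cond
  lapply(rownames(s), function(t) list(
    term = t,
    estimate = unname(s[t, "Estimate"]),
    se = unname(s[t, "Std. Error"]),
    z = unname(s[t, "z value"]),
    p = unname(s[t, "Pr(>|z|)"]),
    ci_low = unname(s[t, "Estimate"] - zq * s[t, "Std. Error"]),
    ci_high = unname(s[t, "Estimate"] + zq * s[t, "Std. Error"])
  ))
}

lm_start <- function(d, f) {
  # informed start: lm fixed effects + participant residual sd for the
  # random-intercept scale (identity-link gamma likelihoods are
  # multimodal enough that nlminb from the default start can collapse
  # the random-intercept variance to the boundary)
  fixed_f <- lme4::nobars(f)
  lm0 <- lm(fixed_f, data = d)
  pm <- tapply(resid(lm0), d$pid, mean)
  list(beta = coef(lm0), theta = log(max(sd(pm), 1)))
}

fit_one <- function(d, f) {
  warns <- character(0)
  simple_ri <- identical(lme4::findbars(f)[[1]], lme4::findbars(rt_ms ~ (1 | pid))[[1]])
  st <- if (simple_ri) tryCatch(lm_start(d, f), error = function(e) NULL) else NULL
  attempts <- list(
    list(start = st, control = glmmTMBControl()),
    list(start = NULL, control = glmmTMBControl()),
    list(start = st,
         control = glmmTMBControl(optimizer = optim, optArgs = list(method = "BFGS")))
  )
  m <- NULL
  for (a in attempts) {
    cand <- withCallingHandlers(
      tryCatch(glmmTMB(f, data = d, family = Gamma(link = "identity"),
                       start = a$start, control = a$control),
               error = function(e) { warns <<- c(warns, conditionMessage(e)); NULL }),
      warning = function(w) { warns <<- c(warns, conditionMessage(w)); invokeRestart("muffleWarning") })
    if (!is.null(cand)) {
      m <- cand
      if (isTRUE(m$fit$convergence == 0) && isTRUE(m$sdr$pdHess)) break
    }
  }
  if (is.null(m)) return(list(converged = FALSE, messages = warns))
  conv <- isTRUE(m$fit$convergence == 0) && isTRUE(m$sdr$pdHess)
  neg_mu <- any(fitted(m) <= 0)
  list(converged = conv, negative_fitted = neg_mu,
       coefficients = coef_list(m),
       loglik = as.numeric(logLik(m)), df = attr(logLik(m), "df"),
       ranef_sd = tryCatch(
         as.numeric(sqrt(unlist(VarCorr(m)$cond))), error = function(e) NA),
       messages = warns, model = m)
}

out <- list()
for (rep in sort(unique(d_all$replicate_id))) {
  d <- d_all[d_all$replicate_id == rep, ]
  res <- fit_one(d, f_main)
  entry <- res[names(res) != "model"]
  if (!is.null(f_alt) && res$converged) {
    res2 <- fit_one(d, f_alt)
    if (res2$converged) {
      lrt_stat <- 2 * (res2$loglik - res$loglik)
      lrt_df <- res2$df - res$df
      entry$alt <- list(coefficients = res2$coefficients,
                        loglik = res2$loglik,
                        lrt_stat = lrt_stat, lrt_df = lrt_df,
                        lrt_p = pchisq(lrt_stat, lrt_df, lower.tail = FALSE))
    }
  }
  out[[as.character(rep)]] <- entry
}
cat(toJSON(out, auto_unbox = TRUE, digits = NA, na = "null"))
"""


def _require_rscript() -> str:
    exe = shutil.which("Rscript")
    if exe is None:
        raise RuntimeError(
            "Rscript not found on PATH; the gamma GLMM backend requires R "
            "with glmmTMB"
        )
    return exe


def _run_glmm_batch(
    frames: list[pd.DataFrame], formula: str, alt_formula: str = ""
) -> list[dict]:
    """Fit one gamma/identity mixed model per frame in a single R session."""
    exe = _require_rscript()
    stacked = pd.concat(
        [f.assign(replicate_id=i) for i, f in enumerate(frames)], ignore_index=True
    )
    with tempfile.TemporaryDirectory() as tmp:
        csv_path = Path(tmp) / "data.csv"
        r_path = Path(tmp) / "fit.R"
        stacked.to_csv(csv_path, index=False)
        r_path.write_text(_R_BATCH_SCRIPT, encoding="utf-8")
        proc = subprocess.run(
            [exe, "--vanilla", str(r_path), str(csv_path), formula, alt_formula],
            capture_output=True,
            text=True,
        )
    if proc.returncode != 0:
        raise RuntimeError(f"R GLMM backend failed:\n{proc.stderr[-4000:]}")
    payload = json.loads(proc.stdout)
    return [payload[str(i)] for i in range(len(frames))]


def _coef_table(entry: dict, meta: dict) -> pd.DataFrame:
    rows = entry["coefficients"]
    df = pd.DataFrame(rows)[["term", "estimate", "ci_low", "ci_high", "se", "z", "p"]]
    df = df.set_index("term")
    df.attrs.update(meta)
    df.attrs["ranef_sd"] = entry.get("ranef_sd")
    df.attrs["loglik"] = entry.get("loglik")
    return df


def _glmm_columns(table: pd.DataFrame, valence: bool) -> pd.DataFrame:
    cols = {
        "rt_ms": table["rt_ms"].astype(float),
        "cb": (table["cb"].astype(int) == 2).astype(int),
        "brooding": table["brooding"].astype(float),
        "sex": table["sex"].astype(int),
        "age": table["age"].astype(float),
        "pid": table["pid"],
    }
    if valence:
        cols["valence_score"] = table["valence_score"].astype(float)
        if "esl" in table:
            cols["esl"] = table["esl"].astype(int)
    else:
        cols["congruency"] = (table["congruency"] == "incongruent").astype(int)
    return pd.DataFrame(cols)


def fit_standard_glmm(
    table: pd.DataFrame, random_structure: str = "intercept", alpha: float = ALPHA_TASKS
) -> pd.DataFrame:
    """Gamma identity-link GLMM for standard-task RTs.

    ``random_structure`` is ``"intercept"`` (the primary analysis) or
    ``"slope"`` (the post hoc ``(1 + congruency | pid)`` refit).
    Returns a coefficient table (estimate, 95% Wald CI, p) with model
    metadata in ``.attrs``.  Raises on non-convergence, carrying the
    optimiser's diagnostics.
    """
    if random_structure not in ("intercept", "slope"):
        raise ValueError("random_structure must be 'intercept' or 'slope'")
    data = _glmm_columns(table, valence=False)
    if data.groupby("pid")["cb"].first().groupby(data.groupby("pid")["cb"].first()).count().min() < 2:
        raise ValueError("need at least 2 participants per counterbalancing group")
    rand = "(1 | pid)" if random_structure == "intercept" else "(1 + congruency | pid)"
    formula = f"rt_ms ~ cb * congruency * brooding + sex + age + {rand}"
    entry = _run_glmm_batch([data], formula)[0]
    if not entry.get("converged"):
        raise RuntimeError(
            f"standard-task GLMM did not converge: {entry.get('messages')}"
        )
    if entry.get("negative_fitted"):
        raise RuntimeError(
            "identity-link fit produced non-positive fitted means; consider "
            "rescaling predictors or adjusting starting values"
        )
    return _coef_table(
        entry,
        {
            "formula": formula,
            "family": "Gamma",
            "link": "identity",
            "random": rand,
            "alpha": alpha,
            "n_obs": len(data),
            "n_participants": data["pid"].nunique(),
        },
    )


def fit_emotional_glmm(
    table: pd.DataFrame, include_esl: bool = False, alpha: float = ALPHA_TASKS
) -> pd.DataFrame:
    """Gamma identity-link GLMM for emotional-task RTs (continuous valence).

    With ``include_esl``, an English-as-second-language main effect is
    added and a likelihood-ratio comparison against the base model is
    attached in ``.attrs['lrt']``.
    """
    data = _glmm_columns(table, valence=True)
    base = "rt_ms ~ cb * valence_score * brooding + sex + age + (1 | pid)"
    alt = base + " + esl" if include_esl else ""
    entry = _run_glmm_batch([data], base, alt)[0]
    if not entry.get("converged"):
        raise RuntimeError(
            f"emotional-task GLMM did not converge: {entry.get('messages')}"
        )
    meta = {
        "formula": base,
        "family": "Gamma",
        "link": "identity",
        "random": "(1 | pid)",
        "alpha": alpha,
        "n_obs": len(data),
        "n_participants": data["pid"].nunique(),
    }
    if include_esl:
        alt_entry = entry.get("alt")
        if alt_entry is None:
            raise RuntimeError("ESL model did not converge")
        out = _coef_table({"coefficients": alt_entry["coefficients"],
                           "ranef_sd": entry.get("ranef_sd"),
                           "loglik": alt_entry["loglik"]}, meta)
        out.attrs["formula"] = alt
        out.attrs["lrt"] = {
            "stat": alt_entry["lrt_stat"],
            "df": alt_entry["lrt_df"],
            "p": alt_entry["lrt_p"],
        }
        return out
    return _coef_table(entry, meta)


# ---------------------------------------------------------------------------
# Nonparametric post hocs
# ---------------------------------------------------------------------------


def friedman_statistic(matrix: np.ndarray) -> tuple[float, int, float]:
    """Tie-corrected Friedman chi-square for an (n subjects, k conditions) matrix.

    Implemented directly from within-subject ranks (the SciPy routine
    refuses k = 2, which the two-condition standard task needs).
    Returns ``(statistic, df, p)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    if n < 1 or k < 2:
        raise ValueError("need at least 1 subject and 2 conditions")
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, matrix)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction: average-rank ties deflate the statistic's scale
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    if denom <= 0:  # every row entirely tied
        return 0.0, k - 1, 1.0
    stat /= denom
    df = k - 1
    return float(stat), df, float(scipy.stats.chi2.sf(stat, df))


def _valence_category(score: float, cut: float = 0.2) -> str:
    if score < -cut:
        return "negative"
    if score > cut:
        return "positive"
    return "neutral"


def friedman_posthoc(
    table: pd.DataFrame,
    task: str,
    aggregate: str = "mean",
    alpha: float = 0.05,
    valence_cut: float = 0.2,
) -> dict:
    """Friedman test over per-participant condition aggregates, with
    Bonferroni-corrected pairwise Wilcoxon signed-rank follow-ups.

    Standard task: congruent vs incongruent.  Emotional task: the three
    valence categories (classified from the continuous score).
    Participants missing a condition are excluded with a log message.
    Wilcoxon pairs are only computed when the Friedman test is
    significant at ``alpha``.
    """
    if task == "standard":
        sub = table[table["task"] == "standard"].copy()
        sub["condition"] = sub["congruency"]
        levels = ["congruent", "incongruent"]
    elif task == "emotional":
        sub = table[table["task"] == "emotional"].copy()
        sub["condition"] = sub["valence_score"].map(
            lambda v: _valence_category(v, valence_cut)
        )
        levels = ["negative", "neutral", "positive"]
    else:
        raise ValueError(f"unknown task {task!r}")
    agg_fn = {"mean": "mean", "median": "median"}[aggregate]
    pivot = sub.pivot_table(
        index="pid", columns="condition", values="rt_ms", aggfunc=agg_fn
    ).reindex(columns=levels)
    complete = pivot.dropna()
    dropped = len(pivot) - len(complete)
    if dropped:
        logger.info("excluded %d participants missing a condition", dropped)
    stat, df, p = friedman_statistic(complete.to_numpy())
    result = {
        "statistic": stat,
        "df": df,
        "p": p,
        "n": len(complete),
        "conditions": levels,
        "pairwise": None,
    }
    if p < alpha:
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
        rows = []
        for a, b in pairs:
            diff = complete[a] - complete[b]
            if np.allclose(diff, 0):
                w, raw = 0.0, 1.0
            else:
                w, raw = scipy.stats.wilcoxon(complete[a], complete[b])
            rows.append(
                {
                    "pair": f"{a} vs {b}",
                    "W": float(w),
                    "p_raw": float(raw),
                    "p_bonferroni": min(1.0, float(raw) * len(pairs)),
                }
            )
        result["pairwise"] = pd.DataFrame(rows).set_index("pair")
    return result


# ---------------------------------------------------------------------------
# Fitted parameters -> brooding linear model
# ---------------------------------------------------------------------------

_PARAM_LM_TERMS = [
    "emotion_task_w",
    "task_emotion_w",
    "task_bias",
    "task_gain",
    "emotion_bias",
    "emotion_gain",
    "task_intg",
    "emotion_intg",
]


def fits_to_frame(fits) -> pd.DataFrame:
    """Flatten FitResults to one row per participant with all parameters."""
    rows = []
    for f in fits:
        row = {"pid": f.pid, "variant": f.variant, "fitness": f.fitness,
               "context": f.context, "converged": f.converged, "seed": f.seed}
        row.update({k: f.params[k] for k in f.params})
        rows.append(row)
    return pd.DataFrame(rows)


def fit_param_lm(
    fits,
    participants: pd.DataFrame,
    cb_subset: int | None = None,
    condition_number_threshold: float = 1e4,
) -> pd.DataFrame:
    """OLS of z-scored brooding on z-scored fitted parameters.

    The full-sample model includes the counterbalancing interaction with
    the two integration rates (``cb*(task_intg*emotion_intg)``) at alpha
    0.05; CB-stratified refits (``cb_subset`` 1 or 2) drop the cb terms
    and use alpha 0.025.  A collinearity warning is attached when the
    design's condition number is extreme.
    """
    params = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    data = params.merge(
        participants[["pid", "cb", "sex", "age", "brooding"]], on="pid", how="inner"
    )
    if cb_subset is not None:
        data = data[data["cb"] == cb_subset]
        alpha = 0.025
    else:
        alpha = ALPHA_PARAMS
    if len(data) < len(_PARAM_LM_TERMS) + 4:
        raise ValueError("too few participants for the parameter model")

    def z(col):
        sd = col.std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero variance in regressor {col.name!r}")
        return (col - col.mean()) / sd

    model_df = pd.DataFrame({name: z(data[name]) for name in _PARAM_LM_TERMS})
    model_df["brooding"] = z(data["brooding"].astype(float))
    model_df["cb"] = (data["cb"].astype(int) == 2).astype(int).to_numpy()
    model_df["sex"] = data["sex"].astype(int).to_numpy()
    model_df["age"] = data["age"].astype(float).to_numpy()

    fixed = (
        "brooding ~ emotion_task_w + task_emotion_w + task_bias + task_gain"
        " + emotion_bias + emotion_gain"
    )
    if cb_subset is None:
        formula = fixed + " + cb*(task_intg*emotion_intg) + sex + age"
    else:
        formula = fixed + " + task_intg*emotion_intg + sex + age"
    res = smf.ols(formula, data=model_df).fit()
    ci = res.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "estimate": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "se": res.bse,
            "p": res.pvalues,
        }
    )
    out.index.name = "term"
    out.attrs.update(
        {
            "formula": formula,
            "alpha": alpha,
            "n": int(res.nobs),
            "r_squared": float(res.rsquared),
            "cb_subset": cb_subset,
            "condition_number": float(res.condition_number),
        }
    )
    if res.condition_number > condition_number_threshold:
        out.attrs["collinearity_warning"] = (
            f"condition number {res.condition_number:.3g} exceeds "
            f"{condition_number_threshold:.3g}"
        )
        logger.warning(out.attrs["collinearity_warning"])
    return out


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------


def power_simulation(
    cfg,
    n_list,
    replicates: int = 20,
    alpha: float = ALPHA_TASKS,
    seed: int = 0,
    term: str = "cb:congruency:brooding",
    random_structure: str = "intercept",
) -> pd.DataFrame:
    """Simulation-based power for a standard-task GLMM term.

    For each candidate sample size, generates cohorts from the
    generative config, fits the GLMM (one R session per sample size) and
    reports the rejection fraction with a binomial (Wilson) interval.
    Non-converged replicates are counted and excluded from the
    denominator.
    """
    from dataclasses import replace

    from statsmodels.stats.proportion import proportion_confint

    from .synth import gen_cohort

    if replicates < 20:
        raise ValueError("use at least 20 replicates")
    rand = "(1 | pid)" if random_structure == "intercept" else "(1 + congruency | pid)"
    formula = f"rt_ms ~ cb * congruency * brooding + sex + age + {rand}"
    ss = np.random.SeedSequence([int(seed), 307])
    rows = []
    for n in n_list:
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(replicates)]
        frames = []
        for s in seeds:
            _, trials = gen_cohort(replace(cfg, n_participants=int(n), seed=s))
            prepared = prepare_trials(trials, task="standard")
            frames.append(_glmm_columns(prepared, valence=False))
        entries = _run_glmm_batch(frames, formula)
        rejections, converged = 0, 0
        for e in entries:
            if not e.get("converged"):
                continue
            converged += 1
            pvals = {c["term"]: c["p"] for c in e["coefficients"]}
            if pvals.get(term, 1.0) < alpha:
                rejections += 1
        power = rejections / converged if converged else np.nan
        lo, hi = (
            proportion_confint(rejections, converged, method="wilson")
            if converged
            else (np.nan, np.nan)
        )
        rows.append(
            {
                "n": int(n),
                "power": power,
                "ci_low": lo,
                "ci_high": hi,
                "replicates": replicates,
                "converged": converged,
            }
        )
        logger.info("power at n=%d: %.3f (%d/%d converged)", n, power, converged, replicates)
    out = pd.DataFrame(rows)
    out.attrs.update({"term": term, "alpha": alpha, "seed": seed, "formula": formula})
    return out
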