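"""Per-participant evolutionary fitting of network parameters to Stroop RTs.

Each participant contributes two observations — their mean correct RT on
congruent and on incongruent standard Stroop trials — and the model is
fitted by minimising a weighted objective that penalises the squared
error on each condition mean (weight 0.3 each) and the squared mismatch
of the congruency effect itself (weight 0.4), the last term guarding
against trivial one-condition solutions:

    fitness = 0.3 (C_D - C_S)^2 + 0.3 (I_D - I_S)^2
            + 0.4 [(I_D - C_D) - (I_S - C_S)]^2

Optimisation uses a real-valued generational GA: uniform initialisation
within bounds, tournament selection, blend crossover, Gaussian mutation
scaled to the parameter range, elitism, and clipping to bounds.  Four
nested model variants control which parameters are free:

    base    pathway weights (colour/word <-> response, task <-> colour/word)
            plus the RT scaling K and I
    weights base + task <-> emotion weights
    neuron  base + gains, biases and integration rates of the
            task-control and emotion layers
    full    everything
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .network import OVERTIME, NetworkSpec, UnitParams, WeightBlock
from .protocol import condition_means

logger = logging.getLogger(__name__)

__all__ = [
    "PARAM_NAMES",
    "PARAM_DEFAULTS",
    "DEFAULT_BOUNDS",
    "ModelVariant",
    "VARIANTS",
    "ParameterVector",
    "ParameterBounds",
    "EAConfig",
    "FitResult",
    "fitness",
    "apply_parameters",
    "simulate_participant_means",
    "fit_participant",
    "fit_cohort",
    "participant_seed",
    "OVERTIME_PENALTY",
]

#: Large finite objective value assigned when a candidate's simulation
#: fails to produce a response within the cycle deadline; dominates any
#: plausible squared millisecond error.
OVERTIME_PENALTY = 1.0e6

PARAM_NAMES = [
    "color_resp_w",
    "word_resp_w",
    "task_colorword_w",
    "task_emotion_w",
    "emotion_task_w",
    "task_gain",
    "task_bias",
    "task_intg",
    "emotion_gain",
    "emotion_bias",
    "emotion_intg",
    "K",
    "I",
]

#: Values used for parameters a variant leaves fixed; chosen to match the
#: shipped default network configuration.
PARAM_DEFAULTS = {
    "color_resp_w": 2.0,
    "word_resp_w": 2.6,
    "task_colorword_w": 4.0,
    "task_emotion_w": 2.0,
    "emotion_task_w": 2.0,
    "task_gain": 1.0,
    "task_bias": 0.0,
    "task_intg": 0.1,
    "emotion_gain": 1.0,
    "emotion_bias": 4.0,
    "emotion_intg": 0.1,
    "K": 4.0,
    "I": 650.0,
}

DEFAULT_BOUNDS = {
    "color_resp_w": (0.0, 10.0),
    "word_resp_w": (0.0, 10.0),
    "task_colorword_w": (0.0, 10.0),
    "task_emotion_w": (0.0, 10.0),
    "emotion_task_w": (0.0, 10.0),
    "task_gain": (0.05, 10.0),
    "task_bias": (-10.0, 10.0),
    "task_intg": (0.01, 1.0),
    "emotion_gain": (0.05, 10.0),
    "emotion_bias": (-10.0, 10.0),
    "emotion_intg": (0.01, 1.0),
    "K": (0.5, 20.0),
    "I": (0.0, 800.0),
}


@dataclass(frozen=True)
class ModelVariant:
    name: str
    free: tuple[str, ...]

    def __post_init__(self):
        unknown = set(self.free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters in free mask: {sorted(unknown)}")

    @property
    def k_params(self) -> int:
        return len(self.free)


_BASE_FREE = ("color_resp_w", "word_resp_w", "task_colorword_w", "K", "I")
_WEIGHT_EXTRA = ("task_emotion_w", "emotion_task_w")
_NEURON_EXTRA = (
    "task_gain",
    "task_bias",
    "task_intg",
    "emotion_gain",
    "emotion_bias",
    "emotion_intg",
)

#: The four compared variants; base < weights < full and base < neuron < full.
VARIANTS = {
    "base": ModelVariant("base", _BASE_FREE),
    "weights": ModelVariant("weights", _BASE_FREE + _WEIGHT_EXTRA),
    "neuron": ModelVariant("neuron", _BASE_FREE + _NEURON_EXTRA),
    "full": ModelVariant("full", _BASE_FREE + _WEIGHT_EXTRA + _NEURON_EXTRA),
}


class ParameterVector(dict):
    """Named parameter values; missing names fall back to the defaults."""

    def __init__(self, values: dict[str, float] | None = None):
        full = dict(PARAM_DEFAULTS)
        if values:
            unknown = set(values) - set(PARAM_NAMES)
            if unknown:
                raise ValueError(f"unknown parameters: {sorted(unknown)}")
            full.update(values)
        super().__init__(full)
        self.validate()

    def validate(self):
        if self["task_gain"] <= 0 or self["emotion_gain"] <= 0:
            raise ValueError("gains must be positive")
        for nm in ("task_intg", "emotion_intg"):
            if not (0.0 < self[nm] <= 1.0):
                raise ValueError(f"{nm} must lie in (0, 1]")
        if self["K"] <= 0:
            raise ValueError("K must be positive")


class ParameterBounds(dict):
    """Per-parameter (lower, upper) bounds; defaults cover published
    interactive-activation values and plausible human RT scales."""

    def __init__(self, overrides: dict[str, tuple[float, float]] | None = None):
        merged = dict(DEFAULT_BOUNDS)
        if overrides:
            merged.update(overrides)
        for name, (lo, hi) in merged.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} must satisfy lower < upper")
        super().__init__(merged)

    def arrays(self, names) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self[n][0] for n in names])
        hi = np.array([self[n][1] for n in names])
        return lo, hi


@dataclass
class EAConfig:
    population_size: int = 50
    generations: int = 100
    mutation_scale: float = 0.1  # Gaussian sd as a fraction of the range
    mutation_rate: float = 0.25  # per-gene mutation probability
    crossover_rate: float = 0.9
    tournament_size: int = 2
    elitism: int = 1
    #: include the default parameter vector in the initial population so the
    #: search starts with one member inside the dynamically viable regime
    seed_defaults: bool = True
    #: solve the RT scaling (K, I) analytically per candidate: given the
    #: candidate's simulated cycle counts the best (K, I) is the solution of
    #: a 2x2 linear system, clipped to bounds (a Lamarckian repair step that
    #: removes two dimensions from the search)
    solve_scaling: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")


@dataclass
class FitResult:
    pid: object
    variant: str
    params: ParameterVector
    fitness: float
    sim_means: tuple  # (congruent, incongruent) ms, may contain OVERTIME
    data_means: tuple
    context: str
    generations: int
    seed: int | None
    converged: bool
    history: list = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def fitness(data_means, sim_means, overtime_penalty: float = OVERTIME_PENALTY) -> float:
    """Weighted squared-error objective between data and simulated means.

    Any overtime simulated condition short-circuits to the penalty
    constant.  Symmetric in (data, sim) and invariant to adding a common
    constant to all four means.
    """
    c_d, i_d = data_means
    c_s, i_s = sim_means
    if c_s is OVERTIME or i_s is OVERTIME:
        return float(overtime_penalty)
    for v in (c_d, i_d, c_s, i_s):
        if not np.isfinite(v):
            raise ValueError("fitness requires finite condition means")
    return (
        0.3 * (c_d - c_s) ** 2
        + 0.3 * (i_d - i_s) ** 2
        + 0.4 * ((i_d - c_d) - (i_s - c_s)) ** 2
    )


# ---------------------------------------------------------------------------
# Applying a parameter vector to the network
# ---------------------------------------------------------------------------

# weight parameters -> the (source, target) blocks they set; the new value
# replaces the magnitude on the block's existing connectivity pattern
_WEIGHT_TARGETS = {
    "color_resp_w": [("color_hidden", "response"), ("response", "color_hidden")],
    "word_resp_w": [("word_hidden", "response"), ("response", "word_hidden")],
    "task_colorword_w": [
        ("task_control", "color_hidden"),
        ("color_hidden", "task_control"),
        ("task_control", "word_hidden"),
        ("word_hidden", "task_control"),
    ],
    "task_emotion_w": [("task_control", "emotion_hidden")],
    "emotion_task_w": [("emotion_hidden", "task_control")],
}


def apply_parameters(base: NetworkSpec, params: ParameterVector) -> NetworkSpec:
    """Build a fresh network spec with the parameter vector applied.

    Weight parameters rescale the magnitude of their blocks on the base
    connectivity pattern; layer-level gain/bias/integration parameters
    replace the unit parameters of every unit in their layer.
    """
    from .network import LayerSpec

    block_map = {}
    for name, targets in _WEIGHT_TARGETS.items():
        for key in targets:
            block_map[key] = params[name]

    weights = []
    for b in base.weights:
        key = (b.source_layer, b.target_layer)
        if key in block_map:
            pattern = (b.matrix != 0).astype(float)
            weights.append(WeightBlock(b.source_layer, b.target_layer, block_map[key] * pattern))
        else:
            weights.append(WeightBlock(b.source_layer, b.target_layer, b.matrix.copy()))

    layers = {}
    for name, lay in base.layers.items():
        if name == "task_control":
            up = [
                UnitParams(params["task_gain"], params["task_bias"], params["task_intg"])
            ] * lay.n_units
        elif name == "emotion_hidden":
            up = [
                UnitParams(
                    params["emotion_gain"], params["emotion_bias"], params["emotion_intg"]
                )
            ] * lay.n_units
        else:
            up = list(lay.unit_params)
        layers[name] = LayerSpec(name, list(lay.unit_labels), up, lay.lateral_inhibition)

    return NetworkSpec(
        layers=layers,
        weights=weights,
        response_threshold=base.response_threshold,
        settle_cycles=base.settle_cycles,
        max_cycles=base.max_cycles,
        integration_mode=base.integration_mode,
    )


def simulate_participant_means(base: NetworkSpec, params: ParameterVector, context: str):
    """Simulated (congruent, incongruent) mean RT in ms under one context."""
    spec = apply_parameters(base, params)
    means = condition_means(
        spec,
        [("congruent", context), ("incongruent", context)],
        K=params["K"],
        I=params["I"],
    )
    return means[("congruent", context)], means[("incongruent", context)]


# ---------------------------------------------------------------------------
# The evolutionary algorithm
# ---------------------------------------------------------------------------


def _evolve(objective, lo, hi, ea: EAConfig, rng: np.random.Generator, x0=None):
    """Generational real-valued GA.  Returns (best_x, best_f, history)."""
    d = lo.size
    pop = rng.uniform(lo, hi, size=(ea.population_size, d))
    if x0 is not None and ea.seed_defaults:
        pop[0] = np.clip(x0, lo, hi)
    fit = np.array([objective(x) for x in pop])
    order = np.argsort(fit)
    best_x, best_f = pop[order[0]].copy(), float(fit[order[0]])
    history = [best_f]
    span = hi - lo

    for _ in range(ea.generations):
        new = np.empty_like(pop)
        # elitism: carry the current best individuals over unchanged
        for e in range(ea.elitism):
            new[e] = pop[order[e % len(order)]]
        for m in range(ea.elitism, ea.population_size):
            p1 = _tournament(pop, fit, ea.tournament_size, rng)
            if rng.random() < ea.crossover_rate:
                p2 = _tournament(pop, fit, ea.tournament_size, rng)
                u = rng.random(d)
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mask = rng.random(d) < ea.mutation_rate
            child[mask] += rng.normal(0.0, ea.mutation_scale * span[mask])
            new[m] = np.clip(child, lo, hi)
        pop = new
        fit = np.array([objective(x) for x in pop])
        order = np.argsort(fit)
        if fit[order[0]] < best_f:
            best_f = float(fit[order[0]])
            best_x = pop[order[0]].copy()
        history.append(best_f)
    return best_x, best_f, history


def _tournament(pop, fit, k, rng):
    idx = rng.integers(0, len(pop), size=k)
    return pop[idx[np.argmin(fit[idx])]]


def fit_participant(
    data_means,
    variant: ModelVariant | str,
    bounds: ParameterBounds | None = None,
    ea: EAConfig | None = None,
    base_spec: NetworkSpec | None = None,
    context: str = "baseline",
    pid=None,
    seed: int | None = None,
) -> FitResult:
    """Fit one participant's condition means under a model variant.

    Fully reproducible given a seed; with elitism the best fitness is
    non-increasing across generations.  The result is flagged
    non-converged when even the best candidate is an overtime penalty.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    bounds = bounds or ParameterBounds()
    ea = ea or EAConfig()
    if base_spec is None:
        from .network import default_network

        base_spec = default_network()
    if seed is None:
        seed = ea.seed
    rng = np.random.default_rng(seed)
    names = list(variant.free)
    lo, hi = bounds.arrays(names)

    def evaluate(x):
        params = ParameterVector(dict(zip(names, x)))
        if ea.solve_scaling:
            cycles = simulate_participant_means(
                base_spec, ParameterVector({**params, "K": 1.0, "I": 0.0}), context
            )
            if cycles[0] is OVERTIME or cycles[1] is OVERTIME:
                return OVERTIME_PENALTY, params, cycles
            c_c, c_i = cycles
            k_lo, k_hi = bounds["K"]
            i_lo, i_hi = bounds["I"]
            if c_i != c_c:
                K = (data_means[1] - data_means[0]) / (c_i - c_c)
            else:
                K = params["K"]
            K = float(np.clip(K, k_lo, k_hi))
            I = float(np.clip((data_means[0] + data_means[1] - K * (c_c + c_i)) / 2.0,
                              i_lo, i_hi))
            params = ParameterVector({**params, "K": K, "I": I})
            sim = (c_c * K + I, c_i * K + I)
        else:
            sim = simulate_participant_means(base_spec, params, context)
        return fitness(data_means, sim), params, sim

    def objective(x):
        return evaluate(x)[0]

    x0 = np.array([PARAM_DEFAULTS[n] for n in names])
    best_x, best_f, history = _evolve(objective, lo, hi, ea, rng, x0=x0)
    best_f, best_params, sim = evaluate(best_x)
    converged = best_f < OVERTIME_PENALTY
    if not converged:
        logger.warning("participant %r: no overtime-free candidate found", pid)
    return FitResult(
        pid=pid,
        variant=variant.name,
        params=best_params,
        fitness=best_f,
        sim_means=sim,
        data_means=tuple(data_means),
        context=context,
        generations=ea.generations,
        seed=seed,
        converged=converged,
        history=history,
    )


def participant_seed(master_seed: int, pid) -> int:
    """Deterministic per-participant seed: CRC-32 mix of (master, pid)."""
    return (int(master_seed) ^ zlib.crc32(str(pid).encode("utf-8"))) % (2**31 - 1)


def cohort_condition_means(trials, use_correct_only: bool = True):
    """Per-participant (congruent, incongruent) mean RT from a trial table.

    Responded, in-window trials only; incorrect responses are dropped by
    default, matching the behavioural RT analyses.  Participants missing
    either condition are skipped with a logged reason.
    """
    import pandas as pd

    # canonical row order so means are identical whatever the input order
    sort_cols = [c for c in ("pid", "block", "trial") if c in trials.columns]
    std = trials.sort_values(sort_cols, kind="mergesort")
    std = std[std["task"] == "standard"]
    std = std[std["outcome"] != "overtime"]
    if use_correct_only:
        std = std[std["outcome"] == "correct"]
    out = {}
    for pid, grp in std.groupby("pid"):
        means = grp.groupby("congruency")["rt_ms"].mean()
        if "congruent" not in means or "incongruent" not in means:
            logger.warning("participant %r missing a condition; skipped", pid)
            continue
        out[pid] = (float(means["congruent"]), float(means["incongruent"]))
    return out


def fit_cohort(
    trials,
    variant: ModelVariant | str = "full",
    bounds: ParameterBounds | None = None,
    ea: EAConfig | None = None,
    base_spec: NetworkSpec | None = None,
    master_seed: int = 0,
    context_by_cb: dict[int, str] | None = None,
) -> list[FitResult]:
    """Fit every participant in a trial table, one at a time.

    The condition context follows the counterbalancing group: group 1
    performed the standard Stroop immediately after the rumination
    induction (induction context), group 2 after the emotional task
    (baseline context).  Per-participant seeds derive deterministically
    from the master seed, so participant order cannot change results.
    """
    context_by_cb = context_by_cb or {1: "induction", 2: "baseline"}
    means = cohort_condition_means(trials)
    cb_of = trials.groupby("pid")["cb"].first().to_dict()
    results = []
    for pid in sorted(means):
        ctx = context_by_cb[int(cb_of[pid])]
        res = fit_participant(
            means[pid],
            variant,
            bounds=bounds,
            ea=ea,
            base_spec=base_spec,
            context=ctx,
            pid=pid,
            seed=participant_seed(master_seed, pid),
        )
        logger.info(
            "fit pid=%r variant=%s fitness=%.3f converged=%s",
            pid,
            res.variant,
            res.fitness,
            res.converged,
        )
        results.append(res)
    return results
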