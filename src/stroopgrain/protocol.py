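"""Standard and emotional Stroop trial protocols for the network model.

A simulated trial has two phases.  First the network *settles* for a
fixed number of cycles under a clamp pattern encoding the condition
context: at baseline only the colour-naming goal unit is clamped on;
under the rumination-induction context the negative-valence unit of the
emotional-semantic layer and the emotional-processing goal unit are
additionally clamped on.  Then the clamps are lifted — goal units keep a
persistent external input of 1 (goal maintenance), emotional-layer
accumulators simply carry the induced state forward — the stimulus units
receive external input, and the network runs until one response unit
crosses threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import (
    OVERTIME,
    NetworkSpec,
    run_to_threshold,
    scale_rt,
    settle_phase,
)

__all__ = [
    "ConditionContext",
    "baseline_context",
    "induction_context",
    "TrialSpec",
    "SimResult",
    "build_trial",
    "simulate_trial",
    "condition_means",
]

#: External input applied to stimulus units during the response phase.
STIMULUS_INPUT = 1.0


@dataclass(frozen=True)
class ConditionContext:
    """A named clamp pattern applied during the settling phase."""

    label: str  # "baseline" | "induction"
    clamp_pattern: tuple[tuple[tuple[str, str], float], ...]

    def clamps(self) -> dict[tuple[str, str], float]:
        return dict(self.clamp_pattern)


def baseline_context() -> ConditionContext:
    """Pre-trial context without the rumination induction.

    Only the colour-naming goal is on; every other task-control and
    emotional-semantic unit is clamped to zero.
    """
    pattern = {
        ("task_control", "color_naming"): 1.0,
        ("task_control", "word_reading"): 0.0,
        ("task_control", "emotional_processing"): 0.0,
        ("emotion_hidden", "negative"): 0.0,
        ("emotion_hidden", "neutral"): 0.0,
        ("emotion_hidden", "positive"): 0.0,
    }
    return ConditionContext("baseline", tuple(sorted(pattern.items())))


def induction_context() -> ConditionContext:
    """Context immediately after the rumination/negative-mood induction.

    The negative-valence semantic unit and the emotional-processing goal
    are clamped on alongside colour naming, modelling heightened
    endogenous bottom-up emotional cues.
    """
    pattern = {
        ("task_control", "color_naming"): 1.0,
        ("task_control", "word_reading"): 0.0,
        ("task_control", "emotional_processing"): 1.0,
        ("emotion_hidden", "negative"): 1.0,
        ("emotion_hidden", "neutral"): 0.0,
        ("emotion_hidden", "positive"): 0.0,
    }
    return ConditionContext("induction", tuple(sorted(pattern.items())))


def context_by_label(label: str) -> ConditionContext:
    if label == "baseline":
        return baseline_context()
    if label == "induction":
        return induction_context()
    raise ValueError(f"unknown context label {label!r}")


@dataclass(frozen=True)
class TrialSpec:
    """One simulated Stroop trial: stimulus pattern plus condition context."""

    task: str  # "standard" | "emotional"
    color_unit: str
    word_unit: str | None
    valence_unit: str | None
    congruency: str | None  # "congruent" | "incongruent" | None
    context: ConditionContext


@dataclass(frozen=True)
class SimResult:
    rt_cycles: object  # int or OVERTIME
    rt_ms: object  # float or OVERTIME
    winner: str | None
    correct: bool | None

    @property
    def overtime(self) -> bool:
        return self.rt_cycles is OVERTIME


def build_trial(
    task: str,
    color: str,
    word: str | None = None,
    valence: str | None = None,
    context: ConditionContext | None = None,
    congruency: str | None = None,
) -> TrialSpec:
    """Validate and assemble a trial specification.

    Standard trials need a word and a colour (congruency follows from
    their identity); emotional trials need a valence category and a
    colour, and carry no congruency flag.
    """
    if context is None:
        context = baseline_context()
    if task == "standard":
        if word is None:
            raise ValueError("standard trials require a word unit")
        implied = "congruent" if word == color else "incongruent"
        if congruency is not None and congruency != implied:
            raise ValueError(
                f"congruency flag {congruency!r} inconsistent with word={word!r}, "
                f"color={color!r}"
            )
        return TrialSpec(task, color, word, None, implied, context)
    if task == "emotional":
        if valence not in ("negative", "neutral", "positive"):
            raise ValueError(f"emotional trials require a valence unit, got {valence!r}")
        if congruency is not None:
            raise ValueError("congruency is not applicable to emotional trials")
        return TrialSpec(task, color, None, valence, None, context)
    raise ValueError(f"unknown task {task!r}")


def simulate_trial(spec: NetworkSpec, trial: TrialSpec, K: float = 1.0, I: float = 0.0) -> SimResult:
    """Run one trial: settle under the context clamps, then respond.

    After settling, task-control clamps are replaced by a persistent
    external input of 1 to the same units (goal maintenance) and
    emotional-layer clamps are released so the induced accumulator state
    decays freely.  Stimulus units then receive external input and the
    network runs to the response threshold.  Deterministic.
    """
    state = settle_phase(spec, trial.context.clamps())

    # lift clamps; convert task goals into persistent external drive
    for (layer, label), value in trial.context.clamps().items():
        idx = spec.unit_index(layer, label)
        state.clamped[idx] = False
        if layer == "task_control" and value > 0:
            state.external_input[idx] = value
        if layer == "emotion_hidden":
            # carry the induced state forward through the accumulator
            state.integrated_net[idx] = _acc_for_activation(spec, idx, value)
            state.activation[idx] = _activation_from_acc(spec, state, idx)

    # stimulus inputs
    state.external_input[spec.unit_index("color_hidden", trial.color_unit)] += STIMULUS_INPUT
    if trial.word_unit is not None:
        state.external_input[spec.unit_index("word_hidden", trial.word_unit)] += STIMULUS_INPUT
    if trial.valence_unit is not None:
        state.external_input[
            spec.unit_index("emotion_hidden", trial.valence_unit)
        ] += STIMULUS_INPUT

    rt_cycles, winner = run_to_threshold(state, spec)
    rt_ms = scale_rt(rt_cycles, K, I)
    correct = None if rt_cycles is OVERTIME else (winner == trial.color_unit)
    return SimResult(rt_cycles, rt_ms, winner, correct)


def _acc_for_activation(spec: NetworkSpec, idx: int, a: float) -> float:
    """Accumulator value whose logistic output equals ``a``.

    Clipped away from {0, 1} so released units re-equilibrate on the
    integration-rate timescale instead of being frozen at infinity.
    """
    import math

    _, gain, bias, _ = spec.compact()
    a = min(max(a, 1e-3), 1.0 - 1e-3)
    return bias[idx] + math.log(a / (1.0 - a)) / gain[idx]


def _activation_from_acc(spec: NetworkSpec, state, idx: int) -> float:
    from .network import _stable_logistic
    import numpy as np

    _, gain, bias, _ = spec.compact()
    return float(
        _stable_logistic(
            np.array([state.integrated_net[idx]]), gain[idx : idx + 1], bias[idx : idx + 1]
        )[0]
    )


def condition_means(
    spec: NetworkSpec,
    conditions: list[tuple[str, str]],
    K: float = 1.0,
    I: float = 0.0,
    color: str = "red",
    other_color: str = "green",
) -> dict[tuple[str, str], object]:
    """Simulated mean RT (ms) per (congruency, context-label) condition.

    The dynamics are deterministic, so a single trial per condition
    suffices; overtime conditions are reported as ``OVERTIME`` for the
    caller's penalty handling.
    """
    out: dict[tuple[str, str], object] = {}
    for congruency, ctx_label in conditions:
        if congruency not in ("congruent", "incongruent"):
            raise ValueError(f"unknown congruency {congruency!r}")
        word = color if congruency == "congruent" else other_color
        trial = build_trial(
            "standard", color=color, word=word, context=context_by_label(ctx_label)
        )
        res = simulate_trial(spec, trial, K=K, I=I)
        out[(congruency, ctx_label)] = res.rt_ms
    return out
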