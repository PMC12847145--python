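"""Extended GRAIN interactive-activation network and its settling dynamics.

The model is a parallel-distributed-processing network in the Cohen &
Huston lineage: parallel colour, word and emotional-semantic pathways
compete for control of a two-unit response layer, moderated by top-down
input from a task-control layer.  Every unit is a logistic unit whose
net input is temporally integrated ("cascaded") so that activity builds
and decays gradually; within-layer connections are uniformly inhibitory,
implementing competition; between-layer connections are excitatory and
bidirectional.

Dynamics (one cycle, synchronous update):

    net_i(t)  = sum_j a_j(t-1) * w_{j,i} + ext_i
    x_i(t)    = (1 - tau_i) * x_i(t-1) + tau_i * net_i(t)
    a_i(t)    = 1 / (1 + exp(-k_i * (x_i(t) - x0_i)))

where ``x`` is the unit's integrated net input (its accumulator), ``tau``
the integration rate, ``k`` the gain and ``x0`` the bias (the inflection
point of the logistic).  Clamped units hold a fixed activation and do not
integrate.  An alternative mode integrating the *activation* rather than
the net input (``a(t) = (1-tau) a(t-1) + tau * logistic(net)``) is
provided for sensitivity analyses; the accumulator form is the default.

The dynamics are fully deterministic: a given specification, clamp
pattern and external input always produce bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

try:  # pragma: no cover - exercised implicitly by every simulation
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "OVERTIME",
    "UnitParams",
    "LayerSpec",
    "WeightBlock",
    "NetworkSpec",
    "NetworkState",
    "logistic_activation",
    "net_input",
    "integrate_step",
    "settle_phase",
    "run_to_threshold",
    "scale_rt",
    "default_network",
    "load_network",
    "save_network",
]


class _Overtime:
    """Sentinel for trials in which no response unit crossed threshold."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "overtime"

    def __bool__(self) -> bool:
        return False


#: Returned in place of a cycle count / latency when the response deadline
#: passes without a threshold crossing.
OVERTIME = _Overtime()


RESPONSE_THRESHOLD_DEFAULT = 0.55
SETTLE_CYCLES_DEFAULT = 50
MAX_CYCLES_DEFAULT = 1000

#: Canonical layer composition of the extended model.
LAYER_SIZES = {
    "color_hidden": 3,
    "word_hidden": 3,
    "emotion_hidden": 3,
    "task_control": 3,
    "response": 2,
}
LAYER_ORDER = ["color_hidden", "word_hidden", "emotion_hidden", "task_control", "response"]


# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitParams:
    """Logistic-unit parameters: gain ``k``, bias ``x0``, integration rate ``tau``.

    ``gain`` sets the steepness of the activation function, ``bias`` its
    inflection point (the net input at which activation is 0.5), and
    ``integration_rate`` the fraction of the instantaneous net input
    blended into the accumulator each cycle (small values give
    persistent activity).
    """

    gain: float = 1.0
    bias: float = 0.0
    integration_rate: float = 0.1

    def __post_init__(self):
        if not (self.gain > 0):
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if not (0.0 < self.integration_rate <= 1.0):
            raise ValueError(
                f"integration_rate must lie in (0, 1], got {self.integration_rate}"
            )
        if not math.isfinite(self.bias):
            raise ValueError("bias must be finite")


@dataclass
class LayerSpec:
    name: str
    unit_labels: list[str]
    unit_params: list[UnitParams]
    lateral_inhibition: float = 0.0

    def __post_init__(self):
        if self.name not in LAYER_SIZES:
            raise ValueError(f"unknown layer name {self.name!r}")
        if len(self.unit_labels) != LAYER_SIZES[self.name]:
            raise ValueError(
                f"layer {self.name!r} must have {LAYER_SIZES[self.name]} units, "
                f"got {len(self.unit_labels)}"
            )
        if len(self.unit_params) != len(self.unit_labels):
            raise ValueError("unit_params must match unit_labels in length")
        if self.lateral_inhibition > 0:
            raise ValueError("lateral_inhibition must be <= 0")

    @property
    def n_units(self) -> int:
        return len(self.unit_labels)


@dataclass
class WeightBlock:
    """Directed bundle of connections from one layer to another.

    Bidirectional pathways are represented by two blocks (forward and
    reverse) that are initialised symmetric but may be fitted
    asymmetrically.
    """

    source_layer: str
    target_layer: str
    matrix: np.ndarray  # (source units, target units)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected = (LAYER_SIZES[self.source_layer], LAYER_SIZES[self.target_layer])
        if self.matrix.shape != expected:
            raise ValueError(
                f"weight block {self.source_layer}->{self.target_layer} must have "
                f"shape {expected}, got {self.matrix.shape}"
            )


@dataclass
class NetworkSpec:
    """Full architecture: layers, weight blocks, threshold and cycle counts."""

    layers: dict[str, LayerSpec]
    weights: list[WeightBlock]
    response_threshold: float = RESPONSE_THRESHOLD_DEFAULT
    settle_cycles: int = SETTLE_CYCLES_DEFAULT
    max_cycles: int = MAX_CYCLES_DEFAULT
    integration_mode: str = "net_input"  # or "activation"

    def __post_init__(self):
        if not (0.0 < self.response_threshold < 1.0):
            raise ValueError("response_threshold must lie in (0, 1)")
        if self.settle_cycles < 1 or self.max_cycles < 1:
            raise ValueError("cycle counts must be positive")
        if self.integration_mode not in ("net_input", "activation"):
            raise ValueError("integration_mode must be 'net_input' or 'activation'")
        for block in self.weights:
            if block.source_layer not in self.layers or block.target_layer not in self.layers:
                raise ValueError(
                    f"weight block references undeclared layer: "
                    f"{block.source_layer}->{block.target_layer}"
                )
        # fixed global unit ordering
        self._offsets = {}
        off = 0
        for name in LAYER_ORDER:
            if name not in self.layers:
                raise ValueError(f"missing layer {name!r}")
            self._offsets[name] = off
            off += self.layers[name].n_units
        self._n_units = off
        self._compact = None

    # -- unit addressing ----------------------------------------------------

    @property
    def n_units(self) -> int:
        return self._n_units

    def unit_index(self, layer: str, label: str) -> int:
        if layer not in self.layers:
            raise KeyError(f"no layer named {layer!r}")
        try:
            j = self.layers[layer].unit_labels.index(label)
        except ValueError:
            raise KeyError(f"layer {layer!r} has no unit {label!r}") from None
        return self._offsets[layer] + j

    def unit_name(self, index: int) -> tuple[str, str]:
        for name in LAYER_ORDER:
            off = self._offsets[name]
            lay = self.layers[name]
            if off <= index < off + lay.n_units:
                return name, lay.unit_labels[index - off]
        raise IndexError(index)

    # -- dense compilation --------------------------------------------------

    def compact(self):
        """Compile to dense arrays ``(W, gain, bias, tau)``.

        ``W[j, i]`` is the weight from global unit j to global unit i,
        including lateral inhibition.  Cached; treat the spec as frozen
        after first use (``apply`` on a fitted parameter vector always
        builds a fresh spec).
        """
        if self._compact is None:
            n = self._n_units
            W = np.zeros((n, n))
            for block in self.weights:
                so = self._offsets[block.source_layer]
                to = self._offsets[block.target_layer]
                sn, tn = block.matrix.shape
                W[so : so + sn, to : to + tn] += block.matrix
            for name in LAYER_ORDER:
                lay = self.layers[name]
                off = self._offsets[name]
                li = lay.lateral_inhibition
                if li != 0.0:
                    for a in range(lay.n_units):
                        for b in range(lay.n_units):
                            if a != b:
                                W[off + a, off + b] += li
            gain = np.empty(n)
            bias = np.empty(n)
            tau = np.empty(n)
            for name in LAYER_ORDER:
                lay = self.layers[name]
                off = self._offsets[name]
                for j, p in enumerate(lay.unit_params):
                    gain[off + j] = p.gain
                    bias[off + j] = p.bias
                    tau[off + j] = p.integration_rate
            self._compact = (W, gain, bias, tau)
        return self._compact

    def response_indices(self) -> tuple[int, int]:
        off = self._offsets["response"]
        return off, off + 1


@dataclass
class NetworkState:
    """Mutable dynamical state: accumulators, activations, clamps, input."""

    integrated_net: np.ndarray
    activation: np.ndarray
    clamped: np.ndarray  # bool mask
    clamp_value: np.ndarray
    external_input: np.ndarray

    @classmethod
    def zeros(cls, spec: NetworkSpec) -> "NetworkState":
        n = spec.n_units
        state = cls(
            integrated_net=np.zeros(n),
            activation=np.zeros(n),
            clamped=np.zeros(n, dtype=bool),
            clamp_value=np.zeros(n),
            external_input=np.zeros(n),
        )
        _, gain, bias, _ = spec.compact()
        state.activation = _stable_logistic(state.integrated_net, gain, bias)
        return state

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.integrated_net.copy(),
            self.activation.copy(),
            self.clamped.copy(),
            self.clamp_value.copy(),
            self.external_input.copy(),
        )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def _stable_logistic(x: np.ndarray, gain: np.ndarray, bias: np.ndarray) -> np.ndarray:
    z = gain * (np.asarray(x, dtype=float) - bias)
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def logistic_activation(net: float, params: UnitParams) -> float:
    """Logistic activation ``1 / (1 + exp(-k (net - x0)))``, in (0, 1).

    Computed in a two-branch numerically stable form; strictly
    increasing in ``net``.
    """
    if not math.isfinite(net):
        raise ValueError(f"non-finite net input ({net}); upstream dynamics diverged")
    z = params.gain * (net - params.bias)
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def net_input(state: NetworkState, spec: NetworkSpec, unit: tuple[str, str] | int) -> float:
    """Weighted sum of presynaptic activations into one unit.

    Includes every incoming weight block, lateral inhibition from
    within-layer neighbours, and the unit's external input.
    """
    idx = unit if isinstance(unit, (int, np.integer)) else spec.unit_index(*unit)
    if not (0 <= idx < spec.n_units):
        raise KeyError(f"unit index {idx} out of range")
    W, _, _, _ = spec.compact()
    return float(W[:, idx] @ state.activation + state.external_input[idx])


def integrate_step(state: NetworkState, spec: NetworkSpec) -> NetworkState:
    """Advance the network by one synchronous cycle.

    Each unclamped unit blends the instantaneous net input into its
    accumulator at rate tau and re-applies the logistic; clamped units
    are left untouched.
    """
    W, gain, bias, tau = spec.compact()
    new = state.copy()
    net = W.T @ state.activation + state.external_input
    free = ~state.clamped
    if spec.integration_mode == "net_input":
        new.integrated_net[free] = (1.0 - tau[free]) * state.integrated_net[free] + tau[
            free
        ] * net[free]
        new.activation[free] = _stable_logistic(
            new.integrated_net[free], gain[free], bias[free]
        )
    else:  # integrate the activation itself
        inst = _stable_logistic(net, gain, bias)
        new.activation[free] = (1.0 - tau[free]) * state.activation[free] + tau[free] * inst[
            free
        ]
        new.integrated_net[free] = net[free]
    new.activation[state.clamped] = state.clamp_value[state.clamped]
    if not np.all(np.isfinite(new.integrated_net)):
        raise FloatingPointError("network dynamics produced non-finite accumulators")
    return new


@njit(cache=True)
def _run_cycles_kernel(
    W, gain, bias, tau, acc, act, ext, clamped, clamp_val, n_cycles, mode, check, thr, r0, r1
):  # pragma: no cover - compiled
    n = W.shape[0]
    net = np.empty(n)
    for t in range(n_cycles):
        for i in range(n):
            s = ext[i]
            for j in range(n):
                s += act[j] * W[j, i]
            net[i] = s
        for i in range(n):
            if clamped[i]:
                act[i] = clamp_val[i]
                continue
            if mode == 0:
                acc[i] = (1.0 - tau[i]) * acc[i] + tau[i] * net[i]
                z = gain[i] * (acc[i] - bias[i])
            else:
                z = gain[i] * (net[i] - bias[i])
            if z >= 0:
                a = 1.0 / (1.0 + math.exp(-z))
            else:
                ez = math.exp(z)
                a = ez / (1.0 + ez)
            if mode == 0:
                act[i] = a
            else:
                act[i] = (1.0 - tau[i]) * act[i] + tau[i] * a
                acc[i] = net[i]
        if check == 1 and (act[r0] > thr or act[r1] > thr):
            if act[r0] > act[r1]:
                return t + 1, 0
            if act[r1] > act[r0]:
                return t + 1, 1
            return t + 1, -2  # exact tie
    return -1, -1


def _run_cycles(state: NetworkState, spec: NetworkSpec, n_cycles: int, check_threshold: bool):
    """Run ``n_cycles`` cycles in place; optionally stop at threshold.

    Returns ``(cycles, winner_index)`` where ``cycles`` is -1 if no
    threshold check was requested or no unit crossed.
    """
    W, gain, bias, tau = spec.compact()
    r0, r1 = spec.response_indices()
    mode = 0 if spec.integration_mode == "net_input" else 1
    cycles, winner = _run_cycles_kernel(
        W,
        gain,
        bias,
        tau,
        state.integrated_net,
        state.activation,
        state.external_input,
        state.clamped,
        state.clamp_value,
        n_cycles,
        mode,
        1 if check_threshold else 0,
        spec.response_threshold,
        r0,
        r1,
    )
    if not np.all(np.isfinite(state.integrated_net)):
        raise FloatingPointError("network dynamics produced non-finite accumulators")
    return cycles, winner


def settle_phase(spec: NetworkSpec, clamps: dict[tuple[str, str], float]) -> NetworkState:
    """Settle the network under a clamp pattern for ``spec.settle_cycles`` cycles.

    Accumulators start at zero; the listed units are held at their clamp
    values (which must lie in [0, 1]) for every cycle.  Deterministic.
    """
    state = NetworkState.zeros(spec)
    for (layer, label), value in clamps.items():
        if not (0.0 <= value <= 1.0):
            raise ValueError(
                f"clamp value for {layer}.{label} must lie in [0, 1], got {value}"
            )
        idx = spec.unit_index(layer, label)
        state.clamped[idx] = True
        state.clamp_value[idx] = value
        state.activation[idx] = value
    _run_cycles(state, spec, spec.settle_cycles, check_threshold=False)
    return state


def run_to_threshold(state: NetworkState, spec: NetworkSpec):
    """Iterate cycles until a response unit exceeds threshold.

    Returns ``(rt_cycles, winner_label)``; ``(OVERTIME, None)`` if
    ``spec.max_cycles`` pass without a crossing.  If both response units
    cross on the same cycle the more active one wins; an exact tie is
    resolved deterministically in favour of the first response label.
    """
    cycles, winner = _run_cycles(state, spec, spec.max_cycles, check_threshold=True)
    labels = spec.layers["response"].unit_labels
    if cycles < 0:
        return OVERTIME, None
    if winner == -2:
        import logging

        logging.getLogger(__name__).debug(
            "exact response tie at cycle %d; first label %r wins", cycles, labels[0]
        )
        winner = 0
    return int(cycles), labels[winner]


def scale_rt(rt_cycles, K: float, I: float):
    """Map cycles to milliseconds: ``RT_ms = RT_cycles * K + I``.

    ``K`` (ms per cycle) rescales model time; ``I`` is a fixed offset for
    stimulus preprocessing and response execution.  Overtime passes
    through unscaled.
    """
    if rt_cycles is OVERTIME:
        return OVERTIME
    if K <= 0:
        raise ValueError("K must be positive")
    if I < 0:
        raise ValueError("I must be non-negative")
    if rt_cycles < 0:
        raise ValueError("rt_cycles must be non-negative")
    return rt_cycles * K + I


# ---------------------------------------------------------------------------
# Configuration file round-trip
# ---------------------------------------------------------------------------


def spec_to_config(spec: NetworkSpec) -> dict:
    return {
        "response_threshold": spec.response_threshold,
        "settle_cycles": spec.settle_cycles,
        "max_cycles": spec.max_cycles,
        "integration_mode": spec.integration_mode,
        "layers": {
            name: {
                "unit_labels": list(lay.unit_labels),
                "lateral_inhibition": lay.lateral_inhibition,
                "unit_params": [
                    {"gain": p.gain, "bias": p.bias, "integration_rate": p.integration_rate}
                    for p in lay.unit_params
                ],
            }
            for name, lay in spec.layers.items()
        },
        "weights": [
            {
                "source": b.source_layer,
                "target": b.target_layer,
                "matrix": b.matrix.tolist(),
            }
            for b in spec.weights
        ],
    }


def spec_from_config(cfg: dict) -> NetworkSpec:
    layers = {
        name: LayerSpec(
            name=name,
            unit_labels=list(lc["unit_labels"]),
            unit_params=[UnitParams(**p) for p in lc["unit_params"]],
            lateral_inhibition=float(lc.get("lateral_inhibition", 0.0)),
        )
        for name, lc in cfg["layers"].items()
    }
    weights = [
        WeightBlock(w["source"], w["target"], np.array(w["matrix"], dtype=float))
        for w in cfg["weights"]
    ]
    return NetworkSpec(
        layers=layers,
        weights=weights,
        response_threshold=float(cfg.get("response_threshold", RESPONSE_THRESHOLD_DEFAULT)),
        settle_cycles=int(cfg.get("settle_cycles", SETTLE_CYCLES_DEFAULT)),
        max_cycles=int(cfg.get("max_cycles", MAX_CYCLES_DEFAULT)),
        integration_mode=cfg.get("integration_mode", "net_input"),
    )


def load_network(path) -> NetworkSpec:
    """Load a network specification from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return spec_from_config(yaml.safe_load(fh))


def save_network(spec: NetworkSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec_to_config(spec), fh, sort_keys=False)


def default_network() -> NetworkSpec:
    """The shipped default parameterisation (see ``data/default_network.yaml``)."""
    from importlib.resources import files

    cfg = yaml.safe_load(
        files("stroopgrain.data").joinpath("default_network.yaml").read_text("utf-8")
    )
    return spec_from_config(cfg)
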