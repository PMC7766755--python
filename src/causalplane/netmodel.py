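"""Feedforward network model: layers, forward passes, initialization, checkpoints.

A network here is a stack of densely connected layers, each a weight matrix
``W`` of shape ``(n_in, n_out)`` followed by an elementwise activation at the
output nodes.  The object of study is the *causal mechanism* of each layer —
how upstream activations map to downstream activations — so every layer also
carries the per-node intervals over which interventions are drawn
(``input_range``) and over which its outputs are discretized (``output_range``).

Range conventions
-----------------
Interventions on a layer's inputs are uniform over the activation range of the
*upstream* nodes: (0, 1) for sigmoid, (−1, 1) for tanh, and [0, 1] for relu
(relu's unbounded codomain is truncated to [0, 1]; out-of-range outputs are
clipped into the boundary bin when discretizing).  The first layer of a
network, which has no upstream activation, uses [0, 1].
"""

from __future__ import annotations

import copy
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivationKind",
    "ACTIVATIONS",
    "get_activation",
    "FeedforwardLayer",
    "NetworkSpec",
    "initialize",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class ActivationKind:
    """An elementwise activation with its natural output interval.

    ``natural_output_range`` is the codomain of the function; ``bin_range`` is
    the finite interval actually used for binning activations (identical to the
    natural range except for relu, whose codomain [0, inf) is truncated).
    """

    name: str
    natural_output_range: tuple[float, float]
    bin_range: tuple[float, float]

    def __call__(self, z: np.ndarray) -> np.ndarray:
        if self.name == "sigmoid":
            return 1.0 / (1.0 + np.exp(-z))
        if self.name == "tanh":
            return np.tanh(z)
        if self.name == "relu":
            return np.maximum(z, 0.0)
        raise ValueError(f"unknown activation {self.name!r}")  # pragma: no cover

    def derivative_from_output(self, a: np.ndarray) -> np.ndarray:
        """d(activation)/d(pre-activation), expressed through the output value."""
        if self.name == "sigmoid":
            return a * (1.0 - a)
        if self.name == "tanh":
            return 1.0 - a * a
        if self.name == "relu":
            return (a > 0.0).astype(a.dtype)
        raise ValueError(f"unknown activation {self.name!r}")  # pragma: no cover


ACTIVATIONS: dict[str, ActivationKind] = {
    "sigmoid": ActivationKind("sigmoid", (0.0, 1.0), (0.0, 1.0)),
    "tanh": ActivationKind("tanh", (-1.0, 1.0), (-1.0, 1.0)),
    "relu": ActivationKind("relu", (0.0, math.inf), (0.0, 1.0)),
}

#: Perturbation range for data-input nodes (no upstream activation exists).
FIRST_LAYER_INPUT_RANGE: tuple[float, float] = (0.0, 1.0)


def get_activation(name: str) -> ActivationKind:
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; expected one of {sorted(ACTIVATIONS)}"
        ) from None


def _as_ranges(r, n: int) -> np.ndarray:
    """Normalize a range spec (pair or per-node array) to an (n, 2) float array."""
    arr = np.asarray(r, dtype=float)
    if arr.shape == (2,):
        arr = np.tile(arr, (n, 1))
    if arr.shape != (n, 2):
        raise ValueError(f"range must be a (lo, hi) pair or an ({n}, 2) array")
    if not np.all(arr[:, 1] > arr[:, 0]):
        raise ValueError("every range must have strictly positive width")
    return arr


@dataclass
class FeedforwardLayer:
    """One dense layer: ``output = activation(inputs @ weights (+ bias))``.

    Parameters
    ----------
    weights:
        ``(n_in, n_out)`` matrix; ``weights[i, j]`` is the edge i -> j.
    activation:
        Applied at the ``n_out`` output nodes.
    bias:
        Optional ``(n_out,)`` vector; absent by default.
    input_range, output_range:
        Per-node intervals; default to the upstream-activation convention
        described in the module docstring.
    """

    weights: np.ndarray
    activation: ActivationKind
    bias: np.ndarray | None = None
    input_range: np.ndarray = None  # type: ignore[assignment]
    output_range: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if isinstance(self.activation, str):
            self.activation = get_activation(self.activation)
        if self.weights.ndim != 2 or min(self.weights.shape) < 1:
            raise ValueError("weights must be a 2-D (n_in, n_out) matrix")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        n_in, n_out = self.weights.shape
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != (n_out,):
                raise ValueError(f"bias must have shape ({n_out},)")
            if not np.all(np.isfinite(self.bias)):
                raise ValueError("bias must be finite")
        if self.input_range is None:
            self.input_range = _as_ranges(FIRST_LAYER_INPUT_RANGE, n_in)
        else:
            self.input_range = _as_ranges(self.input_range, n_in)
        if self.output_range is None:
            self.output_range = _as_ranges(self.activation.bin_range, n_out)
        else:
            self.output_range = _as_ranges(self.output_range, n_out)

    @property
    def n_in(self) -> int:
        return self.weights.shape[0]

    @property
    def n_out(self) -> int:
        return self.weights.shape[1]

    def forward(self, inputs: np.ndarray) -> np.ndarray:
        """Forward pass for a single vector or a batch of row vectors."""
        x = np.asarray(inputs, dtype=float)
        if x.shape[-1] != self.n_in:
            raise ValueError(
                f"expected {self.n_in} inputs, got {x.shape[-1]}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("inputs must be finite")
        z = x @ self.weights
        if self.bias is not None:
            z = z + self.bias
        return self.activation(z)

    def copy(self) -> "FeedforwardLayer":
        return FeedforwardLayer(
            weights=self.weights.copy(),
            activation=self.activation,
            bias=None if self.bias is None else self.bias.copy(),
            input_range=self.input_range.copy(),
            output_range=self.output_range.copy(),
        )


def forward(layer: FeedforwardLayer, inputs: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`FeedforwardLayer.forward`."""
    return layer.forward(inputs)


@dataclass
class NetworkSpec:
    """An ordered stack of layers plus checkpoint metadata."""

    layers: list[FeedforwardLayer]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a network needs at least one layer")
        for k in range(len(self.layers) - 1):
            if self.layers[k].n_out != self.layers[k + 1].n_in:
                raise ValueError(
                    "layer dimension chain violated: layer "
                    f"{k} has {self.layers[k].n_out} outputs but layer "
                    f"{k + 1} has {self.layers[k + 1].n_in} inputs"
                )

    @property
    def architecture(self) -> list[int]:
        return [self.layers[0].n_in] + [l.n_out for l in self.layers]

    @property
    def activation(self) -> ActivationKind:
        return self.layers[0].activation

    def forward(self, inputs: np.ndarray) -> np.ndarray:
        a = np.asarray(inputs, dtype=float)
        for layer in self.layers:
            a = layer.forward(a)
        return a

    def copy(self) -> "NetworkSpec":
        return NetworkSpec(
            layers=[l.copy() for l in self.layers],
            metadata=copy.deepcopy(self.metadata),
        )


def initialize(
    architecture: list[int],
    activation: str | ActivationKind = "sigmoid",
    seed: int = 0,
    bias: bool = False,
) -> NetworkSpec:
    """Build a network with uniform fan-in initialization.

    Every weight of a layer with ``fanin`` inputs is drawn i.i.d. from
    ``U(−1/sqrt(fanin), +1/sqrt(fanin))``; biases are absent by default.
    """
    if len(architecture) < 2:
        raise ValueError("architecture needs at least an input and an output width")
    if any(int(w) < 1 for w in architecture):
        raise ValueError("layer widths must be positive")
    act = get_activation(activation) if isinstance(activation, str) else activation
    rng = np.random.default_rng(seed)
    layers = []
    for k, (n_in, n_out) in enumerate(zip(architecture[:-1], architecture[1:])):
        bound = 1.0 / math.sqrt(n_in)
        W = rng.uniform(-bound, bound, size=(n_in, n_out))
        in_range = FIRST_LAYER_INPUT_RANGE if k == 0 else act.bin_range
        layers.append(
            FeedforwardLayer(
                weights=W,
                activation=act,
                bias=np.zeros(n_out) if bias else None,
                input_range=in_range,
            )
        )
    return NetworkSpec(layers=layers, metadata={"seed": seed})


def save_network(net: NetworkSpec, path: str | os.PathLike) -> None:
    """Serialize to the documented JSON schema (weights as decimal text)."""
    doc = {
        "architecture": net.architecture,
        "activation": net.activation.name,
        "layers": [
            {
                "weights": l.weights.tolist(),
                "bias": None if l.bias is None else l.bias.tolist(),
            }
            for l in net.layers
        ],
        "meta": net.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_network(path: str | os.PathLike) -> NetworkSpec:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed network file {path}: {exc}") from exc
    for key in ("architecture", "activation", "layers"):
        if key not in doc:
            raise ValueError(f"malformed network file {path}: missing {key!r}")
    act = get_activation(doc["activation"])
    arch = [int(w) for w in doc["architecture"]]
    layers = []
    for k, ldoc in enumerate(doc["layers"]):
        W = np.asarray(ldoc["weights"], dtype=float)
        expected = (arch[k], arch[k + 1]) if k + 1 < len(arch) else None
        if expected is not None and W.shape != expected:
            raise ValueError(
                f"layer {k} weights have shape {W.shape}, "
                f"architecture says {expected}"
            )
        in_range = FIRST_LAYER_INPUT_RANGE if k == 0 else act.bin_range
        layers.append(
            FeedforwardLayer(
                weights=W,
                activation=act,
                bias=None if ldoc.get("bias") is None else np.asarray(ldoc["bias"]),
                input_range=in_range,
            )
        )
    if len(layers) != len(arch) - 1:
        raise ValueError("number of layers does not match architecture")
    return NetworkSpec(layers=layers, metadata=doc.get("meta", {}))
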