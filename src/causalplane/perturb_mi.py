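"""Maximum-entropy interventions, activation binning, and plug-in mutual information.

The effective information (EI) of a layer is the mutual information between the
layer's input and output states when the inputs are forced to a maximum-entropy
distribution — i.i.d. uniform over each input node's activation range::

    EI = I(L1; L2) | do(L1 = Hmax)

Activations are discretized into uniform-width bins over fixed per-node ranges
and the MI is the plug-in (maximum-likelihood histogram) estimate in bits.  No
bias correction is applied; instead the estimator exposes a convergence trace
(estimates at doubling sample counts) so the sampling error is visible.  The
plug-in estimate is biased upward at small sample counts, most severely for
wide layers whose joint state space dwarfs the sample count.

Joint states are counted sparsely (a hash map keyed by the tuple of bin
indices), so memory is proportional to the number of *observed* joint states,
never to ``n_bins ** n_nodes``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .netmodel import FeedforwardLayer

__all__ = [
    "InterventionConfig",
    "BinningScheme",
    "PerturbationSample",
    "MIEstimate",
    "sample_intervention",
    "discretize",
    "mutual_information",
    "effective_information",
    "converge_ei",
    "quadrature_ei",
]

#: Use dense joint-histogram accumulation when the full joint state space is
#: at most this many cells; otherwise fall back to sparse byte-keyed counting.
_DENSE_LIMIT = 1 << 22


@dataclass(frozen=True)
class InterventionConfig:
    """Sample budget, seed, and streaming batch size for one noise injection."""

    n_samples: int = 10_000_000
    seed: int = 0
    batch_size: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class BinningScheme:
    """Uniform-width bins over fixed per-node ranges.

    Bins are half-open ``[lo, hi)`` except the top bin, which is closed;
    out-of-range values are clipped into the boundary bins.
    """

    n_bins: int
    ranges: np.ndarray  # (n_nodes, 2)

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        r = np.asarray(self.ranges, dtype=float)
        if r.ndim == 1:
            r = r[None, :]
        if r.shape[-1] != 2 or np.any(r[:, 1] <= r[:, 0]):
            raise ValueError("every binning range must have positive width")
        object.__setattr__(self, "ranges", r)

    @property
    def n_nodes(self) -> int:
        return self.ranges.shape[0]

    @classmethod
    def for_inputs(cls, layer: FeedforwardLayer, n_bins: int) -> "BinningScheme":
        return cls(n_bins, layer.input_range)

    @classmethod
    def for_outputs(cls, layer: FeedforwardLayer, n_bins: int) -> "BinningScheme":
        return cls(n_bins, layer.output_range)

    def bin_indices(self, values: np.ndarray) -> np.ndarray:
        """Map ``(n, n_nodes)`` activations to integer bin indices."""
        v = np.atleast_2d(np.asarray(values, dtype=float))
        lo = self.ranges[:, 0]
        width = self.ranges[:, 1] - lo
        idx = np.floor((v - lo) / width * self.n_bins).astype(np.int64)
        return np.clip(idx, 0, self.n_bins - 1)


def discretize(values: np.ndarray, scheme: BinningScheme) -> np.ndarray:
    """Joint-state labels: one integer per row of ``values``.

    When the full state space fits an int64 the label is the positional code
    of the bin tuple; otherwise rows are relabeled by first occurrence order
    (still deterministic for given data).
    """
    idx = scheme.bin_indices(values)
    k = idx.shape[1]
    if k * math.log2(scheme.n_bins) < 62:
        return np.ravel_multi_index(idx.T, (scheme.n_bins,) * k)
    _, inverse = np.unique(idx, axis=0, return_inverse=True)
    return inverse


@dataclass
class PerturbationSample:
    """Paired realization of the intervention and effect distributions."""

    input_states: np.ndarray  # (n_samples, n_in)
    output_states: np.ndarray  # (n_samples, n_out)


@dataclass
class MIEstimate:
    """A plug-in mutual-information value with its estimation metadata."""

    value_bits: float
    n_samples: int
    n_bins: int | None = None
    n_distinct_joint_states: int = 0
    trace: list[tuple[int, float]] = field(default_factory=list)
    converged: bool | None = None


def _draw_inputs(rng: np.random.Generator, layer: FeedforwardLayer, n: int) -> np.ndarray:
    lo = layer.input_range[:, 0]
    hi = layer.input_range[:, 1]
    return rng.uniform(lo, hi, size=(n, layer.n_in))


def sample_intervention(
    layer: FeedforwardLayer, cfg: InterventionConfig
) -> PerturbationSample:
    """Materialize paired (intervention, effect) samples for a layer.

    Memory is ``n_samples * (n_in + n_out)`` floats; for large budgets prefer
    :func:`effective_information`, which streams in batches.
    """
    rng = np.random.default_rng(cfg.seed)
    x = _draw_inputs(rng, layer, cfg.n_samples)
    return PerturbationSample(input_states=x, output_states=layer.forward(x))


def _entropy_bits(counts: np.ndarray, n: int) -> float:
    c = counts[counts > 0].astype(float)
    if c.size <= 1:
        return 0.0
    return math.log2(n) - float(c @ np.log2(c)) / n


def mutual_information(x_labels: np.ndarray, y_labels: np.ndarray) -> MIEstimate:
    """Plug-in MI between two equal-length label sequences, in bits."""
    x = np.asarray(x_labels).ravel()
    y = np.asarray(y_labels).ravel()
    if x.size == 0:
        raise ValueError("empty label sequences")
    if x.size != y.size:
        raise ValueError("label sequences must have equal length")
    n = x.size
    _, cx = np.unique(x, return_counts=True)
    _, cy = np.unique(y, return_counts=True)
    _, cxy = np.unique(np.stack([x, y], axis=1), axis=0, return_counts=True)
    hx, hy = _entropy_bits(cx, n), _entropy_bits(cy, n)
    if hx == 0.0 or hy == 0.0:
        value = 0.0
    else:
        value = max(0.0, hx + hy - _entropy_bits(cxy, n))
    return MIEstimate(value, n, n_distinct_joint_states=cxy.size)


class _JointCounter:
    """Streaming joint/marginal state counter for one (inputs, outputs) channel.

    Dense (``bincount``) when the joint state space is small, sparse byte-keyed
    hash maps otherwise.  MI can be read off at any point of the stream.
    """

    def __init__(self, n_bins: int, n_in: int, n_out: int) -> None:
        self.n_bins, self.n_in, self.n_out = n_bins, n_in, n_out
        self.n = 0
        self._dense = n_bins ** (n_in + n_out) <= _DENSE_LIMIT
        if self._dense:
            self._joint = np.zeros(n_bins ** (n_in + n_out), dtype=np.int64)
            self._cx = np.zeros(n_bins**n_in, dtype=np.int64)
            self._cy = np.zeros(n_bins**n_out, dtype=np.int64)
        else:
            self._dj: dict[bytes, int] = {}
            self._dx: dict[bytes, int] = {}
            self._dy: dict[bytes, int] = {}
            self._key_dtype = np.uint8 if n_bins <= 256 else np.uint16

    def _sparse_update(self, d: dict, idx: np.ndarray) -> None:
        dtype = self._key_dtype
        rows = np.ascontiguousarray(idx.astype(dtype))
        view = rows.view([("", dtype)] * rows.shape[1]).ravel()
        uniq, counts = np.unique(view, return_counts=True)
        raw = uniq.tobytes()
        stride = uniq.dtype.itemsize
        for k in range(uniq.size):
            key = raw[k * stride : (k + 1) * stride]
            d[key] = d.get(key, 0) + int(counts[k])

    def update(self, in_idx: np.ndarray, out_idx: np.ndarray) -> None:
        b = in_idx.shape[0]
        if self._dense:
            B = self.n_bins
            xi = np.ravel_multi_index(in_idx.T, (B,) * self.n_in)
            yi = np.ravel_multi_index(out_idx.T, (B,) * self.n_out)
            np.add.at(self._cx, xi, 1)
            np.add.at(self._cy, yi, 1)
            np.add.at(self._joint, xi * (B**self.n_out) + yi, 1)
        else:
            self._sparse_update(self._dx, in_idx)
            self._sparse_update(self._dy, out_idx)
            self._sparse_update(self._dj, np.concatenate([in_idx, out_idx], axis=1))
        self.n += b

    def _counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._dense:
            return self._cx, self._cy, self._joint
        to_arr = lambda d: np.fromiter(d.values(), dtype=np.int64, count=len(d))
        return to_arr(self._dx), to_arr(self._dy), to_arr(self._dj)

    def mi_bits(self) -> float:
        cx, cy, cj = self._counts()
        hx = _entropy_bits(cx, self.n)
        hy = _entropy_bits(cy, self.n)
        if hx == 0.0 or hy == 0.0:
            return 0.0
        return max(0.0, hx + hy - _entropy_bits(cj, self.n))

    @property
    def n_distinct_joint_states(self) -> int:
        if self._dense:
            return int(np.count_nonzero(self._joint))
        return len(self._dj)


def _stream_ei(
    layer: FeedforwardLayer,
    n_bins: int,
    seed: int,
    batch_size: int,
    max_samples: int,
    tol: float | None,
    min_samples: int,
    scheme_in: BinningScheme | None = None,
    scheme_out: BinningScheme | None = None,
) -> MIEstimate:
    """Core streaming EI loop with estimates recorded at doubling sample counts.

    With ``tol`` set, stops early once successive doubling estimates differ by
    less than ``tol`` bits; otherwise runs to ``max_samples`` exactly.
    """
    scheme_in = scheme_in or BinningScheme.for_inputs(layer, n_bins)
    scheme_out = scheme_out or BinningScheme.for_outputs(layer, n_bins)
    rng = np.random.default_rng(seed)
    counter = _JointCounter(n_bins, layer.n_in, layer.n_out)
    trace: list[tuple[int, float]] = []
    checkpoint = min(min_samples, max_samples)
    converged = None if tol is None else False
    while counter.n < max_samples:
        b = min(batch_size, checkpoint - counter.n)
        x = _draw_inputs(rng, layer, b)
        counter.update(scheme_in.bin_indices(x), scheme_out.bin_indices(layer.forward(x)))
        if counter.n >= checkpoint:
            trace.append((counter.n, counter.mi_bits()))
            if tol is not None and len(trace) >= 2:
                if abs(trace[-1][1] - trace[-2][1]) < tol:
                    converged = True
                    break
            checkpoint = min(2 * checkpoint, max_samples)
            if tol is None and trace[-1][0] >= max_samples:
                break
    value = trace[-1][1]
    return MIEstimate(
        value_bits=value,
        n_samples=counter.n,
        n_bins=n_bins,
        n_distinct_joint_states=counter.n_distinct_joint_states,
        trace=trace,
        converged=converged,
    )


def effective_information(
    layer: FeedforwardLayer,
    cfg: InterventionConfig,
    scheme: int | BinningScheme = 16,
    scheme_out: BinningScheme | None = None,
) -> MIEstimate:
    """EI of a layer: joint max-entropy intervention, binning, plug-in MI.

    ``scheme`` may be a bin count (ranges taken from the layer) or an explicit
    input :class:`BinningScheme` (then ``scheme_out`` must be given too).
    """
    if isinstance(scheme, BinningScheme):
        n_bins = scheme.n_bins
        scheme_in = scheme
    else:
        n_bins = int(scheme)
        scheme_in = None
    return _stream_ei(
        layer,
        n_bins,
        cfg.seed,
        cfg.batch_size,
        max_samples=cfg.n_samples,
        tol=None,
        min_samples=min(cfg.n_samples, cfg.batch_size),
        scheme_in=scheme_in,
        scheme_out=scheme_out,
    )


def converge_ei(
    layer: FeedforwardLayer,
    scheme: int | BinningScheme = 16,
    tol: float = 0.01,
    max_samples: int = 10_000_000,
    seed: int = 0,
    start_samples: int = 8192,
    batch_size: int = 1_000_000,
) -> MIEstimate:
    """EI with a doubling schedule: stop when successive estimates agree.

    Doubles the cumulative sample count until two successive estimates differ
    by less than ``tol`` bits or ``max_samples`` is reached; non-convergence is
    flagged on the result (``converged=False``), never raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if isinstance(scheme, BinningScheme):
        n_bins, scheme_in = scheme.n_bins, scheme
    else:
        n_bins, scheme_in = int(scheme), None
    return _stream_ei(
        layer,
        n_bins,
        seed,
        batch_size,
        max_samples=max_samples,
        tol=tol,
        min_samples=start_samples,
        scheme_in=scheme_in,
    )


def quadrature_ei(
    layer: FeedforwardLayer,
    n_bins: int = 16,
    cells_per_dim: int | None = None,
) -> float:
    """Deterministic midpoint-quadrature EI for 1- and 2-input layers.

    Partitions each input range into equal cells, pushes every cell midpoint
    through the layer with its exact probability mass, and computes the MI of
    the resulting joint bin table.  Serves as an independent oracle for the
    Monte-Carlo estimator; no random numbers are involved.
    """
    if layer.n_in > 2:
        raise ValueError("quadrature oracle supports at most 2 input nodes")
    if cells_per_dim is None:
        cells_per_dim = 100_000 if layer.n_in == 1 else 2048
    B = n_bins
    mids = []
    for i in range(layer.n_in):
        lo, hi = layer.input_range[i]
        mids.append(lo + (np.arange(cells_per_dim) + 0.5) / cells_per_dim * (hi - lo))
    if layer.n_in == 1:
        x = mids[0][:, None]
    else:
        a, b = np.meshgrid(mids[0], mids[1], indexing="ij")
        x = np.column_stack([a.ravel(), b.ravel()])
    y = layer.forward(x)

    def _bin(v: np.ndarray, ranges: np.ndarray) -> np.ndarray:
        lo = ranges[:, 0]
        w = ranges[:, 1] - lo
        return np.clip(np.floor((v - lo) / w * B).astype(np.int64), 0, B - 1)

    xi = np.ravel_multi_index(_bin(x, layer.input_range).T, (B,) * layer.n_in)
    yi = np.ravel_multi_index(_bin(y, layer.output_range).T, (B,) * layer.n_out)
    n = x.shape[0]
    cj = np.bincount(xi * (B**layer.n_out) + yi)
    hx = _entropy_bits(np.bincount(xi), n)
    hy = _entropy_bits(np.bincount(yi), n)
    if hx == 0.0 or hy == 0.0:
        return 0.0
    return max(0.0, hx + hy - _entropy_bits(cj, n))
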