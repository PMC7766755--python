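"""Decomposition of effective information into sensitivity and degeneracy,
pairwise EI (EI_parts), and feedforward integrated information.

Definitions, all in bits and all under uniform maximum-entropy interventions:

``sensitivity``
    Sum over edges (i, j) of the MI between node i's injected activation and
    node j's response when j is driven through that single edge alone
    (``activation(w_ij * t_i)``, all other incoming edges removed).  Measures
    how well perturbations transmit in the absence of interaction effects.

``degeneracy``
    ``sensitivity - EI``, the information lost because overlapping incoming
    connections make the upstream source of a perturbation ambiguous.  An
    algebraic identity, exact by construction; small negative values from
    Monte-Carlo noise are reported as-is, never clamped.

``EI_parts``
    Sum over (i, j) pairs of the *pairwise* MI between node i's sample and
    node j's sample under a *joint* perturbation of the whole input layer —
    distinguished from sensitivity by the joint injection.

``phi_feedforward``
    ``EI - EI_parts``: the irreducible joint (integrated) effects of one layer
    on the next.  Unbounded below; a negative value means the higher-order
    joint effects are mostly noisy rather than informative.

The causal plane plots degeneracy (x) against sensitivity (y); the 45-degree
line y = x is the EI nullcline — displacement along it leaves EI unchanged.

Edges with exactly zero weight contribute exactly 0 bits to the sensitivity
and EI_parts sums (their targets are constant or independent of the source),
so they are skipped rather than estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netmodel import ActivationKind, FeedforwardLayer, get_activation
from .perturb_mi import (
    BinningScheme,
    InterventionConfig,
    MIEstimate,
    _entropy_bits,
    _JointCounter,
)

__all__ = [
    "EIResult",
    "CausalPlanePoint",
    "measure_layer",
    "sensitivity",
    "degeneracy",
    "ei_parts",
    "phi_feedforward",
    "ei_curve_single_edge",
    "ei_manifold_two_inputs",
    "causal_plane_point",
]


@dataclass
class EIResult:
    """Full causal-structure measurement of one layer at one point in time."""

    ei_bits: float
    sensitivity_bits: float
    degeneracy_bits: float
    ei_parts_bits: float
    phi_feedforward_bits: float
    n_samples: int
    n_bins: int
    seed: int
    layer: int = 0
    step: int | None = None
    converged: bool | None = None
    trace: list[tuple[int, float]] = field(default_factory=list)


@dataclass(frozen=True)
class CausalPlanePoint:
    """Position in the causal plane: degeneracy on x, sensitivity on y."""

    degeneracy: float
    sensitivity: float
    step: int | None = None
    layer: int = 0

    @property
    def nullcline_distance(self) -> float:
        """Perpendicular distance from the EI nullcline y = x."""
        return abs(self.sensitivity - self.degeneracy) / math.sqrt(2.0)


def causal_plane_point(result: EIResult) -> CausalPlanePoint:
    """Project an :class:`EIResult` onto the causal plane."""
    return CausalPlanePoint(
        degeneracy=result.degeneracy_bits,
        sensitivity=result.sensitivity_bits,
        step=result.step,
        layer=result.layer,
    )


def _pair_mi_from_counts(cj: np.ndarray, cx: np.ndarray, cy: np.ndarray, n: int) -> float:
    hx, hy = _entropy_bits(cx, n), _entropy_bits(cy, n)
    if hx == 0.0 or hy == 0.0:
        return 0.0
    return max(0.0, hx + hy - _entropy_bits(cj, n))


def _sensitivity_streamed(
    layer: FeedforwardLayer,
    cfg: InterventionConfig,
    n_bins: int,
    seed_seq: np.random.SeedSequence,
) -> float:
    """Sum of isolated-edge MIs; each source node gets its own sub-stream."""
    B = n_bins
    total = 0.0
    children = seed_seq.spawn(layer.n_in)
    out_ranges = layer.output_range
    for i in range(layer.n_in):
        targets = np.flatnonzero(layer.weights[i])
        if targets.size == 0:
            continue
        rng = np.random.default_rng(children[i])
        lo_i, hi_i = layer.input_range[i]
        counts = np.zeros((targets.size, B * B), dtype=np.int64)
        remaining = cfg.n_samples
        while remaining > 0:
            b = min(cfg.batch_size, remaining)
            t = rng.uniform(lo_i, hi_i, size=b)
            ti = np.clip(((t - lo_i) / (hi_i - lo_i) * B).astype(np.int64), 0, B - 1)
            # isolated edge: target j sees w_ij * t_i only
            y = layer.activation(np.outer(t, layer.weights[i, targets]))
            for k, j in enumerate(targets):
                lo_j, w_j = out_ranges[j, 0], out_ranges[j, 1] - out_ranges[j, 0]
                yi = np.clip(((y[:, k] - lo_j) / w_j * B).astype(np.int64), 0, B - 1)
                np.add.at(counts[k], ti * B + yi, 1)
            remaining -= b
        n = cfg.n_samples
        for k in range(targets.size):
            cj = counts[k]
            cx = cj.reshape(B, B).sum(axis=1)
            cy = cj.reshape(B, B).sum(axis=0)
            total += _pair_mi_from_counts(cj, cx, cy, n)
    return total


def measure_layer(
    layer: FeedforwardLayer,
    cfg: InterventionConfig,
    n_bins: int = 16,
    convergence_tol: float = 0.01,
    layer_index: int = 0,
    step: int | None = None,
) -> EIResult:
    """Measure EI, sensitivity, degeneracy, EI_parts and phi for one layer.

    EI and EI_parts are computed from the *same* joint injection (common
    random numbers, so their difference phi has reduced variance); sensitivity
    uses independent per-node sub-streams derived from the same master seed.
    The convergence flag compares EI estimates at the last two doubling
    checkpoints of the stream against ``convergence_tol`` bits.
    """
    B = n_bins
    ss = np.random.SeedSequence(cfg.seed)
    joint_ss, sens_ss = ss.spawn(2)
    scheme_in = BinningScheme.for_inputs(layer, B)
    scheme_out = BinningScheme.for_outputs(layer, B)

    rng = np.random.default_rng(joint_ss)
    counter = _JointCounter(B, layer.n_in, layer.n_out)
    pairs = np.argwhere(layer.weights != 0.0)
    pair_counts = np.zeros((len(pairs), B * B), dtype=np.int64)
    in_counts = np.zeros((layer.n_in, B), dtype=np.int64)
    out_counts = np.zeros((layer.n_out, B), dtype=np.int64)

    trace: list[tuple[int, float]] = []
    checkpoint = min(cfg.batch_size, cfg.n_samples)
    lo = layer.input_range[:, 0]
    hi = layer.input_range[:, 1]
    done = 0
    while done < cfg.n_samples:
        b = min(cfg.batch_size, checkpoint - done)
        x = rng.uniform(lo, hi, size=(b, layer.n_in))
        y = layer.forward(x)
        xi = scheme_in.bin_indices(x)
        yi = scheme_out.bin_indices(y)
        counter.update(xi, yi)
        for p, (i, j) in enumerate(pairs):
            np.add.at(pair_counts[p], xi[:, i] * B + yi[:, j], 1)
        for i in range(layer.n_in):
            np.add.at(in_counts[i], xi[:, i], 1)
        for j in range(layer.n_out):
            np.add.at(out_counts[j], yi[:, j], 1)
        done += b
        if done >= checkpoint:
            trace.append((done, counter.mi_bits()))
            checkpoint = min(2 * checkpoint, cfg.n_samples)

    n = cfg.n_samples
    ei = trace[-1][1]
    parts = 0.0
    for p, (i, j) in enumerate(pairs):
        parts += _pair_mi_from_counts(pair_counts[p], in_counts[i], out_counts[j], n)
    sens = _sensitivity_streamed(layer, cfg, B, sens_ss)
    converged = None
    if len(trace) >= 2:
        converged = abs(trace[-1][1] - trace[-2][1]) < convergence_tol
    return EIResult(
        ei_bits=ei,
        sensitivity_bits=sens,
        degeneracy_bits=sens - ei,
        ei_parts_bits=parts,
        phi_feedforward_bits=ei - parts,
        n_samples=n,
        n_bins=B,
        seed=cfg.seed,
        layer=layer_index,
        step=step,
        converged=converged,
        trace=trace,
    )


def sensitivity(
    layer: FeedforwardLayer, cfg: InterventionConfig, n_bins: int = 16
) -> float:
    """Sum over edges of the isolated-edge EI (per-edge max-entropy injection)."""
    ss = np.random.SeedSequence(cfg.seed)
    _, sens_ss = ss.spawn(2)
    return _sensitivity_streamed(layer, cfg, n_bins, sens_ss)


def degeneracy(
    layer: FeedforwardLayer, cfg: InterventionConfig, n_bins: int = 16
) -> float:
    """``sensitivity - EI`` with shared configuration (exact identity)."""
    res = measure_layer(layer, cfg, n_bins)
    return res.degeneracy_bits


def ei_parts(
    layer: FeedforwardLayer, cfg: InterventionConfig, n_bins: int = 16
) -> float:
    """Sum of pairwise node-to-node MIs under a joint max-entropy injection."""
    return measure_layer(layer, cfg, n_bins).ei_parts_bits


def phi_feedforward(
    layer: FeedforwardLayer, cfg: InterventionConfig, n_bins: int = 16
) -> float:
    """``EI - EI_parts`` on shared samples; may be negative."""
    return measure_layer(layer, cfg, n_bins).phi_feedforward_bits


def _single_edge_layer(
    activation: ActivationKind, w: float, input_range=None
) -> FeedforwardLayer:
    return FeedforwardLayer(
        weights=np.array([[w]]),
        activation=activation,
        input_range=activation.bin_range if input_range is None else input_range,
    )


def ei_curve_single_edge(
    activation: str | ActivationKind,
    weight_grid: np.ndarray | None = None,
    n_bins: int = 16,
    n_samples: int = 1_000_000,
    seed: int = 0,
    input_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """EI of an isolated A -> B edge at each weight of a grid.

    The same uniform input draw is shared across all grid weights (common
    random numbers), which makes the curve smooth in ``w`` and the located
    argmax stable at the exact plug-in optimum for the given bin count.

    Returns a tidy frame with columns ``weight`` and ``ei_bits``; the grid
    argmax and its resolution are attached as ``df.attrs["argmax_weight"]``
    and ``df.attrs["grid_step"]``.
    """
    act = get_activation(activation) if isinstance(activation, str) else activation
    if weight_grid is None:
        weight_grid = np.arange(0.0, 6.0 + 1e-12, 0.01)
    ws = np.asarray(weight_grid, dtype=float)
    if ws.size == 0:
        raise ValueError("empty weight grid")
    B = n_bins
    ref = _single_edge_layer(act, 1.0, input_range)
    lo, hi = ref.input_range[0]
    olo, ohi = ref.output_range[0]
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=n_samples)
    xi = np.clip(((x - lo) / (hi - lo) * B).astype(np.int64), 0, B - 1)
    cx = np.bincount(xi, minlength=B)
    hx = _entropy_bits(cx, n_samples)
    eis = np.empty(ws.size)
    for k, w in enumerate(ws):
        y = act(w * x)
        yi = np.clip(((y - olo) / (ohi - olo) * B).astype(np.int64), 0, B - 1)
        cj = np.bincount(xi * B + yi, minlength=B * B)
        cy = cj.reshape(B, B).sum(axis=0)
        hy = _entropy_bits(cy, n_samples)
        if hx == 0.0 or hy == 0.0:
            eis[k] = 0.0
        else:
            eis[k] = max(0.0, hx + hy - _entropy_bits(cj, n_samples))
    df = pd.DataFrame({"weight": ws, "ei_bits": eis})
    df.attrs["argmax_weight"] = float(ws[int(np.argmax(eis))])
    df.attrs["grid_step"] = float(np.min(np.diff(ws))) if ws.size > 1 else float("nan")
    df.attrs["n_bins"] = B
    df.attrs["n_samples"] = int(n_samples)
    df.attrs["seed"] = int(seed)
    return df


def ei_manifold_two_inputs(
    activation: str | ActivationKind,
    grid_wa: np.ndarray,
    grid_wb: np.ndarray,
    n_bins: int = 16,
    n_samples: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """EI, sensitivity and degeneracy surfaces for a 2-input/1-output layer.

    ``degeneracy = sensitivity - EI`` holds exactly at every grid point by
    construction.  Inputs are shared across grid points (common random
    numbers); the two sensitivity terms depend only on one weight each, so
    they are computed once per axis value.
    """
    act = get_activation(activation) if isinstance(activation, str) else activation
    was = np.asarray(grid_wa, dtype=float)
    wbs = np.asarray(grid_wb, dtype=float)
    if was.size == 0 or wbs.size == 0:
        raise ValueError("empty weight grid")
    B = n_bins
    lo, hi = act.bin_range
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(c) for c in ss.spawn(2))
    xa = rng_a.uniform(lo, hi, size=n_samples)
    xb = rng_b.uniform(lo, hi, size=n_samples)

    def _bin(v, vlo, vhi):
        return np.clip(((v - vlo) / (vhi - vlo) * B).astype(np.int64), 0, B - 1)

    olo, ohi = act.bin_range
    ai = _bin(xa, lo, hi)
    bi = _bin(xb, lo, hi)
    xi = ai * B + bi  # joint input label
    hx = _entropy_bits(np.bincount(xi, minlength=B * B), n_samples)

    def _edge_mi(x, xbins, w):
        if w == 0.0:
            return 0.0
        y = act(w * x)
        yi = _bin(y, olo, ohi)
        cj = np.bincount(xbins * B + yi, minlength=B * B)
        return _pair_mi_from_counts(
            cj, cj.reshape(B, B).sum(axis=1), cj.reshape(B, B).sum(axis=0), n_samples
        )

    sens_a = {w: _edge_mi(xa, ai, w) for w in np.unique(was)}
    sens_b = {w: _edge_mi(xb, bi, w) for w in np.unique(wbs)}

    rows = []
    for wa in was:
        ya_pre = wa * xa
        for wb in wbs:
            y = act(ya_pre + wb * xb)
            yi = _bin(y, olo, ohi)
            cj = np.bincount(xi * B + yi, minlength=B * B * B)
            cy = np.bincount(yi, minlength=B)
            hy = _entropy_bits(cy, n_samples)
            if hx == 0.0 or hy == 0.0:
                ei = 0.0
            else:
                ei = max(0.0, hx + hy - _entropy_bits(cj, n_samples))
            s = sens_a[wa] + sens_b[wb]
            rows.append((wa, wb, ei, s, s - ei))
    df = pd.DataFrame(
        rows, columns=["w_a", "w_b", "ei_bits", "sensitivity_bits", "degeneracy_bits"]
    )
    df.attrs.update(n_bins=B, n_samples=int(n_samples), seed=int(seed))
    return df
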