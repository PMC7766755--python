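"""Training experiments: synthetic classification tasks, a vanilla-GD trainer,
and causal-plane / phi trajectory tracking across checkpoints.

Two bundled synthetic tasks emulate the character of the classic benchmarks
without any downloads:

``iris_like``
    4 features, 3 classes drawn from Gaussian blobs in the unit cube; one
    class well separated, the other two slightly overlapping — mostly
    linearly separable, like the flower data set.

``mnist_like``
    25 features, 5 classes; each class is a mixture of two *antipodal* modes
    (``c`` and ``1 - c``), so no linear functional can separate a class from
    the rest while a small nonlinear network can.  This emulates the
    degenerate many-to-few mapping of downsampled digit classification.

Training follows the protocol of the study being replicated: MSE loss on
one-hot targets, vanilla gradient descent (lr 0.01, no momentum), uniform
fan-in initialization, no biases; batch size 10 for 4000 epochs (iris-like)
and 50 for 500 epochs (mnist-like).  Measurement checkpoints default to a
geometric schedule (denser early, where loss falls fastest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netmodel import NetworkSpec, initialize
from .perturb_mi import InterventionConfig
from .decompose import EIResult, measure_layer

__all__ = [
    "TaskSpec",
    "SyntheticTask",
    "TrainConfig",
    "TrainResult",
    "make_synthetic_task",
    "train",
    "track",
    "run_experiment",
    "ExperimentResult",
    "redundancy_experiment",
    "RedundancyReport",
    "path_length",
    "mean_nullcline_distance",
    "geometric_schedule",
    "plot_causal_plane",
]

TASK_PRESETS = {
    "iris_like": dict(n_features=4, n_classes=3, n_train=120, n_test=30),
    "mnist_like": dict(n_features=25, n_classes=5, n_train=500, n_test=250),
}

ARCH_PRESETS = {"iris_like": [4, 5, 5, 3], "mnist_like": [25, 6, 6, 5]}

TRAIN_PRESETS = {
    "iris_like": dict(batch_size=10, epochs=4000),
    "mnist_like": dict(batch_size=50, epochs=500),
}


@dataclass(frozen=True)
class TaskSpec:
    name: str
    n_features: int
    n_classes: int
    n_train: int
    n_test: int
    seed: int
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticTask:
    """Generated feature/label tables, scaled to the unit cube."""

    spec: TaskSpec
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray

    def one_hot(self, y: np.ndarray) -> np.ndarray:
        out = np.zeros((y.size, self.spec.n_classes))
        out[np.arange(y.size), y] = 1.0
        return out


def _balanced_labels(n: int, k: int) -> np.ndarray:
    """Exactly balanced labels, n divisible by k or nearly so."""
    reps = -(-n // k)
    return np.tile(np.arange(k), reps)[:n]


def _gaussian_blobs(rng, n, means, std):
    k, d = means.shape
    y = _balanced_labels(n, k)
    X = means[y] + rng.normal(0.0, std, size=(n, d))
    return np.clip(X, 0.0, 1.0), y


def make_synthetic_task(
    kind: str,
    seed: int = 0,
    n_train: int | None = None,
    n_test: int | None = None,
) -> SyntheticTask:
    """Generate a bundled synthetic classification task (reproducible)."""
    if kind not in TASK_PRESETS:
        raise ValueError(f"unknown task kind {kind!r}; expected {sorted(TASK_PRESETS)}")
    preset = dict(TASK_PRESETS[kind])
    if n_train is not None:
        preset["n_train"] = int(n_train)
    if n_test is not None:
        preset["n_test"] = int(n_test)
    kind_id = sorted(TASK_PRESETS).index(kind)
    rng = np.random.default_rng(np.random.SeedSequence((seed, kind_id)))
    if kind == "iris_like":
        # three Gaussian blobs separated by *direction* (bias-free networks can
        # only carve zero-threshold hyperplanes); classes 1 and 2 overlap
        means = np.array(
            [
                [0.75, 0.60, 0.10, 0.10],
                [0.10, 0.60, 0.75, 0.15],
                [0.12, 0.55, 0.68, 0.45],
            ]
        )
        params = dict(means=means.tolist(), std=0.08)
        Xtr, ytr = _gaussian_blobs(rng, preset["n_train"], means, 0.08)
        Xte, yte = _gaussian_blobs(rng, preset["n_test"], means, 0.08)
    else:  # mnist_like
        d, k = 25, 5
        std = 0.12
        centers = rng.uniform(0.25, 0.75, size=(k, d))
        alt = rng.uniform(0.25, 0.75, size=(k, d))
        params = dict(
            centers=centers.tolist(), alt_centers=alt.tolist(), std=std,
            antipodal_classes=[0, 1],
        )

        def _draw(n):
            y = _balanced_labels(n, k)
            mode = rng.integers(0, 2, size=n).astype(bool)
            c = centers[y].copy()
            # each class is two modes: classes 0-1 get an antipodal second mode
            # (no linear functional separates them), classes 2-4 an independent one
            anti = (y < 2) & mode
            other = (y >= 2) & mode
            c[anti] = 1.0 - centers[y[anti]]
            c[other] = alt[y[other]]
            X = np.clip(c + rng.normal(0.0, std, size=(n, d)), 0.0, 1.0)
            return X, y

        Xtr, ytr = _draw(preset["n_train"])
        Xte, yte = _draw(preset["n_test"])
    spec = TaskSpec(
        name=kind,
        n_features=Xtr.shape[1],
        n_classes=int(ytr.max()) + 1,
        n_train=preset["n_train"],
        n_test=preset["n_test"],
        seed=seed,
        params=params,
    )
    return SyntheticTask(spec, Xtr, ytr, Xte, yte)


def geometric_schedule(total_steps: int, n_points: int = 12) -> list[int]:
    """Strictly increasing measurement steps, denser early; includes 0 and the end."""
    if total_steps < 1:
        return [0]
    pts = np.unique(
        np.round(np.geomspace(1, total_steps, n_points - 1)).astype(int)
    )
    return [0] + [int(p) for p in pts if 0 < p <= total_steps]


@dataclass(frozen=True)
class TrainConfig:
    """Vanilla gradient descent on MSE loss with one-hot targets."""

    learning_rate: float = 0.01
    batch_size: int = 10
    epochs: int = 4000
    schedule: tuple[int, ...] | None = None  # measurement steps; None -> geometric
    seed: int = 0


@dataclass
class TrainResult:
    checkpoints: list[tuple[int, NetworkSpec]]
    losses: pd.DataFrame  # step, train_loss, test_loss
    config: TrainConfig

    def checkpoint_at(self, step: int) -> NetworkSpec:
        for s, net in self.checkpoints:
            if s == step:
                return net
        raise KeyError(f"no checkpoint at step {step}")


def _mse(net: NetworkSpec, X: np.ndarray, T: np.ndarray) -> float:
    out = net.forward(X)
    return float(np.mean((out - T) ** 2))


def train(network: NetworkSpec, task: SyntheticTask, config: TrainConfig) -> TrainResult:
    """Train by mini-batch vanilla GD, snapshotting at scheduled steps.

    A *step* is one gradient update; step 0 is the untrained network.  The
    shuffling stream is fixed by ``config.seed``, so the whole run is a pure
    function of (network, task, config).
    """
    arch = network.architecture
    if arch[0] != task.spec.n_features or arch[-1] != task.spec.n_classes:
        raise ValueError(
            f"architecture {arch} does not match task "
            f"({task.spec.n_features} features, {task.spec.n_classes} classes)"
        )
    net = network.copy()
    Ttr = task.one_hot(task.y_train)
    Tte = task.one_hot(task.y_test)
    n = task.X_train.shape[0]
    steps_per_epoch = math.ceil(n / config.batch_size)
    total_steps = steps_per_epoch * config.epochs
    if config.schedule is not None:
        schedule = sorted(set(int(s) for s in config.schedule))
        if schedule[0] != 0:
            raise ValueError("measurement schedule must include step 0")
        if schedule[-1] > total_steps:
            raise ValueError("measurement schedule exceeds total steps")
    else:
        schedule = geometric_schedule(total_steps)
    rng = np.random.default_rng(config.seed)
    lr = config.learning_rate

    checkpoints: list[tuple[int, NetworkSpec]] = []
    rows = []
    wanted = set(schedule)

    def _snapshot(step: int) -> None:
        snap = net.copy()
        snap.metadata = {**snap.metadata, "step": step, "task": task.spec.name}
        checkpoints.append((step, snap))
        rows.append((step, _mse(net, task.X_train, Ttr), _mse(net, task.X_test, Tte)))

    if 0 in wanted:
        _snapshot(0)
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for b0 in range(0, n, config.batch_size):
            idx = order[b0 : b0 + config.batch_size]
            X, T = task.X_train[idx], Ttr[idx]
            # forward, caching activations
            acts = [X]
            for layer in net.layers:
                acts.append(layer.forward(acts[-1]))
            # backward: squared error summed over the batch and output dims
            # (the classic backprop objective; reported losses are per-sample
            # per-output means for readability)
            delta = 2.0 * (acts[-1] - T)
            for li in range(len(net.layers) - 1, -1, -1):
                layer = net.layers[li]
                delta = delta * layer.activation.derivative_from_output(acts[li + 1])
                grad_w = acts[li].T @ delta
                grad_b = delta.sum(axis=0) if layer.bias is not None else None
                if li > 0:
                    delta = delta @ layer.weights.T
                layer.weights -= lr * grad_w
                if grad_b is not None:
                    layer.bias -= lr * grad_b
            step += 1
            if step in wanted:
                _snapshot(step)
    losses = pd.DataFrame(rows, columns=["step", "train_loss", "test_loss"])
    return TrainResult(checkpoints=checkpoints, losses=losses, config=config)


def accuracy(net: NetworkSpec, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(net.forward(X).argmax(axis=1) == y))


def track(
    result: TrainResult,
    n_bins: int = 16,
    n_samples: int = 100_000,
    seed: int = 0,
    convergence_tol: float = 0.05,
) -> pd.DataFrame:
    """Measure the full causal-structure decomposition at every checkpoint.

    Returns a tidy trajectory frame with one row per (step, layer): columns
    ``step, layer, ei, sensitivity, degeneracy, ei_parts, phi, train_loss,
    test_loss, n_samples, n_bins, converged``.  Each (step, layer) measurement
    draws its seeds from a named sub-stream of ``seed``, so adding checkpoints
    does not perturb other measurements.
    """
    rows = []
    loss_by_step = result.losses.set_index("step")
    for ci, (step, net) in enumerate(result.checkpoints):
        for li, layer in enumerate(net.layers):
            sub = np.random.SeedSequence((seed, ci, li))
            cfg = InterventionConfig(
                n_samples=n_samples,
                seed=int(sub.generate_state(1)[0] & 0x7FFFFFFF),
                batch_size=max(1, n_samples // 4),
            )
            res: EIResult = measure_layer(
                layer, cfg, n_bins, convergence_tol=convergence_tol,
                layer_index=li, step=step,
            )
            rows.append(
                dict(
                    step=step,
                    layer=li,
                    ei=res.ei_bits,
                    sensitivity=res.sensitivity_bits,
                    degeneracy=res.degeneracy_bits,
                    ei_parts=res.ei_parts_bits,
                    phi=res.phi_feedforward_bits,
                    train_loss=loss_by_step.loc[step, "train_loss"],
                    test_loss=loss_by_step.loc[step, "test_loss"],
                    n_samples=res.n_samples,
                    n_bins=res.n_bins,
                    converged=res.converged,
                )
            )
    return pd.DataFrame(rows)


@dataclass
class ExperimentResult:
    task: SyntheticTask
    train_result: TrainResult
    trajectory: pd.DataFrame
    seed: int


def run_experiment(
    kind: str,
    seed: int = 0,
    architecture: list[int] | None = None,
    activation: str = "sigmoid",
    epochs: int | None = None,
    batch_size: int | None = None,
    learning_rate: float = 0.01,
    schedule: list[int] | None = None,
    n_bins: int = 16,
    n_samples: int = 100_000,
    n_schedule_points: int = 12,
) -> ExperimentResult:
    """Generate the task, train with the standard protocol, track trajectories.

    The seed tuple (task, init, shuffle, measurement) is expanded from the
    single ``seed`` via named sub-streams, so the whole experiment is a pure
    function of its arguments.
    """
    ss = np.random.SeedSequence(seed)
    s_task, s_init, s_shuffle, s_measure = (
        int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(4)
    )
    task = make_synthetic_task(kind, seed=s_task)
    arch = architecture or ARCH_PRESETS[kind]
    net = initialize(arch, activation, seed=s_init)
    preset = TRAIN_PRESETS[kind]
    cfg = TrainConfig(
        learning_rate=learning_rate,
        batch_size=batch_size or preset["batch_size"],
        epochs=epochs or preset["epochs"],
        schedule=None if schedule is None else tuple(schedule),
        seed=s_shuffle,
    )
    if cfg.schedule is None and n_schedule_points != 12:
        total = math.ceil(task.X_train.shape[0] / cfg.batch_size) * cfg.epochs
        cfg = TrainConfig(
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            schedule=tuple(geometric_schedule(total, n_schedule_points)),
            seed=cfg.seed,
        )
    tr = train(net, task, cfg)
    traj = track(tr, n_bins=n_bins, n_samples=n_samples, seed=s_measure)
    return ExperimentResult(task=task, train_result=tr, trajectory=traj, seed=seed)


def path_length(trajectory: pd.DataFrame, layer: int | None = None) -> float | pd.Series:
    """Euclidean path length in the causal plane (degeneracy, sensitivity).

    With ``layer=None`` returns a Series of per-layer path lengths.
    """
    def _one(df: pd.DataFrame) -> float:
        df = df.sort_values("step")
        dx = np.diff(df["degeneracy"].to_numpy())
        dy = np.diff(df["sensitivity"].to_numpy())
        return float(np.sum(np.hypot(dx, dy)))

    if layer is not None:
        return _one(trajectory[trajectory["layer"] == layer])
    return trajectory.groupby("layer").apply(_one, include_groups=False)


def mean_nullcline_distance(
    trajectory: pd.DataFrame, layer: int | None = None
) -> float | pd.Series:
    """Mean perpendicular distance from the EI nullcline (y = x)."""
    d = (trajectory["sensitivity"] - trajectory["degeneracy"]).abs() / math.sqrt(2.0)
    if layer is not None:
        return float(d[trajectory["layer"] == layer].mean())
    return d.groupby(trajectory["layer"]).mean()


@dataclass
class RedundancyReport:
    """Comparison of base / removed-hidden / added-hidden training runs."""

    runs: dict  # variant -> ExperimentResult
    path_lengths: pd.DataFrame  # variant, layer, path_length, nullcline_distance, redundant
    final_test_loss: dict
    final_test_accuracy: dict
    redundant_layers: list[int]


def redundancy_experiment(
    kind: str = "mnist_like",
    base_architecture: list[int] | None = None,
    n_extra_hidden: int = 1,
    seed: int = 0,
    epochs: int | None = 3000,
    **experiment_kwargs,
) -> RedundancyReport:
    """Train base, removed-hidden-layer and added-redundant-layers variants.

    The added variant inserts ``n_extra_hidden`` hidden layers of the same
    width as the last hidden layer.  All variants share one epoch budget
    (default 3000: bias-free sigmoid stacks deeper than four layers do not
    optimize under plain gradient descent, so the added variant needs more
    epochs than the base preset to reach comparable accuracy).  Reports
    per-layer causal-plane path lengths and mean nullcline distances, plus
    final test losses for the accuracy-parity check.  With
    ``n_extra_hidden=0`` the added variant coincides with the base run.
    """
    experiment_kwargs = dict(experiment_kwargs)
    if epochs is not None:
        experiment_kwargs["epochs"] = epochs
    base = base_architecture or ARCH_PRESETS[kind]
    if len(base) < 4:
        raise ValueError("base architecture needs at least two hidden layers")
    hidden_w = base[-2]
    removed = base[:1] + base[2:]
    added = base[:-1] + [hidden_w] * n_extra_hidden + base[-1:]
    variants = {"base": base, "removed": removed, "added": added}
    # layers inserted between the base's last hidden layer and the output
    redundant_layers = list(range(len(base) - 2, len(base) - 2 + n_extra_hidden))

    runs = {}
    rows = []
    for name, arch in variants.items():
        res = run_experiment(kind, seed=seed, architecture=arch, **experiment_kwargs)
        runs[name] = res
        pl = path_length(res.trajectory)
        nd = mean_nullcline_distance(res.trajectory)
        for li in pl.index:
            rows.append(
                dict(
                    variant=name,
                    layer=int(li),
                    path_length=float(pl[li]),
                    nullcline_distance=float(nd[li]),
                    redundant=(name == "added" and int(li) in redundant_layers),
                )
            )
    final_loss = {
        name: float(r.train_result.losses["test_loss"].iloc[-1]) for name, r in runs.items()
    }
    final_acc = {
        name: accuracy(r.train_result.checkpoints[-1][1], r.task.X_test, r.task.y_test)
        for name, r in runs.items()
    }
    return RedundancyReport(
        runs=runs,
        path_lengths=pd.DataFrame(rows),
        final_test_loss=final_loss,
        final_test_accuracy=final_acc,
        redundant_layers=redundant_layers,
    )


def plot_causal_plane(trajectory: pd.DataFrame, path: str | None = None, title: str = ""):
    """Static causal-plane figure: one path per layer, nullcline dashed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for li, df in trajectory.groupby("layer"):
        df = df.sort_values("step")
        ax.plot(df["degeneracy"], df["sensitivity"], marker="o", ms=3, label=f"layer {li}")
    lim = max(
        trajectory["degeneracy"].abs().max(), trajectory["sensitivity"].abs().max(), 1.0
    )
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="EI nullcline")
    ax.set_xlabel("degeneracy (bits)")
    ax.set_ylabel("sensitivity (bits)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
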