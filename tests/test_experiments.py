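import numpy as np
import pandas as pd
import pytest

from causalplane import (
    TrainConfig,
    geometric_schedule,
    initialize,
    make_synthetic_task,
    mean_nullcline_distance,
    path_length,
    redundancy_experiment,
    run_experiment,
    track,
    train,
)
from causalplane.experiments import accuracy


class TestSyntheticTasks:
    @pytest.mark.parametrize("kind,nf,nc", [("iris_like", 4, 3), ("mnist_like", 25, 5)])
    def test_shapes_balance_and_range(self, kind, nf, nc):
        t = make_synthetic_task(kind, seed=5)
        assert t.X_train.shape[1] == nf
        assert t.spec.n_classes == nc
        counts = np.bincount(t.y_train)
        assert counts.min() == counts.max()  # exactly class-balanced
        assert t.X_train.min() >= 0.0 and t.X_train.max() <= 1.0

    def test_reproducible(self):
        a = make_synthetic_task("mnist_like", seed=9)
        b = make_synthetic_task("mnist_like", seed=9)
        assert np.array_equal(a.X_train, b.X_train)
        assert np.array_equal(a.y_test, b.y_test)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown task kind"):
            make_synthetic_task("cifar_like", seed=0)

    def test_separability_contrast(self):
        """iris_like is linearly separable; mnist_like needs a nonlinear model."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.neural_network import MLPClassifier

        iris = make_synthetic_task("iris_like", seed=1)
        lin = LogisticRegression(max_iter=2000).fit(iris.X_train, iris.y_train)
        assert lin.score(iris.X_test, iris.y_test) >= 0.90

        mn = make_synthetic_task("mnist_like", seed=1)
        lin = LogisticRegression(max_iter=3000).fit(mn.X_train, mn.y_train)
        mlp = MLPClassifier((32,), max_iter=1200, random_state=0).fit(
            mn.X_train, mn.y_train
        )
        lin_acc = lin.score(mn.X_test, mn.y_test)
        mlp_acc = mlp.score(mn.X_test, mn.y_test)
        assert lin_acc < mlp_acc - 0.10


@pytest.fixture(scope="module")
def iris():
    return make_synthetic_task("iris_like", seed=2)


class TestTrain:
    def test_zero_learning_rate_freezes_weights(self, iris):
        net = initialize([4, 5, 5, 3], "sigmoid", seed=0)
        cfg = TrainConfig(learning_rate=0.0, batch_size=10, epochs=3, seed=0)
        res = train(net, iris, cfg)
        for _, snap in res.checkpoints:
            for l0, ls in zip(net.layers, snap.layers):
                assert np.array_equal(l0.weights, ls.weights)

    def test_training_reduces_loss(self, iris):
        net = initialize([4, 5, 5, 3], "sigmoid", seed=1)
        cfg = TrainConfig(batch_size=10, epochs=400, seed=1)
        res = train(net, iris, cfg)
        assert res.losses["train_loss"].iloc[-1] < res.losses["train_loss"].iloc[0]

    def test_same_seed_reproduces_losses(self, iris):
        net = initialize([4, 5, 5, 3], "sigmoid", seed=3)
        cfg = TrainConfig(batch_size=10, epochs=20, seed=5)
        a = train(net, iris, cfg)
        b = train(net, iris, cfg)
        pd.testing.assert_frame_equal(a.losses, b.losses)

    def test_dimension_mismatch_rejected(self, iris):
        net = initialize([5, 5, 3], "sigmoid", seed=0)
        with pytest.raises(ValueError, match="does not match task"):
            train(net, iris, TrainConfig(epochs=1))

    def test_schedule_must_start_at_zero(self, iris):
        net = initialize([4, 5, 3], "sigmoid", seed=0)
        cfg = TrainConfig(batch_size=10, epochs=2, schedule=(3, 12))
        with pytest.raises(ValueError, match="step 0"):
            train(net, iris, cfg)

    def test_schedule_checkpoints_present(self, iris):
        net = initialize([4, 5, 3], "sigmoid", seed=0)
        cfg = TrainConfig(batch_size=10, epochs=2, schedule=(0, 5, 24))
        res = train(net, iris, cfg)
        assert [s for s, _ in res.checkpoints] == [0, 5, 24]


class TestTrack:
    def test_cardinality_and_identities(self):
        task = make_synthetic_task("iris_like", seed=0)
        net = initialize([4, 5, 5, 3], "sigmoid", seed=0)
        cfg = TrainConfig(batch_size=10, epochs=2, schedule=(0, 10, 24), seed=0)
        res = train(net, task, cfg)
        traj = track(res, n_bins=8, n_samples=4000, seed=1)
        assert len(traj) == 3 * 3  # 3 checkpoints x 3 layer-to-layer connections
        assert set(traj["step"]) == {0, 10, 24}
        np.testing.assert_array_equal(
            traj["degeneracy"], traj["sensitivity"] - traj["ei"]
        )
        np.testing.assert_array_equal(traj["phi"], traj["ei"] - traj["ei_parts"])

    def test_trained_and_untrained_trajectories_differ(self):
        task = make_synthetic_task("iris_like", seed=0)
        net = initialize([4, 5, 5, 3], "sigmoid", seed=0)
        frozen = train(net, task, TrainConfig(learning_rate=0.0, batch_size=10,
                                              epochs=5, schedule=(0, 60), seed=0))
        moving = train(net, task, TrainConfig(batch_size=10, epochs=5,
                                              schedule=(0, 60), seed=0))
        t_frozen = track(frozen, n_bins=8, n_samples=4000, seed=2)
        t_moving = track(moving, n_bins=8, n_samples=4000, seed=2)
        assert not np.allclose(t_frozen["ei"], t_moving["ei"])


class TestHelpers:
    def test_path_length_on_known_trajectory(self):
        traj = pd.DataFrame(
            dict(step=[0, 1, 2], layer=[0, 0, 0],
                 degeneracy=[0.0, 3.0, 3.0], sensitivity=[0.0, 4.0, 8.0])
        )
        assert path_length(traj, layer=0) == pytest.approx(9.0)  # 5 + 4

    def test_mean_nullcline_distance_on_nullcline(self):
        traj = pd.DataFrame(
            dict(step=[0, 1], layer=[0, 0], degeneracy=[1.0, 2.5],
                 sensitivity=[1.0, 2.5])
        )
        assert mean_nullcline_distance(traj, layer=0) == 0.0

    def test_geometric_schedule_contract(self):
        sched = geometric_schedule(1000, 10)
        assert sched[0] == 0 and sched[-1] == 1000
        assert all(b > a for a, b in zip(sched, sched[1:]))


class TestExperimentOrchestration:
    def test_run_experiment_is_reproducible(self):
        kw = dict(epochs=3, n_samples=3000, n_bins=8, n_schedule_points=3)
        a = run_experiment("iris_like", seed=4, **kw)
        b = run_experiment("iris_like", seed=4, **kw)
        pd.testing.assert_frame_equal(a.trajectory, b.trajectory)

    def test_redundancy_zero_extra_matches_base(self):
        rep = redundancy_experiment(
            "mnist_like", n_extra_hidden=0, seed=0, epochs=3,
            n_samples=2000, n_bins=8, n_schedule_points=3,
        )
        base = rep.runs["base"].trajectory
        added = rep.runs["added"].trajectory
        pd.testing.assert_frame_equal(base, added)
        assert rep.redundant_layers == []

    def test_redundancy_report_shape(self):
        rep = redundancy_experiment(
            "mnist_like", n_extra_hidden=1, seed=0, epochs=3,
            n_samples=2000, n_bins=8, n_schedule_points=3,
        )
        assert set(rep.runs) == {"base", "removed", "added"}
        assert rep.redundant_layers == [2]
        added = rep.path_lengths[rep.path_lengths.variant == "added"]
        assert added["redundant"].sum() == 1
        assert set(rep.final_test_accuracy) == {"base", "removed", "added"}


def test_accuracy_helper():
    task = make_synthetic_task("iris_like", seed=0)
    net = initialize([4, 5, 5, 3], "sigmoid", seed=0)
    a = accuracy(net, task.X_test, task.y_test)
    assert 0.0 <= a <= 1.0
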