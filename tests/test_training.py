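"""Fold splitting, training loop, grid search, model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spliceconv as sc
from spliceconv.errors import ConfigError, DivergenceError, TrainingError
from spliceconv.seqdata import NucleotideSequence, SpliceDataset, SpliceWindow
from spliceconv.training import CVResult, TrainingConfig, cross_validate, train


def _label_dataset(n_true: int, n_false: int, seq_len: int = 10) -> SpliceDataset:
    """Dataset whose windows only matter for their labels."""
    mk = lambda i, lab: SpliceWindow(
        sequence=NucleotideSequence("A" * seq_len, id=f"{lab[:1]}{i}"),
        site_type="acceptor",
        label=lab,
    )
    return SpliceDataset(
        [mk(i, "true_site") for i in range(n_true)]
        + [mk(i, "false_site") for i in range(n_false)]
    )


class TestStratifiedKFold:
    def test_balanced_fold_counts(self):
        ds = _label_dataset(5000, 5000)
        split = sc.stratified_kfold(ds, k=5, seed=0)
        assert all(len(f) == 2000 for f in split.folds)
        assert split.class_counts == [(1000, 1000)] * 5

    def test_imbalanced_fold_counts(self):
        ds = _label_dataset(7500, 2500)
        split = sc.stratified_kfold(ds, k=5, seed=0)
        assert all(len(f) == 2000 for f in split.folds)
        assert split.class_counts == [(1500, 500)] * 5

    def test_small_class_raises(self):
        with pytest.raises(TrainingError):
            sc.stratified_kfold(_label_dataset(3, 100), k=5, seed=0)

    def test_reproducible_under_seed(self):
        ds = _label_dataset(40, 40)
        a = sc.stratified_kfold(ds, k=5, seed=3)
        b = sc.stratified_kfold(ds, k=5, seed=3)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    @given(
        n_true=st.integers(6, 200),
        n_false=st.integers(6, 200),
        k=st.integers(2, 5),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=40, deadline=None)
    def test_partition_laws(self, n_true, n_false, k, seed):
        """Folds partition the index set; sizes differ by <=1; per-fold class
        proportions track the global ratio to within one record."""
        ds = _label_dataset(n_true, n_false)
        split = sc.stratified_kfold(ds, k=k, seed=seed)
        n = n_true + n_false
        all_idx = np.concatenate(split.folds)
        assert len(all_idx) == n
        assert len(np.unique(all_idx)) == n  # disjoint + coverage
        sizes = [len(f) for f in split.folds]
        assert max(sizes) - min(sizes) <= 1
        for n_t, n_f in split.class_counts:
            # each class is spread as evenly as k-fold arithmetic allows
            assert abs(n_t - n_true / k) <= 1
            assert abs(n_f - n_false / k) <= 1


class TestTrain:
    def test_single_epoch_history(self, small_encoded):
        x, y = small_encoded
        spec, w = sc.build_architecture("C1", seed=0)
        res = train(spec, w, (x[:10], y[:10]), (x[10:14], y[10:14]), TrainingConfig(epochs=1, seed=0))
        assert len(res.history) == 1
        assert {"epoch", "train_loss", "train_accuracy", "val_loss", "val_accuracy"} <= set(
            res.history[0]
        )

    def test_fixed_seed_reproducible_weights(self, small_encoded):
        x, y = small_encoded
        outs = []
        for _ in range(2):
            spec, w = sc.build_architecture("C11M", seed=4)
            res = train(
                spec, w, (x[:60], y[:60]), (x[60:80], y[60:80]), TrainingConfig(epochs=2, seed=4)
            )
            outs.append(res.weights)
        for k in outs[0].tensors:
            np.testing.assert_array_equal(outs[0].tensors[k], outs[1].tensors[k])

    def test_empty_training_set_raises(self, small_encoded):
        x, y = small_encoded
        spec, w = sc.build_architecture("C1", seed=0)
        with pytest.raises(TrainingError):
            train(spec, w, (x[:0], y[:0]), (x[:4], y[:4]), TrainingConfig(epochs=1))

    def test_divergence_raises_explicitly(self, small_encoded):
        """A diverged (non-finite) parameter state is reported, not silent."""
        x, y = small_encoded
        spec, w = sc.build_architecture("C1", seed=0)
        w.tensors["out/W"][0, 0] = np.nan
        cfg = TrainingConfig(epochs=2, seed=0)
        with pytest.raises(DivergenceError):
            train(spec, w, (x[:60], y[:60]), (x[60:80], y[60:80]), cfg)

    def test_early_stopping_restores_best_epoch(self, small_encoded):
        x, y = small_encoded
        spec, w = sc.build_architecture("C1", seed=1)
        cfg = TrainingConfig(epochs=6, early_stop_patience=2, seed=1)
        res = train(spec, w, (x[:80], y[:80]), (x[80:120], y[80:120]), cfg)
        best = min(res.history, key=lambda h: h["val_loss"])
        assert res.best_epoch == best["epoch"]

    def test_strong_motif_data_learnable(self):
        """On separable-by-construction data (strength 1, planted consensus
        plus decoy negatives) a 3-block CNN reaches >=95% validation accuracy
        within 10 epochs."""
        cfg = sc.SyntheticConfig(total=2000, seed=21)
        ds = sc.generate_dataset(cfg)
        x, y = ds.encode(), ds.labels()
        rng = np.random.default_rng(0)
        order = rng.permutation(len(y))
        va, tr = order[:400], order[400:]
        spec, w = sc.build_architecture("MODEL1", seed=21)
        res = train(
            spec, w, (x[tr], y[tr]), (x[va], y[va]),
            TrainingConfig(epochs=8, early_stop_patience=8, seed=21),
        )
        assert max(h["val_accuracy"] for h in res.history) >= 0.95


class TestCrossValidate:
    def test_mean_is_arithmetic_mean_of_folds(self, small_acceptor_ds, small_encoded):
        cfg = TrainingConfig(epochs=1, seed=2)
        res = cross_validate("C1", small_acceptor_ds, cfg, k=3, encoded=small_encoded)
        assert len(res.fold_accuracies) == 3
        assert res.mean_accuracy == pytest.approx(np.mean(res.fold_accuracies), abs=1e-12)
        assert res.mean_loss == pytest.approx(np.mean(res.fold_losses), abs=1e-12)

    def test_reports_best_and_final_epoch_accuracy(self, small_acceptor_ds, small_encoded):
        cfg = TrainingConfig(epochs=2, seed=2)
        res = cross_validate("C1", small_acceptor_ds, cfg, k=2, encoded=small_encoded)
        assert len(res.fold_final_accuracies) == 2


class TestGridSearch:
    def _grid(self):
        return sc.HyperparameterGrid(
            layers=(1,),
            filter_number=(4, 8),
            filter_size=(3,),
            stride=(1,),
            activation=("relu", "tanh"),
            learning_rate=(1e-3,),
            optimizer=("adam", "sgd"),
        )

    def test_budget_one_gives_one_entry(self, small_acceptor_ds):
        res = sc.grid_search(self._grid(), small_acceptor_ds, budget=1, seed=0, epochs=1)
        assert len(res.leaderboard) == 1

    def test_best_has_minimum_loss_and_determinism(self, small_acceptor_ds):
        res1 = sc.grid_search(self._grid(), small_acceptor_ds, budget=3, seed=5, epochs=1)
        res2 = sc.grid_search(self._grid(), small_acceptor_ds, budget=3, seed=5, epochs=1)
        losses = [e["val_loss"] for e in res1.leaderboard]
        assert res1.best["val_loss"] == min(losses)
        assert res1.leaderboard == res2.leaderboard

    def test_points_stay_inside_declared_space(self, small_acceptor_ds):
        grid = self._grid()
        res = sc.grid_search(grid, small_acceptor_ds, budget=4, seed=1, epochs=1)
        for e in res.leaderboard:
            assert e["layers"] in grid.layers
            assert e["filter_number"] in grid.filter_number
            assert e["activation"] in grid.activation
            assert e["optimizer"] in grid.optimizer

    def test_overlap_with_cv_dataset_rejected(self, small_acceptor_ds):
        ids = {w.sequence.id for w in list(small_acceptor_ds)[:5]}
        with pytest.raises(ConfigError, match="disjoint"):
            sc.grid_search(self._grid(), small_acceptor_ds, budget=1, seed=0, cv_dataset_ids=ids)


class TestSelectModels:
    def _cv(self, arch, org, accs):
        return CVResult(
            architecture=arch, organism=org,
            fold_accuracies=list(accs), fold_losses=[0.1] * len(accs),
            fold_final_accuracies=list(accs),
        )

    def test_dominant_architecture_ranks_first(self):
        res = sc.select_models(
            [
                self._cv("A", "h", [0.9]), self._cv("A", "o", [0.9]),
                self._cv("B", "h", [0.7]), self._cv("B", "o", [0.7]),
            ],
            top_k=1,
        )
        assert res.top == ["A"]

    def test_cross_organism_average_arithmetic(self):
        res = sc.select_models(
            [
                self._cv("A", "h", [0.9]), self._cv("A", "o", [0.8]),
                self._cv("B", "h", [0.85]), self._cv("B", "o", [0.86]),
            ]
        )
        assert res.row("A")["cross_organism_mean"] == pytest.approx(0.85)
        assert res.row("B")["cross_organism_mean"] == pytest.approx(0.855)
        assert res.table[0]["architecture"] == "B"

    def test_permutation_invariance(self):
        results = [
            self._cv("A", "h", [0.9]), self._cv("A", "o", [0.8]),
            self._cv("B", "h", [0.85]), self._cv("B", "o", [0.86]),
            self._cv("C", "h", [0.5]), self._cv("C", "o", [0.6]),
        ]
        base = sc.select_models(results)
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = [results[i] for i in rng.permutation(len(results))]
            assert [r["architecture"] for r in sc.select_models(shuffled).table] == [
                r["architecture"] for r in base.table
            ]

    def test_missing_cell_names_gap(self):
        with pytest.raises(ConfigError, match="B.*o|o.*B"):
            sc.select_models([self._cv("A", "h", [0.9]), self._cv("A", "o", [0.9]),
                              self._cv("B", "h", [0.8])])

    def test_top_k_larger_than_catalog_returns_all(self):
        res = sc.select_models(
            [self._cv("A", "h", [0.9]), self._cv("B", "h", [0.8])], top_k=10
        )
        assert res.top == ["A", "B"]
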