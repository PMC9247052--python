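"""CNN architecture, splitting, training, ensembling, and evaluation."""

import numpy as np
import pandas as pd
import pytest

from organspectra import nn
from organspectra.classifier import (
    DEFAULT_GRIDS,
    ArchitectureSpec,
    TrainingConfig,
    build_model,
    class_weights,
    ensemble_predict,
    evaluate,
    grid_search,
    lopo_validation_accuracy,
    run_lopo,
    split_train_test,
    table_classes,
    train_fold,
)
from organspectra.synthetic import (
    GenerativeComponents,
    make_fingerprint_library,
    make_standardized_design,
    simulate_spectra,
)

TINY_ARCH = ArchitectureSpec(conv_filters=(4, 4, 4), fc_sizes=(8, 8))
TINY_CFG = TrainingConfig(lr=1e-3, batch_size=64, samples_per_epoch=1280, epochs=3, seed=0)


@pytest.fixture(scope="module")
def two_organ_table():
    lib = make_fingerprint_library(2, seed=1)
    design = make_standardized_design(4, organs=lib.organs, n_positions=1)
    comps = GenerativeComponents(1e-9, 1e-9, 1e-9)
    return simulate_spectra(design, lib, comps, seed=3, normalize=True)


class TestArchitecture:
    def test_parameter_count_close_to_printed_value(self):
        arch = ArchitectureSpec()
        count = arch.parameter_count()
        assert abs(count - 34_300) / 34_300 < 0.01

    def test_model_matches_closed_form_count(self):
        for arch in (ArchitectureSpec(), TINY_ARCH,
                     ArchitectureSpec(conv_filters=(8, 4, 2), fc_sizes=(10, 5), n_classes=3)):
            model = build_model(arch, seed=0)
            assert model.n_parameters() == arch.parameter_count()

    def test_forward_shape_and_finiteness(self, rng):
        model = build_model(ArchitectureSpec(), seed=0)
        x = rng.dirichlet(np.ones(100), size=7)[:, None, :]
        logits = model.forward(x, train=False)
        assert logits.shape == (7, 20)
        assert np.all(np.isfinite(logits))

    def test_too_short_input_names_minimum(self):
        with pytest.raises(ValueError, match="minimum is 36"):
            ArchitectureSpec(input_bands=20).conv_output_length()
        # the reported minimum really is admissible, one band less is not
        assert ArchitectureSpec(input_bands=36).conv_output_length() == 1
        with pytest.raises(ValueError):
            ArchitectureSpec(input_bands=35).conv_output_length()

    def test_seeded_init_reproducible(self):
        a = build_model(ArchitectureSpec(), seed=5)
        b = build_model(ArchitectureSpec(), seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)


class TestClassWeights:
    def test_closed_form_example(self):
        w = class_weights(np.array([100, 50]))
        assert np.allclose(w, [2 / 3, 4 / 3])
        assert w.mean() == pytest.approx(1.0)

    def test_uniform_counts_give_unit_weights(self):
        assert np.allclose(class_weights(np.array([7, 7, 7])), 1.0)


class TestSplit:
    def test_trivial_constraint_first_draw(self):
        pigs = [f"P{i}" for i in range(15)]
        std = pigs[:11]
        organs = {p: {"liver", "spleen"} for p in pigs}
        split = split_train_test(pigs, std, organs, n_test=8, seed=0)
        assert len(split.test_pigs) == 8
        assert split.constraint_log == []
        assert set(split.test_pigs) <= set(std)
        assert not set(split.test_pigs) & set(split.train_pigs)

    def test_rare_organ_forces_assignment(self):
        # bile_fluid is held by one standardized pig (P0) and one generic
        # pig (G1): P0 is forced into the test set so both sides cover it.
        std = [f"P{i}" for i in range(5)]
        pigs = std + ["G1"]
        organs = {p: {"liver"} for p in pigs}
        organs["P0"] = {"liver", "bile_fluid"}
        organs["G1"] = {"liver", "bile_fluid"}
        accepted = set()
        saw_rejections = False
        for seed in range(10):
            split = split_train_test(pigs, std, organs, n_test=2, seed=seed)
            accepted.add(split.test_pigs)
            assert "P0" in split.test_pigs
            assert "G1" in split.train_pigs
            saw_rejections |= bool(split.constraint_log)
        # brute-force enumeration oracle: acceptable = 2-subsets containing P0
        import itertools

        valid = {
            tuple(sorted(c))
            for c in itertools.combinations(std, 2)
            if "P0" in c
        }
        assert accepted <= valid
        assert saw_rejections  # rejected draws are logged

    def test_unsatisfiable_raises(self):
        std = ["P0", "P1"]
        organs = {"P0": {"liver", "bile_fluid"}, "P1": {"liver"}}
        with pytest.raises(RuntimeError, match="unsatisfiable"):
            split_train_test(std, std, organs, n_test=2, seed=0, max_attempts=50)


class TestTraining:
    def test_separable_two_organ_fold_is_perfect(self, two_organ_table):
        fold = train_fold(two_organ_table, "P36", TINY_ARCH, TINY_CFG)
        assert fold.accuracy == 1.0

    def test_seeded_loss_trajectory_identical(self, two_organ_table):
        a = train_fold(two_organ_table, "P36", TINY_ARCH, TINY_CFG)
        b = train_fold(two_organ_table, "P36", TINY_ARCH, TINY_CFG)
        assert a.loss_history == b.loss_history
        assert np.array_equal(a.logits, b.logits)

    def test_held_out_pig_must_be_present(self, two_organ_table):
        with pytest.raises(ValueError, match="not in training table"):
            train_fold(two_organ_table, "P99", TINY_ARCH, TINY_CFG)

    def test_missing_class_warns(self, two_organ_table):
        from organspectra.hsi_core import SpectraTable

        organs = two_organ_table.df["organ"].unique()
        df = two_organ_table.df[
            (two_organ_table.df["organ"] == organs[0])
            | (two_organ_table.df["pig_id"] == "P36")
        ].reset_index(drop=True)
        tab = SpectraTable(df, two_organ_table.grid)
        with pytest.warns(UserWarning, match="absent from the training fold"):
            train_fold(tab, "P36", TINY_ARCH, TINY_CFG, classes=tuple(sorted(organs)))


class TestGridSearch:
    def test_default_grids_have_96_combinations(self):
        import itertools

        assert len(list(itertools.product(*DEFAULT_GRIDS.values()))) == 96

    def test_single_point_grid_returns_it(self, two_organ_table):
        arch, cfg, results = grid_search(
            two_organ_table,
            grids={"lr": [2e-3], "dropout_p": [0.15]},
            base_arch=TINY_ARCH,
            base_config=TINY_CFG,
        )
        assert cfg.lr == 2e-3
        assert arch.dropout_p == 0.15
        assert len(results) == 1

    def test_empty_grid_rejected(self, two_organ_table):
        with pytest.raises(ValueError):
            grid_search(two_organ_table, grids={"lr": []})


class TestEnsemble:
    def test_singleton_ensemble_is_identity(self, rng):
        model = build_model(TINY_ARCH, seed=0)
        X = rng.dirichlet(np.ones(100), size=5)
        labels, logits, probs = ensemble_predict([model], X)
        solo = model.forward(X[:, None, :], train=False)
        assert np.array_equal(logits, solo)
        assert np.array_equal(labels, solo.argmax(axis=1))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_mean_logits_and_tie_break(self):
        class Stub:
            def __init__(self, logits):
                self._logits = np.asarray(logits, dtype=float)

            def forward(self, X, train):
                return np.tile(self._logits, (len(X), 1))

        a, b = Stub([1, 0, 0]), Stub([0, 1, 0])
        labels, logits, _ = ensemble_predict([a, b], np.zeros((2, 1, 100)))
        assert np.allclose(logits, [[0.5, 0.5, 0.0]] * 2)
        assert np.array_equal(labels, [0, 0])  # tie -> lowest class index

    def test_ensemble_at_least_median_single_model(self, two_organ_table):
        folds = run_lopo(two_organ_table, TINY_ARCH, TINY_CFG)
        test = two_organ_table.subset(two_organ_table.df["pig_id"] == "P39")
        from organspectra.classifier import _encode

        classes = table_classes(two_organ_table)
        X, y = _encode(test, classes)
        singles = [
            (f.model.forward(X, train=False).argmax(axis=1) == y).mean() for f in folds
        ]
        labels, _, _ = ensemble_predict([f.model for f in folds], X)
        assert (labels == y).mean() >= np.median(singles)


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = np.array([0, 1, 2, 0, 1, 2])
        pigs = np.array(["A", "A", "A", "B", "B", "B"])
        rep = evaluate(truth, truth, pigs, ("x", "y", "z"))
        assert rep.micro_accuracy == 1.0
        assert rep.n_misclassified == 0
        assert np.allclose(rep.confusion_mean.to_numpy(), np.eye(3))
        assert rep.macro["sensitivity_mean"] == 1.0
        assert rep.macro["f1_mean"] == 1.0

    def test_missing_organ_column_averaged_over_present_pigs(self):
        # pig B lacks class z: its z-column is missing, average uses pig A only
        truth = np.array([0, 1, 2, 2, 0, 1])
        pred = np.array([0, 1, 2, 0, 0, 1])
        pigs = np.array(["A", "A", "A", "A", "B", "B"])
        rep = evaluate(pred, truth, pigs, ("x", "y", "z"))
        col_z = rep.confusion_mean["z"]
        # pig A: two true z, one predicted z, one predicted x
        assert col_z["z"] == pytest.approx(0.5)
        assert col_z["x"] == pytest.approx(0.5)
        assert np.isnan(rep.confusion_per_pig["B"]["z"]).all()

    def test_binary_toy_closed_form(self):
        # TP=9 FN=1 TN=89 FP=1 for class "pos" within one pig
        truth = np.array([1] * 10 + [0] * 90)
        pred = np.array([1] * 9 + [0] + [1] + [0] * 89)
        pigs = np.array(["A"] * 100)
        rep = evaluate(pred, truth, pigs, ("neg", "pos"))
        assert rep.per_class.loc["pos", "sensitivity"] == pytest.approx(0.9)
        assert rep.per_class.loc["pos", "specificity"] == pytest.approx(89 / 90)
        assert rep.per_class.loc["pos", "f1"] == pytest.approx(0.9)

    def test_micro_accuracy_matches_brute_force_counter(self, rng):
        truth = rng.integers(0, 4, size=200)
        pred = rng.integers(0, 4, size=200)
        pigs = rng.choice(["A", "B", "C"], size=200)
        rep = evaluate(pred, truth, pigs, ("a", "b", "c", "d"))
        correct = sum(1 for p, t in zip(pred, truth) if p == t)
        assert rep.micro_accuracy == pytest.approx(correct / 200)
        # column-normalized columns sum to 1 where the class is present
        for pig in "ABC":
            conf = rep.confusion_per_pig[pig]
            present = conf.columns[~conf.isna().all()]
            assert np.allclose(conf[present].sum(axis=0), 1.0)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            evaluate(np.zeros(3), np.zeros(4), np.zeros(3), ("a",))
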