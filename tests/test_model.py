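"""Metrics identities, forest training/prediction, validation designs."""

import itertools

import numpy as np
import pytest

from pcmscreen.descriptors import FeatureMatrix, assemble_matrix
from pcmscreen.io_standardize import Dialect, merge_datasets
from pcmscreen.labeling import LabelingScheme
from pcmscreen.model import (
    ContractError,
    MetricsReport,
    TrainingError,
    ValidationDesign,
    make_folds,
    mcc_from_rates,
    predict_proba,
    run_validation,
    train,
)


def enumerate_confusion_matrices(max_total):
    for total in range(1, max_total + 1):
        for tp in range(total + 1):
            for fp in range(total - tp + 1):
                for tn in range(total - tp - fp + 1):
                    yield MetricsReport(tp, fp, tn, total - tp - fp - tn)


class TestMetricsReport:
    def test_rates_match_definitions(self):
        r = MetricsReport(tp=24, fp=28, tn=220, fn=11)
        assert r.sensitivity == pytest.approx(24 / 35)
        assert r.specificity == pytest.approx(220 / 248)
        assert r.ppv == pytest.approx(24 / 52)
        assert r.npv == pytest.approx(220 / 231)

    def test_zero_convention(self):
        r = MetricsReport(0, 0, 10, 0)  # no positives anywhere
        assert r.sensitivity == 0.0 and r.ppv == 0.0 and r.mcc == 0.0

    def test_mcc_bounds_exhaustive(self):
        for r in enumerate_confusion_matrices(12):
            assert -1.0 <= r.mcc <= 1.0

    def test_rate_identity_brute_force(self):
        # the rate-form identity agrees with the count-form MCC on every
        # confusion matrix with no zero marginal, total <= 30
        checked = 0
        for r in enumerate_confusion_matrices(30):
            if min(r.tp + r.fp, r.tp + r.fn, r.tn + r.fp, r.tn + r.fn) == 0:
                continue
            rebuilt = mcc_from_rates(r.sensitivity, r.specificity, r.ppv, r.npv)
            assert rebuilt == pytest.approx(r.mcc, abs=1e-9)
            checked += 1
        assert checked > 10000


class TestMccFromRates:
    @pytest.mark.parametrize(
        "rates,expected",
        [
            ((0.69, 0.89, 0.38, 0.97), 0.45),
            ((0.01, 0.98, 0.03, 0.91), -0.03),
            ((1.0, 1.0, 1.0, 1.0), 1.0),
        ],
    )
    def test_reported_rate_sets(self, rates, expected):
        assert mcc_from_rates(*rates) == pytest.approx(expected, abs=0.02)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            mcc_from_rates(1.2, 0.5, 0.5, 0.5)


def _toy_matrix(n=24, n_features=30, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    X = rng.random((n, n_features))
    y = (np.arange(n) % 2).astype(int)
    if separable:
        X[:, 0] = y + 0.1 * rng.random(n)
    rows = [(f"c{i}", "T1") for i in range(n)]
    return FeatureMatrix(X, rows, [f"f{j}" for j in range(n_features)], y)


class TestTrainPredict:
    def test_deterministic_given_seed(self):
        m = _toy_matrix()
        p1 = predict_proba(train(m, n_trees=50, seed=4), m)
        p2 = predict_proba(train(m, n_trees=50, seed=4), m)
        assert np.array_equal(p1, p2)

    def test_separable_data_training_mcc_is_one(self):
        m = _toy_matrix(separable=True)
        ens = train(m, n_trees=50, seed=0)
        pred = (predict_proba(ens, m) >= 0.5).astype(int)
        assert MetricsReport.from_predictions(m.y, pred).mcc == 1.0

    def test_mtry_is_floor_sqrt_of_columns(self):
        m = _toy_matrix(n_features=522)
        ens = train(m, n_trees=10, seed=0)
        assert ens.mtry == 22  # floor(sqrt(522))

    def test_mtry_override(self):
        ens = train(_toy_matrix(), n_trees=10, seed=0, mtry=5)
        assert ens.mtry == 5 and ens.manifest["mtry"] == 5

    def test_single_class_raises(self):
        m = _toy_matrix()
        m.y = np.zeros_like(m.y)
        with pytest.raises(TrainingError):
            train(m, n_trees=10)

    def test_probabilities_are_vote_fractions_in_unit_interval(self):
        m = _toy_matrix(seed=3)
        ens = train(m, n_trees=50, seed=1)
        p = predict_proba(ens, m)
        assert np.all((0.0 <= p) & (p <= 1.0))
        # votes over 50 trees are multiples of 1/50
        assert np.allclose(p * 50, np.round(p * 50))

    def test_overfit_forest_recalls_own_training_rows(self):
        m = _toy_matrix(separable=True)
        ens = train(m, n_trees=50, seed=0)
        p = predict_proba(ens, m)
        for prob, label in zip(p, m.y):
            assert (prob >= 0.5) == bool(label)

    def test_column_mismatch_is_contract_error(self):
        m = _toy_matrix()
        ens = train(m, n_trees=10, seed=0)
        other = _toy_matrix(n_features=29)
        with pytest.raises(ContractError):
            predict_proba(ens, other)

    def test_empty_matrix_empty_predictions(self):
        m = _toy_matrix()
        ens = train(m, n_trees=10, seed=0)
        empty = FeatureMatrix(
            np.zeros((0, m.n_features)), [], m.feature_names, None
        )
        assert predict_proba(ens, empty).size == 0


class TestFolds:
    def test_partition_exact(self):
        ids = [f"c{i}" for i in range(53)]
        labels = [i % 3 == 0 for i in range(53)]
        folds = make_folds(ids, labels, n_folds=5, seed=2)
        flat = [c for f in folds for c in f]
        assert sorted(flat) == sorted(ids)
        assert len(set(flat)) == len(flat)

    def test_stratification_balances_classes(self):
        ids = [f"c{i}" for i in range(100)]
        labels = [i < 20 for i in range(100)]
        folds = make_folds(ids, labels, n_folds=5, seed=0)
        per_fold_pos = [sum(1 for c in f if int(c[1:]) < 20) for f in folds]
        assert per_fold_pos == [4] * 5


@pytest.fixture(scope="module")
def merged_small_study(small_study):
    config, public, inhouse, panel = small_study
    return merge_datasets(public, inhouse), panel


class TestRunValidation:
    def test_folds_cover_inhouse_compounds_and_share_across_modes(
        self, merged_small_study
    ):
        merged, panel = merged_small_study
        scheme = LabelingScheme(8.5, 70.0)
        ih_ids = sorted(
            {
                r.compound_id
                for r in merged.activities
                if r.dialect == Dialect.PERCENT_CONTROL and r.target_id == "T1"
            }
        )
        labeling = {r.compound_id: r.value < 70.0 for r in merged.activities
                    if r.dialect == Dialect.PERCENT_CONTROL and r.target_id == "T1"}
        folds_a = make_folds(ih_ids, [labeling[c] for c in ih_ids], 5, seed=9)
        folds_b = make_folds(ih_ids, [labeling[c] for c in ih_ids], 5, seed=9)
        assert folds_a == folds_b  # identical folds reused across modes
        assert sorted(c for f in folds_a for c in f) == ih_ids

    def test_perfect_oracle_labels_give_mcc_one_per_fold(self):
        # zero generator noise makes labels a deterministic function of the
        # planted substructure, so every fold classifies perfectly
        from pcmscreen.synthetic import GeneratorConfig, generate_study

        config = GeneratorConfig(
            seed=13, n_public_compounds=40, n_inhouse_compounds=120,
            panel_size=4, sequence_length=120, noise_sd_inhouse=0.0,
            motif_prevalence_inhouse=0.5,  # balanced classes: fully separable
        )
        public, inhouse, panel = generate_study(config)
        merged = merge_datasets(public, inhouse)
        res = run_validation(
            ValidationDesign("inhouse_only_cv", seed=1), merged, panel,
            LabelingScheme(8.5, 70.0), "T1", n_trees=100,
        )
        assert [r.mcc for r in res.per_fold] == [1.0] * 5

    def test_combined_training_excludes_test_compounds(self, merged_small_study):
        # leakage guard: no test compound's records may enter training
        merged, panel = merged_small_study
        scheme = LabelingScheme(8.5, 70.0)
        ih = [
            r for r in merged.activities
            if r.dialect == Dialect.PERCENT_CONTROL and r.target_id == "T1"
        ]
        ih_ids = sorted({r.compound_id for r in ih})
        lab = {r.compound_id: int(r.value < 70) for r in ih}
        folds = make_folds(ih_ids, [lab[c] for c in ih_ids], 5, seed=0)
        test_set = set(folds[0])
        train_records = [
            r for r in merged.activities if r.compound_id not in test_set
        ]
        assert not {r.compound_id for r in train_records} & test_set

    def test_qsar_holdout_returns_single_report(self, merged_small_study):
        merged, panel = merged_small_study
        res = run_validation(
            ValidationDesign("qsar_holdout", seed=1), merged, panel,
            LabelingScheme(8.5, 70.0), "T1", n_trees=100,
        )
        assert len(res.per_fold) == 1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ValidationDesign("bootstrap")
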