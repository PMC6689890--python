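"""Random-forest PCM/QSAR classifiers, validation designs, and metrics.

The classifier is a 500-tree random forest whose class "probability" is the
fraction of trees voting active; mtry (features tried per split) defaults to
floor(sqrt(n_features)). Three cross-validation designs share one set of
folds over the in-house primary-target compounds, so that models trained on
public data only, in-house data only, or both are scored on identical test
compounds: the design that exposes how much each source contributes inside
the in-house chemical space.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .descriptors import FeatureMatrix, assemble_matrix
from .io_standardize import ActivityRecord, Dataset, Dialect, ProteinPanel

VALIDATION_MODES = ("qsar_holdout", "public_only_cv", "inhouse_only_cv", "combined_cv")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _safe_div(num: float, den: float) -> float:
    """Ratio with the 0-convention for empty marginals."""
    return num / den if den else 0.0


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "MetricsReport":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    @property
    def sensitivity(self) -> float:
        return _safe_div(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _safe_div(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _safe_div(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _safe_div(self.tn, self.tn + self.fn)

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient; 0 when any marginal is empty."""
        den = math.sqrt(
            (self.tp + self.fp)
            * (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tn + self.fn)
        )
        return _safe_div(self.tp * self.tn - self.fp * self.fn, den)

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "PPV": self.ppv, "NPV": self.npv, "MCC": self.mcc,
        }


def mcc_from_rates(
    sensitivity: float, specificity: float, ppv: float, npv: float
) -> float:
    """MCC reconstructed from the four confusion-matrix rates.

    Uses the identity MCC = sqrt(sens*spec*PPV*NPV)
    − sqrt((1−sens)(1−spec)(1−PPV)(1−NPV)), exact whenever no marginal of
    the underlying confusion matrix is zero. Useful to cross-check reported
    performance tables that print rates and MCC independently.
    """
    for name, r in (
        ("sensitivity", sensitivity), ("specificity", specificity),
        ("ppv", ppv), ("npv", npv),
    ):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    pos = math.sqrt(sensitivity * specificity * ppv * npv)
    neg = math.sqrt((1 - sensitivity) * (1 - specificity) * (1 - ppv) * (1 - npv))
    return pos - neg


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

class TrainingError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass
class TrainedEnsemble:
    model: RandomForestClassifier
    feature_names: list[str]
    manifest: dict

    @property
    def n_trees(self) -> int:
        return self.model.n_estimators

    @property
    def mtry(self) -> int:
        return self.manifest["mtry"]


def _dataset_hash(matrix: FeatureMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(matrix.X).tobytes())
    if matrix.y is not None:
        h.update(np.ascontiguousarray(matrix.y).tobytes())
    return h.hexdigest()[:16]


def train(
    matrix: FeatureMatrix,
    n_trees: int = 500,
    seed: int = 0,
    mtry: int | None = None,
) -> TrainedEnsemble:
    """Fit a random-forest classifier on a labeled feature matrix.

    mtry defaults to floor(sqrt(n_features)); all other hyperparameters are
    library defaults, recorded in the manifest.
    """
    if matrix.y is None:
        raise TrainingError("matrix is unlabeled")
    classes = np.unique(matrix.y)
    if len(classes) < 2:
        raise TrainingError(f"training data is single-class: {classes}")
    mtry = mtry if mtry is not None else int(math.floor(math.sqrt(matrix.n_features)))
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
    )
    rf.fit(matrix.X, matrix.y)
    manifest = {
        "n_trees": n_trees,
        "mtry": mtry,
        "seed": seed,
        "n_rows": len(matrix.rows),
        "n_features": matrix.n_features,
        "dataset_hash": _dataset_hash(matrix),
        "hyperparameters": "scikit-learn RandomForestClassifier defaults",
    }
    return TrainedEnsemble(rf, list(matrix.feature_names), manifest)


def predict_proba(ensemble: TrainedEnsemble, matrix: FeatureMatrix) -> np.ndarray:
    """Active-class probability per row = fraction of trees voting active.

    Each tree casts one vote (its majority leaf class); the score is the
    active-vote proportion, matching classical random-forest voting.
    """
    if list(matrix.feature_names) != list(ensemble.feature_names):
        missing = set(ensemble.feature_names) - set(matrix.feature_names)
        extra = set(matrix.feature_names) - set(ensemble.feature_names)
        raise ContractError(
            f"feature columns do not match training manifest; "
            f"missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]}"
        )
    if matrix.X.shape[0] == 0:
        return np.zeros(0)
    active_idx = int(np.where(ensemble.model.classes_ == 1)[0][0])
    votes = np.zeros(matrix.X.shape[0])
    for tree in ensemble.model.estimators_:
        leaf_proba = tree.predict_proba(matrix.X)
        votes += (np.argmax(leaf_proba, axis=1) == active_idx).astype(float)
    return votes / ensemble.n_trees


# ---------------------------------------------------------------------------
# Validation designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationDesign:
    mode: str
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.mode not in VALIDATION_MODES:
            raise ValueError(f"mode must be one of {VALIDATION_MODES}")


@dataclass
class ValidationResult:
    design: ValidationDesign
    per_fold: list[MetricsReport]
    degenerate_folds: list[int] = field(default_factory=list)

    def summary(self) -> dict[str, tuple[float, float]]:
        """mean ± sd of each rate over folds."""
        out = {}
        for key in ("sensitivity", "specificity", "PPV", "NPV", "MCC"):
            vals = np.array([r.as_dict()[key] for r in self.per_fold], dtype=float)
            out[key] = (float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        return out

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([r.mcc for r in self.per_fold]))


def make_folds(
    compound_ids: Sequence[str],
    labels: Sequence[int],
    n_folds: int = 5,
    seed: int = 0,
) -> list[list[str]]:
    """Label-stratified partition of compounds (not rows) into n_folds folds.

    Deterministic given seed; folds are disjoint and their union is the full
    compound set, so a test compound never appears in its fold's training
    data.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(compound_ids)
    labels = np.asarray(labels)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        members = ids[labels == cls]
        members = members[rng.permutation(len(members))]
        for i, cid in enumerate(members):
            folds[i % n_folds].append(str(cid))
    return [sorted(f) for f in folds]


def _label_fn(scheme) -> Callable[[ActivityRecord], bool]:
    from .labeling import binarize

    return lambda r: binarize(r, scheme)


def run_validation(
    design: ValidationDesign,
    merged: Dataset,
    panel: ProteinPanel | None,
    scheme,
    target_id: str,
    n_trees: int = 500,
    protein_mode: str = "per_position_variable",
    holdout_fraction: float = 0.3,
) -> ValidationResult:
    """Run one of the validation designs.

    All CV modes score on the same folds of in-house primary-target
    compounds; training data varies by mode:

    - public_only_cv: all public (pChEMBL-dialect) records;
    - inhouse_only_cv: in-house records minus any record of a test compound;
    - combined_cv: public + in-house, minus any record of a test compound;
    - qsar_holdout: single ligand-only split — train on primary-target
      public records plus (1 − holdout_fraction) of in-house primary-target
      compounds, test on the rest (the threshold-selection benchmark).

    Public records of test-fold compounds are excluded from training in every
    mode (leakage guard).
    """
    labeling = _label_fn(scheme)
    inhouse = [
        r
        for r in merged.activities
        if r.dialect == Dialect.PERCENT_CONTROL and r.target_id == target_id
    ]
    if not inhouse:
        raise TrainingError(f"no in-house records for target {target_id!r}")
    public = [r for r in merged.activities if r.dialect == Dialect.PCHEMBL]
    ih_ids = sorted({r.compound_id for r in inhouse})
    ih_label = {r.compound_id: int(labeling(r)) for r in inhouse}

    if design.mode == "qsar_holdout":
        from .labeling import _quartile_strata  # shared split logic

        train_ids, test_ids = _quartile_strata(
            inhouse, holdout_fraction, design.seed
        )
        fold_sets = [set(test_ids)]
        ligand_only = True
    else:
        folds = make_folds(
            ih_ids, [ih_label[c] for c in ih_ids], design.n_folds, design.seed
        )
        fold_sets = [set(f) for f in folds]
        ligand_only = False

    use_panel = None if ligand_only else panel
    reports, degenerate = [], []
    for i, test_compounds in enumerate(fold_sets):
        test_records = [r for r in inhouse if r.compound_id in test_compounds]
        if design.mode == "public_only_cv":
            train_records = [
                r for r in public if r.compound_id not in test_compounds
            ]
        elif design.mode == "inhouse_only_cv":
            train_records = [
                r
                for r in merged.activities
                if r.dialect == Dialect.PERCENT_CONTROL
                and r.compound_id not in test_compounds
            ]
        elif design.mode == "combined_cv":
            train_records = [
                r for r in merged.activities if r.compound_id not in test_compounds
            ]
        else:  # qsar_holdout
            train_records = [
                r
                for r in merged.activities
                if r.target_id == target_id and r.compound_id not in test_compounds
            ]
        train_matrix = assemble_matrix(
            merged.compounds, train_records, use_panel, labeling,
            protein_mode=protein_mode,
        )
        test_matrix = assemble_matrix(
            merged.compounds, test_records, use_panel, labeling,
            protein_mode=protein_mode,
        )
        ensemble = train(train_matrix, n_trees=n_trees, seed=design.seed)
        proba = predict_proba(ensemble, test_matrix)
        pred = (proba >= 0.5).astype(int)  # ties classified active
        report = MetricsReport.from_predictions(test_matrix.y, pred)
        if len(np.unique(test_matrix.y)) < 2:
            degenerate.append(i)
        reports.append(report)
    return ValidationResult(design, reports, degenerate)
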