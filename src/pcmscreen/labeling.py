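"""Activity binarization and dual-threshold selection by grid search.

The two dialects cannot be converted into a common potency unit, so the
pipeline classifies: a public pChEMBL record is active above a pChEMBL
cutoff (strict >), an in-house %-control record is active below a percent
cutoff (strict <; 100 = no inhibition). The (pChEMBL, percent) cutoff pair
is chosen by grid search: each candidate pair labels both sets, a
ligand-only random-forest QSAR benchmark is trained on the public
primary-target records plus 70% of the in-house primary-target compounds,
and the pair maximizing MCC on the held-out 30% is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .descriptors import assemble_matrix
from .io_standardize import ActivityRecord, Dataset, Dialect
from .model import MetricsReport, TrainingError, predict_proba, train

log = logging.getLogger(__name__)

DEFAULT_PCHEMBL_GRID = (6.5, 7.0, 7.5, 8.0, 8.5, 9.0)
DEFAULT_PERCENT_GRID = (50.0, 55.0, 60.0, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0)


@dataclass(frozen=True)
class LabelingScheme:
    """Dual activity threshold: active iff pChEMBL > cutoff or % < cutoff."""

    pchembl_cutoff: float = 8.5
    percent_cutoff: float = 70.0

    def __post_init__(self):
        if not 4.0 <= self.pchembl_cutoff <= 10.0:
            raise ValueError("pchembl_cutoff must be in [4, 10]")
        if not 0.0 < self.percent_cutoff < 100.0:
            raise ValueError("percent_cutoff must be in (0, 100)")


def binarize(record: ActivityRecord, scheme: LabelingScheme) -> bool:
    """True iff the record is 'active' under the scheme (strict inequalities)."""
    if record.dialect == Dialect.PCHEMBL:
        return record.value > scheme.pchembl_cutoff
    return record.value < scheme.percent_cutoff


@dataclass(frozen=True)
class GridCell:
    scheme: LabelingScheme
    metrics: MetricsReport
    degenerate: bool = False

    @property
    def mcc(self) -> float:
        return 0.0 if self.degenerate else self.metrics.mcc


@dataclass
class GridResult:
    cells: list[GridCell]
    selected: LabelingScheme
    seed: int = 0

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for c in self.cells:
            d = c.metrics.as_dict()
            rows.append(
                {
                    "pchembl_cutoff": c.scheme.pchembl_cutoff,
                    "percent_cutoff": c.scheme.percent_cutoff,
                    "sensitivity": d["sensitivity"],
                    "specificity": d["specificity"],
                    "PPV": d["PPV"],
                    "NPV": d["NPV"],
                    "MCC": c.mcc,
                    "degenerate": c.degenerate,
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


def default_grid() -> list[LabelingScheme]:
    return [
        LabelingScheme(p, c) for p in DEFAULT_PCHEMBL_GRID for c in DEFAULT_PERCENT_GRID
    ]


def _quartile_strata(
    inhouse: Sequence[ActivityRecord], test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Split in-house compounds into train/test, stratified by %-value quartile.

    Stratifying on the continuous %-control quartiles (rather than on labels)
    keeps one fixed split approximately balanced under every candidate
    percent cutoff of the grid.
    """
    rng = np.random.default_rng(seed)
    by_compound: dict[str, float] = {}
    for r in inhouse:
        by_compound[r.compound_id] = r.value
    ids = np.array(sorted(by_compound))
    values = np.array([by_compound[c] for c in ids])
    quartiles = np.searchsorted(
        np.quantile(values, [0.25, 0.5, 0.75]), values, side="left"
    )
    train_ids, test_ids = [], []
    for q in np.unique(quartiles):
        members = ids[quartiles == q]
        members = members[rng.permutation(len(members))]
        n_test = int(round(test_fraction * len(members)))
        test_ids.extend(members[:n_test])
        train_ids.extend(members[n_test:])
    return sorted(train_ids), sorted(test_ids)


def grid_search(
    public: Dataset,
    inhouse: Dataset,
    target_id: str,
    grid: Sequence[LabelingScheme] | None = None,
    seed: int = 0,
    test_fraction: float = 0.3,
    n_trees: int = 500,
) -> GridResult:
    """Select the activity-threshold pair by QSAR benchmarking.

    For every grid cell: label the primary-target records of both datasets
    with the cell's scheme, train a ligand-only random forest on public +
    70% of in-house compounds, and score MCC on the held-out 30% of in-house
    compounds. The same quartile-stratified split (fixed seed) is reused
    across all cells. Cells whose training labels collapse to a single class
    are marked degenerate (MCC recorded as 0). Ties are broken toward higher
    pChEMBL cutoff, then lower percent cutoff (stricter actives).
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("grid is empty")

    pub_records = [r for r in public.activities if r.target_id == target_id]
    ih_records = [r for r in inhouse.activities if r.target_id == target_id]
    if not ih_records:
        raise TrainingError(f"no in-house records for target {target_id!r}")
    train_ids, test_ids = _quartile_strata(ih_records, test_fraction, seed)
    train_set, test_set = set(train_ids), set(test_ids)

    # Features are label-independent: assemble once, relabel per cell.
    train_records = pub_records + [r for r in ih_records if r.compound_id in train_set]
    test_records = [r for r in ih_records if r.compound_id in test_set]
    compounds = list(public.compounds) + list(inhouse.compounds)
    base_train = assemble_matrix(compounds, train_records, panel=None)
    base_test = assemble_matrix(compounds, test_records, panel=None)

    cells = []
    for scheme in grid:
        y_train = np.array(
            [int(binarize(r, scheme)) for r in train_records], dtype=int
        )
        y_test = np.array([int(binarize(r, scheme)) for r in test_records], dtype=int)
        if len(np.unique(y_train)) < 2:
            log.warning("degenerate grid cell %s: single-class training labels", scheme)
            cells.append(
                GridCell(scheme, MetricsReport(0, 0, 0, 0), degenerate=True)
            )
            continue
        train_matrix = type(base_train)(
            base_train.X, base_train.rows, base_train.feature_names, y_train
        )
        test_matrix = type(base_test)(
            base_test.X, base_test.rows, base_test.feature_names, y_test
        )
        ensemble = train(train_matrix, n_trees=n_trees, seed=seed)
        pred = (predict_proba(ensemble, test_matrix) >= 0.5).astype(int)
        cells.append(GridCell(scheme, MetricsReport.from_predictions(y_test, pred)))

    selected = max(
        cells,
        key=lambda c: (c.mcc, c.scheme.pchembl_cutoff, -c.scheme.percent_cutoff),
    ).scheme
    return GridResult(cells=cells, selected=selected, seed=seed)
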