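"""Prospective virtual screening and compound selection.

A trained PCM ensemble scores every library compound against the primary
target (the protein block is fixed). Candidates are pre-filtered on
predicted class probability ≥ 0.8 and molecular weight > 300 Da (fragments
removed), then two complementary pick lists are made: a Diverse set of
k-medoid cluster centers (one real compound per cluster, 1 − Tanimoto
distance on the circular fingerprints) and per-reference analog sets ranked
by Tanimoto similarity to known inhibitors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import (
    FeatureMatrix,
    circular_fingerprint,
    ligand_block,
    ligand_feature_names,
    molecular_weight,
    zscale_descriptor,
)
from .io_standardize import CompoundRecord, ProteinPanel, StandardizationError
from .model import TrainedEnsemble, predict_proba

log = logging.getLogger(__name__)


def hit_rate_percent(n_active: int, n_tested: int) -> int:
    """Hit rate as an integer percentage, rounded half up (15/40 → 38)."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return int(math.floor(100.0 * n_active / n_tested + 0.5))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_library(
    ensemble: TrainedEnsemble,
    library: Sequence[CompoundRecord],
    panel: ProteinPanel | None,
    target_id: str | None = None,
    protein_mode: str = "per_position_variable",
    batch_size: int = 2000,
    n_bits: int = 512,
    radius: int = 3,
) -> tuple[pd.DataFrame, int]:
    """Predicted active-class probability for every scorable library compound.

    Returns (table with compound_id / probability / mw, count of compounds
    skipped because their structure could not be featurized). Batched so
    memory stays bounded in library size.
    """
    prot_block = np.zeros(0)
    names = ligand_feature_names(n_bits)
    if panel is not None:
        if target_id is None:
            raise ValueError("target_id required when a panel is given")
        d = zscale_descriptor(panel, target_id, protein_mode)
        prot_block = d.zvalues
        names = names + list(d.feature_names)

    ids: list[str] = []
    probs: list[float] = []
    mws: list[float] = []
    n_failed = 0
    for start in range(0, len(library), batch_size):
        batch = library[start : start + batch_size]
        rows, blocks, batch_mw = [], [], []
        for rec in batch:
            try:
                lig = ligand_block(rec.structure, radius, n_bits)
                mw = molecular_weight(rec.structure)
            except StandardizationError as err:
                log.warning("unscorable %s: %s", rec.compound_id, err)
                n_failed += 1
                continue
            rows.append((rec.compound_id, target_id or ""))
            blocks.append(np.concatenate([lig, prot_block]))
            batch_mw.append(mw)
        if not rows:
            continue
        matrix = FeatureMatrix(np.vstack(blocks), rows, list(names))
        p = predict_proba(ensemble, matrix)
        ids.extend(r[0] for r in rows)
        probs.extend(p.tolist())
        mws.extend(batch_mw)
    table = pd.DataFrame({"compound_id": ids, "probability": probs, "mw": mws})
    return table, n_failed


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def prefilter(
    table: pd.DataFrame, p_cut: float = 0.8, mw_cut: float = 300.0
) -> list[str]:
    """Survivor ids: probability ≥ p_cut and molecular weight strictly > mw_cut."""
    mask = (table["probability"] >= p_cut) & (table["mw"] > mw_cut)
    return table.loc[mask, "compound_id"].tolist()


# ---------------------------------------------------------------------------
# k-medoids (PAM-style) on 1 − Tanimoto
# ---------------------------------------------------------------------------

def _tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    fps = (np.asarray(fps) > 0).astype(np.float64)
    inter = fps @ fps.T
    counts = fps.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)
    np.fill_diagonal(sim, 1.0)
    return 1.0 - sim


def kmedoids(
    dist: np.ndarray, k: int, seed: int = 0, max_iter: int = 100
) -> tuple[list[int], np.ndarray]:
    """PAM-style k-medoids on a precomputed distance matrix.

    Greedy BUILD initialization, then alternating assignment / medoid update
    until fixed point. Returns (medoid indices, assignment labels).
    Deterministic given seed (the seed only breaks exact cost ties).
    """
    n = dist.shape[0]
    if k >= n:
        return list(range(n)), np.arange(n)
    rng = np.random.default_rng(seed)
    # PAM BUILD: start from the global medoid, then greedily add the point
    # that most reduces total distance-to-nearest-medoid. Deterministic up
    # to exact-cost ties, which the seeded rng breaks.
    totals = dist.sum(axis=1)
    medoids = [int(np.argmin(totals))]
    d_near = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = np.flatnonzero(gains == gains.max())
        choice = int(best[rng.integers(len(best))])
        medoids.append(choice)
        d_near = np.minimum(d_near, dist[:, choice])
    medoids = sorted(medoids)

    labels = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = []
        for j in range(k):
            members = np.where(labels == j)[0]
            if len(members) == 0:
                new_medoids.append(medoids[j])
                continue
            sub = dist[np.ix_(members, members)]
            new_medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
        new_medoids = sorted(new_medoids)
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if new_medoids == sorted(medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return list(medoids), labels


def select_diverse(
    survivor_fps: Mapping[str, np.ndarray], k: int = 40, seed: int = 0
) -> list[str]:
    """k-medoid cluster centers among survivors (all survivors if ≤ k)."""
    ids = sorted(survivor_fps)
    if len(ids) <= k:
        return ids
    fps = np.vstack([survivor_fps[i] for i in ids])
    dist = _tanimoto_distance_matrix(fps)
    medoid_idx, _ = kmedoids(dist, k, seed=seed)
    return sorted(ids[i] for i in medoid_idx)


def select_analogs(
    reference: CompoundRecord,
    survivor_fps: Mapping[str, np.ndarray],
    n: int = 10,
    n_bits: int = 512,
    radius: int = 3,
) -> list[str]:
    """The n survivors most similar (Tanimoto) to a reference inhibitor.

    Descending similarity; ties broken by lexicographic compound id. If
    fewer than n survivors exist, all are returned with a warning.
    """
    ref_fp = circular_fingerprint(reference.structure, radius, n_bits)
    ids = sorted(survivor_fps)
    sims = []
    for cid in ids:
        fp = survivor_fps[cid]
        a = (ref_fp > 0); b = (np.asarray(fp) > 0)
        union = int(np.sum(a | b))
        sims.append((int(np.sum(a & b)) / union) if union else 0.0)
    order = sorted(range(len(ids)), key=lambda i: (-sims[i], ids[i]))
    if len(ids) < n:
        log.warning(
            "only %d survivors for reference %s (requested %d)",
            len(ids), reference.compound_id, n,
        )
    picked = [ids[i] for i in order[:n]]
    low = [ids[i] for i in order[:n] if sims[i] < 0.2]
    if low:
        log.info("low-similarity analogs for %s: %s", reference.compound_id, low)
    return picked


# ---------------------------------------------------------------------------
# Selection report
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    table: pd.DataFrame  # compound_id, probability, mw, passed_p50/p80/mw
    diverse_picks: list[str]
    analog_picks: dict[str, list[str]] = field(default_factory=dict)

    @property
    def all_picks(self) -> list[str]:
        seen, out = set(), []
        for cid in self.diverse_picks:
            if cid not in seen:
                seen.add(cid); out.append(cid)
        for picks in self.analog_picks.values():
            for cid in picks:
                if cid not in seen:
                    seen.add(cid); out.append(cid)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def build_selection_report(
    scored: pd.DataFrame,
    library: Sequence[CompoundRecord],
    references: Sequence[tuple[CompoundRecord, int]] = (),
    k_diverse: int = 40,
    p_cut: float = 0.8,
    mw_cut: float = 300.0,
    seed: int = 0,
    n_bits: int = 512,
    radius: int = 3,
) -> SelectionReport:
    """Full prospective selection: prefilter, Diverse picks, analog picks.

    ``references`` are (reference compound, n analogs) pairs. Analog picks
    exclude compounds already in the Diverse set (Diverse takes precedence),
    so the combined pick list is duplicate-free.
    """
    table = scored.copy()
    table["passed_p50"] = table["probability"] >= 0.5
    table["passed_p80"] = table["probability"] >= p_cut
    table["passed_mw"] = table["mw"] > mw_cut
    survivors = prefilter(table, p_cut, mw_cut)
    by_id = {c.compound_id: c for c in library}
    survivor_fps = {
        cid: circular_fingerprint(by_id[cid].structure, radius, n_bits)
        for cid in survivors
    }
    diverse = select_diverse(survivor_fps, k=k_diverse, seed=seed)
    analog_pool = {c: f for c, f in survivor_fps.items() if c not in set(diverse)}
    analogs = {}
    for ref, n in references:
        picks = select_analogs(ref, analog_pool, n=n, n_bits=n_bits, radius=radius)
        analogs[ref.compound_id] = picks
        for cid in picks:  # keep pick lists mutually disjoint as well
            analog_pool.pop(cid, None)
    return SelectionReport(table=table, diverse_picks=diverse, analog_picks=analogs)
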