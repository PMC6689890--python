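"""Chemical-space diagnostics: t-SNE embedding, physchem contrasts, clustering.

The embedding works on circular fingerprints folded to 2048 bits and returns
two components (CSNE1, CSNE2) per compound. The physchem summary contrasts
sources (e.g. the glycoside-dominated public set versus a diverse in-house
screen) on MW, ALogP, HBD and HBA. Actives — in-house %-control < 70 plus
public pChEMBL ≥ 6.5, the inclusive cutoff that admits weak binders rather
than the stricter 8.5 modeling cutoff — are grouped by k-medoids into
candidate binding-mode clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .descriptors import circular_fingerprint, physchem_block
from .io_standardize import CompoundRecord, Dataset, Dialect
from .screening import _tanimoto_distance_matrix, kmedoids

log = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    compound_ids: list[str]
    coordinates: np.ndarray  # (n, 2): CSNE1, CSNE2
    perplexity: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "CSNE1": self.coordinates[:, 0],
                "CSNE2": self.coordinates[:, 1],
            }
        )


def embed_tsne(
    fps: Mapping[str, np.ndarray], perplexity: float = 30.0, seed: int = 0
) -> EmbeddingResult:
    """2-D t-SNE of fingerprint vectors (typically folded to 2048 bits)."""
    ids = list(fps)
    n = len(ids)
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} compounds (need n > 3*perplexity)"
        )
    X = np.vstack([fps[i] for i in ids]).astype(np.float32)
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    coords = tsne.fit_transform(X)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return EmbeddingResult(ids, np.asarray(coords, float), perplexity, seed)


def physchem_summary(
    compounds: Sequence[CompoundRecord],
) -> pd.DataFrame:
    """Per-source mean ± sd of MW, ALogP, HBD, HBA (one row per source)."""
    rows = []
    for c in compounds:
        mw, alogp, hba, hbd = physchem_block(c.structure)[:4]
        rows.append(
            {"source": c.source.value, "MW": mw, "ALogP": alogp, "HBD": hbd, "HBA": hba}
        )
    if not rows:
        log.warning("no compounds to summarize")
        return pd.DataFrame(
            columns=["source", "MW_mean", "MW_sd", "ALogP_mean", "ALogP_sd",
                     "HBD_mean", "HBD_sd", "HBA_mean", "HBA_sd"]
        )
    df = pd.DataFrame(rows)
    out = []
    for source, grp in df.groupby("source"):
        entry = {"source": source}
        for prop in ("MW", "ALogP", "HBD", "HBA"):
            entry[f"{prop}_mean"] = float(grp[prop].mean())
            entry[f"{prop}_sd"] = float(grp[prop].std(ddof=0))
        out.append(entry)
    return pd.DataFrame(out)


def select_actives_for_clustering(
    merged: Dataset,
    target_id: str,
    percent_cutoff: float = 70.0,
    pchembl_cutoff: float = 6.5,
) -> list[CompoundRecord]:
    """Primary-target actives for binding-mode clustering.

    In-house: %-control < percent_cutoff (strict). Public: pChEMBL ≥
    pchembl_cutoff (inclusive — deliberately weaker than the modeling
    cutoff so weak binders are clustered too).
    """
    active_ids = set()
    for r in merged.activities:
        if r.target_id != target_id:
            continue
        if r.dialect == Dialect.PERCENT_CONTROL and r.value < percent_cutoff:
            active_ids.add(r.compound_id)
        elif r.dialect == Dialect.PCHEMBL and r.value >= pchembl_cutoff:
            active_ids.add(r.compound_id)
    return [c for c in merged.compounds if c.compound_id in active_ids]


def cluster_actives(
    actives: Sequence[CompoundRecord],
    k: int = 10,
    seed: int = 0,
    n_bits: int = 512,
    radius: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """k-medoids clustering of actives on 1 − Tanimoto.

    Returns (per-compound table with cluster id and physchem values, medoid
    compound ids). k > n degenerates to one singleton cluster per compound.
    """
    ids = [c.compound_id for c in actives]
    if not ids:
        raise ValueError("no actives to cluster")
    if k > len(ids):
        log.warning("k=%d exceeds %d actives; singleton clusters", k, len(ids))
        k = len(ids)
    fps = np.vstack(
        [circular_fingerprint(c.structure, radius, n_bits) for c in actives]
    )
    dist = _tanimoto_distance_matrix(fps)
    medoid_idx, labels = kmedoids(dist, k, seed=seed)
    rows = []
    for i, c in enumerate(actives):
        mw, alogp, hba, hbd = physchem_block(c.structure)[:4]
        rows.append(
            {
                "compound_id": c.compound_id,
                "cluster": int(labels[i]),
                "is_medoid": i in medoid_idx,
                "MW": mw, "ALogP": alogp, "HBD": hbd, "HBA": hba,
            }
        )
    return pd.DataFrame(rows), [ids[i] for i in medoid_idx]


def cluster_physchem_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean ± sd of the physchem properties."""
    out = []
    for cluster, grp in assignments.groupby("cluster"):
        entry = {"cluster": cluster, "n": len(grp)}
        for prop in ("MW", "ALogP", "HBD", "HBA"):
            entry[f"{prop}_mean"] = float(grp[prop].mean())
            entry[f"{prop}_sd"] = float(grp[prop].std(ddof=0))
        out.append(entry)
    return pd.DataFrame(out)
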