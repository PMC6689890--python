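"""Ligand and protein descriptors, and PCM feature-matrix assembly.

Ligands are encoded as functional-class circular fingerprints of diameter 6
(FCFP-style: circular neighborhoods over pharmacophoric atom roles — H-bond
acceptor/donor, positive/negative ionizability, aromaticity, halogen —
hashed and folded to a fixed bit length) concatenated with seven
physicochemical properties. Proteins are encoded with the first three
Z-scales (lipophilicity, size/bulk, polarity) over a multiple sequence
alignment, either per variable alignment column or averaged over the
sequence. A PCM row is ligand block ∥ protein block for one
(compound, target) pair.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors

from .io_standardize import (
    GAP,
    ActivityRecord,
    CompoundRecord,
    ProteinPanel,
    StandardizationError,
)

PHYSCHEM_NAMES = ["mw", "alogp", "hba", "hbd", "rot_bonds", "bridge_bonds", "arom_rings"]


class DescriptorError(ValueError):
    pass


def _load_zscales() -> dict[str, np.ndarray]:
    table = {}
    path = resources.files("pcmscreen.data").joinpath("zscales.csv")
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table[row["residue"]] = np.array(
                [float(row["z1"]), float(row["z2"]), float(row["z3"])]
            )
    assert len(table) == 20
    return table


#: First three Z-scales per residue (z1 lipophilicity, z2 size, z3 polarity).
Z_SCALES: dict[str, np.ndarray] = _load_zscales()


# ---------------------------------------------------------------------------
# Ligand block
# ---------------------------------------------------------------------------

def _mol(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StandardizationError(f"invalid structure: {structure!r}")
    return mol


def circular_fingerprint(
    structure: str, radius: int = 3, n_bits: int = 512
) -> np.ndarray:
    """Functional-class circular fingerprint folded to ``n_bits`` (uint8 0/1).

    radius=3 gives diameter-6 neighborhoods. Folding is by hash modulo
    ``n_bits`` (must be a power of two), so the bit set at 512 is the
    mod-512 image of the bit set at 2048.
    """
    if n_bits < 1 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError(f"n_bits must be a power of two, got {n_bits}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius,
        fpSize=n_bits,
        atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
    )
    fp = gen.GetFingerprint(_mol(structure))
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| on 0/1 bit vectors (empty∪empty → 0)."""
    inter = int(np.sum((a > 0) & (b > 0)))
    union = int(np.sum((a > 0) | (b > 0)))
    return inter / union if union else 0.0


def bridge_bond_count(mol: Chem.Mol) -> int:
    """Number of bonds shared by two or more rings (fused/bridged systems)."""
    counts: dict[int, int] = {}
    for ring in mol.GetRingInfo().BondRings():
        for b in ring:
            counts[b] = counts.get(b, 0) + 1
    return sum(1 for v in counts.values() if v >= 2)


def physchem_block(structure: str) -> np.ndarray:
    """Seven physicochemical properties, in PHYSCHEM_NAMES order.

    Molecular weight (Da), ALogP (atom-contribution Crippen logP), H-bond
    acceptor count, H-bond donor count, rotatable bonds, bridge bonds,
    aromatic rings.
    """
    mol = _mol(structure)
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Lipinski.NumHAcceptors(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumRotatableBonds(mol),
            bridge_bond_count(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
        ],
        dtype=float,
    )


def molecular_weight(structure: str) -> float:
    return Descriptors.MolWt(_mol(structure))


def ligand_block(structure: str, radius: int = 3, n_bits: int = 512) -> np.ndarray:
    return np.concatenate(
        [circular_fingerprint(structure, radius, n_bits).astype(float),
         physchem_block(structure)]
    )


def ligand_feature_names(n_bits: int = 512) -> list[str]:
    return [f"fcfp_{i}" for i in range(n_bits)] + PHYSCHEM_NAMES


# ---------------------------------------------------------------------------
# Protein block
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinDescriptor:
    zvalues: np.ndarray
    mode: str  # per_position_variable | sequence_mean
    feature_names: tuple[str, ...]


def variable_columns(panel: ProteinPanel) -> list[int]:
    """Alignment columns that are not identical across the panel."""
    seqs = [e.aligned_sequence for e in panel.entries]
    return [
        i for i in range(panel.alignment_length)
        if len({s[i] for s in seqs}) > 1
    ]


def zscale_descriptor(
    panel: ProteinPanel, target_id: str, mode: str = "per_position_variable"
) -> ProteinDescriptor:
    """Z-scale descriptor for one panel member.

    per_position_variable: (z1,z2,z3) of the target's residue at every
    non-conserved alignment column, gaps encoded as (0,0,0).
    sequence_mean: mean (z1,z2,z3) over the target's non-gap positions.
    """
    seq = panel.sequence(target_id)
    if mode == "per_position_variable":
        cols = variable_columns(panel)
        values, names = [], []
        for col in cols:
            aa = seq[col]
            if aa == GAP:
                z = np.zeros(3)
            elif aa in Z_SCALES:
                z = Z_SCALES[aa]
            else:
                raise DescriptorError(
                    f"{target_id}: unknown residue {aa!r} at alignment column {col}"
                )
            values.append(z)
            names.extend(f"z{k}_col{col}" for k in (1, 2, 3))
        zv = np.concatenate(values) if values else np.zeros(0)
        return ProteinDescriptor(zv, mode, tuple(names))
    if mode == "sequence_mean":
        residues = [aa for aa in seq if aa != GAP]
        bad = [
            (i, aa) for i, aa in enumerate(seq) if aa not in Z_SCALES and aa != GAP
        ]
        if bad:
            pos, aa = bad[0]
            raise DescriptorError(
                f"{target_id}: unknown residue {aa!r} at alignment column {pos}"
            )
        zv = np.mean([Z_SCALES[aa] for aa in residues], axis=0)
        return ProteinDescriptor(zv, mode, ("z1_mean", "z2_mean", "z3_mean"))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Row-aligned PCM/QSAR design matrix.

    rows[i] = (compound_id, target_id); X[i] = ligand block ∥ protein block;
    y[i] ∈ {0, 1} or None for unlabeled screening libraries.
    """

    X: np.ndarray
    rows: list[tuple[str, str]]
    feature_names: list[str]
    y: np.ndarray | None = None

    def __post_init__(self):
        if self.X.shape != (len(self.rows), len(self.feature_names)):
            raise ValueError("X shape inconsistent with rows/feature_names")
        if self.y is not None and len(self.y) != len(self.rows):
            raise ValueError("y length inconsistent with rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "compound_id", [r[0] for r in self.rows])
        df.insert(1, "target_id", [r[1] for r in self.rows])
        if self.y is not None:
            df["label"] = self.y
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        y = df.pop("label").to_numpy() if "label" in df.columns else None
        rows = list(zip(df.pop("compound_id"), df.pop("target_id")))
        return cls(df.to_numpy(float), rows, list(df.columns), y)

    def save_npz(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            X=self.X,
            rows=np.array(self.rows, dtype=object),
            feature_names=np.array(self.feature_names, dtype=object),
            y=np.array([]) if self.y is None else self.y,
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "FeatureMatrix":
        data = np.load(path, allow_pickle=True)
        y = data["y"]
        return cls(
            data["X"],
            [tuple(r) for r in data["rows"]],
            list(data["feature_names"]),
            None if y.size == 0 else y,
        )


def assemble_matrix(
    compounds: Sequence[CompoundRecord],
    activities: Sequence[ActivityRecord],
    panel: ProteinPanel | None = None,
    labeling=None,
    protein_mode: str = "per_position_variable",
    n_bits: int = 512,
    radius: int = 3,
) -> FeatureMatrix:
    """One design-matrix row per activity record.

    ``panel=None`` builds a ligand-only QSAR matrix (512 + 7 = 519 columns at
    the defaults). ``labeling`` is a callable ActivityRecord → bool (active);
    omit it for unlabeled matrices.
    """
    by_id: Mapping[str, CompoundRecord] = {c.compound_id: c for c in compounds}
    missing = sorted(
        {r.compound_id for r in activities if r.compound_id not in by_id}
        | (
            {r.target_id for r in activities if r.target_id not in panel.target_ids}
            if panel is not None
            else set()
        )
    )
    if missing:
        raise DescriptorError(f"unresolvable references: {missing}")

    lig_cache: dict[str, np.ndarray] = {}
    for cid in {r.compound_id for r in activities}:
        lig_cache[cid] = ligand_block(by_id[cid].structure, radius, n_bits)

    names = ligand_feature_names(n_bits)
    prot_cache: dict[str, np.ndarray] = {}
    if panel is not None:
        prot_names: tuple[str, ...] | None = None
        for tid in {r.target_id for r in activities}:
            d = zscale_descriptor(panel, tid, protein_mode)
            prot_cache[tid] = d.zvalues
            prot_names = d.feature_names
        names = names + list(prot_names or ())

    rows, blocks, labels = [], [], []
    for r in activities:
        block = lig_cache[r.compound_id]
        if panel is not None:
            block = np.concatenate([block, prot_cache[r.target_id]])
        rows.append((r.compound_id, r.target_id))
        blocks.append(block)
        if labeling is not None:
            labels.append(1 if labeling(r) else 0)
    X = np.vstack(blocks) if blocks else np.zeros((0, len(names)))
    y = np.array(labels, dtype=int) if labeling is not None else None
    return FeatureMatrix(X, rows, names, y)
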