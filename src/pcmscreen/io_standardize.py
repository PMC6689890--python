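"""Reading, structure standardization, and curation of bioactivity records.

Two activity dialects coexist in an SGLT screening campaign: public
ChEMBL-style records carry pChEMBL values (−log10 molar potency) with a
curation confidence score, while single-concentration in-house screens report
percent activity versus negative control at 50 µM (100 = no inhibition).
This module reads both, standardizes structures to a canonical neutral parent,
applies the confidence filter, resolves duplicate measurements by activity-unit
ranking, and merges the two sources into one curated dataset.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


class Source(str, Enum):
    PUBLIC = "public"
    IN_HOUSE = "in_house"
    LIBRARY = "library"


class Dialect(str, Enum):
    PCHEMBL = "pchembl"
    PERCENT_CONTROL = "percent_control"


#: Activity standard-unit ranking used to resolve duplicate measurements;
#: lower rank wins.
ACTIVITY_TYPE_RANK = {"Ki": 0, "IC50": 1, "EC50": 2, "Kd": 3, "percent": 4}


class StandardizationError(ValueError):
    """Raised when a structure cannot be parsed/standardized.

    Carries the id of the offending record so streaming readers can report it.
    """

    def __init__(self, message: str, record_id: str | None = None):
        super().__init__(message)
        self.record_id = record_id


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    structure: str  # canonical SMILES after standardization
    source: Source


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    target_id: str
    dialect: Dialect
    activity_type: str  # Ki | IC50 | EC50 | Kd | percent
    value: float
    confidence: int | None = None

    def __post_init__(self):
        if self.activity_type not in ACTIVITY_TYPE_RANK:
            raise ValueError(f"unknown activity_type {self.activity_type!r}")
        is_pct = self.activity_type == "percent"
        if is_pct != (self.dialect == Dialect.PERCENT_CONTROL):
            raise ValueError(
                "activity_type 'percent' must pair with dialect "
                "'percent_control' and vice versa"
            )


@dataclass(frozen=True)
class PanelEntry:
    target_id: str
    species: str
    aligned_sequence: str


@dataclass(frozen=True)
class ProteinPanel:
    entries: tuple[PanelEntry, ...]
    alignment_length: int

    @classmethod
    def from_entries(cls, entries: Iterable[PanelEntry]) -> "ProteinPanel":
        entries = tuple(entries)
        lengths = {len(e.aligned_sequence) for e in entries}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {lengths}")
        return cls(entries=entries, alignment_length=lengths.pop() if lengths else 0)

    @property
    def target_ids(self) -> list[str]:
        return [e.target_id for e in self.entries]

    def sequence(self, target_id: str) -> str:
        for e in self.entries:
            if e.target_id == target_id:
                return e.aligned_sequence
        raise KeyError(f"target {target_id!r} not in panel")


@dataclass
class Dataset:
    """A standardized compound set with its activity records."""

    compounds: list[CompoundRecord] = field(default_factory=list)
    activities: list[ActivityRecord] = field(default_factory=list)

    def compound_by_id(self, compound_id: str) -> CompoundRecord:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)


# ---------------------------------------------------------------------------
# Structure standardization
# ---------------------------------------------------------------------------

_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(raw: str, record_id: str | None = None) -> str:
    """Standardize a SMILES or molblock to a canonical neutral-parent SMILES.

    Steps (in order): parse, sanitize/cleanup, keep the largest organic
    fragment (salt stripping), neutralize charges (protonate acids,
    deprotonate bases), canonicalize. Stereo annotations are retained as
    given. Idempotent: re-applying to the output is a no-op.
    """
    raw = raw.strip()
    if raw.startswith(("\n", " ")) or "\n" in raw or raw.startswith("M  END"):
        mol = Chem.MolFromMolBlock(raw)
    else:
        mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StandardizationError(f"unparseable structure: {raw!r}", record_id)
    mol = rdMolStandardize.Cleanup(mol)
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise StandardizationError(f"standardization emptied: {raw!r}", record_id)
    return Chem.MolToSmiles(mol)


def standardize_compounds(
    raw: Iterable[tuple[str, str]], source: Source
) -> tuple[list[CompoundRecord], list[StandardizationError]]:
    """Standardize (id, structure) pairs, collecting per-record failures."""
    records, failures = [], []
    for cid, smi in raw:
        try:
            records.append(CompoundRecord(cid, standardize_structure(smi, cid), source))
        except StandardizationError as err:
            log.warning("skipping %s: %s", cid, err)
            failures.append(err)
    return records, failures


# ---------------------------------------------------------------------------
# Activity curation
# ---------------------------------------------------------------------------

KEPT_CONFIDENCE = frozenset({7, 9})


def filter_confidence(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Keep public-dialect records with curation confidence 7 or 9.

    Records lacking a confidence score are dropped and logged, not imputed.
    Order is preserved.
    """
    kept = []
    for r in records:
        if r.dialect != Dialect.PCHEMBL:
            raise ValueError("confidence filtering applies to pchembl records only")
        if r.confidence in KEPT_CONFIDENCE:
            kept.append(r)
        else:
            log.info(
                "dropping %s/%s: confidence %r not in {7, 9}",
                r.compound_id, r.target_id, r.confidence,
            )
    return kept


def deduplicate_activities(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Collapse duplicate (compound, target) measurements.

    Within each pair only records of the highest-ranked activity unit
    (Ki > IC50 > EC50 > Kd) are retained and their pChEMBL values averaged.
    """
    if any(r.dialect != Dialect.PCHEMBL for r in records):
        raise ValueError("deduplication by unit ranking applies to pchembl records")
    groups: dict[tuple[str, str], list[ActivityRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in records:
        key = (r.compound_id, r.target_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    out = []
    for key in order:
        grp = groups[key]
        best_rank = min(ACTIVITY_TYPE_RANK[r.activity_type] for r in grp)
        best = [r for r in grp if ACTIVITY_TYPE_RANK[r.activity_type] == best_rank]
        mean_value = sum(r.value for r in best) / len(best)
        out.append(replace(best[0], value=mean_value))
    return out


def merge_datasets(public: Dataset, in_house: Dataset) -> Dataset:
    """Merge the two curated sources into one dataset without duplicates.

    Compounds are identified by canonical SMILES; a compound present in both
    sources keeps a single record (the in-house one, since downstream
    validation lives in the in-house chemical space). When the same
    (compound, target) pair carries measurements in both dialects the
    in-house %-control record wins.
    """
    by_structure: dict[str, CompoundRecord] = {}
    id_remap: dict[tuple[Source, str], str] = {}
    # in-house first so its records take precedence on structure collisions
    for ds, source in ((in_house, Source.IN_HOUSE), (public, Source.PUBLIC)):
        for c in ds.compounds:
            keep = by_structure.setdefault(c.structure, c)
            id_remap[(source, c.compound_id)] = keep.compound_id

    def _remapped(ds: Dataset, source: Source) -> list[ActivityRecord]:
        out = []
        for r in ds.activities:
            key = (source, r.compound_id)
            if key not in id_remap:
                continue  # activity for a compound that failed standardization
            out.append(replace(r, compound_id=id_remap[key]))
        return out

    inhouse_acts = _remapped(in_house, Source.IN_HOUSE)
    inhouse_pairs = {(r.compound_id, r.target_id) for r in inhouse_acts}
    public_acts = [
        r
        for r in _remapped(public, Source.PUBLIC)
        if (r.compound_id, r.target_id) not in inhouse_pairs
    ]
    merged = Dataset(
        compounds=sorted(by_structure.values(), key=lambda c: c.compound_id),
        activities=sorted(
            inhouse_acts + public_acts, key=lambda r: (r.compound_id, r.target_id)
        ),
    )
    log.info(
        "merged dataset: %d unique compounds, %d activities",
        len(merged.compounds), len(merged.activities),
    )
    return merged


# ---------------------------------------------------------------------------
# Readers / writers (streaming; per-record failures reported, never fatal)
# ---------------------------------------------------------------------------

def read_smiles(path: str | Path) -> tuple[list[tuple[str, str]], list[str]]:
    """Read an id<TAB>smiles file; returns ((id, smiles) pairs, bad lines)."""
    pairs, bad = [], []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1]:
                # tolerate smiles<TAB>id order used by some tools? No: strict,
                # but report rather than abort.
                bad.append(f"{path}:{i}: malformed line {line!r}")
                continue
            pairs.append((parts[0], parts[1]))
    for b in bad:
        log.warning("%s", b)
    return pairs, bad


def write_smiles(path: str | Path, records: Iterable[CompoundRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.compound_id}\t{r.structure}\n")


def read_sdf(path: str | Path) -> tuple[list[tuple[str, str]], list[str]]:
    """Read an SDF; id from the _Name field (fallback: running index)."""
    pairs, bad = [], []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            bad.append(f"{path}: record {i}: unparseable molblock")
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        pairs.append((name or f"sdf_{i}", Chem.MolToSmiles(mol)))
    for b in bad:
        log.warning("%s", b)
    return pairs, bad


ACTIVITY_CSV_FIELDS = [
    "compound_id", "target_id", "dialect", "activity_type", "value", "confidence",
]


def read_activities_csv(
    path: str | Path,
) -> tuple[list[ActivityRecord], list[str]]:
    records, bad = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(ACTIVITY_CSV_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, 2):
            try:
                conf = row["confidence"].strip()
                records.append(
                    ActivityRecord(
                        compound_id=row["compound_id"],
                        target_id=row["target_id"],
                        dialect=Dialect(row["dialect"]),
                        activity_type=row["activity_type"],
                        value=float(row["value"]),
                        confidence=int(conf) if conf else None,
                    )
                )
            except (ValueError, KeyError) as err:
                bad.append(f"{path}:{i}: {err}")
    for b in bad:
        log.warning("%s", b)
    return records, bad


def write_activities_csv(path: str | Path, records: Iterable[ActivityRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ACTIVITY_CSV_FIELDS)
        for r in records:
            writer.writerow(
                [
                    r.compound_id, r.target_id, r.dialect.value, r.activity_type,
                    repr(r.value), "" if r.confidence is None else r.confidence,
                ]
            )


def read_alignment(path: str | Path, fmt: str = "fasta") -> ProteinPanel:
    """Read an aligned FASTA ('fasta') or Clustal ('clustal') panel.

    Record ids of the form ``target|species`` carry the species tag; a bare id
    gets species ``unknown``.
    """
    alignment = AlignIO.read(str(path), fmt)
    entries = []
    for rec in alignment:
        target_id, _, species = rec.id.partition("|")
        entries.append(
            PanelEntry(
                target_id=target_id,
                species=species or "unknown",
                aligned_sequence=str(rec.seq).upper(),
            )
        )
    panel = ProteinPanel.from_entries(entries)
    for e in panel.entries:
        stray = set(e.aligned_sequence) - set(AMINO_ACIDS) - {GAP}
        if stray:
            raise ValueError(
                f"{e.target_id}: non-standard residue symbols {sorted(stray)}"
            )
    return panel


def write_alignment_fasta(path: str | Path, panel: ProteinPanel) -> None:
    with open(path, "w") as fh:
        for e in panel.entries:
            fh.write(f">{e.target_id}|{e.species}\n{e.aligned_sequence}\n")


def ungap(aligned_sequence: str) -> str:
    return aligned_sequence.replace(GAP, "")
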