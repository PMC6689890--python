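"""Synthetic two-dialect SGLT-like datasets with planted structure–activity rules.

Emulates the study conditions the pipeline is built for: a public,
pChEMBL-valued bioactivity set concentrated in a narrow glycoside-like
chemotype measured across an 8-member SGLT-like protein panel, plus a
chemically diverse single-concentration %-control screen against two of the
panel proteins, and a diverse screening library. Activity is planted through
substructure rules so that fingerprint-based models can legitimately learn
it: a latent potency (pChEMBL-like scale) is the sum of a baseline, matched
pharmacophore-rule contributions, a small Z-scale-derived target modifier,
and Gaussian noise. The public dialect reports the latent directly as a
clipped pChEMBL; the in-house dialect maps it through a fixed logistic link
onto %-of-control (100 = no inhibition).

The logistic link midpoint is derived in closed form from the configured
``planted_percent_threshold``: it is placed so that the prevalence-weighted
densities of the two latent classes (rule-matching vs baseline compounds)
cross exactly at that %-control value, making it the recoverable optimum of
a downstream threshold grid search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .descriptors import Z_SCALES
from .io_standardize import (
    AMINO_ACIDS,
    ActivityRecord,
    CompoundRecord,
    Dataset,
    Dialect,
    PanelEntry,
    ProteinPanel,
    Source,
    standardize_structure,
    write_activities_csv,
    write_alignment_fasta,
    write_smiles,
)


@dataclass(frozen=True)
class PharmacophoreRule:
    name: str
    smarts: str
    contribution: float  # additive latent-potency contribution (pChEMBL-like)

    def matches(self, mol: Chem.Mol) -> bool:
        patt = Chem.MolFromSmarts(self.smarts)
        return mol.HasSubstructMatch(patt)


#: Default planted rules. The aryl-ethoxy motif lives only in the
#: glycoside-like grammar (public chemotype); the sulfonamide motif only in
#: the diverse grammar (in-house chemotype and library).
DEFAULT_RULES = (
    PharmacophoreRule("aryl_ethoxy", "c1ccc(OC[CH3])cc1", 4.6),
    PharmacophoreRule("sulfonamide", "S(=O)(=O)N", 3.2),
)


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_public_compounds: int = 300
    n_inhouse_compounds: int = 750
    n_library: int = 500
    panel_size: int = 8
    sequence_length: int = 500
    mutation_rate: float = 0.05
    pharmacophore_rules: tuple[PharmacophoreRule, ...] = DEFAULT_RULES
    baseline_latent: float = 4.3
    noise_sd_public: float = 0.3
    noise_sd_inhouse: float = 0.8
    percent_floor: float = 0.0
    percent_ceiling: float = 100.0
    #: The %-control cutoff planted as ground truth: the rule-matching
    #: (active) class is centered ``planted_margin`` below it, so it is the
    #: tightest cutoff enclosing the active class.
    planted_percent_threshold: float = 70.0
    planted_margin: float = 5.0
    link_scale: float = 0.8  # logistic slope of the %-control link, latent units
    motif_prevalence_public: float = 0.20
    motif_prevalence_inhouse: float = 0.15
    motif_prevalence_library: float = 0.10
    public_targets_per_compound: int = 2
    n_inhouse_targets: int = 2
    target_weight: tuple[float, float, float] = (0.15, 0.10, -0.05)

    def __post_init__(self):
        for p in (
            self.mutation_rate,
            self.motif_prevalence_public,
            self.motif_prevalence_inhouse,
            self.motif_prevalence_library,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not all(math.isfinite(r.contribution) for r in self.pharmacophore_rules):
            raise ValueError("rule contributions must be finite")
        if not 0.0 < self.planted_percent_threshold < 100.0:
            raise ValueError("planted_percent_threshold must be in (0, 100)")


# ---------------------------------------------------------------------------
# Protein panel
# ---------------------------------------------------------------------------

def generate_panel(config: GeneratorConfig) -> ProteinPanel:
    """Root random sequence plus panel members mutated at ``mutation_rate``.

    Substitutions always change the residue (drawn from the 19 others), so
    member-vs-root differences are Binomial(length, rate). Sequences are
    emitted pre-aligned: equal length, no indels.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    root = rng.choice(alphabet, size=config.sequence_length)
    entries = []
    for i in range(config.panel_size):
        seq = root.copy()
        if i > 0:
            mutate = rng.random(config.sequence_length) < config.mutation_rate
            for pos in np.where(mutate)[0]:
                others = alphabet[alphabet != seq[pos]]
                seq[pos] = rng.choice(others)
        entries.append(
            PanelEntry(
                target_id=f"T{i + 1}",
                species="synthetic",
                aligned_sequence="".join(seq),
            )
        )
    return ProteinPanel.from_entries(entries)


def target_modifier(config: GeneratorConfig, panel: ProteinPanel, target_id: str) -> float:
    """Small per-target latent shift: fixed weight · mean Z-scales of the target."""
    seq = panel.sequence(target_id).replace("-", "")
    mean_z = np.mean([Z_SCALES[aa] for aa in seq], axis=0)
    return float(np.dot(np.asarray(config.target_weight), mean_z))


# ---------------------------------------------------------------------------
# Compound grammars
# ---------------------------------------------------------------------------

# Glycoside-like: polyol-rich pyranose scaffolds and an oxopyrrolidine-
# carboxamide, mirroring the narrow public chemotype. {R1} carries the
# potency motif for active compounds; {R2} is a small decoration.
GLYCOSIDE_SCAFFOLDS = (
    "OCC1OC(Oc2ccc({R1})c({R2})c2)C(O)C(O)C1O",
    "OCC1OC(c2ccc({R1})c({R2})c2)C(O)C(O)C1O",
    "OCC1OC(Oc2cc({R2})ccc2{R1})C(O)C(O)C1O",
    "O=C1CCC(C(=O)Nc2ccc({R1})c({R2})c2)N1",
    "OCC1OC(Oc2ccc({R1})cc2C{R2})C(O)C(O)C1O",
)

#: Ethoxy-aryl motif substituents (match the aryl_ethoxy rule when attached
#: to the scaffold phenyl).
GLYCOSIDE_MOTIF_SUBS = ("OCC", "OC(C)C", "OC(C)CC")

GLYCOSIDE_NEUTRAL_SUBS = (
    "O", "N", "C", "CC", "CCC", "C(C)C", "CO", "CN", "Cl", "F", "Br",
    "C#N", "C(=O)N", "C(=O)O", "OC",
)

GLYCOSIDE_DECORATIONS = ("C", "O", "N", "F", "Cl", "CC", "OC", "CO")

# Diverse: assorted drug-like scaffolds spanning a broad MW/polarity range.
DIVERSE_SCAFFOLDS = (
    "c1ccc(-c2ccc({R1})c({R2})c2)cc1",
    "c1ccc(CN2CCN({R1})CC2)c({R2})c1",
    "O=C(Nc1ccc({R1})c({R2})c1)c1ccccc1",
    "c1ccc2c(c1)[nH]c(CC({R2})({R1})C)c2C",
    "c1ccc(COc2ccc(C{R1})c({R2})c2)cc1",
    "C1CCC(N(C{R2})C(=O)C{R1})CC1",
    "c1ccc(-n2cnc({R1})c2{R2})cc1",
    "O=S(=O)(c1ccccc1)c1ccc({R1})c({R2})c1",
)

#: Sulfonamide motif substituents (match the sulfonamide rule).
DIVERSE_MOTIF_SUBS = ("S(=O)(=O)N3CCCCC3", "S(=O)(=O)N(C)C", "S(=O)(=O)NC3CC3")

DIVERSE_NEUTRAL_SUBS = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C", "Cc3ccccc3", "c3ccccc3",
    "C3CCCCC3", "CC3CCCCC3", "N(C)C", "N3CCCC3", "CN3CCOCC3", "C(F)(F)F",
    "Cl", "F", "Br", "C#N", "C(=O)NC", "C(=O)N(C)C", "CC(=O)N(C)C",
    "CCN(C)C", "c3ccncc3", "Cc3ccc(Cl)cc3", "CC(C)CC", "CCCCCC",
    "C3CCNCC3", "CC#N", "C=C", "C3CC3",
)

DIVERSE_DECORATIONS = ("C", "F", "Cl", "CC", "C#N", "CCC", "Br", "C(C)C")


def _grammar(style: str):
    if style == "glycoside_like":
        return (
            GLYCOSIDE_SCAFFOLDS, GLYCOSIDE_MOTIF_SUBS, GLYCOSIDE_NEUTRAL_SUBS,
            GLYCOSIDE_DECORATIONS,
        )
    if style == "diverse":
        return (
            DIVERSE_SCAFFOLDS, DIVERSE_MOTIF_SUBS, DIVERSE_NEUTRAL_SUBS,
            DIVERSE_DECORATIONS,
        )
    raise ValueError(f"unknown style {style!r}")


def generate_compounds(
    config: GeneratorConfig,
    style: str,
    n: int | None = None,
    prefix: str = "CMP",
    source: Source = Source.IN_HOUSE,
    motif_prevalence: float | None = None,
    seed_offset: int = 0,
) -> list[CompoundRecord]:
    """Sample n structurally unique compounds from a fragment grammar.

    Each compound is scaffold({R1}, {R2}); active compounds (chosen with the
    style's motif prevalence) carry a motif substituent in the R1 slot.
    Emitted SMILES are standardized and canonical, so they survive
    re-standardization unchanged. If the grammar cannot produce further
    unique structures, sampling falls back to replacement with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    if n is None:
        n = {
            "glycoside_like": config.n_public_compounds,
            "diverse": config.n_inhouse_compounds,
        }[style]
    if motif_prevalence is None:
        motif_prevalence = {
            "glycoside_like": config.motif_prevalence_public,
            "diverse": config.motif_prevalence_inhouse,
        }[style]
    scaffolds, motif_subs, neutral_subs, decorations = _grammar(style)
    rng = np.random.default_rng(config.seed + seed_offset)
    seen: set[str] = set()
    records = []
    width = max(4, len(str(n)))
    for i in range(n):
        is_motif = rng.random() < motif_prevalence
        subs = motif_subs if is_motif else neutral_subs
        structure = None
        for _attempt in range(200):
            raw = (
                scaffolds[rng.integers(len(scaffolds))]
                .replace("{R1}", subs[rng.integers(len(subs))])
                .replace("{R2}", decorations[rng.integers(len(decorations))])
            )
            smi = standardize_structure(raw)
            if smi not in seen:
                structure = smi
                break
        if structure is None:
            log.warning("grammar exhausted for style %s; sampling with replacement", style)
            structure = smi
        seen.add(structure)
        records.append(
            CompoundRecord(f"{prefix}{i + 1:0{width}d}", structure, source)
        )
    return records


# ---------------------------------------------------------------------------
# Activity assignment
# ---------------------------------------------------------------------------

def link_midpoint(config: GeneratorConfig, panel: ProteinPanel) -> float:
    """Logistic-link midpoint realizing the planted %-control threshold.

    The mean latent of the dominant in-house active class (baseline + the
    diverse-grammar rule contribution + the primary target's modifier) is
    mapped onto percent t − margin, centering the active class half a grid
    step below the planted threshold t. The inactive (baseline) class then
    maps far above t, so t is the tightest activity cutoff that encloses the
    active class — the recoverable optimum of the threshold grid search.

    m = μ_a − s·logit((100 − (t − margin)) / 100).
    """
    # dominant in-house rule = the one whose motif substituents live in the
    # diverse grammar; fall back to the strongest positive rule.
    delta = max(r.contribution for r in config.pharmacophore_rules if r.contribution > 0)
    probe_mols = [
        Chem.MolFromSmiles(
            DIVERSE_SCAFFOLDS[0].replace("{R1}", s).replace("{R2}", "C")
        )
        for s in DIVERSE_MOTIF_SUBS
    ]
    for r in config.pharmacophore_rules:
        patt = Chem.MolFromSmarts(r.smarts)
        if any(m is not None and m.HasSubstructMatch(patt) for m in probe_mols):
            delta = r.contribution
            break
    mu_a = (
        config.baseline_latent
        + delta
        + target_modifier(config, panel, panel.target_ids[0])
    )
    p_center = config.planted_percent_threshold - config.planted_margin
    q = (100.0 - p_center) / 100.0
    return mu_a - config.link_scale * math.log(q / (1.0 - q))


def latent_potency(
    structure: str,
    config: GeneratorConfig,
    panel: ProteinPanel,
    target_id: str,
) -> float:
    """Noise-free latent potency: baseline + matched rules + target modifier."""
    mol = Chem.MolFromSmiles(structure)
    latent = config.baseline_latent + target_modifier(config, panel, target_id)
    for rule in config.pharmacophore_rules:
        if rule.matches(mol):
            latent += rule.contribution
    return latent


def percent_from_latent(
    latent: float, config: GeneratorConfig, panel: ProteinPanel
) -> float:
    """Fixed monotone link g: latent potency → % of negative control."""
    m = link_midpoint(config, panel)
    g = 100.0 / (1.0 + math.exp(-(latent - m) / config.link_scale))
    return float(np.clip(100.0 - g, config.percent_floor, config.percent_ceiling))


_ACTIVITY_TYPES = ("Ki", "IC50", "EC50", "Kd")


def assign_activities(
    compounds: Sequence[CompoundRecord],
    panel: ProteinPanel,
    config: GeneratorConfig,
    dialect: Dialect,
    seed_offset: int = 0,
) -> list[ActivityRecord]:
    """Assign activity records to compounds under the planted ground truth.

    Public dialect: pChEMBL = clip(latent + noise, 4, 10) with confidence 9,
    on ``public_targets_per_compound`` random panel targets per compound.
    In-house dialect: % of control = clip(100 − g(latent + noise)) on the
    first ``n_inhouse_targets`` panel targets for every compound.
    """
    rng = np.random.default_rng(config.seed + 1000 + seed_offset)
    records = []
    m = link_midpoint(config, panel)
    for c in compounds:
        if dialect == Dialect.PCHEMBL:
            k = min(config.public_targets_per_compound, len(panel.entries))
            targets = list(rng.choice(panel.target_ids, size=k, replace=False))
        else:
            targets = panel.target_ids[: config.n_inhouse_targets]
        for tid in targets:
            latent = latent_potency(c.structure, config, panel, tid)
            if dialect == Dialect.PCHEMBL:
                value = float(
                    np.clip(latent + rng.normal(0, config.noise_sd_public), 4.0, 10.0)
                )
                records.append(
                    ActivityRecord(
                        c.compound_id, tid, dialect,
                        _ACTIVITY_TYPES[rng.integers(len(_ACTIVITY_TYPES))],
                        round(value, 3), confidence=9,
                    )
                )
            else:
                noisy = latent + rng.normal(0, config.noise_sd_inhouse)
                g = 100.0 / (1.0 + math.exp(-(noisy - m) / config.link_scale))
                value = float(
                    np.clip(100.0 - g, config.percent_floor, config.percent_ceiling)
                )
                records.append(
                    ActivityRecord(
                        c.compound_id, tid, dialect, "percent", round(value, 2)
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

def generate_study(
    config: GeneratorConfig,
) -> tuple[Dataset, Dataset, ProteinPanel]:
    """Generate (public dataset, in-house dataset, panel) for one seed."""
    panel = generate_panel(config)
    public_compounds = generate_compounds(
        config, "glycoside_like", prefix="PUB", source=Source.PUBLIC, seed_offset=1
    )
    inhouse_compounds = generate_compounds(
        config, "diverse", prefix="IH", source=Source.IN_HOUSE, seed_offset=2
    )
    public = Dataset(
        compounds=public_compounds,
        activities=assign_activities(
            public_compounds, panel, config, Dialect.PCHEMBL, seed_offset=1
        ),
    )
    inhouse = Dataset(
        compounds=inhouse_compounds,
        activities=assign_activities(
            inhouse_compounds, panel, config, Dialect.PERCENT_CONTROL, seed_offset=2
        ),
    )
    return public, inhouse, panel


def generate_library(config: GeneratorConfig) -> list[CompoundRecord]:
    """Diverse screening library (some compounds carry the planted motif)."""
    return generate_compounds(
        config, "diverse", n=config.n_library, prefix="LIB",
        source=Source.LIBRARY,
        motif_prevalence=config.motif_prevalence_library, seed_offset=3,
    )


def write_workspace(config: GeneratorConfig, outdir: str | Path) -> dict[str, str]:
    """Write a complete demo workspace in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    public, inhouse, panel = generate_study(config)
    library = generate_library(config)
    paths = {
        "public_compounds": outdir / "public_compounds.smi",
        "public_activities": outdir / "public_activities.csv",
        "inhouse_compounds": outdir / "inhouse_compounds.smi",
        "inhouse_activities": outdir / "inhouse_activities.csv",
        "panel": outdir / "panel.fasta",
        "library": outdir / "library.smi",
    }
    write_smiles(paths["public_compounds"], public.compounds)
    write_activities_csv(paths["public_activities"], public.activities)
    write_smiles(paths["inhouse_compounds"], inhouse.compounds)
    write_activities_csv(paths["inhouse_activities"], inhouse.activities)
    write_alignment_fasta(paths["panel"], panel)
    write_smiles(paths["library"], library)
    return {k: str(v) for k, v in paths.items()}
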