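"""Single-file pipeline configuration with study defaults, plus run manifests.

Every tunable threshold of the pipeline lives here with its default from the
modeling campaign: probability cuts 0.5 (active class) and 0.8 (prefilter),
MW cut 300 Da, activity thresholds < 70% control / pChEMBL > 8.5, 40 diverse
clusters, 10 binding-mode clusters, 500 trees. Configs round-trip through
YAML canonically; each pipeline output directory gets one RunManifest
recording the config snapshot, seeds, input hashes, library versions and
per-stage row counts/timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .labeling import DEFAULT_PCHEMBL_GRID, DEFAULT_PERCENT_GRID, LabelingScheme
from .synthetic import DEFAULT_RULES, GeneratorConfig, PharmacophoreRule


@dataclass
class LabelingConfig:
    pchembl_cutoff: float = 8.5
    percent_cutoff: float = 70.0
    pchembl_grid: list[float] = field(default_factory=lambda: list(DEFAULT_PCHEMBL_GRID))
    percent_grid: list[float] = field(default_factory=lambda: list(DEFAULT_PERCENT_GRID))
    test_fraction: float = 0.3

    @property
    def scheme(self) -> LabelingScheme:
        return LabelingScheme(self.pchembl_cutoff, self.percent_cutoff)


@dataclass
class ModelConfig:
    n_trees: int = 500
    n_folds: int = 5
    mtry: int | None = None  # None → floor(sqrt(n_features))
    protein_mode: str = "per_position_variable"


@dataclass
class ScreeningConfig:
    p_active: float = 0.5
    p_prefilter: float = 0.8
    mw_cut: float = 300.0
    k_diverse: int = 40
    n_analogs: int = 10


@dataclass
class ChemspaceConfig:
    perplexity: float = 30.0
    tsne_bits: int = 2048
    k_clusters: int = 10
    cluster_pchembl_cutoff: float = 6.5
    cluster_percent_cutoff: float = 70.0


@dataclass
class PipelineConfig:
    seed: int = 0
    target_id: str = "T1"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    chemspace: ChemspaceConfig = field(default_factory=ChemspaceConfig)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def serialize(config: PipelineConfig) -> str:
    """Canonical YAML form (sorted keys, stable across round-trips)."""
    return yaml.safe_dump(_to_plain(config), sort_keys=True)


def parse(text: str) -> PipelineConfig:
    data = yaml.safe_load(text) or {}
    gen = data.get("generator", {})
    rules = tuple(
        PharmacophoreRule(r["name"], r["smarts"], float(r["contribution"]))
        for r in gen.get("pharmacophore_rules", [])
    ) or DEFAULT_RULES
    gen = {k: v for k, v in gen.items() if k != "pharmacophore_rules"}
    if "target_weight" in gen:
        gen["target_weight"] = tuple(gen["target_weight"])
    return PipelineConfig(
        seed=data.get("seed", 0),
        target_id=data.get("target_id", "T1"),
        generator=GeneratorConfig(pharmacophore_rules=rules, **gen),
        labeling=LabelingConfig(**data.get("labeling", {})),
        model=ModelConfig(**data.get("model", {})),
        screening=ScreeningConfig(**data.get("screening", {})),
        chemspace=ChemspaceConfig(**data.get("chemspace", {})),
    )


def load(path: str | Path) -> PipelineConfig:
    return parse(Path(path).read_text())


def save(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(serialize(config))


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _library_versions() -> dict[str, str]:
    import numpy, pandas, rdkit, sklearn

    return {
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "rdkit": rdkit.__version__,
        "scikit-learn": sklearn.__version__,
    }


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    stage: str
    config: dict
    seed: int
    input_hashes: dict[str, str] = field(default_factory=dict)
    library_versions: dict[str, str] = field(default_factory=_library_versions)
    row_counts: dict[str, int] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        path = Path(outdir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def make_manifest(
    stage: str, config: PipelineConfig, inputs: dict[str, str | Path] | None = None
) -> RunManifest:
    return RunManifest(
        stage=stage,
        config=_to_plain(config),
        seed=config.seed,
        input_hashes={
            k: file_sha256(v) for k, v in (inputs or {}).items() if Path(v).exists()
        },
    )
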