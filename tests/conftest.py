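import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcmscreen.io_standardize import (
    ActivityRecord,
    CompoundRecord,
    Dataset,
    Dialect,
    PanelEntry,
    ProteinPanel,
    Source,
)
from pcmscreen.synthetic import GeneratorConfig, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: Assorted clean structures for idempotence / determinism properties.
FIXTURE_SMILES = [
    "CCO",
    "c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "OCC1OC(Oc2ccccc2)C(O)C(O)C1O",
    "CN1CCC(c2ccccc2)CC1",
    "O=S(=O)(N)c1ccc(Cl)cc1",
    "C1CCNCC1",
    "c1ccc2[nH]ccc2c1",
]


@pytest.fixture(scope="session")
def tiny_panel() -> ProteinPanel:
    return ProteinPanel.from_entries(
        [
            PanelEntry("T1", "synthetic", "ACDEFGHIKL"),
            PanelEntry("T2", "synthetic", "ACDEFGHIKV"),
            PanelEntry("T3", "synthetic", "ACDEYGHIKL"),
        ]
    )


@pytest.fixture(scope="session")
def small_study():
    """A small generated two-dialect study shared across fast tests."""
    config = GeneratorConfig(
        seed=7, n_public_compounds=60, n_inhouse_compounds=120, n_library=60,
        panel_size=4, sequence_length=120,
    )
    public, inhouse, panel = generate_study(config)
    return config, public, inhouse, panel


def make_activity(
    compound_id="c1",
    target_id="T1",
    dialect=Dialect.PCHEMBL,
    activity_type="Ki",
    value=7.0,
    confidence=9,
):
    if dialect == Dialect.PERCENT_CONTROL:
        activity_type = "percent"
        confidence = None
    return ActivityRecord(compound_id, target_id, dialect, activity_type, value, confidence)
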