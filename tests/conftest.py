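import numpy as np
import pytest

from pbsmine import PipelineConfig, build_dataset, profile_dataset
from pbsmine.align import ScoringScheme
from pbsmine.refpanel import build_reference_panel


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def panel():
    return build_reference_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {f.family_name: f for f in panel}


@pytest.fixture(scope="session")
def full_dataset(tmp_path_factory):
    """The complete synthetic dataset at seed 1 plus its truth manifest."""
    out = tmp_path_factory.mktemp("dataset")
    manifest = build_dataset(str(out), seed=1)
    return str(out), manifest


@pytest.fixture(scope="session")
def full_profiles(full_dataset, config):
    """All 21 strains profiled end-to-end from the raw FASTA/GFF3 files."""
    dataset_dir, _ = full_dataset
    return profile_dataset(dataset_dir, config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
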