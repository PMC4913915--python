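import importlib.resources
from pathlib import Path

import pytest

from famscan import SimulationConfig, generate_proteome, write_bundle


def data_path(name: str) -> Path:
    return Path(importlib.resources.files("famscan") / "data" / name)


@pytest.fixture(scope="session")
def qtl_table_path() -> Path:
    return data_path("qtl_stress_table.csv")


@pytest.fixture(scope="session")
def evidence_table_path() -> Path:
    return data_path("stress_expression_evidence.csv")


@pytest.fixture(scope="session")
def refs_path() -> Path:
    return data_path("reference_domains_synthetic.fasta")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def synthetic(default_config):
    """Zero-noise synthetic genome: (records, loci, manifest)."""
    return generate_proteome(default_config)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, default_config):
    """Full synthetic bundle written to disk once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = write_bundle(default_config, outdir)
    return outdir, manifest
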