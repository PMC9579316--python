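"""Shared fixtures: small synthetic panels, frequencies and genotype tables."""

from pathlib import Path

import pandas as pd
import pytest

from mhkit import simdata
from mhkit.simdata import SimConfig

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_stats() -> pd.DataFrame:
    """Published 48-locus forensic battery (Ae/He/PD/PED/PET/TPI)."""
    return pd.read_csv(DATA / "che48_reference_stats.tsv", sep="\t", comment="#")


@pytest.fixture(scope="session")
def reference_mixture_report() -> pd.DataFrame:
    """Published 45-locus mixture detection-rate report (2-5 contributors)."""
    return pd.read_csv(DATA / "mixture_detection_reference.tsv", sep="\t", comment="#")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_loci=8, n_samples=20, depth_mean=200, depth_dispersion=0.0, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simdata.generate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_freqs(small_panel, small_cfg):
    return simdata.generate_frequency_table(small_panel, small_cfg)


@pytest.fixture(scope="session")
def small_genotypes(small_freqs):
    return simdata.sample_genotypes(small_freqs, 20, seed=17)
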