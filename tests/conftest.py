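"""Shared fixtures and synthetic-study builders for the test suite."""

import numpy as np
import pandas as pd
import pytest

from gutliver.config import AnalysisConfig
from gutliver.simulate import generate_study, standard_design
from gutliver.tables import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    values = pd.DataFrame(
        rng.uniform(0, 100, size=(5, 4)),
        index=[f"f{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(4)],
    )
    return FeatureTable(values, compartment="liver", layer="metabolite")


@pytest.fixture
def config():
    return AnalysisConfig()


def two_compartment_study(seed, n_modules=4, module_size=40, loading=1.0, noise_sd=0.5):
    """The module-recovery setting: equal modules spanning SI and liver."""
    per_block = n_modules * module_size // 2
    design = standard_design(
        blocks=[("SI", "metabolite", per_block), ("liver", "metabolite", per_block)],
        n_modules=n_modules,
        module_size=module_size,
        loading=loading,
        noise_sd=noise_sd,
        seed=seed,
    )
    return design, generate_study(design)


def truth_labels(design, index):
    """Planted module labels aligned to prefixed network feature ids."""
    mapping = {}
    for fid, m in design.module_assignment.items():
        compartment, layer, _ = fid.split("_", 2)
        mapping[f"{compartment}/{layer}:{fid}"] = m
    return pd.Series(mapping).reindex(index).fillna(0).astype(int)
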