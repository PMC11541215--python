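"""Shared fixtures: everything is generated in-process, no data files."""

import numpy as np
import pytest

from glycokit.conformers.library import ConformerLibrary
from glycokit.core.linkage import load_linkage_table
from glycokit.fixtures import make_sequon_protein, make_toy_glycan, reference_glcnac


@pytest.fixture(scope="session")
def linkage_table():
    return load_linkage_table()


@pytest.fixture(scope="session")
def n_linkage(linkage_table):
    return linkage_table["N-GlcNAc"]


@pytest.fixture()
def toy_glycan():
    return make_toy_glycan()


@pytest.fixture(scope="session")
def glcnac_library():
    return ConformerLibrary.from_single(reference_glcnac(), glycan_id="GlcNAc-probe")


@pytest.fixture()
def bare_sequon_protein():
    return make_sequon_protein("GNAS")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
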