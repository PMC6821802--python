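import numpy as np
import pytest

from gmocap.classify import index_database
from gmocap.dna import random_dna
from gmocap.element_db import (
    ElementCategory, ElementDatabase, StructuralElement, design_probes,
)
from gmocap.panel import synthetic_panel_database


@pytest.fixture(scope="session")
def panel_db():
    return synthetic_panel_database(0)


@pytest.fixture(scope="session")
def probes(panel_db):
    return design_probes(panel_db)


@pytest.fixture(scope="session")
def kindex(panel_db):
    return index_database(panel_db, k=15)


@pytest.fixture(scope="session")
def toy_db():
    """Three small elements for exhaustive-oracle comparisons."""
    rng = np.random.default_rng(42)
    return ElementDatabase([
        StructuralElement("alpha", ElementCategory.PROMOTER, random_dna(150, rng)),
        StructuralElement("beta", ElementCategory.GENE, random_dna(220, rng)),
        StructuralElement("gamma", ElementCategory.TERMINATOR, random_dna(180, rng)),
    ])


@pytest.fixture(scope="session")
def toy_index(toy_db):
    return index_database(toy_db, k=15)
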