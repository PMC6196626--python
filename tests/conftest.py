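import numpy as np
import pytest

from hhccdf.datasets import load_worked_example


@pytest.fixture(scope="session")
def worked_example():
    """The bundled 20-individual, single-marker dataset."""
    return load_worked_example()


@pytest.fixture(scope="session")
def worked_marker(worked_example):
    geno, pheno = worked_example
    return geno.marker(0), pheno


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
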