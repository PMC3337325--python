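import numpy as np
import pytest

from crossqtl.linkage import origin_grid
from crossqtl.linmod import ModelSpec
from crossqtl.simulate import CrossDesign, PhenotypeModel, make_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    """One full-scale synthetic cross (1912 F2, 1029 phenotyped)."""
    return make_fixture("qtn_genotyped", seed=42)


@pytest.fixture(scope="session")
def paper_states(paper_fixture):
    fx = paper_fixture
    return origin_grid(fx.pedigree, fx.genotypes, fx.gmap, step=1.0)


@pytest.fixture(scope="session")
def small_fixture():
    """A scaled-down cross for cheap pipeline-level tests."""
    design = CrossDesign(n_f2=300, n_phenotyped=300)
    return make_fixture("paper_like", seed=7, design=design)


@pytest.fixture(scope="session")
def small_states(small_fixture):
    fx = small_fixture
    return origin_grid(fx.pedigree, fx.genotypes, fx.gmap, step=1.0)


@pytest.fixture
def base_spec():
    return ModelSpec()
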