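import numpy as np
import pytest

from mitoribo.annotation import AnnotationConfig, build_default_annotation
from mitoribo.simulate import TruthTable, paired_design


@pytest.fixture(scope="session")
def small_config():
    return AnnotationConfig(n_nu_oxphos=5, n_mito_associated=4, n_other=6,
                            n_rrna=2, n_trna=6,
                            mito_length_range=(200, 500),
                            nuclear_length_range=(300, 800))


@pytest.fixture(scope="session")
def annotation(small_config):
    return build_default_annotation(small_config, seed=11)


@pytest.fixture(scope="session")
def gene_ids(annotation):
    return [r.gene_id for r in annotation if not r.is_contaminant]


@pytest.fixture
def design():
    return paired_design(3)


@pytest.fixture
def null_truth(gene_ids):
    return TruthTable.null(gene_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
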