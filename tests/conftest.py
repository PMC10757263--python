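import pytest

from basicpathways import (
    augment_with_dilution,
    build_fundamental_null_basis,
    build_glycolysis_tca_model,
    compute_basic_pathways,
    sparsify,
)


@pytest.fixture(scope="session")
def case_model():
    return build_glycolysis_tca_model()


@pytest.fixture(scope="session")
def case_S(case_model):
    return augment_with_dilution(case_model).S


@pytest.fixture(scope="session")
def case_G(case_model):
    return build_fundamental_null_basis(case_model)


@pytest.fixture(scope="session")
def case_basis_raw(case_model):
    """Elimination output before the sparsification pass."""
    return compute_basic_pathways(case_model, sparsify_result=False)


@pytest.fixture(scope="session")
def case_basis(case_basis_raw):
    """The sparsified basic-pathway basis W_s of the case model."""
    return sparsify(case_basis_raw)
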