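import pytest

from leptomr import (
    HarmonizePolicy,
    harmonize_pairs,
    load_fixture,
    retained,
    select_instruments,
)

# The packaged tables are pre-aligned on a shared effect allele, so the
# "keep" palindromic policy is the faithful harmonization for them.
FIXTURE_POLICY = HarmonizePolicy(palindromic="keep")


@pytest.fixture(scope="session")
def gwas_pairs():
    return load_fixture("gwas_combined")


@pytest.fixture(scope="session")
def ewas_pairs():
    return load_fixture("ewas_eur")


@pytest.fixture(scope="session")
def gwas5(gwas_pairs):
    """All five GWAS leptin instruments, harmonized."""
    exp, out = gwas_pairs
    instruments, dropped = harmonize_pairs(exp, out, FIXTURE_POLICY)
    assert not dropped
    return instruments


@pytest.fixture(scope="session")
def gwas4(gwas5):
    """The four GWAS instruments left after excluding the FTO SNP."""
    return [h for h in gwas5 if h.snp_id != "rs8043757"]


@pytest.fixture(scope="session")
def ewas7(ewas_pairs):
    """The seven EWAS instruments passing the strength filter, harmonized."""
    exp, out = ewas_pairs
    records = select_instruments(exp, subgroup=True)
    instruments, dropped = harmonize_pairs(retained(records), out, FIXTURE_POLICY)
    assert not dropped
    return instruments
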