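import pytest

from nblib import diversity_design as dd
from nblib import repertoire_analysis as ra
from nblib import synthetic_data as syn


@pytest.fixture(scope="session")
def template():
    return syn.example_template()


@pytest.fixture(scope="session")
def scaffold():
    return syn.example_scaffold()


@pytest.fixture(scope="session")
def germline_ref():
    from nblib.scaffold_design import GermlineReference

    return GermlineReference("germline_vh3", syn.example_germline())


@pytest.fixture(scope="session")
def small_repertoire(scaffold):
    model = syn.RepertoireModel(
        scaffold=scaffold, n_sequences=120, seed=11, cdr_entropy=0.3
    )
    return syn.gen_repertoire(model)


@pytest.fixture(scope="session")
def profile(small_repertoire):
    return ra.positional_profile(small_repertoire)


@pytest.fixture(scope="session")
def diversity_spec(profile):
    return dd.build_diversity_spec(profile)


@pytest.fixture(scope="session")
def codon_plan(diversity_spec):
    return dd.choose_codons(diversity_spec)
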