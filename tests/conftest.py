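import logging

import pytest

import mitotbl as m


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.getLogger("mitotbl").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def code2():
    return m.load_code(2)


@pytest.fixture(scope="session")
def code5():
    return m.load_code(5)


@pytest.fixture(scope="session")
def full_fixture():
    """Canonical 37-gene complement plus control region, invertebrate code."""
    spec = m.SyntheticGenomeSpec(seed=11, gene_plan=m.full_gene_plan(), code_id=5)
    return m.generate_fixture(spec)


@pytest.fixture(scope="session")
def truncated_fixture():
    """Mixed truncated-stop and non-canonical-start plan, vertebrate code."""
    spec = m.SyntheticGenomeSpec(
        seed=3,
        gene_plan=m.full_gene_plan(
            stop_styles={"cox1": "T", "nad3": "TA", "nad5": "T"},
            start_styles={"nad2": "non_canonical"},
        ),
        code_id=2,
    )
    return m.generate_fixture(spec)


def convert(fixture, code_id):
    asm = m.parse_assembly(fixture.assembly_fasta)
    fwd = m.parse_forward_genes(fixture.forward_genes)
    return m.build_features(asm, fwd, m.load_code(code_id))
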