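import pytest

from pathcdm.config import PipelineConfig
from pathcdm.synth import GeneratorParams, generate_corpus
from pathcdm.vocab import load_dictionary


@pytest.fixture(scope="session")
def dictionary():
    return load_dictionary()


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_corpus():
    """A 5-patient corpus (15 reports) with gold annotations."""
    return generate_corpus(GeneratorParams(n_patients=5, seed=101))


def make_surgical_text(sub_id="S 110023456", site="colon", diagnosis="Tubular adenoma, NOS"):
    return (
        "SURGICAL PATHOLOGY REPORT\n"
        f"Pathology No: {sub_id}\n\n"
        f"SAMPLE NAME: {site}\n"
        f"DIAGNOSIS: {diagnosis}\n\n"
        "EXAMINER: staff pathologist\n"
    )


def make_ihc_text(rows=("EGFR (GI) | 1+/3",), sub_id="S 120034567"):
    body = "\n".join(rows)
    return (
        "IMMUNOCHEMISTRY TEST REPORT\n"
        f"Pathology No: {sub_id}\n\n"
        "----------\n"
        f"{body}\n"
        "----------\n"
        "SUMMARY: see stains. EXAMINER: staff pathologist\n"
    )


def make_molecular_text(test="NRAS mutation", rows=("Codon 12 (exon 2) | Positive",),
                        sub_id="S 130045678"):
    body = "\n".join(rows)
    return (
        "MOLECULAR STUDY REPORT\n"
        f"Pathology No: {sub_id}\n\n"
        f"{test}\n"
        "----------\n"
        f"{body}\n"
        "----------\n"
        "SUMMARY: see tests. EXAMINER: staff pathologist\n"
    )
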