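import pytest

from medsafecode import build_paper_fixture_kb, save_kb
from medsafecode.genotype_io import GenotypeProfile


@pytest.fixture(scope="session")
def paper_kb():
    return build_paper_fixture_kb()


@pytest.fixture
def paper_kb_file(paper_kb, tmp_path):
    return save_kb(paper_kb, tmp_path / "kb.json")


@pytest.fixture
def rule9_calls():
    """Worked-example genotype: *1/*3 compound heterozygote, rs9923231 T/T."""
    return {
        "rs1057910": ("A", "C"),
        "rs1057911": ("A", "A"),
        "rs1799853": ("C", "C"),
        "rs2256871": ("A", "A"),
        "rs9923231": ("T", "T"),
    }


@pytest.fixture
def rule9_profile(rule9_calls):
    return GenotypeProfile(calls=dict(rule9_calls), source_format="manual")
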