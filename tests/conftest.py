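import numpy as np
import pytest

from evescan.formats_io import SequenceRecord, load_taxdump
from evescan.simulate import write_mock_taxdump


@pytest.fixture(scope="session")
def taxdb(tmp_path_factory):
    """The ~30-node mock taxonomy loaded through the dmp parser."""
    outdir = tmp_path_factory.mktemp("taxdump")
    nodes, names = write_mock_taxdump(outdir)
    return load_taxdump(nodes, names)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_protein(rng, length):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture()
def dna_record(rng):
    return SequenceRecord("d1", "d1", random_dna(rng, 300), "dna")
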