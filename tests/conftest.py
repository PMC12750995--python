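import pytest
from rdkit import RDLogger

from pmk import chemistry, synthdata

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def libs():
    return synthdata.fragment_libraries()


@pytest.fixture(scope="session")
def peg3_protac(libs):
    """A CRBN / PEG3 / cresol PROTAC with its assembly ground truth."""
    record, truth = synthdata.assemble_protac(
        libs["e3_ligands"]["crbn_pomalidomide_n"],
        libs["linkers"]["linker_peg3"],
        libs["poi_ligands"]["poi_cresol"],
        record_id="peg3",
        e3_class="CRBN",
    )
    return record, truth


@pytest.fixture(scope="session")
def peg3_decomposition(peg3_protac):
    record, _ = peg3_protac
    return chemistry.decompose(record.smiles)
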