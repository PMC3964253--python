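import numpy as np
import pytest

from fibrosnp import Cohort, PatientRecord, SnpDef, datasets
from fibrosnp.simulate import SimConfig, npc_sim_panel


@pytest.fixture(scope="session")
def npc_panel():
    return datasets.npc_panel()


@pytest.fixture(scope="session")
def npc_tables():
    return datasets.npc_allele_tables()


@pytest.fixture(scope="session")
def npc_results(npc_panel, npc_tables):
    from fibrosnp import associate_tables

    return associate_tables(npc_panel, npc_tables)


@pytest.fixture
def toy_panel():
    return (
        SnpDef(gene="G1", rs_id="rs1", allele1="A", allele2="G"),
        SnpDef(gene="G2", rs_id="rs2", allele1="C", allele2="T"),
    )


@pytest.fixture
def toy_cohort(toy_panel):
    patients = tuple(
        PatientRecord(patient_id=f"P{i}", fibrosis_grade=g)
        for i, g in enumerate([0, 2, 3, 4, 1, 3])
    )
    dosage = np.array(
        [
            [0, 1],
            [1, 0],
            [2, 2],
            [1, np.nan],
            [0, 0],
            [2, 1],
        ],
        dtype=float,
    )
    return Cohort(panel=toy_panel, patients=patients, dosage=dosage)


@pytest.fixture(scope="session")
def effect_sim_config():
    """Reference-panel simulation carrying the six published effects."""
    return SimConfig(panel=npc_sim_panel(effects=True), seed=11)


@pytest.fixture(scope="session")
def null_sim_config():
    return SimConfig(panel=npc_sim_panel(effects=False), seed=11)
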