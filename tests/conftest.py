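import numpy as np
import pytest

from gik.genotypes import AccessionRecord, GenotypeTable
from gik.simulate import (
    CloneSpec,
    NameErrorSpec,
    PedigreeSpec,
    SimulationConfig,
    assemble_collection,
)


def make_table(rows: dict[str, list], markers: list[str], **acc_kwargs) -> GenotypeTable:
    """Tiny genotype table from {accession_id: [call, ...]}; acc_kwargs may
    hold per-accession dicts keyed by field name."""
    accs, calls = [], []
    for acc_id, row in rows.items():
        kw = {k: v.get(acc_id) for k, v in acc_kwargs.items() if v.get(acc_id) is not None}
        accs.append(AccessionRecord(acc_id, name=kw.pop("name", acc_id), **kw))
        calls.append([None if c is None else tuple(sorted(c)) for c in row])
    return GenotypeTable(markers, accs, calls)


@pytest.fixture(scope="session")
def clean_collection():
    """Species-only collection: no clones, pedigree, missingness or planted
    name errors — a clean substrate for statistics tests."""
    cfg = SimulationConfig(
        seed=11,
        n_markers=60,
        missing_rate=0.0,
        name_errors=NameErrorSpec(0, 0, 0),
    )
    return assemble_collection(cfg)


@pytest.fixture(scope="session")
def full_collection():
    """Everything on: pedigree, clones with somatic mutation, missing data,
    planted name errors. Truth log drives the assertions."""
    cfg = SimulationConfig(
        seed=23,
        n_markers=80,
        missing_rate=0.05,
        pedigree_spec=[PedigreeSpec("species_A_000", "species_A_001", 3)],
        clone_spec=[CloneSpec("species_B_000", 20, 0.05)],
        name_errors=NameErrorSpec(5, 5, 3),
    )
    return assemble_collection(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
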