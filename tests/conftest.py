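import numpy as np
import pytest

from orthoforest.io import Dataset, ProteinRecord


def make_record(
    accession: str,
    species: str = "ARA",
    sequence: str = "ACDEFGHIKL",
    **kwargs,
) -> ProteinRecord:
    return ProteinRecord(
        accession=accession, species=species, sequence=sequence, **kwargs
    )


@pytest.fixture
def small_dataset() -> Dataset:
    """Five records, two carrying GO:0016730, one carrying PF01593."""
    return Dataset(
        [
            make_record("P1", go_terms={"GO:0016730"}, name="NADPH Oxidoreductase 2"),
            make_record("P2", go_terms={"GO:0016730", "GO:0046872"}),
            make_record("P3", pfam_terms={"PF01593"}),
            make_record("P4", keywords={"Chloroplast"}),
            make_record("P5"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
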