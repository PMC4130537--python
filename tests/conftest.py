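import numpy as np
import pytest

from abmut.regions import DEFAULT_VH_REGION_MAP, AnnotatedSequence
from abmut.stats import StratifiedTable, Stratum2x2
from abmut.synthetic import GeometrySpec, generate_germline, generate_toy_complex


@pytest.fixture(scope="session")
def region_map():
    return DEFAULT_VH_REGION_MAP


@pytest.fixture(scope="session")
def germline(region_map) -> AnnotatedSequence:
    return generate_germline(seed=1, n_codons=98, region_map=region_map)


@pytest.fixture(scope="session")
def vh_strata() -> StratifiedTable:
    """The four-antibody VH panel: (CDR R, CDR S, FR R, FR S) per clone."""
    return StratifiedTable(
        [
            Stratum2x2("BR55-2", 4, 1, 2, 1),
            Stratum2x2("B3", 6, 1, 3, 3),
            Stratum2x2("BR96", 4, 0, 3, 1),
            Stratum2x2("mu3S193", 5, 0, 2, 1),
        ]
    )


@pytest.fixture()
def toy_complex():
    return generate_toy_complex(
        seed=42, n_receptor_atoms=50, n_ligand_atoms=50,
        geometry_spec=GeometrySpec(box_size=18.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
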