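import numpy as np
import pytest

from gutneutral.otu_io import OtuTable


@pytest.fixture
def toy_table() -> OtuTable:
    """3 samples x 4 OTUs with known hand-tallied counts."""
    counts = np.array(
        [
            [0, 2, 5, 9],
            [1, 3, 0, 7],
            [4, 0, 6, 2],
        ]
    )
    return OtuTable(
        sample_ids=["S1", "S2", "S3"],
        otu_ids=["OTU_1", "OTU_2", "OTU_3", "OTU_4"],
        counts=counts,
        taxonomy={
            "OTU_1": "Bacteria;Proteobacteria;Gammaproteobacteria",
            "OTU_2": "Bacteria;Firmicutes;Bacilli",
            "OTU_3": "Bacteria;Proteobacteria;Alphaproteobacteria",
            "OTU_4": "Bacteria;Bacteroidota;Bacteroidia",
        },
    )


@pytest.fixture
def random_table() -> OtuTable:
    """Seeded 10 x 20 random integer table with two groups."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(10, 20))
    counts[:, 0] += 1  # guarantee non-zero rows
    sample_ids = [f"S{i}" for i in range(10)]
    return OtuTable(
        sample_ids=sample_ids,
        otu_ids=[f"OTU_{j}" for j in range(20)],
        counts=counts,
        group={s: ("A" if i < 5 else "B") for i, s in enumerate(sample_ids)},
    )
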