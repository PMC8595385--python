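import numpy as np
import pytest

import rarebands as rb


@pytest.fixture
def tiny_table() -> rb.FeatureTable:
    """3 features x 2 samples with taxonomy, library sizes 100 and 250."""
    counts = np.array([[60, 100], [30, 100], [10, 50]], dtype=np.int64)
    taxonomy = {
        "ASV1": "Bacteria;Proteobacteria;Gammaproteobacteria",
        "ASV2": "Bacteria;Cyanobacteria;Chloroplast",
        "ASV3": "Bacteria;Alphaproteobacteria;Rickettsiales;Mitochondria",
    }
    return rb.FeatureTable(("ASV1", "ASV2", "ASV3"), ("S_A", "S_B"), counts, taxonomy)


@pytest.fixture(scope="session")
def paperlike():
    """The six-sample synthetic preset at a fixed seed, with its truth."""
    return rb.generate_paperlike(seed=7)


@pytest.fixture(scope="session")
def paperlike_table(paperlike) -> rb.FeatureTable:
    return paperlike[0]
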