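import numpy as np
import pandas as pd
import pytest

from gocrispr.screen_io import (
    CountMatrix,
    LibraryReference,
    ScreenDesign,
)
from gocrispr.simulator import SimulationParams, simulate_screen


@pytest.fixture
def tiny_library() -> LibraryReference:
    """3 genes x 2 guides with distinct 20-mers."""
    records = []
    spacers = [
        "ACGTACGTACGTACGTACGT", "TTTTAAAACCCCGGGGACGT",
        "GGGGCCCCAAAATTTTACGT", "ATATATATATATATATACGT",
        "CGCGCGCGCGCGCGCGACGT", "GAGAGAGAGAGAGAGAACGT",
    ]
    k = 0
    for g in ("GENE1", "GENE2", "GENE3"):
        for i in (1, 2):
            records.append((f"{g.lower()}_s{i}", g, spacers[k]))
            k += 1
    return LibraryReference(tuple(records))


@pytest.fixture
def design() -> ScreenDesign:
    return ScreenDesign.default(n_replicates=3)


@pytest.fixture
def tiny_counts(tiny_library, design) -> CountMatrix:
    """Deterministic small counts over the 13-sample default design."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(5, 200, size=(len(tiny_library), len(design.samples))),
        index=tiny_library.sgrna_ids,
        columns=design.sample_ids,
    )
    return CountMatrix(counts, tiny_library, design)


@pytest.fixture(scope="session")
def small_screen():
    """A modest simulated screen shared across tests (fixed seed)."""
    params = SimulationParams(n_genes=200, n_ntc=20, seed=7)
    return simulate_screen(params)
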