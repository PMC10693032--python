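import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from placomp import CellComposition, generate_cohort, generate_reference_panel, mix_bulk


@pytest.fixture(scope="session")
def six_type_panel():
    """Standard synthetic panel: 6 cell types, 100 markers each."""
    return generate_reference_panel(K=6, markers_per_type=100, contrast=0.6, seed=7)


@pytest.fixture(scope="session")
def noiseless_study(six_type_panel):
    """Small noise-free study: cohort, truth composition and exact bulk."""
    cohort, truth = generate_cohort(n=60, seed=11, composition_noise_sd=0.2, noise_sd=0.0)
    bulk = mix_bulk(six_type_panel, truth, sample_ids=list(cohort["sample_id"]))
    comp = CellComposition(
        sample_ids=list(cohort["sample_id"]),
        cell_types=truth.cell_types,
        values=truth.compositions,
    )
    return cohort, truth, bulk, comp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
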