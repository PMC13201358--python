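import numpy as np
import pandas as pd
import pytest

from prsport.data import GenotypePanel
from prsport.synthio import PopulationSpec, simulate_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """60-variant, 2000-sample panel with moderate blockwise LD."""
    rng = np.random.default_rng(11)
    spec = PopulationSpec("A", 2000, [3] * 20, rng.uniform(0.1, 0.9, 60), 0.8)
    return simulate_genotypes(spec, 101)


@pytest.fixture()
def toy_panel():
    """Tiny deterministic panel for hand-checkable scoring."""
    dosages = np.array([[0.0, 2.0, 1.0],
                        [1.0, 1.0, 0.0],
                        [2.0, 0.0, 2.0],
                        [1.0, 2.0, 1.0]])
    variants = pd.DataFrame({
        "chrom": "1", "pos": [100, 200, 300],
        "id": ["v1", "v2", "v3"], "a1": "A", "a2": "G"})
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(4)]})
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)
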