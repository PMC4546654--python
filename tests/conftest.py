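import numpy as np
import pandas as pd
import pytest

from metabscape.ingest import PeakTable
from metabscape.simulate import SyntheticDesign, generate_tissue_cohort


def make_table(values, genotype, diet, tissue="striatum", metabolites=None):
    """Build a small single-tissue PeakTable from raw arrays."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    metabolites = metabolites or [f"met_{j}" for j in range(p)]
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "tissue": [tissue] * n,
            "genotype": list(genotype),
            "diet": list(diet),
        }
    )
    frame = pd.DataFrame(
        values, index=pd.Index(samples["sample_id"], name="sample_id"),
        columns=metabolites,
    )
    return PeakTable(samples, frame)


@pytest.fixture(scope="session")
def null_cohort():
    """30 virtual mice x 6 tissues, 120 metabolites, no planted effects."""
    design = SyntheticDesign(
        n_metabolites=120, detect_prob=1.0, log_sd=0.4, seed=101
    )
    return generate_tissue_cohort(design)


@pytest.fixture(scope="session")
def balanced_2x2():
    """8 samples per arm of the 2x2 design (labels only)."""
    genotype = ["mutant"] * 16 + ["wildtype"] * 16
    diet = (["fat45"] * 8 + ["fat60"] * 8) * 2
    return np.array(genotype), np.array(diet)
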