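import numpy as np
import pytest

from n15quant.peptide_db import build_databases
from n15quant.pipeline import run_pipeline
from n15quant.synthetic import SimConfig, random_proteome, simulate_run


class Study:
    """A simulated run, its ground truth, databases and pipeline result."""

    def __init__(self, seed: int, **overrides):
        self.config = SimConfig(seed=seed, **overrides)
        self.run, self.peptide_truth, self.species_truth = simulate_run(self.config)
        self.proteome = self.config.proteome or random_proteome(
            self.config, np.random.default_rng(seed)
        )
        self.db_unlabeled, self.db_labeled = build_databases(self.proteome)
        self.result = run_pipeline(self.run, self.db_unlabeled, self.db_labeled)


@pytest.fixture(scope="session")
def study() -> Study:
    """The canonical 300-peptide study: 50 proteins x 6 peptides, 0.98
    enrichment, 1 ppm mass error."""
    return Study(seed=7)


@pytest.fixture(scope="session")
def small_study() -> Study:
    """A 20-peptide study for faster unit-level checks."""
    return Study(seed=11, n_proteins=5, peptides_per_protein=4, gradient_min=6.0)
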