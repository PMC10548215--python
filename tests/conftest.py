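import numpy as np
import pandas as pd
import pytest

import ricehsi as rh
from ricehsi import groundtruth as gt


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment shared by read-only tests."""
    cfg = rh.SyntheticConfig()
    scans, traits, design = rh.generate_experiment(cfg, seed=0)
    return cfg, scans, traits, design


@pytest.fixture(scope="session")
def weekly_spectra(default_experiment):
    _, scans, _, _ = default_experiment
    return rh.weekly_average(rh.scans_to_spectraset(scans))


@pytest.fixture(scope="session")
def full_traits(default_experiment):
    """Trait table with derived and transformed columns plus subpopulation."""
    _, _, traits, design = default_experiment
    tt = gt.transform_traits(gt.add_derived_traits(traits))
    return tt.merge(design[["plant_id", "subpopulation"]], on="plant_id",
                    suffixes=("", "_design"))


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced design for fast orchestration tests."""
    cfg = rh.SyntheticConfig(n_accessions_ind=4, n_accessions_trj=2,
                             triple_rep_accession=None, weeks=(6, 9),
                             scans_per_week=2, n_missing_traits=2)
    scans, traits, design = rh.generate_experiment(cfg, seed=1)
    return cfg, scans, traits, design
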