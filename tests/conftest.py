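import numpy as np
import pytest
from hypothesis import settings

from hlabquant import calibration, cohort

# reproducible property tests
settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def identity_curve():
    """Noise-free identity standard curve spanning 10..1e7 MFI."""
    beads = cohort.simulate_bead_standards(1.0, 0.0, [1e1, 1e3, 1e5, 1e7])
    return calibration.fit_standard_curve(beads, mode="log-log")


def make_cohort_design(**kwargs):
    """Two-allele cohort with every required (allele, subset) mean filled."""
    alleles = kwargs.pop("alleles", {"B*08:01": "Bw6", "B*07:02": "Bw6"})
    subsets = kwargs.pop("cell_subsets", cohort.DEFAULT_SUBSETS)
    base = kwargs.pop("base_abc",
                      {"B*08:01": 40_000.0, "B*07:02": 25_000.0})
    mean_abc = {(a, s): base.get(a, 30_000.0)
                for a in alleles for s in subsets}
    return cohort.CohortDesign(alleles=alleles, cell_subsets=subsets,
                               mean_abc=mean_abc, **kwargs)


@pytest.fixture
def zero_noise_cohort():
    design = make_cohort_design(donor_cv=0.0, replicate_cv=0.0,
                                n_donors_per_allele=3, n_draws=2,
                                n_homozygous_per_allele=1, seed=7)
    stains, genotypes, truth = cohort.simulate_cohort(design)
    return design, stains, genotypes, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
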