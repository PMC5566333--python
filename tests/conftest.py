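import pytest

from swathbench import build_design, make_site_profiles, score_and_filter, simulate_study


@pytest.fixture(scope="session")
def design3():
    """Three-site default dilution design."""
    return build_design(n_sites=3)


@pytest.fixture(scope="session")
def small_study(design3):
    """A small but complete synthetic study (3 sites x 21 runs, 120 proteins)."""
    profiles = make_site_profiles(design3, seed=11)
    return simulate_study(
        design3, profiles, seed=11, n_proteins=120, mean_peptides=5.0, absent_fraction=0.4
    )


@pytest.fixture(scope="session")
def scored_study(small_study):
    """The small study scored and consecutively filtered at 1% FDR."""
    scored, qtables, detection = score_and_filter(small_study.peakgroups, seed=11)
    return small_study, scored, qtables, detection
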