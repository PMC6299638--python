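import pytest

from sf6dbayes import cohort, gibbs


@pytest.fixture(scope="session")
def replica_raw():
    """Full-scale synthetic survey with the UK study's structure (bounded
    values, exclusion categories, 148 missing)."""
    return cohort.generate_survey(cohort.CohortConfig(seed=3))


@pytest.fixture(scope="session")
def replica_analysed(replica_raw):
    return cohort.apply_exclusions(replica_raw)


@pytest.fixture(scope="session")
def untruncated_analysed():
    """Replica-scale survey drawn exactly from the model class (no
    truncation), for calibration checks against the generator truth."""
    ds = cohort.generate_survey(cohort.CohortConfig(seed=5, truncate=False))
    return cohort.apply_exclusions(ds)


@pytest.fixture(scope="session")
def small_config():
    """Short but well-mixing chain schedule for full-scale designs."""
    return gibbs.SamplerConfig(n_burn=200, n_keep=600, n_chains=2, seed=11)


@pytest.fixture(scope="session")
def m4_draws_replica(replica_analysed, small_config):
    return gibbs.fit(replica_analysed, "M4", small_config)


@pytest.fixture(scope="session")
def m4_draws_untruncated(untruncated_analysed, small_config):
    return gibbs.fit(untruncated_analysed, "M4", small_config)
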