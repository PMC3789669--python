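import pytest

from cnvassoc.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort reused by read-only tests."""
    return simulate_cohort(
        SimConfig(
            n_cases=60,
            n_controls=90,
            n_chrom=2,
            markers_per_chrom=800,
            background_cnv_rate=2.0,
            n_genes=20,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size cohort under default (study) conditions, one seed."""
    return simulate_cohort(SimConfig(seed=7, qc_outlier_fraction=0.0))
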