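import numpy as np
import pytest

from strideloop import pipeline, synthio


@pytest.fixture(scope="session")
def noise_free_spec():
    return synthio.CohortSpec(
        n_individuals=3, strides_per_trial=10, sample_rate_hz=2000.0,
        noise_sd=0.0, individual_sd=0.0, force_individual_rel_sd=0.0,
        emg_onset_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_spec):
    return synthio.generate_cohort(noise_free_spec)


@pytest.fixture(scope="session")
def noise_free_run(noise_free_cohort):
    """Stride table + cycles of the noise-free cohort through the pipeline."""
    trials, gt = noise_free_cohort
    table, cycles = pipeline.build_stride_table(trials)
    merged = table.merge(gt.table, on=["bird_id", "trial_id", "stride_index"],
                         suffixes=("", "_gt"))
    assert len(merged) == len(gt.table)
    return merged, cycles, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
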