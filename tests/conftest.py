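import numpy as np
import pytest

import nkstrat as nk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phenotypes():
    return nk.build_default_phenotypes()


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-size default cohort: full study structure (30 patients x 2
    timepoints + 1 healthy donor, 2 degenerate samples), fewer events."""
    config = nk.CohortConfig(events_per_sample=400, seed=7)
    return nk.simulate_cohort(config)


@pytest.fixture(scope="session")
def pipeline_result(small_cohort):
    """Full pipeline run on the reduced cohort (shared across tests)."""
    params = nk.PipelineParams(
        mixture=nk.MixtureOptions(seed=7, n_init=2, max_iter=80)
    )
    return nk.analyze_cohort(
        small_cohort.samples,
        small_cohort.metadata,
        gate_thresholds=small_cohort.gate_thresholds,
        params=params,
    )


@pytest.fixture(scope="session")
def truth_grouping(small_cohort):
    """Planted patient -> group map (grouped patients only)."""
    truth = small_cohort.truth_frequencies
    t0 = truth[truth["timepoint"] == "T0"]
    return {
        p: g
        for p, g in zip(t0["patient_id"], t0["group_label"])
        if g in ("X", "Y", "Z")
    }
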