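import numpy as np
import pytest

from eibalance.io import RoiTimeSeries
from eibalance.pipeline import PipelineConfig, run_simulate
from eibalance.synthetic import (CohortSpec, GroupSpec, HEALTHY_PRESET,
                                 AD_PRESET, default_cohort_spec, gen_cohort)
from dataclasses import replace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """A 150-s three-ROI series of plain Gaussian noise at 1250 Hz."""
    data = rng.standard_normal((int(150 * 1250), 3))
    return RoiTimeSeries(data=data, fs=1250.0,
                         roi_labels=("ROI_1", "ROI_2", "ROI_3"),
                         subject_id="sub-01", group="HE_like")


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    """2 vs 2 subjects, 2 ROIs, short but long enough for 10 epochs."""
    he = replace(HEALTHY_PRESET, duration_s=140.0)
    ad = replace(AD_PRESET, duration_s=140.0)
    return CohortSpec(
        groups=(GroupSpec("HE_like", 2, he, {"envelope_hurst": 0.03}),
                GroupSpec("AD_like", 2, ad, {"envelope_hurst": 0.03})),
        rois=("ROI_1", "ROI_2"),
        master_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_spec):
    return gen_cohort(tiny_cohort_spec)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory, tiny_cohort_spec):
    out = tmp_path_factory.mktemp("cohort")
    cfg = PipelineConfig(master_seed=7, n_per_group=2)
    run_simulate(cfg, out, cohort_spec=tiny_cohort_spec)
    return out
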