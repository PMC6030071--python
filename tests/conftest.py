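import numpy as np
import pytest

from qppdyn.core import BoldSeries, SliceGeometry
from qppdyn.pipeline import PipelineConfig, run_pipeline
from qppdyn.simulate import make_atlas


@pytest.fixture(scope="session")
def atlas_geom():
    """Default synthetic atlas and geometry (48 x 32 slice, 12 ROIs)."""
    return make_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_series(rng):
    """A tiny fully-masked series: 3 x 4 slice, 40 frames."""
    geom = SliceGeometry.from_mask(np.ones((3, 4), bool))
    data = rng.standard_normal((12, 40))
    return BoldSeries(data=data, geometry=geom, tr_seconds=0.5, subject_id="s1")


@pytest.fixture(scope="session")
def fast_cohort_result():
    """One full fast-profile pipeline run shared across the heavier tests.

    8 WT + 10 TG subjects, 10-minute scans at TR 0.5 s, 50 detection
    restarts per pattern, full regression / FC / classification.
    """
    cfg = PipelineConfig.fast()
    return run_pipeline(cfg, seed=7)
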