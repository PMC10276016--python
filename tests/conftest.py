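import numpy as np
import pandas as pd
import pytest

from foveamorph import ScanGeometry, build_boundaries, control_spec, ept_spec, sample_cohort_metrics
from foveamorph.simulate import EyeGeometry


@pytest.fixture(scope="session")
def scan() -> ScanGeometry:
    return ScanGeometry()


@pytest.fixture(scope="session")
def small_scan() -> ScanGeometry:
    """Quarter-size raster for cheap image tests."""
    return ScanGeometry(n_ascans=256, n_axial=512, lateral_scale=6000.0 / 256, axial_scale=2000.0 / 512)


@pytest.fixture
def control_targets() -> pd.Series:
    """One eye at exactly the control calibration means."""
    return pd.Series(
        {
            "eye_id": "ctl-mean",
            "laterality": "OS",
            "GCLp_FC": 3.47,
            "GCLp_Q2Q": 10.23,
            "ONL_FC": 107.78,
            "RT_FC": 208.36,
            "FD": 131.15,
            "RT_FWM_nasal": 339.51,
            "RT_FWM_temporal": 339.51,
        }
    )


@pytest.fixture
def ept_targets() -> pd.Series:
    """One eye at exactly the EPT-NoROP calibration means."""
    return pd.Series(
        {
            "eye_id": "ept-mean",
            "laterality": "OD",
            "GCLp_FC": 13.95,
            "GCLp_Q2Q": 27.19,
            "ONL_FC": 150.52,
            "RT_FC": 247.09,
            "FD": 89.46,
            "RT_FWM_nasal": 338.55,
            "RT_FWM_temporal": 334.55,
        }
    )


@pytest.fixture
def control_bset(control_targets, scan):
    return build_boundaries(control_targets, EyeGeometry(), scan)


@pytest.fixture(scope="session")
def mixed_cohort() -> pd.DataFrame:
    """Fifty eyes from each group at the default calibration."""
    ctl = sample_cohort_metrics(control_spec(50, seed=11001))
    ept = sample_cohort_metrics(ept_spec(50, seed=11002))
    return pd.concat([ctl, ept], ignore_index=True)
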