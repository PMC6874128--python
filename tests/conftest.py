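import numpy as np
import pandas as pd
import pytest

from hnqi.grid import VolumeGrid
from hnqi.phantom import (
    AIFParams,
    Blob,
    PhantomSpec,
    TumorSpec,
    render_phantom,
    simulate_aif,
)


@pytest.fixture(scope="session")
def dce_times():
    return np.arange(60) * 6.0


@pytest.fixture(scope="session")
def aif_curve(dce_times):
    return simulate_aif(AIFParams(), dce_times)


def make_tumor(**kw):
    base = dict(
        kind="primary",
        center=(36.0, 36.0, 48.0),
        radius_pre=14.0,
        radius_mid=13.0,
        necrotic_core_radius=4.0,
        lowbv_blob=Blob((36.0, 42.5, 48.0), 6.0),
        lowadc_blob=Blob((36.0, 29.5, 48.0), 5.0),
    )
    base.update(kw)
    return TumorSpec(**base)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(
        grid_shape=(48, 48, 32),
        tumors=[make_tumor()],
        noise_sd_dwi=0.0,
        noise_sd_dce=0.0,
        noise_sd_suv=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_case(noiseless_spec):
    return render_phantom(noiseless_spec)


@pytest.fixture
def uniform_grid():
    def _make(value, shape=(8, 8, 4), voxel=(1.0, 1.0, 1.0), units=""):
        return VolumeGrid(np.full(shape, float(value)), voxel, units)

    return _make


@pytest.fixture
def outcome_frame():
    """Hand-constructed tumor outcomes covering every censoring branch."""
    rows = [
        # P1: tumor never progressed, DF at 6, follow-up 24 -> censored at 6
        dict(patient_id="P1", tumor_id="P1_T0", kind="primary",
             prog_time=np.nan, df_time=6.0, death_time=np.nan, last_followup=24.0),
        # P2: LF at 10, DF at 14 -> event at 10
        dict(patient_id="P2", tumor_id="P2_T0", kind="primary",
             prog_time=10.0, df_time=14.0, death_time=np.nan, last_followup=30.0),
        # P3: no events, follow-up 24 -> censored at 24
        dict(patient_id="P3", tumor_id="P3_T0", kind="primary",
             prog_time=np.nan, df_time=np.nan, death_time=np.nan, last_followup=24.0),
        # P4: nodal RF at 8, then DF at 12 (for the DFFS censor-at-LRF rule)
        dict(patient_id="P4", tumor_id="P4_T0", kind="nodal",
             prog_time=8.0, df_time=12.0, death_time=np.nan, last_followup=36.0),
        # P5: LF at 20 months (landmark exclusion: progression after cutoff)
        dict(patient_id="P5", tumor_id="P5_T0", kind="primary",
             prog_time=20.0, df_time=np.nan, death_time=np.nan, last_followup=28.0),
        # P6: no progression, follow-up 15 (landmark exclusion: short follow-up)
        dict(patient_id="P6", tumor_id="P6_T0", kind="primary",
             prog_time=np.nan, df_time=np.nan, death_time=np.nan, last_followup=15.0),
        # P7: death at 9, tumor never progressed -> censored at 9
        dict(patient_id="P7", tumor_id="P7_T0", kind="nodal",
             prog_time=np.nan, df_time=np.nan, death_time=9.0, last_followup=9.0),
    ]
    return pd.DataFrame(rows)
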