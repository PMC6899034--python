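import numpy as np
import pandas as pd
import pytest

from larvascreen import CampaignConfig, build_campaign, simulate_measurements

DEMO_MIXTURE = {
    "inactive": 0.90,
    "suppressor": 0.06,
    "enhancer_toxic": 0.02,
    "bzb_inactivator": 0.01,
    "species_restricted": 0.01,
}


@pytest.fixture
def worm_config():
    return CampaignConfig(
        seed=7, n_compounds=320, class_mixture=dict(DEMO_MIXTURE),
        plate_format="worm384",
    )


@pytest.fixture
def small_campaign(worm_config):
    """One worm plate in triplicate with simulated measurements."""
    truth, layout = build_campaign(worm_config)
    rng = np.random.default_rng(11)
    measurements = simulate_measurements(layout, truth, rng)
    return truth, layout, measurements


def make_plate_tables(neg, pos, test, plate_id="PX-R1"):
    """Hand-built single-plate layout + measurement tables.

    ``neg``/``pos``/``test`` are lists of areas; test wells get compound
    ids T001, T002, ...
    """
    rows = []
    meas = []
    for i, v in enumerate(pos):
        rows.append((plate_id, f"A{i+1:02d}", 0, i, "positive", None, 0.0, "uM", 1))
        meas.append((plate_id, f"A{i+1:02d}", v))
    for i, v in enumerate(neg):
        rows.append((plate_id, f"B{i+1:02d}", 1, i, "negative", None, 0.0, "uM", 1))
        meas.append((plate_id, f"B{i+1:02d}", v))
    for i, v in enumerate(test):
        rows.append(
            (plate_id, f"C{i+1:02d}", 2, i, "test", f"T{i+1:03d}", 25.0, "uM", 1)
        )
        meas.append((plate_id, f"C{i+1:02d}", v))
    layout = pd.DataFrame(
        rows,
        columns=["plate_id", "well", "row", "col", "role", "compound_id",
                 "dose", "dose_unit", "replicate"],
    )
    measurements = pd.DataFrame(meas, columns=["plate_id", "well", "total_area"])
    measurements["object_count"] = 15
    measurements["normalized_area"] = np.nan
    measurements["artifact"] = False
    measurements["artifact_reason"] = None
    return layout, measurements
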