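"""Simulation-based performance checks for the screening pipeline.

Each function runs the full relevant slice of the pipeline on synthetic
campaigns with known ground truth and returns summary statistics:

* null false-positive calibration of the 3-of-3 consensus rule,
* suppressor recall / inactive false-call rates at study noise levels,
* imaging round-trip accuracy against rendered ground truth,
* EC50 recovery error of the 4PL fitter,
* end-to-end detection of a planted all-paradigm + reporter active.

These are the package's own power/calibration experiments; they are
deliberately deterministic given a base seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .campaign import (
    build_campaign,
    simulate_dose_series,
    simulate_measurements,
    simulate_validation_outcomes,
)
from .cascade import CascadeRules, build_matrix, classify_all
from .config import CampaignConfig, CascadeConfig
from .doseresponse import fit_4pl, fold_sensitivity
from .hits import WORM_SUPPRESSOR, call_consensus
from .imaging import measure_well, segment_well
from .plate import score_campaign
from .render import render_well_image

RECOVERY_MIXTURE = {
    "inactive": 0.90,
    "suppressor": 0.10,
}


def _screen(ccfg: CampaignConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate + score + call one campaign; returns the consensus table
    joined with ground truth."""
    truth, layout = build_campaign(ccfg)
    meas = simulate_measurements(layout, truth, rng)
    zscores, _ = score_campaign(meas, layout)
    keyed = zscores.merge(
        layout[["plate_id", "well", "replicate"]], on=["plate_id", "well"]
    )
    tables = [
        keyed[keyed.replicate == r] for r in range(1, ccfg.n_replicates + 1)
    ]
    calls = call_consensus(tables, WORM_SUPPRESSOR)
    return calls.merge(truth.effects, on="compound_id")


def null_consensus_calibration(
    base_seed: int = 0,
    n_campaigns: int = 12,
    n_compounds: int = 20240,
) -> dict:
    """False-positive rate of the worm 3-of-3 Z >= 2 rule on all-inactive
    campaigns with Gaussian well noise, vs the analytic p^3 approximation.

    ``p`` is the per-replicate tail probability P(Z >= 2) estimated from
    the same simulated test wells (it exceeds the normal tail value
    because each plate's control moments are themselves estimates). The
    consensus rate is a small-count Poisson quantity, so campaigns are
    pooled until the comparison is meaningful.
    """
    n_hits = 0
    n_total = 0
    tail = []
    for k in range(n_campaigns):
        ccfg = CampaignConfig(
            seed=base_seed * 1000 + k, n_compounds=n_compounds,
            class_mixture={"inactive": 1.0}, noise_model="gaussian",
        )
        rng = np.random.default_rng((base_seed * 7919 + k) % 2**31)
        calls = _screen(ccfg, rng)
        n_hits += int((calls.call == "suppressor").sum())
        n_total += len(calls)
        z = calls[[f"z_{i}" for i in (1, 2, 3)]].to_numpy(float)
        tail.append(np.nanmean(z >= 2.0))
    p_hat = float(np.mean(tail))
    expected_fpr = p_hat**3
    observed_fpr = n_hits / n_total
    return {
        "observed_fpr": observed_fpr,
        "expected_fpr": expected_fpr,
        "ratio": observed_fpr / expected_fpr,
        "n_consensus_hits": n_hits,
        "n_compounds_total": n_total,
        "p_hat": p_hat,
    }


def suppressor_recovery(
    base_seed: int = 0,
    n_campaigns: int = 20,
    n_compounds: int = 640,
    strong_rescue: float = 0.8,
) -> dict:
    """Recall of strong suppressors (rescue fraction >= 0.8) and the
    false-call rate on inactive compounds at the study noise level."""
    strong_called = strong_total = 0
    inactive_called = inactive_total = 0
    for k in range(n_campaigns):
        ccfg = CampaignConfig(
            seed=base_seed * 1000 + 500 + k, n_compounds=n_compounds,
            class_mixture=dict(RECOVERY_MIXTURE),
        )
        rng = np.random.default_rng((base_seed * 104729 + k) % 2**31)
        calls = _screen(ccfg, rng)
        strong = calls[
            (calls.effect_class == "suppressor")
            & (calls.rescue_fraction >= strong_rescue)
        ]
        strong_called += int((strong.call == "suppressor").sum())
        strong_total += len(strong)
        inactive = calls[calls.effect_class == "inactive"]
        inactive_called += int((inactive.call == "suppressor").sum())
        inactive_total += len(inactive)
    return {
        "strong_recall": strong_called / strong_total,
        "inactive_false_call_rate": inactive_called / inactive_total,
        "n_strong": strong_total,
        "n_inactive": inactive_total,
    }


def imaging_roundtrip(
    base_seed: int = 0,
    n_wells: int = 12,
    target_px: int = 200,
    n_objects: int = 2,
    snr: float = 10.0,
) -> dict:
    """Area and count recovery of the segmentation path on rendered wells."""
    rel_errors = []
    counts_exact = 0
    for k in range(n_wells):
        rng = np.random.default_rng((base_seed * 613 + k) % 2**31)
        img, mask = render_well_image(
            target_px, n_objects, (96, 96), rng, snr=snr, no_overlap=True
        )
        m = measure_well(segment_well(img))
        rel_errors.append(abs(m.total_area - mask.sum()) / mask.sum())
        counts_exact += m.object_count == n_objects
    return {
        "max_rel_area_error": float(max(rel_errors)),
        "count_exact_fraction": counts_exact / n_wells,
    }


def ec50_recovery(
    base_seed: int = 0,
    n_sims: int = 200,
    truth: tuple[float, float, float, float] = (0.0, 100.0, 205.0, 1.0),
    noise_sigma: float = 0.1,
    n_reps: int = 4,
) -> dict:
    """Median relative EC50 error over repeated noisy 8-dose fits."""
    doses = np.geomspace(10.0, 2000.0, 8)
    rng = np.random.default_rng((base_seed * 2689 + 7) % 2**31)
    bottom, top, ec50_true, hill = truth
    errors = []
    for _ in range(n_sims):
        s = simulate_dose_series(truth, doses, n_reps, noise_sigma, rng)
        c = fit_4pl(s)
        errors.append(abs(c.ec50 - ec50_true) / ec50_true)
    return {
        "median_rel_ec50_error": float(np.median(errors)),
        "n_sims": n_sims,
    }


def fly_fold_sensitivity(
    base_seed: int = 0, noise_sigma: float = 0.1, n_pairs: int = 10
) -> float:
    """Recovered heterozygote-vs-wild-type EC50 fold shift (truth: 2x),
    as the median over repeated simulated experiment pairs."""
    doses = np.array([0.0, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0])
    rng = np.random.default_rng((base_seed * 433 + 11) % 2**31)
    ratios = []
    for _ in range(n_pairs):
        wt = simulate_dose_series((10, 100, 18.0, 2.0), doses, 4, noise_sigma,
                                  rng, genotype="wild_type", dose_unit="uM")
        het = simulate_dose_series((10, 100, 9.0, 2.0), doses, 4, noise_sigma,
                                   rng, genotype="heterozygote",
                                   dose_unit="uM")
        ratios.append(fold_sensitivity(fit_4pl(wt), fit_4pl(het)))
    return float(np.median(ratios))


def planted_active_detection(
    base_seed: int = 0,
    n_seeds: int = 20,
    n_compounds: int = 320,
) -> dict:
    """End-to-end uniqueness check: a campaign with exactly one compound
    active in all four invertebrate paradigms *and* the NRF2 reporter
    must yield exactly that compound as all-assay active."""
    exact = 0
    for k in range(n_seeds):
        ccfg = CampaignConfig(
            seed=base_seed * 1000 + 900 + k, n_compounds=n_compounds,
            class_mixture={"inactive": 0.92, "suppressor": 0.05,
                           "enhancer_toxic": 0.01, "bzb_inactivator": 0.01,
                           "species_restricted": 0.01},
            plant_all_assay_active=True,
        )
        rng = np.random.default_rng((base_seed * 15269 + k) % 2**31)
        truth, layout = build_campaign(ccfg)
        meas = simulate_measurements(layout, truth, rng)
        zscores, _ = score_campaign(meas, layout)
        keyed = zscores.merge(
            layout[["plate_id", "well", "replicate"]], on=["plate_id", "well"]
        )
        tables = [keyed[keyed.replicate == r] for r in (1, 2, 3)]
        calls = call_consensus(tables, WORM_SUPPRESSOR)
        suppressors = calls.loc[calls.call == "suppressor", "compound_id"]
        outcomes = simulate_validation_outcomes(
            truth, suppressors.tolist(), rng, CascadeConfig()
        )
        status = classify_all(build_matrix(outcomes), CascadeRules())
        active = set(status.loc[status.all_assay_active, "compound_id"])
        planted = truth.effects.compound_id.iloc[0]
        exact += active == {planted}
    return {"exact_detection_rate": exact / n_seeds, "n_seeds": n_seeds}
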