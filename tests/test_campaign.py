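"""Synthetic campaign generator: determinism, closed-form anchors, mixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from larvascreen import (
    CampaignConfig,
    CompoundEffect,
    build_campaign,
    simulate_dose_series,
    simulate_measurements,
    simulate_well,
)
from larvascreen.errors import ConfigError


class TestConfig:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            CampaignConfig(n_compounds=4, class_mixture={"inactive": 0.5})

    def test_nonpositive_library_rejected(self):
        with pytest.raises(ConfigError):
            CampaignConfig(n_compounds=0)

    def test_area_ordering_enforced(self):
        with pytest.raises(ConfigError):
            CampaignConfig(arrest_area_AU=100.0, full_area_AU=50.0)

    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception):
            CampaignConfig(n_compounds=4, not_a_key=1)


class TestEffects:
    def test_degenerate_mixture_all_inactive(self):
        cfg = CampaignConfig(seed=1, n_compounds=4, class_mixture={"inactive": 1.0})
        truth, _ = build_campaign(cfg)
        assert (truth.effects.effect_class == "inactive").all()
        assert (truth.effects.rescue_fraction == 0).all()

    def test_inactive_effect_invariant(self):
        with pytest.raises(ConfigError):
            CompoundEffect("X", "inactive", rescue_fraction=0.5)
        with pytest.raises(ConfigError):
            CompoundEffect("X", "suppressor", rescue_fraction=0.0)

    def test_class_counts_within_binomial_99ci(self):
        # 2560 draws at (0.97, 0.02, 0.01): counts must land inside the
        # exact binomial 0.5%/99.5% quantile band for each class
        cfg = CampaignConfig(
            seed=7, n_compounds=2560,
            class_mixture={"inactive": 0.97, "suppressor": 0.02,
                           "enhancer_toxic": 0.01},
        )
        truth, _ = build_campaign(cfg)
        counts = truth.effects.effect_class.value_counts()
        for cls, p in [("inactive", 0.97), ("suppressor", 0.02),
                       ("enhancer_toxic", 0.01)]:
            lo, hi = sps.binom.ppf([0.005, 0.995], 2560, p)
            assert lo <= counts.get(cls, 0) <= hi

    def test_class_fractions_converge_to_mixture(self):
        # law of large numbers at the lead-discovery library size
        mix = {"inactive": 0.94, "suppressor": 0.04, "enhancer_toxic": 0.02}
        cfg = CampaignConfig(seed=3, n_compounds=20240, class_mixture=mix)
        truth, _ = build_campaign(cfg)
        frac = truth.effects.effect_class.value_counts(normalize=True)
        for cls, p in mix.items():
            sd = np.sqrt(p * (1 - p) / 20240)
            assert abs(frac[cls] - p) <= 3 * sd


class TestCampaignStructure:
    def test_same_seed_bit_identical(self, worm_config):
        t1, l1 = build_campaign(worm_config)
        t2, l2 = build_campaign(worm_config)
        assert t1.effects.to_csv() == t2.effects.to_csv()
        assert l1.to_csv() == l2.to_csv()
        m1 = simulate_measurements(l1, t1, np.random.default_rng(5))
        m2 = simulate_measurements(l2, t2, np.random.default_rng(5))
        assert m1.to_csv() == m2.to_csv()

    def test_control_well_counts(self, worm_config):
        _, layout = build_campaign(worm_config)
        per_plate = layout.groupby("plate_id").role.value_counts().unstack()
        assert (per_plate["positive"] == 32).all()
        assert (per_plate["negative"] == 32).all()

    def test_well_ids_letter_number(self, worm_config):
        _, layout = build_campaign(worm_config)
        assert layout.well.str.fullmatch(r"[A-P]\d{2}").all()
        assert "A01" in set(layout.well) and "P24" in set(layout.well)

    def test_fly_plate_geometry(self):
        cfg = CampaignConfig(
            seed=2, n_compounds=80, plate_format="fly96",
            class_mixture={"inactive": 1.0},
        )
        _, layout = build_campaign(cfg)
        one = layout[layout.plate_id == layout.plate_id.iloc[0]]
        assert len(one) == 96
        assert (one.role == "positive").sum() == 8
        assert (one.role == "negative").sum() == 8
        assert one.well.str.fullmatch(r"[A-H]\d{2}").all()

    def test_replicates_share_layout(self, worm_config):
        _, layout = build_campaign(worm_config)
        by_rep = {
            rep: grp.set_index("well").compound_id
            for rep, grp in layout.groupby("replicate")
        }
        assert by_rep[1].equals(by_rep[2]) and by_rep[2].equals(by_rep[3])


class TestSimulateWell:
    def zero_noise_config(self, **kw):
        return CampaignConfig(
            seed=0, n_compounds=4, class_mixture={"inactive": 1.0},
            noise_sigma=0.0, **kw,
        )

    def test_negative_control_hits_arrest_area(self):
        cfg = self.zero_noise_config()
        area, count = simulate_well("negative", None, cfg, np.random.default_rng(0))
        assert area == cfg.arrest_area_AU
        assert count == cfg.animals_per_test_well

    def test_full_rescue_hits_full_area(self):
        cfg = self.zero_noise_config()
        eff = CompoundEffect("S", "suppressor", rescue_fraction=1.0)
        area, count = simulate_well("test", eff, cfg, np.random.default_rng(0))
        assert area == cfg.full_area_AU
        assert count == cfg.animals_per_test_well * 10  # progeny amplification

    def test_bzb_inactivator_silent_without_bortezomib(self):
        cfg = self.zero_noise_config()
        eff = CompoundEffect("B", "bzb_inactivator", rescue_fraction=1.0)
        area_czb, _ = simulate_well(
            "test", eff, cfg, np.random.default_rng(0), paradigm="worm_czb"
        )
        area_bzb, _ = simulate_well(
            "test", eff, cfg, np.random.default_rng(0), paradigm="worm_bzb"
        )
        assert area_czb == cfg.arrest_area_AU
        assert area_bzb == cfg.full_area_AU

    def test_species_restricted_silent_in_other_species(self):
        cfg = self.zero_noise_config()
        eff = CompoundEffect(
            "R", "species_restricted", rescue_fraction=1.0,
            active_species=frozenset({"fly"}),
        )
        area, _ = simulate_well(
            "test", eff, cfg, np.random.default_rng(0), paradigm="worm_bzb"
        )
        assert area == cfg.arrest_area_AU

    def test_toxicity_clamped_at_zero(self):
        cfg = self.zero_noise_config()
        eff = CompoundEffect("T", "enhancer_toxic", toxicity_fraction=1.0)
        area, _ = simulate_well("test", eff, cfg, np.random.default_rng(0))
        assert area == 0.0

    def test_zero_noise_vectorized_matches_closed_form(self):
        mix = {"inactive": 0.5, "suppressor": 0.3, "enhancer_toxic": 0.2}
        cfg = CampaignConfig(
            seed=9, n_compounds=100, class_mixture=mix, noise_sigma=0.0
        )
        truth, layout = build_campaign(cfg)
        meas = simulate_measurements(layout, truth, np.random.default_rng(1))
        merged = layout.merge(meas, on=["plate_id", "well"]).merge(
            truth.effects, on="compound_id", how="left"
        )
        span = cfg.full_area_AU - cfg.arrest_area_AU
        r = merged.rescue_fraction.fillna(0) - merged.toxicity_fraction.fillna(0)
        r = r.where(merged.role == "test", 0.0)
        r = r.mask(merged.role == "positive", 1.0)
        expected = np.maximum(0.0, cfg.arrest_area_AU + r * span)
        assert np.allclose(merged.total_area, expected)


class TestDoseSeries:
    def test_midpoint_identity(self):
        s = simulate_dose_series(
            (10, 100, 100, 1.0), [0, 50, 100, 200], 2, 0.0,
            np.random.default_rng(0),
        )
        at_ec50 = s.responses[s.doses == 100][0]
        assert np.allclose(at_ec50, (100 + 10) / 2)

    def test_dose_zero_maps_to_top(self):
        s = simulate_dose_series(
            (10, 100, 100, 1.0), [0, 100], 1, 0.0, np.random.default_rng(0)
        )
        assert np.allclose(s.responses[0], 100)

    def test_hand_checked_point(self):
        # 10 + 90 / (1 + 300/100) = 32.5
        s = simulate_dose_series(
            (10, 100, 100, 1.0), [0, 300], 1, 0.0, np.random.default_rng(0)
        )
        assert np.allclose(s.responses[s.doses == 300], 32.5)

    def test_invalid_ec50_rejected(self):
        with pytest.raises(ConfigError):
            simulate_dose_series(
                (10, 100, -5, 1.0), [0, 1], 1, 0.0, np.random.default_rng(0)
            )

    def test_decreasing_doses_rejected(self):
        with pytest.raises(ConfigError):
            simulate_dose_series(
                (10, 100, 5, 1.0), [10, 5], 1, 0.0, np.random.default_rng(0)
            )
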