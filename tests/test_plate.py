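"""Plate statistics: Tukey fences, control summaries, Z-scores, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvascreen import (
    PlateZScorer,
    qc_plate,
    summarize_controls,
    tukey_retain,
    zscore_plate,
)
from larvascreen.errors import (
    DataIntegrityError,
    DegeneratePlateError,
    StatsError,
)
from larvascreen.plate import ControlStats

from conftest import make_plate_tables


def brute_force_tukey(values, side="both"):
    """Independent oracle: sort, fence, filter."""
    v = sorted(values)
    n = len(v)

    def quantile(q):  # type-7 linear interpolation
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    lo = -np.inf if side == "upper" else q1 - 1.5 * iqr
    hi = q3 + 1.5 * iqr
    return [x for x in values if lo <= x <= hi], [
        x for x in values if not lo <= x <= hi
    ]


class TestTukey:
    def test_hand_computed_example(self):
        # Q1=11, Q3=13, IQR=2 -> fences [8, 16]; 200 out
        retained, eliminated = tukey_retain([10, 11, 12, 13, 200])
        assert retained == [10, 11, 12, 13]
        assert eliminated == [200]

    def test_zero_iqr_retains_everything(self):
        retained, eliminated = tukey_retain([5, 5, 5, 5, 5])
        assert len(retained) == 5 and eliminated == []

    def test_too_few_values(self):
        with pytest.raises(StatsError):
            tukey_retain([1, 2, 3])

    def test_upper_side_keeps_low_outliers(self):
        retained, eliminated = tukey_retain([-500, 10, 11, 12, 13], side="upper")
        assert -500 in retained and eliminated == []

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6,
                      allow_nan=False, allow_infinity=False),
            min_size=4, max_size=40,
        ),
        st.sampled_from(["both", "upper"]),
    )
    def test_matches_brute_force_oracle(self, values, side):
        got_r, got_e = tukey_retain(values, side=side)
        exp_r, exp_e = brute_force_tukey(values, side=side)
        assert got_r == pytest.approx(exp_r)
        assert got_e == pytest.approx(exp_e)


class TestControlStats:
    def test_hand_computed_means_and_sd(self):
        layout, meas = make_plate_tables(
            neg=[90, 100, 110, 100], pos=[900, 1000, 1100, 1000], test=[]
        )
        stats = summarize_controls(meas, layout)
        assert stats.mean_neg == 100
        assert stats.mean_pos == 1000
        assert stats.sd_neg == pytest.approx(8.16496580927726)

    def test_outlier_removed_before_stats(self):
        layout, meas = make_plate_tables(
            neg=[90, 100, 110, 100, 10000], pos=[900, 1000, 1100, 1000], test=[]
        )
        stats = summarize_controls(meas, layout)
        assert stats.mean_neg == 100
        assert len(stats.eliminated) == 1

    def test_degenerate_plate(self):
        layout, meas = make_plate_tables(
            neg=[100, 100, 100, 100], pos=[900, 1000, 1100, 1000], test=[]
        )
        with pytest.raises(DegeneratePlateError):
            summarize_controls(meas, layout)

    def test_too_few_controls(self):
        layout, meas = make_plate_tables(
            neg=[90, 100, 110], pos=[900, 1000, 1100, 1000], test=[]
        )
        with pytest.raises(StatsError):
            summarize_controls(meas, layout)


class TestZScores:
    def stats(self, **kw):
        base = dict(plate_id="PX-R1", mean_pos=1000.0, mean_neg=100.0,
                    sd_neg=50.0, n_pos=4, n_neg=4)
        base.update(kw)
        return ControlStats(**base)

    def test_centering_and_scaling(self):
        layout, meas = make_plate_tables(
            neg=[90, 100, 110, 100], pos=[900, 1000, 1100, 1000],
            test=[100, 500],
        )
        z = zscore_plate(meas, layout, self.stats())
        assert z.z.tolist() == [0.0, 8.0]

    def test_missing_measurement_is_integrity_error(self):
        layout, meas = make_plate_tables(
            neg=[90, 100, 110, 100], pos=[900, 1000, 1100, 1000], test=[100]
        )
        with pytest.raises(DataIntegrityError, match="C01"):
            zscore_plate(meas.iloc[:-1], layout, self.stats())

    def test_artifact_wells_excluded(self):
        layout, meas = make_plate_tables(
            neg=[90, 100, 110, 100], pos=[900, 1000, 1100, 1000],
            test=[100, 500],
        )
        meas.loc[meas.well == "C02", "artifact"] = True
        z = zscore_plate(meas, layout, self.stats())
        assert bool(z.loc[z.well == "C02", "excluded"].iloc[0])
        assert np.isnan(z.loc[z.well == "C02", "z"]).all()

    def test_affine_invariance(self):
        layout, meas = make_plate_tables(
            neg=[90, 100, 110, 100, 95, 105], pos=[900, 1000, 1100, 1000],
            test=[100, 250, 400, 700],
        )
        s1 = summarize_controls(meas, layout)
        z1 = zscore_plate(meas, layout, s1)
        scaled = meas.assign(total_area=3.7 * meas.total_area + 11.0)
        s2 = summarize_controls(scaled, layout)
        z2 = zscore_plate(scaled, layout, s2)
        assert np.allclose(z1.z, z2.z)

    def test_negative_controls_self_score_standardized(self):
        neg = list(np.linspace(90.0, 110.0, 32))  # no fence outliers
        layout, meas = make_plate_tables(
            neg=neg, pos=[1000.0] * 4 + [1001.0], test=[]
        )
        stats = summarize_controls(meas, layout)
        assert len(stats.retained_neg) == 32  # none eliminated for this draw
        z = (np.array(neg) - stats.mean_neg) / stats.sd_neg
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_permutation_invariance(self):
        layout, meas = make_plate_tables(
            neg=[90, 100, 110, 100, 95], pos=[900, 1000, 1100, 1000],
            test=[100, 250, 400],
        )
        s1 = summarize_controls(meas, layout)
        perm = meas.sample(frac=1.0, random_state=1).reset_index(drop=True)
        s2 = summarize_controls(perm, layout)
        assert (s1.mean_pos, s1.mean_neg, s1.sd_neg) == (
            s2.mean_pos, s2.mean_neg, s2.sd_neg
        )


class TestPlateZScorer:
    def test_sklearn_roundtrip(self):
        scorer = PlateZScorer()
        scorer.fit([90, 100, 110, 100])
        assert scorer.transform([100]) == pytest.approx([0.0])
        assert scorer.get_params() == {"outlier_side": "both"}

    def test_degenerate_controls_rejected(self):
        with pytest.raises(DegeneratePlateError):
            PlateZScorer().fit([7, 7, 7, 7])


class TestQC:
    def stats(self, mean_pos, mean_neg, eliminated=()):
        return ControlStats(
            plate_id="P", mean_pos=mean_pos, mean_neg=mean_neg, sd_neg=10.0,
            eliminated=list(eliminated), n_pos=32, n_neg=32,
        )

    def test_good_separation_passes(self):
        assert qc_plate(self.stats(1000, 100)).passed

    def test_poor_separation_fails(self):
        qc = qc_plate(self.stats(120, 100))
        assert not qc.passed and "poor_separation" in qc.reasons

    def test_excess_control_outliers_fail(self):
        qc = qc_plate(self.stats(1000, 100, eliminated=[f"w{i}" for i in range(20)]))
        assert not qc.passed and "control_outliers" in qc.reasons
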