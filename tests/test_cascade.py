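"""Validation-cascade matrix building, classification, summaries."""

import numpy as np
import pandas as pd
import pytest

from larvascreen import (
    build_matrix,
    cascade_summary,
    classify_all,
    classify_compound,
)
from larvascreen.cascade import DEFAULT_STAGES, StageDef
from larvascreen.errors import CascadeError
from larvascreen.examples import fly_repurposing_matrix, worm_repurposing_matrix


def records(cells, ec50=None):
    rows = []
    for cid, cell_map in cells.items():
        for paradigm, result in cell_map.items():
            rows.append({
                "compound_id": cid, "paradigm": paradigm, "dose": 25.0,
                "result": result,
                "ec50_uM": (ec50 or {}).get(cid) if paradigm == "nrf2_reporter"
                else None,
            })
    return pd.DataFrame(rows)


ALL4 = ("worm_bzb", "worm_czb", "fly_het_bzb", "fly_homo_nodrug")


class TestBuildMatrix:
    def test_empty_records_empty_matrix(self):
        m = build_matrix(pd.DataFrame(columns=["compound_id", "paradigm", "result"]))
        assert m.compounds == []

    def test_unknown_paradigm_rejected(self):
        rec = pd.DataFrame([
            {"compound_id": "A", "paradigm": "zebrafish", "result": "pass"}
        ])
        with pytest.raises(CascadeError, match="zebrafish"):
            build_matrix(rec)

    def test_conflicting_duplicates_rejected(self):
        rec = pd.DataFrame([
            {"compound_id": "A", "paradigm": "worm_bzb", "result": "pass"},
            {"compound_id": "A", "paradigm": "worm_bzb", "result": "fail"},
        ])
        with pytest.raises(CascadeError, match="conflicting"):
            build_matrix(rec)

    def test_fully_populated_grid(self):
        cells = {
            f"C{i}": {p: "pass" for p in ALL4} for i in range(30)
        }
        m = build_matrix(records(cells))
        tested = (m.cells[list(ALL4)] != "not_tested").to_numpy()
        assert tested.all() and tested.size == 120

    def test_missing_cells_not_tested(self):
        m = build_matrix(records({"A": {"worm_bzb": "pass"}}))
        assert m.cells.at["A", "fly_het_bzb"] == "not_tested"


class TestClassify:
    def test_all_assay_active_pattern(self):
        # active in all four invertebrate paradigms plus the reporter
        cells = {"ARI": {**{p: "pass" for p in ALL4}, "nrf2_reporter": "pass"}}
        m = build_matrix(records(cells, ec50={"ARI": 10.0}))
        st = classify_compound(m, "ARI")
        assert {"validated_worm", "validated_fly", "cross_validated_all4",
                "nrf2_active", "all_assay_active"} <= st.flags

    def test_bortezomib_inactivator_pattern(self):
        # rescues only where bortezomib is present: chemical false positive
        cells = {"GOS": {"worm_bzb": "pass", "worm_czb": "fail",
                         "fly_het_bzb": "pass", "fly_homo_nodrug": "fail"}}
        st = classify_compound(build_matrix(records(cells)), "GOS")
        assert "bzb_inactivator_candidate" in st.flags
        assert "validated_worm" not in st.flags
        assert "validated_fly" not in st.flags

    def test_single_paradigm_failure_blocks_fly_validation(self):
        cells = {"X": {"worm_bzb": "pass", "worm_czb": "pass",
                       "fly_het_bzb": "pass", "fly_homo_nodrug": "fail"}}
        st = classify_compound(build_matrix(records(cells)), "X")
        assert "validated_worm" in st.flags
        assert "validated_fly" not in st.flags
        assert "all_assay_active" not in st.flags

    def test_untested_row_rejected(self):
        m = build_matrix(records({"A": {"worm_bzb": "pass"}}))
        m.cells.at["A", "worm_bzb"] = "not_tested"
        with pytest.raises(CascadeError):
            classify_compound(m, "A")

    def test_inactivator_and_validated_disjoint(self):
        # partition property over all 3^4 cell patterns
        states = ("pass", "fail", "not_tested")
        for i in range(3 ** 4):
            pattern = [states[(i // 3 ** k) % 3] for k in range(4)]
            if all(s == "not_tested" for s in pattern):
                continue
            m = build_matrix(records({"A": {
                p: s for p, s in zip(ALL4, pattern) if s != "not_tested"
            }}))
            st = classify_compound(m, "A")
            if "bzb_inactivator_candidate" in st.flags:
                assert "validated_worm" not in st.flags
                assert "validated_fly" not in st.flags

    def test_flipping_fail_to_pass_never_removes_flags(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pattern = rng.choice(["pass", "fail"], size=4)
            cells = {"A": dict(zip(ALL4, pattern))}
            m = build_matrix(records(cells))
            base = classify_compound(m, "A").flags - {"bzb_inactivator_candidate",
                                                      "retested"}
            fails = [p for p, s in zip(ALL4, pattern) if s == "fail"]
            for p in fails:
                flipped = dict(zip(ALL4, pattern))
                flipped[p] = "pass"
                m2 = build_matrix(records({"A": flipped}))
                up = classify_compound(m2, "A").flags - {"bzb_inactivator_candidate",
                                                         "retested"}
                assert base <= up


class TestSummary:
    def test_worm_repurposing_stage_percentages(self):
        m = worm_repurposing_matrix()
        stages = tuple(s for s in DEFAULT_STAGES
                       if s.name in ("worm_bzb_retest", "worm_czb_crosstest",
                                     "validated_worm"))
        out = cascade_summary(m, stages).set_index("stage")
        assert out.at["worm_bzb_retest", "numerator"] == 48
        assert out.at["worm_bzb_retest", "percent"] == 80
        assert out.at["validated_worm", "numerator"] == 15
        assert out.at["validated_worm", "percent"] == 25

    def test_fly_repurposing_stage_percentages(self):
        m = fly_repurposing_matrix()
        stages = tuple(s for s in DEFAULT_STAGES
                       if s.name in ("fly_het_retest", "validated_fly"))
        out = cascade_summary(m, stages).set_index("stage")
        assert out.at["fly_het_retest", "percent"] == 70
        assert out.at["validated_fly", "numerator"] == 13
        assert out.at["validated_fly", "percent"] == 43

    def test_all_passing_stage_is_100(self):
        cells = {f"C{i}": {"fly_het_bzb": "pass"} for i in range(11)}
        m = build_matrix(records(cells))
        stage = StageDef("retest", ("cell", "fly_het_bzb"), ("tested", "fly_het_bzb"))
        out = cascade_summary(m, (stage,))
        assert out.percent.iloc[0] == 100

    def test_zero_passing_stage_is_0(self):
        cells = {f"C{i}": {"worm_bzb": "fail"} for i in range(7)}
        m = build_matrix(records(cells))
        stage = StageDef("retest", ("cell", "worm_bzb"), ("tested", "worm_bzb"))
        assert cascade_summary(m, (stage,)).percent.iloc[0] == 0

    def test_empty_denominator_rejected(self):
        m = build_matrix(records({"A": {"worm_bzb": "pass"}}))
        stage = StageDef("fly", ("cell", "fly_het_bzb"), ("tested", "fly_het_bzb"))
        with pytest.raises(CascadeError):
            cascade_summary(m, (stage,))


def test_classify_all_one_row_per_compound():
    m = worm_repurposing_matrix()
    status = classify_all(m)
    assert len(status) == 60
    assert status.validated_worm.sum() == 15
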