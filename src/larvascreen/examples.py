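"""Synthetic example cascade matrices.

Worked fixtures modeled on the validation bookkeeping of a two-species
(worm + fly) bortezomib-suppressor repurposing campaign: each builder
returns outcome records whose per-stage pass counts match the campaign's
reported stage tallies, with anonymized compound labels. The compound
identities and per-cell patterns are synthetic — only the stage counts
are meaningful — so these serve as ground-truth inputs for exercising
:func:`larvascreen.cascade.cascade_summary` and
:func:`larvascreen.hits.hit_rate`, not as a reanalysis of any dataset.
"""

from __future__ import annotations

import pandas as pd

from .cascade import CascadeMatrix, build_matrix


def _records(prefix: str, cells: list[dict]) -> pd.DataFrame:
    rows = []
    for i, cell_map in enumerate(cells, start=1):
        cid = f"{prefix}{i:03d}"
        for paradigm, result in cell_map.items():
            if paradigm == "ec50_uM":
                continue
            rows.append({
                "compound_id": cid, "paradigm": paradigm, "dose": 25.0,
                "result": result, "ec50_uM": cell_map.get("ec50_uM"),
            })
    return pd.DataFrame(rows)


def _fill(n: int, **groups: int):
    """Expand group sizes into per-compound cell dicts (padded with fails)."""
    out = []
    for pattern, count in groups.items():
        out.extend([pattern] * count)
    assert len(out) <= n
    out.extend(["none"] * (n - len(out)))
    return out


def worm_repurposing_matrix() -> CascadeMatrix:
    """60 worm primary suppressors retested with bortezomib and
    cross-tested with carfilzomib: 48 retest, 15 pass both."""
    patterns = _fill(60, both=15, bzb_only=33)
    cells = []
    for p in patterns:
        cells.append({
            "worm_bzb": "pass" if p in ("both", "bzb_only") else "fail",
            "worm_czb": "pass" if p == "both" else "fail",
        })
    return build_matrix(_records("WR", cells))


def fly_repurposing_matrix() -> CascadeMatrix:
    """30 fly primary suppressors: 21 retest in the heterozygote
    bortezomib assay, 20 pass the homozygote no-drug assay, 13 both."""
    patterns = _fill(30, both=13, het_only=8, homo_only=7)
    cells = []
    for p in patterns:
        cells.append({
            "fly_het_bzb": "pass" if p in ("both", "het_only") else "fail",
            "fly_homo_nodrug": "pass" if p in ("both", "homo_only") else "fail",
        })
    return build_matrix(_records("FR", cells))


def worm_hits_in_fly_matrix() -> CascadeMatrix:
    """11 validated worm hits cross-tested in both fly paradigms:
    all pass the heterozygote assay, 6 validate in both."""
    cells = [
        {"fly_het_bzb": "pass",
         "fly_homo_nodrug": "pass" if i < 6 else "fail"}
        for i in range(11)
    ]
    return build_matrix(_records("WF", cells))


def fly_hits_in_worm_matrix() -> CascadeMatrix:
    """19 validated fly hits cross-tested in both worm paradigms:
    3 pass bortezomib, 3 pass carfilzomib, exactly 1 passes both."""
    patterns = _fill(19, both=1, bzb_only=2, czb_only=2)
    cells = []
    for p in patterns:
        cells.append({
            "worm_bzb": "pass" if p in ("both", "bzb_only") else "fail",
            "worm_czb": "pass" if p in ("both", "czb_only") else "fail",
        })
    return build_matrix(_records("FW", cells))


def novel_worm_matrix() -> CascadeMatrix:
    """28 lead-discovery worm suppressors: 12 retest with bortezomib,
    10 pass carfilzomib, 5 validate in both."""
    patterns = _fill(28, both=5, bzb_only=7, czb_only=5)
    cells = []
    for p in patterns:
        cells.append({
            "worm_bzb": "pass" if p in ("both", "bzb_only") else "fail",
            "worm_czb": "pass" if p in ("both", "czb_only") else "fail",
        })
    return build_matrix(_records("NW", cells))


#: synthetic in-window reporter EC50s (µM) for the 7 active compounds
_NRF2_ACTIVE_EC50S = (3.0, 5.0, 8.0, 12.0, 18.0, 24.0, 29.0)


def nrf2_panel_matrix() -> CascadeMatrix:
    """91 validated invertebrate hits tested in the human NRF2 reporter:
    7 are active (EC50 inside the 2–30 µM window), 84 lack potency
    (EC50 above 50 µM)."""
    cells = []
    for i in range(91):
        if i < len(_NRF2_ACTIVE_EC50S):
            cells.append({"nrf2_reporter": "pass",
                          "ec50_uM": _NRF2_ACTIVE_EC50S[i]})
        else:
            cells.append({"nrf2_reporter": "fail", "ec50_uM": 80.0})
    return build_matrix(_records("NR", cells))
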