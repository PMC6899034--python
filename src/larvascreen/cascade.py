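"""Validation-cascade bookkeeping.

Primary-screen positives are winnowed through orthogonal assay
paradigms: retest with bortezomib, counter-screen with carfilzomib (worm)
or the homozygote no-drug assay (fly), cross-species tests, and a human
Keap1-NRF2 reporter. The matrix of compound × paradigm outcomes yields
derived statuses:

* ``validated_worm`` — rescues with both proteasome inhibitors in worm;
* ``validated_fly`` — rescues in both fly paradigms;
* ``cross_validated_all4`` — all four invertebrate paradigms;
* ``bzb_inactivator_candidate`` — rescues in every tested
  bortezomib-containing paradigm but no non-bortezomib paradigm: a
  chemical false positive that neutralizes the drug rather than the
  phenotype;
* ``nrf2_active`` — reporter EC50 inside the potency window;
* ``all_assay_active`` — all four invertebrate paradigms plus NRF2.

Stage summaries (numerator / tested denominator / rounded percent) are
always computed from the matrix, never hand-entered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BZB_PARADIGMS, INVERTEBRATE_PARADIGMS, PARADIGMS
from .doseresponse import nrf2_active as _nrf2_active
from .errors import CascadeError
from .hits import hit_rate

FLAGS = (
    "retested",
    "validated_worm",
    "validated_fly",
    "cross_validated_all4",
    "nrf2_active",
    "all_assay_active",
    "bzb_inactivator_candidate",
)


@dataclass
class CascadeMatrix:
    """Compound × paradigm outcome grid plus attached reporter EC50s."""

    cells: pd.DataFrame            # index compounds, columns PARADIGMS, values pass/fail/not_tested
    ec50_uM: dict = field(default_factory=dict)

    def tested(self, compound_id: str, paradigm: str) -> bool:
        return self.cells.at[compound_id, paradigm] != "not_tested"

    @property
    def compounds(self) -> list[str]:
        return list(self.cells.index)


@dataclass
class CascadeRules:
    nrf2_window_uM: tuple[float, float] = (2.0, 30.0)
    nrf2_lower_exclusionary: bool = False


@dataclass
class ValidationStatus:
    compound_id: str
    flags: set = field(default_factory=set)

    def __contains__(self, flag: str) -> bool:
        return flag in self.flags


def build_matrix(outcome_records: pd.DataFrame) -> CascadeMatrix:
    """Assemble a cascade matrix from long-format outcome records.

    ``outcome_records`` columns: compound_id, paradigm, result
    ('pass'/'fail'), optional dose and ec50_uM. Unknown paradigms are
    schema errors; conflicting duplicate records for one cell are
    reported together; untested cells become ``not_tested``.
    """
    rec = outcome_records.copy()
    if rec.empty:
        return CascadeMatrix(cells=pd.DataFrame(columns=list(PARADIGMS)))
    unknown = set(rec.paradigm) - set(PARADIGMS)
    if unknown:
        raise CascadeError(f"unknown paradigm labels: {sorted(unknown)}")
    bad = set(rec.result) - {"pass", "fail"}
    if bad:
        raise CascadeError(f"invalid result values: {sorted(bad)}")

    conflicts = []
    for (cid, par), grp in rec.groupby(["compound_id", "paradigm"]):
        if grp.result.nunique() > 1:
            conflicts.append((cid, par))
    if conflicts:
        raise CascadeError(f"conflicting records for cells: {conflicts}")

    compounds = list(pd.unique(rec.compound_id))
    cells = pd.DataFrame(
        "not_tested", index=compounds, columns=list(PARADIGMS), dtype=object
    )
    for (cid, par), grp in rec.groupby(["compound_id", "paradigm"]):
        cells.at[cid, par] = grp.result.iloc[0]

    ec50 = {}
    if "ec50_uM" in rec:
        nrf2 = rec[(rec.paradigm == "nrf2_reporter") & rec.ec50_uM.notna()]
        ec50 = dict(zip(nrf2.compound_id, nrf2.ec50_uM.astype(float)))
    return CascadeMatrix(cells=cells, ec50_uM=ec50)


def classify_compound(
    matrix: CascadeMatrix,
    compound_id: str,
    rules: CascadeRules | None = None,
) -> ValidationStatus:
    """Derive validation flags for one compound row of the matrix."""
    rules = rules or CascadeRules()
    if compound_id not in matrix.cells.index:
        raise CascadeError(f"unknown compound {compound_id!r}")
    row = matrix.cells.loc[compound_id]
    if (row == "not_tested").all():
        raise CascadeError(f"compound {compound_id!r} has no tested cells")

    def p(par: str) -> bool:
        return row[par] == "pass"

    flags: set[str] = set()
    if p("worm_bzb") or p("fly_het_bzb"):
        flags.add("retested")
    if p("worm_bzb") and p("worm_czb"):
        flags.add("validated_worm")
    if p("fly_het_bzb") and p("fly_homo_nodrug"):
        flags.add("validated_fly")
    if all(p(par) for par in INVERTEBRATE_PARADIGMS):
        flags.add("cross_validated_all4")

    bzb_tested = [q for q in INVERTEBRATE_PARADIGMS
                  if q in BZB_PARADIGMS and row[q] != "not_tested"]
    nonbzb_tested = [q for q in INVERTEBRATE_PARADIGMS
                     if q not in BZB_PARADIGMS and row[q] != "not_tested"]
    if (
        bzb_tested and nonbzb_tested
        and all(p(q) for q in bzb_tested)
        and not any(p(q) for q in nonbzb_tested)
    ):
        flags.add("bzb_inactivator_candidate")

    ec50 = matrix.ec50_uM.get(compound_id, np.nan)
    if _nrf2_active(ec50, rules.nrf2_window_uM, rules.nrf2_lower_exclusionary):
        flags.add("nrf2_active")
    if "cross_validated_all4" in flags and "nrf2_active" in flags:
        flags.add("all_assay_active")
    return ValidationStatus(compound_id=compound_id, flags=flags)


def classify_all(
    matrix: CascadeMatrix, rules: CascadeRules | None = None
) -> pd.DataFrame:
    """Status table: one boolean column per validation flag."""
    rows = []
    for cid in matrix.compounds:
        st = classify_compound(matrix, cid, rules)
        rows.append({"compound_id": cid, **{f: f in st.flags for f in FLAGS}})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StageDef:
    """One cascade-summary stage.

    ``numerator`` / ``denominator`` are selector specs:
      ("cell", paradigm)          — compounds passing that paradigm;
      ("flag", flag_name)         — compounds carrying a validation flag;
      ("tested", paradigm, ...)   — compounds tested in all listed paradigms;
      ("all",)                    — every compound in the matrix.
    The numerator is always intersected with the denominator.
    """

    name: str
    numerator: tuple
    denominator: tuple


def _select(matrix: CascadeMatrix, status: pd.DataFrame, spec: tuple) -> set:
    kind = spec[0]
    cells = matrix.cells
    if kind == "all":
        return set(cells.index)
    if kind == "cell":
        return set(cells.index[cells[spec[1]] == "pass"])
    if kind == "tested":
        mask = np.ones(len(cells), dtype=bool)
        for par in spec[1:]:
            mask &= (cells[par] != "not_tested").to_numpy()
        return set(cells.index[mask])
    if kind == "flag":
        return set(status.loc[status[spec[1]], "compound_id"])
    raise CascadeError(f"unknown selector {spec!r}")


DEFAULT_STAGES = (
    StageDef("worm_bzb_retest", ("cell", "worm_bzb"), ("tested", "worm_bzb")),
    StageDef("worm_czb_crosstest", ("cell", "worm_czb"), ("tested", "worm_czb")),
    StageDef("validated_worm", ("flag", "validated_worm"),
             ("tested", "worm_bzb", "worm_czb")),
    StageDef("fly_het_retest", ("cell", "fly_het_bzb"), ("tested", "fly_het_bzb")),
    StageDef("fly_homo_crosstest", ("cell", "fly_homo_nodrug"),
             ("tested", "fly_homo_nodrug")),
    StageDef("validated_fly", ("flag", "validated_fly"),
             ("tested", "fly_het_bzb", "fly_homo_nodrug")),
    StageDef("cross_validated_all4", ("flag", "cross_validated_all4"),
             ("tested",) + INVERTEBRATE_PARADIGMS),
    StageDef("nrf2_active", ("flag", "nrf2_active"), ("tested", "nrf2_reporter")),
    StageDef("all_assay_active", ("flag", "all_assay_active"),
             ("tested",) + INVERTEBRATE_PARADIGMS),
)


def cascade_summary(
    matrix: CascadeMatrix,
    stage_definitions: tuple[StageDef, ...] = DEFAULT_STAGES,
    precision: int = 0,
    rules: CascadeRules | None = None,
) -> pd.DataFrame:
    """(stage, numerator, denominator, percent) table over the matrix.

    Denominators are the tested sets the stage defines; percent uses the
    half-away-from-zero convention of :func:`~larvascreen.hits.hit_rate`.
    """
    status = classify_all(matrix, rules)
    rows = []
    for stage in stage_definitions:
        den = _select(matrix, status, stage.denominator)
        if not den:
            raise CascadeError(f"stage {stage.name!r} has an empty denominator")
        num = _select(matrix, status, stage.numerator) & den
        rows.append({
            "stage": stage.name,
            "numerator": len(num),
            "denominator": len(den),
            "percent": hit_rate(len(num), len(den), precision),
        })
    return pd.DataFrame(rows)
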