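"""Per-plate control statistics and Z-score normalization.

Each screening plate carries its own positive controls (untreated, fully
grown) and negative controls (drug-arrested). Control wells are cleaned
with a 1.5×IQR Tukey fence per group, then every test well is scored as

    z = (area - mean_neg) / sd_neg

against the retained negative controls of its own plate (sample s.d.,
n−1). Suppressors trend positive, enhancers negative. Conventions that
the source procedure leaves open are fixed and test-locked here:
type-7 linear-interpolation quantiles, two-sided fences by default (with
an ``upper``-only switch), sample standard deviation, per-plate (never
campaign-global) normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataIntegrityError, DegeneratePlateError, StatsError


def tukey_fences(values, side: str = "both") -> tuple[float, float]:
    """[Q1 − 1.5·IQR, Q3 + 1.5·IQR] with type-7 quantiles; closed interval."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise StatsError(f"Tukey fences need >= 4 values, got {v.size}")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # numpy default = linear (type 7)
    iqr = q3 - q1
    lo = -np.inf if side == "upper" else q1 - 1.5 * iqr
    return float(lo), float(q3 + 1.5 * iqr)


def tukey_retain(values, side: str = "both") -> tuple[list[float], list[float]]:
    """Split values into (retained, eliminated) by the 1.5×IQR rule.

    The fence interval is closed, so with IQR = 0 identical values are
    all retained. Input order is preserved in both outputs.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = tukey_fences(v, side=side)
    keep = (v >= lo) & (v <= hi)
    return list(v[keep]), list(v[~keep])


@dataclass
class ControlStats:
    """Per-plate control summary after outlier elimination."""

    plate_id: str
    mean_pos: float
    mean_neg: float
    sd_neg: float
    retained_pos: list = field(default_factory=list)
    retained_neg: list = field(default_factory=list)
    eliminated: list = field(default_factory=list)
    n_pos: int = 0
    n_neg: int = 0

    @property
    def separation(self) -> float:
        return self.mean_pos / self.mean_neg if self.mean_neg else np.inf


@dataclass
class QCResult:
    plate_id: str
    passed: bool
    reasons: list = field(default_factory=list)


class PlateZScorer(TransformerMixin, BaseEstimator):
    """Z-score transformer anchored to a plate's negative controls.

    ``fit`` takes the raw negative-control readouts, applies the Tukey
    fence, and stores the retained-group moments; ``transform`` maps any
    readouts on the same plate to Z-scores. Affine rescaling of all
    readouts (controls and test wells alike) leaves the scores unchanged.
    """

    def __init__(self, outlier_side: str = "both"):
        self.outlier_side = outlier_side

    def fit(self, X, y=None):
        v = np.asarray(X, dtype=float).ravel()
        retained, eliminated = tukey_retain(v, side=self.outlier_side)
        r = np.asarray(retained)
        self.retained_ = retained
        self.eliminated_ = eliminated
        self.mean_ = float(r.mean())
        self.sd_ = float(r.std(ddof=1))
        if self.sd_ == 0:
            raise DegeneratePlateError(
                "negative-control spread is zero; Z-scores undefined"
            )
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_


def _value_column(measurements: pd.DataFrame, prefer_normalized: bool) -> pd.Series:
    if prefer_normalized and "normalized_area" in measurements:
        na = measurements["normalized_area"]
        if na.notna().any():
            return na.fillna(measurements["total_area"])
    return measurements["total_area"]


def summarize_controls(
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    outlier_side: str = "both",
    use_normalized: bool = False,
) -> ControlStats:
    """Summarize one plate's control wells after per-group Tukey cleanup.

    ``measurements`` and ``layout`` must cover a single plate. Artifact
    wells are dropped before the fence; each control group needs at least
    4 clean wells.
    """
    plates = layout.plate_id.unique()
    if len(plates) != 1:
        raise DataIntegrityError(f"expected a single plate, got {list(plates)}")
    plate_id = plates[0]
    merged = layout.merge(measurements, on=["plate_id", "well"], how="left")
    ctrl = merged[merged.role.isin(["positive", "negative"])]
    missing = ctrl[ctrl.total_area.isna()].well.tolist()
    if missing:
        raise DataIntegrityError(
            f"plate {plate_id}: no measurement for control wells {missing}"
        )
    clean = ctrl[~ctrl.artifact.astype(bool)]
    groups = {}
    eliminated_wells: list[str] = []
    for role in ("positive", "negative"):
        sub = clean[clean.role == role]
        if len(sub) < 4:
            raise StatsError(
                f"plate {plate_id}: only {len(sub)} usable {role} controls (need >= 4)"
            )
        vals = _value_column(sub, use_normalized).to_numpy(float)
        lo, hi = tukey_fences(vals, side=outlier_side)
        keep = (vals >= lo) & (vals <= hi)
        groups[role] = (sub.well.to_numpy()[keep], vals[keep])
        eliminated_wells.extend(sub.well.to_numpy()[~keep])
    pos_wells, pos_vals = groups["positive"]
    neg_wells, neg_vals = groups["negative"]
    sd_neg = float(neg_vals.std(ddof=1))
    if sd_neg == 0:
        raise DegeneratePlateError(
            f"plate {plate_id}: retained negative controls have zero spread"
        )
    return ControlStats(
        plate_id=plate_id,
        mean_pos=float(pos_vals.mean()),
        mean_neg=float(neg_vals.mean()),
        sd_neg=sd_neg,
        retained_pos=list(pos_wells),
        retained_neg=list(neg_wells),
        eliminated=eliminated_wells,
        n_pos=int((clean.role == "positive").sum()),
        n_neg=int((clean.role == "negative").sum()),
    )


def zscore_plate(
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    stats: ControlStats,
    use_normalized: bool = False,
) -> pd.DataFrame:
    """Score one plate's test wells against its negative-control stats.

    Returns (plate_id, well, compound_id, z, excluded); artifact wells
    carry ``excluded=True`` and no Z-score. A layout test well with no
    measurement at all is a data-integrity error.
    """
    if stats.sd_neg <= 0:
        raise DegeneratePlateError(f"plate {stats.plate_id}: sd_neg must be > 0")
    test = layout[layout.role == "test"]
    merged = test.merge(measurements, on=["plate_id", "well"], how="left")
    missing = merged[merged.total_area.isna()].well.tolist()
    if missing:
        raise DataIntegrityError(
            f"plate {stats.plate_id}: missing measurements for wells {missing}"
        )
    vals = _value_column(merged, use_normalized).to_numpy(float)
    z = (vals - stats.mean_neg) / stats.sd_neg
    excluded = merged.artifact.astype(bool).to_numpy()
    return pd.DataFrame({
        "plate_id": merged.plate_id,
        "well": merged.well,
        "compound_id": merged.compound_id,
        "z": np.where(excluded, np.nan, z),
        "excluded": excluded,
    })


def qc_plate(
    stats: ControlStats,
    min_separation: float = 3.0,
    max_eliminated_fraction: float = 0.25,
) -> QCResult:
    """Plate-level quality control on the control summary.

    A plate passes iff positive/negative mean separation is at least
    ``min_separation`` and the Tukey fence eliminated at most
    ``max_eliminated_fraction`` of the control wells.
    """
    reasons = []
    if stats.separation < min_separation:
        reasons.append("poor_separation")
    n_ctrl = stats.n_pos + stats.n_neg
    if n_ctrl and len(stats.eliminated) / n_ctrl > max_eliminated_fraction:
        reasons.append("control_outliers")
    return QCResult(plate_id=stats.plate_id, passed=not reasons, reasons=reasons)


def score_campaign(
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    outlier_side: str = "both",
    use_normalized: bool = False,
    min_separation: float = 3.0,
    max_eliminated_fraction: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every plate of a campaign; returns (zscores, plate_qc).

    Plates failing QC are excluded from the Z-score table and recorded in
    the QC table with their reasons.
    """
    z_frames, qc_rows = [], []
    for plate_id, plate_layout in layout.groupby("plate_id", sort=True):
        plate_meas = measurements[measurements.plate_id == plate_id]
        stats = summarize_controls(
            plate_meas, plate_layout,
            outlier_side=outlier_side, use_normalized=use_normalized,
        )
        qc = qc_plate(stats, min_separation, max_eliminated_fraction)
        qc_rows.append({
            "plate_id": plate_id, "passed": qc.passed,
            "reasons": ";".join(qc.reasons),
            "mean_pos": stats.mean_pos, "mean_neg": stats.mean_neg,
            "sd_neg": stats.sd_neg, "n_eliminated": len(stats.eliminated),
        })
        if qc.passed:
            z_frames.append(
                zscore_plate(plate_meas, plate_layout, stats, use_normalized)
            )
    zscores = (
        pd.concat(z_frames, ignore_index=True)
        if z_frames
        else pd.DataFrame(columns=["plate_id", "well", "compound_id", "z", "excluded"])
    )
    return zscores, pd.DataFrame(qc_rows)
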