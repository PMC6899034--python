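"""Four-parameter-logistic (4PL) dose-response fitting and derived quantities.

The model is

    r(d) = bottom + (top - bottom) / (1 + (d / ec50)^hill)

with ``hill > 0`` for toxicity curves (response falls from ``top`` at
dose 0 toward ``bottom``) and ``hill < 0`` for activation curves. Fitting
is least squares on log-dose; zero-dose points are anchored to the
no-drug asymptote rather than placed on the log grid.

Derived quantities cover the screening workflow: inversion of the fitted
curve to pick a screening dose producing a target size reduction,
EC50-ratio fold-sensitivity between genotypes, and percent-of-maximal
response against a positive-control activator (the reporter-assay
ranking statistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, FitError


def four_pl(
    dose, bottom: float, top: float, ec50: float, hill: float
) -> np.ndarray:
    """Evaluate the 4PL curve; dose 0 maps to the no-drug asymptote."""
    d = np.asarray(dose, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.empty_like(d)
    zero = d == 0
    with np.errstate(divide="ignore", over="ignore"):
        ratio = (d[~zero] / ec50) ** hill
    out[~zero] = bottom + (top - bottom) / (1.0 + ratio)
    out[zero] = top if hill > 0 else bottom
    return out[0] if scalar else out


def round_half_away(x: float, precision: int) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    q = Decimal(1).scaleb(-precision)
    sign = -1 if x < 0 else 1
    return sign * float(Decimal(repr(abs(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DoseResponseCurve:
    """Fitted 4PL parameters and diagnostics."""

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    n_points: int
    converged: bool
    dose_unit: str | None = None

    def predict(self, dose) -> np.ndarray:
        if not self.converged:
            raise DomainError("curve did not converge; no predictions available")
        return four_pl(dose, self.bottom, self.top, self.ec50, self.hill)

    @property
    def amplitude(self) -> float:
        return self.top - self.bottom


class FourParamLogistic(RegressorMixin, BaseEstimator):
    """Scikit-learn style 4PL regressor.

    Parameters
    ----------
    ec50_bounds_factor : float
        The fitted EC50 is constrained to
        ``[min_positive_dose / factor, max_dose * factor]``.
    min_amplitude : float or None
        Signal floor: if the spread of per-dose mean responses is at or
        below this value (or, when None, below twice the pooled replicate
        standard error), the data are declared effect-free and the fit is
        marked unconverged rather than chasing noise.

    Attributes (after ``fit``)
    --------------------------
    bottom_, top_, ec50_, hill_ : float
        Fitted curve parameters (stored with ``top_ >= bottom_``).
    rss_ : float
        Residual sum of squares.
    converged_ : bool
    """

    def __init__(
        self,
        ec50_bounds_factor: float = 100.0,
        min_amplitude: float | None = None,
        max_hill: float = 10.0,
    ):
        self.ec50_bounds_factor = ec50_bounds_factor
        self.min_amplitude = min_amplitude
        self.max_hill = max_hill

    def fit(self, X, y):
        """Fit doses ``X`` (1-D, may include repeats and zeros) to responses ``y``."""
        d = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if d.shape != y.shape:
            raise FitError("dose and response arrays must have equal length")
        if np.any(d < 0):
            raise FitError("doses must be non-negative")
        unique = np.unique(d)
        if unique.size < 4:
            raise FitError(f"need >= 4 distinct doses, got {unique.size}")
        self.n_points_ = y.size

        means = np.array([y[d == u].mean() for u in unique])
        amplitude = means.max() - means.min()
        floor = self._noise_floor(d, y, unique)
        if amplitude <= floor:
            # flat signal: report a degenerate no-effect curve
            self.bottom_ = self.top_ = float(means.mean())
            self.ec50_ = float(np.nan)
            self.hill_ = float(np.nan)
            self.rss_ = float(((y - means.mean()) ** 2).sum())
            self.converged_ = False
            return self

        pos = unique[unique > 0]
        lo = np.log10(pos.min() / self.ec50_bounds_factor)
        hi = np.log10(pos.max() * self.ec50_bounds_factor)
        top0, bottom0 = means.max(), means.min()
        log_ec50_0 = 0.5 * (np.log10(pos.min()) + np.log10(pos.max()))
        # orientation: response falling with dose => hill > 0
        falling = means[np.argmin(unique)] >= means[np.argmax(unique)]
        hill0 = 1.0 if falling else -1.0

        def model(dose, bottom, top, log_ec50, hill):
            return four_pl(dose, bottom, top, 10.0 ** log_ec50, hill)

        span = max(abs(top0 - bottom0), 1e-12)
        p0 = [bottom0, top0, log_ec50_0, hill0]
        bounds = (
            [bottom0 - 10 * span, top0 - 10 * span, lo, -self.max_hill],
            [bottom0 + 10 * span, top0 + 10 * span, hi, self.max_hill],
        )
        try:
            popt, _ = curve_fit(model, d, y, p0=p0, bounds=bounds, maxfev=20000)
            converged = True
        except RuntimeError:
            popt, converged = p0, False
        bottom, top, log_ec50, hill = popt
        resid = y - model(d, *popt)
        self.rss_ = float((resid ** 2).sum())
        if top < bottom:  # store with top >= bottom, flipping the slope sign
            bottom, top, hill = top, bottom, -hill
        self.bottom_, self.top_ = float(bottom), float(top)
        self.ec50_, self.hill_ = float(10.0 ** log_ec50), float(hill)
        self.converged_ = bool(converged)
        return self

    def _noise_floor(self, d, y, unique) -> float:
        if self.min_amplitude is not None:
            return self.min_amplitude
        reps = [y[d == u] for u in unique]
        pooled = [r.std(ddof=1) / np.sqrt(len(r)) for r in reps if len(r) > 1]
        if not pooled:
            return 0.0
        return 2.0 * float(np.mean(pooled))

    def predict(self, X):
        if not self.converged_:
            raise DomainError("fit did not converge")
        return four_pl(np.asarray(X, float), self.bottom_, self.top_,
                       self.ec50_, self.hill_)

    def curve_(self, dose_unit: str | None = None) -> DoseResponseCurve:
        return DoseResponseCurve(
            bottom=self.bottom_, top=self.top_, ec50=self.ec50_,
            hill=self.hill_, rss=self.rss_, n_points=self.n_points_,
            converged=self.converged_, dose_unit=dose_unit,
        )


def fit_4pl(series, ec50_bounds_factor: float = 100.0,
            min_amplitude: float | None = None) -> DoseResponseCurve:
    """Fit a 4PL curve to a :class:`~larvascreen.campaign.DoseSeries` or
    long-format DataFrame with ``dose`` and ``response`` columns."""
    if isinstance(series, pd.DataFrame):
        d = series["dose"].to_numpy(float)
        y = series["response"].to_numpy(float)
        unit = str(series["dose_unit"].iloc[0]) if "dose_unit" in series else None
    else:
        n_reps = series.responses.shape[1]
        d = np.repeat(series.doses, n_reps)
        y = series.responses.ravel()
        unit = series.dose_unit
    est = FourParamLogistic(
        ec50_bounds_factor=ec50_bounds_factor, min_amplitude=min_amplitude
    ).fit(d, y)
    return est.curve_(dose_unit=unit)


def invert_curve(curve: DoseResponseCurve, reduction: float = 0.85) -> float:
    """Dose producing a target fractional reduction from the top asymptote.

    Solves ``r(d) = top * (1 - reduction)`` in closed form. Used to pick
    the screening dose (default: the dose shrinking mean size by 85%).
    """
    if not curve.converged:
        raise DomainError("cannot invert an unconverged curve")
    if not 0.0 < reduction < 1.0:
        raise DomainError(f"reduction must be in (0, 1), got {reduction}")
    r_star = curve.top * (1.0 - reduction)
    if not curve.bottom < r_star < curve.top:
        raise DomainError(
            f"target response {r_star} outside the open interval "
            f"({curve.bottom}, {curve.top})"
        )
    x = (curve.top - r_star) / (r_star - curve.bottom)
    return float(curve.ec50 * x ** (1.0 / curve.hill))


def select_screening_dose(
    curve: DoseResponseCurve, target_reduction: float = 0.85
) -> float:
    """Screening dose at the target mean-size reduction (alias of inversion)."""
    return invert_curve(curve, reduction=target_reduction)


def fold_sensitivity(
    curve_reference: DoseResponseCurve, curve_test: DoseResponseCurve
) -> float:
    """EC50 ratio reference/test; > 1 means the test genotype is more sensitive."""
    for c in (curve_reference, curve_test):
        if not c.converged:
            raise FitError("both curves must be converged")
    if (
        curve_reference.dose_unit is not None
        and curve_test.dose_unit is not None
        and curve_reference.dose_unit != curve_test.dose_unit
    ):
        raise FitError(
            f"dose unit mismatch: {curve_reference.dose_unit!r} vs "
            f"{curve_test.dose_unit!r}"
        )
    return float(curve_reference.ec50 / curve_test.ec50)


def percent_max_response(
    curve_test: DoseResponseCurve, curve_positive_control: DoseResponseCurve
) -> int:
    """Response amplitude of a test compound as an integer percent of the
    positive-control activator's amplitude."""
    for c in (curve_test, curve_positive_control):
        if not c.converged:
            raise FitError("both curves must be converged")
    ref = curve_positive_control.amplitude
    if ref == 0:
        raise FitError("reference amplitude is zero")
    return int(round_half_away(100.0 * curve_test.amplitude / ref, 0))


def nrf2_active(
    ec50_uM: float,
    window_uM: tuple[float, float] = (2.0, 30.0),
    lower_exclusionary: bool = False,
) -> bool:
    """Reporter-activity call from a measured EC50 (µM).

    The upper bound is the potency cutoff; the lower bound brackets the
    observed actives and is descriptive unless ``lower_exclusionary``.
    """
    if ec50_uM is None or np.isnan(ec50_uM):
        return False
    lo, hi = window_uM
    if ec50_uM > hi:
        return False
    return ec50_uM >= lo if lower_exclusionary else True
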