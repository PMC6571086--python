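"""Dye-ratio viability estimators.

SYTO 9 is a membrane-permeant nucleic-acid stain (green emission) and
propidium iodide (PI) a membrane-impermeant counterstain (red emission) that
only enters membrane-compromised cells.  Under ideal staining the SYTO 9
signal tracks the live count L and the PI signal the dead count D, so with
R = SYTO9/PI (integrated peak intensities):

* the plain *dye ratio* R is proportional to L/D, which is nonlinear in the
  percentage of live cells, and
* the *adjusted dye ratio* 100*R/(1+R) = 100*L/(L+D) is exactly the
  percentage of live cells.

Both are simple univariate proxies calibrated against a reference method by
ordinary least squares; the proportionality constants are absorbed into the
calibration slope and intercept.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra_io import MeasurementSeries, SampleRecord, Spectrum

#: Integration windows over the emission peaks, in nm.
SYTO9_WINDOW: tuple[float, float] = (509.0, 529.0)
PI_WINDOW: tuple[float, float] = (609.0, 629.0)


def integrated_intensity(spectrum: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of intensity over a closed wavelength window.

    The integral runs over the native grid points lying inside ``window``
    (inclusive); no resampling is performed.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window lower bound must be below upper bound")
    wl = spectrum.wavelengths
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(f"window {window} outside wavelength grid")
    mask = (wl >= lo) & (wl <= hi)
    return float(np.trapezoid(spectrum.intensities[mask], wl[mask]))


@dataclasses.dataclass
class DyeSignals:
    """Integrated SYTO 9 and PI peak intensities of one spectrum."""

    syto9: float
    pi: float
    windows: tuple[tuple[float, float], tuple[float, float]] = (
        SYTO9_WINDOW,
        PI_WINDOW,
    )

    def __post_init__(self) -> None:
        if not (np.isfinite(self.syto9) and np.isfinite(self.pi)):
            raise ValueError("dye signals must be finite")


def dye_signals(
    spectrum: Spectrum,
    syto9_window: tuple[float, float] = SYTO9_WINDOW,
    pi_window: tuple[float, float] = PI_WINDOW,
) -> DyeSignals:
    return DyeSignals(
        syto9=integrated_intensity(spectrum, syto9_window),
        pi=integrated_intensity(spectrum, pi_window),
        windows=(syto9_window, pi_window),
    )


def dye_ratio(signals: DyeSignals) -> float:
    """SYTO9:PI integrated-intensity ratio (proportional to percent live)."""
    if signals.pi <= 0:
        raise ValueError("dye ratio undefined: PI integrated intensity <= 0")
    return signals.syto9 / signals.pi


def adjusted_dye_ratio(signals: DyeSignals) -> float:
    """100*R/(1+R) with R the dye ratio; linear in percent live under ideal
    staining, and approximately equal to 100*R when R is small."""
    r = dye_ratio(signals)
    return 100.0 * r / (1.0 + r)


@dataclasses.dataclass
class RatioCalibration:
    """OLS line of reference percent-live on a ratio value."""

    slope: float
    intercept: float
    r_squared: float
    std_err: float  # residual standard error of the fit

    def predict(self, values: np.ndarray | float) -> np.ndarray:
        return self.slope * np.asarray(values, dtype=float) + self.intercept


def fit_ratio_calibration(
    values: Sequence[float], f_live_refs: Sequence[float]
) -> RatioCalibration:
    """Least-squares calibration of reference percent-live on a ratio.

    R^2 is computed as 1 - SS_res/SS_tot; for an OLS fit evaluated in-sample
    it is non-negative, but the same definition applied to external
    predictions (see :mod:`vitaspec.evaluation`) may be negative, meaning the
    model is worse than predicting the mean.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(f_live_refs, dtype=float)
    if len(x) != len(y):
        raise ValueError("values and references differ in length")
    if len(x) < 3:
        raise ValueError("at least 3 samples are required for calibration")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor: calibration is degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(x) - 2, 1)
    std_err = float(np.sqrt(ss_res / dof))
    return RatioCalibration(float(slope), float(intercept), r_squared, std_err)


def sample_ratio_table(
    measurements: Sequence[MeasurementSeries],
    samples: Sequence[SampleRecord],
    syto9_window: tuple[float, float] = SYTO9_WINDOW,
    pi_window: tuple[float, float] = PI_WINDOW,
) -> pd.DataFrame:
    """Per-sample dye-signal table from the first frame of each measurement.

    Replicate measurements of a sample are averaged at the signal level
    before the ratios are formed.
    """
    by_id = {m.measurement_id: m for m in measurements}
    rows = []
    for s in samples:
        sig_s9, sig_pi = [], []
        for mid in s.measurement_ids:
            series = by_id[mid]
            sig = dye_signals(series.frame(0), syto9_window, pi_window)
            sig_s9.append(sig.syto9)
            sig_pi.append(sig.pi)
        syto9 = float(np.mean(sig_s9))
        pi = float(np.mean(sig_pi))
        sig = DyeSignals(syto9, pi, (syto9_window, pi_window))
        ratio = dye_ratio(sig) if pi > 0 else np.nan
        adjusted = adjusted_dye_ratio(sig) if pi > 0 else np.nan
        rows.append(
            {
                "sample_id": s.sample_id,
                "f_live_ref": s.f_live_ref,
                "syto9": syto9,
                "pi": pi,
                "dye_ratio": ratio,
                "adjusted_dye_ratio": adjusted,
            }
        )
    return pd.DataFrame(rows)
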