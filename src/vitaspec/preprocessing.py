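"""Spectral pre-processing chain.

Fixed order: dark removal -> normalisation to reference acquisition
conditions (8 ms integration, 10 mW laser power) -> background subtraction
-> replicate-based anomaly screening -> frame selection at the analysis
time points -> optional frame summing -> mean-centring with *training*
means.  The chain is enforced through the ``normalised`` flags on spectra
and series.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .spectra_io import MeasurementSeries, Spectrum

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PreprocessConfig:
    """Parameters of the pre-processing chain.

    ``dark_spectrum`` may be a constant offset or a per-wavelength vector
    (zero for synthetic data, whose generator has no dark offset).
    ``timepoints`` are the ms offsets at which frames are selected for the
    regression features: 0 (the first 20-ms spectrum) plus photobleaching
    half-life candidates.
    """

    reference_integration_time: float = 8.0  # ms
    reference_power: float = 10.0  # mW
    dark_spectrum: float | np.ndarray = 0.0
    background: Spectrum | None = None
    anomaly_threshold: float = 3.0  # multiples of the replicate MAD
    min_relative_deviation: float = 0.2  # "noticeably" higher/lower floor
    two_replicate_factor: float = 1.5
    timepoints: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.reference_integration_time <= 0 or self.reference_power <= 0:
            raise ValueError("reference integration time and power must be > 0")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be >= 0")


def remove_dark(spectrum: Spectrum, dark: float | np.ndarray) -> Spectrum:
    """Subtract the instrument dark signal (constant or per-wavelength)."""
    out = spectrum.copy()
    out.intensities = out.intensities - np.asarray(dark, dtype=float)
    return out


def normalize_spectrum(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> Spectrum:
    """Rescale intensities to the reference integration time and laser power.

    Counts scale linearly with both, so the factor is
    ``(t_ref / t) * (P_ref / P)``.  Dark noise must have been removed first;
    double normalisation is an error.
    """
    config = config or PreprocessConfig()
    if spectrum.normalised:
        raise ValueError("spectrum is already normalised")
    factor = (config.reference_integration_time / spectrum.integration_time) * (
        config.reference_power / spectrum.laser_power
    )
    return Spectrum(
        spectrum.wavelengths,
        spectrum.intensities * factor,
        integration_time=config.reference_integration_time,
        laser_power=config.reference_power,
        normalised=True,
    )


def subtract_background(spectrum: Spectrum, background: Spectrum) -> Spectrum:
    """Subtract the averaged saline background spectrum, elementwise.

    Negative residual intensities are kept (clipping would bias window
    integrals); a fully negative spectrum integral is logged as suspicious.
    """
    if not np.array_equal(spectrum.wavelengths, background.wavelengths):
        raise ValueError("background wavelength grid differs from spectrum")
    if not (spectrum.normalised and background.normalised):
        raise ValueError("both spectra must be normalised before subtraction")
    out = spectrum.copy()
    out.intensities = out.intensities - background.intensities
    if np.trapezoid(out.intensities, out.wavelengths) < 0:
        logger.warning("full-window integral negative after background subtraction")
    return out


def preprocess_series(
    series: MeasurementSeries, config: PreprocessConfig | None = None
) -> MeasurementSeries:
    """Dark removal + normalisation (+ background subtraction) of all frames."""
    config = config or PreprocessConfig()
    if series.normalised:
        raise ValueError("series is already normalised")
    frames = series.frame_matrix - np.asarray(config.dark_spectrum, dtype=float)
    factor = (config.reference_integration_time / series.integration_time) * (
        config.reference_power / series.laser_power
    )
    frames = frames * factor
    if config.background is not None:
        bg = config.background
        if not np.array_equal(bg.wavelengths, series.wavelengths):
            raise ValueError("background wavelength grid differs from series")
        if not bg.normalised:
            raise ValueError("background spectrum must be normalised")
        frames = frames - bg.intensities[None, :]
    return dataclasses.replace(
        series,
        frame_matrix=frames,
        integration_time=config.reference_integration_time,
        laser_power=config.reference_power,
        normalised=True,
    )


def flag_anomalous(
    measurements: Sequence[MeasurementSeries],
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Screen replicate measurements of one sample for anomalous intensity.

    A measurement is flagged when its frame-0 full-window integral deviates
    from the replicate median by more than ``anomaly_threshold`` times the
    replicate MAD *and* by more than ``min_relative_deviation`` of the median
    (with few replicates the MAD itself is noise-level, so the relative floor
    encodes that an anomaly must be noticeably higher or lower, not merely
    the largest of a few tightly clustered values).  A single measurement is
    never flagged.  With exactly two replicates no automatic flag is set; a
    discrepancy beyond ``two_replicate_factor`` is logged for manual review.
    """
    config = config or PreprocessConfig()
    n = len(measurements)
    flags = np.zeros(n, dtype=bool)
    if n <= 1:
        return flags
    integrals = np.array(
        [
            np.trapezoid(m.frame_matrix[0], m.wavelengths)
            for m in measurements
        ]
    )
    if n == 2:
        lo, hi = sorted(np.abs(integrals))
        if lo == 0 or hi / lo > config.two_replicate_factor:
            logger.warning(
                "two replicates differ by more than %.2fx "
                "(integrals %.4g vs %.4g); flag manually after review",
                config.two_replicate_factor,
                integrals[0],
                integrals[1],
            )
        return flags
    median = np.median(integrals)
    deviations = np.abs(integrals - median)
    mad = np.median(deviations)
    flags = (deviations > config.anomaly_threshold * mad) & (
        deviations > config.min_relative_deviation * np.abs(median)
    )
    return flags


def select_frames(
    series: MeasurementSeries, timepoints: Sequence[float]
) -> list[Spectrum]:
    """Select the frame nearest (by midpoint timestamp) to each time point.

    Ties break toward the earlier frame (less photobleaching); time point 0
    maps to frame 0.  At most 5 frames may be selected from a series.
    """
    if series.n_frames < 1:
        raise ValueError("series has no frames")
    if len(timepoints) > 5:
        raise ValueError("at most 5 frames may be selected per measurement")
    midpoints = series.frame_times
    out = []
    for tp in timepoints:
        if tp < 0 or tp >= series.duration:
            raise ValueError(
                f"timepoint {tp} ms outside measurement duration "
                f"[0, {series.duration}) ms"
            )
        k = int(np.argmin(np.abs(midpoints - tp)))  # argmin -> earliest on ties
        out.append(series.frame(k))
    return out


def sum_frames(series: MeasurementSeries, frame_range: range) -> Spectrum:
    """Elementwise sum of a frame range; the effective integration time is
    the sum of the per-frame times, keeping normalisation semantics
    consistent."""
    idx = list(frame_range)
    if not idx:
        raise ValueError("empty frame range")
    if idx[0] < 0 or idx[-1] >= series.n_frames:
        raise ValueError("frame range out of bounds")
    summed = series.frame_matrix[idx].sum(axis=0)
    return Spectrum(
        series.wavelengths,
        summed,
        integration_time=series.integration_time * len(idx),
        laser_power=series.laser_power,
        normalised=series.normalised,
    )


def training_mean_spectra(
    frames_per_measurement: Sequence[Sequence[Spectrum]],
) -> list[Spectrum]:
    """Per-timepoint mean spectrum over a training set.

    ``frames_per_measurement[i][j]`` is the j-th selected frame of training
    measurement i; all measurements must provide the same time points.
    """
    if not frames_per_measurement:
        raise ValueError("no training measurements")
    n_timepoints = len(frames_per_measurement[0])
    means = []
    for j in range(n_timepoints):
        stack = np.stack(
            [frames[j].intensities for frames in frames_per_measurement]
        )
        template = frames_per_measurement[0][j]
        means.append(
            Spectrum(
                template.wavelengths,
                stack.mean(axis=0),
                template.integration_time,
                template.laser_power,
                template.normalised,
            )
        )
    return means


def mean_center(
    frames: Sequence[Spectrum], training_means: Sequence[Spectrum]
) -> list[np.ndarray]:
    """Subtract the training mean of each time point from the matching frame.

    Test data must always be centred with *training* means, never its own.
    """
    if len(frames) != len(training_means):
        raise ValueError("one training mean per selected frame is required")
    out = []
    for frame, mean in zip(frames, training_means):
        if not np.array_equal(frame.wavelengths, mean.wavelengths):
            raise ValueError("wavelength grid mismatch in mean-centring")
        out.append(frame.intensities - mean.intensities)
    return out
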