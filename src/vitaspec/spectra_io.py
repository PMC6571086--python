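"""Data model and plain-text I/O for optrode fluorescence measurements.

An *optrode* measurement is a 10-s burst of consecutively acquired emission
spectra (by default 500 frames of 20 ms each) from one stained bacterial
sample.  This module defines the in-memory containers for single spectra,
whole measurement series, sample metadata and persisted calibration models,
plus readers/writers for a human-auditable interchange bundle:

* one CSV table per measurement (``wavelength_nm, frame_0000, frame_0001, ...``)
* one JSON metadata sidecar linking measurements to samples
* calibration models as JSON carrying the primal linear-SVR weights, so a
  saved model is portable and auditable without any binary serialisation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MODEL_FORMAT_VERSION = "vitaspec-model-1"
BUNDLE_FORMAT_VERSION = "vitaspec-bundle-1"

#: Default wavelength grid: a 495-nm longpass filter blocks the excitation
#: line, so the usable emission range starts at 500 nm.
DEFAULT_WAVELENGTHS = np.arange(500.0, 751.0, 1.0)


class BundleFormatError(ValueError):
    """Raised when an interchange bundle or model file is malformed."""


@dataclasses.dataclass
class Spectrum:
    """One wavelength-indexed fluorescence intensity vector.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm.
    intensities
        Fluorescence counts (arbitrary units), same length as ``wavelengths``.
    integration_time
        CCD integration time in ms (> 0).
    laser_power
        Excitation power in mW (> 0).
    normalised
        True once intensities have been rescaled to the reference
        8 ms / 10 mW acquisition conditions.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    integration_time: float = 20.0
    laser_power: float = 10.0
    normalised: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if len(self.wavelengths) != len(self.intensities):
            raise ValueError("wavelengths and intensities differ in length")
        if len(self.wavelengths) >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.integration_time <= 0:
            raise ValueError("integration_time must be > 0")
        if self.laser_power <= 0:
            raise ValueError("laser_power must be > 0")

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.wavelengths.copy(),
            self.intensities.copy(),
            self.integration_time,
            self.laser_power,
            self.normalised,
        )


@dataclasses.dataclass
class MeasurementSeries:
    """The frame series from one optrode measurement of one sample.

    Frames are stored as a single ``(n_frames, n_wavelengths)`` matrix; all
    frames share the wavelength grid and acquisition settings.  Frame ``k``
    (0-based) covers the interval ``[k*frame_duration, (k+1)*frame_duration)``
    ms and its nominal timestamp is the interval midpoint.
    """

    wavelengths: np.ndarray
    frame_matrix: np.ndarray  # (n_frames, n_wavelengths)
    frame_duration: float = 20.0  # ms
    integration_time: float = 20.0  # ms, per frame
    laser_power: float = 10.0  # mW
    measurement_id: str = ""
    sample_id: str = ""
    normalised: bool = False
    anomalous: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.frame_matrix = np.asarray(self.frame_matrix, dtype=float)
        if self.frame_matrix.ndim != 2:
            raise ValueError("frame_matrix must be 2-D (frames x wavelengths)")
        if self.frame_matrix.shape[1] != len(self.wavelengths):
            raise ValueError("frame_matrix width must match wavelength grid")
        if len(self.wavelengths) >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frame_matrix.shape[0]

    @property
    def duration(self) -> float:
        """Total measurement duration in ms (n_frames x frame_duration)."""
        return self.n_frames * self.frame_duration

    @property
    def frame_times(self) -> np.ndarray:
        """Nominal per-frame timestamps (interval midpoints), in ms."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration

    def frame(self, k: int) -> Spectrum:
        if not 0 <= k < self.n_frames:
            raise IndexError(f"frame {k} out of range (n_frames={self.n_frames})")
        return Spectrum(
            self.wavelengths,
            self.frame_matrix[k],
            self.integration_time,
            self.laser_power,
            self.normalised,
        )

    @property
    def frames(self) -> list[Spectrum]:
        return [self.frame(k) for k in range(self.n_frames)]

    def copy(self) -> "MeasurementSeries":
        return dataclasses.replace(
            self,
            wavelengths=self.wavelengths.copy(),
            frame_matrix=self.frame_matrix.copy(),
        )


@dataclasses.dataclass
class SampleRecord:
    """Sample identity, grouping and the flow-cytometry reference value.

    ``experiment_id`` is the grouped-cross-validation key: measurements from
    one wet-lab experiment are never split between folds.  ``f_live_ref`` is
    the reference percentage of live bacteria (flow cytometry in the original
    workflow), in [0, 100].
    """

    sample_id: str
    experiment_id: str
    concentration_class: float  # bacteria/mL, e.g. 1e8 or 1e7
    f_live_ref: float
    measurement_ids: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_live_ref <= 100.0:
            raise ValueError("f_live_ref must be within [0, 100]")
        if self.concentration_class <= 0:
            raise ValueError("concentration_class must be > 0")


@dataclasses.dataclass
class CalibrationModel:
    """A persisted viability calibration.

    For ``model_kind="svr"`` this is a linear epsilon-SVR in primal form: the
    feature vector of a measurement is the concatenation, in ``timepoints``
    order, of its mean-centred selected frames, and the prediction is
    ``weights . features + intercept`` (percent live).
    """

    model_kind: str  # {"dye_ratio", "adjusted_dye_ratio", "svr"}
    timepoints: list[float]  # ms offsets; first is 0 (frame 0)
    wavelengths: np.ndarray
    mean_spectra: list[np.ndarray]  # training mean per timepoint
    weights: np.ndarray
    intercept: float
    C: float
    epsilon: float
    concentration_class: float
    version: str = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.mean_spectra = [np.asarray(m, dtype=float) for m in self.mean_spectra]
        if sorted(self.timepoints) != list(self.timepoints):
            raise ValueError("timepoints must be sorted ascending")
        if len(self.mean_spectra) != len(self.timepoints):
            raise ValueError("one mean spectrum per timepoint is required")
        n_expected = len(self.timepoints) * len(self.wavelengths)
        if self.weights.shape != (n_expected,):
            raise ValueError(
                f"weights must have length n_timepoints*n_wavelengths={n_expected}"
            )
        for m in self.mean_spectra:
            if m.shape != self.wavelengths.shape:
                raise ValueError("mean spectra must match the wavelength grid")

    def features_from_frames(self, frames: Sequence[Spectrum]) -> np.ndarray:
        """Mean-centre and concatenate already-selected frames."""
        if len(frames) != len(self.timepoints):
            raise ValueError("one frame per model timepoint is required")
        blocks = []
        for frame, mean in zip(frames, self.mean_spectra):
            if not np.array_equal(frame.wavelengths, self.wavelengths):
                raise ValueError("frame wavelength grid differs from the model's")
            blocks.append(frame.intensities - mean)
        return np.concatenate(blocks)

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights + self.intercept

    def predict_frames(self, frames: Sequence[Spectrum]) -> float:
        return float(self.features_from_frames(frames) @ self.weights + self.intercept)


# ---------------------------------------------------------------------------
# measurement bundles
# ---------------------------------------------------------------------------

def _spectra_filename(measurement_id: str) -> str:
    return f"spectra_{measurement_id}.csv"


def write_measurement_bundle(
    measurements: Sequence[MeasurementSeries],
    samples: Sequence[SampleRecord],
    path: str | Path,
) -> Path:
    """Write a bundle directory readable by :func:`read_measurement_bundle`.

    Column and record ordering is deterministic (input order for rows,
    frame order for columns), so write-read-write is byte-stable.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    known_measurements = {m.measurement_id for m in measurements}
    for s in samples:
        for mid in s.measurement_ids:
            if mid not in known_measurements:
                raise BundleFormatError(
                    f"sample {s.sample_id!r} references unknown measurement {mid!r}"
                )
    meta = {
        "version": BUNDLE_FORMAT_VERSION,
        "samples": [
            {
                "sample_id": s.sample_id,
                "experiment_id": s.experiment_id,
                "concentration_class": s.concentration_class,
                "f_live_ref": s.f_live_ref,
                "measurement_ids": list(s.measurement_ids),
            }
            for s in samples
        ],
        "measurements": [
            {
                "measurement_id": m.measurement_id,
                "sample_id": m.sample_id,
                "n_frames": m.n_frames,
                "frame_duration_ms": m.frame_duration,
                "integration_time_ms": m.integration_time,
                "laser_power_mw": m.laser_power,
                "normalised": m.normalised,
                "spectra_file": _spectra_filename(m.measurement_id),
            }
            for m in measurements
        ],
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    for m in measurements:
        header = "wavelength_nm," + ",".join(
            f"frame_{k:04d}" for k in range(m.n_frames)
        )
        table = np.column_stack([m.wavelengths, m.frame_matrix.T])
        np.savetxt(
            path / _spectra_filename(m.measurement_id),
            table,
            delimiter=",",
            header=header,
            comments="",
            fmt="%.10g",
        )
    return path


def read_measurement_bundle(
    path: str | Path,
) -> tuple[list[MeasurementSeries], list[SampleRecord]]:
    """Read a bundle directory written by :func:`write_measurement_bundle`."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise BundleFormatError(f"no metadata.json in bundle {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("version") != BUNDLE_FORMAT_VERSION:
        raise BundleFormatError(
            f"unsupported bundle version {meta.get('version')!r}"
        )
    measurements: list[MeasurementSeries] = []
    for rec in meta["measurements"]:
        spectra_path = path / rec["spectra_file"]
        if not spectra_path.exists():
            raise BundleFormatError(
                f"spectra file missing for measurement {rec['measurement_id']!r}"
            )
        table = pd.read_csv(spectra_path)
        if table.columns[0] != "wavelength_nm":
            raise BundleFormatError(
                f"{spectra_path.name}: first column must be wavelength_nm"
            )
        wavelengths = table["wavelength_nm"].to_numpy(dtype=float)
        if len(wavelengths) >= 2 and not np.all(np.diff(wavelengths) > 0):
            raise BundleFormatError(f"{spectra_path.name}: non-monotone wavelengths")
        frame_matrix = table.iloc[:, 1:].to_numpy(dtype=float).T
        if frame_matrix.shape[0] != rec["n_frames"]:
            raise BundleFormatError(
                f"measurement {rec['measurement_id']!r}: "
                f"{frame_matrix.shape[0]} frames on disk, "
                f"{rec['n_frames']} in metadata"
            )
        measurements.append(
            MeasurementSeries(
                wavelengths=wavelengths,
                frame_matrix=frame_matrix,
                frame_duration=rec["frame_duration_ms"],
                integration_time=rec["integration_time_ms"],
                laser_power=rec["laser_power_mw"],
                measurement_id=rec["measurement_id"],
                sample_id=rec["sample_id"],
                normalised=rec.get("normalised", False),
            )
        )
    known = {m.measurement_id for m in measurements}
    samples: list[SampleRecord] = []
    for rec in meta["samples"]:
        missing = [mid for mid in rec["measurement_ids"] if mid not in known]
        if missing:
            raise BundleFormatError(
                f"sample {rec['sample_id']!r} references missing measurement(s) "
                f"{missing}"
            )
        samples.append(
            SampleRecord(
                sample_id=rec["sample_id"],
                experiment_id=rec["experiment_id"],
                concentration_class=rec["concentration_class"],
                f_live_ref=rec["f_live_ref"],
                measurement_ids=list(rec["measurement_ids"]),
            )
        )
    return measurements, samples


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model: CalibrationModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "version": model.version,
        "kind": model.model_kind,
        "timepoints_ms": list(model.timepoints),
        "wavelengths_nm": model.wavelengths.tolist(),
        "mean_spectra": [m.tolist() for m in model.mean_spectra],
        "weights": model.weights.tolist(),
        "intercept": model.intercept,
        "C": model.C,
        "epsilon": model.epsilon,
        "concentration_class": model.concentration_class,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_model(path: str | Path) -> CalibrationModel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise BundleFormatError(f"truncated or invalid model file {path}") from exc
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise BundleFormatError(
            f"model version tag {payload.get('version')!r} is not "
            f"{MODEL_FORMAT_VERSION!r}"
        )
    return CalibrationModel(
        model_kind=payload["kind"],
        timepoints=list(payload["timepoints_ms"]),
        wavelengths=np.asarray(payload["wavelengths_nm"], dtype=float),
        mean_spectra=[np.asarray(m, dtype=float) for m in payload["mean_spectra"]],
        weights=np.asarray(payload["weights"], dtype=float),
        intercept=float(payload["intercept"]),
        C=float(payload["C"]),
        epsilon=float(payload["epsilon"]),
        concentration_class=float(payload["concentration_class"]),
        version=payload["version"],
    )
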