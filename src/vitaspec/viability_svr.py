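"""Epsilon-SVR viability calibration with grouped cross-validation.

Features are mean-centred spectra selected at analysis time points and
concatenated per measurement ("single-spectrum" = frame 0 only,
"multi-spectra" = frame 0 plus frames at photobleaching half-lives).  Model
selection is by group K-fold cross-validation (GKCV): folds are whole
experiments, so within-experiment correlation never leaks between training
and held-out sets.  Candidate time-point sets are first screened at default
hyperparameters (C=1, epsilon=0.1); the chosen set's C and epsilon are then
tuned by exhaustive grid search, minimising the RMSE pooled over all
held-out predictions.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from . import preprocessing
from .spectra_io import CalibrationModel, MeasurementSeries, SampleRecord, Spectrum

#: Default hyperparameter grid; spans the typical optimum region for
#: percent-scale targets on mean-centred spectral features.
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "C": (0.01, 0.1, 0.5, 1.0, 10.0, 100.0),
    "epsilon": (0.001, 0.01, 0.1, 1.0),
}

#: Screening defaults used to rank candidate time-point sets.
DEFAULT_SCREENING_PARAMS = {"C": 1.0, "epsilon": 0.1}

#: Convergence tolerance passed to libsvm; tight enough that the primal
#: weight representation reproduces trainer predictions.
SVR_TOL = 1e-7


@dataclasses.dataclass
class SVRConfig:
    """Hyperparameters and candidate time-point sets for calibration."""

    C: float = 1.0
    epsilon: float = 0.1
    candidate_timepoint_sets: tuple[tuple[float, ...], ...] = ((0.0,),)
    grid: Mapping[str, Sequence[float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GRID)
    )

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        for tps in self.candidate_timepoint_sets:
            if not tps or tps[0] != 0.0:
                raise ValueError("every candidate set must start with timepoint 0")


def make_svr(C: float, epsilon: float) -> SVR:
    return SVR(kernel="linear", C=C, epsilon=epsilon, tol=SVR_TOL)


def compute_training_means(
    series_list: Sequence[MeasurementSeries], timepoints: Sequence[float]
) -> list[Spectrum]:
    """Mean spectrum per time point over a training set of measurements."""
    selected = [preprocessing.select_frames(s, timepoints) for s in series_list]
    return preprocessing.training_mean_spectra(selected)


def build_features(
    series_list: Sequence[MeasurementSeries],
    timepoints: Sequence[float],
    training_means: Sequence[Spectrum],
) -> np.ndarray:
    """One row per measurement: mean-centred selected frames concatenated in
    time-point order (row length = n_timepoints * n_wavelengths)."""
    rows = []
    for series in series_list:
        frames = preprocessing.select_frames(series, timepoints)
        centred = preprocessing.mean_center(frames, training_means)
        rows.append(np.concatenate(centred))
    return np.vstack(rows)


def targets_and_groups(
    series_list: Sequence[MeasurementSeries], samples: Sequence[SampleRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Reference percent-live target and experiment group per measurement."""
    by_sample = {s.sample_id: s for s in samples}
    y, groups = [], []
    for m in series_list:
        if m.sample_id not in by_sample:
            raise KeyError(
                f"measurement {m.measurement_id!r} references unknown sample "
                f"{m.sample_id!r}"
            )
        rec = by_sample[m.sample_id]
        y.append(rec.f_live_ref)
        groups.append(rec.experiment_id)
    return np.asarray(y, dtype=float), np.asarray(groups, dtype=object)


def gkcv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    C: float,
    epsilon: float,
) -> np.ndarray:
    """Held-out predictions from leave-one-experiment-out cross-validation.

    Each of the M folds holds out exactly one experiment; folds are iterated
    in sorted group order for determinism.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    unique = sorted(set(groups.tolist()))
    if len(unique) < 2:
        raise ValueError("grouped cross-validation needs at least 2 groups")
    pred = np.empty_like(y)
    for g in unique:
        held = groups == g
        model = make_svr(C, epsilon).fit(X[~held], y[~held])
        pred[held] = model.predict(X[held])
    return pred


def gkcv_rmse(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    C: float,
    epsilon: float,
) -> float:
    """RMSE pooled over all held-out predictions of the GKCV folds."""
    pred = gkcv_predictions(X, y, groups, C, epsilon)
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def screen_timepoint_sets(
    features_by_set: Sequence[np.ndarray],
    candidate_sets: Sequence[Sequence[float]],
    y: np.ndarray,
    groups: np.ndarray,
    C: float = DEFAULT_SCREENING_PARAMS["C"],
    epsilon: float = DEFAULT_SCREENING_PARAMS["epsilon"],
) -> tuple[pd.DataFrame, int]:
    """Rank candidate time-point sets by GKCV RMSE at default parameters.

    Returns the full screening table and the index of the chosen set; ties
    break toward fewer time points, then earlier candidate order.
    """
    if len(features_by_set) != len(candidate_sets):
        raise ValueError("one feature matrix per candidate set is required")
    if not candidate_sets:
        raise ValueError("at least one candidate set is required")
    rows = []
    for i, (X, tps) in enumerate(zip(features_by_set, candidate_sets)):
        rows.append(
            {
                "candidate_index": i,
                "timepoints_ms": list(tps),
                "n_timepoints": len(tps),
                "gkcv_rmse": gkcv_rmse(X, y, groups, C, epsilon),
            }
        )
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(rows)),
        key=lambda i: (rows[i]["gkcv_rmse"], rows[i]["n_timepoints"], i),
    )
    return table, order[0]


def tune_and_train(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    grid: Mapping[str, Sequence[float]],
    timepoints: Sequence[float],
    training_means: Sequence[Spectrum],
    concentration_class: float = 0.0,
) -> tuple[CalibrationModel, pd.DataFrame]:
    """Exhaustive (C, epsilon) grid search by GKCV, then refit on all data.

    The refit linear SVR is persisted in primal form (weights + intercept)
    together with the preprocessing state (time points and training means).
    Grid ties break toward the earlier grid entry (C-major order).
    """
    Cs = list(grid["C"])
    epsilons = list(grid["epsilon"])
    if not Cs or not epsilons:
        raise ValueError("grid must contain at least one C and one epsilon")
    rows = []
    best = None
    for C in Cs:
        for eps in epsilons:
            rmse = gkcv_rmse(X, y, groups, C, eps)
            rows.append({"C": C, "epsilon": eps, "gkcv_rmse": rmse})
            if best is None or rmse < best["gkcv_rmse"]:
                best = rows[-1]
    final = make_svr(best["C"], best["epsilon"]).fit(X, y)
    wavelengths = training_means[0].wavelengths
    model = CalibrationModel(
        model_kind="svr",
        timepoints=list(timepoints),
        wavelengths=wavelengths,
        mean_spectra=[m.intensities for m in training_means],
        weights=final.coef_.ravel(),
        intercept=float(final.intercept_[0]),
        C=float(best["C"]),
        epsilon=float(best["epsilon"]),
        concentration_class=concentration_class,
    )
    return model, pd.DataFrame(rows)


def is_valid_prediction(value: float) -> bool:
    """Percent-live predictions outside [0, 100] are invalid; the boundary
    values 0 and 100 are valid."""
    return 0.0 <= value <= 100.0


def predict_samples(
    model: CalibrationModel,
    measurements: Sequence[MeasurementSeries],
    samples: Sequence[SampleRecord],
) -> pd.DataFrame:
    """Per-sample predictions: replicate measurement predictions averaged,
    then flagged invalid when the average is negative or above 100."""
    by_id = {m.measurement_id: m for m in measurements}
    rows = []
    for rec in samples:
        values = []
        for mid in rec.measurement_ids:
            if mid not in by_id:
                raise KeyError(f"sample {rec.sample_id!r}: no measurement {mid!r}")
            series = by_id[mid]
            frames = preprocessing.select_frames(series, model.timepoints)
            values.append(model.predict_frames(frames))
        prediction = float(np.mean(values))
        rows.append(
            {
                "sample_id": rec.sample_id,
                "f_live_ref": rec.f_live_ref,
                "prediction": prediction,
                "valid": is_valid_prediction(prediction),
                "n_measurements": len(values),
                "per_measurement": values,
            }
        )
    return pd.DataFrame(rows)
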