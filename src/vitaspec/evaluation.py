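"""Validation metrics: agreement with the reference method and diagnostics.

All regression metrics are computed about the 1:1 line (a viability
predictor should reproduce the reference value, not merely correlate with
it), so R^2 = 1 - SS_res/SS_tot can be negative when predictions are worse
than the reference mean.  "Standard error" is the residual standard
deviation about the 1:1 line with an n-1 denominator; the +/- 2 SE band
around the 1:1 line is the acceptance region used for the within-2SE
fraction.  Method agreement is summarised Bland-Altman style (bias and 95%
limits of agreement) with a Shapiro-Wilk normality check on the
differences.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .spectra_io import Spectrum


@dataclasses.dataclass
class RegressionMetrics:
    rmse: float
    explained_variance: float
    r_squared: float
    standard_error: float


def regression_metrics(
    predictions: Sequence[float], references: Sequence[float]
) -> RegressionMetrics:
    """RMSE, explained variance, R^2 and standard error about the 1:1 line.

    explained variance = 1 - Var(ref - pred)/Var(ref) ignores a constant
    offset; RMSE, R^2 and SE do not.
    """
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("predictions and references must be 1-D, equal length")
    n = len(pred)
    if n < 2:
        raise ValueError("at least 2 points are required")
    resid = ref - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance references: explained variance undefined")
    r_squared = 1.0 - ss_res / ss_tot
    explained_variance = 1.0 - float(np.var(resid)) / float(np.var(ref))
    standard_error = float(np.sqrt(ss_res / (n - 1)))
    return RegressionMetrics(rmse, explained_variance, r_squared, standard_error)


def within_2se_fraction(
    predictions: Sequence[float],
    references: Sequence[float],
    standard_error: float,
) -> float:
    """Percent of samples with |prediction - reference| <= 2 SE."""
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    inside = np.abs(pred - ref) <= 2.0 * standard_error
    return float(100.0 * inside.mean())


@dataclasses.dataclass
class BlandAltman:
    bias: float  # mean(reference - prediction)
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    shapiro_p: float  # NaN when undefined (n < 3 or constant differences)


def bland_altman(
    predictions: Sequence[float], references: Sequence[float]
) -> BlandAltman:
    """Bland-Altman agreement between predictions and the reference method.

    Differences are reference - prediction; limits of agreement are
    bias +/- 1.96 sd (95%, sd with ddof=1).
    """
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("predictions and references must be 1-D, equal length")
    d = ref - pred
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    if len(d) >= 3 and np.ptp(d) > 0:
        shapiro_p = float(stats.shapiro(d).pvalue)
    else:
        shapiro_p = float("nan")
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, shapiro_p)


@dataclasses.dataclass
class ConcentrationGate:
    """Nearest-centroid classifier in the first-two-PC score space.

    Routes blind samples to the concentration class whose calibration model
    should analyse them; trained on first-frame spectra.
    """

    mean_spectrum: np.ndarray
    components: np.ndarray  # (2, n_wavelengths)
    centroids: dict[float, np.ndarray]  # class -> 2-D score centroid
    training_scores: np.ndarray
    training_labels: np.ndarray

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_spectrum) @ self.components.T

    def classify(self, X: np.ndarray) -> np.ndarray:
        scores = self.scores(X)
        classes = sorted(self.centroids)
        dists = np.stack(
            [np.linalg.norm(scores - self.centroids[c], axis=1) for c in classes]
        )
        return np.asarray(classes, dtype=float)[np.argmin(dists, axis=0)]


def _first_frame_matrix(spectra: Sequence[Spectrum] | np.ndarray) -> np.ndarray:
    if isinstance(spectra, np.ndarray):
        return np.atleast_2d(np.asarray(spectra, dtype=float))
    return np.vstack([s.intensities for s in spectra])


def pca_concentration_gate(
    spectra: Sequence[Spectrum] | np.ndarray,
    labels: Sequence[float],
) -> ConcentrationGate:
    """Fit the PCA concentration gate on mean-centred first-frame spectra.

    Uses exactly two principal components.  A single training class yields a
    constant classifier (with a warning).
    """
    X = _first_frame_matrix(spectra)
    y = np.asarray(labels, dtype=float)
    if len(X) != len(y):
        raise ValueError("one label per spectrum is required")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        warnings.warn(
            "only one concentration class in training data; "
            "the gate classifies everything to it",
            stacklevel=2,
        )
    n_comp = min(2, X.shape[0] - 1, X.shape[1]) or 1
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    if scores.shape[1] < 2:  # degenerate: pad with a zero coordinate
        scores = np.column_stack([scores, np.zeros(len(scores))])
        components = np.vstack([pca.components_, np.zeros_like(pca.mean_)])
    else:
        components = pca.components_
    centroids = {c: scores[y == c].mean(axis=0) for c in classes}
    return ConcentrationGate(
        mean_spectrum=pca.mean_,
        components=components,
        centroids=centroids,
        training_scores=scores,
        training_labels=y,
    )
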