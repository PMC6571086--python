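import numpy as np
import pytest

from vitaspec import preprocessing
from vitaspec.spectra_io import MeasurementSeries, SampleRecord, Spectrum
from vitaspec.synthetic_data import GeneratorDesign, generate_dataset


@pytest.fixture(scope="session")
def ideal_dataset():
    """Noise-free ideal-staining dataset (one class, 3 experiments, 2 reps),
    preprocessed (dark removal + normalisation)."""
    design = GeneratorDesign.ideal(
        n_experiments={1e8: 3}, replicates_per_sample=2, seed=11
    )
    dataset = generate_dataset(design)
    processed = [preprocessing.preprocess_series(m) for m in dataset.measurements]
    return processed, dataset.samples, dataset


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise single-class dataset at study-condition settings."""
    design = GeneratorDesign(
        concentration_classes=(1e8,),
        n_experiments={1e8: 3},
        unbound_syto9={1e8: 80.0},
        unbound_pi={1e8: 120.0},
        seed=5,
    )
    dataset = generate_dataset(design)
    processed = [preprocessing.preprocess_series(m) for m in dataset.measurements]
    return processed, dataset.samples, dataset


def make_series(
    frame_matrix,
    wavelengths=None,
    frame_duration=20.0,
    integration_time=20.0,
    measurement_id="m0",
    sample_id="s0",
    normalised=False,
):
    frame_matrix = np.atleast_2d(np.asarray(frame_matrix, dtype=float))
    if wavelengths is None:
        wavelengths = np.arange(500.0, 500.0 + frame_matrix.shape[1], 1.0)
    return MeasurementSeries(
        wavelengths=np.asarray(wavelengths, dtype=float),
        frame_matrix=frame_matrix,
        frame_duration=frame_duration,
        integration_time=integration_time,
        measurement_id=measurement_id,
        sample_id=sample_id,
        normalised=normalised,
    )


def make_spectrum(intensities, wavelengths=None, **kwargs):
    intensities = np.asarray(intensities, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(500.0, 500.0 + len(intensities), 1.0)
    return Spectrum(np.asarray(wavelengths, dtype=float), intensities, **kwargs)


def make_sample(sample_id="s0", experiment_id="E0", f_live_ref=50.0, mids=("m0",)):
    return SampleRecord(
        sample_id=sample_id,
        experiment_id=experiment_id,
        concentration_class=1e8,
        f_live_ref=f_live_ref,
        measurement_ids=list(mids),
    )
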