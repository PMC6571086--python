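"""Synthetic optrode measurement generator.

Emulates the statistical structure of time-resolved dual-stain (SYTO 9 +
propidium iodide) fluorescence measurements of live/dead bacterial mixtures:

* four emission components — each dye in a *bound* and an *unbound* pool —
  modelled as Gaussian peaks (SYTO 9 near 519 nm with a subtle bound-state
  shoulder at 501 nm, PI near 617 nm);
* component amplitudes that depend on the live fraction f (in percent) and
  the total concentration class: bound SYTO 9 ~ alpha1*L + alpha2*D and
  bound PI ~ gamma*D + gamma'*L with L = f/100, D = 1 - f/100, both scaled
  by the concentration; unbound amplitudes are concentration-independent
  (the same dye volume is added to every sample), so dilute samples carry a
  larger unbound:bound ratio;
* per-component double-exponential photobleaching calibrated to target
  half-lives (defaults: mB-SYTO9 1244, mU-SYTO9 1472, mB-PI 1124,
  mU-PI 1084 ms);
* additive dark noise, shot-like signal-dependent noise, a multiplicative
  log-normal experiment factor shared within each experiment, occasional
  anomalous measurements, and Gaussian error on the flow-cytometry
  reference value.

Amplitude coefficients are expressed in *window-integrated* units: each
component's unit spectrum is internally rescaled so its trapezoid integral
over its own dye window equals 1.  In "ideal mode" (no unbound dye, no
cross-staining, no noise, one shared bleach curve) this makes the adjusted
dye ratio equal to the live percentage as an algebraic identity on the
discrete grid.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
import numpy as np
import pandas as pd

from .dye_ratios import PI_WINDOW, SYTO9_WINDOW
from .photobleaching import curve_half_life, double_exponential
from .spectra_io import (
    DEFAULT_WAVELENGTHS,
    MeasurementSeries,
    SampleRecord,
    write_measurement_bundle,
)

#: Target photobleaching half-lives (ms) used as generator truth.
DEFAULT_HALF_LIVES = {
    ("SYTO9", "bound"): 1244.0,
    ("SYTO9", "unbound"): 1472.0,
    ("PI", "bound"): 1124.0,
    ("PI", "unbound"): 1084.0,
}


@dataclasses.dataclass
class EmissionComponent:
    """One dye/state emission component.

    ``bleach_params = (A1, tau1, A2, tau2)`` define the double-exponential
    photobleaching curve, normalised so the curve starts at 1.
    """

    dye: str  # "SYTO9" | "PI"
    state: str  # "bound" | "unbound"
    peak_centers: tuple[float, ...]
    peak_widths: tuple[float, ...]
    relative_weights: tuple[float, ...]
    bleach_params: tuple[float, float, float, float]
    target_half_life: float | None = None

    def __post_init__(self) -> None:
        if len(self.peak_centers) != len(self.peak_widths) or len(
            self.peak_centers
        ) != len(self.relative_weights):
            raise ValueError("peak centers/widths/weights must align")
        if any(w <= 0 for w in self.peak_widths):
            raise ValueError("peak widths must be positive")
        if any(a < 0 for a in self.relative_weights):
            raise ValueError("relative weights must be non-negative")
        a1, t1, a2, t2 = self.bleach_params
        if a1 < 0 or a2 < 0 or t1 <= 0 or t2 <= 0:
            raise ValueError("bleach curve must be non-negative and non-increasing")

    @classmethod
    def with_half_life(
        cls,
        dye: str,
        state: str,
        peak_centers: tuple[float, ...],
        peak_widths: tuple[float, ...],
        relative_weights: tuple[float, ...],
        half_life: float,
        fast_fraction: float = 0.6,
        tau_ratio: float = 4.0,
    ) -> "EmissionComponent":
        """Build a component whose bleach curve has the requested half-life.

        The curve shape is ``f*exp(-t/tau1) + (1-f)*exp(-t/(r*tau1))``; its
        half-life scales linearly with tau1, so tau1 is solved in closed
        form from the unit-tau1 half-life.
        """
        unit_hl = curve_half_life(fast_fraction, 1.0, 1.0 - fast_fraction, tau_ratio)
        tau1 = half_life / unit_hl
        return cls(
            dye=dye,
            state=state,
            peak_centers=peak_centers,
            peak_widths=peak_widths,
            relative_weights=relative_weights,
            bleach_params=(fast_fraction, tau1, 1.0 - fast_fraction, tau_ratio * tau1),
            target_half_life=half_life,
        )

    def bleach_curve(self, times_ms: np.ndarray) -> np.ndarray:
        a1, t1, a2, t2 = self.bleach_params
        return np.asarray(double_exponential(times_ms, a1, t1, a2, t2)) / (a1 + a2)

    @property
    def window(self) -> tuple[float, float]:
        return SYTO9_WINDOW if self.dye == "SYTO9" else PI_WINDOW


def default_components(shared_bleach: bool = False) -> list[EmissionComponent]:
    """The four default dye/state components.

    With ``shared_bleach=True`` every component gets the bound-SYTO 9 bleach
    curve, so ratios of window integrals are time-invariant (ideal mode).
    """
    specs = [
        ("SYTO9", "bound", (519.0, 501.0), (7.0, 3.0), (1.0, 0.15)),
        ("SYTO9", "unbound", (521.0,), (8.0,), (1.0,)),
        ("PI", "bound", (617.0,), (10.0,), (1.0,)),
        ("PI", "unbound", (620.0,), (11.0,), (1.0,)),
    ]
    components = []
    for dye, state, centers, widths, weights in specs:
        hl = (
            DEFAULT_HALF_LIVES[("SYTO9", "bound")]
            if shared_bleach
            else DEFAULT_HALF_LIVES[(dye, state)]
        )
        components.append(
            EmissionComponent.with_half_life(dye, state, centers, widths, weights, hl)
        )
    return components


def component_spectrum(
    component: EmissionComponent, wavelengths: np.ndarray
) -> np.ndarray:
    """Unit-amplitude emission profile of a component on a wavelength grid.

    A sum of Gaussians normalised to peak amplitude 1 (all-zero if every
    relative weight is zero).  Peaks outside the grid are an error, except
    that secondary peaks truncated by the grid's short-wavelength edge (the
    495-nm longpass filter region) are permitted.
    """
    wl = np.asarray(wavelengths, dtype=float)
    main_center = component.peak_centers[
        int(np.argmax(component.relative_weights))
    ]
    if not wl[0] <= main_center <= wl[-1]:
        raise ValueError(
            f"peak center {main_center} nm outside grid [{wl[0]}, {wl[-1]}] nm"
        )
    profile = np.zeros_like(wl)
    for center, width, weight in zip(
        component.peak_centers, component.peak_widths, component.relative_weights
    ):
        profile += weight * np.exp(-0.5 * ((wl - center) / width) ** 2)
    peak = profile.max()
    if peak > 0:
        profile = profile / peak
    return profile


@dataclasses.dataclass
class GeneratorDesign:
    """Study design and noise model for a synthetic dataset.

    Defaults follow the original study layout: live fractions
    0–100% in 8 steps, concentration classes 1e8 and 1e7 bacteria/mL with 4
    and 3 experiments respectively, three replicate optrode measurements per
    sample, 500 frames of 20 ms.
    """

    live_fractions: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 25.0, 50.0, 75.0, 100.0)
    concentration_classes: tuple[float, ...] = (1e8, 1e7)
    n_experiments: dict[float, int] = dataclasses.field(
        default_factory=lambda: {1e8: 4, 1e7: 3}
    )
    replicates_per_sample: int = 3
    # amplitude model (window-integrated units at the reference concentration)
    alpha1: float = 1000.0  # live -> bound SYTO 9
    alpha2: float = 250.0  # dead -> bound SYTO 9 (cross-staining)
    gamma: float = 1000.0  # dead -> bound PI
    gamma_prime: float = 60.0  # live -> bound PI
    unbound_syto9: dict[float, float] = dataclasses.field(
        default_factory=lambda: {1e8: 80.0, 1e7: 80.0}
    )
    unbound_pi: dict[float, float] = dataclasses.field(
        default_factory=lambda: {1e8: 120.0, 1e7: 120.0}
    )
    pi_enhancement: float = 0.0  # optional SYTO9->PI enhancement, off by default
    reference_concentration: float = 1e8
    # noise model
    experiment_sd: float = 0.10  # log-scale multiplicative spread
    dark_noise_sd: float = 2.0  # counts per wavelength per frame
    shot_noise_scale: float = 0.5  # sd = scale * sqrt(intensity)
    anomaly_prob: float = 0.02
    anomaly_factor: float = 3.0
    fcm_error_sd: float = 1.5  # percent-live error on the reference value
    # acquisition
    n_frames: int = 500
    frame_duration: float = 20.0  # ms
    integration_time: float = 20.0  # ms
    laser_power: float = 10.0  # mW
    wavelengths: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_WAVELENGTHS.copy()
    )
    components: list[EmissionComponent] = dataclasses.field(
        default_factory=default_components
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= f <= 100 for f in self.live_fractions):
            raise ValueError("live fractions must be in [0, 100]")
        for sd in (
            self.experiment_sd,
            self.dark_noise_sd,
            self.shot_noise_scale,
            self.fcm_error_sd,
        ):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.anomaly_prob <= 1:
            raise ValueError("anomaly_prob must be in [0, 1]")
        for cls in self.concentration_classes:
            if cls not in self.n_experiments:
                raise ValueError(f"n_experiments missing class {cls}")
            if cls not in self.unbound_syto9 or cls not in self.unbound_pi:
                raise ValueError(f"unbound amplitudes missing class {cls}")

    @classmethod
    def ideal(cls, **overrides) -> "GeneratorDesign":
        """Noise-free ideal-staining design.

        alpha2 = gamma' = 0, alpha1 = gamma, no unbound dye, zero noise, and
        a single shared bleach curve; the adjusted dye ratio then equals the
        live percentage to machine precision.
        """
        classes = overrides.pop("concentration_classes", (1e8,))
        defaults = dict(
            concentration_classes=classes,
            n_experiments={c: 3 for c in classes},
            alpha2=0.0,
            gamma_prime=0.0,
            unbound_syto9={c: 0.0 for c in classes},
            unbound_pi={c: 0.0 for c in classes},
            experiment_sd=0.0,
            dark_noise_sd=0.0,
            shot_noise_scale=0.0,
            anomaly_prob=0.0,
            fcm_error_sd=0.0,
            components=default_components(shared_bleach=True),
        )
        defaults.update(overrides)
        return cls(**defaults)


def _window_unit_shapes(design: GeneratorDesign) -> list[np.ndarray]:
    """Component profiles rescaled to unit integral over their dye window."""
    wl = design.wavelengths
    shapes = []
    for comp in design.components:
        profile = component_spectrum(comp, wl)
        lo, hi = comp.window
        mask = (wl >= lo) & (wl <= hi)
        norm = np.trapezoid(profile[mask], wl[mask])
        shapes.append(profile / norm if norm > 0 else profile)
    return shapes


def _component_amplitudes(
    design: GeneratorDesign, f_live: float, concentration_class: float
) -> list[float]:
    live = f_live / 100.0
    dead = 1.0 - live
    scale = concentration_class / design.reference_concentration
    amps = []
    for comp in design.components:
        if comp.dye == "SYTO9" and comp.state == "bound":
            amp = (design.alpha1 * live + design.alpha2 * dead) * scale
        elif comp.dye == "SYTO9" and comp.state == "unbound":
            amp = design.unbound_syto9[concentration_class]
        elif comp.dye == "PI" and comp.state == "bound":
            amp = (design.gamma * dead + design.gamma_prime * live) * scale
            amp *= 1.0 + design.pi_enhancement * live
        else:
            amp = design.unbound_pi[concentration_class]
        amps.append(amp)
    return amps


def simulate_measurement(
    f_live: float,
    concentration_class: float,
    design: GeneratorDesign,
    experiment_factor: float = 1.0,
    seed: int | np.random.Generator = 0,
    measurement_id: str = "m0",
    sample_id: str = "s0",
) -> tuple[MeasurementSeries, bool]:
    """Simulate one optrode measurement.

    Returns the series and the ground-truth anomaly tag.  The tag is *not*
    stored on the series (``anomalous`` stays False): the analysis pipeline
    must rediscover anomalies itself.
    """
    if not 0 <= f_live <= 100:
        raise ValueError("f_live must be in [0, 100]")
    if concentration_class not in design.concentration_classes:
        raise ValueError(f"unknown concentration class {concentration_class}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    times = (np.arange(design.n_frames) + 0.5) * design.frame_duration
    shapes = _window_unit_shapes(design)
    amps = _component_amplitudes(design, f_live, concentration_class)
    signal = np.zeros((design.n_frames, len(design.wavelengths)))
    for comp, shape, amp in zip(design.components, shapes, amps):
        if amp == 0:
            continue
        signal += amp * comp.bleach_curve(times)[:, None] * shape[None, :]
    anomalous = bool(rng.uniform() < design.anomaly_prob)
    total = signal
    if design.dark_noise_sd > 0:
        total = total + rng.normal(0.0, design.dark_noise_sd, signal.shape)
    if design.shot_noise_scale > 0:
        total = total + rng.standard_normal(
            signal.shape
        ) * design.shot_noise_scale * np.sqrt(np.maximum(signal, 0.0))
    total = total * experiment_factor
    if anomalous:
        total = total * design.anomaly_factor
    series = MeasurementSeries(
        wavelengths=design.wavelengths,
        frame_matrix=total,
        frame_duration=design.frame_duration,
        integration_time=design.integration_time,
        laser_power=design.laser_power,
        measurement_id=measurement_id,
        sample_id=sample_id,
    )
    return series, anomalous


def _sub_seed(*parts: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])


def _id_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf8"))


def class_label(concentration_class: float) -> str:
    return f"c{int(round(np.log10(concentration_class)))}"


@dataclasses.dataclass
class SyntheticDataset:
    """A generated bundle plus its ground truth."""

    measurements: list[MeasurementSeries]
    samples: list[SampleRecord]
    truth: pd.DataFrame  # per-measurement: true f, anomaly tag, experiment factor
    design: GeneratorDesign

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        write_measurement_bundle(self.measurements, self.samples, path)
        (path / "truth.json").write_text(
            self.truth.to_json(orient="records", indent=1)
        )
        return path


def generate_dataset(design: GeneratorDesign) -> SyntheticDataset:
    """Generate one SampleRecord per (fraction x class x experiment), each
    with ``replicates_per_sample`` measurements.

    Reproducibility: every random stream is derived deterministically from
    ``design.seed`` plus stable identifiers (class/experiment for the
    experiment factor, sample id hash and replicate index for measurements),
    so regenerating with the same design is bit-identical and individual
    measurements can be re-simulated in isolation.
    """
    measurements: list[MeasurementSeries] = []
    samples: list[SampleRecord] = []
    truth_rows = []
    for ci, conc in enumerate(design.concentration_classes):
        for exp in range(design.n_experiments[conc]):
            experiment_id = f"{class_label(conc)}-E{exp}"
            rng_exp = np.random.default_rng(_sub_seed(design.seed, 101, ci, exp))
            factor = (
                float(np.exp(rng_exp.normal(0.0, design.experiment_sd)))
                if design.experiment_sd > 0
                else 1.0
            )
            for f in design.live_fractions:
                sample_id = f"{experiment_id}-F{f:g}"
                rng_sample = np.random.default_rng(
                    _sub_seed(design.seed, 202, _id_hash(sample_id))
                )
                f_ref = float(
                    np.clip(f + rng_sample.normal(0.0, design.fcm_error_sd), 0, 100)
                ) if design.fcm_error_sd > 0 else float(f)
                mids = []
                for rep in range(design.replicates_per_sample):
                    mid = f"{sample_id}-r{rep}"
                    rng_meas = np.random.default_rng(
                        _sub_seed(design.seed, 303, _id_hash(sample_id), rep)
                    )
                    series, anomalous = simulate_measurement(
                        f,
                        conc,
                        design,
                        experiment_factor=factor,
                        seed=rng_meas,
                        measurement_id=mid,
                        sample_id=sample_id,
                    )
                    measurements.append(series)
                    mids.append(mid)
                    truth_rows.append(
                        {
                            "measurement_id": mid,
                            "sample_id": sample_id,
                            "experiment_id": experiment_id,
                            "concentration_class": conc,
                            "true_f_live": f,
                            "anomalous": anomalous,
                            "experiment_factor": factor,
                        }
                    )
                samples.append(
                    SampleRecord(
                        sample_id=sample_id,
                        experiment_id=experiment_id,
                        concentration_class=conc,
                        f_live_ref=f_ref,
                        measurement_ids=mids,
                    )
                )
    return SyntheticDataset(measurements, samples, pd.DataFrame(truth_rows), design)
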