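# Methods

## The measurement and the estimation problem

A dual-stained bacterial sample (SYTO 9 + propidium iodide) is excited
continuously for 10 s while a CCD spectrometer records 500 consecutive
emission spectra of 20 ms integration each.  SYTO 9 enters all cells but
dominates the green band (peak inside 509–529 nm) in live cells when
counterstained; PI enters only membrane-compromised cells and dominates the
red band (609–629 nm).  The quantity of interest is the percentage of live
cells, with flow cytometry supplying the reference value for calibration.
`vitaspec` implements four estimators of increasing sophistication — dye
ratio, adjusted dye ratio, single-spectrum ε-SVR, multi-spectra ε-SVR — and
the validation machinery to compare them.

## Pre-processing

The chain is fixed: dark-signal removal → normalisation to 8 ms integration
and 10 mW excitation (counts scale linearly in both, factor
`(8/t)·(10/P)`) → subtraction of the averaged saline background → anomaly
screening → frame selection → optional frame summing → mean-centring.
Normalisation state is tracked by a flag and double normalisation is an
error.  Negative post-background intensities are kept; clipping would bias
window integrals.

**Anomaly screening.**  Replicate optrode measurements of one sample are
compared on their frame-0 full-window integral.  A measurement is excluded
when it deviates from the replicate median by more than 3 robust spreads
(MAD) *and* by more than 20% of the median.  The relative floor matters:
with three replicates the MAD is itself at noise level, and a pure MAD rule
flagged roughly a fifth of perfectly ordinary measurements in simulation.
Both thresholds are configurable and flags are advisory (logged, reported in
the exclusion file).  With exactly two replicates nothing is flagged
automatically; a >1.5× discrepancy is logged for manual review.  Known
limitation: the rule is purely within-sample, so if anomalous replicates are
the majority the median moves onto them and the screen flags the wrong
measurement; in simulation at the default 2% anomaly rate this costs ~5% of
injected anomalies.

**Frame selection.**  Frame `k` covers `[20k, 20k+20)` ms and carries the
midpoint timestamp.  A time point selects the frame with the nearest
midpoint, ties toward the earlier frame (less photobleached); time point 0
is frame 0.  At most 5 frames per measurement are used.

## Photobleaching kinetics

Per-frame integrated intensity over a dye window is fitted as
`I(t) = A₁·exp(−t/τ₁) + A₂·exp(−t/τ₂)` (non-negative amplitudes, no offset —
background subtraction is assumed to have removed any; the fit is
deterministic multi-start least squares, time constants seeded on the crossed
grid {0.2, 1, 5} s with the initial intensity split equally, best SSE wins,
τ₁ ≤ τ₂ canonical).  The half-life is the unique root of `I(t) = I(0)/2`,
found by bracketed root-finding (Brent, xtol 1 ns-scale); it is invariant to
amplitude scaling and bounded by `min(τ)·ln2` and `max(τ)·ln2`.  Half-lives
are fitted per measurement and then averaged (standard error over
measurements), with mostly-bound (mB) SYTO 9 and mostly-unbound (mU) PI read
from all-live samples and mU-SYTO 9 / mB-PI from all-dead samples.  Groups of
half-lives are compared with a two-sided Welch t-test.

## SVR calibration

Features are the mean-centred selected frames of one measurement,
concatenated in time-point order (no variance scaling).  Test data are always
centred with *training* means.  The regression is linear-kernel ε-SVR
(scikit-learn/libsvm, tolerance 1e-7); the fitted model is persisted in
primal form (weight vector + intercept + preprocessing state) as JSON, so
saved models predict bit-identically and are auditable.

Model selection is group K-fold cross-validation: each fold holds out one
whole experiment, and the RMSE is pooled over all held-out predictions rather
than averaged per fold (folds of unequal size then contribute per
measurement).  Candidate time-point sets — the first frame alone, plus
combinations of the four fitted half-lives, eight candidates in all — are
screened at default `C=1, ε=0.1`; ties break toward fewer time points
(parsimony), then candidate order.  The chosen set's hyperparameters are
tuned by exhaustive search over `C ∈ {0.01, 0.1, 0.5, 1, 10, 100}` and
`ε ∈ {0.001, 0.01, 0.1, 1}` (grid ties toward the earlier entry), then refit
on all training data.

Per-sample predictions are the mean over replicate measurements; a sample
prediction below 0 or above 100% is flagged invalid and excluded from the
agreement statistics (exclusion happens after averaging; the boundary values
0 and 100 are valid).

## Validation statistics

All regression metrics are computed about the 1:1 line: RMSE;
explained variance `1 − Var(ref−pred)/Var(ref)` (offset-insensitive);
`R² = 1 − SS_res/SS_tot`, which is negative when predictions are worse than
the reference mean; and the *standard error*, defined here as the residual
standard deviation about the 1:1 line with an `n−1` denominator — this is a
documented convention, and the same SE feeds the ±2 SE acceptance band used
for the within-2SE fraction.  Bland–Altman agreement uses differences
`ref − pred`, bias = mean difference, 95% limits = bias ± 1.96·sd (ddof 1),
with a Shapiro–Wilk normality check (undefined for n < 3 or constant
differences).  The concentration gate is a PCA (exactly 2 components) on
mean-centred first-frame spectra with nearest-centroid classification in
score space; one training class degenerates to a constant classifier with a
warning.

## Synthetic data generator

No instrument data ship with the package; the generator emulates the
statistical structure the analysis assumes.

**Emission model.**  Four components — each dye in a bound and an unbound
pool — are Gaussian peaks: bound SYTO 9 at 519 nm with a subtle 501 nm
shoulder (the bound-state dual peak, truncated by the 500 nm grid edge),
unbound SYTO 9 at 521 nm, bound PI at 617 nm, unbound PI at 620 nm, on a
500–750 nm grid at 1 nm (the instrument's native spacing is not modelled; the
grid is configurable).  Internally each component is rescaled to unit
trapezoid integral over its own dye window, so amplitude coefficients are in
window-integrated units — this is what makes the ideal-mode identity below
exact on the discrete grid rather than approximate.

**Amplitudes.**  With `L = f/100`, `D = 1−L` and concentration scale
`c = class/10⁸`: bound SYTO 9 `= (α₁L + α₂D)·c`, bound PI `= (γD + γ′L)·c`,
with defaults α₁ = γ = 1000, α₂ = 250 (SYTO 9 staining of dead cells; with
the counterstain present dead samples show *less* SYTO 9 than live, matching
observation), γ′ = 60.  Unbound amplitudes (80 / 120) are
concentration-independent — the same dye volume is added to every sample — so
the unbound:bound ratio is 10× larger at 10⁷ bacteria/mL, reproducing the
lower signal-to-noise of dilute samples.  An optional SYTO 9→PI enhancement
coefficient exists and is off by default.  These coefficients are
illustrative, chosen for qualitative realism, not fitted to any instrument.

**Kinetics.**  Each component bleaches double-exponentially, calibrated in
closed form (half-life scales linearly in τ₁ for a fixed shape, default
0.6/0.4 amplitude split and τ₂ = 4τ₁) to target half-lives mB-SYTO 9 1244 ms,
mU-SYTO 9 1472 ms, mB-PI 1124 ms, mU-PI 1084 ms.

**Noise and design.**  Additive Gaussian dark noise (sd 2 counts), shot-like
noise (sd = 0.5·√intensity), a log-normal per-experiment gain factor
(sd 0.10 on the log scale) shared by all measurements of one experiment
(this is what grouped cross-validation must not leak), anomalous measurements
(probability 0.02, whole series ×3, the tag kept only in the ground-truth
table), and Gaussian error on the flow-cytometry reference (sd 1.5%,
clipped to [0, 100]).  The default layout mirrors the study: live fractions
0, 2.5, 5, 10, 25, 50, 75, 100%, classes 10⁸ (4 experiments) and 10⁷
(3 experiments), three replicate measurements per sample, blind test sets
from 2 further experiments.  Every random stream derives deterministically
from the design seed plus stable identifiers (class/experiment for gain
factors, sample-id hash and replicate index for measurements), so datasets
are bit-reproducible and single measurements can be re-simulated in
isolation.

**Ideal mode** (`GeneratorDesign.ideal()`) sets α₂ = γ′ = 0, α₁ = γ, no
unbound dye, all noise to zero and one shared bleach curve.  Then the SYTO 9
and PI window integrals are proportional to the live and dead counts with
equal constants, and `100·R/(1+R)` equals the live percentage as an algebraic
identity (asserted to machine precision in the tests).  The shared bleach
curve and the absence of unbound dye are both necessary: different frame-0
bleach factors or any unbound contribution break exactness.

**What passing tests do and do not show.**  The generator reproduces the
*structure* real data are assumed to have (two dye bands, mixture-dependent
amplitudes, slow double-exponential bleaching, experiment-level gain,
heteroscedastic noise).  It does not model dye–DNA binding chemistry, energy
transfer between dyes, spectral drift, or instrument wavelength error, and
its coefficients are not fitted to any instrument.  Green tests therefore
demonstrate correctness of the algorithms under the stated assumptions, not
instrument-level accuracy; the published error statistics of the original
study are not reproducible without its (undeposited) raw data, and the
package does not attempt to match them.

## Problem sizes and runtime

The shipped defaults are the study-scale conditions (500 frames × 20 ms,
full factorial design); a complete two-class pipeline run takes ~10 s on one
CPU.  Tests that need many datasets (e.g. the anomaly-screen catch-rate
property, pooled over 100 seeds) shorten the series to a few frames because
the screened statistic uses frame 0 only; kinetics and SVR tests always use
full-length series.
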