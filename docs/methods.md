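# Methods

This note documents the models, the parameter choices that matter, and the
limits of what the synthetic validation shows. Units: microvolts, Hz,
milliseconds; sample indices are 0-based and energy windows half-open
`[t, t+w)` unless stated.

## Signal model and preprocessing

The ECG is modelled as a repeating deterministic beat plus additive
disturbances (broadband noise, baseline wander, mains). The front end is a
**causal** Butterworth band-pass (default 25–300 Hz, 4 poles overall, i.e.
two per edge). Causality matters: a zero-phase (forward-backward) filter
would smear QRS energy both ways in time, planting QRS-derived
high-frequency content in the ST segment where it is indistinguishable from
a late potential. The cost of causality is a ~10 ms group delay and a
post-QRS ringing tail; both are properties of the measurement chain that the
downstream fiducial logic must live with (see *Noise floor* below).

Mains interference is removed only when a Welch-periodogram test finds a
tone at the base frequency or a harmonic exceeding the local median power
by a configurable factor (default 10×). The notch is a 2-pole Butterworth
band-stop with a 5 Hz total stop width. A notch this narrow has Q ≈ 10 and
rings for ~130 ms after each QRS at tens of microvolts — an inherent
trade-off; for that reason the synthetic noise model does not include mains
by default, and the notch path is validated separately.

## Averaging and alignment

The signal-averaged ECG (SAECG) reduces stationary zero-mean noise variance
by the number of beats averaged, provided alignment is sample-accurate.
Default alignment is Woody's method: each beat's delay is the lag of the
peak normalized cross-correlation with a template (initially the first
usable beat, refined once by the running average). The correlation is
evaluated on a 200 ms window centred on the R peak: the beat window is
700 ms, and normalizing over its noise-dominated remainder would cap the
attainable correlation well below the 0.95 artifact-rejection gate at
realistic noise levels. Shifts are estimated on the highest-amplitude lead
and applied to all leads. The double-level and normalized-integrals methods
are provided for comparison; the normalized-integrals delay is computed on
the squared signal so it tolerates the zero-mean (biphasic) shape of a
band-passed beat.

Residual noise after averaging is estimated as the **median of per-10 ms-bin
standard deviations** of the averaged reference lead — the median sits in
the isoelectric majority of the window and is essentially unbiased, where a
minimum-energy window would underestimate the level by ~20 %.

## Wavelet denoising

Coiflet-5 decomposition to 5 levels; the noise scale σ̂ is the standard
deviation of the level-2 detail coefficients restricted to the
lowest-energy 10 ms bins of the signal; hard thresholding at T = c·σ̂ on all
detail levels. The `wavelet_denoise` function defaults to the universal
constant c = √(2 ln L). The **pipeline** default is c = 1.5: at the default
acquisition noise (~7 µV in-band per lead per beat), the universal choice
puts T ≈ 18 µV — above the wavelet coefficients of the very late potentials
the method exists to find — and per-beat detection collapses (measured:
0.4 effectiveness at 10 µV vs 0.97 at c = 1.5). c = 1.5 suppresses most
noise coefficients while passing VLPs down to the method's claimed ~6 µV
sensitivity; both constants are exposed in the configuration.

## Fiducials and the noise floor

On the all-lead vector magnitude, the R peak is the absolute maximum; the
noise energy is the minimum over complete 10 ms bins (sum of squares,
trailing partial bin excluded); the J point and QRSoff are the first
samples after R whose forward 10 ms energy drops below 5× and 100× the
noise energy respectively; the QRS onset uses the mirrored backward search.

The two factors encode a deliberate asymmetry: the J point *should* be
dragged later by a late potential (that is the detection signal for the
temporal parameters), while QRSoff *must not* be. This only holds if the
thresholds sit in the right absolute range: 100× noise above the bin energy
of the largest clinical VLPs (~20 µV), 5× noise below the energy of a
10 µV artificial VLP. Deep averaging and hard-threshold denoising can push
the *measured* minimum-bin energy to zero, which would collapse both
thresholds and break the asymmetry, so the estimate is floored at a
calibrated acquisition-floor constant (130 µV²·samples per 10 ms bin for
the default three-lead synthetic montage, `fiducials.noise_floor_uv2`).
Threshold-level calibration per acquisition hardware is an explicit part of
the method, not an implementation convenience; the floor is the single
constant a new hardware setup would need to revisit.

## Temporal parameters

`QRSd` is defined R-peak→J rather than onset→J: late potentials only move
the end of the complex, and the R peak is a far more robust landmark than
the onset (the onset-based value is still computed and reported when the
onset search succeeds, but no rule uses it). `RMS40` is the RMS of the VM
over `[J−40 ms, J)`; `LAS40` the length of the contiguous sub-40 µV run
ending at J. The 2-of-3 rule ships with the study thresholds
(95 ms / 63.5 µV / 44.2 ms) as defaults; these are acquisition-dependent,
and `fit_gaussian_thresholds` refits each as the equal-likelihood crossing
of two fitted normal densities (midpoint of means for equal or degenerate
variances).

## Wigner-Ville analysis

The discrete WVD of the real VM: for each time sample, the FFT over lag k
of the kernel x[t+k]·x[t−k] (two-sided even extension, real part), scaled
so the time marginal is exact: Σ_f W(t,f)·Δf = x(t)² with Δf = fs/(2K),
K = 256 lag bins by default. The frequency axis is calibrated so a pure
tone at f₀ reads f₀; because the real signal's lag kernel is undersampled,
every component also produces an alias image mirrored about f/f_N = 0.5.
The transform of the real signal (not the analytic signal) is the default —
the alias is part of the method's published behaviour — and since numerator
and denominator windows share the 55–300 Hz band, the aliased energy
largely cancels in the normalized indices; an analytic-signal option
exists. The WVD is computed only over a region of interest
(R−100 ms to QRSoff+200 ms) to bound cost; all energy windows fall inside
it, and a window that partially leaves the matrix is clipped with a
warning.

Window energies are means of TFR² over the window (the normalization count
k = rows × columns); negative WVD values (cross-terms) are handled by that
squaring, with no rectification beforehand. Cross-terms are not merely
tolerated but *help*: the QRS×VLP interference in the E_END window scales
with the product of the two amplitudes, amplifying the footprint of a
microvolt VLP against a millivolt QRS. EN and EN_END are invariant to
amplitude scaling of the input (both scale as amplitude⁴), so the
EN_END > EN/10 verdict is calibration-free; ties fall on the negative side
(specificity first).

## The synthetic study conditions

Defaults (all adjustable): fs = 1 kHz, 3 leads with gains 1/(1+0.4·i),
heart rate 60 bpm with 20 ms RR jitter and 2 % beat-amplitude jitter,
R amplitude 1 mV. Noise: white σ = 10 µV per lead (SAECG residual at
120 beats ≈ 0.9 µV), baseline wander 100 µV at 0.3 Hz, no mains. aVLPs: a
sum of cosines at 70/130/210/280 Hz over 40 ms starting at the true QRS
end, per-component amplitude either fixed (3–10 µV studies) or R/100
(post-acquisition study).

The beat template is a deliberate design: a quadriphasic qRSr' complex
(Q −197 µV, R 1000 µV, S −163 µV, r′ 115 µV over ~60 ms) whose wave
amplitudes balance its sub-25 Hz spectral content, so the causal band-pass
leaves a post-QRS tail below ~0.2 µV within a few milliseconds of the
morphological QRS end. A simple monophasic-Gaussian QRS fails the
generator's core requirement — that injected VLPs be the *only* post-QRS
high-frequency energy — because its low-frequency bulk rings 10–30 µV into
the ST segment for tens of milliseconds after causal filtering. The slow,
distant T wave survives only as sub-55 Hz residue, outside every energy
window.

**What the generator does not emulate:** respiration coupling, ectopic or
morphologically variable beats, electrode motion artifacts, non-Gaussian or
nonstationary noise, inter-lead morphology differences beyond scaling, and
real pathological VLP waveshapes (which are nonstationary rather than fixed
cosine bursts). Passing tests therefore demonstrate the pipeline's
correctness and its operating-point calibration under these idealized
conditions, not clinical performance on patient data.

## Numerical choices and degenerate inputs

Filters use second-order sections with zero initial conditions; the first
0.5 s of filtered output is flagged as start-up transient and excluded from
beat extraction. Beat windows span R−300 ms to R+400 ms. Correlation with a
zero-norm segment is defined as 0 (which makes an all-zero template reject
every beat rather than divide by zero). Shifts are integer samples,
rounded. The noise-energy floor also covers all-zero records, where the
minimum bin is 0 and a proportional threshold could never be crossed; a J
search that still never crosses raises a fiducial error rather than
returning a guess, and in beat-to-beat mode such beats count as
non-detections. Problem sizes in the validation suite (cohorts of 10–100
records of 30–120 beats) were chosen as the smallest that make the binomial
acceptance margins meaningful.

## Known limitations

* The J point inherits the causal filter's delay (~1 ms net against the
  similarly delayed R peak at the default settings, but morphology- and
  filter-dependent); absolute fiducial accuracy is only validated on the
  synthetic morphology.
* The noise floor constant couples the fiducial thresholds to the
  acquisition model; grossly different lead counts, gains or noise levels
  require recalibration (as the method itself prescribes).
* The EN_END = EN/10 separation line is dataset-dependent; on other
  hardware the slope should be re-derived from a labelled cohort.
* WFDB support is a format-16 subset (one signal file, µV gain units)
  sufficient for the package's own records and PTB-style data, not a full
  implementation of the standard.
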