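# Methods

## Signal model

The simulator emulates a single photoacoustic point source (a fiber tip)
received one-way by a linear array. Element i records the shared pulse
delayed by t_i = √((x_s−x_i)² + s²)/c, where (x_s, s) is the source
position and c the sound speed. The pulse is evaluated continuously at
each sample instant (no resampling error at the simulation stage), so the
received wavefront is perfectly coherent across the aperture up to the
optional 1/r spherical-spreading decay (off by default, so coherent-limit
checks stay exact). Channel noise is i.i.d. zero-mean Gaussian, scaled so
that the channel SNR — 20·log₁₀ of the rms ratio of the noiseless frame
to the noise, both taken over the entire recording — matches the request
exactly (the drawn noise matrix is rescaled to its target rms, so the
round trip is exact rather than approximate).

Defaults: 128 elements, 0.3 mm pitch (half-pitch lateral resolution of
0.15 mm), 40 MHz sampling, c = 1540 m/s, Gaussian-modulated sinusoid at
5 MHz with 60% fractional bandwidth (an N-shaped pulse is available).
Depth maps one way: sample t sits at z = c·t/fs, so a 30-mm recording at
40 MHz holds 779 samples. Element directivity, attenuation, tissue
heterogeneity and fluence modeling are out of scope.

## Beamforming chain

Regrouping concatenates Nc-channel acquisition blocks into an Ni-element
frame (NA = Ni/Nc must be an integer). DC removal convolves each element
column with a 33-tap linear-phase windowed-sinc high-pass (0.5 MHz cutoff
at 40 MHz; the residual DC leakage of the window design is subtracted so
the DC gain is exactly zero). The analytic signal is the FFT Hilbert
transform per column. Receive delays are one-way: delay(i,l,t) =
hypot(t, Δx/dz) in fractional samples, evaluated by linear interpolation;
samples needing data beyond the recording are zero. Scanlines coincide
with element positions at line density 1.

SLSC compounds the ensemble coherence factors over an odd axial kernel k
(window truncated at the image edges — implemented as a zero-padded
moving sum, which is identical to truncation for sums) and the first M
lags; the real part of the compounded C_ij sum is normalized by the
square root of the product of the compounded auto terms, negative totals
are clipped to zero. Pixels whose compounded auto-coherence is below
1e−30 of the image's maximum auto-coherence yield 0 rather than NaN; the
guard is relative so the image is exactly invariant under amplitude
rescaling of the input (a defining property of coherence imaging, and a
tested one). DAS is the envelope of the coherent element sum. Display
images are normalized to 0 dB and floored at −15 dB by default.

Defaults M = 25, k = 11 follow the parameter-selection study: the (M, k)
sweep (M = 5…35 step 5, k ∈ {3, 11, 19, 31}) shows lateral FWHM
decreasing monotonically in M while gCNR saturates by k ≈ 11.

## A property of strictly noise-free point-source SLSC

With exactly zero noise, pixels far from the source can reach per-lag
coherence ≈ 1: wherever the pixel's delay curve is stationary relative to
the true arrival curve over a band of elements, that band contributes
identical full-amplitude samples and dominates the amplitude-weighted
coherence ratio. Since SLSC is amplitude independent, these ghost regions
tie with the true target at the image maximum. Any realistic noise floor
decorrelates them (their non-stationary elements contribute noise power
to the auto terms), which is why measured SLSC images show a single
dominant target. Consequences for this package's synthetic studies:

* target-location and segmentation demonstrations add a noise floor
  (−15 dB channel SNR) rather than running strictly noise-free;
* the parameter sweep accepts a ground-truth target center for
  noise-free frames instead of trusting the brightest pixel;
* the degradation study's "clean" reference recordings carry a +5 dB
  intrinsic channel-noise floor — the cleanest level at which reference
  segmentations are ghost-free for both beamformers — mirroring the fact
  that real high-energy acquisitions are never noiseless.

A related numerical choice: delay interpolation is linear (as in
texture-memory hardware); at 4 samples per carrier cycle the
interpolation phase error measurably decorrelates the aperture signals
and erodes SLSC's advantage, so all study geometries sample at 8 samples
per cycle (40 MHz for the 5 MHz pulse).

## Metrics

gCNR uses 256 equal-width bins spanning the pooled min–max of both ROIs
(shared support makes the histogram-overlap integral well defined and the
statistic invariant to monotone rescaling); the inside ROI is 3×3 mm on
the target center (brightest pixel; ties resolve to the smallest axial
then lateral index) and the outside ROI is the same size 5 mm to its
right at the same depth. Lateral width is the FWHM of the lateral profile
through the target, with linear interpolation at the half-max crossings
(the crossing pair nearest the peak). Image SNR is μ_in/σ_out for a
2.5×2.5 mm target ROI against five same-size background ROIs at lateral
offsets −10, −11.25, −12.5, −13.75 and −15 mm (the stated 10–15 mm band),
reported as mean ± std of the five ratios. All image metrics operate on
the normalized pre-log image.

## Visual servoing

Segmentation binarizes at a threshold fraction of the image maximum
(default 0.50, the midpoint of the 0.35–0.66 sweep range), applies
morphological closing (disk radius 2 px for both dilation and erosion,
configurable), keeps the largest 8-connected component (ties to the
shallower centroid), and reports the intensity-weighted centroid. The
controller is a discrete proportional velocity law: the probe moves by
gain·Δp·Δt per frame toward the centroid's lateral offset Δp; with loop
gain g·Δt ∈ (0, 2) and perfect segmentation the error contracts
geometrically. After 1 s of consecutive failures the probe sweeps an
expanding lateral search (±2, ±4, … mm up to ±10 mm, restarting if
exhausted). Frames are clocked at the 10-Hz laser pulse-repetition
frequency. The per-frame scene is probe-centric: the apparent source
position is the trajectory position minus the probe position; the noise
amplitude is fixed once from a centered reference frame at the requested
channel SNR, so an out-of-view target degrades to pure noise rather than
silence. Probe-centering errors are summarized (median/IQR) over the
12–15 s window after the error first crosses the convergence tolerance;
tracking errors over the full record.

The degradation experiment adds Gaussian noise at each grid SNR to each
reference recording, beamforms with DAS and SLSC (identical noise per
frame across methods), segments at 10 thresholds evenly spaced in
[0.35, 0.66], and counts a failure as no segmentation or no overlap with
the reference segmentation (default threshold) of the same frame;
results are mean ± std over thresholds of the failure percentage across
the 10 frames. All-zero frames (the pure-noise control) receive unit-std
noise, since a target channel SNR is undefined at zero signal.

## Laser safety

Only the nanosecond-pulse skin MPE band 700–1050 nm is implemented
(covering both wavelengths of interest, 750 and 900 nm):
MPE = 2.0·C_A·10⁻² J/cm², C_A = 10^{2(λ−0.700)} with λ in μm. The
per-pulse limit assumes a flat-top beam over the fiber core:
E = MPE·π(D/2)². At 900 nm this gives 50.24 mJ/cm² and 394.6 μJ for a
1.0-mm core (142 μJ at 0.6 mm); at 750 nm the fluence is 25.18 mJ/cm².

## Study sizes

The test suite and examples run desk-scale versions of the experiments:
a 48-element, 30-mm-deep geometry (source at 22 mm) for the pipeline,
sweep and servo studies; a 64-element, 40-mm-deep geometry (source at
30 mm, lateral positions spread over ±2 mm across 10 frames) for the
degradation study with added noise from −36 to −21 dB in 3-dB steps;
servo runs of 16 s (centering, 6-mm initial offset) and 20 s (tracking,
10 mm total) at 10 Hz. These sizes preserve the coherence structure and
the qualitative orderings while keeping a full study in minutes on one
core.

## What passing tests do and do not show

The simulator produces an ideal coherent wavefront plus white Gaussian
noise. It contains no acoustic clutter, reverberation, element
directivity or frequency-dependent attenuation, so passing tests
demonstrate the correctness of the processing chain and the *relative*
behavior of coherence vs amplitude beamforming under noise — not the
absolute SNR, tracking-error or failure-rate values to expect on tissue
data. Quantities tied to tissue experiments or hardware (frame rates,
speedups, ex vivo SNR values) are outside this package's scope.
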