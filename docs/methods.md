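# Methods

`fulmkit` implements the analysis chain of transcranial functional
ultrasound localization microscopy (fULM) in the mouse brain, together
with a ground-truthed generator of synthetic ultrafast movies that stands
in for in vivo acquisitions. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## Acquisition model and conventions

The pipeline assumes ultrafast compound imaging: groups of 11 tilted
plane waves at a 5.5 kHz pulse repetition frequency, summed into compound
frames at 500 Hz. Frames are processed in non-overlapping blocks of 200
(0.4 s). Two clutter-filter settings are carried in the acquisition
configuration: a cut of 20 singular values for ULM processing and 60 for
power Doppler, the values used on in vivo data at this block size.

Geometry: `x` runs along the 128-element, 110 µm-pitch transducer; `z`
is depth with 0 at the cortical surface, so descending arteriolar flow
has `v_z > 0` and ascending venular flow `v_z < 0`. The native axial
pitch defaults to the wavelength λ = c/f₀ ≈ 102.67 µm (15 MHz in
1540 m/s tissue). Super-resolved maps live on the *fine* grid of pitch
native/16 — 6.875 µm laterally and λ/16 ≈ 6.42 µm axially (displayed
rounded as 6.5 µm); localization runs on an intermediate ×6 Lanczos
compute grid. Pixels are half-open intervals; a continuous position `p`
rasterizes to `floor(p/pitch)`.

## Synthetic scenes

`fulmkit.synth` builds a cortical vascular tree, simulates microbubble
(MB) transits through it, and renders frames.

**Tree.** The desk-scale default is a 3.96 × 3.08 mm² coronal field with
5 penetrating arterioles (28 µm, 8 mm/s, descending) that continue below
the 400 µm depth threshold as arteriole–capillary-transition (ACT)
trunks (14 µm, 3 mm/s) with 3 extra oblique ACT branches, and 2
ascending venules (36 µm, 5 mm/s, upward). Vessels stay ≥420 µm from
the lateral field edges so the point-spread-function footprint never
clips (clipping biases localization inward). Phenotype knobs re-create
the contrasts of pericyte dysfunction: `dilation_factor` scales
arteriolar-side diameters (venules are untouched, matching the observed
localisation of the dilation), `speed_factor_act` scales ACT speeds,
`tortuosity_amplitude/wavelength` superimpose a sinusoid on arteriolar
centerlines (pinned at the parent junction), and the activation
parameters below modulate stimulus-evoked flux.

**Bubbles.** Entries per segment follow an inhomogeneous Poisson process
(baseline rates 5/2/4 MBs/s for arterioles/ACT/venules — roughly 10–20
bubbles in transit per frame, the scaled-down analogue of a continuous
SonoVue infusion). During the 30 s stimulation window of each 70 s
pattern (30 s rest / 30 s stim / 10 s rest, 25 patterns by default), the
entry rate of activated segments rises by `activation_gain` after
`activation_delay_s`, ramping linearly over 2 s, with an optional
transient overshoot — the two-phase shape of the functional hyperaemic
response. Each bubble advances along the centerline at the segment speed
with a constant lateral offset drawn uniformly within the lumen radius
(per bubble, not per frame, so tracks stay smooth), and carries a
log-normal echo amplitude (median 1, σ = 0.3).

**Rendering.** Frame = clutter + bubbles + white noise. Bubbles are
isotropic Gaussian spots of σ = λ ≈ 103 µm (FWHM ≈ 242 µm), the
realistic transcranial spot of an f-number ≳ 1 system with skull
aberration; a λ/2 spot would be badly under-sampled on the λ-pitch
native grid and alias. Clutter is a sum of `rank` (default 5) smooth
random spatial fields, each modulated by a cardiac-band sinusoidal
envelope (periods 50–100 ms ≈ 10–20 Hz, the anesthetized-mouse heart
band), scaled 30 dB above the median bubble amplitude. The fast
envelopes matter: they make the clutter occupy exactly `rank` singular
components *within a 0.4 s block* and keep the clutter's temporal band
above the slow per-pixel bumps of transiting bubbles, which is also what
separates tissue from bubbles in vivo. Noise σ defaults to 0.1 (20 dB
below a unit bubble).

## Stage-by-stage processing choices

**Clutter filter.** Truncated SVD of the space×time Casorati matrix per
block; removed and kept parts are orthogonal (energy decomposition holds
to 1e-8). On desk-scale scenes the analysis cut is 5 — the synthetic
clutter rank, visible as a sharp elbow in the singular spectrum —
rather than the in vivo 20: with only ~1100 native pixels and ~15
vessels, bubble signal is itself low-rank and a deep cut absorbs it.

**Localization.** Frames are upsampled ×6 with a Lanczos-3 kernel
(row-normalized at the edges), cross-correlated (zero-normalized) with a
Gaussian PSF template over a ±2σ window, and 8-neighbour maxima above
correlation 0.7 are kept, with non-maximum suppression at one FWHM.
Real-valued frames are correlated in signed form — a bubble echo is a
positive lobe, and rectifying first turns negative noise lobes into
PSF-like bumps. Correlation alone is amplitude-blind, so peaks must also
exceed an intensity gate of 2.5 robust noise standard deviations
(median absolute deviation per frame); regions whose local window is
numerically constant are excluded, as is a border of one template
half-width. Subpixel refinement fits a 2D quadratic to the 3×3
correlation neighbourhood (offsets clamped to ±0.5 px; non-concave fits
fall back to the integer peak and are flagged). Backscatter is the
cubic-spline-interpolated magnitude at the subpixel position. Isolated
20 dB bubbles localize to ≈12 µm RMSE (≈ λ/9, ~0.11 native pixels);
inside dense scenes neighbour interference raises this to ~15–20 µm.

**Tracking.** Frame-to-frame optimal assignment (Hungarian) under a
gating radius of `max_speed/frame_rate`; no gap closing (a missed frame
splits a track); tracks shorter than 5 frames are discarded. The in
vivo gate is 100 mm/s; desk scenes use 50 mm/s, scaled to their 8 mm/s
top speed. Before velocity estimation, track positions are smoothed
with a first-order Savitzky–Golay filter (window 41 frames = 82 ms,
capped at the track length; exact for constant-velocity motion,
including endpoints). This step is essential at 500 Hz: raw per-step
differentiation of ~15 µm jitter produces ~10 mm/s speed noise, far
above capillary flow. Per-step velocities are forward differences of
the smoothed positions.

**Maps.** Every fine pixel crossed by the straight segment between two
successive positions receives one presence mark (exact supercover
rasterization; the bulk path vectorizes the 0/1/2-boundary-crossing
cases and falls back to Amanatides–Woo traversal). MB flow is marks per
pixel per second; speed, velocity components and backscatter are
presence-weighted means, exactly 0 where no bubble passed. Dynamic
stacks use contiguous 2 s windows; pattern averaging recombines windows
of kept patterns by within-pattern index (density-weighted for speeds).
`pattern_average_from_tracks` computes the same result in one pass for
long multi-pattern runs. The square-root display transform is for
rendering only.

**Vessel quantification.** Vesselness (Frangi, σ = 1–8 fine px) of
`sqrt(flow) × speed/p99(speed)`, binarized by hysteresis — seeds above
Otsu's threshold grown down to 8% of it — so slow, dim ACT
continuations stay attached to their bright parent arterioles; a
disk(2) closing bridges single-pixel gaps. Components are filtered by
major-axis length (default 500 µm) and classified
arteriole/venule by the sign of the flow-weighted mean `v_z`. The
centerline is the per-depth-row flow-weighted centroid (penetrating
vessels are near-vertical; this is ordered by construction and robust
to speckle, unlike skeletonization). Depth profiles sample lines
orthogonal to the centerline; the per-depth speed summary is the
flow-weighted mean across the line (the synthetic lumen is plug-flow; a
peak option exists for parabolic profiles). Diameters are the FWHM of
the orthogonal backscatter profile, with interpolated half-maximum
crossings; flat or multi-lobed profiles are flagged with no value. The
scene-level dilation readout in the pipeline recipes instead measures
the FWHM of the depth-averaged, re-centered MB-count profile: in the
generator, echo amplitudes carry no out-of-plane encoding, so the
backscatter profile is flat over every visited pixel and its FWHM
tracks the blur-tail extent rather than the lumen (on real data, where
amplitude does encode elevation, the backscatter map is the sharper
choice, which is why the operation keeps it).
Tortuosity is the circular standard deviation of the flow-direction
angles of all track steps inside the vessel (tracks ≥ 0.1 mm path
length only); the standard deviation of scalar products of consecutive
unit vectors is available as a variant mode.

**fUS.** Power Doppler is the per-pixel mean squared magnitude per
block after an SVD cut of 60. Activation is a single-subject GLM: each
linearly detrended pixel series is regressed on the stimulus boxcar
convolved with a single-gamma HRF (unit area, mode 1.5 s — rodent fUS
responses are much faster than human BOLD); the regression t maps to a
z-score (monotonically saturated where the tail underflows; numerically
constant pixels get z = 0). The ΔCBV response is read in a 1.4 mm
circular ROI at the peak z: pattern-averaged, normalized per pattern to
the pre-stimulation baseline, summarized by early/late window means
(protocol-relative windows, 36–44 s and 44–60 s for the 30/30 design)
and the 20→90% rise time. Because a pure onset delay shifts a curve
without changing its 20→90% duration, the response also reports the
onset-to-90% latency, which moves one-for-one with a delayed response.

**fULM activation.** The activation map is `(stim − baseline)/baseline`
MB flow per fine pixel, defined only where baseline flow is non-zero
(the 60–70 s post window enters neither subset). Activation signals
average flow over a vessel mask split at 400 µm depth, normalized to
100% at baseline, with early (30–40 s) and late (40–60 s) means.
Pattern QC is rule-based: keep a pattern iff the arteriolar ROI signal
correlates > 0.3 with the stimulus boxcar, a contralateral control
signal stays within ±0.5, and the whole-image bubble flux has a
coefficient of variation < 0.3 (the automated stand-in for manual
selection of stable-infusion patterns); keep an acquisition iff the
pattern-averaged signal reaches a 10% stimulation increase.

## What the synthetic validation shows — and does not

Desk-scale problem sizes: resting-state recoveries use 24 s scenes
(12 000 frames, ~36×31 native pixels); activation analyses use 10
patterns of the 70 s protocol on ground-truth track tables; isolated
localization uses 500 single-bubble frames. Phenotype recovery through
the full rendered pipeline reproduces an injected 30% ACT slowdown
within a few percentage points and an injected 1.3× arteriolar dilation
as a diameter ratio near 1.3; the injected stimulation flux gain is
recovered from the activation map within Poisson counting error.

Known limitations, which passing tests do not dispel:

* **Diameters carry localization blur.** Localization error and the
  residual low-rank imprint of the vessel add ~5–10 µm in quadrature to
  apparent lumen widths (a 28 µm vessel reads ~26–32 µm on the count
  profile, and ~46 µm on the amplitude-flat synthetic backscatter
  profile); contrasts (ratios) between scenes are the robust readout —
  which is also how in vivo ULM diameters, themselves PSF-broadened
  relative to two-photon calibres, are used.
* The generator collapses elevation: no out-of-plane motion, no
  aberration or attenuation, no RF/beamforming physics, no bubble
  disruption. Backscatter amplitudes carry no out-of-plane encoding, so
  the backscatter map's advantage here is statistical (amplitude
  weighting), not physical.
* Clutter is a low-rank sinusoid model; real tissue has broadband
  motion, so the in vivo cut (20) cannot be validated at desk scale,
  only the filter's algebra and the rank-matched behaviour.
* Flow is plug-shaped with constant per-segment speed; velocity
  profiles across the lumen and pulsatility are not modelled.
* Track-level recall on dense scenes is ~50–70% (slow bubbles lose
  amplitude to the clutter filter — the same slow-flow suppression SVD
  filtering shows in vivo); quantities built from many tracks are
  unbiased, but per-bubble completeness is not claimed.
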