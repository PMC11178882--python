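# Methods

## Scope and intent

`scanvolt` models the computational side of scanless two-photon (2P)
voltage imaging: what a camera records when a soma-sized, sculpted 2P spot
excites a membrane-localised, negative-going voltage indicator; how
single-cell traces and spike trains are recovered from those movies; and
how much the illumination heats the tissue. Optics (hologram computation,
beam shaping) and indicator photophysics beyond a configurable linear
sensitivity are out of scope.

## Synthetic recordings

**Geometry.** A cell is a membrane annulus (default soma diameter 14 µm,
annulus width 1 µm) on a pixel grid (default 0.1625 µm pixels at the
sample plane; coarser pixels emulate binning). The camera row budget is
enforced at 266 rows at 1 kHz, scaling inversely with rate (532 at
500 Hz), as for an sCMOS detector in 16-bit dynamic-range mode.

**Voltage → fluorescence.** Relative fluorescence is linear and
negative-going, F/F₀ = 1 − s·ΔV/100 mV with s = 0.43 by default (the
per-100 mV response of a fast soma-targeted GEVI), convolved with a
unit-area rise/decay kernel (defaults 1 ms / 2 ms). The kernel constants
are plumbing, not fits: the indicator's true on/off kinetics are not
parameterised here; unit area guarantees steady-state amplitudes are
preserved, so 100 ms steps read exactly −43% and 3 ms AP-like pulses reach
near-steady amplitude.

**Photon model.** Expected counts per pixel are
`background + F0 · (P/P_ref)² · relF(t) · bleach(t) · gate(t)`, with the
quadratic power-density factor characteristic of 2P excitation; realised
counts are Poisson. All randomness derives from one master seed through
named substreams (scene, shot noise, spikes, speckle), so a
(configuration, seed) pair is bit-reproducible.

**Bleaching.** Single exponential toward a floor (default 0.5),
calibrated so 3 s of continuous illumination at the reference power
bleaches to 0.80 of the initial fluorescence; the bleach rate scales with
the squared power-density ratio. Dark intervals recover toward 0.97 of the
previous epoch-start value with a 0.55 s time constant, so a 2.5 s gap
restores ≈ 0.97 — the photostability/photorecovery figures of merit the
extraction stage is tested against. Recovery is parameterised by the
epoch-start ratio (not the fraction of lost fluorescence) because that is
the quantity the photorecovery metric measures.

**Protocols.** Five stimulus protocols are built in: (1) three 100 ms,
100 mV steps under 3 s of continuous light; (2) the same steps under
strobed 200 ms illumination with the steps 2.5 s apart; (3) a train of ten
3 ms, 100 mV pulses — 20 Hz within a 500 ms window by default,
generalisable to 25–125 Hz; (4) six 20 ms sub-threshold steps, 0–2.5 mV in
0.5 mV increments under 40 ms strobes; (5) Poisson random AP-like pulses
(default ≈ 50 in 30 s, 20 ms refractory) under continuous light. Command
waveforms are sampled at 10 kHz, the resolution of an ephys digitiser.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: speckle statistics of real holographic spots
(only an optional log-normal static gain), neuropil and blood-flow
background dynamics, cell-to-cell variability of indicator kinetics,
sub-Poisson camera noise terms (read noise, fixed-pattern noise), and
genuine motion. Detection scores on synthetic movies are therefore upper
bounds, not forecasts, for tissue recordings.

## Trace extraction

ROIs are cropped around *known* spot centroids (targeted illumination
means the cell position is known a priori). Segmentation correlates each
pixel's high-passed trace with the high-passed ROI mean and thresholds
adaptively (floor of five null standard deviations, 5/√T, combined with an
Otsu split). Pixel weights are ordinary-least-squares slopes of each pixel
on the segmented-mean trace, kept where significantly positive (slope
t-statistic ≥ 2) and renormalised; the significance cut is what shrinks
the analysed pixel set relative to the segmentation and concentrates
weight on the membrane. Detrending fits a bi-exponential-with-offset to a
running-percentile baseline (80th percentile for a negative-going
indicator) inside the illumination epochs, falling back to the smoothed
percentile baseline with a warning if the fit fails; step responses are
attenuated by < 2%. −%ΔF/F₀ = 100·(F₀ − F)/F₀ with F₀ the mean of a
baseline window of the detrended trace. SNR is the signal-window amplitude
over the baseline-window standard deviation. The signal-to-background
ratio is the in-support amplitude over the amplitude in a disjoint
surrounding region, with the definition recorded in the result object.
Background fluorescence in a movie dilutes −%ΔF/F₀ exactly as in real
recordings; amplitude-calibration tests therefore use zero-background
scenes.

## Spike analysis

Detection is three-stage: prominence-based peak picking (2.5 robust σ,
refractory spacing 4 ms) seeds the template with the top-decile-prominence
peaks (minimum 5); the peak-normalised mean seed waveform (20 ms window)
re-scores every candidate by least-squares template fit; events pass at
fitted amplitude ≥ 5 robust σ (the working threshold). The noise scale is
the median absolute deviation of the first difference, which is immune to
the spikes themselves. Event matching against ground truth is
maximum-cardinality one-to-one matching within ±5 ms (Hopcroft–Karp); a
greedy pass ordered by |Δt| was rejected because it provably misses valid
pairings when events chain within the tolerance. Precision, recall and F1
use the standard formulas with TN ≡ 0; undefined denominators raise
explicit errors rather than returning 0. Upsampling to the ephys rate uses
a Hann-windowed sinc whose taps vanish at non-zero multiples of the
upsampling factor, so original samples pass through exactly; the input is
reflect-padded so edges see full kernel support.

## Tissue heating

**Model.** Heat diffusion in a homogeneous, isotropic medium via the
Green's-function (heat-kernel) solution, with the volumetric source
Q = μₐ·I(r) built from the *entire* illumination column — light is
absorbed all along its propagation path, which deposits μₐ·P watts per
metre, far more in total than the focal volume alone. The column is
discretised into thin Gaussian slabs (lateral top-hat of the stated FWHM
represented by an equal-power, equal-peak-density Gaussian; a converging/
diverging cone with 5° half-angle about the focus; truncated at 1 mm, the
approximate extent of cortex). Gaussians convolve analytically with the
heat kernel, leaving a single log-spaced time quadrature per element —
fast and accurate to ~0.1% (verified against the steady-state point-source
law P/(4πκr) and an explicit 3-D finite-difference solver).

**Boundary.** The exposed tissue surface is a perfect heat sink, imposed
by the method of images (mirrored negative sources); this matters once
heat has diffused from the focal plane (depth 150 µm by default) to the
surface, i.e. beyond a few tens of milliseconds, and is the default for
30 s recordings. Strobed schedules superpose step responses by linearity.

**Constants.** The tissue constants are exposed in `Medium` and default to
the brain-heating literature: κ = 0.52 W m⁻¹ K⁻¹, ρ = 1040 kg m⁻³,
c = 3650 J kg⁻¹ K⁻¹ (ρc ≈ 3.8 MJ m⁻³ K⁻¹, D ≈ 1.4×10⁻⁷ m² s⁻¹), and
μₐ = 50 m⁻¹ — grey-matter absorption in the 1000–1100 nm window, used for
all wavelengths as the conservative 1030 nm value. Pure water would give
μₐ ≈ 15 m⁻¹; tissue chromophores roughly triple it, and the heating
figures below scale linearly with the choice, which is why the
single-target check carries a ±30% band. Pulsed trains (80 MHz to
hundreds of kHz) are treated as CW at the average power: absorption is
linear and inter-pulse spacing is far below thermal timescales.

**Headline figures under the defaults** (recomputed by
`scripts/acceptance.py` and the test suite): a 12 µm spot at 75 mW for
30 s peaks at ≈ 4.6 K; the rise is fast (≈ 3 K by 12.5 ms); doubling the
power exactly doubles ΔT (so 150 mW exceeds 8 K); a 17 µm spot at 12.5 mW
stays below 0.74 K; sixteen 10 mW spots in a 300 × 300 µm² field heat the
field centre by ≈ 2.6 K, independent of placement to < 10% at 30 s.

**Scattering.** Reaching a target power at depth ℓ requires inflating the
surface power; the printed convention exp(ℓₛ/ℓ) is the default, with the
Beer–Lambert form exp(ℓ/ℓₛ) selectable — the printed form is dimensionally
odd (larger correction at shallower depth) and the two agree only near
ℓ ≈ ℓₛ, so both are provided and no intent is guessed. With scattering on,
ballistic power decays as exp(−z/ℓₛ) and the scattered remainder is
re-deposited in a widening halo (rms single-scattering angle √(2(1−g))),
conserving energy. The optional beam-propagation engine implements the
same physics wave-optically: split-step propagation through random phase
screens with per-screen phase variance dz/ℓₛ (ballistic decay) and a
correlation length set by the anisotropy.

**Maximum simultaneous targets.** `max_targets` finds the largest n such
that the 30 s field-centre ΔT of n targets at the depth-inflated surface
power stays below a limit; the default limit is the single-target
75 mW/30 s peak (the validated perturbation-free recording condition).
At 150 µm depth with 8.3 mW per target at focus this yields 12 targets.
Note the monotonicity caveat: under the printed exp(ℓₛ/ℓ) convention the
inflation *decreases* with depth, so depth-monotonicity of the cap holds
only under the Beer–Lambert convention.

## Motion QC

Movies are smoothed with a 3-D Gaussian (sigmas 1 frame, 5 px, 5 px), the
per-frame intensity centre of mass is computed on background-subtracted
frames (per-frame median, clipped at zero — raw offsets bias the CoM), and
a recording is rejected when |Pearson r| between per-frame |ΔCoM| and
|Δ mean intensity| exceeds 0.5 *and* the maximum displacement exceeds
0.5 px. The thresholds are configurable; QC annotates and rejects, it
never alters data.

## Numerical choices and degenerate inputs

Time quadrature: 220 log-spaced points (relative error ≈ 2×10⁻⁵ against
880). Zero-power sources, all-off schedules and empty event lists return
exact zeros rather than erroring; zero-variance baselines (noise-free
synthetic traces) and zero-denominator metrics raise explicit typed
errors; the SBR guards a fluctuation-free background by capping and
flagging. Ties between overlapping ROIs are resolved by manual sub-region
hints (pixel-to-nearer-centroid assignment is not needed for
non-overlapping spots). Problem sizes in the test suite — 3–6 s movies at
64 × 64 px, 12–20 placement seeds, a 64³ finite-difference grid — were
chosen as the smallest at which the tested statistics are stable.

## Known limitations

The heating model reproduces the fast predicted rise (~3 K by 12.5 ms),
but such model rise times are known to disagree with experimentally
observed onset times of physiological effects; the model is implemented
as formulated, not corrected. The F–V relation is linear by default (a
sigmoid hook exists) and saturation at large depolarisations is not
modelled. The BPM engine calibrates ballistic decay and anisotropy but
does not reproduce full speckle statistics of tissue. Perfusion (bioheat),
metabolic heat and temperature-dependent conductivity are deliberately
omitted; they reduce long-time temperature rises, so the CW figures here
are conservative.
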