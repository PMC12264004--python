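# Methods

`rumposcope` reproduces, entirely in silico, a single-molecule
localization microscopy (SMLM/PALM) study of the chytrid zoospore
"eye": the rumposome, a honeycomb-like tubular membrane organelle that
carries the natively fluorescent, bistable photoreceptor NeoR.  The
package simulates photoswitching movies of a hexagonal emitter lattice,
localizes and drift-corrects them, counts molecules from blink events,
measures the lattice repeat by autocorrelation of intensity profiles,
and fits guanylyl-cyclase saturation kinetics.  This note records the
models, the tunable parameters, the numerical choices, and the limits of
what the synthetic data can and cannot show.

## Ground-truth geometry

Emitters sit on a hexagonal lattice (pitch 30 nm; row spacing
pitch·√3/2 ≈ 26 nm) restricted to an annular arc band — the rumposome —
inside a 4 µm cell body.  Rows are concentric arcs with *exact* 30 nm
arc-length spacing at each row's own radius and alternate half-pitch
stagger, so same-row neighbours are exactly one pitch apart and nearest
neighbours are one pitch apart to curvature accuracy.  Defaults: band
radius 1.4 µm, span 206°, width 530 nm — 21 rows holding ~3430 nodes, so
the fixture population of 3417 molecules fills the band almost
completely (a seeded random subset of nodes is used).  A straight-band
mode (`band_arc_radius=inf`) exists for exact-pitch unit checks.
Positional jitter of nodes is available and off by default.

## Photophysics

Photoswitching is a discrete-frame Markov chain per molecule
(ON/DARK/BLEACHED, BLEACHED absorbing; frame time 35 ms only scales
rates).  All molecules start DARK: the movie models the post-bleach
regime in which the far-red state has been depleted and molecules are
brought back in low doses by 405 nm light.  Per ON frame a molecule
bleaches with probability `p_bleach`, otherwise switches off with
probability `p_off`; photons per ON frame are geometric with mean 350
(memoryless emission; the mean matches the reported average photon
count per localization).  A proportional-feedback controller emulates
the gradually increased 405 nm power: it tracks activations over a
trailing 200-frame window and nudges the expected ON-switch rate toward
a target chosen so the expected burst supply is spent within 98% of the
10,000-frame movie; stability requires gain × window ≪ 1 (gain 0.002).

Defaults `p_off=0.04`, `p_bleach=0.13` give mean ON spells of 6 frames
and 1.27 bursts per molecule before photobleaching.  These rates are
free fixture parameters (no published values exist); they were
calibrated once so that the full pipeline's blink-event count returns
the ground-truth molecule number to within a few percent — re-blinking
(+) and missed dim bursts (−) then nearly cancel, mirroring the
published remark that counting may be slightly underestimated by
photobleaching.

## Camera and background

EMCCD model: 160 nm pixels (16 µm / 100×), Gaussian PSF σ = 102 nm
(≈0.21·λ/NA at 708 nm, NA 1.46), 128×128 sensor, Poisson photon noise,
optional EM gain (Gamma register) and read noise, 16-bit output.
Background is uniform Poisson at 1139.12 photons/px/frame — calibrated
by inverting the Thompson precision formula so that a 350-photon
localization has exactly 32 nm precision, the reported mean.  In the
formula

σ² = (s² + a²/12)/N + 8π·s⁴·b²/(a²·N²)

`b` is the *background noise* per pixel (for Poisson background, the
square root of the rate).  The calibration therefore implies a bright,
strongly background-dominated acquisition; that is a property of the
reported precision itself, not a choice of this package.

A consequence worth stating plainly: the exact Cramér–Rao bound for
this model at N=350 is 41 nm, 1.28× the Thompson value — the Thompson
formula is known to be optimistic when background dominates.  The
precision-consistency checks therefore compare the empirical scatter to
the exact bound (robust MAD scatter within ±15%) and separately verify
that the bound stays inside the stated [0.75, 1.3] band around
Thompson.

## Localization

Detection: difference-of-Gaussians at the PSF scale, response converted
to an equivalent photon amplitude, threshold 5× the matched-filter
noise estimated from the frame median, local maxima with non-maximum
suppression.  Fitting: pixel-integrated 2D Gaussian by Poisson maximum
likelihood (batched Fisher-scoring with Levenberg damping), PSF width
free but bounded to [0.5, 2]× nominal, background fixed per frame at
the frame median by default (a per-ROI free-background mode exists; the
fixed mode is what lets the estimator reach the information bound).
ROI 13×13 px; border candidates dropped; ROI collisions keep the
brighter candidate.  Per-localization precision is Thompson's formula
with the fitted photon count and width and the square root of the
background rate.  Fit quality is Poisson deviance per degree of
freedom.

Because detection thresholds near the typical amplitude, detected
localizations are a brightness-selected subset: their mean fitted
photon count exceeds the emission mean.  Unselected fits at true burst
positions recover the 350-photon average (tested), and photon linearity
holds to within 5% in background-free renders.

## Drift

Synthesis: linear velocity plus Gaussian random walk, cumulative per
frame.  The movie fixture uses (0.015, −0.01) nm/frame with 0.2 nm/frame
random-walk steps (~200 nm over the movie).

Estimation: localizations are first grouped into burst events (one
centroid per burst — otherwise bursts straddling a block boundary place
identical coordinates in adjacent blocks and pin the correlation at
zero lag); events are split into 10 temporal blocks, rendered at 25 nm,
and registered by per-lag Pearson cross-correlation (plain
mean-subtracted correlation acquires a spurious zero-lag maximum from
the finite overlap of the supports).  Consecutive-block chaining is
polished by correlating each block against the sum of the others with a
shrinking search window, then an optional (default-on) refinement links
recurring well-localized events across the movie — repeated activations
of the same molecule — and solves a weighted least-squares problem for
the drift at node frames with a mild second-difference penalty.
Per-frame drift is a monotone cubic (pchip) interpolation.

Limitations, measured on synthetic data: on a generic scattered
specimen at fixture density the endpoint of a 500 nm linear drift is
recovered with a median error of ~7 nm (seed-dependent range ~2–25 nm)
and interior residuals of ~3–5 nm RMS.  On the *periodic* rumposome
lattice, any correlation-based estimator is nearly degenerate modulo
lattice vectors: block offsets can lock 26–30 nm away from truth and
residuals of 15–35 nm RMS are typical.  The drift validation fixtures
therefore use the scattered specimen, and the periodicity analysis is
designed to tolerate block-level registration errors (below).  An
optional parsimony check (`select_model=True`) can replace the anchored
estimate by a constant-velocity fit when recurring-event coherence does
not support the extra freedom.

## Blink-event counting

Greedy temporal linkage: scanning frames in order, a localization joins
the nearest open event within 96 nm (3× the 32 nm fixture precision) of
its inverse-variance-weighted centroid and within 2 dark frames of its
last frame, else opens a new event.  Counting modes: events-as-molecules
(the post-bleach regime default) and recurrence-corrected (events
divided by a known mean blink count).  Cohort summaries use the sample
SD (n−1).  Under fixture defaults the single-cell count is biased by
−0.1% to −5.4% (6 seeds; mean −2.6%): re-blinks overcount, missed dim
bursts and co-active merges undercount, and the calibration balances
them.

## Periodicity

Rendering follows Thompson blurring (each localization a unit-mass 2D
Gaussian of width equal to its precision); for periodicity work the
kernel can be fixed or capped, since blurring at the 30 nm scale with
30 nm-class precision erases the repeat.  Profiles are arc-length
samples along polyline paths with perpendicular averaging (bilinear);
background is removed by a 1D rolling-ball opening (circular
structuring element, depth scaled to the signal range; radius default
4× pitch); autocorrelations are FFT-based, normalized to ACF(0)=1; the
first non-zero-lag peak is screened by prominence (default 3/√n
white-noise band, plus a peak-height check) and refined by a 3-point
parabola.

The end-to-end spacing analysis (`rumposome_spacing`) merges events
(link radius 60 nm here, tighter than the counting radius, to avoid
absorbing co-active neighbours 30 nm away), keeps events localized to
better than 9 nm — grouping a burst's frames multiplies its photons, so
a meaningful fraction of events beats the single-frame precision —
renders them with a narrow 3 nm kernel, extracts a profile along each
of the 21 known row arcs in each of 10 temporal blocks, rolling-ball
corrects, and accumulates *unnormalized* autocorrelations (pair-count
weighting; the ACF is invariant both to each row's half-pitch stagger
and to any residual per-block drift offset).  A subharmonic check
accepts half the first-peak lag when the fundamental tooth is locally
elevated but too weak to register as a maximum.

Honest accounting: the recovered spacing is information-limited.  With
~1000–1700 sufficiently precise events spread over 3400 lattice sites,
pair coherence at the 30 nm period is attenuated by
exp(−(2πσ/30)²) with σ the total event error (centroid precision ⊕
residual drift), and the first ACF tooth rides on the central lobe.
With ground-truth drift correction the analysis returns 30.0 nm on
every tested seed; with estimated drift it lands within 15% of the
pitch in roughly half to two-thirds of seeds and otherwise grabs the
second harmonic or a noise lag (observed spread ≈24–61 nm).  This is a
property of the simulated photon budget, not of the real experiment,
where eight structures were averaged and the precision distribution is
not knowable from the printed mean alone.

### Hexagonal-pattern rotation simulation

The forward check renders 200×200 Gaussian distributions (FWHM 30 nm)
on a 30 nm-pitch hexagonal grid, convolves with a localization-accuracy
Gaussian, rotates node coordinates exactly in 5° steps over 0–360°,
computes an analytic line-band profile at each angle (each node
contributes a Gaussian weighted by its distance to the line), applies
the same rolling-ball correction, autocorrelates, averages the ACFs
over angles and over 5 line offsets spanning one row spacing, and fits
the first peak.  Free parameters the original description does not fix
were set once: localization accuracy 5 nm, band σ 8/30 of the pitch,
profile step pitch/30, ball radius 5/3 of the pitch — chosen so the
axis-aligned case returns the pitch exactly and the analysis is
scale-invariant in the pitch.  The rolling-ball step is essential: at
30 nm FWHM the first ACF tooth otherwise merges into the central lobe
and the first detectable peak sits at twice the repeat.  Defaults give
30.7 nm for the full rotation average (deterministic), 30.0 nm for the
axis-aligned case, and recovered/true ratios within 10% for pitches
24–39 nm.  A power-spectrum mode is provided as a cross-check.  Note
that projections of a hexagonal lattice mix the 30 nm same-row period
with the 26 nm row-spacing family; the narrow band and the rolling-ball
sharpening keep the average near the pitch.

## Cyclase kinetics

Hill model v(S) = Vmax·Sʰ/(K_Mʰ + Sʰ).  Nucleotide quantification by
linear inverse prediction from a cGMP standard curve
(0.05–5 mM) or by peak-area fraction of a known total; turnover as the
OLS slope of mean product versus time over 2–3 points; activities
normalizable by intrinsic NeoR fluorescence (reference = first sample).
Fits are unweighted free-exponent nonlinear least squares by default
(the presumed plotting-software default), initialized at
Vmax₀=max(v), K_M₀=S at half-max, h₀=1, with asymptotic SEs; `fix_h=1`
reduces exactly to Michaelis–Menten, and `weighting="relative"` scales
residuals by the measured rates.  The synthetic generator draws
v·(1+N(0, CV)) per replicate on the standard-curve grid or a log grid
spanning 0.1–4× K_M.

For the parameter-recovery benchmarks the generating truth is
Michaelis–Menten (h=1) with 5% constant-CV noise and 3 replicates; the
benchmark fit therefore holds h at 1 and uses relative weighting — a
floated exponent and unweighted residuals are poorly constrained by 21
points and roughly double the K_M error (free-h unweighted: ~63% of
trials within 15%; MM-weighted: ~97%).  Reported fits always include h.

## Problem sizes

The study conditions are simulated at full scale: 3417 emitters,
10,000 frames of 128×128 px, one movie per seed; the full pipeline
takes about a minute per movie.  The Hill benchmarks run 200 seeded
trials per construct.  The rotation simulation evaluates all 72 angles
at 1 nm profile steps.

## Known limitations

- 2D only: no astigmatic/3D PSF, no sCMOS pixel maps, no spectral
  channels, no flagellar motion.
- One table = one cell; segmentation is upstream's responsibility.
- No multi-emitter fitting: co-active molecules inside one ROI bias
  positions; at fixture density this contributes a few nm of
  correlated error per event and is one driver of the spacing
  estimator's heavy tail.
- Correlation-based drift estimation is nearly degenerate on perfectly
  periodic specimens (offsets modulo lattice vectors); this is a
  genuine property of the method class, handled here by validating the
  estimator on scattered specimens and making the periodicity analysis
  block-tolerant.
- The bulk two-state model is a single-exponential ensemble
  description; no intermediate photocycle states.
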