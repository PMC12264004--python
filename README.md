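# rumposcope

Simulation and analysis of photoswitching single-molecule localization
microscopy (SMLM/PALM) of the chytrid zoospore "eye", plus the
guanylyl-cyclase enzymology that goes with it.

Chytrid fungi steer their swimming spores with an eyespot-like organelle
whose photoreceptor, NeoR, is a natively fluorescent, bistable microbial
rhodopsin: it can be switched between a far-red fluorescent state and a
UV-absorbing dark state.  That bistability makes in-vivo PALM possible —
bleach the fluorescent state, reactivate single molecules in low doses
with 405 nm light, and localize them one burst at a time.  The
photoreceptors sit in the rumposome, a honeycomb of membrane tubes with
a ~30 nm lattice repeat, at roughly 3,400 copies per spore.

No raw microscope data for this experiment are publicly deposited, so
`rumposcope` rebuilds the entire measurement chain in silico and
validates every stage against ground truth:

- **simulate** — hexagonal emitter lattice on a crescent band inside a
  4 µm cell; per-frame ON/DARK/BLEACHED photoswitching with a
  feedback-controlled 405 nm reactivation rate; EMCCD rendering
  (pixel-integrated Gaussian PSF, Poisson noise, background calibrated
  so a 350-photon localization has 32 nm Thompson precision); lateral
  drift.
- **localize** — difference-of-Gaussians detection and batched Poisson
  maximum-likelihood Gaussian fitting; per-localization precision from
  the Thompson formula σ² = (s²+a²/12)/N + 8πs⁴b²/(a²N²).
- **drift** — temporal-block cross-correlation (overlap-corrected
  Pearson), burst-centroid based, with a recurring-event least-squares
  refinement; monotone cubic interpolation.
- **events** — greedy blink-event merging and molecule counting
  (events-as-molecules or recurrence-corrected), cohort summaries.
- **periodicity** — Thompson-blur rendering, arc-length intensity
  profiles, 1D rolling-ball background correction, FFT autocorrelation,
  first-peak spacing; plus the hexagonal-pattern rotation simulation
  (30 nm pitch / 30 nm FWHM / 200×200 distributions / 5° steps).
- **kinetics** — cGMP quantification from chromatogram peak areas,
  turnover slopes, Hill fits v(S) = Vmax·Sʰ/(K_Mʰ+Sʰ), fluorescence
  normalization, and a seeded synthetic-data generator.

See `docs/methods.md` for models, parameter choices, and limitations.

## Worked example

```python
from rumposcope import (simulate_zoospore_movie, localize_and_correct,
                        count_zoospore, rumposome_spacing)

sim = simulate_zoospore_movie(n_molecules=3417, seed=1)
table, traj = localize_and_correct(sim)
count, events = count_zoospore(table)
spacing = rumposome_spacing(table, sim.geometry, camera=sim.camera)
print(f"{len(table)} localizations, {count} molecules, "
      f"lattice repeat {spacing.spacing:.1f} nm")
```

prints

```
5278 localizations, 3368 molecules, lattice repeat 30.4 nm
```

— one simulated spore carrying 3417 photoreceptors yields ~5,300
localizations; blink-event counting recovers the copy number to −1.4%,
and the autocorrelation of intensity profiles along the band recovers
the generating 30 nm lattice pitch.  The forward check from the other
direction:

```python
from rumposcope import HexPatternParams, rotated_projection_analysis
est = rotated_projection_analysis(HexPatternParams(), seed=1)
print(f"rotation-averaged spacing: {est.spacing:.1f} nm")
# rotation-averaged spacing: 30.7 nm
```

a hexagonal pattern with a 30 nm pitch still shows a ~30 nm
autocorrelation peak when averaged over all orientations of the lattice
relative to the measurement plane.

Kinetics:

```python
from rumposcope import fit_hill, generate_kinetics
from rumposcope.kinetics import make_truth
data = generate_kinetics(make_truth(vmax=1.0, km=0.55), noise_cv=0.05, seed=1)
fit = fit_hill(data)
print(f"K_M = {fit.km:.2f} ± {fit.km_se:.2f} mM, h = {fit.h:.2f}")
# K_M = 0.53 ± 0.02 mM, h = 1.00
```

A command-line interface mirrors the library
(`rumposcope simulate|localize|drift|count|periodicity|hexsim|kinetics`).

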