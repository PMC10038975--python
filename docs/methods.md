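# Methods

## The model

A CEST (chemical exchange saturation transfer) acquisition measures the
water signal `I(ω)` after frequency-selective pre-saturation at offsets `ω`
(in ppm relative to water), together with an unsaturated reference `I0`.
The normalized saturation effect

```
y(ω) = 1 − I(ω)/I0
```

is modeled as a sum of `K` Lorentzian lines, one per exchangeable proton
pool:

```
y(ω) = Σ_k  a_k / (1 + 4 ((ω − w_k) / s_k)²)
```

with amplitude `a_k` (fraction of I0, in [0, 1]), center `w_k` (ppm) and
width `s_k` (ppm).  In this parameterization `s_k` is the full width at
half maximum: the line attains `a_k` at `ω = w_k` and `a_k/2` at
`w_k ± s_k/2`.  The area under one line is `a_k π s_k / 2`, reported as the
pool integral.  No baseline term is added; the model is the pure Lorentzian
sum, which also makes it linear in the amplitudes (`y = Ψ a` with the
N×K design matrix `Ψ` of unit-amplitude lines).

### Assumptions

* Each pool contributes an independent Lorentzian line; exchange dynamics
  (Bloch–McConnell), Gaussian/super-Lorentzian MT lineshapes and B1 effects
  are out of scope.
* Offsets stay in ppm throughout; field strength never enters the model.
* Spectra are sampled on a strictly increasing offset grid with at least
  3K points for a K-pool fit.

## Fitting

Per spectrum the objective is the sum of squared residuals
`Φ = Σ_i (y_i − model(ω_i))²`, minimized under per-parameter box bounds
(lower/upper limits on every `a_k, w_k, s_k` carried by the pool table,
which also supplies start values).  The bounds are how prior knowledge
enters: known pool positions get narrow center windows, semisolid MT gets a
width of 5–30 ppm, amplitudes stay in [0, 1].

The minimizer is SciPy's trust-region reflective least-squares solver with
the analytic model Jacobian

```
∂y/∂a = 1/D,   ∂y/∂w = 8 a (ω−w) / (s² D²),   ∂y/∂s = 8 a (ω−w)² / (s³ D²),
D = 1 + 4 ((ω−w)/s)²
```

negated at the solver boundary because the residual is `y − model`.
Defaults: `ftol = xtol = gtol = 1e-8`, Jacobian-based parameter scaling,
at most 400 function evaluations.  On noiseless phantom spectra this
recovers generating parameters to ~1e-8; tightening to 1e-12 only changes
weakly determined parameters (e.g. the MT width at high noise, where the
objective is multi-modal) at several times the cost.  Estimates are clipped
to the bounds after the solve to remove round-off excursions; convergence
failure is reported as a flag, never an exception, and a failed pixel never
aborts a volume.

### Water-shift (B0) pre-fit

Static-field inhomogeneity translates the whole z-spectrum along the offset
axis (shifts can exceed 1 ppm).  Before the pool fit, each spectrum is
centered by fitting a loose six-line template — a dominant water line, four
satellites at ±1 and ±2 ppm from the water peak, and a broad MT line — and
taking the fitted water center as the shift estimate.  Three refinements
keep the estimate accurate to better than 0.01 ppm on the phantom
compositions:

* the water line is seeded at the spectrum's deepest dip;
* only offsets within 3 ppm of that dip enter the pre-fit, so resonances
  the template cannot represent (amide at 3.5 ppm, NH at 3.2 ppm) do not
  drag the water center;
* the pre-fit iterates (≤4 rounds, stopping when the increment drops below
  0.005 ppm), re-centering the spectrum so the satellites sit where the
  template expects them.

The correction is a pure axis translation — values are never interpolated
or resampled, since interpolating sparsely sampled spectra introduces
oscillation artifacts.  The estimated shift is stored per pixel in the
output maps.

## Denoising

Two image-space filters can be applied per offset frame (and symmetrically
to I0) before spectra are extracted; nothing is ever filtered along the
spectral axis, so lineshapes are not distorted.

* **Non-local means** (scikit-image): patch size 5, search window 11,
  smoothing strength `h = 0.8 σ̂` with `σ̂` a wavelet-based per-frame noise
  estimate (so the filter adapts to the noise level and is a near-no-op on
  clean frames).  Edge-preserving: the filter of choice when region
  boundaries carry the contrast.
* **Gaussian**: a discretized unit-sum kernel (default 3×3) with reflective
  borders, which conserves the global mean exactly.  Included as the
  simple baseline; it smooths edges more than NLM.

## Pyramidal coarse-to-fine fitting

The volume is block-averaged in-plane by `2^N` (default N = 2), which
averages `4^N` spectra per coarse pixel and raises SNR accordingly.  The
coarse level is fitted with the user table; its parameter maps are enlarged
by 2 (block replication by default — the values only seed start points) and
each parameter's bounds are narrowed to a tolerance band
`prev ± |prev|·t/100` (default t = 50%), intersected with the global
bounds.  When the coarse value is exactly 0 the multiplicative band
collapses, so it is widened to 5% of the global bound width.  This repeats
until full resolution.  Images not divisible by `2^N` are edge-padded and
the maps cropped back; the water pre-fit runs at every level on that
level's spectra.

Expected artifact: coarse blocks that straddle a region boundary average
different compositions, and the tolerance band then prevents the finer
levels from recovering the jump — the pyramid smooths edges.  On noiseless
data the pyramid and the direct fit agree (to 1e-3) away from region
borders; the equivalence is asserted on eroded region interiors for exactly
this reason.

## Digital phantoms and noise

The built-in phantoms provide ground truth for every test:

* **Phantom 1** (default 128×128, geometry scales with image size): a
  water cylinder (radius 48 px) with two 16-px circles whose amide
  (3.5 ppm) and creatine (1.9 ppm) amplitudes are swapped, 0.30/0.10
  vs 0.10/0.30, over identical water (0.95 at 0 ppm, FWHM 0.5), hydroxyl
  (0.03 at 1.0) and MT (0.03 at −2.0, FWHM 15) lines.
* **Phantom 2**: five stacked 24×12-px "intervertebral discs", each split
  into an inner nucleus pulposus and outer annulus fibrosus that differ
  only in the GAG amplitude (0.06 vs 0.03 at 1.0 ppm) on top of water
  (0.75, FWHM 2), NOE lines at −2.6 and −1.0 ppm, NH at 3.2 ppm and MT
  (0.15 at −2.4, FWHM 10).  Small structures and a 0.03 amplitude contrast
  make this the deliberately hard case.

The default offset grid is 63 points over −7…7 ppm.  Intensity frames are
`I = I0·(1 − y)` with I0 = 1000 inside the structure and 0 outside.

Noise is Rice-distributed, as in magnitude MR images:
`I' = √((I + n₁)² + n₂²)` with independent zero-mean Gaussians `n₁, n₂`
whose standard deviation is `noise_pct/100 · I0` ("noise amplitude" is the
Gaussian-component SD; in empty regions the magnitude then follows a
Rayleigh law with mean `σ√(π/2)`, which the tests verify).  Noise is
applied to every frame including I0, and generation is bit-reproducible
under a fixed seed.

What the phantoms do **not** emulate: saturation physics (amplitudes are
prescribed, not derived from exchange rates), B1 inhomogeneity, motion,
spatially varying B0, partial-volume anatomy, or spatially correlated
noise.  Passing the phantom suite therefore demonstrates the correctness
and noise behavior of the *analysis*, not the physical fidelity of any
particular in-vivo protocol.

## Problem sizes and numerical choices

* Noiseless recovery is validated at 64×64; identical spectra within a
  volume are fitted once and reused (bit-identical inputs give identical
  results), which makes piecewise-constant noiseless volumes cheap.
* Noise sweeps run at 32×32 with levels {0, 5, 10, 20}%, five seeds, and
  fit only the labeled analysis regions: at ≥10% Rician noise the
  background magnitude floor exceeds any sensible I0 threshold, and
  background pixels belong to no analysis region.  Trend assertions
  (SD non-decreasing in noise, NLM < unfiltered at ≥10%, regional residual
  sum of squares increasing) are made on seed-averaged statistics, not on
  single realizations.
* Regional statistics use the sample SD (ddof = 1) over converged pixels.
* Degenerate widths are excluded by construction (width lower bounds must
  be positive), not regularized.
* The tolerance band in the pyramid uses `|prev|` for its half-width so
  negative centers behave symmetrically.

## Known limitations

* At high noise the objective is multi-modal; different but equally valid
  local minima can be reached for weakly determined parameters (broad MT
  width foremost).  The validation quantifies this as regional SD rather
  than pretending a unique solution exists.
* The water pre-fit assumes the water line dominates the spectrum near its
  dip; compositions where water is not the deepest feature would need a
  different seeding rule.
* DICOM support covers single-frame series ordered by InstanceNumber with
  offsets supplied in a sidecar text file; no private-tag parsing.
* The pyramid's edge smoothing is inherent to block averaging and is
  documented behavior, not a defect the implementation tries to hide.
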