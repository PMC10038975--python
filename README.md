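# cestfit

Multi-pool Lorentzian decomposition of CEST-MRI z-spectra.

CEST (chemical exchange saturation transfer) imaging detects dilute
metabolites — amide protons, creatine, glycosaminoglycans — through their
effect on the water signal after frequency-selective saturation.  The
measured z-spectrum, `y(ω) = 1 − I(ω)/I0`, is a superposition of broad,
overlapping resonances sampled at a few dozen offsets with limited SNR.
`cestfit` decomposes it into per-pool Lorentzian lines

    y(ω) = Σ_k  a_k / (1 + 4 ((ω − w_k)/s_k)²)

by bounded nonlinear least squares: each pool carries start values and
lower/upper bounds for its amplitude `a_k`, center `w_k` (ppm) and width
`s_k` (FWHM, ppm), so prior spectral knowledge constrains the fit.  The
minimizer is a trust-region reflective solver driven by the analytic
Jacobian of the model.  Around the core fit the package provides:

* **B0 correction** — a loose six-pool pre-fit locates the water resonance
  and the offset axis is translated back (never interpolated);
* **denoising** — edge-preserving non-local means or a Gaussian filter,
  applied per offset frame before spectra are extracted;
* **pyramidal fitting** — coarse-to-fine analysis that fits block-averaged
  (higher-SNR) images first and propagates parameters as tolerance-bounded
  start values to full resolution;
* **digital phantoms** — two built-in ground-truth phantoms (a two-circle
  amide/creatine cylinder and a spine-like GAG phantom) with Rician noise
  simulation, used by the entire validation suite;
* **I/O** — NIfTI and DICOM-series input, NIfTI parameter-map output,
  JSON/CSV pool tables, tidy CSV region statistics.

It is intended for researchers analyzing CEST acquisitions (or validating
CEST analysis methods) who want a scriptable, tested pipeline rather than a
GUI.

## A worked example

Fitting one noiseless pixel of the built-in two-circle phantom
(`python examples/fit_single_spectrum.py`):

```
pool       amplitude  freq/ppm  fwhm/ppm  integral
water         0.9500    0.0000    0.5000    0.7461
amide         0.3000    3.5000    0.5000    0.2356
creatine      0.1000    1.9000    0.5000    0.0785
oh            0.0300    1.0000    0.5000    0.0236
mt            0.0300   -2.0000   15.0000    0.7069

residual sum of squares: 2.344e-20  (converged: True)
```

The fit recovers the generating composition exactly: the amide pool removes
30% of the water signal at 3.5 ppm, creatine 10% at 1.9 ppm, and the broad
magnetization-transfer line (FWHM 15 ppm) underlies everything.  The
integral column is the area `a·π·s/2` of each line.

Whole-volume fitting produces spatial maps of every parameter plus a
residual sum-of-squares (fit quality) map:

```python
from cestfit import fit_volume, make_phantom1, pool_table_phantom1, region_stats

spec, volume = make_phantom1((64, 64))
maps = fit_volume(volume, pool_table_phantom1())   # preprocess="nlm"/"pyramid"/...
stats = region_stats(maps, spec.labels)
```

The `examples/` directory has one short script per capability: single
spectrum fitting, B0-shift recovery, parameter maps with region statistics,
and the noise-robustness comparison of the unfiltered / NLM / pyramid
methods.

A thin command line mirrors the library for shell use:

```sh
cestfit phantom --which 1 --size 64 --noise 5 --seed 1 --out phantom/
cestfit fit --data phantom/data.nii.gz --i0 phantom/i0.nii.gz \
            --offsets phantom/offsets.txt --pools phantom/pools.json \
            --preprocess nlm --out maps/
cestfit stats --maps maps/ --labels phantom/labels.nii.gz --out stats.csv
```

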