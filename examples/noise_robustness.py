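"""Compare unfiltered, NLM-filtered and pyramidal fitting under noise.

Adds 10% Rician noise to the two-circle phantom and reports the regional
standard deviation of the fitted amide amplitude for each analysis method.
Lower SD means a more stable estimate; non-local means filtering and the
coarse-to-fine pyramid both stabilize the fit relative to the direct
pixel-wise analysis.  (Runs a single seed at 32x32 to stay quick: about two
minutes.)
"""

from cestfit import (
    NoiseSpec,
    PyramidConfig,
    add_rice_noise,
    fit_volume,
    make_phantom1,
    pool_table_phantom1,
    region_stats,
)

spec, volume = make_phantom1((32, 32))
table = pool_table_phantom1()
noisy = add_rice_noise(volume, NoiseSpec(noise_pct=10.0, seed=0))
mask = spec.labels > 0

print(f"{'method':<10}{'left SD':>10}{'right SD':>10}{'outer SD':>10}")
for method in ("none", "nlm", "pyramid"):
    maps = fit_volume(noisy, table, preprocess=method, mask=mask,
                      pyramid_config=PyramidConfig(levels=2, tolerance_pct=50))
    stats = region_stats(maps, spec.labels)
    rows = stats[(stats.pool == "amide") & (stats.parameter == "amplitude")]
    sds = {int(r.region): r["sd"] for _, r in rows.iterrows()}
    print(f"{method:<10}{sds[2]:>10.4f}{sds[3]:>10.4f}{sds[1]:>10.4f}")

print("\nAt 10% noise the unfiltered fit scatters strongly; NLM filtering")
print("and the pyramid reduce the within-region spread of the amide map.")
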