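"""Fit a five-pool Lorentzian model to a single synthetic z-spectrum.

Builds the z-spectrum of a pixel from the two-circle digital phantom and
decomposes it into water, amide, creatine, hydroxyl and magnetization-
transfer lines under box constraints.
"""

import numpy as np

from cestfit import (
    ZSpectrum,
    fit_spectrum,
    make_phantom1,
    normalize,
    pool_table_phantom1,
)

spec, volume = make_phantom1((32, 32))
i, j, k = np.argwhere(spec.labels == spec.label_of("left"))[0]
y = normalize(volume.data[i, j, k], volume.i0[i, j, k])
spectrum = ZSpectrum(volume.offsets, y)

result = fit_spectrum(spectrum, pool_table_phantom1())

print(f"{'pool':<10}{'amplitude':>10}{'freq/ppm':>10}{'fwhm/ppm':>10}{'integral':>10}")
for pool, (a, w, s), integral in zip(result.pool_names, result.params,
                                     result.integrals):
    print(f"{pool:<10}{a:>10.4f}{w:>10.4f}{s:>10.4f}{integral:>10.4f}")
print(f"\nresidual sum of squares: {result.ssq:.3e}  (converged: {result.converged})")
print("Amplitudes are fractions of the unsaturated signal I0: the amide line")
print("removes 30% of the water signal at 3.5 ppm in this region.")
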