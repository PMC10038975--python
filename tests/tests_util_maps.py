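"""Shared helper: minimal ParameterMaps construction for map-level tests."""

import numpy as np

from cestfit import ParameterMaps


def constant_maps(value: float, shape) -> ParameterMaps:
    """Single-pool maps filled with a constant, all pixels converged."""
    full = lambda v: np.full(shape, float(v))
    return ParameterMaps(
        pool_names=("p",),
        amplitude={"p": full(value)},
        frequency={"p": full(1.0)},
        width={"p": full(1.0)},
        integral={"p": full(value * np.pi / 2)},
        ssq=full(0.0),
        converged=np.ones(shape, dtype=bool),
        fitted=np.ones(shape, dtype=bool),
        water_shift=full(0.0),
    )
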