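"""Digital phantoms with known Lorentzian composition, plus Rician noise.

Two phantoms are provided as ground-truth test beds for the fitting
pipeline:

* **Phantom 1** — a cylinder of water containing two inner circles whose
  amide and creatine amplitudes are swapped (0.30/0.10 left vs 0.10/0.30
  right) on top of identical water, hydroxyl and magnetization-transfer
  lines.  Large regions, strong peaks: the easy case.
* **Phantom 2** — five intervertebral-disc-like structures, each split into
  an inner nucleus pulposus (NP) and outer annulus fibrosus (AF) that differ
  only in the glycosaminoglycan (GAG) amplitude (0.06 vs 0.03).  Small
  regions, tiny contrast: the hard case.

Magnitude-image noise is simulated as Rice-distributed:
``I' = sqrt((I + n1)^2 + n2^2)`` with independent zero-mean Gaussians whose
standard deviation is a percentage of the unsaturated reference intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PoolSpec, PoolTable, eval_model
from .volume import CESTVolume

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "make_phantom1",
    "make_phantom2",
    "add_rice_noise",
    "noise_sweep",
    "default_offsets",
    "pool_table_phantom1",
    "pool_table_phantom2",
]

#: Reference design size the stated geometry refers to; other shapes scale.
_DESIGN_SIZE = 128


def default_offsets(n: int = 63, span: float = 7.0) -> np.ndarray:
    """Default saturation-offset grid: 63 points over -7..7 ppm."""
    return np.linspace(-span, span, n)


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise amplitude as percent of I0, with an RNG seed."""

    noise_pct: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.noise_pct <= 100):
            raise ValueError("noise_pct must be in [0, 100]")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and ground-truth composition of a digital phantom."""

    shape: tuple[int, int]
    labels: np.ndarray  # (X, Y, 1) int region labels, 0 = background
    region_names: dict[int, str]
    compositions: dict[int, dict[str, tuple[float, float, float]]]
    offsets: np.ndarray
    i0_value: float

    def truth(self, region: int | str, pool: str) -> tuple[float, float, float]:
        """Ground-truth (amplitude, frequency, width) for a region's pool."""
        if isinstance(region, str):
            region = {v: k for k, v in self.region_names.items()}[region]
        return self.compositions[region][pool]

    def label_of(self, name: str) -> int:
        return {v: k for k, v in self.region_names.items()}[name]


def _render(
    labels: np.ndarray,
    compositions: dict[int, dict[str, tuple[float, float, float]]],
    offsets: np.ndarray,
    i0_value: float,
) -> CESTVolume:
    """Intensity frames I = I0 * (1 - model) per labeled region; background 0."""
    x, y, z = labels.shape
    data = np.zeros((x, y, z, offsets.size))
    i0 = np.zeros((x, y, z))
    for region, comp in compositions.items():
        params = np.array(list(comp.values()))
        signal = i0_value * (1.0 - eval_model(params, offsets))
        mask = labels == region
        data[mask] = signal
        i0[mask] = i0_value
    return CESTVolume(data=data, i0=i0, offsets=offsets.copy())


_PHANTOM1_POOLS = ("water", "amide", "creatine", "oh", "mt")

# (frequency ppm, width ppm) common to all phantom-1 regions
_PHANTOM1_LINES = {
    "water": (0.0, 0.5),
    "amide": (3.5, 0.5),
    "creatine": (1.9, 0.5),
    "oh": (1.0, 0.5),
    "mt": (-2.0, 15.0),
}

_PHANTOM1_AMPLITUDES = {
    # region: water, amide, creatine, oh, mt
    "left": (0.95, 0.30, 0.10, 0.03, 0.03),
    "right": (0.95, 0.10, 0.30, 0.03, 0.03),
    "outer": (0.95, 0.00, 0.00, 0.00, 0.00),
}


def make_phantom1(
    shape: tuple[int, int] = (128, 128),
    offsets: np.ndarray | None = None,
    i0_value: float = 1000.0,
) -> tuple[PhantomSpec, CESTVolume]:
    """Cylinder phantom with left/right circles of swapped amide/creatine.

    Geometry scales with the image size: at 128x128 the outer disc has
    radius 48 px and the two inner circles radius 16 px, centered 24 px to
    either side.  Labels: 1 = outer (water only), 2 = left, 3 = right.
    """
    offsets = default_offsets() if offsets is None else np.asarray(offsets, float)
    x, y = shape
    scale = min(x, y) / _DESIGN_SIZE
    cx, cy = (x - 1) / 2.0, (y - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(x), np.arange(y), indexing="ij")

    def disc(cx_, cy_, r):
        return (xx - cx_) ** 2 + (yy - cy_) ** 2 <= r**2

    outer = disc(cx, cy, 48 * scale)
    left = disc(cx, cy - 24 * scale, 16 * scale)
    right = disc(cx, cy + 24 * scale, 16 * scale)
    labels2d = np.zeros(shape, dtype=int)
    labels2d[outer] = 1
    labels2d[left] = 2
    labels2d[right] = 3
    labels = labels2d[:, :, None]

    region_names = {1: "outer", 2: "left", 3: "right"}
    compositions = {
        label: {
            pool: (amp, *_PHANTOM1_LINES[pool])
            for pool, amp in zip(_PHANTOM1_POOLS, _PHANTOM1_AMPLITUDES[name])
        }
        for label, name in region_names.items()
    }
    spec = PhantomSpec(shape, labels, region_names, compositions, offsets, i0_value)
    return spec, _render(labels, compositions, offsets, i0_value)


_PHANTOM2_COMPOSITION = {
    # pool: (amp AF, amp NP, frequency, width)
    "water": (0.75, 0.75, 0.0, 2.0),
    "gag": (0.03, 0.06, 1.0, 1.0),
    "noe_2.6": (0.05, 0.05, -2.6, 1.0),
    "noe_1.0": (0.001, 0.001, -1.0, 2.0),
    "nh": (0.03, 0.03, 3.2, 0.5),
    "mt": (0.15, 0.15, -2.4, 10.0),
}


def make_phantom2(
    shape: tuple[int, int] = (128, 128),
    offsets: np.ndarray | None = None,
    i0_value: float = 1000.0,
    n_discs: int = 5,
) -> tuple[PhantomSpec, CESTVolume]:
    """Spine-like phantom: stacked discs split into AF (outer) and NP (inner).

    Each disc is a 24x12 px rectangle at 128x128 (scaled otherwise) whose
    central half is the NP; the AF is the remainder.  NP and AF share every
    line except the GAG amplitude.  Labels: 1 = AF, 2 = NP.
    """
    offsets = default_offsets() if offsets is None else np.asarray(offsets, float)
    x, y = shape
    scale = min(x, y) / _DESIGN_SIZE
    dw = max(2, round(24 * scale))  # disc extent along y
    dh = max(2, round(12 * scale))  # disc extent along x
    gap = max(1, round(8 * scale))
    total = n_discs * dh + (n_discs - 1) * gap
    top = max(0, (x - total) // 2)
    cy = y // 2

    labels2d = np.zeros(shape, dtype=int)
    for d in range(n_discs):
        r0 = top + d * (dh + gap)
        r1 = min(x, r0 + dh)
        c0, c1 = cy - dw // 2, cy - dw // 2 + dw
        labels2d[r0:r1, c0:c1] = 1  # AF fills the disc ...
        nr = max(1, dh // 2)
        nc = max(1, dw // 2)
        nr0 = r0 + (dh - nr) // 2
        nc0 = c0 + (dw - nc) // 2
        labels2d[nr0: nr0 + nr, nc0: nc0 + nc] = 2  # ... NP overwrites the core
    labels = labels2d[:, :, None]

    region_names = {1: "af", 2: "np"}
    compositions = {
        1: {p: (v[0], v[2], v[3]) for p, v in _PHANTOM2_COMPOSITION.items()},
        2: {p: (v[1], v[2], v[3]) for p, v in _PHANTOM2_COMPOSITION.items()},
    }
    spec = PhantomSpec(shape, labels, region_names, compositions, offsets, i0_value)
    return spec, _render(labels, compositions, offsets, i0_value)


def pool_table_phantom1() -> PoolTable:
    """Start values and constraints for fitting phantom 1 (5 pools)."""
    return PoolTable([
        PoolSpec("water", 0.8, 0.0, 1.0, 0.0, -0.5, 0.5, 1.0, 0.1, 4.0),
        PoolSpec("amide", 0.1, 0.0, 1.0, 3.5, 3.3, 3.7, 1.0, 0.1, 3.0),
        PoolSpec("creatine", 0.1, 0.0, 1.0, 1.9, 1.7, 2.1, 1.0, 0.1, 3.0),
        PoolSpec("oh", 0.02, 0.0, 1.0, 1.0, 0.8, 1.2, 1.0, 0.1, 3.0),
        PoolSpec("mt", 0.1, 0.0, 0.5, -2.0, -3.0, -1.0, 15.0, 5.0, 30.0),
    ])


def pool_table_phantom2() -> PoolTable:
    """Start values and constraints for fitting phantom 2 (6 pools)."""
    return PoolTable([
        PoolSpec("water", 0.6, 0.0, 1.0, 0.0, -0.5, 0.5, 1.5, 0.5, 6.0),
        PoolSpec("gag", 0.02, 0.0, 0.3, 1.0, 0.8, 1.2, 0.8, 0.3, 3.0),
        PoolSpec("noe_2.6", 0.03, 0.0, 0.3, -2.6, -2.9, -2.3, 0.8, 0.3, 3.0),
        PoolSpec("noe_1.0", 0.005, 0.0, 0.1, -1.0, -1.2, -0.8, 1.5, 0.5, 4.0),
        PoolSpec("nh", 0.02, 0.0, 0.3, 3.2, 3.0, 3.4, 0.8, 0.2, 2.0),
        PoolSpec("mt", 0.1, 0.0, 0.5, -2.4, -3.5, -1.5, 12.0, 5.0, 30.0),
    ])


def add_rice_noise(volume: CESTVolume, noise: NoiseSpec) -> CESTVolume:
    """Overlay Rice-distributed noise on every intensity frame and on I0.

    Each intensity ``I`` becomes ``sqrt((I + n1)^2 + n2^2)`` with ``n1, n2``
    independent zero-mean Gaussians of standard deviation
    ``noise_pct/100`` of the unsaturated reference intensity (the I0
    maximum).  Output is bit-reproducible for a fixed seed.
    """
    if noise.noise_pct == 0:
        return volume.copy_with()
    rng = np.random.default_rng(noise.seed)
    sd = noise.noise_pct / 100.0 * float(volume.i0.max())

    def ricify(arr: np.ndarray) -> np.ndarray:
        n1 = rng.normal(0.0, sd, arr.shape)
        n2 = rng.normal(0.0, sd, arr.shape)
        return np.sqrt((arr + n1) ** 2 + n2**2)

    return volume.copy_with(data=ricify(volume.data), i0=ricify(volume.i0))


def noise_sweep(
    volume: CESTVolume,
    labels: np.ndarray,
    table: PoolTable,
    levels: list[float],
    methods: list[str],
    seeds: list[int],
    options=None,
    denoise_params=None,
    pyramid_config=None,
    b0_correct: bool = True,
) -> pd.DataFrame:
    """Fit a phantom across noise levels, methods and seeds.

    For every combination the clean volume is re-noised, processed with the
    requested method (``none``/``gaussian``/``nlm``/``pyramid``/
    ``nlm+pyramid``), fitted, and summarized per region.  Returns a tidy
    table of regional means/SDs (including the regional residual
    sum-of-squares) tagged with ``noise_pct``, ``method`` and ``seed`` —
    the raw material for noise-robustness curves.
    """
    from .fitting import fit_volume, region_stats

    frames = []
    labels = np.asarray(labels)
    mask = labels > 0
    for pct in levels:
        for seed in seeds:
            noisy = add_rice_noise(volume, NoiseSpec(pct, seed))
            for method in methods:
                maps = fit_volume(
                    noisy, table, options=options, preprocess=method,
                    denoise_params=denoise_params,
                    pyramid_config=pyramid_config, b0_correct=b0_correct,
                    mask=mask,
                )
                stats = region_stats(maps, labels)
                stats.insert(0, "noise_pct", pct)
                stats.insert(1, "method", method)
                stats.insert(2, "seed", seed)
                frames.append(stats)
    return pd.concat(frames, ignore_index=True)
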