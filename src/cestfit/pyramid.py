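"""Coarse-to-fine (pyramidal) volume fitting.

The volume is spatially block-averaged by a factor ``2^N``, which raises the
SNR of the averaged z-spectra at the cost of resolution.  The coarse fit uses
the user's pool table; its parameter maps are then upsampled by 2 and serve
as per-pixel start values for the next finer level, with bounds narrowed to a
percentage tolerance band around the coarse estimate (intersected with the
global bounds).  Repeating until full resolution yields noise-robust maps at
the price of some edge smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitOptions, ParameterMaps, _empty_maps, _fit_volume_direct
from .model import PoolTable
from .volume import CESTVolume

__all__ = [
    "PyramidConfig",
    "downsample",
    "upsample_params",
    "propagate_bounds",
    "pyramid_fit",
]


@dataclass(frozen=True)
class PyramidConfig:
    """Pyramid controls.

    ``levels`` is the number of halvings at the coarsest scale (downsample
    factor ``2**levels``).  ``tolerance_pct`` is how far, in percent of the
    coarse value, each parameter may move from one level to the next.
    ``zero_floor_fraction`` keeps the propagated interval non-degenerate
    when the coarse value is 0 (where a multiplicative band collapses): the
    interval is widened to this fraction of the global bound width.
    ``interpolation`` selects how coarse maps seed the finer grid:
    ``nearest`` (block replication, default) or ``bilinear``.
    """

    levels: int = 2
    tolerance_pct: float = 50.0
    zero_floor_fraction: float = 0.05
    interpolation: str = "nearest"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not (0 < self.tolerance_pct <= 100):
            raise ValueError("tolerance_pct must be in (0, 100]")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


def _block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """In-plane (X, Y) block average; trailing axes untouched."""
    x, y = arr.shape[:2]
    rest = arr.shape[2:]
    out = arr.reshape(x // factor, factor, y // factor, factor, *rest)
    return out.mean(axis=(1, 3))


def downsample(volume: CESTVolume, factor: int) -> CESTVolume:
    """Block-average each offset frame and I0 by ``factor`` in-plane."""
    if factor < 1 or factor & (factor - 1):
        raise ValueError(f"downsample factor must be a power of two, got {factor}")
    x, y = volume.spatial_shape[:2]
    if factor > min(x, y):
        raise ValueError(f"factor {factor} exceeds image size {x}x{y}")
    if x % factor or y % factor:
        raise ValueError(
            f"image size {x}x{y} not divisible by {factor}; pad first"
        )
    if factor == 1:
        return volume.copy_with()
    return volume.copy_with(
        data=_block_mean(volume.data, factor),
        i0=_block_mean(volume.i0, factor),
    )


def _enlarge(arr: np.ndarray, factor: int, interpolation: str) -> np.ndarray:
    if interpolation == "nearest":
        return np.repeat(np.repeat(arr, factor, axis=0), factor, axis=1)
    from scipy.ndimage import zoom

    filled = np.where(np.isfinite(arr), arr, 0.0)
    out = zoom(filled, (factor, factor) + (1,) * (arr.ndim - 2), order=1,
               mode="nearest", grid_mode=True)
    mask = np.repeat(np.repeat(~np.isfinite(arr), factor, axis=0), factor, axis=1)
    out[mask] = np.nan
    return out


def upsample_params(
    maps: ParameterMaps, factor: int = 2, interpolation: str = "nearest"
) -> ParameterMaps:
    """Spatially enlarge all parameter maps to seed the next finer level.

    Default is block replication (each coarse pixel covers a
    ``factor x factor`` block), which preserves values exactly; bilinear
    interpolation is available for smoother seeding.
    """
    def up(arr: np.ndarray) -> np.ndarray:
        return _enlarge(arr, factor, interpolation)

    def up_bool(arr: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(arr, factor, axis=0), factor, axis=1)

    return ParameterMaps(
        pool_names=maps.pool_names,
        amplitude={n: up(a) for n, a in maps.amplitude.items()},
        frequency={n: up(a) for n, a in maps.frequency.items()},
        width={n: up(a) for n, a in maps.width.items()},
        integral={n: up(a) for n, a in maps.integral.items()},
        ssq=up(maps.ssq),
        converged=up_bool(maps.converged),
        fitted=up_bool(maps.fitted),
        water_shift=up(maps.water_shift),
    )


def propagate_bounds(
    prev_value: float,
    tolerance_pct: float,
    global_lo: float,
    global_hi: float,
    zero_floor: float | None = None,
) -> tuple[float, float]:
    """Tolerance band around a coarse-level estimate, clamped to global bounds.

    The band is ``prev_value * (1 -/+ tolerance_pct/100)`` (widened
    symmetrically by ``|prev_value| * tol`` so negative centers behave the
    same as positive ones).  A degenerate band — the coarse value is exactly
    0 — is widened by ``zero_floor`` (default 5% of the global bound width)
    so the finer level can still move.
    """
    if not (global_lo <= prev_value <= global_hi):
        raise ValueError(
            f"previous value {prev_value} outside global bounds "
            f"[{global_lo}, {global_hi}]"
        )
    half = abs(prev_value) * tolerance_pct / 100.0
    lo = max(global_lo, prev_value - half)
    hi = min(global_hi, prev_value + half)
    if hi - lo == 0.0:
        floor = zero_floor if zero_floor is not None else 0.05 * (global_hi - global_lo)
        lo = max(global_lo, prev_value - floor)
        hi = min(global_hi, prev_value + floor)
    return lo, hi


def _propagate_arrays(
    prev: np.ndarray,
    tolerance_pct: float,
    global_lo: float,
    global_hi: float,
    floor: float,
) -> tuple[np.ndarray, np.ndarray]:
    half = np.abs(prev) * tolerance_pct / 100.0
    lo = np.maximum(global_lo, prev - half)
    hi = np.minimum(global_hi, prev + half)
    degenerate = (hi - lo) == 0.0
    lo = np.where(degenerate, np.maximum(global_lo, prev - floor), lo)
    hi = np.where(degenerate, np.minimum(global_hi, prev + floor), hi)
    return lo, hi


def _pad_volume(volume: CESTVolume, multiple: int) -> tuple[CESTVolume, tuple[int, int]]:
    x, y = volume.spatial_shape[:2]
    px = (-x) % multiple
    py = (-y) % multiple
    if px == 0 and py == 0:
        return volume, (x, y)
    pad4 = ((0, px), (0, py), (0, 0), (0, 0))
    pad3 = ((0, px), (0, py), (0, 0))
    return (
        volume.copy_with(
            data=np.pad(volume.data, pad4, mode="edge"),
            i0=np.pad(volume.i0, pad3, mode="edge"),
        ),
        (x, y),
    )


def _crop_maps(maps: ParameterMaps, shape: tuple[int, int]) -> ParameterMaps:
    x, y = shape

    def crop(arr: np.ndarray) -> np.ndarray:
        return arr[:x, :y]

    return ParameterMaps(
        pool_names=maps.pool_names,
        amplitude={n: crop(a) for n, a in maps.amplitude.items()},
        frequency={n: crop(a) for n, a in maps.frequency.items()},
        width={n: crop(a) for n, a in maps.width.items()},
        integral={n: crop(a) for n, a in maps.integral.items()},
        ssq=crop(maps.ssq),
        converged=crop(maps.converged),
        fitted=crop(maps.fitted),
        water_shift=crop(maps.water_shift),
    )


def _seed_arrays(
    coarse: ParameterMaps,
    table: PoolTable,
    config: PyramidConfig,
    shape: tuple[int, ...],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel start/bound vectors (3K) from upsampled coarse maps.

    Pixels the coarse level did not fit (or did not converge on) fall back
    to the user table's starts and global bounds.
    """
    k = len(table)
    x0 = np.empty(shape + (3 * k,))
    lo = np.empty_like(x0)
    hi = np.empty_like(x0)
    table_x0 = table.start_vector()
    table_lo, table_hi = table.bound_vectors()
    for j, name in enumerate(table.names):
        for p, stack in enumerate((coarse.amplitude, coarse.frequency, coarse.width)):
            col = 3 * j + p
            g_lo, g_hi = table_lo[col], table_hi[col]
            floor = config.zero_floor_fraction * (g_hi - g_lo)
            prev = np.clip(stack[name], g_lo, g_hi)
            valid = np.isfinite(prev) & coarse.converged
            prev = np.where(valid, prev, table_x0[col])
            plo, phi = _propagate_arrays(
                prev, config.tolerance_pct, g_lo, g_hi, floor
            )
            x0[..., col] = np.where(valid, prev, table_x0[col])
            lo[..., col] = np.where(valid, plo, g_lo)
            hi[..., col] = np.where(valid, phi, g_hi)
    return x0, lo, hi


def pyramid_fit(
    volume: CESTVolume,
    table: PoolTable,
    config: PyramidConfig | None = None,
    options: FitOptions | None = None,
    b0_correct: bool = True,
    i0_fraction: float = 0.05,
    mask: np.ndarray | None = None,
) -> ParameterMaps:
    """Coarse-to-fine fit of a whole volume.

    The coarsest level (downsample ``2**levels``) is fitted with the user
    table; each finer level is seeded by the upsampled coarse maps with
    tolerance-restricted bounds, until full resolution.  Image sizes not
    divisible by ``2**levels`` are edge-padded and the final maps cropped
    back.  The water-shift pre-fit runs at every level on that level's
    spectra.  An explicit ``mask`` restricts fitting; a coarse pixel is
    fitted if any fine pixel of its block is masked in.
    """
    config = config or PyramidConfig()
    options = options or FitOptions()
    padded, orig_xy = _pad_volume(volume, 2 ** config.levels)
    if mask is not None:
        pad = ((0, padded.spatial_shape[0] - mask.shape[0]),
               (0, padded.spatial_shape[1] - mask.shape[1]), (0, 0))
        mask = np.pad(mask.astype(bool), pad, mode="edge")

    maps: ParameterMaps | None = None
    for level in range(config.levels, -1, -1):
        factor = 2 ** level
        vol_l = downsample(padded, factor)
        mask_l = None
        if mask is not None:
            mask_l = _block_mean(mask.astype(float), factor) > 0 if factor > 1 else mask
        if maps is None:
            maps = _fit_volume_direct(
                vol_l, table, options, b0_correct, i0_fraction, mask=mask_l
            )
        else:
            seeded = upsample_params(maps, 2, config.interpolation)
            x0, lo, hi = _seed_arrays(seeded, table, config, vol_l.spatial_shape)
            maps = _fit_volume_direct(
                vol_l, table, options, b0_correct, i0_fraction,
                starts=x0, lowers=lo, uppers=hi, mask=mask_l,
            )
    return _crop_maps(maps, orig_xy)
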