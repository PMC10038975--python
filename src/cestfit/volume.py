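"""In-memory container for a 4D CEST acquisition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CESTVolume"]


@dataclass
class CESTVolume:
    """A 4D CEST image series plus its unsaturated reference.

    Attributes
    ----------
    data:
        Intensity array of shape ``(X, Y, Z, N)`` with one frame per
        saturation offset.
    i0:
        Reference intensity array of shape ``(X, Y, Z)``, acquired without
        pre-saturation; used both to normalize z-spectra and to define the
        foreground mask.
    offsets:
        Saturation offsets in ppm, length ``N``.  Stored strictly increasing;
        an unsorted input is sorted and the frames reordered consistently.
    affine:
        4x4 voxel-to-world matrix carried opaquely through the pipeline.
    """

    data: np.ndarray
    i0: np.ndarray
    offsets: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.i0 = np.asarray(self.i0, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (X, Y, Z, N), got shape {self.data.shape}")
        if self.i0.shape != self.data.shape[:3]:
            raise ValueError(
                f"I0 shape {self.i0.shape} does not match data spatial shape "
                f"{self.data.shape[:3]}"
            )
        if self.offsets.ndim != 1 or self.offsets.size != self.data.shape[3]:
            raise ValueError(
                f"{self.offsets.size} offsets for {self.data.shape[3]} frames"
            )
        if np.unique(self.offsets).size != self.offsets.size:
            raise ValueError("offsets contain duplicates")
        order = np.argsort(self.offsets)
        if not np.array_equal(order, np.arange(order.size)):
            self.offsets = self.offsets[order]
            self.data = self.data[..., order]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_offsets(self) -> int:
        return self.data.shape[3]

    def foreground_mask(self, i0_fraction: float = 0.05) -> np.ndarray:
        """Pixels whose I0 exceeds ``i0_fraction`` of the volume maximum."""
        if self.i0.size == 0 or self.i0.max() <= 0:
            return np.zeros(self.spatial_shape, dtype=bool)
        return self.i0 > i0_fraction * self.i0.max()

    def copy_with(self, data: np.ndarray | None = None, i0: np.ndarray | None = None) -> "CESTVolume":
        return CESTVolume(
            data=self.data.copy() if data is None else data,
            i0=self.i0.copy() if i0 is None else i0,
            offsets=self.offsets.copy(),
            affine=self.affine.copy(),
        )
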