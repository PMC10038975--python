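"""Readers and writers for the formats the pipeline touches.

Volumes come in as 4D NIfTI or a DICOM series (one 2D frame per offset),
always accompanied by a plain-text offsets file (one ppm value per line);
offsets are sorted ascending internally and frames reordered to match.
Pool tables travel as JSON or CSV with one row per pool.  Parameter maps go
out as one NIfTI per (pool, parameter) plus the sum-of-squares map and
convergence mask, with a JSON manifest capturing the file list and the
configuration for exact re-runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import ParameterMaps
from .model import PoolSpec, PoolTable
from .volume import CESTVolume

__all__ = [
    "RunConfig",
    "read_offsets",
    "write_offsets",
    "read_volume",
    "write_volume",
    "read_pool_table",
    "write_pool_table",
    "write_maps",
    "read_map",
]

_METHODS = ("none", "gaussian", "nlm", "pyramid", "nlm+pyramid")

_POOL_COLUMNS = [
    "name",
    "a_start", "a_lo", "a_hi",
    "w_start", "w_lo", "w_hi",
    "s_start", "s_lo", "s_hi",
]


@dataclass
class RunConfig:
    """A complete, reproducible pipeline run description (YAML or JSON).

    Example::

        data: phantom/data.nii.gz
        i0: phantom/i0.nii.gz
        offsets: phantom/offsets.txt
        pools: phantom/pools.json
        preprocess: nlm
        denoise: {nlm_patch: 5, nlm_search: 11}
        pyramid: {levels: 2, tolerance_pct: 50}
        fit: {max_iterations: 400}
        out: maps/
        seed: 1
    """

    data: str
    offsets: str
    pools: str
    out: str
    i0: str | None = None
    i0_frame: int | None = None
    preprocess: str = "none"
    denoise: dict = field(default_factory=dict)
    pyramid: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    b0_correct: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preprocess not in _METHODS:
            raise ValueError(
                f"preprocess must be one of {_METHODS}, got {self.preprocess!r}"
            )
        for label in ("data", "offsets", "pools"):
            path = getattr(self, label)
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.i0 is not None and not Path(self.i0).exists():
            raise FileNotFoundError(f"i0 file not found: {self.i0}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: expected a mapping of run options")
        return cls(**payload)

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    def execute(self) -> dict:
        """Run the configured fit and write maps; returns the manifest."""
        from .denoise import DenoiseParams
        from .fitting import FitOptions, fit_volume
        from .pyramid import PyramidConfig

        volume = read_volume(self.data, self.offsets, i0_path=self.i0,
                             i0_frame=self.i0_frame)
        table = read_pool_table(self.pools)
        maps = fit_volume(
            volume, table,
            options=FitOptions(**self.fit),
            preprocess=self.preprocess,
            denoise_params=DenoiseParams(**self.denoise) if self.denoise else None,
            pyramid_config=PyramidConfig(**self.pyramid) if self.pyramid else None,
            b0_correct=self.b0_correct,
        )
        return write_maps(maps, self.out, affine=volume.affine,
                          config=self.as_dict())


def read_offsets(path: str | Path) -> np.ndarray:
    """Read a plain-text offsets file: one ppm value per line."""
    values = [
        float(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
    if not values:
        raise ValueError(f"no offsets found in {path}")
    return np.array(values)


def write_offsets(offsets: np.ndarray, path: str | Path) -> None:
    Path(path).write_text("".join(f"{v:.10g}\n" for v in offsets))


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, np.ndarray]:
    """Stack a directory of single-frame DICOMs in InstanceNumber order."""
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise IOError(f"no DICOM files in {directory}")
    frames = []
    for path in files:
        ds = pydicom.dcmread(str(path))
        frames.append((int(ds.InstanceNumber), ds.pixel_array.astype(float)))
    frames.sort(key=lambda t: t[0])
    data = np.stack([f for _, f in frames], axis=-1)  # (rows, cols, N)
    return data[:, :, None, :], np.eye(4)


def read_volume(
    path: str | Path,
    offsets_path: str | Path,
    i0_path: str | Path | None = None,
    i0_frame: int | None = None,
) -> CESTVolume:
    """Load a 4D CEST series (NIfTI file or DICOM directory) plus offsets.

    The unsaturated reference comes either from a separate volume
    (``i0_path``) or from a designated frame of the series (``i0_frame``,
    0-based index into the file's frame order before sorting); exactly one
    must be given.  The offset count must match the (remaining) frame count.
    """
    path = Path(path)
    offsets = read_offsets(offsets_path)
    if path.is_dir():
        data, affine = _read_dicom_series(path)
    else:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
        if data.ndim == 3:
            data = data[:, :, :, None]
        if data.ndim != 4:
            raise ValueError(f"expected a 4D volume, got shape {data.shape}")

    if (i0_path is None) == (i0_frame is None):
        raise ValueError("provide exactly one of i0_path or i0_frame")
    if i0_frame is not None:
        if not (0 <= i0_frame < data.shape[3]):
            raise ValueError(f"i0_frame {i0_frame} out of range for {data.shape[3]} frames")
        i0 = data[..., i0_frame]
        data = np.delete(data, i0_frame, axis=3)
    else:
        i0_img = nib.load(str(i0_path))
        i0 = np.asarray(i0_img.dataobj, dtype=float)
        if i0.ndim == 4 and i0.shape[3] == 1:
            i0 = i0[..., 0]

    if data.shape[3] != offsets.size:
        raise ValueError(
            f"offset count mismatch: {offsets.size} offsets in file, "
            f"{data.shape[3]} image frames"
        )
    return CESTVolume(data=data, i0=i0, offsets=offsets, affine=affine)


def write_volume(volume: CESTVolume, data_path: str | Path, i0_path: str | Path,
                 offsets_path: str | Path) -> None:
    """Write a volume as 4D NIfTI + I0 NIfTI + offsets text file."""
    nib.save(nib.Nifti1Image(volume.data, volume.affine), str(data_path))
    nib.save(nib.Nifti1Image(volume.i0, volume.affine), str(i0_path))
    write_offsets(volume.offsets, offsets_path)


def _table_from_records(records: list[dict], source: str) -> PoolTable:
    pools = []
    for rec in records:
        missing = [c for c in _POOL_COLUMNS if c not in rec]
        if missing:
            raise ValueError(f"{source}: pool entry missing fields {missing}")
        try:
            pools.append(PoolSpec(
                name=str(rec["name"]),
                **{c: float(rec[c]) for c in _POOL_COLUMNS[1:]},
            ))
        except ValueError as exc:
            raise ValueError(f"{source}: {exc}") from exc
    return PoolTable(pools)


def read_pool_table(path: str | Path) -> PoolTable:
    """Read a pool table from JSON (``{"pools": [...]}`` or a bare list) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = payload["pools"] if isinstance(payload, dict) else payload
    else:
        records = pd.read_csv(path).to_dict("records")
    return _table_from_records(records, str(path))


def write_pool_table(table: PoolTable, path: str | Path) -> None:
    path = Path(path)
    records = [
        {c: getattr(p, c) for c in _POOL_COLUMNS} for p in table
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"pools": records}, indent=2) + "\n")
    else:
        pd.DataFrame(records, columns=_POOL_COLUMNS).to_csv(path, index=False)


def write_maps(
    maps: ParameterMaps,
    out_dir: str | Path,
    affine: np.ndarray | None = None,
    config: dict | None = None,
) -> dict:
    """Write parameter maps as NIfTI files plus a JSON manifest.

    One file per (pool, parameter), plus the residual sum-of-squares map and
    the convergence mask.  The manifest lists every file and echoes the
    run configuration (method, seed, ...) so results can be reproduced
    exactly.  Returns the manifest dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    files: list[str] = []

    def save(arr: np.ndarray, name: str) -> None:
        nib.save(nib.Nifti1Image(arr.astype(np.float64), affine),
                 str(out_dir / name))
        files.append(name)

    for pool in maps.pool_names:
        for param, stack in (
            ("amplitude", maps.amplitude),
            ("frequency", maps.frequency),
            ("width", maps.width),
            ("integral", maps.integral),
        ):
            save(stack[pool], f"{pool}_{param}.nii.gz")
    save(maps.ssq, "ssq.nii.gz")
    save(maps.converged.astype(np.float64), "converged.nii.gz")

    manifest = {
        "files": files,
        "pools": list(maps.pool_names),
        "config": config or {},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)
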