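"""Inversion-recovery image series container and NIfTI/JSON round-trip.

An :class:`IRSeries` is a stack of co-registered 2D magnitude images, one per
inversion time, together with the acquisition metadata needed for T1
estimation (inversion times, repetition time, pixel size).  Series are stored
on disk as a single 3D NIfTI volume (x, y, TI) with a JSON sidecar carrying
the timing metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["IRSeries"]


@dataclass
class IRSeries:
    """A magnitude inversion-recovery series.

    Parameters
    ----------
    images : ndarray, shape (n_ti, ny, nx)
        Non-negative magnitude images, one per inversion time.
    inversion_times_ms : ndarray, shape (n_ti,)
        Inversion times in milliseconds, strictly increasing.
    repetition_time_ms : float
        Repetition time in milliseconds.
    pixel_size_mm : float
        Isotropic in-plane pixel size in millimetres.
    """

    images: np.ndarray
    inversion_times_ms: np.ndarray
    repetition_time_ms: float
    pixel_size_mm: float = 0.47
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.inversion_times_ms = np.asarray(self.inversion_times_ms, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_ti, ny, nx) stack")
        if self.images.shape[0] != self.inversion_times_ms.size:
            raise ValueError(
                f"{self.images.shape[0]} images but "
                f"{self.inversion_times_ms.size} inversion times"
            )
        if np.any(np.diff(self.inversion_times_ms) <= 0):
            raise ValueError("inversion times must be strictly increasing")
        if np.any(self.images < 0):
            raise ValueError("magnitude images must be non-negative")

    @property
    def n_ti(self) -> int:
        return int(self.inversion_times_ms.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def to_nifti(self, path: str | Path) -> Path:
        """Write the series as ``<path>.nii.gz`` plus a ``.json`` sidecar."""
        path = Path(path)
        if path.suffix == ".gz":
            stem = path.with_suffix("").with_suffix("")
        elif path.suffix == ".nii":
            stem = path.with_suffix("")
        else:
            stem = path
        nii_path = stem.with_suffix(".nii.gz")
        affine = np.diag([self.pixel_size_mm, self.pixel_size_mm, 1.0, 1.0])
        # store as (nx, ny, n_ti) so each TI frame is one slice
        data = np.moveaxis(self.images, 0, -1).transpose(1, 0, 2)
        nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(nii_path))
        sidecar = {
            "inversion_times_ms": self.inversion_times_ms.tolist(),
            "repetition_time_ms": float(self.repetition_time_ms),
            "pixel_size_mm": float(self.pixel_size_mm),
            **self.meta,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return nii_path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "IRSeries":
        """Load a series written by :meth:`to_nifti`."""
        path = Path(path)
        stem = path
        while stem.suffix in {".nii", ".gz"}:
            stem = stem.with_suffix("")
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        images = np.moveaxis(data.transpose(1, 0, 2), -1, 0)
        return cls(
            images=images,
            inversion_times_ms=np.asarray(sidecar.pop("inversion_times_ms")),
            repetition_time_ms=sidecar.pop("repetition_time_ms"),
            pixel_size_mm=sidecar.pop("pixel_size_mm", 0.47),
            meta=sidecar,
        )
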