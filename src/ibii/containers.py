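"""Shared data containers for the IBII processing chain.

Conventions used throughout the package:

* fields are stored as ``(n_frames, n_rows, n_cols)`` arrays;
* column index grows with x, the impact axis, with x = 0 at the free edge and
  x = L at the impacted edge;
* row index grows with y, measured from the section centroid, so row 0 sits at
  y = -H/2;
* SI units everywhere (m, s, Pa, kg/m^3).

The validity mask distinguishes measured pixels from the one-pitch border the
grid method cannot resolve, and from border pixels filled by extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import h5py
import numpy as np

__all__ = ["MASK_INVALID", "MASK_VALID", "MASK_EXTRAPOLATED", "FieldSequence", "GridImageStack"]

MASK_INVALID = 0
MASK_VALID = 1
MASK_EXTRAPOLATED = 2

_ARRAY_FIELDS = (
    "ux", "uy", "ax", "ay",
    "eps_xx", "eps_yy", "gamma_xy",
    "eps_xx_rate", "eps_yy_rate", "gamma_xy_rate",
)


@dataclass
class FieldSequence:
    """Per-frame gridded kinematic fields; the currency of the pipeline.

    Any of the arrays may be absent (None).  ``mask`` is a 2-D int8 map with
    values in {MASK_INVALID, MASK_VALID, MASK_EXTRAPOLATED}.
    """

    pixel_size: float
    dt: float
    ux: np.ndarray | None = None
    uy: np.ndarray | None = None
    ax: np.ndarray | None = None
    ay: np.ndarray | None = None
    eps_xx: np.ndarray | None = None
    eps_yy: np.ndarray | None = None
    gamma_xy: np.ndarray | None = None
    eps_xx_rate: np.ndarray | None = None
    eps_yy_rate: np.ndarray | None = None
    gamma_xy_rate: np.ndarray | None = None
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.shape
        for name in _ARRAY_FIELDS:
            arr = getattr(self, name)
            if arr is not None and arr.shape != shape:
                raise ValueError(f"field {name} has shape {arr.shape}, expected {shape}")
        if self.mask is None and shape is not None:
            self.mask = np.full(shape[1:], MASK_VALID, dtype=np.int8)

    @property
    def shape(self) -> tuple[int, int, int] | None:
        for name in _ARRAY_FIELDS:
            arr = getattr(self, name)
            if arr is not None:
                return arr.shape
        return None

    @property
    def n_frames(self) -> int:
        return self.shape[0]

    @property
    def valid(self) -> np.ndarray:
        """Boolean map of pixels carrying data (measured or extrapolated)."""
        return self.mask != MASK_INVALID

    def x_coords(self) -> np.ndarray:
        """x of pixel-column centres, measured from the free edge (m)."""
        return (np.arange(self.shape[2]) + 0.5) * self.pixel_size

    def y_coords(self) -> np.ndarray:
        """y of pixel-row centres, measured from the section centroid (m)."""
        n_rows = self.shape[1]
        return (np.arange(n_rows) + 0.5 - n_rows / 2.0) * self.pixel_size

    def times(self) -> np.ndarray:
        return np.arange(self.shape[0]) * self.dt

    def copy(self) -> "FieldSequence":
        kw = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else (dict(v) if isinstance(v, dict) else v)
        return FieldSequence(**kw)

    # ---------------------------------------------------------------- I/O
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as h5:
            h5.attrs["pixel_size"] = self.pixel_size
            h5.attrs["dt"] = self.dt
            for k, v in self.meta.items():
                h5.attrs[f"meta_{k}"] = v
            for name in _ARRAY_FIELDS + ("mask",):
                arr = getattr(self, name)
                if arr is not None:
                    h5.create_dataset(name, data=arr)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "FieldSequence":
        with h5py.File(path, "r") as h5:
            kw = {"pixel_size": float(h5.attrs["pixel_size"]), "dt": float(h5.attrs["dt"])}
            kw["meta"] = {
                k[len("meta_"):]: v for k, v in h5.attrs.items() if k.startswith("meta_")
            }
            for name in _ARRAY_FIELDS + ("mask",):
                if name in h5:
                    kw[name] = h5[name][()]
        return cls(**kw)


@dataclass
class GridImageStack:
    """Synthetic or measured grid images plus grid metadata.

    ``images``: (n_frames, n_rows, n_cols) grey levels (counts); frame 0 is
    the pre-impact reference.  ``pitch`` is the grid period in metres and
    ``pxpp`` the (integer) number of pixels sampling one period; the grid
    method needs pxpp >= 5 to isolate the first harmonic (the study's cameras
    used 6, 5 for one animal's specimens).
    """

    images: np.ndarray
    pitch: float
    pxpp: int
    dt: float
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pxpp < 5:
            raise ValueError("grid sampling pxpp must be >= 5")
        if self.images.ndim != 3:
            raise ValueError("images must be (n_frames, n_rows, n_cols)")

    @property
    def pixel_size(self) -> float:
        return self.pitch / self.pxpp

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(path, self.images.astype(np.uint16), metadata={
            "pitch_m": self.pitch, "pxpp": self.pxpp, "dt_s": self.dt,
        })

    @classmethod
    def from_tiff(cls, path: str | Path, pitch: float, pxpp: int, dt: float) -> "GridImageStack":
        import tifffile

        return cls(images=tifffile.imread(path), pitch=pitch, pxpp=pxpp, dt=dt)
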