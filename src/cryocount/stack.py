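"""Two-channel cryo-image volume container and TIFF I/O.

A cryo-image volume is an aligned stack of block-face fluorescence images,
one per 40 µm-scale section, with a red and a green channel.  Arrays are
indexed ``(slice, row, col)`` with slice index increasing into the block
(deeper sections have larger indices).  Sub-pixel positions use ``x`` for
columns and ``y`` for rows; pixel ``(r, c)`` covers the unit square centred
on ``(r, c)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """Aligned 3D two-channel (red, green) fluorescence volume.

    Parameters
    ----------
    red, green : ndarray, shape (slices, rows, cols)
        Per-channel intensity in arbitrary digital units.
    pixel_size_um : float
        In-plane pixel size in micrometres.
    section_um : float
        Section (slice) thickness in micrometres.
    """

    red: np.ndarray
    green: np.ndarray | None
    pixel_size_um: float = 15.6
    section_um: float = 40.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=np.float64)
        if self.red.ndim != 3:
            raise ValueError("red channel must be 3D (slices, rows, cols)")
        if self.green is not None:
            self.green = np.asarray(self.green, dtype=np.float64)
            if self.green.shape != self.red.shape:
                raise ValueError("red and green channel shapes differ")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.red.shape

    @property
    def n_slices(self) -> int:
        return self.red.shape[0]

    def copy(self) -> "ImageStack":
        return ImageStack(
            self.red.copy(),
            None if self.green is None else self.green.copy(),
            self.pixel_size_um,
            self.section_um,
            dict(self.meta),
        )

    # -- TIFF dialect: one multi-page float32 TIFF per channel ------------

    def save(self, directory: str | Path, prefix: str = "stack") -> None:
        """Write ``<prefix>_red.tif``, ``<prefix>_green.tif`` and a JSON
        sidecar with the voxel geometry (one TIFF page per section, page
        order = acquisition order)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(directory / f"{prefix}_red.tif",
                         self.red.astype(np.float32))
        if self.green is not None:
            tifffile.imwrite(directory / f"{prefix}_green.tif",
                             self.green.astype(np.float32))
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "section_um": self.section_um,
            "shape": list(self.shape),
            "channels": ["red"] + ([] if self.green is None else ["green"]),
        }
        (directory / f"{prefix}_meta.json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path, prefix: str = "stack") -> "ImageStack":
        directory = Path(directory)
        red = np.asarray(tifffile.imread(directory / f"{prefix}_red.tif"),
                         dtype=np.float64)
        if red.ndim == 2:
            red = red[None]
        green_path = directory / f"{prefix}_green.tif"
        green = None
        if green_path.exists():
            green = np.asarray(tifffile.imread(green_path), dtype=np.float64)
            if green.ndim == 2:
                green = green[None]
        meta_path = directory / f"{prefix}_meta.json"
        pixel_size_um, section_um = 15.6, 40.0
        if meta_path.exists():
            sidecar = json.loads(meta_path.read_text())
            pixel_size_um = float(sidecar.get("pixel_size_um", pixel_size_um))
            section_um = float(sidecar.get("section_um", section_um))
        return cls(red, green, pixel_size_um, section_um)
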