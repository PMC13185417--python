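"""Core image containers: multi-channel 3D stacks and cell regions of interest.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)``, 0-based;
* the axial sampling is coarse relative to the lateral one (0.3 µm z-steps
  versus ~0.1 µm pixels for a 60x objective), so object geometry is
  anisotropic in voxel space;
* all sizes are reported in voxels (no µm³ conversion by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: z-slice counts used by the imaging protocols this package models
#: (5 slices for TASQ chemodetection, 7 for gamma-H2AX immunodetection).
PROTOCOL_Z_COUNTS = (5, 7)


class ImageStackError(ValueError):
    """Raised for malformed stacks or ROIs."""


@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence stack.

    Parameters
    ----------
    channels
        Mapping from channel name (``"dapi"``, ``"foci"``) to a 3D float
        array indexed ``(z, y, x)``. All channels must share one shape and
        contain non-negative intensities.
    z_spacing_um
        Axial step between consecutive z-slices, in micrometres.
    pixel_size_um
        Lateral pixel size, in micrometres (metadata only).
    provenance
        Free-form record of the processing applied so far (background
        estimates, ROI ids, seeds).
    """

    channels: dict[str, np.ndarray]
    z_spacing_um: float = 0.3
    pixel_size_um: float = 0.108
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ImageStackError("stack must carry at least one channel")
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ImageStackError(f"channels disagree in shape: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ImageStackError(f"channel {name!r} is not 3D")
            if np.any(arr < 0):
                raise ImageStackError(f"channel {name!r} has negative intensities")
        nz = self.shape[0]
        if nz not in PROTOCOL_Z_COUNTS:
            warnings.warn(
                f"stack has {nz} z-slices; the imaging protocols modelled here "
                f"use {PROTOCOL_Z_COUNTS}",
                stacklevel=3,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def copy(self) -> "ImageStack":
        return ImageStack(
            channels={k: v.copy() for k, v in self.channels.items()},
            z_spacing_um=self.z_spacing_um,
            pixel_size_um=self.pixel_size_um,
            provenance=dict(self.provenance),
        )

    # ------------------------------------------------------------------ I/O
    def write(self, directory: str | Path, stem: str = "stack") -> dict[str, Path]:
        """Write one multi-page TIFF per channel plus a JSON metadata sidecar.

        Pages are z-slices in order; axis order inside each page is (y, x).
        Returns the mapping of written paths.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for name, arr in self.channels.items():
            path = directory / f"{stem}_{name}.tif"
            tifffile.imwrite(path, arr.astype(np.float32))
            written[name] = path
        sidecar = directory / f"{stem}_meta.json"
        meta = {
            "axes": "zyx",
            "z_spacing_um": self.z_spacing_um,
            "pixel_size_um": self.pixel_size_um,
            "channels": sorted(self.channels),
            "provenance": self.provenance,
        }
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
        written["meta"] = sidecar
        return written

    @classmethod
    def read(cls, directory: str | Path, stem: str = "stack") -> "ImageStack":
        directory = Path(directory)
        meta = json.loads((directory / f"{stem}_meta.json").read_text())
        channels = {
            name: np.asarray(tifffile.imread(directory / f"{stem}_{name}.tif"), dtype=float)
            for name in meta["channels"]
        }
        return cls(
            channels=channels,
            z_spacing_um=meta["z_spacing_um"],
            pixel_size_um=meta["pixel_size_um"],
            provenance=meta.get("provenance", {}),
        )


@dataclass
class CellROI:
    """One outlined cell, as a 3D boolean mask over the stack grid.

    The original experiments outline cells by hand on the projected image;
    synthetic studies ship the outline with the ground truth. ``provenance``
    records which of the two produced this ROI.
    """

    roi_id: str
    mask: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ImageStackError("ROI mask must be 3D")
        if not self.mask.any():
            raise ImageStackError(f"ROI {self.roi_id!r} is empty")
        if self.provenance not in ("manual", "synthetic"):
            raise ImageStackError("ROI provenance must be 'manual' or 'synthetic'")
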