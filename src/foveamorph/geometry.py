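"""Scan geometry and the B-scan raster container.

The default geometry mimics a spectral-domain macular-cube B-scan:
512 A-scans spanning 6 mm laterally (11.72 µm per A-scan) and 1024 axial
pixels spanning 2 mm in depth (1.95 µm per pixel).  Axial coordinate 0 is
the most anterior (vitreous) row and increases posteriorly; A-scan index
runs temporal→nasal for a right eye (OD) and nasal→temporal for a left
eye (OS).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ScanGeometry", "BScan", "save_bscan", "load_bscan"]

#: intensity ceiling used when quantizing float rasters to 16 bit
_INTENSITY_MAX = 2.0


@dataclass(frozen=True)
class ScanGeometry:
    """Raster dimensions and physical pixel scales of a B-scan."""

    n_ascans: int = 512
    n_axial: int = 1024
    lateral_scale: float = 6000.0 / 512  # µm per A-scan
    axial_scale: float = 2000.0 / 1024   # µm per axial pixel

    def __post_init__(self) -> None:
        if self.n_ascans < 1 or self.n_axial < 1:
            raise ValueError("scan must have at least one A-scan and one axial pixel")
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise ValueError("pixel scales must be positive")

    @property
    def width_um(self) -> float:
        return self.n_ascans * self.lateral_scale

    @property
    def depth_um(self) -> float:
        return self.n_axial * self.axial_scale

    def lateral_positions(self, laterality: str) -> np.ndarray:
        """Signed lateral position (µm) of each A-scan, nasal positive.

        The sign convention makes nasal retina positive for both eyes, so
        downstream landmarks are comparable across lateralities.
        """
        if laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {laterality!r}")
        idx = np.arange(self.n_ascans, dtype=float)
        centre = (self.n_ascans - 1) / 2.0
        signed = (idx - centre) * self.lateral_scale
        return signed if laterality == "OD" else -signed


@dataclass
class BScan:
    """A single OCT B-scan raster with physical pixel scales."""

    pixels: np.ndarray
    axial_scale: float
    lateral_scale: float
    laterality: str = "OD"
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.axial_scale <= 0 or self.lateral_scale <= 0:
            raise ValueError("pixel scales must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")

    @property
    def n_axial(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.pixels.shape[1]


def save_bscan(bscan: BScan, path: str | Path) -> Path:
    """Write a B-scan as 16-bit grayscale TIFF/PNG plus a JSON sidecar.

    Intensities are clipped to [0, 2] and quantized linearly; the sidecar
    ``<path>.json`` records both pixel scales, laterality, eye id and the
    quantization ceiling so :func:`load_bscan` can restore physical units.
    """
    path = Path(path)
    raw = np.clip(bscan.pixels, 0.0, _INTENSITY_MAX)
    img16 = np.round(raw / _INTENSITY_MAX * 65535.0).astype(np.uint16)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img16)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, img16)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use .tif/.tiff/.png)")
    sidecar = {
        "axial_scale_um_per_px": bscan.axial_scale,
        "lateral_scale_um_per_px": bscan.lateral_scale,
        "laterality": bscan.laterality,
        "eye_id": bscan.eye_id,
        "intensity_max": _INTENSITY_MAX,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def load_bscan(path: str | Path) -> BScan:
    """Read a B-scan written by :func:`save_bscan`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        img16 = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        img16 = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    pixels = img16.astype(float) / 65535.0 * meta["intensity_max"]
    return BScan(
        pixels=pixels,
        axial_scale=meta["axial_scale_um_per_px"],
        lateral_scale=meta["lateral_scale_um_per_px"],
        laterality=meta["laterality"],
        eye_id=meta.get("eye_id", ""),
    )
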