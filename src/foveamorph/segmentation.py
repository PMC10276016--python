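"""Boundary annotation ingestion, RPE flattening and thickness profiles.

A :class:`BoundarySet` holds one axial position (in pixels, anterior = 0,
possibly fractional) per A-scan for each of seven retinal boundaries,
ordered anterior→posterior::

    ILM  GCLp_inner  GCLp_outer  ONL_inner  ONL_outer  ISOS  RPE_posterior

Flattening shifts every A-scan column by an integer so the posterior RPE
boundary becomes (nearly) constant; because all boundaries of a column
share the same integer shift, every pairwise boundary distance — hence
every thickness — is preserved to floating-point addition precision.

Thickness profiles convert boundary distances to micrometres and resolve
the lateral axis so nasal retina is positive for either eye.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .geometry import BScan

__all__ = [
    "BOUNDARY_ORDER",
    "BoundarySet",
    "BoundaryOrderError",
    "ThicknessProfile",
    "read_boundaries",
    "write_boundaries",
    "flatten_to_rpe",
    "thickness_profiles",
    "moving_average",
]

logger = logging.getLogger(__name__)

BOUNDARY_ORDER = (
    "ILM",
    "GCLp_inner",
    "GCLp_outer",
    "ONL_inner",
    "ONL_outer",
    "ISOS",
    "RPE_posterior",
)

#: longest run of missing A-scans that is repaired by linear interpolation
MAX_GAP = 3


class BoundaryOrderError(ValueError):
    """Raised when boundaries cross (violate the anterior→posterior order)."""


@dataclass
class BoundarySet:
    """Per-A-scan axial positions (pixels) of the seven retinal boundaries."""

    boundaries: dict[str, np.ndarray]
    laterality: str = "OD"
    eye_id: str = ""

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        missing = [n for n in BOUNDARY_ORDER if n not in self.boundaries]
        if missing:
            raise ValueError(f"missing boundaries: {missing}")
        arrays = {}
        n = None
        for name in BOUNDARY_ORDER:
            arr = np.asarray(self.boundaries[name], dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"boundary {name!r} must be a non-empty 1-D array")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError(f"boundary {name!r} has {arr.size} A-scans, expected {n}")
            if np.isnan(arr).any():
                raise ValueError(f"boundary {name!r} contains missing values")
            arrays[name] = arr
        self.boundaries = arrays

    @property
    def n_ascans(self) -> int:
        return self.boundaries[BOUNDARY_ORDER[0]].size

    def __getitem__(self, name: str) -> np.ndarray:
        return self.boundaries[name]

    def validate(self, n_axial: int | None = None, tol: float = 1e-6) -> None:
        """Check the anterior→posterior ordering and, optionally, raster bounds."""
        stack = np.stack([self.boundaries[n] for n in BOUNDARY_ORDER])
        diffs = np.diff(stack, axis=0)
        if (diffs < -tol).any():
            k, i = np.argwhere(diffs < -tol)[0]
            raise BoundaryOrderError(
                f"boundary {BOUNDARY_ORDER[k + 1]!r} is anterior to "
                f"{BOUNDARY_ORDER[k]!r} at A-scan {i}"
            )
        if (stack < -tol).any():
            raise ValueError("boundary position above the raster (negative pixels)")
        if n_axial is not None and (stack > n_axial - 1 + tol).any():
            raise ValueError(f"boundary position below the raster (>{n_axial - 1} px)")

    def mirrored(self) -> "BoundarySet":
        """Horizontally mirrored copy with toggled laterality.

        Mirroring the raster and swapping OD/OS leaves the signed
        (nasal-positive) lateral axis unchanged, so thickness profiles and
        all derived metrics are invariant under this operation.
        """
        return BoundarySet(
            boundaries={n: a[::-1].copy() for n, a in self.boundaries.items()},
            laterality="OS" if self.laterality == "OD" else "OD",
            eye_id=self.eye_id,
        )


def _fill_gaps(name: str, positions: dict[int, float], n_ascans: int) -> np.ndarray:
    """Linearly interpolate runs of ≤ MAX_GAP missing A-scans, else reject."""
    present = np.zeros(n_ascans, dtype=bool)
    arr = np.full(n_ascans, np.nan)
    for i, v in positions.items():
        present[i] = True
        arr[i] = v
    if not present.any():
        raise ValueError(f"boundary {name!r} has no annotated A-scans")
    missing = ~present
    if missing.any():
        # locate runs of consecutive missing indices
        idx = np.flatnonzero(missing)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            if len(run) > MAX_GAP:
                raise ValueError(
                    f"boundary {name!r}: gap of {len(run)} A-scans at index "
                    f"{run[0]} exceeds the interpolation limit of {MAX_GAP}"
                )
            logger.info(
                "boundary %s: interpolating %d-A-scan gap at index %d",
                name, len(run), run[0],
            )
        xp = np.flatnonzero(present)
        arr[missing] = np.interp(np.flatnonzero(missing), xp, arr[present])
    return arr


def read_boundaries(path: str | Path, fmt: str | None = None) -> BoundarySet:
    """Read a boundary annotation file (long CSV or JSON).

    CSV layout: columns ``boundary_name, a_scan_index, axial_px`` plus
    optional ``eye_id`` / ``laterality`` columns.  Isolated gaps of at
    most three consecutive A-scans per boundary are linearly interpolated
    (and logged); larger gaps and crossing boundaries are rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path)
        required = {"boundary_name", "a_scan_index", "axial_px"}
        if not required.issubset(df.columns):
            raise ValueError(f"boundary CSV must have columns {sorted(required)}")
        laterality = str(df["laterality"].iloc[0]) if "laterality" in df else "OD"
        eye_id = str(df["eye_id"].iloc[0]) if "eye_id" in df else path.stem
        n_ascans = int(df["a_scan_index"].max()) + 1
        boundaries = {}
        for name, sub in df.groupby("boundary_name"):
            positions = dict(zip(sub["a_scan_index"].astype(int), sub["axial_px"].astype(float)))
            boundaries[str(name)] = _fill_gaps(str(name), positions, n_ascans)
    elif fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        laterality = payload.get("laterality", "OD")
        eye_id = payload.get("eye_id", path.stem)
        boundaries = {k: np.asarray(v, dtype=float) for k, v in payload["boundaries"].items()}
    else:
        raise ValueError(f"unsupported boundary format {fmt!r} (use csv or json)")
    bset = BoundarySet(boundaries=boundaries, laterality=laterality, eye_id=eye_id)
    bset.validate()
    return bset


def write_boundaries(bset: BoundarySet, path: str | Path) -> Path:
    """Write a BoundarySet as long CSV or JSON (chosen by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for name in BOUNDARY_ORDER:
            arr = bset[name]
            for i, v in enumerate(arr):
                rows.append((bset.eye_id, bset.laterality, name, i, v))
        pd.DataFrame(
            rows, columns=["eye_id", "laterality", "boundary_name", "a_scan_index", "axial_px"]
        ).to_csv(path, index=False)
    elif path.suffix.lower() == ".json":
        payload = {
            "eye_id": bset.eye_id,
            "laterality": bset.laterality,
            "boundaries": {n: bset[n].tolist() for n in BOUNDARY_ORDER},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
    else:
        raise ValueError(f"unsupported suffix {path.suffix!r}")
    return path


def flatten_to_rpe(
    bset: BoundarySet, bscan: BScan | None = None
) -> tuple[BoundarySet, BScan | None]:
    """Flatten boundaries (and optionally the raster) to the posterior RPE.

    Each A-scan column is shifted by the integer nearest to
    ``round(median(RPE)) − RPE[i]``, so the output RPE is constant to
    within half a pixel (exactly constant for integer-valued input) and
    every inter-boundary distance is preserved.  The operation is
    idempotent.  Raster columns are shifted with zero fill; shifts that
    would push any boundary off the raster are rejected.
    """
    rpe = bset["RPE_posterior"]
    target = float(np.round(np.median(rpe)))
    # floor(x + 0.5) rounding gives a fixed tie direction, which makes the
    # transform idempotent (a second pass always yields zero offsets)
    offsets = np.floor(target - rpe + 0.5).astype(int)

    new_bounds = {n: bset[n] + offsets for n in BOUNDARY_ORDER}
    flat = BoundarySet(new_bounds, laterality=bset.laterality, eye_id=bset.eye_id)
    n_axial = bscan.n_axial if bscan is not None else None
    try:
        flat.validate(n_axial=n_axial)
    except ValueError as exc:
        raise ValueError(f"flattening pushed a boundary off the raster: {exc}") from exc

    flat_scan = None
    if bscan is not None:
        if bscan.n_ascans != bset.n_ascans:
            raise ValueError("raster and boundary set have different A-scan counts")
        pixels = np.zeros_like(bscan.pixels)
        h = bscan.n_axial
        for i, off in enumerate(offsets):
            col = bscan.pixels[:, i]
            if off >= 0:
                pixels[off:, i] = col[: h - off]
            else:
                pixels[: h + off, i] = col[-off:]
        flat_scan = BScan(
            pixels=pixels,
            axial_scale=bscan.axial_scale,
            lateral_scale=bscan.lateral_scale,
            laterality=bscan.laterality,
            eye_id=bscan.eye_id,
        )
    return flat, flat_scan


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with odd window, edge values replicated."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"smooth window must be a positive odd integer, got {window}")
    if window == 1:
        return np.asarray(x, dtype=float).copy()
    return uniform_filter1d(np.asarray(x, dtype=float), size=window, mode="nearest")


@dataclass
class ThicknessProfile:
    """Per-A-scan layer thickness (µm) on a signed nasal-positive axis.

    Arrays are ordered by ascending lateral position (temporal → nasal)
    regardless of the eye's raster order, so profiles from OD and OS eyes
    are directly comparable.  Raw arrays carry the exact boundary
    distances; ``*_smooth`` views (used only for landmark localization)
    apply a centred moving average of ``smooth_window`` A-scans.
    """

    lateral_um: np.ndarray
    gclp: np.ndarray
    onl: np.ndarray
    rt: np.ndarray
    isos_elev: np.ndarray  # (RPE_posterior − ISOS) · axial_scale, µm
    smooth_window: int = 5
    laterality: str = "OD"
    eye_id: str = ""

    def __post_init__(self) -> None:
        n = self.lateral_um.size
        for name in ("gclp", "onl", "rt", "isos_elev"):
            if getattr(self, name).size != n:
                raise ValueError(f"profile array {name!r} length mismatch")

    @property
    def n_ascans(self) -> int:
        return self.lateral_um.size

    def smoothed(self, name: str) -> np.ndarray:
        return moving_average(getattr(self, name), self.smooth_window)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lateral_um": self.lateral_um,
                "gclp_um": self.gclp,
                "onl_um": self.onl,
                "rt_um": self.rt,
                "isos_elev_um": self.isos_elev,
            }
        )


def thickness_profiles(
    bset: BoundarySet,
    axial_scale: float,
    lateral_scale: float,
    smooth_window: int = 5,
) -> ThicknessProfile:
    """Convert a BoundarySet into µm thickness profiles.

    Thickness is a boundary difference, so the result is identical for
    flattened and unflattened input.  ``smooth_window`` must be odd; 1
    disables smoothing.
    """
    if smooth_window % 2 == 0 or smooth_window < 1:
        raise ValueError(f"smooth window must be a positive odd integer, got {smooth_window}")
    if axial_scale <= 0 or lateral_scale <= 0:
        raise ValueError("pixel scales must be positive")
    bset.validate()

    gclp = (bset["GCLp_outer"] - bset["GCLp_inner"]) * axial_scale
    onl = (bset["ONL_outer"] - bset["ONL_inner"]) * axial_scale
    rt = (bset["RPE_posterior"] - bset["ILM"]) * axial_scale
    elev = (bset["RPE_posterior"] - bset["ISOS"]) * axial_scale

    n = bset.n_ascans
    centre = (n - 1) / 2.0
    signed = (np.arange(n, dtype=float) - centre) * lateral_scale
    if bset.laterality == "OS":
        signed = -signed
        order = slice(None, None, -1)  # reorder so lateral is ascending
    else:
        order = slice(None)

    return ThicknessProfile(
        lateral_um=signed[order].copy(),
        gclp=gclp[order].copy(),
        onl=onl[order].copy(),
        rt=rt[order].copy(),
        isos_elev=elev[order].copy(),
        smooth_window=smooth_window,
        laterality=bset.laterality,
        eye_id=bset.eye_id,
    )
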