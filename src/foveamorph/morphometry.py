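"""Foveal landmark detection and the six foveal parameters.

The foveal centre (FC) is the A-scan where the photoreceptor IS/OS
junction is most elevated above the (flattened) RPE within a central
search window; if the IS/OS elevation is essentially flat there, the
A-scan of minimum retinal thickness is used instead.  The foveal wall
maximum (FWM) on each side is the A-scan where the smoothed GCL+
thickness profile attains its maximum within a window away from FC.

From these landmarks the per-eye parameters are read off the raw
(unsmoothed) profiles:

* ``GCLp_FC``, ``ONL_FC``, ``RT_FC`` — thickness at FC
* ``RT_FWM_nasal/temporal`` — retinal thickness at the rims
* ``FD`` — foveal depth, mean rim retinal thickness minus ``RT_FC``
* ``GCLp_Q2Q`` — GCL+ averaged over the two quarter points located 25 %
  of the FC→FWM distance from FC on each side

Smoothing is used only to localize argmax landmarks; point values come
from the raw profile so degenerate cases (e.g. zero GCL+ at FC) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import BoundarySet, ThicknessProfile, thickness_profiles

__all__ = [
    "FovealCentre",
    "RimPair",
    "FovealMetrics",
    "locate_foveal_centre",
    "locate_rims",
    "compute_metrics",
    "extract_metrics",
    "metrics_table",
]

METRIC_COLUMNS = [
    "eye_id",
    "group_label",
    "laterality",
    "GCLp_FC",
    "GCLp_Q2Q",
    "ONL_FC",
    "RT_FC",
    "FD",
    "RT_FWM_nasal",
    "RT_FWM_temporal",
    "RT_FWM_mean",
    "fc_lateral_um",
    "rim_lateral_nasal_um",
    "rim_lateral_temporal_um",
    "quality_flags",
]


@dataclass
class FovealCentre:
    index: int
    lateral_um: float
    method: str  # "isos_peak" or "min_rt"
    flags: list[str] = field(default_factory=list)


@dataclass
class RimPair:
    nasal_index: int
    nasal_lateral_um: float
    temporal_index: int
    temporal_lateral_um: float
    flags: list[str] = field(default_factory=list)


@dataclass
class FovealMetrics:
    """The six foveal parameters plus landmark positions for one eye."""

    eye_id: str
    laterality: str
    GCLp_FC: float
    GCLp_Q2Q: float
    ONL_FC: float
    RT_FC: float
    RT_FWM_nasal: float
    RT_FWM_temporal: float
    fc_lateral_um: float
    rim_lateral_nasal_um: float
    rim_lateral_temporal_um: float
    group_label: str = ""
    quality_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.rim_lateral_temporal_um < self.fc_lateral_um < self.rim_lateral_nasal_um):
            raise ValueError(
                "rim/centre geometry violated: expected temporal rim < FC < nasal rim, got "
                f"{self.rim_lateral_temporal_um} / {self.fc_lateral_um} / {self.rim_lateral_nasal_um}"
            )
        for name in ("GCLp_FC", "GCLp_Q2Q", "ONL_FC", "RT_FC", "RT_FWM_nasal", "RT_FWM_temporal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is negative")

    @property
    def RT_FWM_mean(self) -> float:
        return (self.RT_FWM_nasal + self.RT_FWM_temporal) / 2.0

    @property
    def FD(self) -> float:
        """Foveal depth; holds FD = mean(RT@FWM) − RT@FC by construction."""
        return self.RT_FWM_mean - self.RT_FC

    def to_dict(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "group_label": self.group_label,
            "laterality": self.laterality,
            "GCLp_FC": self.GCLp_FC,
            "GCLp_Q2Q": self.GCLp_Q2Q,
            "ONL_FC": self.ONL_FC,
            "RT_FC": self.RT_FC,
            "FD": self.FD,
            "RT_FWM_nasal": self.RT_FWM_nasal,
            "RT_FWM_temporal": self.RT_FWM_temporal,
            "RT_FWM_mean": self.RT_FWM_mean,
            "fc_lateral_um": self.fc_lateral_um,
            "rim_lateral_nasal_um": self.rim_lateral_nasal_um,
            "rim_lateral_temporal_um": self.rim_lateral_temporal_um,
            "quality_flags": ";".join(self.quality_flags),
        }


def _argmax_with_ties(
    values: np.ndarray, candidates: np.ndarray, pref_key: np.ndarray, tol: float = 1e-9
) -> int:
    """Index of the maximum of ``values[candidates]``; ties resolved by the
    smallest ``pref_key`` (and, at an exact key tie, the first = most
    temporal candidate, since candidates are in ascending lateral order)."""
    v = values[candidates]
    top = v.max()
    tied = candidates[v >= top - tol]
    return int(tied[np.argmin(pref_key[tied])])


def locate_foveal_centre(
    profile: ThicknessProfile,
    search_halfwidth_um: float = 750.0,
    flatness_threshold_um: float = 2.0,
) -> FovealCentre:
    """Locate the foveal centre within a window around the scan centre.

    FC is the A-scan of maximum smoothed IS/OS elevation within
    ``±search_halfwidth_um`` of lateral 0.  If the elevation range within
    the window is below ``flatness_threshold_um`` the detector falls back
    to the A-scan of minimum smoothed retinal thickness.  Ties are broken
    toward the window centre; at an exact symmetric tie the temporal
    candidate wins.  An FC on the window edge is flagged as unreliable.
    """
    if search_halfwidth_um <= 0:
        raise ValueError("search_halfwidth_um must be positive")
    lat = profile.lateral_um
    window = np.flatnonzero(np.abs(lat) <= search_halfwidth_um)
    if window.size == 0:
        raise ValueError("foveal-centre search window contains no A-scans")

    dist_from_centre = np.abs(lat)
    elev = profile.smoothed("isos_elev")
    flags: list[str] = []
    if elev[window].max() - elev[window].min() >= flatness_threshold_um:
        method = "isos_peak"
        idx = _argmax_with_ties(elev, window, dist_from_centre)
    else:
        method = "min_rt"
        flags.append("isos_flat_fallback_min_rt")
        idx = _argmax_with_ties(-profile.smoothed("rt"), window, dist_from_centre)
    if idx == window[0] or idx == window[-1]:
        flags.append("fc_on_window_edge")
    return FovealCentre(index=idx, lateral_um=float(lat[idx]), method=method, flags=flags)


def locate_rims(
    profile: ThicknessProfile,
    fc: FovealCentre,
    window_um: tuple[float, float] = (300.0, 3000.0),
) -> RimPair:
    """Locate the nasal and temporal foveal wall maxima (FWM).

    On each side of FC, the FWM is the A-scan of maximum smoothed GCL+
    thickness with lateral distance from FC inside ``window_um``.  Ties
    are broken toward FC; a maximum on the outer window edge is flagged
    (the true rim may lie outside the scan).
    """
    lo, hi = window_um
    if not (0 <= lo < hi):
        raise ValueError(f"invalid rim search window {window_um}")
    lat = profile.lateral_um
    d = lat - fc.lateral_um
    gclp_s = profile.smoothed("gclp")
    dist_from_fc = np.abs(d)

    sides = {}
    flags: list[str] = []
    for side, mask in (("nasal", (d >= lo) & (d <= hi)), ("temporal", (d <= -lo) & (d >= -hi))):
        candidates = np.flatnonzero(mask)
        if candidates.size == 0:
            raise ValueError(f"{side} rim search window contains no A-scans")
        idx = _argmax_with_ties(gclp_s, candidates, dist_from_fc)
        # the true rim may lie outside the scan when the outer window edge
        # attains (or ties) the maximum, even if ties resolve inward
        outer = candidates[-1] if side == "nasal" else candidates[0]
        if gclp_s[outer] >= gclp_s[idx] - 1e-9:
            flags.append(f"rim_at_window_edge_{side}")
        sides[side] = idx
    return RimPair(
        nasal_index=sides["nasal"],
        nasal_lateral_um=float(lat[sides["nasal"]]),
        temporal_index=sides["temporal"],
        temporal_lateral_um=float(lat[sides["temporal"]]),
        flags=flags,
    )


def compute_metrics(
    profile: ThicknessProfile,
    fc: FovealCentre,
    rims: RimPair,
    eye_id: str | None = None,
    group_label: str = "",
) -> FovealMetrics:
    """Read the six foveal parameters off the raw profile at the landmarks.

    Quarter points for GCL+@Q2Q sit at 25 % of the FC→FWM lateral distance
    on each side, rounded to the nearest A-scan.  Landmark quality flags
    are propagated into ``quality_flags``.
    """
    lat = profile.lateral_um

    def nearest(target_um: float) -> int:
        return int(np.argmin(np.abs(lat - target_um)))

    q_nasal = nearest(fc.lateral_um + 0.25 * (rims.nasal_lateral_um - fc.lateral_um))
    q_temporal = nearest(fc.lateral_um + 0.25 * (rims.temporal_lateral_um - fc.lateral_um))

    return FovealMetrics(
        eye_id=profile.eye_id if eye_id is None else eye_id,
        group_label=group_label,
        laterality=profile.laterality,
        GCLp_FC=float(profile.gclp[fc.index]),
        GCLp_Q2Q=float((profile.gclp[q_nasal] + profile.gclp[q_temporal]) / 2.0),
        ONL_FC=float(profile.onl[fc.index]),
        RT_FC=float(profile.rt[fc.index]),
        RT_FWM_nasal=float(profile.rt[rims.nasal_index]),
        RT_FWM_temporal=float(profile.rt[rims.temporal_index]),
        fc_lateral_um=fc.lateral_um,
        rim_lateral_nasal_um=rims.nasal_lateral_um,
        rim_lateral_temporal_um=rims.temporal_lateral_um,
        quality_flags=tuple(fc.flags) + tuple(rims.flags),
    )


def extract_metrics(
    bset: BoundarySet,
    axial_scale: float,
    lateral_scale: float,
    smooth_window: int = 5,
    search_halfwidth_um: float = 750.0,
    rim_window_um: tuple[float, float] = (300.0, 3000.0),
    group_label: str = "",
) -> FovealMetrics:
    """End-to-end extraction: profiles → FC → rims → metrics.

    Thickness and IS/OS elevation are differences of boundary positions
    and therefore invariant to RPE flattening, so this accepts flattened
    or unflattened boundary sets and yields identical results for both.
    """
    profile = thickness_profiles(bset, axial_scale, lateral_scale, smooth_window)
    fc = locate_foveal_centre(profile, search_halfwidth_um)
    rims = locate_rims(profile, fc, rim_window_um)
    return compute_metrics(profile, fc, rims, group_label=group_label)


def metrics_table(metrics: list[FovealMetrics]) -> pd.DataFrame:
    """Stack per-eye metrics into a tidy DataFrame (one row per eye, µm)."""
    df = pd.DataFrame([m.to_dict() for m in metrics])
    return df[METRIC_COLUMNS] if len(df) else pd.DataFrame(columns=METRIC_COLUMNS)
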