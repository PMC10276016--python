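"""Synthetic foveal cohorts, ground-truth boundaries and speckled B-scans.

The generator works at three levels:

1. :func:`sample_cohort_metrics` draws per-eye target parameters from a
   truncated multivariate normal calibrated to the reference cohort
   summaries (:mod:`foveamorph.reference`).  Four parameters are sampled
   directly (GCL+@FC, GCL+@Q2Q, ONL@FC, FD); retinal thickness at the
   foveal centre is the structural sum GCL+ + ONL + residual layers, and
   rim retinal thickness is RT@FC + FD, so per-eye anatomical identities
   hold exactly.
2. :func:`build_boundaries` solves the inverse problem: it constructs
   smooth, single-valued, non-crossing boundary polylines (a raised-rim
   pit) whose extracted morphometry reproduces the target parameters.
3. :func:`render_bscan` paints piecewise-constant layer reflectivities
   between the boundaries and applies multiplicative unit-mean gamma
   speckle.

All randomness flows through a caller-supplied integer seed; identical
seeds give identical tables, boundaries and rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import reference as ref
from .geometry import BScan, ScanGeometry
from .segmentation import BOUNDARY_ORDER, BoundarySet

__all__ = [
    "CohortSpec",
    "EyeGeometry",
    "control_spec",
    "ept_spec",
    "sample_cohort_metrics",
    "build_boundaries",
    "build_cohort_boundaries",
    "render_bscan",
    "DEFAULT_REFLECTIVITIES",
]

#: anatomical floor (µm) for the residual layers between ONL and RPE plus
#: INL/OPL — these cannot vanish in an intact retina
RESIDUAL_FLOOR = 50.0


def default_correlation(group_label: str) -> pd.DataFrame:
    """Default correlation among the sampled parameters (G, Q2Q, ONL, FD).

    EPT-NoROP eyes show strong coupling of all thickness parameters and an
    opposite-signed coupling with foveal depth; in mature control eyes the
    central GCL+ is decoupled from the other parameters and only weak
    structure remains.  Correlations of RT@FC / RT@FWM are induced by
    their structural definitions and are not specified here.
    """
    p = list(ref.SAMPLED_PARAMS)
    if group_label == "EPT-NoROP":
        m = np.array(
            [
                [1.0, 0.7, 0.7, -0.7],
                [0.7, 1.0, 0.7, -0.7],
                [0.7, 0.7, 1.0, -0.7],
                [-0.7, -0.7, -0.7, 1.0],
            ]
        )
    elif group_label == "control":
        m = np.array(
            [
                [1.0, 0.4, 0.0, 0.0],
                [0.4, 1.0, 0.2, -0.2],
                [0.0, 0.2, 1.0, -0.3],
                [0.0, -0.2, -0.3, 1.0],
            ]
        )
    else:
        raise ValueError(f"unknown group label {group_label!r}")
    return pd.DataFrame(m, index=p, columns=p)


@dataclass
class CohortSpec:
    """Distributional recipe for one synthetic cohort.

    ``param_means``/``param_sds`` cover the sampled parameters
    (GCL+@FC, GCL+@Q2Q, ONL@FC, FD); ``residual_mean``/``residual_sd``
    describe the remaining retinal layers so that
    RT@FC = GCL+@FC + ONL@FC + residual.  Thickness draws are truncated
    at 0 µm (the residual at an anatomical floor) by rejection sampling.
    """

    group_label: str
    n_eyes: int
    param_means: dict[str, float]
    param_sds: dict[str, float]
    residual_mean: float
    residual_sd: float
    correlation: pd.DataFrame
    seed: int | None = None
    laterality_policy: str = "all-left"
    rim_asymmetry_sd: float = 4.0

    def validate(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if self.laterality_policy not in ("all-left", "all-right", "mixed"):
            raise ValueError(f"unknown laterality policy {self.laterality_policy!r}")
        for p in ref.SAMPLED_PARAMS:
            if p not in self.param_means or p not in self.param_sds:
                raise ValueError(f"missing mean/SD for parameter {p!r}")
            if self.param_sds[p] < 0:
                raise ValueError(f"negative SD for {p!r}")
            if self.param_means[p] < 0:
                raise ValueError(f"negative mean for {p!r}")
        if self.residual_sd < 0 or self.rim_asymmetry_sd < 0:
            raise ValueError("negative SD")
        if self.residual_mean < 0:
            raise ValueError(
                "impossible constraint: mean RT@FC below mean GCL+@FC + ONL@FC "
                "(negative residual-layer mean)"
            )
        corr = self.correlation.loc[list(ref.SAMPLED_PARAMS), list(ref.SAMPLED_PARAMS)].to_numpy()
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal must be 1")
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-8:
            raise ValueError(
                f"correlation matrix is not positive semi-definite (min eigenvalue {w.min():.3g})"
            )


def control_spec(n_eyes: int = 92, seed: int | None = None, **overrides) -> CohortSpec:
    """Default full-term control cohort (left eyes)."""
    spec = CohortSpec(
        group_label="control",
        n_eyes=n_eyes,
        param_means=dict(ref.CONTROL_MEANS),
        param_sds=dict(ref.CONTROL_SDS),
        residual_mean=ref.CONTROL_RESIDUAL_MEAN,
        residual_sd=ref.CONTROL_RESIDUAL_SD,
        correlation=default_correlation("control"),
        seed=seed,
        laterality_policy="all-left",
    )
    return replace(spec, **overrides) if overrides else spec


def ept_spec(n_eyes: int = 37, seed: int | None = None, **overrides) -> CohortSpec:
    """Default extremely-preterm-born (no ROP) cohort (both eyes)."""
    spec = CohortSpec(
        group_label="EPT-NoROP",
        n_eyes=n_eyes,
        param_means=dict(ref.EPT_MEANS),
        param_sds=dict(ref.EPT_SDS),
        residual_mean=ref.EPT_RESIDUAL_MEAN,
        residual_sd=ref.EPT_RESIDUAL_SD,
        correlation=default_correlation("EPT-NoROP"),
        seed=seed,
        laterality_policy="mixed",
    )
    return replace(spec, **overrides) if overrides else spec


def _truncated_gaussian_copula(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    corr: np.ndarray,
    n: int,
    lower: np.ndarray,
) -> np.ndarray:
    """Draw n rows with exact (left-truncated) normal marginals coupled by
    a Gaussian copula.

    A latent standard MVN with the given correlation is mapped through its
    marginal CDF and each column's truncated-normal inverse CDF.  Unlike
    joint rejection sampling, this leaves barely-truncated marginals (e.g.
    ONL@FC) unbiased even when they correlate with a strongly truncated
    one (central GCL+ in controls).  SD = 0 columns are held constant.
    """
    from scipy.special import ndtr
    from scipy.stats import truncnorm

    w, v = np.linalg.eigh(corr)
    a = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, mean.size)) @ a.T
    u = np.clip(ndtr(z), 1e-15, 1.0 - 1e-15)
    x = np.empty_like(u)
    for j in range(mean.size):
        if sd[j] == 0.0:
            x[:, j] = mean[j]
        else:
            alpha = (lower[j] - mean[j]) / sd[j]
            x[:, j] = truncnorm.ppf(u[:, j], alpha, np.inf, loc=mean[j], scale=sd[j])
    return x


def _lateralities(policy: str, n: int) -> tuple[list[str], list[str]]:
    """Eye lateralities and subject ids under a laterality policy.

    ``mixed`` pairs consecutive eyes (OD then OS) into one subject,
    emulating cohorts that include both eyes of most children.
    """
    if policy == "all-left":
        return ["OS"] * n, [f"S{i:04d}" for i in range(n)]
    if policy == "all-right":
        return ["OD"] * n, [f"S{i:04d}" for i in range(n)]
    lats = ["OD" if i % 2 == 0 else "OS" for i in range(n)]
    subjects = [f"S{i // 2:04d}" for i in range(n)]
    return lats, subjects


def sample_cohort_metrics(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-eye target foveal parameters for one cohort.

    Returns a DataFrame with one row per eye and columns ``eye_id,
    subject_id, group_label, laterality, GCLp_FC, GCLp_Q2Q, ONL_FC,
    RT_FC, FD, RT_FWM_nasal, RT_FWM_temporal, RT_FWM_mean`` (µm).
    Identical seeds give identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    params = list(ref.SAMPLED_PARAMS)
    mean = np.array([spec.param_means[p] for p in params])
    sd = np.array([spec.param_sds[p] for p in params])
    corr = spec.correlation.loc[params, params].to_numpy()

    # thickness parameters and foveal depth truncated at 0
    x = _truncated_gaussian_copula(
        rng, mean, sd, corr, spec.n_eyes, lower=np.zeros(len(params))
    )

    resid_floor = min(RESIDUAL_FLOOR, spec.residual_mean)
    resid = _truncated_gaussian_copula(
        rng,
        np.array([spec.residual_mean]),
        np.array([spec.residual_sd]),
        np.eye(1),
        spec.n_eyes,
        lower=np.array([resid_floor]),
    )[:, 0]

    gclp_fc, gclp_q2q, onl_fc, fd = x.T
    rt_fc = gclp_fc + onl_fc + resid
    rt_fwm_mean = rt_fc + fd
    delta = rng.normal(0.0, spec.rim_asymmetry_sd, spec.n_eyes) if spec.rim_asymmetry_sd > 0 else np.zeros(spec.n_eyes)
    lats, subjects = _lateralities(spec.laterality_policy, spec.n_eyes)

    prefix = "ctl" if spec.group_label == "control" else "ept"
    return pd.DataFrame(
        {
            "eye_id": [f"{prefix}-{i:05d}" for i in range(spec.n_eyes)],
            "subject_id": subjects,
            "group_label": spec.group_label,
            "laterality": lats,
            "GCLp_FC": gclp_fc,
            "GCLp_Q2Q": gclp_q2q,
            "ONL_FC": onl_fc,
            "RT_FC": rt_fc,
            "FD": fd,
            "RT_FWM_nasal": rt_fwm_mean + delta,
            "RT_FWM_temporal": rt_fwm_mean - delta,
            "RT_FWM_mean": rt_fwm_mean,
        }
    )


@dataclass
class EyeGeometry:
    """Shape parameters of the synthetic pit not fixed by the targets.

    Distances in µm.  The rim radii place the foveal wall maxima; the
    IS/OS bump makes the junction most elevated exactly at the pit
    centre; the fractions split the residual thickness budget between
    RNFL, INL+OPL and the inner-segment band.
    """

    pit_center_lateral_um: float = 0.0
    rim_radius_nasal_um: float = 1000.0
    rim_radius_temporal_um: float = 1060.0
    rpe_depth_um: float = 1500.0
    onl_shoulder_um: float = 60.0
    onl_sigma_um: float = 500.0
    osrpe_base_um: float = 35.0
    isos_bump_um: float = 10.0
    isos_sigma_um: float = 80.0
    gcl_annulus_peak_um: float | None = None  # default: max(GCL+@FC, Q2Q) + 25
    rnfl_fraction: float = 0.15
    inlopl_fraction: float = 0.55
    rt_shoulder_fraction: float = 0.9
    rt_shoulder_width: float = 0.6
    gcl_shoulder_fraction: float = 0.75
    gcl_shoulder_width: float = 0.5

    def validate(self) -> None:
        if self.rim_radius_nasal_um <= 0 or self.rim_radius_temporal_um <= 0:
            raise ValueError("rim radii must be positive")
        if not (0 < self.rnfl_fraction + self.inlopl_fraction < 1):
            raise ValueError("residual fractions must leave a positive IS band")
        for name in ("onl_sigma_um", "isos_sigma_um", "rpe_depth_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sample_eye_geometry(rng: np.random.Generator, base: EyeGeometry | None = None) -> EyeGeometry:
    """Jitter pit-centre position and rim radii for cohort realism."""
    base = base or EyeGeometry()
    return replace(
        base,
        pit_center_lateral_um=float(rng.uniform(-30.0, 30.0)),
        rim_radius_nasal_um=float(np.clip(rng.normal(1000.0, 60.0), 700.0, 1500.0)),
        rim_radius_temporal_um=float(np.clip(rng.normal(1060.0, 60.0), 700.0, 1500.0)),
    )


def _rt_shape(u: np.ndarray, shoulder: float, width: float) -> np.ndarray:
    """Pit wall profile: 0 at the centre, 1 at the rim with zero slope,
    decaying to a shoulder beyond the rim."""
    inner = np.sin(np.pi * np.minimum(u, 1.0) / 2.0) ** 2
    outer = shoulder + (1.0 - shoulder) * np.exp(-((u - 1.0) ** 2) / (2.0 * width**2))
    return np.where(u <= 1.0, inner, outer)


def _gcl_profile(
    u: np.ndarray, g_fc: float, q2q: float, peak: float, shoulder_frac: float, width: float
) -> np.ndarray:
    """GCL+ thickness versus normalized rim distance u.

    A monotonicity-preserving cubic passes through (0, GCL+@FC) with zero
    slope, (0.25, Q2Q) and (1, peak); beyond the rim the profile decays to
    a shoulder so the in-window maximum sits exactly at u = 1.  Handles
    both the immature case (GCL+@FC < Q2Q, rising bowl) and the mature
    case (central GCL+ above Q2Q, dip-then-rise annulus).
    """
    knots = np.array([0.0, 0.08, 0.25, 0.625, 1.0])
    vals = np.array([g_fc, g_fc, q2q, (q2q + peak) / 2.0, peak])
    interp = PchipInterpolator(knots, vals)
    inner = interp(np.minimum(u, 1.0))
    g_out = shoulder_frac * peak
    outer = g_out + (peak - g_out) * np.exp(-((u - 1.0) ** 2) / (2.0 * width**2))
    return np.where(u <= 1.0, inner, outer)


def build_boundaries(
    targets,
    geometry: EyeGeometry | None = None,
    scan: ScanGeometry | None = None,
) -> BoundarySet:
    """Construct boundary polylines realizing the target foveal metrics.

    ``targets`` is a mapping (or DataFrame row) with keys ``GCLp_FC,
    GCLp_Q2Q, ONL_FC, RT_FC, RT_FWM_nasal, RT_FWM_temporal`` and
    optionally ``eye_id``/``laterality``.  The returned boundaries are
    single-valued per A-scan and ordered anterior→posterior; running the
    morphometry pipeline on them recovers the targets (GCL+@FC, ONL@FC,
    RT@FC, RT@FWM within 1 µm; FD within 2 µm).

    Raises ``ValueError`` naming the violated constraint when the targets
    cannot be realized as a physically ordered layer stack.
    """
    geometry = geometry or EyeGeometry()
    scan = scan or ScanGeometry()
    geometry.validate()

    g_fc = float(targets["GCLp_FC"])
    q2q = float(targets["GCLp_Q2Q"])
    onl_fc = float(targets["ONL_FC"])
    rt_fc = float(targets["RT_FC"])
    fwm_n = float(targets["RT_FWM_nasal"])
    fwm_t = float(targets["RT_FWM_temporal"])
    laterality = str(targets.get("laterality", "OD") or "OD")
    eye_id = str(targets.get("eye_id", "") or "")

    for name, v in (("GCLp_FC", g_fc), ("GCLp_Q2Q", q2q), ("ONL_FC", onl_fc), ("RT_FC", rt_fc)):
        if v < 0:
            raise ValueError(f"target {name} is negative")
    fd = (fwm_n + fwm_t) / 2.0 - rt_fc
    if fd <= 0:
        raise ValueError("constraint violated: foveal depth must be positive (rim RT above RT@FC)")
    if rt_fc < g_fc + onl_fc:
        raise ValueError("constraint violated: RT@FC below GCL+@FC + ONL@FC")

    x = scan.lateral_positions(laterality)
    dx = x - geometry.pit_center_lateral_um
    nasal = dx >= 0
    r_side = np.where(nasal, geometry.rim_radius_nasal_um, geometry.rim_radius_temporal_um)
    u = np.abs(dx) / r_side

    fwm_side = np.where(nasal, fwm_n, fwm_t)
    rt = rt_fc + (fwm_side - rt_fc) * _rt_shape(
        u, geometry.rt_shoulder_fraction, geometry.rt_shoulder_width
    )

    peak = geometry.gcl_annulus_peak_um
    if peak is None:
        peak = max(g_fc, q2q) + 25.0
    if peak <= max(g_fc, q2q):
        raise ValueError("constraint violated: GCL+ annulus peak must exceed GCL+@FC and Q2Q")
    t_g = _gcl_profile(u, g_fc, q2q, peak, geometry.gcl_shoulder_fraction, geometry.gcl_shoulder_width)

    onl_far = min(geometry.onl_shoulder_um, 0.7 * onl_fc) if onl_fc > 0 else 0.0
    t_o = onl_far + (onl_fc - onl_far) * np.exp(-(dx**2) / (2.0 * geometry.onl_sigma_um**2))

    t_os = geometry.osrpe_base_um + geometry.isos_bump_um * np.exp(
        -(dx**2) / (2.0 * geometry.isos_sigma_um**2)
    )

    resid = rt - t_g - t_o - t_os
    if resid.min() < 0:
        i = int(np.argmin(resid))
        raise ValueError(
            "constraint violated: residual inner/outer layer thickness negative at "
            f"A-scan {i} (RT too small for the GCL+/ONL/IS-OS stack)"
        )

    rpe_um = np.full(scan.n_ascans, geometry.rpe_depth_um)
    ilm_um = rpe_um - rt
    gclp_inner_um = ilm_um + geometry.rnfl_fraction * resid
    gclp_outer_um = gclp_inner_um + t_g
    onl_inner_um = gclp_outer_um + geometry.inlopl_fraction * resid
    onl_outer_um = onl_inner_um + t_o
    isos_um = rpe_um - t_os

    boundaries_um = {
        "ILM": ilm_um,
        "GCLp_inner": gclp_inner_um,
        "GCLp_outer": gclp_outer_um,
        "ONL_inner": onl_inner_um,
        "ONL_outer": onl_outer_um,
        "ISOS": isos_um,
        "RPE_posterior": rpe_um,
    }
    bset = BoundarySet(
        boundaries={n: v / scan.axial_scale for n, v in boundaries_um.items()},
        laterality=laterality,
        eye_id=eye_id,
    )
    bset.validate(n_axial=scan.n_axial)
    return bset


def build_cohort_boundaries(
    metrics: pd.DataFrame,
    scan: ScanGeometry | None = None,
    seed: int | None = None,
    base_geometry: EyeGeometry | None = None,
) -> dict[str, BoundarySet]:
    """Build per-eye boundary sets for every row of a metrics table,
    sampling nuisance pit geometry (centre jitter, rim radii) per eye."""
    scan = scan or ScanGeometry()
    rng = np.random.default_rng(seed)
    out: dict[str, BoundarySet] = {}
    for _, row in metrics.iterrows():
        geom = sample_eye_geometry(rng, base_geometry)
        out[str(row["eye_id"])] = build_boundaries(row, geom, scan)
    return out


#: reflectivity (arbitrary units in [0, 1]) of the eight raster regions,
#: anterior→posterior: vitreous, RNFL, GCL+, INL/OPL, ONL, inner
#: segments, OS+RPE complex, choroid
DEFAULT_REFLECTIVITIES = (0.03, 0.65, 0.45, 0.35, 0.12, 0.30, 0.88, 0.22)


def render_bscan(
    bset: BoundarySet,
    scan: ScanGeometry | None = None,
    reflectivities=DEFAULT_REFLECTIVITIES,
    noise_level: float = 0.1,
    seed: int | None = None,
) -> BScan:
    """Render a boundary set as a speckled piecewise-constant raster.

    Each pixel takes the reflectivity of the region its centre falls in,
    then (for ``noise_level > 0``) is multiplied by unit-mean gamma
    speckle with standard deviation ``noise_level``.  ``noise_level = 0``
    yields the noiseless layered image; identical seeds give bit-identical
    rasters.
    """
    scan = scan or ScanGeometry()
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    reflectivities = tuple(float(r) for r in reflectivities)
    if len(reflectivities) != len(BOUNDARY_ORDER) + 1:
        raise ValueError(f"expected {len(BOUNDARY_ORDER) + 1} reflectivities")
    bset.validate(n_axial=scan.n_axial)
    if bset.n_ascans != scan.n_ascans:
        raise ValueError("boundary set A-scan count does not match scan geometry")

    stack = np.stack([bset[n] for n in BOUNDARY_ORDER])  # (7, n_ascans)
    depth = np.arange(scan.n_axial, dtype=float)[:, None]
    region = (depth >= stack[:, None, :]).sum(axis=0)  # 0..7
    img = np.asarray(reflectivities)[region].astype(float)

    if noise_level > 0:
        rng = np.random.default_rng(seed)
        shape = 1.0 / noise_level**2
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)
    return BScan(
        pixels=img,
        axial_scale=scan.axial_scale,
        lateral_scale=scan.lateral_scale,
        laterality=bset.laterality,
        eye_id=bset.eye_id,
    )
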