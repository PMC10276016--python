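"""Foveal centre / rim detection and the six foveal parameters."""

import numpy as np
import pandas as pd
import pytest

from foveamorph import (
    ScanGeometry,
    build_boundaries,
    compute_metrics,
    extract_metrics,
    locate_foveal_centre,
    locate_rims,
    thickness_profiles,
)
from foveamorph.morphometry import FovealCentre, FovealMetrics, RimPair
from foveamorph.segmentation import ThicknessProfile
from foveamorph.simulate import EyeGeometry


def synthetic_profile(n=512, lateral_scale=11.72, gclp=None, rt=None, elev=None):
    lat = (np.arange(n) - (n - 1) / 2) * lateral_scale
    zeros = np.zeros(n)
    return ThicknessProfile(
        lateral_um=lat,
        gclp=zeros if gclp is None else np.asarray(gclp, float),
        onl=zeros + 100.0,
        rt=zeros + 250.0 if rt is None else np.asarray(rt, float),
        isos_elev=zeros + 40.0 if elev is None else np.asarray(elev, float),
        smooth_window=5,
    )


class TestLocateFovealCentre:
    def test_programmed_pit_centre_recovered(self, scan, control_targets):
        geom = EyeGeometry(pit_center_lateral_um=0.0)
        bset = build_boundaries(control_targets, geom, scan)
        profile = thickness_profiles(bset, scan.axial_scale, scan.lateral_scale)
        fc = locate_foveal_centre(profile)
        assert abs(fc.lateral_um) <= scan.lateral_scale  # within 1 A-scan of 0
        assert fc.method == "isos_peak"

    def test_exact_symmetric_tie_prefers_temporal(self):
        n = 101
        elev = np.zeros(n)
        elev[[30, 70]] = 50.0  # two equal peaks equidistant from centre
        prof = synthetic_profile(n=n, lateral_scale=10.0, elev=elev, gclp=np.zeros(n))
        prof.smooth_window = 1
        fc = locate_foveal_centre(prof, search_halfwidth_um=480.0)
        assert fc.index == 30  # temporal (negative-lateral) candidate wins
        assert fc.lateral_um < 0

    def test_flat_isos_falls_back_to_minimum_rt(self):
        n = 101
        rt = 250.0 - 60.0 * np.exp(-(((np.arange(n) - 44) / 8.0) ** 2))
        prof = synthetic_profile(n=n, lateral_scale=10.0, rt=rt)
        fc = locate_foveal_centre(prof, search_halfwidth_um=300.0)
        assert fc.method == "min_rt"
        assert "isos_flat_fallback_min_rt" in fc.flags
        assert fc.index == 44

    def test_empty_window_rejected(self):
        prof = synthetic_profile(n=10, lateral_scale=1000.0)  # no A-scan near lateral 0
        with pytest.raises(ValueError, match="no A-scans"):
            locate_foveal_centre(prof, search_halfwidth_um=100.0)


class TestLocateRims:
    def test_programmed_annulus_peaks_recovered(self):
        n = 512
        lat = (np.arange(n) - (n - 1) / 2) * 11.72
        gclp = 40.0 * (np.exp(-(((lat - 1000) / 150) ** 2)) + np.exp(-(((lat + 1100) / 150) ** 2)))
        prof = synthetic_profile(n=n, gclp=gclp, elev=np.where(np.abs(lat) < 50, 45.0, 40.0))
        fc = locate_foveal_centre(prof)
        rims = locate_rims(prof, fc)
        assert abs(rims.nasal_lateral_um - 1000) <= 3 * 11.72
        assert abs(rims.temporal_lateral_um + 1100) <= 3 * 11.72

    def test_flat_gclp_returns_innermost_index_flagged(self):
        n = 512
        prof = synthetic_profile(n=n, gclp=np.full(n, 20.0))
        fc = FovealCentre(index=n // 2, lateral_um=prof.lateral_um[n // 2], method="isos_peak")
        rims = locate_rims(prof, fc)
        # tie rule: toward FC -> innermost window A-scan on each side
        assert rims.nasal_lateral_um - fc.lateral_um == pytest.approx(300.0, abs=11.72)
        assert fc.lateral_um - rims.temporal_lateral_um == pytest.approx(300.0, abs=11.72)
        assert any(f.startswith("rim_at_window_edge") for f in rims.flags)

    def test_maximum_on_outer_edge_flagged(self):
        n = 512
        lat = (np.arange(n) - (n - 1) / 2) * 11.72
        gclp = np.abs(lat) / 100.0  # increases to the scan edges
        prof = synthetic_profile(n=n, gclp=gclp)
        fc = FovealCentre(index=n // 2, lateral_um=prof.lateral_um[n // 2], method="isos_peak")
        rims = locate_rims(prof, fc, window_um=(300.0, 2000.0))
        assert any(f.startswith("rim_at_window_edge") for f in rims.flags)

    def test_empty_window_rejected(self):
        prof = synthetic_profile(n=21, lateral_scale=10.0)
        fc = FovealCentre(index=10, lateral_um=0.0, method="isos_peak")
        with pytest.raises(ValueError, match="no A-scans"):
            locate_rims(prof, fc, window_um=(300.0, 3000.0))


class TestComputeMetrics:
    def test_foveal_depth_formula(self):
        # FD = (340 + 330)/2 - 247.09 = 87.91 µm
        m = FovealMetrics(
            eye_id="e", laterality="OD", GCLp_FC=14.0, GCLp_Q2Q=27.0, ONL_FC=150.0,
            RT_FC=247.09, RT_FWM_nasal=340.0, RT_FWM_temporal=330.0,
            fc_lateral_um=0.0, rim_lateral_nasal_um=1000.0, rim_lateral_temporal_um=-1000.0,
        )
        assert m.FD == pytest.approx(87.91)
        assert m.RT_FWM_mean == pytest.approx(335.0)

    def test_symmetric_eye_quarter_points_agree(self, scan, control_targets):
        geom = EyeGeometry(pit_center_lateral_um=0.0, rim_radius_nasal_um=1000.0,
                           rim_radius_temporal_um=1000.0)
        bset = build_boundaries(control_targets, geom, scan)
        prof = thickness_profiles(bset, scan.axial_scale, scan.lateral_scale)
        fc = locate_foveal_centre(prof)
        rims = locate_rims(prof, fc)
        m = compute_metrics(prof, fc, rims)
        q_n = fc.lateral_um + 0.25 * (rims.nasal_lateral_um - fc.lateral_um)
        q_t = fc.lateral_um + 0.25 * (rims.temporal_lateral_um - fc.lateral_um)
        g_n = prof.gclp[np.argmin(np.abs(prof.lateral_um - q_n))]
        g_t = prof.gclp[np.argmin(np.abs(prof.lateral_um - q_t))]
        assert m.GCLp_Q2Q == pytest.approx((g_n + g_t) / 2)
        assert g_n == pytest.approx(g_t, abs=0.5)

    def test_rim_geometry_invariant_enforced(self):
        with pytest.raises(ValueError, match="temporal rim < FC < nasal rim"):
            FovealMetrics(
                eye_id="e", laterality="OD", GCLp_FC=1, GCLp_Q2Q=1, ONL_FC=1,
                RT_FC=200, RT_FWM_nasal=300, RT_FWM_temporal=300,
                fc_lateral_um=0.0, rim_lateral_nasal_um=-10.0, rim_lateral_temporal_um=-1000.0,
            )


class TestEndToEndInvariants:
    def test_mirror_invariance_of_all_parameters(self, scan, ept_targets):
        geom = EyeGeometry(pit_center_lateral_um=17.0, rim_radius_nasal_um=950.0,
                           rim_radius_temporal_um=1100.0)
        bset = build_boundaries(ept_targets, geom, scan)
        a = extract_metrics(bset, scan.axial_scale, scan.lateral_scale)
        b = extract_metrics(bset.mirrored(), scan.axial_scale, scan.lateral_scale)
        for k in ("GCLp_FC", "GCLp_Q2Q", "ONL_FC", "RT_FC", "FD", "RT_FWM_nasal", "RT_FWM_temporal"):
            assert getattr(a, k) == pytest.approx(getattr(b, k), abs=1e-9), k

    def test_fd_monotone_in_rim_and_centre_thickness(self, scan, ept_targets):
        base = extract_metrics(build_boundaries(ept_targets, EyeGeometry(), scan),
                               scan.axial_scale, scan.lateral_scale)
        thicker_rim = ept_targets.copy()
        thicker_rim["RT_FWM_nasal"] += 20
        thicker_rim["RT_FWM_temporal"] += 20
        up = extract_metrics(build_boundaries(thicker_rim, EyeGeometry(), scan),
                             scan.axial_scale, scan.lateral_scale)
        assert up.FD > base.FD
        thicker_fc = ept_targets.copy()
        thicker_fc["RT_FC"] += 20
        thicker_fc["ONL_FC"] += 10
        down = extract_metrics(build_boundaries(thicker_fc, EyeGeometry(), scan),
                               scan.axial_scale, scan.lateral_scale)
        assert down.FD < base.FD

    def test_zero_central_gclp_extracted_exactly_zero(self, scan, control_targets):
        targets = control_targets.copy()
        targets["GCLp_FC"] = 0.0
        m = extract_metrics(build_boundaries(targets, EyeGeometry(), scan),
                            scan.axial_scale, scan.lateral_scale)
        assert m.GCLp_FC == 0.0

    def test_fd_identity_holds_exactly_on_extracted_records(self, scan, mixed_cohort):
        for _, row in mixed_cohort.head(6).iterrows():
            m = extract_metrics(build_boundaries(row, EyeGeometry(), scan),
                                scan.axial_scale, scan.lateral_scale)
            assert m.FD == (m.RT_FWM_nasal + m.RT_FWM_temporal) / 2 - m.RT_FC
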