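"""Simulate → extract → analyze pipeline with reproducible outputs.

``run_pipeline`` generates both cohorts, builds ground-truth boundaries
and renders B-scans for a subset of eyes, runs the morphometry extractor
on those boundaries as an internal round-trip check, computes normative
limits/classification, layer proportions, correlation matrices, a
subgroup factor comparison, and writes everything as CSV/JSON (plus
optional correlation heatmaps).  A single seed fans out to independent
per-stage streams via ``numpy.random.SeedSequence.spawn``, so rerunning
with the same configuration is bit-identical for all CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import reference as ref
from .geometry import ScanGeometry, save_bscan
from .morphometry import extract_metrics, metrics_table
from .normative import classify, compare_with_published, compute_limits, summarize_cohorts
from .segmentation import write_boundaries
from .simulate import (
    build_cohort_boundaries,
    control_spec,
    ept_spec,
    render_bscan,
    sample_cohort_metrics,
)
from .stats import correlation_matrix, group_compare_from_summary, layer_proportions, normality_test

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

#: stage names in execution order, used to derive per-stage seeds
STAGES = ("simulate_control", "simulate_ept", "boundaries", "render", "analyze")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str = "foveamorph_out"
    seed: int = 0
    n_control: int = 92
    n_ept: int = 37
    n_boundary_eyes: int = 4   # eyes per group that get ground-truth boundaries
    n_render_eyes: int = 2     # of those, eyes per group that get rendered images
    noise_level: float = 0.15
    image_format: str = "png"
    n_ascans: int = 512
    n_axial: int = 1024
    lateral_scale: float = 6000.0 / 512
    axial_scale: float = 2000.0 / 1024
    smooth_window: int = 5
    fc_search_halfwidth_um: float = 750.0
    rim_window_um: tuple[float, float] = (300.0, 3000.0)
    correlation_alpha: float = 0.001
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_control < 2:
            raise ValueError("n_control must be >= 2 (limits need at least two eyes)")
        if self.n_ept < 1:
            raise ValueError("n_ept must be >= 1")
        if self.n_render_eyes > self.n_boundary_eyes:
            raise ValueError("n_render_eyes cannot exceed n_boundary_eyes")
        if self.image_format not in ("png", "tif", "tiff"):
            raise ValueError(f"unsupported image format {self.image_format!r}")

    def scan_geometry(self) -> ScanGeometry:
        return ScanGeometry(
            n_ascans=self.n_ascans,
            n_axial=self.n_axial,
            lateral_scale=self.lateral_scale,
            axial_scale=self.axial_scale,
        )

    def stage_seeds(self) -> dict[str, int]:
        """Derive one independent 31-bit seed per stage from the root seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(STAGES, children)
        }


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the full pipeline; returns a mapping of output names to paths."""
    config.validate()
    if config.n_control < 10:
        logger.warning(
            "normative limits from only %d control eyes will be unstable", config.n_control
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan = config.scan_geometry()
    seeds = config.stage_seeds()
    paths: dict[str, str] = {}
    stage = "simulate_control"
    try:
        control = sample_cohort_metrics(
            control_spec(n_eyes=config.n_control, seed=seeds["simulate_control"])
        )
        stage = "simulate_ept"
        ept = sample_cohort_metrics(ept_spec(n_eyes=config.n_ept, seed=seeds["simulate_ept"]))
        for name, df in (("control_metrics", control), ("ept_metrics", ept)):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)

        stage = "boundaries"
        bdir = out / "boundaries"
        bdir.mkdir(exist_ok=True)
        extracted = []
        rendered_ids: list[str] = []
        for group_df, label in ((control, "control"), (ept, "EPT-NoROP")):
            subset = group_df.head(config.n_boundary_eyes)
            bsets = build_cohort_boundaries(subset, scan, seed=seeds["boundaries"])
            for eye_id, bset in bsets.items():
                write_boundaries(bset, bdir / f"{eye_id}.csv")
                m = extract_metrics(
                    bset,
                    scan.axial_scale,
                    scan.lateral_scale,
                    smooth_window=config.smooth_window,
                    search_halfwidth_um=config.fc_search_halfwidth_um,
                    rim_window_um=config.rim_window_um,
                    group_label=label,
                )
                extracted.append(m)
            rendered_ids.extend(list(bsets)[: config.n_render_eyes])
        extracted_df = metrics_table(extracted)
        p = out / "extracted_metrics.csv"
        extracted_df.to_csv(p, index=False)
        paths["extracted_metrics"] = str(p)

        stage = "render"
        idir = out / "images"
        idir.mkdir(exist_ok=True)
        render_rng = np.random.default_rng(seeds["render"])
        from .segmentation import read_boundaries

        for eye_id in rendered_ids:
            bset = read_boundaries(bdir / f"{eye_id}.csv")
            bscan = render_bscan(
                bset,
                scan,
                noise_level=config.noise_level,
                seed=int(render_rng.integers(2**31)),
            )
            save_bscan(bscan, idir / f"{eye_id}.{config.image_format}")

        stage = "analyze"
        limits = compute_limits(control)
        limits.to_frame().to_csv(out / "normative_limits.csv")
        paths["normative_limits"] = str(out / "normative_limits.csv")

        limit_check = compare_with_published(limits)
        limit_check.to_csv(out / "limit_consistency.csv")
        for param, row in limit_check.iterrows():
            if not row["consistent"]:
                logger.warning(
                    "published %s limit %.1f inconsistent with recomputed mean+2SD %.2f",
                    param, row["published_limit"], row["computed_limit"],
                )

        cls_ept = classify(ept, limits)
        cls_ept.outside.to_csv(out / "ept_classification.csv")
        summary = summarize_cohorts(control, ept, limits, cls_ept)
        summary.to_csv(out / "normative_summary.csv")
        paths["normative_summary"] = str(out / "normative_summary.csv")

        _, proportions = layer_proportions(pd.concat([control, ept], ignore_index=True))
        proportions.to_csv(out / "layer_proportions.csv")
        paths["layer_proportions"] = str(out / "layer_proportions.csv")

        norm_rows = []
        for label, df in (("control", control), ("EPT-NoROP", ept)):
            for param in ref.REPORTED_PARAMS:
                if 3 <= len(df) <= 5000:
                    res = normality_test(df[param])
                    norm_rows.append(
                        {"group": label, "parameter": param, "W": res.W, "p": res.p, "n": res.n}
                    )
        pd.DataFrame(norm_rows).to_csv(out / "normality_tests.csv", index=False)

        corr_params = list(ref.REPORTED_PARAMS) + ["RT_FWM_mean"]
        for label, df in (("control", control), ("ept", ept)):
            cm = correlation_matrix(df, corr_params, alpha=config.correlation_alpha)
            cm.r.to_csv(out / f"correlations_{label}.csv")
            cm.to_long().to_csv(out / f"correlations_{label}_long.csv", index=False)
            if config.make_figures:
                _heatmap(cm, out / f"correlations_{label}.png", title=f"{label} (n={len(df)})")

        table2 = group_compare_from_summary(ref.SUBGROUP_FACTORS, welch=True)
        table2.to_csv(out / "subgroup_comparison.csv", index=False)
        paths["subgroup_comparison"] = str(out / "subgroup_comparison.csv")

        provenance = {
            "package_version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "config": asdict(config),
            "config_hash": _config_hash(config),
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, default=str)
        paths["provenance"] = str(out / "provenance.json")
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return paths


def _heatmap(cm, path: Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = list(cm.r.index)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(params)), params, rotation=45, ha="right")
    ax.set_yticks(range(len(params)), params)
    for i in range(len(params)):
        for j in range(len(params)):
            r = cm.r.iloc[i, j]
            star = "*" if (i != j and np.isfinite(cm.p.iloc[i, j]) and cm.p.iloc[i, j] < cm.alpha) else ""
            ax.text(j, i, f"{r:.2f}{star}", ha="center", va="center", fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
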