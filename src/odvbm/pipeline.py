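"""End-to-end orchestration: generate/ingest -> adjust -> map -> infer -> report.

A run is driven by a :class:`RunConfig`, writes every intermediate artifact
(NIfTI volumes, CSV tables, JSON manifest) under an output directory, and is
fully reproducible from its manifest: all seeds are explicit and every stage
is deterministic given its inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adjust import NuisanceRegressor, build_design
from .grid import save_volume, stack_cohort, unstack_values
from .inference import PermutationScheme, PermutationTest, threshold_map
from .odvba import ODVBA, OdvbaParams
from .report import format_report, make_report
from .synthetic import (
    LabelAtlas,
    SynthConfig,
    cohort_to_frame,
    generate_atlas,
    generate_cohort,
)

log = logging.getLogger("odvbm")

__all__ = ["RunConfig", "subgroup_filter", "run_pipeline"]


@dataclass
class RunConfig:
    synth: SynthConfig = None
    directions: tuple = ("less",)
    odvba: OdvbaParams = None
    scheme: PermutationScheme = None
    alpha_trend: float = 0.05
    alpha_cluster: float = 0.05
    exclusions: tuple = ()
    n_atlas_regions: int = 12
    atlas_seed: int = 7
    adjust_covariates: bool = True
    outdir: str = "odvbm_run"

    def __post_init__(self):
        if self.synth is None:
            self.synth = SynthConfig()
        if self.odvba is None:
            self.odvba = OdvbaParams()
        if self.scheme is None:
            self.scheme = PermutationScheme()
        for a in (self.alpha_trend, self.alpha_cluster):
            if not 0 < a < 1:
                raise ValueError("alpha levels must be in (0, 1)")


def subgroup_filter(cohort, exclusions):
    """Drop subjects with any named sensitivity flag set.

    Raises on unknown flag names; logs removed counts per arm.
    """
    cohort = list(cohort)
    known = set()
    for rec in cohort:
        known |= set(rec.covariates.flags)
    for name in exclusions:
        if name not in known:
            raise ValueError(f"unknown exclusion flag {name!r}")
    kept, removed = [], {0: 0, 1: 0}
    for rec in cohort:
        if any(rec.covariates.flags.get(name, False) for name in exclusions):
            removed[rec.covariates.group] += 1
        else:
            kept.append(rec)
    if exclusions:
        log.info(
            "subgroup filter %s removed %d treated / %d placebo subjects",
            sorted(exclusions), removed[1], removed[0],
        )
    return kept


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    return str(o)


def run_pipeline(config: RunConfig, cohort=None, atlas: LabelAtlas | None = None) -> dict:
    """Execute all stages and return the run manifest (also written as JSON).

    When ``cohort`` is None a synthetic cohort is generated from
    ``config.synth``; a pre-built cohort (list of SubjectRecord) and atlas
    may be supplied instead.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = {
        "versions": {"odvbm": __version__, "numpy": np.__version__},
        "stages": {},
        "seeds": {"synth": config.synth.seed,
                  "perm": config.scheme.seed,
                  "atlas": config.atlas_seed},
    }
    t0 = time.time()

    # --- simulate / ingest ---
    if cohort is None:
        cohort, truth = generate_cohort(config.synth)
        save_volume(outdir / "effect_mask.nii.gz",
                    truth.effect_mask.astype(np.float32), config.synth.grid)
    mask = cohort[0].volume.mask
    grid = cohort[0].volume.grid
    cohort_to_frame(cohort).to_csv(outdir / "covariates.csv", index=False)
    manifest["stages"]["simulate"] = {"n_subjects": len(cohort),
                                      "elapsed_s": time.time() - t0}
    log.info("cohort: %d subjects, %d in-mask voxels", len(cohort), int(mask.sum()))

    # --- sensitivity subgroup filter ---
    cohort = subgroup_filter(cohort, config.exclusions)

    if atlas is None:
        atlas = generate_atlas(grid, config.n_atlas_regions, config.atlas_seed, mask=mask)
    save_volume(outdir / "atlas.nii.gz", atlas.labels.astype(np.float32), grid)
    pd.DataFrame(
        {"label": list(atlas.names), "name": list(atlas.names.values()),
         "side": [atlas.sides[k] for k in atlas.names]}
    ).to_csv(outdir / "atlas_labels.csv", index=False)

    y = np.array([rec.covariates.group for rec in cohort], dtype=np.int8)
    X = stack_cohort([rec.volume for rec in cohort])

    # --- covariate adjustment ---
    t1 = time.time()
    if config.adjust_covariates:
        design = build_design(cohort_to_frame(cohort))
        model = NuisanceRegressor().fit(X, design)
        X = model.transform(X)
        coef = model.coefficients_frame()
        for c in coef.columns:
            save_volume(outdir / f"coef_{c.replace('[', '_').replace(']', '')}.nii.gz",
                        unstack_values(coef[c].to_numpy(), mask), grid)
        manifest["stages"]["adjust"] = {"columns": design.columns,
                                        "elapsed_s": time.time() - t1}
        log.info("adjusted for %s", design.columns[1:])

    # --- map + inference + report per direction ---
    maps_adj = [rec.volume.copy_with(np.clip(unstack_values(X[i], mask), 0, None))
                for i, rec in enumerate(cohort)]
    reports = []
    for direction in config.directions:
        t2 = time.time()
        est = ODVBA(mask=mask, grid=grid, radius_mm=config.odvba.radius_mm,
                    stride=config.odvba.stride, lam=config.odvba.lam,
                    max_iter=config.odvba.max_iter, tol=config.odvba.tol,
                    direction=direction)
        test = PermutationTest(est, config.scheme).fit(X, y)
        tag = direction
        save_volume(outdir / f"stat_{tag}.nii.gz", test.stat_map_.phi, grid)
        save_volume(outdir / f"p_{tag}.nii.gz", test.p_map_.p, grid)
        with np.errstate(divide="ignore"):
            neglog = np.where(mask, -np.log10(test.p_map_.p), 0.0)
        save_volume(outdir / f"neglog10p_{tag}.nii.gz", neglog, grid)
        trend = threshold_map(test.p_map_, config.alpha_trend)
        sig = test.significant_mask(config.alpha_cluster)
        save_volume(outdir / f"sig_fwe_{tag}.nii.gz", sig.astype(np.float32), grid)
        save_volume(outdir / f"sig_trend_{tag}.nii.gz", trend.astype(np.float32), grid)
        pd.DataFrame(
            [{"id": c.id, "size": c.size, "corrected_p": c.corrected_p}
             for c in test.clusters_],
            columns=["id", "size", "corrected_p"],
        ).to_csv(outdir / f"clusters_{tag}.csv", index=False)
        comp = "treated < placebo" if direction == "less" else "treated > placebo"
        rep = make_report({"fwe": sig, "trend": trend}, atlas, maps_adj, y,
                          comparison=comp, direction=direction)
        rep.to_csv(outdir / f"report_{tag}.csv", index=False)
        (outdir / f"report_{tag}.txt").write_text(format_report(rep) + "\n")
        reports.append(rep)
        manifest["stages"][f"infer_{tag}"] = {
            "n_perm": test.p_map_.n_perm,
            "n_clusters": len(test.clusters_),
            "n_sig_fwe_voxels": int(sig.sum()),
            "n_trend_voxels": int(trend.sum()),
            "elapsed_s": time.time() - t2,
        }
        log.info("[%s] %d trend voxels, %d FWE-significant voxels",
                 direction, int(trend.sum()), int(sig.sum()))

    manifest["config"] = {
        "n_per_group": config.synth.n_per_group,
        "grid_shape": list(grid.shape),
        "directions": list(config.directions),
        "n_perm": config.scheme.n_perm,
        "alpha_trend": config.alpha_trend,
        "alpha_cluster": config.alpha_cluster,
        "exclusions": list(config.exclusions),
        "radius_mm": config.odvba.radius_mm,
        "stride": config.odvba.stride,
        "lam": config.odvba.lam,
    }
    manifest["elapsed_s"] = time.time() - t0
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default)
    )
    return manifest
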