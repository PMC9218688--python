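"""Reproducible pipeline driver: simulate -> reconstruct -> regions -> analyze.

A :class:`RunConfig` is fully JSON-serializable; a run is reproducible
bit-for-bit from its config and seed for the deterministic stages and
statistically for stochastic summaries.  The single global seed is expanded
into independent per-stage streams (``numpy.random.SeedSequence`` children,
in the fixed order sweep, cohort), so stages can be rerun independently; the
per-stage seeds are logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .cohort import CohortParams, GroupSpec, RegionModel, reference_cohort_params, simulate_cohort
from .phantom import SweepConfig, TendonPhantom, simulate_sweep
from .reconstruct import KernelConfig, VoxelGridSpec, compound
from .regions import partition_regions, rasterize_phantom_mask, regional_means, apply_mask, segment_bmode
from .stats import (PREDICTOR_POOL, WITHIN_GROUP_POOL, design_from_cohort,
                    regional_delta_test, select_model, two_sample_t)

__all__ = ["RunConfig", "run_pipeline", "analyze_cohort"]

log = logging.getLogger("tendonswe")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; serializable to/from JSON."""

    seed: int = 0
    phantom: TendonPhantom = field(default_factory=TendonPhantom)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    voxel_spacing: float = 0.5
    cut_distance: float = 10.0
    mask_source: str = "ground_truth"  # or "segment"
    cohort: CohortParams = field(default_factory=reference_cohort_params)
    criterion: str = "adjusted_r2"
    alpha: float = 0.05

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj
        return clean(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = dict(d.pop("phantom"))
        ph["radii"] = tuple(ph["radii"])
        ph["swv_bounds"] = tuple(ph["swv_bounds"])
        sw = dict(d.pop("sweep"))
        co = dict(d.pop("cohort"))
        co["control"] = GroupSpec(**co["control"])
        co["skier"] = GroupSpec(**co["skier"])
        co["swv_bounds"] = tuple(co["swv_bounds"])
        co["swv_model"] = {k: RegionModel(**v)
                           for k, v in co["swv_model"].items()}
        return cls(phantom=TendonPhantom(**ph), sweep=SweepConfig(**sw),
                   cohort=CohortParams(**co), **d)


def _fit_to_rows(fit) -> list[dict]:
    return [
        {"predictor": name, "estimate": float(est), "std_error": float(se),
         "p_value": float(p)}
        for name, est, se, p in zip(fit.names, fit.params, fit.se, fit.pvalues)
    ]


def analyze_cohort(cohort, criterion: str = "adjusted_r2",
                   regions=("overall", "proximal", "mid", "distal")) -> dict:
    """Cohort-level inference: best-subset models for the whole population and
    within each group, univariate group t tests, and the regional-pattern
    delta comparisons.  Returns a JSON-ready dict of coefficient tables."""
    out = {"criterion": criterion, "population": {}, "within_group": {},
           "group_t_tests": {}, "regional_deltas": {}}
    for region in regions:
        y = cohort[f"swv_{region}"]
        ok = y.notna()
        sub = cohort[ok]
        yv = y[ok].to_numpy()
        pool = [p for p in PREDICTOR_POOL]
        sel = select_model(yv, design_from_cohort(sub, pool), criterion)
        out["population"][region] = {
            "selected": list(sel.selected),
            "coefficients": _fit_to_rows(sel.fit),
            "adj_r2": sel.fit.adj_r2,
        }
        tt = two_sample_t(yv[(sub["group"] == "skier").to_numpy()],
                          yv[(sub["group"] == "control").to_numpy()])
        out["group_t_tests"][region] = {
            "statistic": tt.statistic, "df": tt.df, "p_value": tt.pvalue,
            "mean_difference": tt.mean_diff,
        }
        out["within_group"][region] = {}
        for grp in ("control", "skier"):
            gsub = sub[sub["group"] == grp]
            gsel = select_model(gsub[f"swv_{region}"].to_numpy(),
                                design_from_cohort(gsub, list(WITHIN_GROUP_POOL)),
                                criterion)
            out["within_group"][region][grp] = {
                "selected": list(gsel.selected),
                "coefficients": _fit_to_rows(gsel.fit),
                "adj_r2": gsel.fit.adj_r2,
            }
    for name, res in regional_delta_test(cohort).items():
        out["regional_deltas"][name] = {
            "mean_control": res.mean_control, "mean_skier": res.mean_skier,
            "statistic": res.test.statistic, "df": res.test.df,
            "p_value": res.test.pvalue, "n_control": res.n_control,
            "n_skier": res.n_skier, "n_dropped": res.n_dropped,
        }
    return out


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the full pipeline, writing every artifact into ``outdir``.

    Artifacts: config.json; sweep stacks + poses CSV; compounded SWE/B-mode
    NRRD volumes; landmarks JSON; regional-means CSV for the phantom
    reconstruction; simulated cohort CSV; inference JSON; run.log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        ss = np.random.SeedSequence(config.seed)
        sweep_ss, cohort_ss = ss.spawn(2)
        log.info("run seed=%d sweep_stream=%s cohort_stream=%s", config.seed,
                 sweep_ss.spawn_key, cohort_ss.spawn_key)
        with open(outdir / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=1)

        log.info("stage simulate_sweep: n_frames=%d", config.sweep.n_frames)
        frames = simulate_sweep(config.phantom, config.sweep,
                                rng=np.random.default_rng(sweep_ss))
        tio.write_frame_stack(outdir / "sweep", frames)

        log.info("stage reconstruct: voxel_spacing=%.3g", config.voxel_spacing)
        from .reconstruct import pixel_world_positions
        pts = np.concatenate([pixel_world_positions(f).reshape(-1, 3)
                              for f in frames])
        spec = VoxelGridSpec.bounding(pts, config.voxel_spacing)
        swe, bmode = compound(frames, spec, KernelConfig())
        tio.write_volume(outdir / "swe.nrrd", swe)
        tio.write_volume(outdir / "bmode.nrrd", bmode)

        log.info("stage regions: mask_source=%s cut_distance=%.3g",
                 config.mask_source, config.cut_distance)
        if config.mask_source == "segment":
            mask = segment_bmode(bmode)
        else:
            mask = rasterize_phantom_mask(config.phantom, spec)
        tio.write_landmarks_json(outdir / "landmarks.json",
                                 mask.proximal_landmark, mask.distal_landmark)
        labels = partition_regions(mask, config.cut_distance)
        summary = regional_means(apply_mask(swe, mask), labels,
                                 tendon_length=mask.tendon_length)
        import pandas as pd
        pd.DataFrame([summary.as_dict()]).to_csv(
            outdir / "regional.csv", index=False)

        log.info("stage simulate_cohort: n=%d+%d",
                 config.cohort.control.n, config.cohort.skier.n)
        cohort = simulate_cohort(config.cohort,
                                 seed=np.random.default_rng(cohort_ss))
        tio.write_cohort_csv(outdir / "cohort.csv", cohort)

        log.info("stage analyze: criterion=%s alpha=%.3g",
                 config.criterion, config.alpha)
        fits = analyze_cohort(cohort, criterion=config.criterion)
        with open(outdir / "fits.json", "w") as fh:
            json.dump(fits, fh, indent=1)
        log.info("run complete")
    except Exception as e:  # annotate failures with the stage via the log
        log.error("pipeline failed: %s", e)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
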