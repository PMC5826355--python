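"""End-to-end orchestration on the synthetic cohort.

Stage order mirrors the study: acquisition scheme -> phantom cohort ->
per-acquisition DTI and 3D-SHORE index maps -> tract/ROI quantification
-> test-retest reproducibility on controls -> longitudinal group
inference -> outcome regression.  Every run is deterministic given the
config seed and writes the resolved configuration (with its hash) next to
the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .inference import group_delta_tests, mixed_anova, rm_anova
from .outcome import run_model_families
from .phantom import (
    CohortSpec,
    build_cohort,
    build_toy_geometry,
    cohort_covariates,
    estimate_snr,
    tissue_mask,
)
from .qspace import build_dsi_scheme, subset_by_bvalue
from .quantify import gm_mask, measure_records
from .reproducibility import summarize_repro
from .shore import fit_shore_volume
from .sphere import icosphere_sampling
from .tensor import fit_tensor_volume

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "compute_index_maps"]


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run (fully serializable)."""

    # acquisition
    radial_grid_size: int = 5
    b_max: float = 8000.0
    tau: float = 0.0538
    dti_b_limit: float = 1500.0
    # SHORE model
    n_max: int = 6
    lambda_reg: float = 1e-8
    odf_subdivisions: int = 3
    # phantom geometry / cohort
    grid_shape: tuple[int, int, int] = (26, 16, 14)
    block_size: int = 2
    n_gm_regions: int = 36
    n_streamlines: int = 5
    n_controls: int = 10
    n_patients: int = 10
    snr_b0: float = 28.0
    intra_subject_cv: float = 0.03
    inter_subject_cv: float = 0.10
    # quantification
    fiber_step: float = 0.5
    gm_threshold: float = 0.95
    # statistics
    n_indices_family: int = 7
    alpha: float = 0.05
    p_out: float = 0.10
    # execution
    seed: int = 0
    image_level: bool = False  # volumes + voxel fits vs measure-level cohort
    outdir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def compute_index_maps(volume, scheme, config: RunConfig, mask=None):
    """DTI (low-b subset) and SHORE index maps for one 4-D acquisition."""
    dti_scheme = subset_by_bvalue(scheme, 0.0, config.dti_b_limit)
    sel = (scheme.bvals < config.dti_b_limit) | scheme.is_b0
    dti_maps = fit_tensor_volume(volume[..., sel], dti_scheme, mask=mask)
    sampling = icosphere_sampling(config.odf_subdivisions)
    shore_maps = fit_shore_volume(
        volume,
        scheme,
        md_map=dti_maps["md"],
        e1_map=dti_maps["e1"],
        mask=mask,
        n_max=config.n_max,
        lambda_reg=config.lambda_reg,
        sampling=sampling,
    )
    maps = {"md": dti_maps["md"], "fa": dti_maps["fa"]}
    for name in ("gfa", "pa", "rtap", "rtpp", "msd"):
        maps[name] = shore_maps[name]
    return maps


def _image_level_measures(config: RunConfig, spec: CohortSpec, geometry, scheme):
    tissue = tissue_mask(geometry)
    gmask = gm_mask(geometry.gm_probability, config.gm_threshold)
    frames = []
    snr_values = []
    cc_roi = geometry.parcellation == geometry.cc_label
    background = ~tissue
    for record, volume in build_cohort(spec, geometry, scheme):
        t0 = time.perf_counter()
        snr_values.append(
            estimate_snr(volume, cc_roi, background, b0_index=scheme.b0_index)
        )
        maps = compute_index_maps(volume, scheme, config, mask=tissue)
        for index_name, index_map in maps.items():
            frames.append(
                measure_records(
                    record["subject"],
                    record["group"],
                    record["session"],
                    index_name,
                    index_map,
                    geometry,
                    gmask,
                    step=config.fiber_step,
                )
            )
        logger.info(
            "fitted %s session %s in %.1fs",
            record["subject"],
            record["session"],
            time.perf_counter() - t0,
        )
    measures = pd.concat(frames, ignore_index=True)
    covariates = cohort_covariates(spec)
    return measures, covariates, snr_values


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a result bundle and (optionally) writes
    TSV/JSON outputs plus the resolved config under ``config.outdir``."""
    t_start = time.perf_counter()
    scheme = build_dsi_scheme(config.radial_grid_size, config.b_max, config.tau)
    geometry = build_toy_geometry(
        grid_shape=tuple(config.grid_shape),
        n_streamlines_per_bundle=config.n_streamlines,
        n_gm_regions=config.n_gm_regions,
        block_size=config.block_size,
    )
    spec = CohortSpec(
        n_controls=config.n_controls,
        n_patients=config.n_patients,
        snr_b0=config.snr_b0,
        intra_subject_cv=config.intra_subject_cv,
        inter_subject_cv=config.inter_subject_cv,
        seed=config.seed,
    )
    snr_values: list[float] = []
    if config.image_level:
        measures, covariates, snr_values = _image_level_measures(
            config, spec, geometry, scheme
        )
    else:
        from .phantom import simulate_measure_table

        measures, covariates = simulate_measure_table(spec, geometry)

    # reproducibility on controls
    repro_tract = summarize_repro(measures, grouping="loop_pooled")
    repro_gm = summarize_repro(measures, grouping="per_unit")

    # tract-based longitudinal comparisons
    delta_tests = group_delta_tests(measures, n_indices=config.n_indices_family)

    # GM ANOVAs: mixed on tp1/tp2 of both groups, RM on the patient tps
    roi = measures[measures["unit_type"] == "roi"]
    anova_mixed = {}
    anova_rm = {}
    for index_name, sub in roi.groupby("index", sort=True):
        mixed_tab = sub[sub["session"].isin([1, 2])]
        anova_mixed[index_name] = mixed_anova(mixed_tab)
        pat = sub[sub["group"] == "patient"]
        if pat["session"].nunique() >= 3:
            anova_rm[index_name] = rm_anova(pat)

    # outcome regression: the largest family (clinical + 5 propagator
    # indices) has 8 predictors, so fewer than 10 patients cannot
    # estimate the full model
    if config.n_patients >= 10:
        models = run_model_families(measures, covariates, p_out=config.p_out)
    else:
        logger.warning(
            "skipping outcome regression: %d patients cannot estimate the "
            "full 8-predictor model",
            config.n_patients,
        )
        models = {}

    results = {
        "config": config,
        "scheme": scheme,
        "geometry": geometry,
        "measures": measures,
        "covariates": covariates,
        "snr_values": snr_values,
        "repro_tract": repro_tract,
        "repro_gm": repro_gm,
        "delta_tests": delta_tests,
        "anova_mixed": anova_mixed,
        "anova_rm": anova_rm,
        "models": models,
        "runtime_s": time.perf_counter() - t_start,
    }
    if config.outdir:
        _write_outputs(results)
    return results


def _write_outputs(results: dict) -> None:
    config: RunConfig = results["config"]
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict(), "config_hash": config.config_hash()}
    pio.write_json(meta, out / "run_config.json")
    pio.write_table(results["measures"], out / "measures.tsv")
    pio.write_table(results["covariates"], out / "covariates.tsv")
    pio.write_table(results["delta_tests"], out / "delta_tests.tsv")
    repro = pd.concat(
        [r.to_frame() for r in results["repro_tract"] + results["repro_gm"]],
        ignore_index=True,
    )
    pio.write_table(repro, out / "reproducibility.tsv")
    anova_rows = []
    for kind, tables in (("mixed", results["anova_mixed"]), ("rm", results["anova_rm"])):
        for index_name, tab in tables.items():
            df = tab.to_frame()
            df.insert(0, "index", index_name)
            df.insert(0, "design", kind)
            anova_rows.append(df)
    if anova_rows:
        pio.write_table(pd.concat(anova_rows, ignore_index=True), out / "anova.tsv")
    pio.write_json(
        {f"{fam}:{net}": res.to_dict() for (fam, net), res in results["models"].items()},
        out / "models.json",
    )
    preds = []
    for (fam, net), res in results["models"].items():
        if res.predictions is not None:
            p = res.predictions.copy()
            p.insert(0, "family", fam)
            p.insert(1, "network", net if net else "")
            preds.append(p)
    if preds:
        pio.write_table(pd.concat(preds, ignore_index=True), out / "predictions.tsv")
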