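"""End-to-end orchestration: synthesize, extract, measure, fit, report.

``run_pipeline`` executes the enabled stages in the order of the study
design — cohort synthesis, phantom rasterization + threshold extraction
+ mesh morphometry on a subset of objects, then regression analysis at
case, plaque and calcification level — writing CSV artifacts and a JSON
manifest with config hash, seed, and artifact checksums so identical
configurations reproduce identical outputs.

``verify_models`` runs the package's internal consistency suite: the
asymptotic-exponent limits of the growth hypotheses, the agreement of
discrete mesh measurement with the closed forms, the S/V decay, and the
comparison of population-fitted exponents against the model-derived
bracket (the fitted surface-area-volume exponent should lie in
[2/3, 1] and the length-volume exponent in [1/3, 2/3]).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from plaquegeom.association_stats import (
    classify,
    linear_fit,
    matrix_to_frame,
    pairwise_matrix,
    power_fit,
)
from plaquegeom.geometry_models import (
    GrowthHypothesis,
    Model1Params,
    Model2Params,
    model1_metrics,
    model2_metrics,
    sv_ratio_trajectory,
    asymptotic_exponent,
)
from plaquegeom.mesh_morphometry import measure_profile, mesh_surface_area, mesh_volume
from plaquegeom.mesh_synthesis import (
    MeshResolution,
    mesh_from_model1,
    mesh_from_model2,
    model_centerline,
)
from plaquegeom.phantom_extraction import (
    ROI,
    ThresholdConfig,
    components_to_mesh,
    dice_coefficient,
    extract_two_step,
    rasterize,
)
from plaquegeom.population_synthesis import (
    PopulationConfig,
    cohort_table,
    generate_population,
    summarize_cases,
)

__all__ = ["RunConfig", "run_pipeline", "verify_models"]

log = logging.getLogger("plaquegeom")

CASE_VARIABLES = [
    "n_plaques",
    "n_calcifications",
    "total_plaque_volume",
    "total_calcification_volume",
]
PLAQUE_PAIRS = [
    ("volume_mm3", "surface_area_mm2"),
    ("volume_mm3", "length_mm"),
    ("volume_mm3", "surface_distance_mm"),
    ("volume_mm3", "xsec_area_mm2"),
    ("surface_area_mm2", "length_mm"),
    ("surface_area_mm2", "surface_distance_mm"),
    ("length_mm", "surface_distance_mm"),
    ("xsec_diameter_mm", "xsec_area_mm2"),
]
CALC_PAIRS = [
    ("volume_mm3", "length_mm"),
    ("volume_mm3", "surface_distance_mm"),
    ("length_mm", "surface_distance_mm"),
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end run.

    ``stages`` is any subset of {"cohort", "phantom", "stats"}; the
    phantom stage closes the rasterize-extract-mesh-measure loop on
    ``n_phantom_objects`` plaques from the cohort.  A mandatory ``seed``
    fans out to per-stage substreams, so each stage reruns identically
    in isolation.  When ``stats`` runs without ``cohort``,
    ``measurements_csv`` supplies the plaque-level table.
    """

    out_dir: str | Path = "plaquegeom_run"
    seed: int = 0
    stages: tuple[str, ...] = ("cohort", "phantom", "stats")
    population: PopulationConfig | None = None
    resolution: MeshResolution = field(default_factory=MeshResolution)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    n_phantom_objects: int = 2
    phantom_spacing: float = 0.25
    measurements_csv: str | Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - {"cohort", "phantom", "stats"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("at least one stage must be enabled")


def _config_hash(cfg: RunConfig) -> str:
    text = repr(cfg).encode()
    return hashlib.sha256(text).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    return {
        stage: int(child.generate_state(1)[0] % (2**31 - 1))
        for stage, child in zip(("cohort", "phantom", "stats"), children)
    }


def _fit_table(table: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Linear and power fits side by side for each parameter pair."""
    rows = []
    for x_var, y_var in pairs:
        sub = table[[x_var, y_var]].dropna()
        sub = sub[(sub[x_var] > 0) & (sub[y_var] > 0)]
        if len(sub) < 3:
            continue
        x = sub[x_var].to_numpy()
        y = sub[y_var].to_numpy()
        lin = linear_fit(x, y)
        pw = power_fit(x, y)
        rows.append(
            {
                "x": x_var,
                "y": y_var,
                "n": lin.n,
                "linear_r": lin.pearson_r,
                "linear_r2": lin.r_squared,
                "linear_p": lin.p_value,
                "class": classify(lin).label,
                "power_c": pw.multiplier,
                "power_exponent": pw.exponent,
                "power_r2": pw.r_squared,
                "power_beats_linear": pw.r_squared > lin.r_squared,
            }
        )
    return pd.DataFrame(rows)


def _phantom_loop(
    cohort, n_objects: int, resolution: MeshResolution,
    thresholds: ThresholdConfig, spacing: float, seed: int,
) -> pd.DataFrame:
    """Close the loop: mesh -> phantom -> extraction -> mesh -> measure.

    Takes the first ``n_objects`` plaques of the cohort, rasterizes each
    alone on a grid fitted to its bounds, extracts by thresholds, meshes
    the largest extracted component and compares volumes/Dice against
    the ground truth.
    """
    rows = []
    picked = []
    for case in cohort:
        for params, _profile in case.plaques:
            picked.append((case.case_id, params))
            if len(picked) >= n_objects:
                break
        if len(picked) >= n_objects:
            break
    for case_id, params in picked:
        if isinstance(params, Model1Params):
            mesh = mesh_from_model1(params, resolution)
            truth = model1_metrics(params)
        else:
            mesh = mesh_from_model2(params, resolution)
            truth = model2_metrics(params)
        # resolve the shell wall with >= 6 voxels across its thickness; the
        # half-voxel origin offset keeps voxel centers off the flat faces
        # (a center exactly on the surface counts as outside)
        sp = min(spacing, (params.R - params.r) / 6.0)
        lo = mesh.bounds[0] - 3.5 * sp
        hi = mesh.bounds[1] + 4 * sp
        shape = tuple(int(math.ceil((h - l) / sp)) for l, h in zip(lo, hi))
        # pad with fat-range HU so the soft-tissue background (≈40 HU, inside
        # the non-calcified window) does not merge with the plaque component
        phantom = rasterize(
            [(mesh, "noncalcified")],
            shape=shape,
            spacing=sp,
            origin=tuple(lo),
            hu_map={"background": -100.0},
            blooming_sigma=thresholds.blooming_sigma,
            noise_sd=thresholds.noise_sd,
            seed=seed,
        )
        _calc, noncalc, _outer = extract_two_step(phantom, cfg=thresholds)
        if not noncalc:
            rows.append({"case_id": case_id, "extracted": False})
            continue
        comp = noncalc[0]
        extracted_mesh = components_to_mesh(comp, phantom.spacing, phantom.origin)
        profile = measure_profile(extracted_mesh, model_centerline(params))
        truth_mask = phantom.truth_labels > 0
        rows.append(
            {
                "case_id": case_id,
                "extracted": True,
                "truth_volume_mm3": truth.V,
                "voxel_volume_mm3": comp.volume_mm3,
                "mesh_volume_mm3": profile.volume,
                "rel_volume_error": (profile.volume - truth.V) / truth.V,
                "dice": dice_coefficient(comp.mask, truth_mask),
                "surface_area_mm2": profile.surface_area,
                "length_mm": profile.length,
                "surface_distance_mm": profile.surface_distance,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "stages": list(cfg.stages),
        "artifacts": {},
    }

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        manifest["artifacts"][name] = _checksum(path)

    cohort = None
    plaque_table = None
    try:
        if "cohort" in cfg.stages:
            log.info("stage cohort: synthesizing population")
            pop = (
                cfg.population
                if cfg.population is not None
                else PopulationConfig(seed=seeds["cohort"])
            )
            cohort = generate_population(pop)
            _write(summarize_cases(cohort), "case_summary.csv")
            plaque_table = cohort_table(cohort, "plaque")
            _write(plaque_table, "plaque_table.csv")
            _write(cohort_table(cohort, "calcification"), "calcification_table.csv")

        if "phantom" in cfg.stages:
            if cohort is None:
                raise RuntimeError("phantom stage requires the cohort stage")
            log.info("stage phantom: rasterize/extract/measure loop")
            loop = _phantom_loop(
                cohort, cfg.n_phantom_objects, cfg.resolution,
                cfg.thresholds, cfg.phantom_spacing, seeds["phantom"],
            )
            _write(loop, "phantom_loop.csv")

        if "stats" in cfg.stages:
            log.info("stage stats: regression analysis")
            if plaque_table is None:
                if cfg.measurements_csv is None:
                    raise RuntimeError(
                        "stats-only runs need measurements_csv with a plaque table"
                    )
                plaque_table = pd.read_csv(cfg.measurements_csv)
            if cohort is not None:
                summary = summarize_cases(cohort)
                matrix = pairwise_matrix(summary, CASE_VARIABLES)
                frame = matrix_to_frame(matrix)
                path = out / "case_matrix.csv"
                frame.to_csv(path)
                manifest["artifacts"]["case_matrix.csv"] = _checksum(path)
                calc_table = cohort_table(cohort, "calcification")
                if len(calc_table) >= 3:
                    _write(_fit_table(calc_table, CALC_PAIRS), "calcification_fits.csv")
            _write(_fit_table(plaque_table, PLAQUE_PAIRS), "plaque_fits.csv")
    except Exception as exc:
        manifest["failed"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def verify_models(
    fitted_sv_exponent: float = 0.741,
    fitted_lv_exponent: float = 0.414,
    resolution: MeshResolution | None = None,
) -> pd.DataFrame:
    """Internal verification suite of the geometric models.

    Checks the asymptotic power-law exponents of all growth hypotheses
    against their derived limits, the agreement of discrete mesh
    measurement with the closed forms at a demo resolution, the decay
    of S/V under growth, and whether population-fitted exponents
    (defaults: surface-area-volume 0.741, length-volume 0.414, as
    fitted on a real plaque cohort) fall inside the model bracket —
    within 0.08 of the S-V lower bound 2/3 and 0.09 of the L-V lower
    bound 1/3.

    Returns a DataFrame with one row per check: name, value, expected,
    tolerance, passed.
    """
    rows = []

    def _check(name: str, value: float, expected: float, tol: float) -> None:
        rows.append(
            {
                "check": name,
                "value": value,
                "expected": expected,
                "tolerance": tol,
                "passed": abs(value - expected) <= tol,
            }
        )

    base1 = Model1Params(2.0, 1.0, 10.0, 0.3, 0.2)
    base2 = Model2Params(2.0, 1.0, 10.0, 1.0)
    h11 = GrowthHypothesis("H1_1", base1)
    h12 = GrowthHypothesis("H1_2", Model1Params(2.0, 1.0, 10.0), secant_base=2.0)
    h21 = GrowthHypothesis("H2_1", base2)

    _check("exponent_SV_H1.1", asymptotic_exponent(h11, "S_V", k_max=1e4), 2 / 3, 1e-9)
    _check("exponent_LV_H1.1_wall",
           asymptotic_exponent(h11, "L_V", "wall", k_max=1e4), 1 / 3, 1e-9)
    _check("exponent_SV_H1.2", asymptotic_exponent(h12, "S_V", k_max=1e6), 1.0, 0.01)
    _check("exponent_LV_H1.2_wall",
           asymptotic_exponent(h12, "L_V", "wall", k_max=1e6), 2 / 3, 0.01)
    _check("exponent_SV_H2.1", asymptotic_exponent(h21, "S_V", k_max=1e6), 2 / 3, 0.01)
    _check("exponent_LV_H2.1_chord",
           asymptotic_exponent(h21, "L_V", "chord", k_max=1e6), 1 / 3, 0.01)

    _check("fitted_SV_exponent_vs_lower_bound", fitted_sv_exponent, 2 / 3, 0.08)
    _check("fitted_LV_exponent_vs_lower_bound", fitted_lv_exponent, 1 / 3, 0.09)
    rows.append(
        {
            "check": "fitted_SV_exponent_in_bracket",
            "value": fitted_sv_exponent,
            "expected": 2 / 3,
            "tolerance": 1.0 - 2 / 3,
            "passed": 2 / 3 < fitted_sv_exponent < 1.0,
        }
    )
    rows.append(
        {
            "check": "fitted_LV_exponent_in_bracket",
            "value": fitted_lv_exponent,
            "expected": 1 / 3,
            "tolerance": 2 / 3 - 1 / 3,
            "passed": 1 / 3 < fitted_lv_exponent < 2 / 3,
        }
    )

    res = resolution or MeshResolution(192, 48, 6)
    m1 = mesh_from_model1(base1, res)
    cf1 = model1_metrics(base1)
    _check("mesh_vs_closed_volume_model1",
           abs(mesh_volume(m1) - cf1.V) / cf1.V, 0.0, 0.005)
    _check("mesh_vs_closed_area_model1",
           abs(mesh_surface_area(m1) - cf1.S) / cf1.S, 0.0, 0.005)
    m2 = mesh_from_model2(base2, res)
    cf2 = model2_metrics(base2)
    _check("mesh_vs_closed_volume_model2",
           abs(mesh_volume(m2) - cf2.V) / cf2.V, 0.0, 0.005)
    _check("mesh_vs_closed_area_model2",
           abs(mesh_surface_area(m2) - cf2.S) / cf2.S, 0.0, 0.005)

    ks, sv = sv_ratio_trajectory(h21, k_max=1e4)
    monotone = bool(np.all(np.diff(sv) < 0))
    rows.append(
        {
            "check": "sv_ratio_decays_to_zero_H2.1",
            "value": float(sv[-1]),
            "expected": 0.0,
            "tolerance": 1e-3,
            "passed": monotone and sv[-1] < 1e-3,
        }
    )
    return pd.DataFrame(rows)
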