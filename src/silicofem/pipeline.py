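"""End-to-end orchestration: generate → atlas → expand → strength → risk → compare.

Each stage writes its result to the output directory and reads its inputs
back from the previous stage's artifact, so any stage can be re-run in
isolation.  The whole pipeline is a deterministic function of (config,
master seed): the master seed spawns one child seed per stage.  Subjects
never leave a cohort silently — QC failures stay in the tables with an
explicit status and are only excluded from the FE sweep.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import stats as st
from .atlas import (
    AtlasTopology,
    assemble_vector,
    build_atlas,
    disassemble_vector,
    explained_variance,
    load_atlas,
    save_atlas,
)
from .config import PipelineConfig, _to_plain
from .covariates import fit_covariate_models
from .phantom import generate_paired_cohort, make_template
from .risk import evaluate_subject
from .sampler import SamplingConfig, sample_component_weights, synthesize_cohort
from .strength import SolverFailure, failure_surface

__all__ = [
    "run_pipeline",
    "stage_phantoms",
    "stage_atlas",
    "stage_expand",
    "stage_strength",
    "stage_risk",
    "stage_compare",
]

__version__ = "0.1.0"

PHYSICAL_CSV = "physical_cohort.csv"
SYNTHETIC_CSV = "synthetic_cohort.csv"
VECTORS_H5 = "subject_vectors.h5"
ATLAS_H5 = "atlas.h5"
SCORES_H5 = "synthetic_scores.h5"
FAILURE_CSV = "failure_loads.csv"
REPORT_JSON = "report.json"
MANIFEST_JSON = "manifest.json"


def _stage_seeds(seed: int | None) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["phantoms", "expand", "covariates"]
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for n, c in zip(names, children)
    }


def _template_arrays(outdir: Path):
    with h5py.File(Path(outdir) / VECTORS_H5, "r") as f:
        tets = f["tets"][:]
        surface = f["surface_node_ids"][:]
        topo = AtlasTopology(
            int(f.attrs["n_nodes"]), int(f.attrs["n_landmarks"]),
            int(f.attrs["n_elements"]),
        )
    return tets, surface, topo


def stage_phantoms(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    subjects, table, template = generate_paired_cohort(
        config.n_pairs, config.cohort, seed
    )
    topo = AtlasTopology(template.n_nodes, 4, template.n_elements)
    X = np.array(
        [
            assemble_vector(
                s.geometry.node_coords,
                s.geometry.landmark_coords,
                s.materials.young_modulus,
                topo,
                config.block_scale,
            )
            for s in subjects
        ]
    ) if subjects else np.empty((0, 3 * (topo.n_nodes + 4) + topo.n_elements))
    with h5py.File(outdir / VECTORS_H5, "w") as f:
        f.create_dataset("vectors", data=X)
        f.create_dataset("tets", data=template.tets)
        f.create_dataset("surface_node_ids", data=template.surface_node_ids)
        f.create_dataset("template_coords", data=template.node_coords)
        f.create_dataset("template_landmarks", data=template.landmark_coords)
        f.attrs["n_nodes"] = topo.n_nodes
        f.attrs["n_landmarks"] = 4
        f.attrs["n_elements"] = topo.n_elements
        f.attrs["block_scale"] = config.block_scale
    sio.write_cohort(outdir / PHYSICAL_CSV, table)
    if config.write_meshes:
        mesh_dir = outdir / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for s in subjects:
            sio.write_vtu(
                mesh_dir / f"{s.subject_id}.vtu",
                s.geometry.node_coords,
                template.tets,
                cell_data={"rho_app": s.materials.rho_app,
                           "E": s.materials.young_modulus},
                field_data={"landmarks": s.geometry.landmark_coords},
            )
    return {"n_subjects": len(subjects)}


def stage_atlas(config: PipelineConfig, outdir: Path) -> dict:
    with h5py.File(outdir / VECTORS_H5, "r") as f:
        X = f["vectors"][:]
        topo = AtlasTopology(
            int(f.attrs["n_nodes"]), int(f.attrs["n_landmarks"]),
            int(f.attrs["n_elements"]),
        )
        block_scale = float(f.attrs["block_scale"])
    model = build_atlas(X, topo, block_scale, config.equalize_blocks)
    save_atlas(outdir / ATLAS_H5, model)
    return {
        "n_components": model.n_components,
        "explained_95": next(
            (
                k
                for k in range(model.n_components + 1)
                if explained_variance(model, k) >= 0.95
            ),
            model.n_components,
        ),
    }


def stage_expand(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    model = load_atlas(outdir / ATLAS_H5)
    tets, surface, _ = _template_arrays(outdir)
    template = _make_template_view(outdir, tets, surface)
    physical = sio.read_cohort(outdir / PHYSICAL_CSV)
    cov_models = fit_covariate_models(
        physical,
        reference_abmd=(
            config.cohort.tscore_ref_mean,
            config.cohort.tscore_ref_sd,
        ),
    )
    sampling = SamplingConfig(
        n_synthetic=config.n_synthetic,
        u_range=config.sampling.u_range,
        seed=seed,
        aspect_threshold=config.sampling.aspect_threshold,
    )
    W = sample_component_weights(model, sampling)
    _, table = synthesize_cohort(
        model,
        W,
        template,
        cov_models,
        sampling,
        density_law=(config.cohort.density.modulus_a, config.cohort.density.modulus_b),
    )
    with h5py.File(outdir / SCORES_H5, "w") as f:
        f.create_dataset("scores", data=W)
    sio.write_cohort(outdir / SYNTHETIC_CSV, table)
    n_pass = int((table["qc_status"] == "pass").sum())
    return {"n_synthetic": len(table), "n_qc_pass": n_pass}


class _TemplateView:
    """Minimal template stand-in reconstructed from the vectors artifact."""

    def __init__(self, tets, surface_node_ids):
        self.tets = tets
        self.surface_node_ids = surface_node_ids


def _make_template_view(outdir, tets, surface):
    return _TemplateView(tets, surface)


def _iter_subject_geometries(config: PipelineConfig, outdir: Path):
    """Yield (subject_id, cohort, coords, landmarks, moduli) for all subjects."""
    tets, surface, topo = _template_arrays(outdir)
    with h5py.File(outdir / VECTORS_H5, "r") as f:
        X = f["vectors"][:]
        block_scale = float(f.attrs["block_scale"])
    physical = sio.read_cohort(outdir / PHYSICAL_CSV)
    for i, row in physical.iterrows():
        coords, lms, E = disassemble_vector(X[i], topo, block_scale)
        yield row["subject_id"], "physical", coords, lms, E

    atlas_path = outdir / ATLAS_H5
    scores_path = outdir / SCORES_H5
    if atlas_path.exists() and scores_path.exists():
        model = load_atlas(atlas_path)
        with h5py.File(scores_path, "r") as f:
            W = f["scores"][:]
        synthetic = sio.read_cohort(outdir / SYNTHETIC_CSV)
        from .atlas import reconstruct

        for i, row in synthetic.iterrows():
            vec = reconstruct(model, W[i])
            coords, lms, E = disassemble_vector(vec, topo, model.block_scale)
            yield row["subject_id"], "synthetic", coords, lms, np.clip(E, 1.0, None)


def stage_strength(config: PipelineConfig, outdir: Path) -> dict:
    tets, surface, _ = _template_arrays(outdir)
    tables = {
        "physical": sio.read_cohort(outdir / PHYSICAL_CSV),
        "synthetic": sio.read_cohort(outdir / SYNTHETIC_CSV)
        if (outdir / SYNTHETIC_CSV).exists()
        else None,
    }
    qc_by_id = {}
    for name, t in tables.items():
        if t is not None:
            qc_by_id.update(dict(zip(t["subject_id"], t["qc_status"])))
    rows = []
    msf_by_id = {}
    n_solver_fail = 0
    for sid, cohort, coords, lms, E in _iter_subject_geometries(config, outdir):
        if qc_by_id.get(sid, "pass") != "pass":
            continue
        try:
            grid = failure_surface(coords, tets, E, lms, surface, config.strength)
        except (SolverFailure, ValueError):
            qc_by_id[sid] = "fail:solver"
            n_solver_fail += 1
            continue
        msf_by_id[sid] = grid.msf
        for i, ap in enumerate(grid.ap_angles):
            for j, ml in enumerate(grid.ml_angles):
                rows.append(
                    dict(subject_id=sid, cohort=cohort, ap_angle=ap, ml_angle=ml,
                         failure_load_N=grid.loads[i, j])
                )
    pd.DataFrame(rows).to_csv(outdir / FAILURE_CSV, index=False)
    for name, path in ((
        "physical", outdir / PHYSICAL_CSV), ("synthetic", outdir / SYNTHETIC_CSV)):
        t = tables[name]
        if t is None:
            continue
        t["qc_status"] = [qc_by_id[s] for s in t["subject_id"]]
        t["msf"] = [msf_by_id.get(s, np.nan) for s in t["subject_id"]]
        t.to_csv(path, index=False)
    return {"n_simulated": len(msf_by_id), "n_solver_fail": n_solver_fail}


def stage_risk(config: PipelineConfig, outdir: Path) -> dict:
    failure = pd.read_csv(outdir / FAILURE_CSV)
    n_risk = 0
    for path in (outdir / PHYSICAL_CSV, outdir / SYNTHETIC_CSV):
        if not path.exists():
            continue
        table = sio.read_cohort(path)
        P_col, arf_col = [], []
        for _, row in table.iterrows():
            sub = failure[failure["subject_id"] == row["subject_id"]]
            if len(sub) == 0 or not np.isfinite(row.get("msf", np.nan)):
                P_col.append(np.nan)
                arf_col.append(np.nan)
                continue
            n_ap = sub["ap_angle"].nunique()
            n_ml = sub["ml_angle"].nunique()
            grid = _grid_from_rows(sub, n_ap, n_ml)
            res = evaluate_subject(
                grid, row["height_cm"], row["weight_kg"], config.fall,
                config.fall_rate,
            )
            P_col.append(res.P)
            arf_col.append(res.arf0)
            n_risk += 1
        table["p_fracture"] = P_col
        table["arf0"] = arf_col
        table.to_csv(path, index=False)
    return {"n_risk_evaluated": n_risk}


def _grid_from_rows(sub: pd.DataFrame, n_ap: int, n_ml: int):
    from .strength import FailureLoadGrid

    pivot = sub.pivot_table(
        index="ap_angle", columns="ml_angle", values="failure_load_N"
    )
    return FailureLoadGrid(
        ap_angles=pivot.index.to_numpy(dtype=float),
        ml_angles=pivot.columns.to_numpy(dtype=float),
        loads=pivot.to_numpy(dtype=float),
    )


def stage_compare(config: PipelineConfig, outdir: Path) -> dict:
    physical = sio.read_cohort(outdir / PHYSICAL_CSV)
    synthetic = sio.read_cohort(outdir / SYNTHETIC_CSV)
    phys = physical.dropna(subset=["arf0"])
    synt = synthetic.dropna(subset=["arf0"])

    threshold, sens, spec = st.roc_equal_error_threshold(
        phys["arf0"].to_numpy(), (phys["label"] == "fractured").to_numpy()
    )
    report: dict = {
        "physical": _cohort_summary(phys),
        "synthetic": _cohort_summary(synt),
        "eer_threshold": {
            "threshold": threshold, "sensitivity": sens, "specificity": spec
        },
    }
    D, p = st.ks_two_sample(phys["arf0"].to_numpy(), synt["arf0"].to_numpy())
    report["ks_physical_vs_synthetic"] = {"D": D, "p_value": p}
    strat = st.stratify(synt, threshold)
    report["stratification"] = asdict(strat)
    Path(outdir / REPORT_JSON).write_text(json.dumps(report, indent=2, default=float))
    return {"threshold": threshold, "fraction_above": strat.fraction_above}


def _cohort_summary(table: pd.DataFrame) -> dict:
    arf = table["arf0"].to_numpy(dtype=float)
    out: dict = {"n": int(len(arf))}
    if len(arf) >= 4 and np.unique(arf).size >= 2:
        fit = st.fit_gmm2_em(arf)
        out["gmm"] = {
            "weight_low": fit.weight, "mu_low": fit.mu1, "mu_high": fit.mu2,
            "sigma_low": fit.sigma1, "sigma_high": fit.sigma2,
            "loglik": fit.loglik, "converged": fit.converged,
        }
        out["gmm_vs_single_bic"] = {
            "bic_2comp": st.bic(fit.loglik, 5, len(arf)),
            "bic_1comp": st.bic(st.gaussian_loglik(arf), 2, len(arf)),
        }
        norm = st.normality_suite(arf)
        out["normality"] = {
            k: {"statistic": r.statistic, "p_value": r.p_value,
                "available": r.available, "note": r.note}
            for k, r in norm.items()
        }
    return out


def config_hash(config: PipelineConfig) -> str:
    text = yaml.safe_dump(_to_plain(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig, seed: int, outdir: str | Path
) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    manifest: dict = {
        "version": __version__,
        "config_hash": config_hash(config),
        "master_seed": seed,
        "stage_seeds": seeds,
        "stages": {},
        "outputs": [],
    }
    stages = [
        ("phantoms", lambda: stage_phantoms(config, outdir, seeds["phantoms"])),
        ("atlas", lambda: stage_atlas(config, outdir)),
        ("expand", lambda: stage_expand(config, outdir, seeds["expand"])),
        ("strength", lambda: stage_strength(config, outdir)),
        ("risk", lambda: stage_risk(config, outdir)),
        ("compare", lambda: stage_compare(config, outdir)),
    ]
    try:
        for name, fn in stages:
            t0 = time.perf_counter()
            info = fn()
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **info,
            }
    finally:
        manifest["outputs"] = sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
            if p.name != MANIFEST_JSON
        )
        (outdir / MANIFEST_JSON).write_text(
            json.dumps(manifest, indent=2, default=float)
        )
    return manifest
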