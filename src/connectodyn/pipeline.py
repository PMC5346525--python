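"""End-to-end cohort pipeline: simulate -> networks -> metrics -> Hurst -> stats.

File layout under the output directory::

    config.json, manifest.json, provenance.json
    timeseries/sub-XXX.tsv        volumes x regions, header = region labels
    gm/sub-XXX.nii.gz             gray-matter density volumes
    parcellation.nii.gz           integer atlas labels (0 = background)
    fc/sub-XXX.tsv                functional z-score connectivity matrices
    sc/sub-XXX.npz                structural similarity matrices + cube centers
    cohort.csv                    one row per subject: covariates, scores, metrics
    fc_local.csv / sc_local.csv / hurst_local.csv   subject x region tables
    results/*.csv, results/summary.json             statistics bundle

Each stage is restartable from the cached outputs of the stage before it; a
failure aborts with the stage name and subject id.  The in-memory
:func:`compute_cohort_metrics` path runs the same computation without file
I/O for simulation studies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .functional import RoiTimeSeries, ConnectivityMatrix, correlation_matrix
from .graphs import find_min_density, threshold_at_density, clustering_coefficients
from .hurst import hurst_profile
from .simulate import (
    SimulationConfig,
    build_truth_manifest,
    simulate_cognitive_scores,
    simulate_gray_matter_cohort,
    simulate_latents,
    simulate_roi_timeseries,
)
from .stats import DEFAULT_COMPOSITE_SCORES, run_statistical_battery
from .structural import (
    GrayMatterMap,
    build_similarity_matrix,
    extract_cubes,
    nodal_clustering_by_label,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "compute_cohort_metrics"]

STAGES = ("simulate", "fc-build", "sc-build", "metrics", "hurst", "stats")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and (when known) the subject id."""


@dataclass
class PipelineConfig:
    """Serializable pipeline options (echoed verbatim into the output dir)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    density_policy: str = "per-modality"  # or "common"
    use_rotations: bool = False
    gm_threshold: float = 0.1
    min_window: int = 8
    composite_scores: list[str] = field(default_factory=lambda: list(DEFAULT_COMPOSITE_SCORES))

    def __post_init__(self) -> None:
        if self.density_policy not in ("per-modality", "common"):
            raise ValueError("density_policy must be 'per-modality' or 'common'")

    def to_json(self) -> str:
        d = asdict(self)
        d["simulation"] = json.loads(self.simulation.to_json())
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["simulation"] = SimulationConfig.from_json(json.dumps(d["simulation"]))
        return cls(**d)


def _write_tsv_matrix(path: Path, matrix: np.ndarray, columns: list[str]) -> None:
    pd.DataFrame(matrix, columns=columns).to_csv(path, sep="\t", index=False)


def _read_timeseries(path: Path, subject_id: str, tr: float) -> RoiTimeSeries:
    try:
        frame = pd.read_csv(path, sep="\t")
        data = frame.to_numpy(dtype=float).T  # stored volumes x regions
        return RoiTimeSeries(
            subject_id=subject_id,
            data=data,
            region_labels=list(frame.columns),
            tr_seconds=tr,
        )
    except Exception as exc:
        raise PipelineError(
            f"stage fc-build: failed reading time series for subject {subject_id}: {exc}"
        ) from exc


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.simulation
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    latents = simulate_latents(sim)
    (out / "manifest.json").write_text(build_truth_manifest(sim, latents).to_json())

    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for i, sid in enumerate(sim.subject_ids()):
        ts = simulate_roi_timeseries(sim, i, latents)
        _write_tsv_matrix(ts_dir / f"{sid}.tsv", ts.data.T, ts.region_labels)

    gm_dir = out / "gm"
    gm_dir.mkdir(exist_ok=True)
    maps, parcellation = simulate_gray_matter_cohort(sim, latents)
    affine = np.diag([*sim.voxel_size_mm, 1.0])
    for gm in maps:
        nib.save(
            nib.Nifti1Image(gm.volume.astype(np.float32), affine),
            gm_dir / f"{gm.subject_id}.nii.gz",
        )
    nib.save(
        nib.Nifti1Image(parcellation.astype(np.int16), affine),
        out / "parcellation.nii.gz",
    )
    simulate_cognitive_scores(sim, latents).to_csv(out / "cohort.csv", index=False)


def stage_fc_build(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.simulation
    fc_dir = out / "fc"
    fc_dir.mkdir(exist_ok=True)
    for sid in sim.subject_ids():
        ts = _read_timeseries(out / "timeseries" / f"{sid}.tsv", sid, sim.tr_seconds)
        try:
            m = correlation_matrix(ts)
        except Exception as exc:
            raise PipelineError(
                f"stage fc-build failed for subject {sid}: {exc}"
            ) from exc
        _write_tsv_matrix(fc_dir / f"{sid}.tsv", m.weights, m.node_labels)


def stage_sc_build(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.simulation
    sc_dir = out / "sc"
    sc_dir.mkdir(exist_ok=True)
    for sid in sim.subject_ids():
        try:
            vol = np.asarray(
                nib.load(out / "gm" / f"{sid}.nii.gz").get_fdata(), dtype=float
            )
            gm = GrayMatterMap(
                subject_id=sid,
                volume=np.clip(vol, 0.0, 1.0),
                voxel_size_mm=sim.voxel_size_mm,
                mask=vol > 0,
            )
            cubes = extract_cubes(gm, cfg.gm_threshold)
            matrix, kept = build_similarity_matrix(cubes, cfg.use_rotations)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage sc-build failed for subject {sid}: {exc}"
            ) from exc
        np.savez_compressed(
            sc_dir / f"{sid}.npz",
            weights=matrix.weights.astype(np.float32),
            centers=kept.centers,
            n_extracted=cubes.n_nodes,
            n_dropped=cubes.n_nodes - kept.n_nodes,
        )


def _load_fc(out: Path, sid: str) -> ConnectivityMatrix:
    frame = pd.read_csv(out / "fc" / f"{sid}.tsv", sep="\t")
    w = frame.to_numpy(dtype=float)
    w = (w + w.T) / 2.0
    return ConnectivityMatrix(
        subject_id=sid, weights=w, modality="functional", node_labels=list(frame.columns)
    )


def stage_metrics(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.simulation
    ids = sim.subject_ids()
    parcellation = np.asarray(
        nib.load(out / "parcellation.nii.gz").get_fdata(), dtype=int
    )
    fc_mats = [_load_fc(out, sid) for sid in ids]
    sc_payload = {sid: np.load(out / "sc" / f"{sid}.npz") for sid in ids}
    sc_mats = [
        ConnectivityMatrix(
            subject_id=sid,
            weights=sc_payload[sid]["weights"].astype(float),
            modality="structural",
        )
        for sid in ids
    ]
    fc_density = find_min_density(fc_mats)
    sc_density = find_min_density(sc_mats)
    if cfg.density_policy == "common":
        fc_density = sc_density = max(fc_density, sc_density)

    cohort = pd.read_csv(out / "cohort.csv")
    labels = sim.region_labels()
    fc_local_rows, sc_local_rows = [], []
    fc_glob, sc_glob, sc_nodes = {}, {}, {}
    for sid, fc_m, sc_m in zip(ids, fc_mats, sc_mats):
        try:
            fc_graph = threshold_at_density(fc_m, fc_density)
            fc_res = clustering_coefficients(fc_graph)
            fc_glob[sid] = fc_res.global_
            fc_local_rows.append(
                {"subject_id": sid, **dict(zip(labels, fc_res.local))}
            )
            sc_graph = threshold_at_density(sc_m, sc_density)
            sc_res = clustering_coefficients(sc_graph)
            sc_glob[sid] = sc_res.global_
            sc_nodes[sid] = sc_graph.n_nodes
            nodal = nodal_clustering_by_label(
                sc_graph, sc_payload[sid]["centers"], parcellation
            )
            sc_local_rows.append(
                {
                    "subject_id": sid,
                    **{labels[k - 1]: v for k, v in nodal.values.items()},
                }
            )
        except Exception as exc:
            raise PipelineError(f"stage metrics failed for subject {sid}: {exc}") from exc
    cohort["fc_global_clust"] = cohort["subject_id"].map(fc_glob)
    cohort["sc_global_clust"] = cohort["subject_id"].map(sc_glob)
    cohort["sc_n_nodes"] = cohort["subject_id"].map(sc_nodes)
    cohort.to_csv(out / "cohort.csv", index=False)
    meta = cohort[["subject_id", "group", "minority", "cad_score"]]
    pd.DataFrame(fc_local_rows).merge(meta, on="subject_id").to_csv(
        out / "fc_local.csv", index=False
    )
    pd.DataFrame(sc_local_rows).merge(meta, on="subject_id").to_csv(
        out / "sc_local.csv", index=False
    )
    (out / "densities.json").write_text(
        json.dumps({"functional": fc_density, "structural": sc_density}, indent=2)
    )


def stage_hurst(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.simulation
    cohort = pd.read_csv(out / "cohort.csv")
    rows, glob = [], {}
    for sid in sim.subject_ids():
        ts = _read_timeseries(out / "timeseries" / f"{sid}.tsv", sid, sim.tr_seconds)
        try:
            prof = hurst_profile(ts, cfg.min_window)
        except Exception as exc:
            raise PipelineError(f"stage hurst failed for subject {sid}: {exc}") from exc
        glob[sid] = prof.global_h
        rows.append({"subject_id": sid, **dict(zip(prof.region_labels, prof.local_h))})
    cohort["global_h"] = cohort["subject_id"].map(glob)
    cohort.to_csv(out / "cohort.csv", index=False)
    meta = cohort[["subject_id", "group"]]
    pd.DataFrame(rows).merge(meta, on="subject_id").to_csv(
        out / "hurst_local.csv", index=False
    )


def stage_stats(cfg: PipelineConfig, out: Path) -> None:
    cohort = pd.read_csv(out / "cohort.csv")
    nodal = {}
    for family, fname in [
        ("fc_local", "fc_local.csv"),
        ("sc_local", "sc_local.csv"),
        ("hurst_local", "hurst_local.csv"),
    ]:
        path = out / fname
        if path.exists():
            nodal[family] = pd.read_csv(path)
    try:
        results = run_statistical_battery(
            cohort, nodal, composite_scores=cfg.composite_scores
        )
    except Exception as exc:
        raise PipelineError(f"stage stats failed: {exc}") from exc
    res_dir = out / "results"
    res_dir.mkdir(exist_ok=True)
    summary: dict = {}
    for key in (
        "cognitive",
        "global_metrics",
        "within_group_correlations",
        "correlation_differences",
        "exploratory",
    ):
        results[key].to_csv(res_dir / f"{key}.csv", index=False)
    for family, frame in results["local_metrics"].items():
        frame.to_csv(res_dir / f"local_{family}.csv", index=False)
    if "pca" in results:
        pca = results["pca"]
        summary["pca"] = {
            "loadings": pca.loadings,
            "variance_explained": pca.variance_explained,
        }
    if "composite" in results:
        comp = results["composite"]
        pd.DataFrame(
            {
                "subject_id": comp.subject_ids,
                "mahalanobis_distance": comp.distance,
                "log_mhd": comp.log_mhd,
            }
        ).to_csv(res_dir / "composite.csv", index=False)
    if "pca_vs_composite" in results:
        res = results["pca_vs_composite"]
        summary["pca_vs_composite"] = {
            "r": res.r,
            "n": res.n,
            "p_two_tailed": res.p_two_tailed,
        }
    fisher = results["correlation_differences"]
    if len(fisher):
        row = fisher[(fisher["x"] == "sc_global_clust") & (fisher["y"] == "fc_global_clust")]
        if len(row):
            summary["sc_fc_fisher"] = {
                "z": float(row["z"].iloc[0]),
                "p": float(row["p"].iloc[0]),
                "r_patient": float(row["r_patient"].iloc[0]),
                "r_control": float(row["r_control"].iloc[0]),
            }
    (res_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fc-build": stage_fc_build,
    "sc-build": stage_sc_build,
    "metrics": stage_metrics,
    "hurst": stage_hurst,
    "stats": stage_stats,
}


def _write_provenance(cfg: PipelineConfig, out: Path, stages: list[str]) -> None:
    outputs = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
    )
    record = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(cfg.to_json().encode()).hexdigest(),
        "seed": cfg.simulation.seed,
        "stages_run": stages,
        "n_subjects": cfg.simulation.n_subjects,
        "outputs": outputs,
    }
    (out / "provenance.json").write_text(json.dumps(record, indent=2, sort_keys=True))


def run_pipeline(
    cfg: PipelineConfig, out_dir, stages: list[str] | None = None
) -> Path:
    """Run the requested stages (default: all) into ``out_dir``.

    Idempotent at fixed seed: rerunning reproduces the statistics bundle.
    """
    out = Path(out_dir)
    todo = list(stages or STAGES)
    for s in todo:
        if s not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    for s in todo:
        _STAGE_FUNCS[s](cfg, out)
    _write_provenance(cfg, out, todo)
    return out


def compute_cohort_metrics(
    cfg: PipelineConfig, include_hurst: bool = True
) -> pd.DataFrame:
    """In-memory cohort table (covariates, scores, global metrics).

    Runs the same computations as the file-based pipeline without touching
    disk; used for replicated simulation studies.
    """
    sim = cfg.simulation
    latents = simulate_latents(sim)
    cohort = simulate_cognitive_scores(sim, latents)
    ids = sim.subject_ids()

    fc_mats, hurst_glob = [], {}
    for i, sid in enumerate(ids):
        ts = simulate_roi_timeseries(sim, i, latents)
        fc_mats.append(correlation_matrix(ts))
        if include_hurst:
            hurst_glob[sid] = hurst_profile(ts, cfg.min_window).global_h
    maps, _ = simulate_gray_matter_cohort(sim, latents)
    sc_payload = [
        build_similarity_matrix(extract_cubes(gm, cfg.gm_threshold), cfg.use_rotations)
        for gm in maps
    ]
    sc_mats = [m for m, _ in sc_payload]
    fc_density = find_min_density(fc_mats)
    sc_density = find_min_density(sc_mats)
    if cfg.density_policy == "common":
        fc_density = sc_density = max(fc_density, sc_density)
    fc_glob, sc_glob, sc_nodes = {}, {}, {}
    for sid, fc_m, sc_m in zip(ids, fc_mats, sc_mats):
        fc_glob[sid] = clustering_coefficients(
            threshold_at_density(fc_m, fc_density)
        ).global_
        g = threshold_at_density(sc_m, sc_density)
        sc_glob[sid] = clustering_coefficients(g).global_
        sc_nodes[sid] = g.n_nodes
    cohort["fc_global_clust"] = cohort["subject_id"].map(fc_glob)
    cohort["sc_global_clust"] = cohort["subject_id"].map(sc_glob)
    cohort["sc_n_nodes"] = cohort["subject_id"].map(sc_nodes)
    if include_hurst:
        cohort["global_h"] = cohort["subject_id"].map(hurst_glob)
    return cohort
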