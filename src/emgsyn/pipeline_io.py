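"""Serialization and end-to-end pipeline orchestration.

Interchange is plain text: one TSV matrix per trial plus a TSV label table
and a JSON manifest for datasets; W_t.tsv / W_s.tsv / A.tsv (long format)
plus a manifest for fitted models.  ``run_pipeline`` wires the stages
(simulate -> fit -> per-synergy decode -> information -> cluster -> report)
deterministically from a single seeded config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from emgsyn.clustering import cut_and_summarize, build_tree, functional_similarity_matrix
from emgsyn.dataset import LABEL_COLUMNS, EMGDataset
from emgsyn.decoding import decode_loocv, synergy_features
from emgsyn.decomposition import SpaceByTimeModel, fit_space_by_time
from emgsyn.information import pt_corrected_information
from emgsyn.synthetic_data import (
    build_task_design,
    make_ground_truth,
    make_subject_variant,
    synthesize_dataset,
)

logger = logging.getLogger("emgsyn")

_FLOAT_FMT = "%.12g"


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# dataset / model serialization


def write_dataset(dataset: EMGDataset, path: str | Path, manifest_extra: dict | None = None) -> None:
    """Write a dataset as per-trial TSVs, a label table and a JSON manifest."""
    path = Path(path)
    trials_dir = path / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    for l in range(dataset.L):
        np.savetxt(trials_dir / f"trial_{l:05d}.tsv", dataset.trials[l],
                   delimiter="\t", fmt=_FLOAT_FMT)
    dataset.labels.to_csv(path / "labels.tsv", sep="\t", index=False)
    manifest = {"L": dataset.L, "T": dataset.T, "M": dataset.M}
    if manifest_extra:
        manifest.update(manifest_extra)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(path: str | Path) -> EMGDataset:
    """Read a dataset written by :func:`write_dataset`, validating shapes."""
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    manifest = json.loads(manifest_file.read_text())
    L, T, M = manifest["L"], manifest["T"], manifest["M"]
    trials = np.empty((L, T, M))
    for l in range(L):
        trial_file = path / "trials" / f"trial_{l:05d}.tsv"
        if not trial_file.exists():
            raise FileNotFoundError(f"missing trial file {trial_file}")
        mat = np.loadtxt(trial_file, delimiter="\t", ndmin=2)
        if mat.shape != (T, M):
            raise ValueError(
                f"{trial_file} has shape {mat.shape}, manifest says {(T, M)}"
            )
        trials[l] = mat
    labels = pd.read_csv(path / "labels.tsv", sep="\t")
    if len(labels) != L:
        raise ValueError(
            f"label table has {len(labels)} rows, manifest says L={L}"
        )
    return EMGDataset(trials=trials, labels=labels)


def write_model(model: SpaceByTimeModel, path: str | Path, extra: dict | None = None) -> None:
    """Write W_t.tsv, W_s.tsv, A.tsv (long: trial, i, j, value) and a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "W_t.tsv", model.W_t, delimiter="\t", fmt=_FLOAT_FMT)
    np.savetxt(path / "W_s.tsv", model.W_s, delimiter="\t", fmt=_FLOAT_FMT)
    L, K, N = model.A.shape
    idx = np.indices((L, K, N)).reshape(3, -1).T
    long = pd.DataFrame(
        {"trial": idx[:, 0], "i": idx[:, 1], "j": idx[:, 2],
         "value": model.A.ravel()}
    )
    long.to_csv(path / "A.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    manifest = {
        "K": K, "N": N, "L": L, "T": model.W_t.shape[0], "M": model.W_s.shape[1],
        "seed": model.seed, "restarts": model.restarts,
        "objective": model.objective, "converged": bool(model.converged),
    }
    if extra:
        manifest.update(extra)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_model(path: str | Path) -> SpaceByTimeModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    W_t = np.loadtxt(path / "W_t.tsv", delimiter="\t", ndmin=2)
    W_s = np.loadtxt(path / "W_s.tsv", delimiter="\t", ndmin=2)
    long = pd.read_csv(path / "A.tsv", sep="\t")
    L, K, N = manifest["L"], manifest["K"], manifest["N"]
    A = np.zeros((L, K, N))
    A[long["trial"], long["i"], long["j"]] = long["value"]
    if W_t.shape[1] != K or W_s.shape[0] != N:
        raise ValueError("factor shapes disagree with manifest")
    return SpaceByTimeModel(
        W_t=W_t, W_s=W_s, A=A, seed=manifest.get("seed"),
        restarts=manifest.get("restarts", 1),
        objective=manifest.get("objective", np.nan),
        converged=manifest.get("converged", True),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """All stage parameters for one deterministic run."""

    seed: int = 0
    subjects: int = 1
    reps_per_movement: int = 5
    K: int = 3
    N: int = 3
    coefficient_noise_sigma: float = 0.2
    emg_noise_sd: float = 0.02
    restarts: int = 5
    max_iter: int = 300
    tol: float = 1e-8
    temporal_cutoff: float = 0.5
    spatial_cutoff: float = 0.6
    input_path: str | None = None  # read a dataset instead of simulating
    out_dir: str = "pipeline_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Provenance plus the summary tables of one pipeline run."""

    config: PipelineConfig
    vaf: dict = field(default_factory=dict)  # subject -> VAF
    decoding: pd.DataFrame | None = None
    cluster_assignments: pd.DataFrame | None = None
    stage_seconds: dict = field(default_factory=dict)
    clustering_ran: bool = False


def _decode_all(model: SpaceByTimeModel, data: EMGDataset, subject: int) -> tuple[pd.DataFrame, dict]:
    """Per-(synergy, parameter) decoding summary rows and full-movement confusions."""
    rows = []
    confusions: dict = {}
    parameters = [
        "start_target", "start_bar", "start_height", "direction",
        "horizontal_direction", "vertical_direction", "end_bar",
        "end_height", "end_target", "movement_id",
    ]
    jobs = [("temporal", i) for i in range(model.K)] + [
        ("spatial", j) for j in range(model.N)]
    for mode, index in jobs:
        feats = synergy_features(model, index, mode)
        for parameter in parameters:
            labels = data.label_values(parameter)
            result = decode_loocv(feats, labels, task_parameter=parameter)
            info = pt_corrected_information(result.confusion.counts)
            rows.append({
                "subject": subject, "mode": mode, "synergy": index,
                "parameter": parameter,
                "percent_correct": result.percent_correct,
                "bits": info.corrected_bits,
                "percent_of_max": info.percent_of_max,
            })
            if parameter == "movement_id":
                confusions[(mode, index)] = result.confusion.D
    return pd.DataFrame(rows), confusions


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full workflow and persist all intermediates under ``out_dir``."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    report = RunReport(config=config)
    design = build_task_design()

    # --- data stage
    t0 = time.perf_counter()
    datasets: list[EMGDataset] = []
    if config.input_path is not None:
        if not Path(config.input_path).exists():
            raise PipelineError("ingest", f"input path not found: {config.input_path}")
        datasets.append(read_dataset(config.input_path))
    else:
        truth = make_ground_truth(
            config.K, config.N, seed=config.seed,
            coefficient_noise_sigma=config.coefficient_noise_sigma,
            emg_noise_sd=config.emg_noise_sd, design=design,
        )
        for s in range(config.subjects):
            subject_truth = truth if s == 0 else make_subject_variant(truth, config.seed + 101 + s)
            ds = synthesize_dataset(
                subject_truth, design, config.reps_per_movement,
                seed=config.seed + 11 * s,
            )
            datasets.append(ds.emg)
            write_dataset(ds.emg, out / f"subject_{s}" / "data",
                          manifest_extra={"seed": config.seed,
                                          "emg_noise_sd": config.emg_noise_sd})
    report.stage_seconds["data"] = time.perf_counter() - t0
    logger.info("data stage done (%d subject datasets)", len(datasets))

    # --- fit stage
    t0 = time.perf_counter()
    models = []
    for s, data in enumerate(datasets):
        try:
            fit = fit_space_by_time(
                data, config.K, config.N, restarts=config.restarts,
                tol=config.tol, max_iter=config.max_iter,
                seed=config.seed + 977 * (s + 1),
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("fit", str(exc)) from exc
        models.append(fit.model)
        report.vaf[s] = fit.vaf
        write_model(fit.model, out / f"subject_{s}" / "model",
                    extra={"VAF": fit.vaf})
    report.stage_seconds["fit"] = time.perf_counter() - t0

    # --- decode + information stage
    t0 = time.perf_counter()
    tables = []
    registry_rows = []
    movement_confusions = []
    synergy_profiles = []
    for s, (model, data) in enumerate(zip(models, datasets)):
        table, confusions = _decode_all(model, data, s)
        tables.append(table)
        sdir = out / f"subject_{s}" / "decoding"
        sdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(sdir / "summary.tsv", sep="\t", index=False)
        for (mode, index), D in confusions.items():
            np.savetxt(sdir / f"confusion_movement_{mode}_{index}.tsv", D,
                       delimiter="\t", fmt=_FLOAT_FMT)
            registry_rows.append({"subject": s, "synergy": index, "mode": mode})
            movement_confusions.append(D)
            profile = model.W_t[:, index] if mode == "temporal" else model.W_s[index]
            synergy_profiles.append(profile)
    report.decoding = pd.concat(tables, ignore_index=True)
    report.decoding.to_csv(out / "decoding_summary.tsv", sep="\t", index=False)
    report.stage_seconds["decode"] = time.perf_counter() - t0

    # --- clustering stage (needs >= 2 synergies of a mode)
    t0 = time.perf_counter()
    registry = pd.DataFrame(registry_rows)
    assignment_frames = []
    for mode, cutoff in (("temporal", config.temporal_cutoff),
                         ("spatial", config.spatial_cutoff)):
        mask = registry["mode"] == mode
        if mask.sum() < 2:
            continue
        idx = np.flatnonzero(mask.to_numpy())
        sim = functional_similarity_matrix(
            [movement_confusions[i] for i in idx], registry[mask])
        tree = build_tree(sim)
        clusters, summaries = cut_and_summarize(
            tree, cutoff,
            [synergy_profiles[i] for i in idx],
            [movement_confusions[i] for i in idx],
        )
        frame = registry[mask].reset_index(drop=True).copy()
        frame["cluster"] = clusters.assignments
        assignment_frames.append(frame)
        cdir = out / "clusters" / mode
        cdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(cdir / "similarity.tsv", sim.r, delimiter="\t", fmt=_FLOAT_FMT)
        np.savetxt(cdir / "tree.tsv", tree, delimiter="\t", fmt=_FLOAT_FMT)
        frame.to_csv(cdir / "assignments.tsv", sep="\t", index=False)
        for summary in summaries:
            np.savetxt(cdir / f"cluster_{summary.cluster_id}_mean_synergy.tsv",
                       summary.mean_synergy, delimiter="\t", fmt=_FLOAT_FMT)
            np.savetxt(cdir / f"cluster_{summary.cluster_id}_mean_confusion.tsv",
                       summary.mean_confusion, delimiter="\t", fmt=_FLOAT_FMT)
        report.clustering_ran = True
    if assignment_frames:
        report.cluster_assignments = pd.concat(assignment_frames, ignore_index=True)
        report.cluster_assignments.to_csv(out / "cluster_assignments.tsv",
                                          sep="\t", index=False)
    report.stage_seconds["cluster"] = time.perf_counter() - t0

    (out / "report.txt").write_text(render_report(report))
    return report


def render_report(report: RunReport) -> str:
    """Human-readable run summary (bits to 2 decimals, percents to integers)."""
    lines = ["space-by-time synergy analysis run", "=" * 40]
    for s, vaf in report.vaf.items():
        lines.append(f"subject {s}: VAF = {vaf:.3f}")
    if report.decoding is not None:
        lines.append("")
        lines.append("decoding summary (per synergy, per parameter):")
        lines.append("subj  mode      syn  parameter              %corr  bits  %max")
        for _, row in report.decoding.iterrows():
            lines.append(
                f"{row['subject']:>4}  {row['mode']:<8}  {row['synergy']:>3}  "
                f"{row['parameter']:<21}  {round(row['percent_correct']):>4}  "
                f"{row['bits']:.2f}  {round(row['percent_of_max']):>4}"
            )
    lines.append("")
    if report.clustering_ran and report.cluster_assignments is not None:
        lines.append("cluster assignments (-1 = unclustered):")
        for _, row in report.cluster_assignments.iterrows():
            lines.append(
                f"  subject {row['subject']} {row['mode']} synergy "
                f"{row['synergy']}: cluster {row['cluster']}"
            )
    else:
        lines.append("clustering: not run")
    return "\n".join(lines) + "\n"
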