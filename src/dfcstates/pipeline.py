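"""End-to-end orchestration: conditioning -> windowed connectivity ->
(optional) regularization -> k sweep of state clustering -> dwell/
reliability -> group statistics -> edge aggregation -> strength
composition, with deterministic seeding and a run manifest of checksums.

The configuration holds every printed analysis constant as a named,
overridable default: 10 dropped volumes, TR 2 s, window width 22 TR with
Gaussian taper 3 TR and step 1 TR, 0.15 Hz low-pass, k = 2..20 with 150
replicates, 10-window reliability, edge alpha 0.001, recurrence >= 5.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .clustering import (
    cluster_states,
    dwell_records,
    reliability_filter,
    reliable_state_ids,
    subject_state_medoid,
)
from .conditioning import condition
from .stats import (
    aggregate_edges,
    composition_profile,
    compute_thresholds,
    edgewise_state_test,
    mdt_group_test,
)
from .synthetic import GroupScenario, generate_dataset
from .windows import GraphicalLassoConfig, make_taper, regularize_series, windowed_correlation

log = logging.getLogger("dfcstates")


@dataclass
class PipelineConfig:
    """All analysis parameters; defaults are the study's printed values."""

    manifest_path: str = ""
    output_dir: str = "results/run"
    drop_volumes: int = 10
    tr_seconds: float = 2.0
    cutoff_hz: float = 0.15
    window_width_tr: int = 22
    window_gaussian_sigma_tr: float = 3.0
    window_step_tr: int = 1
    regularize: bool = True
    glasso: GraphicalLassoConfig = field(default_factory=GraphicalLassoConfig)
    k_min: int = 2
    k_max: int = 20
    n_replicates: int = 150
    reliability_min_windows: int = 10
    edge_alpha: float = 0.001
    min_recurrence: int = 5
    case_group: str = "asd_like"
    control_group: str = "td_like"
    composition_source: str = "members"  # or "centroids"
    seed: int = 0

    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["glasso"]["lambda_grid"] = [float(x) for x in self.glasso.lambda_grid]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        glasso = doc.pop("glasso", None)
        cfg = cls(**doc)
        if glasso is not None:
            glasso["lambda_grid"] = np.asarray(glasso["lambda_grid"], dtype=float)
            cfg.glasso = GraphicalLassoConfig(**glasso)
        return cfg


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, per-stage wall time, and a
    checksum per written output file."""

    config: dict
    version: str
    stage_seconds: dict
    checksums: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_to_dir(
    scenario: GroupScenario, output_dir, overwrite: bool = False
) -> pd.DataFrame:
    """Write a scenario's dataset as per-subject TSV time courses, zero
    motion stubs, a truth table, the scenario YAML and an input manifest.
    Returns the manifest table."""
    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    timecourses, truth = generate_dataset(scenario)
    rows = []
    for tc in timecourses:
        tc_path = out / f"{tc.subject_id}_timecourse.tsv"
        mo_path = out / f"{tc.subject_id}_motion.txt"
        dio.write_timecourse(tc_path, tc)
        np.savetxt(mo_path, np.zeros((tc.n_timepoints, 6)), fmt="%.1f")
        rows.append(
            dict(
                subject_id=tc.subject_id,
                group=truth.subject_group[tc.subject_id],
                timecourse=tc_path.name,
                motion=mo_path.name,
            )
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    dio.write_truth(out / "truth.tsv", truth)
    dio.scenario_to_yaml(out / "scenario.yaml", scenario)
    return manifest


def sweep_edge_tests(
    series,
    groups: dict,
    k_range,
    case_group: str,
    control_group: str,
    n_replicates: int = 150,
    seed: int = 0,
    alpha: float = 0.001,
    reliability_min_windows: int = 10,
) -> list:
    """Edge-wise group tests for every reliable state across a k sweep.

    Returns one list of :class:`~dfcstates.stats.EdgeTest` per (k, state)
    test, ready for :func:`~dfcstates.stats.aggregate_edges`. This is the
    in-memory core of the pipeline's edge analysis, reusable without file
    I/O (e.g. for null-calibration studies).
    """
    ss = np.random.SeedSequence(seed)
    edge_lists = []
    by_subject = {s.subject_id: s for s in series}
    for k, child in zip(k_range, ss.spawn(len(list(k_range)))):
        k_seed = int(child.generate_state(1)[0] % (2**31))
        model = cluster_states(series, k, n_replicates=n_replicates, seed=k_seed)
        rel = reliability_filter(model, groups, reliability_min_windows)
        for state in reliable_state_ids(rel):
            medoids = {}
            for sid, s in by_subject.items():
                labels = model.assignments[sid]
                if (labels == state).any():
                    medoids[sid] = subject_state_medoid(s, labels, state)
            n_case = sum(1 for s in medoids if groups[s] == case_group)
            n_ctrl = sum(1 for s in medoids if groups[s] == control_group)
            if n_case >= 2 and n_ctrl >= 2:
                edge_lists.append(
                    edgewise_state_test(
                        medoids, groups, case_group, control_group, alpha
                    )
                )
    return edge_lists


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full analysis described by ``config`` and write all tables.

    Subjects whose time-course length disagrees with the rest are excluded
    with a logged reason; fewer than two subjects per group aborts.
    """
    t_all = time.perf_counter()
    stage_seconds: dict[str, float] = {}
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_dir = Path(config.manifest_path).parent
    manifest = pd.read_csv(config.manifest_path, sep="\t")

    # --- conditioning -----------------------------------------------------
    t0 = time.perf_counter()
    groups: dict[str, str] = {}
    conditioned = []
    for _, row in manifest.iterrows():
        tc = dio.read_timecourse(
            manifest_dir / row["timecourse"],
            tr_seconds=config.tr_seconds,
            subject_id=row["subject_id"],
        )
        motion = None
        if isinstance(row.get("motion"), str) and row["motion"]:
            motion = dio.read_motion(manifest_dir / row["motion"])
        conditioned.append(
            condition(
                tc,
                motion,
                n_drop=config.drop_volumes,
                cutoff_hz=config.cutoff_hz,
            )
        )
        groups[row["subject_id"]] = row["group"]
    lengths = [tc.n_timepoints for tc in conditioned]
    mode_len = max(set(lengths), key=lengths.count)
    kept = []
    for tc in conditioned:
        if tc.n_timepoints != mode_len:
            log.warning(
                "excluding %s: %d timepoints, expected %d",
                tc.subject_id, tc.n_timepoints, mode_len,
            )
            groups.pop(tc.subject_id)
        else:
            kept.append(tc)
    counts = pd.Series(list(groups.values())).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise RuntimeError(f"need >= 2 subjects in >= 2 groups, have {counts.to_dict()}")
    log.info("conditioned %d subjects (%s)", len(kept), counts.to_dict())
    stage_seconds["conditioning"] = time.perf_counter() - t0

    # --- windowed connectivity -------------------------------------------
    t0 = time.perf_counter()
    taper = make_taper(config.window_width_tr, config.window_gaussian_sigma_tr)
    series = [windowed_correlation(tc, taper) for tc in kept]
    if config.regularize:
        series = [regularize_series(s, config.glasso) for s in series]
    log.info("windows per subject: %d", series[0].n_windows)
    stage_seconds["connectivity"] = time.perf_counter() - t0

    # --- clustering sweep + group statistics ------------------------------
    t0 = time.perf_counter()
    dwell_rows, mdt_rows, comp_rows = [], [], []
    edge_lists = []
    ss = np.random.SeedSequence(config.seed)
    k_seeds = {
        k: int(child.generate_state(1)[0] % (2**31))
        for k, child in zip(config.k_range(), ss.spawn(len(list(config.k_range()))))
    }
    group_names = sorted(set(groups.values()))
    thresholds = {
        g: compute_thresholds(
            np.concatenate(
                [s.matrices for s in series if groups[s.subject_id] == g]
            ),
            group=g,
        )
        for g in group_names
    }
    for k in config.k_range():
        model = cluster_states(
            series, k, n_replicates=config.n_replicates, seed=k_seeds[k]
        )
        records = dwell_records(model)
        rel = reliability_filter(model, groups, config.reliability_min_windows)
        rel_states = reliable_state_ids(rel)
        log.info("k=%d: %d/%d states reliable", k, len(rel_states), k)
        for rec in records:
            dwell_rows.append(
                dict(
                    subject_id=rec.subject_id,
                    group=groups[rec.subject_id],
                    k=k,
                    state=rec.state_id,
                    occupancy=rec.occupancy_windows,
                    mdt=rec.mean_dwell_windows,
                )
            )
        tests = mdt_group_test(
            records, groups, rel_states,
            group_order=(config.case_group, config.control_group),
        )
        for state, res in tests.items():
            mdt_rows.append(
                dict(
                    k=k, state=state, t=res.t_value, p=res.p_value,
                    n_case=res.n1, n_control=res.n2,
                    significant=res.p_value < 0.05,
                )
            )
        by_subject = {s.subject_id: s for s in series}
        for state in rel_states:
            medoids = {}
            for sid, s in by_subject.items():
                labels = model.assignments[sid]
                if (labels == state).any():
                    medoids[sid] = subject_state_medoid(s, labels, state)
            n_case = sum(1 for s in medoids if groups[s] == config.case_group)
            n_ctrl = sum(1 for s in medoids if groups[s] == config.control_group)
            if n_case >= 2 and n_ctrl >= 2:
                edge_lists.append(
                    edgewise_state_test(
                        medoids, groups, config.case_group,
                        config.control_group, config.edge_alpha,
                    )
                )
            for g in group_names:
                if config.composition_source == "centroids":
                    mats = model.centroids[state - 1][None]
                else:
                    member = [
                        s.matrices[model.assignments[sid] == state]
                        for sid, s in by_subject.items()
                        if groups[sid] == g
                    ]
                    mats = np.concatenate([m for m in member if m.size], axis=0)
                prof = composition_profile(mats, thresholds[g], k=k, state_id=state)
                comp_rows.append(asdict(prof))
    stage_seconds["clustering_stats"] = time.perf_counter() - t0

    # --- aggregation + outputs -------------------------------------------
    t0 = time.perf_counter()
    findings = aggregate_edges(edge_lists, min_count=config.min_recurrence)
    region_ids = series[0].region_ids
    outputs = {
        "dwell_records.tsv": pd.DataFrame(dwell_rows),
        "mdt_tests.tsv": pd.DataFrame(mdt_rows),
        "composition.tsv": pd.DataFrame(comp_rows),
        "edge_findings.tsv": pd.DataFrame(
            [
                dict(
                    region_i=region_ids[f.region_pair[0]],
                    region_j=region_ids[f.region_pair[1]],
                    recurrence=f.recurrence_count,
                    direction=f.direction,
                )
                for f in findings
            ],
            columns=["region_i", "region_j", "recurrence", "direction"],
        ),
    }
    checksums = {}
    for name, df in outputs.items():
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        checksums[name] = _sha256(path)
    summary = {
        "n_subjects": int(len(kept)),
        "group_counts": {g: int(counts[g]) for g in counts.index},
        "n_windows": int(series[0].n_windows),
        "thresholds": {
            g: {"mean_abs": th.mean_abs, "sd_abs": th.sd_abs,
                "low_cut": th.low_cut, "high_cut": th.high_cut}
            for g, th in thresholds.items()
        },
        "n_edge_findings": len(findings),
        "significant_mdt_states": [
            dict(k=r["k"], state=r["state"], t=r["t"], p=r["p"])
            for r in mdt_rows if r["significant"]
        ],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    checksums["summary.json"] = _sha256(out / "summary.json")
    stage_seconds["aggregation"] = time.perf_counter() - t0
    stage_seconds["total"] = time.perf_counter() - t_all

    cfg = asdict(config)
    cfg["glasso"] = {
        "lambda_grid": list(map(float, config.glasso.lambda_grid)),
        "selection": config.glasso.selection,
        "fixed_lambda": config.glasso.fixed_lambda,
        "convergence_tol": config.glasso.convergence_tol,
        "max_iter": config.glasso.max_iter,
        "max_holdout_windows": config.glasso.max_holdout_windows,
    }
    run_manifest = RunManifest(
        config=cfg,
        version=_package_version(),
        stage_seconds=stage_seconds,
        checksums=checksums,
    )
    (out / "run_manifest.json").write_text(json.dumps(asdict(run_manifest), indent=2))
    return run_manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("dfcstates")
    except PackageNotFoundError:
        return "0.0.0+local"
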