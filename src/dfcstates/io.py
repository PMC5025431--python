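"""Readers and writers for the delimited-text interchange formats.

Time courses travel as timepoints x regions matrices (tab- or
comma-separated, autodetected, optional header row of region ids); motion
parameters as 6-column whitespace/tab text (SPM ``rp_*.txt`` layout);
ground-truth labels as a long TSV (subject_id, timepoint, state_id);
scenarios as YAML.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conditioning import MotionParameters, TimecourseMatrix
from .synthetic import GroundTruth, GroupScenario, StateSpec


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_timecourse(
    path, tr_seconds: float = 2.0, subject_id: str | None = None
) -> TimecourseMatrix:
    """Read a timepoints x regions matrix; a non-numeric first row is
    treated as the header of region ids."""
    path = Path(path)
    text = path.read_text()
    first = text.splitlines()[0]
    sep = _sniff_delimiter(first)
    try:
        [float(x) for x in first.split(sep)]
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(_io.StringIO(text), sep=sep, header=header)
    region_ids = tuple(str(c) for c in df.columns) if header == 0 else None
    return TimecourseMatrix(
        values=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        subject_id=subject_id or path.stem,
        region_ids=region_ids,
    )


def write_timecourse(path, tc: TimecourseMatrix) -> None:
    pd.DataFrame(tc.values, columns=list(tc.region_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_motion(path) -> MotionParameters:
    """Read a 6-column motion-parameter file (whitespace or tab separated)."""
    return MotionParameters(np.loadtxt(path))


def write_motion(path, motion: MotionParameters) -> None:
    np.savetxt(path, motion.values, fmt="%.6e")


def write_truth(path, truth: GroundTruth) -> None:
    rows = []
    for sid, seq in truth.state_sequences.items():
        for t, state in enumerate(seq):
            rows.append((sid, t, int(state)))
    pd.DataFrame(rows, columns=["subject_id", "timepoint", "state_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    sequences = {
        sid: grp.sort_values("timepoint")["state_id"].to_numpy()
        for sid, grp in df.groupby("subject_id")
    }
    groups = {sid: sid.rsplit("_", 1)[0] for sid in sequences}
    return GroundTruth(sequences, groups)


def write_series_h5(path, series) -> None:
    """Write a windowed connectivity series to an HDF5 container with
    datasets ``/matrices``, ``/window_starts`` and ``/lambda``."""
    import h5py

    from .windows import WindowedConnectivitySeries  # noqa: F401 (doc aid)

    with h5py.File(path, "w") as f:
        f.create_dataset("matrices", data=series.matrices, compression="gzip")
        f.create_dataset("window_starts", data=series.window_starts)
        f.create_dataset(
            "lambda",
            data=np.nan if series.lambda_used is None else float(series.lambda_used),
        )
        f.attrs["kind"] = series.kind
        f.attrs["subject_id"] = series.subject_id
        f.attrs["region_ids"] = list(series.region_ids)


def read_series_h5(path):
    """Read back a series written by :func:`write_series_h5`."""
    import h5py

    from .windows import WindowedConnectivitySeries

    with h5py.File(path, "r") as f:
        lam = float(f["lambda"][()])
        return WindowedConnectivitySeries(
            matrices=f["matrices"][:],
            kind=f.attrs["kind"],
            window_starts=f["window_starts"][:],
            subject_id=f.attrs["subject_id"],
            lambda_used=None if np.isnan(lam) else lam,
            region_ids=tuple(f.attrs["region_ids"]),
        )


def series_to_long_tsv(path, series) -> None:
    """Optional long-format TSV: subject, window, region_i, region_j, value
    (upper triangle only)."""
    r = series.n_regions
    iu = np.triu_indices(r, k=1)
    rows = []
    for w in range(series.n_windows):
        vals = series.matrices[w][iu]
        for (i, j, v) in zip(iu[0], iu[1], vals):
            rows.append((series.subject_id, w, series.region_ids[i], series.region_ids[j], v))
    pd.DataFrame(
        rows, columns=["subject", "window", "region_i", "region_j", "value"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def scenario_to_yaml(path, scenario: GroupScenario) -> None:
    doc = {
        "n_subjects": dict(scenario.n_subjects),
        "n_regions": scenario.n_regions,
        "n_timepoints": scenario.n_timepoints,
        "tr_seconds": scenario.tr_seconds,
        "noise_sd": scenario.noise_sd,
        "seed": scenario.seed,
        "transition_matrix": scenario.transition_matrix.tolist(),
        "mean_dwell_windows": {
            g: {int(s): float(v) for s, v in d.items()}
            for g, d in scenario.mean_dwell_windows.items()
        },
        "states": {
            g: [
                {"state_id": spec.state_id, "covariance": spec.covariance.tolist()}
                for spec in specs
            ]
            for g, specs in scenario.states.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def scenario_from_yaml(path) -> GroupScenario:
    doc = yaml.safe_load(Path(path).read_text())
    return GroupScenario(
        n_subjects=doc["n_subjects"],
        states={
            g: tuple(
                StateSpec(s["state_id"], np.asarray(s["covariance"]))
                for s in specs
            )
            for g, specs in doc["states"].items()
        },
        mean_dwell_windows=doc["mean_dwell_windows"],
        transition_matrix=np.asarray(doc["transition_matrix"]),
        n_regions=doc["n_regions"],
        n_timepoints=doc["n_timepoints"],
        tr_seconds=doc["tr_seconds"],
        noise_sd=doc["noise_sd"],
        seed=doc["seed"],
    )
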