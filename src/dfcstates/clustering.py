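"""Connectivity-state estimation by k-means under Manhattan (L1) distance.

All subjects' windowed matrices are pooled and vectorized (upper triangle,
diagonal excluded) and clustered with an L1 k-means: assignment by minimal
L1 distance, centroid update by the element-wise median (the L1-optimal
centroid), best of many random restarts (k-means++-style seeding with L1
distances) by total L1 cost. Centroid matrices are the connectivity states;
per-window assignments give each subject a state sequence from which
occupancy and mean dwell time follow.

State labels are 1-based (1..k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .windows import WindowedConnectivitySeries


def upper_vec(mats: np.ndarray) -> np.ndarray:
    """Vectorize (stacks of) symmetric matrices: upper triangle, no diagonal."""
    mats = np.asarray(mats)
    r = mats.shape[-1]
    iu = np.triu_indices(r, k=1)
    return mats[..., iu[0], iu[1]]


def vec_to_matrix(vec: np.ndarray, n_regions: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`upper_vec` for a single vector."""
    m = np.full((n_regions, n_regions), 0.0)
    iu = np.triu_indices(n_regions, k=1)
    m[iu] = vec
    m = m + m.T
    np.fill_diagonal(m, diagonal)
    return m


@dataclass(frozen=True)
class StateModel:
    """Result of clustering at one k: centroid matrices, per-subject window
    assignments (labels 1..k), and the best replicate's total L1 cost."""

    k: int
    centroids: np.ndarray  # (k, R, R)
    assignments: dict  # subject_id -> int array of labels in 1..k
    total_l1_cost: float
    replicate_seed: int
    n_replicates: int

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate([self.assignments[s] for s in self.assignments])


def _l1_kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seed k centers: first uniform, then with probability proportional to
    the L1 distance to the nearest chosen center."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d = np.abs(X - centers[0]).sum(axis=1)
    for j in range(1, k):
        total = d.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d / total)
        centers[j] = X[idx]
        d = np.minimum(d, np.abs(X - centers[j]).sum(axis=1))
    return centers


def _lloyd_l1(
    X: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    update: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations under L1 distance; returns (labels, centers, cost).

    An empty cluster is re-seeded at the point currently farthest (L1) from
    its assigned centroid. Convergence: assignments unchanged.
    """
    k = centers.shape[0]
    n = X.shape[0]
    prev = None
    for _ in range(max_iter):
        D = cdist(X, centers, metric="cityblock")
        labels = D.argmin(axis=1)
        for j in range(k):
            if not (labels == j).any():
                far = D[np.arange(n), labels].argmax()
                centers[j] = X[far]
                labels[far] = j
        if prev is not None and np.array_equal(labels, prev):
            break
        prev = labels.copy()
        for j in range(k):
            members = X[labels == j]
            centers[j] = (
                np.median(members, axis=0) if update == "median" else members.mean(axis=0)
            )
    D = cdist(X, centers, metric="cityblock")
    labels = D.argmin(axis=1)
    cost = float(D[np.arange(n), labels].sum())
    return labels, centers, cost


def cluster_states(
    all_series: Sequence[WindowedConnectivitySeries],
    k: int,
    n_replicates: int = 150,
    seed: int = 0,
    max_iter: int = 300,
    centroid_update: str = "median",
) -> StateModel:
    """Cluster all subjects' windowed matrices into ``k`` states.

    Parameters
    ----------
    all_series : sequence of WindowedConnectivitySeries
        One per subject; all must share the region count.
    k : int
        Number of states (>= 2).
    n_replicates : int
        Random restarts; the replicate with smallest total L1 cost wins.
    seed : int
        Seeds the replicate stream; results are deterministic given it.
    centroid_update : {"median", "mean"}
        "median" is the L1-optimal centroid; "mean" probes sensitivity to
        the update rule while keeping L1 assignment.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if centroid_update not in ("median", "mean"):
        raise ValueError("centroid_update must be 'median' or 'mean'")
    region_counts = {s.n_regions for s in all_series}
    if len(region_counts) != 1:
        raise ValueError("all series must share the region count")
    X = np.concatenate([upper_vec(s.matrices) for s in all_series], axis=0)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the total number of windows {X.shape[0]}")

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        centers = _l1_kmeanspp_init(X, k, rng)
        labels, centers, cost = _lloyd_l1(X, centers.copy(), max_iter, centroid_update)
        if best is None or cost < best[2]:
            best = (labels, centers, cost)
    labels, centers, cost = best

    n_regions = all_series[0].n_regions
    # centroid matrices: element-wise median (or mean) over member matrices,
    # consistent with the vector-space update including the diagonal
    reducer = np.median if centroid_update == "median" else np.mean
    mats = np.concatenate([s.matrices for s in all_series], axis=0)
    centroid_mats = np.stack(
        [reducer(mats[labels == j], axis=0) for j in range(k)]
    )

    assignments = {}
    pos = 0
    for s in all_series:
        assignments[s.subject_id] = labels[pos : pos + s.n_windows] + 1
        pos += s.n_windows
    return StateModel(
        k=k,
        centroids=centroid_mats,
        assignments=assignments,
        total_l1_cost=cost,
        replicate_seed=seed,
        n_replicates=n_replicates,
    )


def cluster_number_diagnostics(
    all_series: Sequence[WindowedConnectivitySeries],
    k_range: Iterable[int],
    seed: int = 0,
    n_replicates: int = 10,
    n_reference: int = 20,
) -> pd.DataFrame:
    """Elbow cost, Calinski-Harabasz index (L1) and gap statistic per k.

    The gap statistic compares ``log`` of the within-cluster L1 cost with
    its mean over ``n_reference`` uniform draws from the data's bounding
    box. These diagnostics describe the k sweep; the pipeline never
    auto-selects k from them.
    """
    all_series = list(all_series)
    X = np.concatenate([upper_vec(s.matrices) for s in all_series], axis=0)
    n = X.shape[0]
    lo, hi = X.min(axis=0), X.max(axis=0)
    overall = np.median(X, axis=0)
    ss = np.random.SeedSequence(seed)
    rows = []
    for k in k_range:
        model = cluster_states(all_series, k, n_replicates=n_replicates, seed=seed + k)
        W = model.total_l1_cost
        labels = model.pooled_labels()
        B = 0.0
        for j in range(1, k + 1):
            nj = int((labels == j).sum())
            B += nj * np.abs(
                upper_vec(model.centroids[j - 1]) - overall
            ).sum()
        ch = (B / (k - 1)) / (W / (n - k)) if W > 0 and n > k else np.inf
        ref_costs = []
        for child in ss.spawn(n_reference):
            rng = np.random.default_rng(child)
            ref = rng.uniform(lo, hi, size=X.shape)
            centers = _l1_kmeanspp_init(ref, k, rng)
            _, _, cost = _lloyd_l1(ref, centers, 100, "median")
            ref_costs.append(cost)
        gap = float(np.mean(np.log(ref_costs)) - np.log(W)) if W > 0 else np.inf
        rows.append(
            dict(k=k, elbow_cost=W, calinski_harabasz=ch, gap_statistic=gap)
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DwellRecord:
    """Occupancy and mean dwell time of one subject in one state.

    ``mean_dwell_windows`` is the average length (in windows) of maximal
    consecutive runs of the state; ``None`` when the subject never visits
    the state.
    """

    subject_id: str
    state_id: int
    occupancy_windows: int
    mean_dwell_windows: float | None


def run_lengths(labels: np.ndarray, state_id: int) -> list[int]:
    """Lengths of maximal consecutive runs of ``state_id`` in a sequence."""
    labels = np.asarray(labels)
    runs = []
    count = 0
    for v in labels:
        if v == state_id:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def mean_dwell_time(
    labels: np.ndarray, state_id: int, subject_id: str = "subject"
) -> DwellRecord:
    """Mean dwell time (in windows) of one subject in one state."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("assignment sequence is empty")
    runs = run_lengths(labels, state_id)
    occ = int(sum(runs))
    mdt = float(np.mean(runs)) if runs else None
    return DwellRecord(subject_id, state_id, occ, mdt)


def estimate_mean_dwell(labels: np.ndarray, state_id: int) -> float | None:
    """Censoring-aware estimate of the underlying mean dwell time.

    Runs truncated by the end of the sequence are right-censored; for a
    memoryless (geometric) dwell process the maximum-likelihood estimate of
    the mean is total occupancy divided by the number of observed exits
    from the state. Use this to recover a configured generator dwell;
    :func:`mean_dwell_time` remains the descriptive statistic used in the
    group tests. Returns None when the state never occurs; when it occurs
    but never exits, the (lower-bound) occupancy is returned.
    """
    labels = np.asarray(labels)
    in_state = labels == state_id
    occ = int(in_state.sum())
    if occ == 0:
        return None
    exits = int((in_state[:-1] & ~in_state[1:]).sum())
    return float(occ) / exits if exits else float(occ)


def dwell_records(model: StateModel) -> list[DwellRecord]:
    """All (subject, state) dwell records for a state model."""
    out = []
    for subject_id, labels in model.assignments.items():
        for state in range(1, model.k + 1):
            out.append(mean_dwell_time(labels, state, subject_id))
    return out


@dataclass(frozen=True)
class StateReliability:
    """Window coverage of one state in one group; a state is reliable for a
    group when it covers at least ``min_windows`` windows there."""

    state_id: int
    group: str
    covered_windows: int
    reliable: bool


def reliability_filter(
    model: StateModel, groups: Mapping[str, str], min_windows: int = 10
) -> list[StateReliability]:
    """Per (state, group) coverage records. A state enters group statistics
    only when reliable in every group (see :func:`reliable_state_ids`)."""
    missing = set(model.assignments) - set(groups)
    if missing:
        raise ValueError(f"no group label for subjects: {sorted(missing)}")
    group_names = sorted(set(groups[s] for s in model.assignments))
    out = []
    for state in range(1, model.k + 1):
        for g in group_names:
            covered = int(
                sum(
                    (model.assignments[s] == state).sum()
                    for s in model.assignments
                    if groups[s] == g
                )
            )
            out.append(
                StateReliability(state, g, covered, covered >= min_windows)
            )
    return out


def reliable_state_ids(reliability: Iterable[StateReliability]) -> list[int]:
    """States reliable in every group (AND across groups)."""
    by_state: dict[int, list[bool]] = {}
    for rec in reliability:
        by_state.setdefault(rec.state_id, []).append(rec.reliable)
    return sorted(s for s, flags in by_state.items() if all(flags))


def subject_state_medoid(
    series: WindowedConnectivitySeries, labels: np.ndarray, state_id: int
) -> np.ndarray:
    """The subject's "median" matrix for a state: among the subject's
    windows assigned to the state, the matrix minimizing total L1 distance
    to the others (the L1 medoid). Ties break to the earliest window."""
    labels = np.asarray(labels)
    if labels.size != series.n_windows:
        raise ValueError("labels must match the series' window count")
    members = series.matrices[labels == state_id]
    if members.shape[0] == 0:
        raise ValueError(
            f"subject {series.subject_id!r} has no windows in state {state_id}"
        )
    if members.shape[0] == 1:
        return members[0].copy()
    V = upper_vec(members)
    D = cdist(V, V, metric="cityblock")
    idx = int(D.sum(axis=1).argmin())  # argmin returns the earliest tie
    return members[idx].copy()
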