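"""Synthetic switching-covariance time series with known ground truth.

Emulates the data-generating assumptions behind a connectivity-state
analysis: each subject's multivariate signal is zero-mean Gaussian whose
covariance switches among a small set of latent states via a semi-Markov
process — run lengths are geometric (so the mean dwell time is the single
dwell parameter, with a closed-form target) and the next state is drawn
from a zero-diagonal row-stochastic transition matrix. Group differences
enter through per-group dwell means and per-group state covariances (a
designated state may carry a larger fraction of weak edges in the
case-like group).

State covariances are built as block-diagonal elevated correlations on top
of the identity — disjoint equicorrelated blocks are positive definite by
construction — mimicking subnetwork structure without copying real data.
No hemodynamic convolution is applied: the pipeline operates on
already-extracted component time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conditioning import TimecourseMatrix


@dataclass(frozen=True)
class StateSpec:
    """One latent connectivity state: an id and its covariance matrix
    (correlation-scale: unit diagonal, symmetric positive definite)."""

    state_id: int
    covariance: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", c)

    def validate(self, correlation_scale: bool = True) -> None:
        c = self.covariance
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"state {self.state_id}: covariance must be square")
        if np.max(np.abs(c - c.T)) > 1e-10:
            raise ValueError(f"state {self.state_id}: covariance not symmetric")
        if np.linalg.eigvalsh(c)[0] <= 0:
            raise ValueError(
                f"state {self.state_id}: covariance not positive definite"
            )
        if correlation_scale and np.max(np.abs(np.diag(c) - 1.0)) > 1e-10:
            raise ValueError(f"state {self.state_id}: diagonal must be 1")


@dataclass(frozen=True)
class GroupScenario:
    """Full specification of a two-group (or single-group) simulation.

    ``states`` maps each group to its ordered state specs (state ids shared
    across groups); ``mean_dwell_windows`` maps group -> state_id -> target
    mean run length in windows (the window slides one TR per step, so one
    window equals one timepoint of dwell). ``transition_matrix`` is shared,
    row-stochastic with zero diagonal (dwell is handled by run-length
    draws, not self-transitions).
    """

    n_subjects: Mapping[str, int]
    states: Mapping[str, Sequence[StateSpec]]
    mean_dwell_windows: Mapping[str, Mapping[int, float]]
    transition_matrix: np.ndarray
    n_regions: int = 54
    n_timepoints: int = 170
    tr_seconds: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "transition_matrix", np.asarray(self.transition_matrix, dtype=float)
        )

    @property
    def groups(self) -> list[str]:
        return list(self.n_subjects)

    @property
    def k_states(self) -> int:
        return len(next(iter(self.states.values())))

    def state_ids(self) -> list[int]:
        return [s.state_id for s in next(iter(self.states.values()))]

    def validate(self) -> None:
        k = self.k_states
        T = self.transition_matrix
        if T.shape != (k, k):
            raise ValueError("transition_matrix shape must be (k, k)")
        if np.max(np.abs(np.diag(T))) > 1e-10:
            raise ValueError("transition_matrix diagonal must be zero")
        if k > 1 and np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("transition_matrix rows must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for g in self.groups:
            if len(self.states[g]) != k:
                raise ValueError("every group needs the same number of states")
            for spec in self.states[g]:
                spec.validate()
                if spec.covariance.shape[0] != self.n_regions:
                    raise ValueError(
                        f"state {spec.state_id}: covariance size != n_regions"
                    )
            for sid in self.state_ids():
                dwell = self.mean_dwell_windows[g].get(sid)
                if dwell is None or dwell <= 0:
                    raise ValueError(
                        f"mean_dwell_windows must be > 0 for group {g}, state {sid}"
                    )


@dataclass(frozen=True)
class GroundTruth:
    """Latent state id per timepoint per subject, plus group labels."""

    state_sequences: dict  # subject_id -> int array (n_timepoints,)
    subject_group: dict  # subject_id -> group label


def _simulate_sequence(
    state_ids: Sequence[int],
    mean_dwell: Mapping[int, float],
    transition: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Semi-Markov state sequence: geometric run lengths (support 1, 2, ...)
    with the given per-state mean, transitions from the embedded chain."""
    k = len(state_ids)
    seq = np.empty(n_timepoints, dtype=int)
    pos = 0
    current = int(rng.integers(k))
    while pos < n_timepoints:
        sid = state_ids[current]
        run = int(rng.geometric(1.0 / mean_dwell[sid]))
        end = min(pos + run, n_timepoints)
        seq[pos:end] = sid
        pos = end
        if k > 1:
            current = int(rng.choice(k, p=transition[current]))
    return seq


def generate_state_sequences(
    scenario: GroupScenario,
) -> tuple[dict, dict]:
    """Ground-truth state sequences only (no signals) — cheap Monte-Carlo
    of dwell behavior. Deterministic under the scenario seed; subjects are
    independent streams."""
    scenario.validate()
    state_ids = scenario.state_ids()
    ss = np.random.SeedSequence(scenario.seed)
    total = sum(scenario.n_subjects.values())
    children = iter(ss.spawn(total))
    sequences, subject_group = {}, {}
    for g in scenario.groups:
        for i in range(scenario.n_subjects[g]):
            rng = np.random.default_rng(next(children))
            sid = f"{g}_{i:03d}"
            sequences[sid] = _simulate_sequence(
                state_ids,
                scenario.mean_dwell_windows[g],
                scenario.transition_matrix,
                scenario.n_timepoints,
                rng,
            )
            subject_group[sid] = g
    return sequences, subject_group


def generate_dataset(
    scenario: GroupScenario,
) -> tuple[list[TimecourseMatrix], GroundTruth]:
    """Simulate every subject's signal.

    At timepoint t the signal is N(0, Sigma_state) plus isotropic noise of
    variance ``noise_sd**2``. Bit-identical under a fixed seed (the signal
    stream reuses the same per-subject seed stream as the sequences, so
    truth and signals stay paired).
    """
    scenario.validate()
    state_ids = scenario.state_ids()
    chol = {
        g: {
            spec.state_id: np.linalg.cholesky(spec.covariance)
            for spec in scenario.states[g]
        }
        for g in scenario.groups
    }
    ss = np.random.SeedSequence(scenario.seed)
    total = sum(scenario.n_subjects.values())
    children = iter(ss.spawn(total))
    timecourses, sequences, subject_group = [], {}, {}
    region_ids = tuple(f"r{i}" for i in range(scenario.n_regions))
    for g in scenario.groups:
        for i in range(scenario.n_subjects[g]):
            rng = np.random.default_rng(next(children))
            sid = f"{g}_{i:03d}"
            seq = _simulate_sequence(
                state_ids,
                scenario.mean_dwell_windows[g],
                scenario.transition_matrix,
                scenario.n_timepoints,
                rng,
            )
            z = rng.standard_normal((scenario.n_timepoints, scenario.n_regions))
            x = np.empty_like(z)
            for sid_state in state_ids:
                mask = seq == sid_state
                if mask.any():
                    x[mask] = z[mask] @ chol[g][sid_state].T
            if scenario.noise_sd > 0:
                x += scenario.noise_sd * rng.standard_normal(x.shape)
            timecourses.append(
                TimecourseMatrix(
                    values=x,
                    tr_seconds=scenario.tr_seconds,
                    subject_id=sid,
                    region_ids=region_ids,
                )
            )
            sequences[sid] = seq
            subject_group[sid] = g
    return timecourses, GroundTruth(sequences, subject_group)


def _block_state_covariance(
    n_regions: int,
    block_size: int,
    active_blocks: Sequence[int],
    rho: float,
    perm: np.ndarray,
) -> np.ndarray:
    """Correlation matrix with equicorrelated blocks of strength ``rho`` on
    a permuted region order; identity elsewhere. PD whenever 0 <= rho < 1."""
    c = np.eye(n_regions)
    n_blocks = n_regions // block_size
    for b in active_blocks:
        members = perm[b * block_size : (b + 1) * block_size]
        if b == n_blocks - 1:  # last block absorbs the remainder
            members = perm[b * block_size :]
        for a in members:
            for d in members:
                if a != d:
                    c[a, d] = rho
    return c


def make_paper_like_scenario(
    k_states: int = 3,
    weak_fraction_shift: float = 0.0,
    dwell_ratio: float = 1.0,
    seed: int = 0,
    n_regions: int = 54,
    n_timepoints: int = 170,
    n_subjects: tuple[int, int] = (44, 31),
    group_names: tuple[str, str] = ("td_like", "asd_like"),
    base_dwell_windows: float = 40.0,
    block_corr: float = 0.6,
    weak_corr: float = 0.02,
    noise_sd: float = 0.2,
    designated_state: int = 1,
) -> GroupScenario:
    """Two-group scenario encoding the study's qualitative effects.

    Each state elevates correlation (``block_corr``) inside half of the
    subnetwork-like blocks of a state-specific random region permutation.
    In the case-like group the designated state has (a) a fraction
    ``weak_fraction_shift`` of its active blocks demoted to near-zero
    correlation (``weak_corr``), raising its weak-edge fraction, and
    (b) its mean dwell multiplied by ``dwell_ratio``. With
    ``weak_fraction_shift=0`` and ``dwell_ratio=1`` the groups are
    stochastically identical.

    Group sizes default to 44 and 31; dwell defaults to 40 windows per
    state (the order of magnitude sliding-window state analyses report).
    """
    if k_states < 1:
        raise ValueError("k_states must be >= 1")
    if dwell_ratio <= 0:
        raise ValueError("dwell_ratio must be positive")
    if not 0 <= weak_fraction_shift <= 1:
        raise ValueError("weak_fraction_shift must lie in [0, 1]")
    block_size = max(2, n_regions // 9)
    n_blocks = n_regions // block_size
    if n_blocks < 2 or k_states > 2 ** (n_blocks - 1):
        raise ValueError(
            f"n_regions={n_regions} cannot support {k_states} distinct block states"
        )
    rng = np.random.default_rng(seed)
    n_active = max(1, n_blocks // 2)
    control, case = group_names
    control_states, case_states = [], []
    for s in range(1, k_states + 1):
        perm = rng.permutation(n_regions)
        active = list(rng.choice(n_blocks, size=n_active, replace=False))
        cov = _block_state_covariance(n_regions, block_size, active, block_corr, perm)
        control_states.append(StateSpec(s, cov))
        if s == designated_state and weak_fraction_shift > 0:
            n_demote = int(round(weak_fraction_shift * n_active))
            strong, demoted = active[n_demote:], active[:n_demote]
            # off-diagonal supports of disjoint block sets do not overlap
            cov_case = (
                np.eye(n_regions)
                + _block_state_covariance(n_regions, block_size, strong, block_corr, perm)
                - np.eye(n_regions)
                + _block_state_covariance(n_regions, block_size, demoted, weak_corr, perm)
                - np.eye(n_regions)
            )
            case_states.append(StateSpec(s, cov_case))
        else:
            case_states.append(StateSpec(s, cov))
    dwell_control = {s: float(base_dwell_windows) for s in range(1, k_states + 1)}
    dwell_case = dict(dwell_control)
    dwell_case[designated_state] = float(base_dwell_windows) * float(dwell_ratio)
    if k_states == 1:
        T = np.zeros((1, 1))
    else:
        T = (np.ones((k_states, k_states)) - np.eye(k_states)) / (k_states - 1)
    scenario = GroupScenario(
        n_subjects={control: n_subjects[0], case: n_subjects[1]},
        states={control: tuple(control_states), case: tuple(case_states)},
        mean_dwell_windows={control: dwell_control, case: dwell_case},
        transition_matrix=T,
        n_regions=n_regions,
        n_timepoints=n_timepoints,
        noise_sd=noise_sd,
        seed=seed,
    )
    scenario.validate()
    return scenario


def window_truth_labels(sequence: np.ndarray, width_tr: int) -> np.ndarray:
    """Ground-truth label per sliding window: the state active at the
    window's center timepoint.

    For even widths the center falls between two samples; the lower one,
    ``start + (width_tr - 1) // 2``, is used because it is the convention
    consistent with the symmetric taper's center of mass: the window's
    weighted state mixture and the center label then switch at the same
    offset when the sequence changes state.
    """
    sequence = np.asarray(sequence)
    n_w = sequence.size - width_tr
    if n_w <= 0:
        raise ValueError("sequence shorter than one window")
    centers = np.arange(n_w) + (width_tr - 1) // 2
    return sequence[centers]
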