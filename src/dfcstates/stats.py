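"""Group-level statistics on dwell times, state medoids and strength levels.

Two-sample comparisons use the pooled-variance Student t-test (df =
n1 + n2 - 2, two-sided p), which also reproduces printed demographic
p-values from (n, mean, SD) summaries. Edge-level differences between
groups are tested on per-subject state medoid matrices at a strict
uncorrected threshold and then aggregated across the k sweep: an edge
counts as a finding only when it recurs in at least ``min_count``
(k, state) tests. Connectivity strength is discretized into three levels
by each group's pooled mean +/- SD of absolute strengths: level 1 ("weak")
below mean - SD, level 3 ("strong") above mean + SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .clustering import DwellRecord, StateModel, upper_vec


@dataclass(frozen=True)
class TwoSampleTestResult:
    t_value: float
    p_value: float
    df: float
    n1: int
    n2: int
    direction: str  # group1_higher | group2_higher | none

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05


def _pooled_t(n1, m1, s1, n2, m2, s2) -> TwoSampleTestResult:
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0.0:
        if m1 == m2:
            return TwoSampleTestResult(0.0, 1.0, df, n1, n2, "none")
        raise ValueError("zero pooled variance with unequal means")
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    direction = "none" if t == 0 else ("group1_higher" if t > 0 else "group2_higher")
    return TwoSampleTestResult(float(t), float(p), float(df), int(n1), int(n2), direction)


def two_sample_t(
    group1=None,
    group2=None,
    *,
    summary1: tuple | None = None,
    summary2: tuple | None = None,
) -> TwoSampleTestResult:
    """Pooled-variance two-sample t-test from raw samples or (n, mean, sd)
    summaries.

    Examples
    --------
    >>> r = two_sample_t(summary1=(44, 12.46, 3.1), summary2=(31, 11.51, 2.64))
    >>> round(r.p_value, 4)
    0.1693
    """
    if summary1 is not None or summary2 is not None:
        if summary1 is None or summary2 is None:
            raise ValueError("provide both summaries or both sample arrays")
        n1, m1, s1 = summary1
        n2, m2, s2 = summary2
    else:
        a = np.asarray(group1, dtype=float)
        b = np.asarray(group2, dtype=float)
        n1, m1, s1 = len(a), a.mean(), a.std(ddof=1)
        n2, m2, s2 = len(b), b.mean(), b.std(ddof=1)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    return _pooled_t(n1, m1, s1, n2, m2, s2)


def mdt_group_test(
    records: Iterable[DwellRecord],
    groups: Mapping[str, str],
    reliable_states: Sequence[int],
    group_order: Sequence[str] | None = None,
) -> dict[int, TwoSampleTestResult]:
    """Two-sample t-test of mean dwell times per reliable state.

    Subjects that never occupy a state are excluded from that state's test;
    a state with fewer than two remaining subjects in either group is
    skipped with a warning. ``group_order`` fixes which group is "group 1"
    (sign convention of t); default is sorted label order.
    """
    by_state: dict[int, dict[str, list[float]]] = {}
    for rec in records:
        if rec.mean_dwell_windows is None:
            continue
        g = groups[rec.subject_id]
        by_state.setdefault(rec.state_id, {}).setdefault(g, []).append(
            rec.mean_dwell_windows
        )
    if group_order is None:
        group_order = sorted({groups[s] for s in groups})
    if len(group_order) != 2:
        raise ValueError("exactly two groups are required")
    g1, g2 = group_order
    out: dict[int, TwoSampleTestResult] = {}
    for state in reliable_states:
        samples = by_state.get(state, {})
        a, b = samples.get(g1, []), samples.get(g2, [])
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"state {state}: fewer than 2 occupying subjects in a group; skipped"
            )
            continue
        out[state] = two_sample_t(a, b)
    return out


@dataclass(frozen=True)
class EdgeTest:
    """One edge's group test within one (k, state) comparison."""

    region_pair: tuple  # (i, j) with i < j (region indices)
    t_value: float
    p_value: float
    direction: str  # increase | decrease (case vs control)


def edgewise_state_test(
    medoids: Mapping[str, np.ndarray],
    groups: Mapping[str, str],
    case_group: str,
    control_group: str,
    alpha: float = 0.001,
) -> list[EdgeTest]:
    """Edge-wise pooled t-tests on per-subject state medoid matrices.

    ``medoids`` maps subject -> medoid matrix for one state (subjects
    occupying the state only). Returns the edges with p < ``alpha``
    (all non-degenerate edges when alpha >= 1); an edge constant across
    all subjects is skipped. Direction is "increase" when the case-group
    mean exceeds the control-group mean.
    """
    case = [medoids[s] for s in medoids if groups[s] == case_group]
    ctrl = [medoids[s] for s in medoids if groups[s] == control_group]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least two subjects per group")
    A = upper_vec(np.stack(case))  # (n_case, n_edges)
    B = upper_vec(np.stack(ctrl))
    n1, n2 = A.shape[0], B.shape[0]
    df = n1 + n2 - 2
    m1, m2 = A.mean(axis=0), B.mean(axis=0)
    v1, v2 = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    ok = sp2 > 0
    t = np.zeros_like(m1)
    t[ok] = (m1[ok] - m2[ok]) / np.sqrt(sp2[ok] * (1.0 / n1 + 1.0 / n2))
    p = np.ones_like(m1)
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df)
    r = np.stack(case)[0].shape[0]
    iu = np.triu_indices(r, k=1)
    out = []
    for e in np.nonzero(ok & ((p < alpha) | (alpha >= 1.0)))[0]:
        out.append(
            EdgeTest(
                region_pair=(int(iu[0][e]), int(iu[1][e])),
                t_value=float(t[e]),
                p_value=float(p[e]),
                direction="increase" if m1[e] > m2[e] else "decrease",
            )
        )
    return out


@dataclass(frozen=True)
class EdgeFinding:
    """An edge recurring across the k sweep, with its recurrence count and
    majority direction."""

    region_pair: tuple
    recurrence_count: int
    direction: str


def aggregate_edges(
    edge_lists: Iterable[Sequence[EdgeTest]], min_count: int = 5
) -> list[EdgeFinding]:
    """Aggregate per-(k, state) significant edges across the whole sweep.

    ``recurrence_count`` is the number of (k, state) tests in which the
    edge was significant; only edges with count >= ``min_count`` are kept.
    Direction is by majority over tests; a tie goes to the direction of the
    largest \\|t\\|. Output is sorted by decreasing count then pair.
    """
    hits: dict[tuple, list[EdgeTest]] = {}
    for tests in edge_lists:
        for et in tests:
            i, j = et.region_pair
            pair = (min(i, j), max(i, j))
            hits.setdefault(pair, []).append(et)
    findings = []
    for pair, tests in hits.items():
        if len(tests) < min_count:
            continue
        n_inc = sum(1 for t in tests if t.direction == "increase")
        n_dec = len(tests) - n_inc
        if n_inc != n_dec:
            direction = "increase" if n_inc > n_dec else "decrease"
        else:
            direction = max(tests, key=lambda t: abs(t.t_value)).direction
        findings.append(EdgeFinding(pair, len(tests), direction))
    return sorted(findings, key=lambda f: (-f.recurrence_count, f.region_pair))


@dataclass(frozen=True)
class StrengthThresholds:
    """Three-level discretization cutpoints for one group: mean +/- SD of
    pooled absolute off-diagonal connectivity strengths."""

    group: str
    mean_abs: float
    sd_abs: float

    @property
    def low_cut(self) -> float:
        return self.mean_abs - self.sd_abs

    @property
    def high_cut(self) -> float:
        return self.mean_abs + self.sd_abs


def compute_thresholds(
    matrices: np.ndarray | Sequence[np.ndarray], group: str = "group"
) -> StrengthThresholds:
    """Mean and SD of pooled absolute off-diagonal entries of a group's
    matrices (each off-diagonal pair counted once)."""
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    if mats.size == 0:
        raise ValueError("empty matrix set")
    v = np.abs(upper_vec(mats)).ravel()
    mean, sd = float(v.mean()), float(v.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):
        raise ValueError("degenerate thresholds: zero spread of strengths")
    return StrengthThresholds(group, mean, sd)


@dataclass(frozen=True)
class CompositionProfile:
    """Fractions of weak (level 1), intermediate (level 2) and strong
    (level 3) absolute connectivity in one state for one group."""

    k: int
    state_id: int
    group: str
    pct_level1: float
    pct_level2: float
    pct_level3: float


def composition_profile(
    matrices: np.ndarray | Sequence[np.ndarray],
    thresholds: StrengthThresholds,
    k: int = 0,
    state_id: int = 0,
) -> CompositionProfile:
    """Strength composition of a state's matrices under a group's cutpoints.

    Entries exactly at a cutpoint belong to the lower level (closed-below):
    level 1 is \\|v\\| <= low_cut, level 3 is \\|v\\| > high_cut.
    """
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    v = np.abs(upper_vec(mats)).ravel()
    if v.size == 0:
        raise ValueError("empty matrix set")
    p1 = float((v <= thresholds.low_cut).mean())
    p3 = float((v > thresholds.high_cut).mean())
    p2 = 1.0 - p1 - p3
    return CompositionProfile(k, state_id, thresholds.group, p1, p2, p3)
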