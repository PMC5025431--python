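"""Two-sample tests, edge-wise comparisons and aggregation, and
connectivity-strength discretization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dfcstates as d
from dfcstates.stats import EdgeTest


class TestTwoSampleT:
    def test_raw_samples_match_summary_formula(self, rng):
        a = rng.standard_normal(20) + 0.3
        b = rng.standard_normal(25)
        r1 = d.two_sample_t(a, b)
        r2 = d.two_sample_t(
            summary1=(20, a.mean(), a.std(ddof=1)),
            summary2=(25, b.mean(), b.std(ddof=1)),
        )
        assert r1.t_value == pytest.approx(r2.t_value, abs=1e-10)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)
        assert r1.df == 43

    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0]
        r = d.two_sample_t(x, x)
        assert r.t_value == 0.0
        assert r.p_value == 1.0
        assert r.direction == "none"

    def test_zero_variance_equal_means(self):
        r = d.two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert (r.t_value, r.p_value) == (0.0, 1.0)

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(ValueError):
            d.two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_direction_follows_sign(self):
        r = d.two_sample_t([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert r.t_value > 0 and r.direction == "group1_higher"


class TestMdtGroupTest:
    def _records(self, values_by_subject, state=1):
        return [
            d.DwellRecord(s, state, 10, v) if v is not None
            else d.DwellRecord(s, state, 0, None)
            for s, v in values_by_subject.items()
        ]

    def test_detects_dwell_difference(self, rng):
        vals = {f"a{i}": 20.0 + rng.normal(0, 2) for i in range(20)}
        vals.update({f"b{i}": 10.0 + rng.normal(0, 2) for i in range(20)})
        groups = {s: ("case" if s.startswith("a") else "control") for s in vals}
        res = d.mdt_group_test(
            self._records(vals), groups, [1], group_order=("case", "control")
        )
        assert res[1].p_value < 1e-6 and res[1].t_value > 0

    def test_unoccupied_subjects_excluded_and_state_skipped(self):
        vals = {"a1": 5.0, "a2": None, "a3": None, "b1": 4.0, "b2": 6.0}
        groups = {"a1": "case", "a2": "case", "a3": "case", "b1": "control", "b2": "control"}
        with pytest.warns(UserWarning, match="skipped"):
            res = d.mdt_group_test(
                self._records(vals), groups, [1], group_order=("case", "control")
            )
        assert res == {}


class TestEdgewise:
    def _medoids(self, rng, n_per_group=50, shift=0.0, n_regions=6):
        iu = np.triu_indices(n_regions, k=1)
        medoids, groups = {}, {}
        for g, n in (("case", n_per_group), ("control", n_per_group)):
            for i in range(n):
                m = np.zeros((n_regions, n_regions))
                vals = rng.normal(0, 0.1, size=len(iu[0]))
                if g == "case":
                    vals[0] += shift
                m[iu] = vals
                m = m + m.T
                np.fill_diagonal(m, 1.0)
                sid = f"{g}_{i}"
                medoids[sid] = m
                groups[sid] = g
        return medoids, groups

    def test_shifted_edge_detected(self, rng):
        # 2 pooled-SD shift at one edge, n=50/group: noncentral-t power >> 0.95
        medoids, groups = self._medoids(rng, shift=0.2)
        hits = d.edgewise_state_test(medoids, groups, "case", "control", alpha=0.001)
        assert any(h.region_pair == (0, 1) and h.direction == "increase" for h in hits)

    def test_alpha_one_returns_all_nondegenerate_edges(self, rng):
        medoids, groups = self._medoids(rng, n_per_group=5)
        hits = d.edgewise_state_test(medoids, groups, "case", "control", alpha=1.0)
        assert len(hits) == 15  # all edges of 6 regions

    def test_constant_edge_skipped(self, rng):
        medoids, groups = self._medoids(rng, n_per_group=5)
        for m in medoids.values():
            m[0, 1] = m[1, 0] = 0.5
        hits = d.edgewise_state_test(medoids, groups, "case", "control", alpha=1.0)
        assert all(h.region_pair != (0, 1) for h in hits)

    def test_null_false_positive_rate_matches_alpha(self, rng):
        # identical distributions: expected hits ~ alpha * n_edges
        alpha, n_edges, sims = 0.01, 15, 150
        counts = []
        for _ in range(sims):
            medoids, groups = self._medoids(rng, n_per_group=10)
            counts.append(
                len(d.edgewise_state_test(medoids, groups, "case", "control", alpha))
            )
        expected = alpha * n_edges
        se = np.sqrt(expected / sims)  # Poisson-ish error of the mean
        assert abs(np.mean(counts) - expected) < 5 * se + 0.1


class TestAggregate:
    def _et(self, pair, t, direction):
        return EdgeTest(pair, t, 1e-5, direction)

    def test_recurrent_increase_reported(self):
        lists = [[self._et((3, 8), 4.0, "increase")] for _ in range(10)]
        out = d.aggregate_edges(lists, min_count=5)
        assert out == [d.EdgeFinding((3, 8), 10, "increase")]

    def test_below_min_count_excluded(self):
        lists = [[self._et((1, 2), 4.0, "increase")] for _ in range(4)]
        assert d.aggregate_edges(lists, min_count=5) == []

    def test_empty_input(self):
        assert d.aggregate_edges([]) == []

    def test_order_invariance(self):
        lists = [
            [self._et((1, 2), 4.0, "increase"), self._et((2, 5), -4.0, "decrease")],
            [self._et((2, 5), -3.0, "decrease")],
        ] + [[self._et((1, 2), 3.0, "increase")] for _ in range(5)]
        a = d.aggregate_edges(lists, min_count=2)
        b = d.aggregate_edges(list(reversed(lists)), min_count=2)
        assert a == b

    def test_tie_broken_by_largest_t(self):
        lists = [
            [self._et((0, 1), 2.0, "increase")],
            [self._et((0, 1), -6.0, "decrease")],
        ]
        out = d.aggregate_edges(lists, min_count=2)
        assert out[0].direction == "decrease"


class TestThresholds:
    def test_printed_moments_give_printed_cutpoints(self):
        th = d.StrengthThresholds("td", mean_abs=0.1828, sd_abs=0.1363)
        assert th.low_cut == pytest.approx(0.0465, abs=1e-10)
        assert th.high_cut == pytest.approx(0.3191, abs=1e-10)

    def test_computed_from_matrices(self, rng):
        mats = rng.uniform(-1, 1, size=(20, 6, 6))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        th = d.compute_thresholds(mats, "g")
        iu = np.triu_indices(6, k=1)
        vals = np.abs(mats[:, iu[0], iu[1]]).ravel()
        assert th.mean_abs == pytest.approx(vals.mean())
        assert th.sd_abs == pytest.approx(vals.std(ddof=1))

    def test_constant_entries_degenerate(self):
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            d.compute_thresholds(np.stack([m, m]), "g")

    def test_cutpoints_scale_homogeneously(self, rng):
        mats = rng.uniform(-1, 1, size=(5, 5, 5))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        th1 = d.compute_thresholds(mats, "g")
        th2 = d.compute_thresholds(2.0 * mats, "g")
        assert th2.low_cut == pytest.approx(2 * th1.low_cut)
        assert th2.high_cut == pytest.approx(2 * th1.high_cut)


class TestComposition:
    def test_all_entries_weak(self):
        m = np.eye(4) + 0.01 * (np.ones((4, 4)) - np.eye(4))
        th = d.StrengthThresholds("g", mean_abs=0.2, sd_abs=0.1)
        prof = d.composition_profile(m, th)
        assert (prof.pct_level1, prof.pct_level2, prof.pct_level3) == (1.0, 0.0, 0.0)

    def test_cutpoint_entries_assigned_to_lower_level(self):
        th = d.StrengthThresholds("g", mean_abs=0.2, sd_abs=0.1)
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.1  # exactly low_cut -> level 1
        m[0, 2] = m[2, 0] = 0.3  # exactly high_cut -> level 2
        m[1, 2] = m[2, 1] = 0.31  # just above -> level 3
        prof = d.composition_profile(m, th)
        assert prof.pct_level1 == pytest.approx(1 / 3)
        assert prof.pct_level2 == pytest.approx(1 / 3)
        assert prof.pct_level3 == pytest.approx(1 / 3)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None)
    def test_percentages_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        mats = rng.uniform(-1, 1, size=(3, 5, 5))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        th = d.StrengthThresholds("g", mean_abs=0.4, sd_abs=0.3)
        prof = d.composition_profile(mats, th)
        total = prof.pct_level1 + prof.pct_level2 + prof.pct_level3
        assert total == pytest.approx(1.0, abs=1e-10)
        assert 0 <= prof.pct_level1 <= 1

    def test_seventy_percent_weak_construction(self, rng):
        # deterministic construction: 70% of edges below the weak cut
        n_edges = 45  # 10 regions
        vals = np.empty(n_edges)
        n_weak = int(round(0.7 * n_edges))
        vals[:n_weak] = rng.uniform(0.0, 0.04, size=n_weak)
        vals[n_weak:] = rng.uniform(0.06, 0.25, size=n_edges - n_weak)
        from dfcstates.clustering import vec_to_matrix

        m = vec_to_matrix(vals, 10)
        th = d.StrengthThresholds("g", mean_abs=0.1828, sd_abs=0.1363)
        prof = d.composition_profile(m, th)
        assert 0.65 <= prof.pct_level1 <= 0.75
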