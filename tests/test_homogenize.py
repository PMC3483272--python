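import numpy as np
import pytest

from conftest import make_cohort
from homogwas.contingency import extremeness
from homogwas.homogenize import (
    CohortHomogenizer,
    HomogenizationParams,
    homogenize,
    knock_down_step,
    num_cycles,
    select_extreme_sphere,
    total_weight_after,
)
from homogwas.simulate import StructuredCohortSpec, simulate_cohort
from homogwas.spheres import build_neighbor_index


class TestNumCycles:
    @pytest.mark.parametrize(
        "total,f,w_kd,expected",
        [
            (3986, 0.07, 0.2, 349),  # 348.775 rounds up
            (500, 0.0, 0.2, 0),
            (1000, 0.08, 0.2, 100),  # exact
        ],
    )
    def test_cycle_count(self, total, f, w_kd, expected):
        assert num_cycles(total, f, w_kd) == expected


class TestSelectExtremeSphere:
    def test_inverse_ors_compete_by_extremeness(self):
        assert select_extreme_sphere(np.array([2.0, 0.25, 1.0])) == 1
        assert select_extreme_sphere(np.array([3.0, 1 / 3])) == 0  # tie -> earlier
        assert select_extreme_sphere(np.ones(5)) == 0


class TestKnockDownStep:
    def test_knocks_diseased_in_diseased_heavy_cluster(self):
        # one tight diseased-only cluster + a balanced far-away background
        coords = [[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]]
        diseased = [True, True, True, True, False, False]
        cohort = make_cohort(coords, diseased)
        params = HomogenizationParams(sphere_weight=3.0, knockdown_weight=0.2,
                                      weight_reduction=0.1)
        rec = knock_down_step(cohort, params)
        assert rec.knocked_phenotype == "diseased"
        assert rec.knocked_id in {"s0", "s1", "s2"}
        assert cohort.weights[cohort.index_of(rec.knocked_id)] == 0.2

    def test_no_eligible_signal_when_everyone_knocked(self):
        cohort = make_cohort([[0.0], [1.0], [2.0], [3.0]], [True, True, False, False])
        cohort.weights = np.full(4, 0.2)
        params = HomogenizationParams(sphere_weight=0.5, knockdown_weight=0.2,
                                      weight_reduction=0.1)
        assert knock_down_step(cohort, params) is None

    def test_local_improvement_for_fixed_membership(self, structured_cohort):
        """Knocking the over-represented phenotype pulls the sphere OR toward 1."""
        from homogwas.spheres import all_sphere_tables

        cohort, index = structured_cohort
        work = cohort.copy()
        params = HomogenizationParams(30.0, 0.2, 0.05)
        a, b, c, d, j_end = all_sphere_tables(30.0, work, index)
        ors = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        center = select_extreme_sphere(ors)
        before = extremeness(ors[center])
        rec = knock_down_step(work, params, index)
        # recompute the selected sphere's table over its original members
        members = index.order[center, : j_end[center] + 1]
        w = work.weights[members]
        dis = work.diseased[members]
        a2 = float((w * dis).sum())
        c2 = float((w * ~dis).sum())
        b2 = work.total_diseased_weight - a2
        d2 = work.total_healthy_weight - c2
        after = extremeness(((a2 + 0.5) * (d2 + 0.5)) / ((b2 + 0.5) * (c2 + 0.5)))
        assert rec is not None
        assert after <= before


class TestHomogenize:
    def test_zero_reduction_is_a_no_op(self, structured_cohort):
        cohort, index = structured_cohort
        res = homogenize(cohort, HomogenizationParams(30.0, 0.2, 0.0), index=index)
        assert res.log == []
        assert np.array_equal(res.final_weights, np.ones(cohort.n))

    def test_weight_conservation_and_log_invariants(self, structured_cohort):
        cohort, index = structured_cohort
        params = HomogenizationParams(30.0, 0.2, 0.07)
        res = homogenize(cohort, params, index=index)
        expected_cycles = num_cycles(cohort.total_weight, 0.07, 0.2)
        assert len(res.log) == expected_cycles
        knocked = [r.knocked_id for r in res.log]
        assert len(set(knocked)) == len(knocked)  # nobody knocked twice
        assert res.final_total_weight == pytest.approx(
            cohort.total_weight - expected_cycles * 0.8
        )
        assert np.sum(res.final_weights) == pytest.approx(res.final_total_weight)
        # knocked subjects at exactly w_kd, everyone else untouched
        idx = [cohort.index_of(s) for s in knocked]
        assert np.all(res.final_weights[idx] == 0.2)
        mask = np.ones(cohort.n, bool)
        mask[idx] = False
        assert np.all(res.final_weights[mask] == 1.0)
        # knocked phenotypes recorded faithfully
        for r in res.log:
            assert (r.knocked_phenotype == "diseased") == bool(
                cohort.diseased[cohort.index_of(r.knocked_id)]
            )

    def test_deterministic_logs(self, structured_cohort):
        cohort, index = structured_cohort
        params = HomogenizationParams(30.0, 0.2, 0.04)
        r1 = homogenize(cohort, params, index=index)
        r2 = homogenize(cohort, params, index=index)
        assert r1.log == r2.log
        assert np.array_equal(r1.final_weights, r2.final_weights)

    def test_rejects_sphere_weight_at_or_above_total(self, line_cohort):
        with pytest.raises(ValueError):
            homogenize(line_cohort, HomogenizationParams(4.0, 0.2, 0.1))

    def test_knockdowns_concentrate_in_imbalanced_region(self):
        """Knocked diseased subjects should sit mostly inside the box region.

        Checked at a knee-scale weight reduction: early cycles target the
        genuine box imbalance, while much deeper reduction starts chasing
        local sampling fluctuations spread over the whole cloud.
        """
        spec = StructuredCohortSpec(n_subjects=2000, seed=3)
        cohort = simulate_cohort(spec)
        res = homogenize(cohort, HomogenizationParams(30.0, 0.2, 0.04))
        knocked_dis = [
            cohort.index_of(r.knocked_id)
            for r in res.log
            if r.knocked_phenotype == "diseased"
        ]
        assert len(knocked_dis) > 10
        in_box = spec.box.contains(cohort.coords[knocked_dis])
        assert in_box.mean() >= 0.6


class TestEstimator:
    def test_sklearn_interface_round_trip(self):
        spec = StructuredCohortSpec(n_subjects=300, seed=8)
        cohort = simulate_cohort(spec)
        est = CohortHomogenizer(sphere_weight=20.0, weight_reduction=0.05)
        est.fit(cohort.coords, cohort.diseased.astype(int))
        assert est.weights_.shape == (300,)
        assert est.n_cycles_ == num_cycles(300, 0.05, 0.2)
        assert set(np.unique(est.weights_)) == {0.2, 1.0}
        params = est.get_params()
        assert params["sphere_weight"] == 20.0
        clone = CohortHomogenizer(**params).fit(cohort.coords, cohort.diseased)
        assert np.array_equal(clone.weights_, est.weights_)

    def test_total_weight_after_helper(self):
        assert total_weight_after(3986, 350, 0.2) == pytest.approx(3706)
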