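import numpy as np
import pytest

from homogwas.association import fisher_assoc
from homogwas.simulate import (
    FALSE_NEGATIVE_PROBS,
    PC2_LINE,
    Box,
    StructuredCohortSpec,
    default_schemes,
    expected_or,
    gen_false_negative,
    gen_false_positive,
    gen_true_positive,
    run_study,
    simulate_cohort,
)


class TestExpectedOr:
    @pytest.mark.parametrize(
        "pd,ph,expected",
        [
            (0.15, 0.10, 1.59),
            (0.06, 0.03, 2.06),
            (0.08, 0.05, 1.65),
            (0.95, 0.92, 1.65),
        ],
    )
    def test_scheme_ors_round_to_published_values(self, pd, ph, expected):
        assert round(expected_or(pd, ph), 2) == expected

    def test_equal_probabilities_give_unity(self):
        assert expected_or(0.37, 0.37) == pytest.approx(1.0)

    def test_false_negative_strata_share_one_or(self):
        below = expected_or(*FALSE_NEGATIVE_PROBS[:2])
        above = expected_or(*FALSE_NEGATIVE_PROBS[2:])
        assert below == pytest.approx(above, rel=1e-9)

    def test_boundary_probabilities_rejected(self):
        with pytest.raises(ValueError):
            expected_or(0.0, 0.5)
        with pytest.raises(ValueError):
            expected_or(0.5, 1.0)


class TestSimulateCohort:
    def test_null_phenotype_fraction(self):
        spec = StructuredCohortSpec(
            n_subjects=10_000, p_diseased_in_box=0.5, p_diseased_outside=0.5, seed=1
        )
        cohort = simulate_cohort(spec)
        assert cohort.diseased.mean() == pytest.approx(0.5, abs=0.015)

    def test_box_imbalance_matches_spec(self):
        spec = StructuredCohortSpec(n_subjects=50_000, seed=2)
        cohort = simulate_cohort(spec)
        in_box = spec.box.contains(cohort.coords)
        assert in_box.sum() > 8000  # box holds roughly a fifth of subjects
        assert cohort.diseased[in_box].mean() == pytest.approx(0.6, abs=0.015)
        assert cohort.diseased[~in_box].mean() == pytest.approx(0.5, abs=0.01)

    def test_seed_reproducibility(self):
        spec = StructuredCohortSpec(n_subjects=500, seed=3)
        c1, c2 = simulate_cohort(spec), simulate_cohort(spec)
        assert np.array_equal(c1.coords, c2.coords)
        assert np.array_equal(c1.diseased, c2.diseased)
        c3 = simulate_cohort(StructuredCohortSpec(n_subjects=500, seed=4))
        assert not np.array_equal(c1.coords, c3.coords)

    def test_all_unit_weights_and_line_strata_nonempty(self):
        cohort = simulate_cohort(StructuredCohortSpec(n_subjects=2000, seed=5))
        assert np.all(cohort.weights == 1.0)
        below = cohort.coords[:, 1] < PC2_LINE
        assert 0 < below.sum() < cohort.n

    def test_empty_box_warns(self):
        spec = StructuredCohortSpec(
            n_subjects=50, box=Box(lower=(99.0, 99.0, 99.0), upper=(100.0, 100.0, 100.0)),
            seed=6,
        )
        with pytest.warns(UserWarning, match="box"):
            simulate_cohort(spec)


@pytest.fixture(scope="module")
def big_cohort():
    return simulate_cohort(StructuredCohortSpec(n_subjects=10_000, seed=7))


class TestGenerators:
    def test_rep_count_and_determinism(self, big_cohort):
        g1 = gen_true_positive(big_cohort, 0.57, 0.50, n_reps=7, seed=1)
        g2 = gen_true_positive(big_cohort, 0.57, 0.50, n_reps=7, seed=1)
        assert g1.shape == (7, big_cohort.n)
        assert np.array_equal(g1, g2)
        assert not np.array_equal(g1, gen_true_positive(big_cohort, 0.57, 0.50, 7, seed=2))

    @pytest.mark.parametrize("pd,ph", [(0.57, 0.50), (0.15, 0.10)])
    def test_true_positive_frequencies_and_or(self, big_cohort, pd, ph):
        genos = gen_true_positive(big_cohort, pd, ph, n_reps=20, seed=3)
        dis = big_cohort.diseased
        se = 3 * np.sqrt(pd * (1 - pd) / (20 * dis.sum()))
        assert genos[:, dis].mean() == pytest.approx(pd, abs=se)
        assert genos[:, ~dis].mean() == pytest.approx(ph, abs=3 * np.sqrt(ph * (1 - ph) / (20 * (~dis).sum())))
        # pooled empirical OR near the analytic value
        fd, fh = genos[:, dis].mean(), genos[:, ~dis].mean()
        emp_or = (fd / (1 - fd)) / (fh / (1 - fh))
        assert emp_or == pytest.approx(expected_or(pd, ph), abs=0.05)

    def test_false_positive_depends_only_on_box(self, big_cohort):
        spec = StructuredCohortSpec()
        genos = gen_false_positive(big_cohort, 0.9, 0.1, n_reps=20, seed=4)
        in_box = spec.box.contains(big_cohort.coords)
        assert genos[:, in_box].mean() == pytest.approx(0.9, abs=0.01)
        assert genos[:, ~in_box].mean() == pytest.approx(0.1, abs=0.01)
        # within each stratum the phenotype-genotype OR is ~1
        for stratum in (in_box, ~in_box):
            dis = big_cohort.diseased[stratum]
            g = genos[:, stratum]
            fd, fh = g[:, dis].mean(), g[:, ~dis].mean()
            emp_or = (fd / (1 - fd)) / (fh / (1 - fh))
            assert emp_or == pytest.approx(1.0, abs=0.05)

    def test_false_negative_concealment(self, big_cohort):
        """Within-stratum OR 1.65, but the pooled naive OR sits near 1."""
        genos = gen_false_negative(big_cohort, n_reps=20, seed=5)
        below = big_cohort.coords[:, 1] < PC2_LINE
        dis = big_cohort.diseased
        for stratum in (below, ~below):
            g = genos[:, stratum]
            d = dis[stratum]
            fd, fh = g[:, d].mean(), g[:, ~d].mean()
            emp_or = (fd / (1 - fd)) / (fh / (1 - fh))
            assert emp_or == pytest.approx(1.652, abs=0.1)
        fd, fh = genos[:, dis].mean(), genos[:, ~dis].mean()
        pooled = (fd / (1 - fd)) / (fh / (1 - fh))
        assert abs(np.log(pooled)) < 0.35 * np.log(1.65)

    def test_uncorrected_fisher_flags_false_positives(self):
        """The confounded null genotypes produce small naive Fisher p-values."""
        cohort = simulate_cohort(StructuredCohortSpec(n_subjects=2000, seed=8))
        genos = gen_false_positive(cohort, 0.9, 0.1, n_reps=20, seed=9)
        ps = [fisher_assoc(g, cohort).p_value for g in genos]
        assert float(np.median(ps)) < 0.05


class TestSchemes:
    def test_five_schemes_with_correct_null_split(self):
        schemes = default_schemes()
        assert len(schemes) == 6  # 3 TP presets + 2 FP presets + 1 FN
        null = [s for s in schemes if s.is_null]
        assert {s.kind for s in null} == {"false_positive"}
        assert all(s.implied_or > 1 for s in schemes if not s.is_null)


def test_run_study_reduced_shape():
    study = run_study(
        StructuredCohortSpec(n_subjects=400, seed=10), n_reps=3, seed=10
    )
    assert set(study.rocs) == {
        "fisher_original", "fisher_homogenized", "logistic_pc", "logistic_pc_weighted"
    }
    n_geno = 6 * 3
    for rs in study.results.values():
        assert len(rs) == n_geno
    assert len(study.positive_ids) == 4 * 3
    for roc in study.rocs.values():
        assert 0 <= roc.auc <= 1
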