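import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellscreen.biomarker import (bh_fdr, correlation_matrix, gene_screen,
                                  mann_whitney, mean_signature, rank_u, raw_auc,
                                  roc_auc, spearman_vs_response, BiomarkerStat)
from cellscreen.errors import ValidationError
from cellscreen.response import RESISTANT, SENSITIVE
from cellscreen.synthdata import SyntheticCohortSpec, generate_cohort
from cellscreen.datastore import normalize_pipeline
from cellscreen.response import classify_tertile, select_metric


def brute_force_u(x, y):
    """All-pairs U statistic for x with midrank tie handling."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert 0 < p <= 0.1

    def test_identical_multisets(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n^2 / 2
        assert p > 0.9

    def test_midranks_with_ties(self):
        u, _ = mann_whitney([1, 2], [1, 2])
        assert u == 2.0

    def test_all_identical_values(self):
        u, p = mann_whitney([5, 5, 5], [5, 5])
        assert u == 3.0
        assert p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([1], [2, 3])

    def test_u_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            nx, ny = rng.integers(2, 12, size=2)
            x = rng.integers(0, 8, size=nx).astype(float)
            y = rng.integers(0, 8, size=ny).astype(float)
            u, _ = mann_whitney(x, y)
            assert u == brute_force_u(x, y)


class TestRawAuc:
    def test_rank_u_matches_brute_force_exactly(self):
        # midranks are multiples of 0.5, so both sides are exact dyadic floats
        rng = np.random.default_rng(7)
        for _ in range(300):
            n_pos, n_neg = rng.integers(2, 15, size=2)
            pos = rng.integers(0, 10, size=n_pos).astype(float)
            neg = rng.integers(0, 10, size=n_neg).astype(float)
            u = rank_u(pos, neg)
            assert u == brute_force_u(pos, neg)
            assert raw_auc(pos, neg) == u / (n_pos * n_neg)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        pos = rng.normal(1, 1, size=10)
        neg = rng.normal(0, 1, size=12)
        a = raw_auc(pos, neg)
        assert raw_auc(np.exp(pos), np.exp(neg)) == pytest.approx(a)
        assert raw_auc(3 * pos + 7, 3 * neg + 7) == pytest.approx(a)


def two_class_labeling(labeling_factory, sensitive, resistant):
    labels = {cl: SENSITIVE for cl in sensitive}
    labels.update({cl: RESISTANT for cl in resistant})
    return labeling_factory(labels)


class TestRocAuc:
    def test_perfect_separation_higher_in_resistant(self, labeling_factory):
        lab = two_class_labeling(labeling_factory, ["s1", "s2"], ["r1", "r2"])
        expr = {"s1": 1.0, "s2": 1.0, "r1": 10.0, "r2": 10.0}
        stat = roc_auc(expr, lab)
        assert stat.auc == 1.0
        assert stat.direction == "higher_in_resistant"

    def test_identical_expression_no_direction(self, labeling_factory):
        lab = two_class_labeling(labeling_factory, ["s1", "s2"], ["r1", "r2"])
        stat = roc_auc({cl: 5.0 for cl in lab.labels}, lab)
        assert stat.auc == 0.5
        assert stat.direction == "none"
        assert stat.mw_p == 1.0

    def test_folding_when_higher_in_sensitive(self, labeling_factory):
        lab = two_class_labeling(labeling_factory, ["s1", "s2", "s3"], ["r1", "r2", "r3"])
        expr = {"s1": 4.0, "s2": 5.0, "s3": 6.0, "r1": 1.0, "r2": 2.0, "r3": 3.0}
        stat = roc_auc(expr, lab)
        assert stat.auc == 1.0
        assert stat.direction == "higher_in_sensitive"

    def test_relabeling_flips_direction_not_auc(self, labeling_factory):
        rng = np.random.default_rng(3)
        sens, res = [f"s{i}" for i in range(8)], [f"r{i}" for i in range(9)]
        expr = {cl: float(rng.normal(i % 3)) for i, cl in enumerate(sens + res)}
        a = roc_auc(expr, two_class_labeling(labeling_factory, sens, res))
        b = roc_auc(expr, two_class_labeling(labeling_factory, res, sens))
        assert a.auc == pytest.approx(b.auc)
        if a.direction != "none":
            assert a.direction != b.direction

    def test_missing_expression_majority_errors(self, labeling_factory):
        lab = two_class_labeling(labeling_factory, ["s1", "s2", "s3"], ["r1", "r2", "r3"])
        with pytest.raises(ValidationError, match="missing"):
            roc_auc({"s1": 1.0, "r1": 2.0}, lab)

    def test_some_missing_dropped_with_warning(self, labeling_factory):
        lab = two_class_labeling(labeling_factory, ["s1", "s2", "s3"], ["r1", "r2", "r3"])
        expr = {"s1": 1., "s2": 2., "s3": 3., "r1": 4., "r2": 5.}
        with pytest.warns(UserWarning, match="dropped"):
            stat = roc_auc(expr, lab)
        assert stat.n_resistant == 2


class TestSpearman:
    def test_perfect_anticorrelation(self):
        rho, _ = spearman_vs_response({"a": 1, "b": 2, "c": 3, "d": 4},
                                      {"a": 4, "b": 3, "c": 2, "d": 1})
        assert rho == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        rho, _ = spearman_vs_response({"a": 1, "b": 2, "c": 3, "d": 4},
                                      {"a": 1, "b": 2, "c": 3, "d": 4})
        assert rho == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        rho, _ = spearman_vs_response({"a": 1, "b": 2, "c": 3, "d": 4},
                                      {"a": 2, "b": 1, "c": 4, "d": 3})
        assert rho == pytest.approx(0.6)

    def test_too_few_shared_lines(self):
        with pytest.raises(ValidationError):
            spearman_vs_response({"a": 1, "b": 2, "c": 3}, {"a": 1, "b": 2, "c": 3})


class TestMeanSignature:
    def test_mean_of_two_genes(self, matrix_factory):
        m = matrix_factory([[100, 100], [300, 300]], genes=["A", "B"])
        out = mean_signature(["A", "B"], m)
        assert out == {"CL0": 200.0, "CL1": 200.0}

    def test_single_gene_identity(self, matrix_factory):
        m = matrix_factory([[1, 2], [3, 4]], genes=["A", "B"])
        assert mean_signature(["B"], m) == {"CL0": 3.0, "CL1": 4.0}

    def test_absent_gene_warns(self, matrix_factory):
        m = matrix_factory([[1, 2]], genes=["A"])
        with pytest.warns(UserWarning, match="ZZZ"):
            out = mean_signature(["A", "ZZZ"], m)
        assert out == {"CL0": 1.0, "CL1": 2.0}

    def test_all_absent_errors(self, matrix_factory):
        m = matrix_factory([[1, 2]], genes=["A"])
        with pytest.raises(ValidationError, match="ZZZ"):
            mean_signature(["ZZZ"], m)


class TestBhFdr:
    def test_equal_spacing_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.5]), [0.5])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.1], [-0.2]):
            with pytest.raises(ValidationError):
                bh_fdr(bad)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    def test_q_bounded_and_order_free(self, pvals):
        q = bh_fdr(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        assert (q <= 1.0).all()
        # q-values don't depend on input order
        order = np.argsort(pvals)
        np.testing.assert_allclose(np.asarray(q)[order], bh_fdr(np.sort(pvals)))

    def test_q_never_below_p_and_rejections_nested(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-6, 1, size=100)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        small = set(np.flatnonzero(q <= 0.05))
        large = set(np.flatnonzero(q <= 0.20))
        assert small <= large


def screened_cohort(seed=1, n_genes=50, n_cell_lines=120, planted=((0, 2.0, 1),)):
    spec = SyntheticCohortSpec(n_genes=n_genes, n_cell_lines=n_cell_lines, seed=seed,
                               planted_genes=list(planted))
    cohort = generate_cohort(spec)
    m = normalize_pipeline(cohort.expression["DS1"])
    metric, vals = select_metric(cohort.records, "audrc_first")
    labeling = classify_tertile(vals, dataset="DS1", compound=cohort.truth.compound,
                                metric=metric)
    return cohort, m, labeling, vals


class TestGeneScreen:
    def test_planted_marker_ranked_first(self):
        cohort, m, labeling, vals = screened_cohort()
        stats = gene_screen(m, labeling, audrc=vals)
        assert stats[0].gene == cohort.truth.planted_genes[0][0]
        assert stats[0].auc > 0.9
        assert stats[0].fdr_q is not None

    def test_restricted_gene_list_scopes_fdr(self):
        _, m, labeling, vals = screened_cohort()
        subset = m.genes[:3]
        stats = gene_screen(m, labeling, audrc=vals, genes=subset)
        assert len(stats) == 3
        expected_q = bh_fdr([s.mw_p for s in sorted(stats, key=lambda s: s.gene)])
        got_q = [s.fdr_q for s in sorted(stats, key=lambda s: s.gene)]
        np.testing.assert_allclose(got_q, expected_q)

    def test_ordering_deterministic(self):
        _, m, labeling, vals = screened_cohort()
        a = gene_screen(m, labeling, audrc=vals)
        b = gene_screen(m, labeling, audrc=vals)
        assert [s.gene for s in a] == [s.gene for s in b]
        aucs = [s.auc for s in a]
        assert aucs == sorted(aucs, reverse=True)

    def test_null_cohort_type_i_rate_calibrated(self):
        _, m, labeling, vals = screened_cohort(seed=5, n_genes=400, planted=())
        stats = gene_screen(m, labeling, audrc=vals)
        frac = np.mean([s.mw_p < 0.05 for s in stats])
        assert 0.01 <= frac <= 0.10  # loose band at m=400; tight version in acceptance


class TestCorrelationMatrix:
    def make_screen(self, gene, rho, p):
        return [BiomarkerStat(gene=gene, n_sensitive=5, n_resistant=5, auc=0.8,
                              direction="higher_in_resistant", mw_p=p,
                              spearman_rho=rho, spearman_p=0.01)]

    def test_sub_threshold_rho_excluded(self, matrix_factory):
        m = matrix_factory(np.arange(8, dtype=float).reshape(1, 8), genes=["A"])
        audrc = {cl: float(i) for i, cl in enumerate(m.cell_lines)}
        with pytest.warns(UserWarning, match="no gene"):
            out = correlation_matrix(m, self.make_screen("A", 0.19, 0.01), audrc)
        assert out.empty

    def test_retained_gene_included(self, matrix_factory):
        m = matrix_factory(np.arange(8, dtype=float).reshape(1, 8), genes=["A"])
        audrc = {cl: float(-i) for i, cl in enumerate(m.cell_lines)}
        out = correlation_matrix(m, self.make_screen("A", -0.25, 0.01), audrc)
        assert list(out.columns) == ["AUDRC", "A"]
        assert out.loc["A", "AUDRC"] == pytest.approx(-1.0)

    def test_unit_diagonal(self, matrix_factory):
        rng = np.random.default_rng(2)
        m = matrix_factory(rng.normal(size=(2, 10)) ** 2, genes=["A", "B"])
        audrc = {cl: float(rng.normal()) for cl in m.cell_lines}
        screen = (self.make_screen("A", 0.5, 0.01) + self.make_screen("B", -0.5, 0.02))
        out = correlation_matrix(m, screen, audrc)
        np.testing.assert_allclose(np.diag(out.values), 1.0)
        np.testing.assert_allclose(out.values, out.values.T, atol=1e-12)
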