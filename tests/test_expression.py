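import math

import numpy as np
import pytest
from scipy.stats import rankdata

from sh2ascreen.errors import ValidationError
from sh2ascreen.expression import (
    CTAScoreResult,
    apply_tmm,
    compare_scores,
    cross_cancer_common_genes,
    cta_score,
    DEResult,
    differential_expression,
    locus_neighborhood,
    marker_panel_comparison,
    paralogue_concordance,
    tmm_factors,
    x_autosome_ratio,
)
from sh2ascreen.model import AnnotationTable, GeneAnnotation, SampleTable
from sh2ascreen.reactivation import classify_sh2a_status, sample_groups
from sh2ascreen.simulate import CohortConfig, simulate_cohort

from conftest import make_expr


def oracle_tmm_factor(x_obs, x_ref, trim_m=0.30, trim_a=0.05):
    """Independent spreadsheet-style trimmed weighted mean for one sample
    against a reference: explicit loops, no shared code with the package."""
    n_obs, n_ref = sum(x_obs), sum(x_ref)
    rows = []
    for xo, xr in zip(x_obs, x_ref):
        if xo > 0 and xr > 0:
            po, pr = xo / n_obs, xr / n_ref
            m = math.log2(po / pr)
            a = 0.5 * math.log2(po * pr)
            w = (1 - po) / po + (1 - pr) / pr
            rows.append((m, a, w))
    n = len(rows)
    m_ranks = rankdata([r[0] for r in rows])
    a_ranks = rankdata([r[1] for r in rows])
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    num = den = 0.0
    for (m, a, w), rm, ra in zip(rows, m_ranks, a_ranks):
        if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
            num += m / w
            den += 1.0 / w
    return 2.0 ** (num / den)


class TestTMM:
    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(2, 1, 30)
        em = make_expr([f"g{i}" for i in range(30)], ["a", "b"],
                       np.column_stack([v, v]))
        f = tmm_factors(em)
        assert f["a"] == pytest.approx(1.0, abs=1e-12)
        assert f["b"] == pytest.approx(1.0, abs=1e-12)

    def test_pure_scaling_unit_factors(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(2, 1, 30)
        em = make_expr([f"g{i}" for i in range(30)], ["a", "b"],
                       np.column_stack([v, 7.0 * v]))
        f = tmm_factors(em)
        assert f["a"] == pytest.approx(1.0, abs=1e-12)
        assert f["b"] == pytest.approx(1.0, abs=1e-12)

    def test_compositional_outlier_matches_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(3, 0.8, 20)
        perturbed = base.copy()
        perturbed[0] *= 8.0  # one 8-fold compositional outlier
        em = make_expr([f"g{i}" for i in range(20)], ["ref", "obs"],
                       np.column_stack([base, perturbed]))
        f = tmm_factors(em, reference="ref")
        expected = oracle_tmm_factor(perturbed, base)
        # package factors are rescaled to geometric mean 1
        expected_pair = (1 / math.sqrt(expected), math.sqrt(expected))
        assert f["ref"] == pytest.approx(expected_pair[0], rel=1e-9)
        assert f["obs"] == pytest.approx(expected_pair[1], rel=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(2, 1, size=(50, 6))
        em = make_expr([f"g{i}" for i in range(50)], [f"s{i}" for i in range(6)], X)
        f = np.array(list(tmm_factors(em).values()))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(4)
        X = rng.lognormal(2, 1, size=(40, 4))
        ids = [f"g{i}" for i in range(40)]
        ss = [f"s{i}" for i in range(4)]
        f1 = tmm_factors(make_expr(ids, ss, X))
        f2 = tmm_factors(make_expr(ids, ss, X * np.array([1.0, 3.0, 0.5, 10.0])))
        for s in ss:
            assert f1[s] == pytest.approx(f2[s], rel=1e-9)

    def test_coding_restriction_and_errors(self):
        rng = np.random.default_rng(5)
        X = rng.lognormal(2, 1, size=(30, 3))
        ids = [f"g{i}" for i in range(30)]
        em = make_expr(ids, ["a", "b", "c"], X)
        coding = set(ids[:20])
        f_all = tmm_factors(em)
        f_cod = tmm_factors(em, coding_genes=coding)
        assert f_all != f_cod
        with pytest.raises(ValidationError, match="coding"):
            tmm_factors(em, coding_genes={"nope"})
        with pytest.raises(ValidationError):
            tmm_factors(make_expr(["g1"], ["a"], [[1.0]]))

    def test_apply_tmm_sets_flag(self):
        rng = np.random.default_rng(6)
        X = rng.lognormal(2, 1, size=(30, 3))
        em = make_expr([f"g{i}" for i in range(30)], ["a", "b", "c"], X)
        out = apply_tmm(em, tmm_factors(em))
        assert out.normalized and not em.normalized


class TestDifferentialExpression:
    def test_identical_groups_fc_one(self):
        em = make_expr(["g1"], ["p1", "p2", "n1", "n2"], [[2.0, 3.0, 2.0, 3.0]])
        r = differential_expression(em, ["p1", "p2"], ["n1", "n2"])[0]
        assert r.fold_change == 1.0 and r.direction == "none"

    def test_all_zero_gene(self):
        em = make_expr(["g1"], ["p1", "p2", "n1", "n2"], [[0.0, 0.0, 0.0, 0.0]])
        r = differential_expression(em, ["p1", "p2"], ["n1", "n2"])[0]
        assert r.fold_change == 1.0 and r.p_value == 1.0 and r.direction == "none"

    def test_overlapping_groups_rejected(self):
        em = make_expr(["g1"], ["a", "b"], [[1.0, 2.0]])
        with pytest.raises(ValidationError, match="overlap"):
            differential_expression(em, ["a"], ["a", "b"])

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        base = rng.lognormal(1.0, 0.3, size=(1, 40))
        vals = base.copy()
        vals[0, :20] *= 2.0
        ss = [f"s{i}" for i in range(40)]
        em = make_expr(["g1"], ss, vals)
        r = differential_expression(em, ss[:20], ss[20:])[0]
        assert r.direction == "up" and r.p_value < 0.01

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(8)
        n_genes, reps = 400, 5
        rej = 0
        for _ in range(reps):
            X = rng.lognormal(1, 0.5, size=(n_genes, 40))
            ss = [f"s{i}" for i in range(40)]
            em = make_expr([f"g{i}" for i in range(n_genes)], ss, X)
            res = differential_expression(em, ss[:20], ss[20:])
            rej += sum(r.p_value < 0.05 for r in res)
        assert rej / (n_genes * reps) == pytest.approx(0.05, abs=0.015)


class TestConcordance:
    def _de(self, fcs):
        return [DEResult(f"g{i + 1}", fc, math.log2(fc), 0.01,
                         "up" if fc > 1.19 else ("down" if fc < 1 / 1.19 else "none"))
                for i, fc in enumerate(fcs)]

    def test_identity_r_one(self):
        de = self._de([1.5, 1.3, 1.0, 0.9, 0.7, 1.25])
        r, up, down = paralogue_concordance(de, de)
        assert r == pytest.approx(1.0)
        assert up == {"g1", "g2", "g6"} and down == {"g5"}

    def test_negation_r_minus_one(self):
        de_a = self._de([1.5, 1.3, 1.01, 0.9, 0.7, 1.25])
        de_b = self._de([1 / f for f in [1.5, 1.3, 1.01, 0.9, 0.7, 1.25]])
        r, up, down = paralogue_concordance(de_a, de_b)
        assert r == pytest.approx(-1.0)
        assert up == set() and down == set()

    def test_six_gene_toy(self):
        de_a = self._de([1.5, 1.3, 1.0, 0.9, 0.7, 1.25])
        de_b = self._de([1.4, 1.1, 1.0, 0.8, 0.6, 1.30])
        _, up, down = paralogue_concordance(de_a, de_b)
        assert up == {"g1", "g6"}
        assert down == {"g5"}

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            paralogue_concordance(self._de([1.5]), self._de([1.5, 2.0]))


class TestCrossCancer:
    def _res(self, gene, direction):
        fc = 1.5 if direction == "up" else (0.6 if direction == "down" else 1.0)
        return DEResult(gene, fc, math.log2(fc), 0.01, direction)

    def test_up_in_all_types(self):
        de = {ct: [self._res("g1", "up")] for ct in "ABCD"}
        for mt in (1, 2, 3, 4):
            up, down = cross_cancer_common_genes(de, min_types=mt)
            assert up == {"g1"} and down == set()

    def test_conflict_excluded_by_default(self):
        de = {
            "A": [self._res("g1", "up")],
            "B": [self._res("g1", "up")],
            "C": [self._res("g1", "down")],
        }
        up, down = cross_cancer_common_genes(de, min_types=2)
        assert up == set() and down == set()
        up2, _ = cross_cancer_common_genes(de, min_types=2, allow_conflict=True)
        assert up2 == {"g1"}

    def test_monotone_in_min_types(self):
        rng = np.random.default_rng(9)
        de = {}
        for ct in "ABCDE":
            de[ct] = [self._res(f"g{i}", rng.choice(["up", "down", "none"]))
                      for i in range(30)]
        prev_up, prev_down = None, None
        for mt in (1, 2, 3, 4, 5):
            up, down = cross_cancer_common_genes(de, min_types=mt)
            if prev_up is not None:
                assert up <= prev_up and down <= prev_down
            prev_up, prev_down = up, down

    def test_planted_pan_cancer_genes_recovered(self):
        de = {}
        rng = np.random.default_rng(10)
        for ct in ("A", "B", "C"):
            results = [self._res(f"bg{i}", "none") for i in range(50)]
            results += [self._res(f"planted{i}", "up") for i in range(10)]
            rng.shuffle(results)
            de[ct] = results
        up, down = cross_cancer_common_genes(de, min_types=3)
        assert up == {f"planted{i}" for i in range(10)} and down == set()

    def test_needs_two_types(self):
        with pytest.raises(ValidationError):
            cross_cancer_common_genes({"A": []})


class TestCTAScore:
    def test_hand_example(self):
        # g1 log2 expression (1,2,3); g2 constant -> excluded
        tpm = np.array([[1.0, 3.0, 7.0], [5.0, 5.0, 5.0]])
        em = make_expr(["g1", "g2"], ["a", "b", "c"], tpm)
        st = SampleTable(["a", "b", "c"], ["CT"] * 3, ["tumor"] * 3)
        res = cta_score(em, st, ["g1", "g2"], k=2)
        assert all(r.selected_genes == ("g1",) for r in res)
        assert [r.score for r in res] == pytest.approx([-1.0, 0.0, 1.0])

    def test_all_constant_error(self):
        em = make_expr(["g1"], ["a", "b"], [[2.0, 2.0]])
        st = SampleTable(["a", "b"], ["CT"] * 2, ["tumor"] * 2)
        with pytest.raises(ValidationError, match="variance"):
            cta_score(em, st, ["g1"])

    def test_shift_invariance(self):
        rng = np.random.default_rng(11)
        tpm = rng.lognormal(1, 1, size=(6, 10))
        ids = [f"g{i}" for i in range(6)]
        ss = [f"s{i}" for i in range(10)]
        st = SampleTable(ss, ["CT"] * 10, ["tumor"] * 10)
        res1 = cta_score(make_expr(ids, ss, tpm), st, ids, k=4)
        scaled = tpm.copy()
        scaled[2, :] = (tpm[2, :] + 1) * 4 - 1  # log2(x+1) shifted by +2
        res2 = cta_score(make_expr(ids, ss, scaled), st, ids, k=4)
        assert [r.score for r in res1] == pytest.approx([r.score for r in res2])

    def test_scores_sum_to_zero_per_type(self, small_cohort):
        expr, samples, annotation, _, _, truth = small_cohort
        res = cta_score(expr, samples, truth.cta_gene_ids, k=10)
        by_type = {}
        for r in res:
            by_type.setdefault(r.cancer_type, []).append(r.score)
        for scores in by_type.values():
            assert sum(scores) == pytest.approx(0.0, abs=1e-9)

    def test_compare_scores_identical_p_one(self):
        scores = [CTAScoreResult(f"s{i}", "CT", v, ("g1",))
                  for i, v in enumerate([1.0, 2.0, 1.0, 2.0])]
        p = compare_scores(scores, ["s0", "s1"], ["s2", "s3"])
        assert p["CT"] == 1.0


class TestPanelsAndRatios:
    def test_empty_panel(self):
        em = make_expr(["g1"], ["a", "b"], [[1.0, 2.0]])
        assert marker_panel_comparison(em, [], ["a"], ["b"]) == []

    def test_single_gene_identical_groups(self):
        em = make_expr(["g1"], ["a", "b", "c", "d"], [[2.0, 3.0, 2.0, 3.0]])
        res = marker_panel_comparison(em, ["g1"], ["a", "b"], ["c", "d"])
        assert res[0].p_value == 1.0

    def test_planted_panel_shift_detected(self):
        rng = np.random.default_rng(12)
        vals = rng.lognormal(1, 0.2, size=(3, 60))
        vals[:, :30] *= 1.5
        ids = ["m1", "m2", "m3"]
        ss = [f"s{i}" for i in range(60)]
        res = marker_panel_comparison(make_expr(ids, ss, vals), ids,
                                      ss[:30], ss[30:])
        assert all(r.direction == "up" for r in res)

    def _ratio_setup(self):
        ann = AnnotationTable([
            GeneAnnotation("gx", "GX", "chrX", 1, 10, "+", frozenset({"coding"})),
            GeneAnnotation("ga", "GA", "chr2", 1, 10, "+", frozenset({"coding"})),
        ])
        return ann

    def test_ratio_equal_totals(self):
        ann = self._ratio_setup()
        em = make_expr(["gx", "ga"], ["a", "b", "c", "d"],
                       [[5, 5, 5, 5], [5, 5, 5, 5]])
        ratios, p = x_autosome_ratio(em, ann, ["a", "b"], ["c", "d"])
        assert all(v == 1.0 for v in ratios.values())
        assert p == 1.0

    def test_ratio_linearity(self):
        ann = self._ratio_setup()
        em = make_expr(["gx", "ga"], ["a", "b"], [[5, 10], [5, 5]])
        ratios, _ = x_autosome_ratio(em, ann, ["a"], ["b"])
        assert ratios["b"] == 2 * ratios["a"]

    def test_null_cohort_ratio_not_significant(self):
        # truly null: no planted effects, arbitrary 20/20 split
        ps = []
        for seed in range(100):
            expr, samples, annotation, _, _, _ = simulate_cohort(
                CohortConfig(n_cancer_types=1, samples_per_type=40, n_genes=20,
                             n_cta_genes=4, n_marker_genes=2,
                             n_splice_events_per_class=1,
                             reactivation_fraction=0.0, seed=seed)
            )
            _, p = x_autosome_ratio(expr, annotation,
                                    expr.sample_ids[:20], expr.sample_ids[20:])
            ps.append(p)
        assert np.mean(np.array(ps) > 0.05) >= 0.93


class TestLocusNeighborhood:
    def _setup(self, focal_up, neighbors_up):
        ann = AnnotationTable([
            GeneAnnotation("f", "F", "chr5", 100_000, 101_000, "+",
                           frozenset({"coding"})),
            GeneAnnotation("n1", "N1", "chr5", 150_000, 151_000, "+",
                           frozenset({"coding"})),
            GeneAnnotation("n2", "N2", "chr5", 50_000, 51_000, "+",
                           frozenset({"coding"})),
            GeneAnnotation("far", "FAR", "chr5", 90_000_000, 90_001_000, "+",
                           frozenset({"coding"})),
        ])
        rng = np.random.default_rng(13)
        vals = rng.lognormal(1, 0.1, size=(4, 40))
        if focal_up:
            vals[0, :20] *= 3
        if neighbors_up:
            vals[1, :20] *= 3
            vals[2, :20] *= 3
        ids = ["f", "n1", "n2", "far"]
        ss = [f"s{i}" for i in range(40)]
        return make_expr(ids, ss, vals), ann, ss[:20], ss[20:]

    def test_locus_restricted(self):
        em, ann, pos, neg = self._setup(True, False)
        results, verdict = locus_neighborhood(em, ann, "f", 100_000, pos, neg)
        assert verdict == "locus_restricted"
        assert {r.gene_id for r in results} == {"f", "n1", "n2"}  # 'far' outside

    def test_regional(self):
        em, ann, pos, neg = self._setup(True, True)
        _, verdict = locus_neighborhood(em, ann, "f", 100_000, pos, neg)
        assert verdict == "regional"

    def test_no_neighbors_error(self):
        em, ann, pos, neg = self._setup(True, False)
        with pytest.raises(ValidationError, match="window"):
            locus_neighborhood(em, ann, "far", 1_000, pos, neg)


class TestEndToEndGroups:
    def test_planted_de_recovered_via_classifier(self, small_cohort):
        expr, samples, annotation, _, _, truth = small_cohort
        statuses = classify_sh2a_status(expr, annotation)
        pos, neg, inter = sample_groups(statuses)
        assert sorted(pos) == sorted(truth.reactivated_samples)
        res = differential_expression(expr, pos, neg)
        by_id = {r.gene_id: r for r in res}
        for g in truth.de_gene_ids:
            assert by_id[g].direction == "up"
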