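import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import otopattern as op
from otopattern.exceptions import ValidationError
from otopattern.patterns import (assign_patterns_matrix, pearson3,
                                 GROUP_LABEL_ORDER)


def _log2_matrix(values, sample_ids):
    values = np.asarray(values, float)
    return op.ExpressionMatrix(
        probe_ids=[f"p{i}" for i in range(values.shape[0])],
        sample_ids=sample_ids, values=values,
        scale="log2", stage="filtered",
    )


def _sheet(n_es=2, n_os=2, n_cse=3, pair=()):
    entries = []
    for g, n in (("ES", n_es), ("OS", n_os), ("CSE", n_cse)):
        for i in range(n):
            sid = f"{g}{i + 1}"
            entries.append(op.SampleEntry(sid, g, "pr" if sid in pair else ""))
    return op.SampleSheet(entries)


class TestGroupMeans:
    def test_plain_arithmetic(self):
        sheet = _sheet()
        m = _log2_matrix([[2, 4, 1, 1, 0, 0, 0]], sheet.sample_ids)
        np.testing.assert_allclose(op.group_means(m, sheet)[0], [3, 1, 0])

    def test_balanced_pair_averaging_is_identical(self):
        sheet = _sheet(pair=("ES1", "ES2"))
        m = _log2_matrix([[2, 4, 1, 1, 0, 0, 0]], sheet.sample_ids)
        np.testing.assert_allclose(op.group_means(m, sheet)[0], [3, 1, 0])

    def test_unbalanced_groups_match_brute_force(self, rng):
        sheet = _sheet(n_es=4, n_os=2, n_cse=5)
        values = rng.normal(8, 2, size=(50, 11))
        m = _log2_matrix(values, sheet.sample_ids)
        got = op.group_means(m, sheet)
        cols = {g: [i for i, s in enumerate(sheet.sample_ids)
                    if sheet.groups[i] == g] for g in ("ES", "OS", "CSE")}
        expected = np.column_stack(
            [values[:, cols[g]].mean(axis=1) for g in ("ES", "OS", "CSE")]
        )
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_pair_averaging_weights_unbalanced_group(self):
        # pair (8, 2) averages to 5 before joining the single sample 2:
        # (5 + 2) / 2 = 3.5, not the plain mean 4
        sheet = _sheet(n_es=3, n_os=1, n_cse=1, pair=("ES1", "ES2"))
        m = _log2_matrix([[8, 2, 2, 0, 0]], sheet.sample_ids)
        np.testing.assert_allclose(op.group_means(m, sheet)[0], [3.5, 0, 0])


class TestAnova:
    def test_no_between_group_variance(self):
        sheet = _sheet(2, 2, 3)
        m = _log2_matrix([[1, 1, 1, 1, 1, 1, 1]], sheet.sample_ids)
        res = op.anova_per_probe(m, sheet)
        assert res.loc[0, "F"] == 0.0 and res.loc[0, "p"] == 1.0

    def test_textbook_example(self):
        # groups (1,2),(3,4),(5,6): SSB=16, SSW=1.5, F=(16/2)/(1.5/3)=16
        sheet = _sheet(2, 2, 2)
        m = _log2_matrix([[1, 2, 3, 4, 5, 6]], sheet.sample_ids)
        res = op.anova_per_probe(m, sheet)
        assert res.loc[0, "F"] == pytest.approx(16.0, rel=1e-12)
        f_sp, p_sp = stats.f_oneway([1, 2], [3, 4], [5, 6])
        assert res.loc[0, "F"] == pytest.approx(f_sp, rel=1e-12)
        assert res.loc[0, "p"] == pytest.approx(p_sp, rel=1e-12)

    def test_zero_within_variance_gives_p_zero(self):
        sheet = _sheet(2, 2, 2)
        m = _log2_matrix([[1, 1, 2, 2, 3, 3]], sheet.sample_ids)
        res = op.anova_per_probe(m, sheet)
        assert np.isinf(res.loc[0, "F"]) and res.loc[0, "p"] == 0.0

    def test_matches_scipy_on_random_probes(self, rng):
        sheet = _sheet(3, 4, 3)
        values = rng.normal(8, 1, size=(500, 10))
        m = _log2_matrix(values, sheet.sample_ids)
        res = op.anova_per_probe(m, sheet)
        groups = [[i for i in range(10) if sheet.groups[i] == g]
                  for g in ("ES", "OS", "CSE")]
        for i in range(0, 500, 37):
            f_sp, p_sp = stats.f_oneway(*[values[i, c] for c in groups])
            assert res.loc[i, "F"] == pytest.approx(f_sp, rel=1e-10)
            assert res.loc[i, "p"] == pytest.approx(p_sp, rel=1e-10)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(123)
        sheet = _sheet(5, 5, 5)
        values = rng.normal(0, 1, size=(2000, 15))
        m = _log2_matrix(values, sheet.sample_ids)
        res = op.anova_per_probe(m, sheet)
        rate = (res["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 3 * se

    def test_degrees_of_freedom_guard(self):
        sheet = _sheet(1, 1, 1)
        m = _log2_matrix([[1, 2, 3]], sheet.sample_ids)
        with pytest.raises(ValidationError, match="n > k"):
            op.anova_per_probe(m, sheet)


class TestBhAdjust:
    @staticmethod
    def _brute_force(p):
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [None] * m
        for pos, i in enumerate(order):
            q[i] = min(
                min(p[order[j]] * m / (j + 1) for j in range(pos, m)), 1.0
            )
        return q

    def test_hand_stepup(self):
        np.testing.assert_allclose(op.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert op.bh_adjust([0.3])[0] == 0.3

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(200):
            p = rng.random(size=rng.integers(1, 25))
            q = op.bh_adjust(p)
            np.testing.assert_allclose(q, self._brute_force(list(p)),
                                       rtol=1e-12)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_sm, rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_monotone_in_sorted_p(self, p):
        q = op.bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            op.bh_adjust([0.5, 1.2])


class TestTemplates:
    def test_binary6_enumeration_and_names(self):
        ts = op.generate_templates("binary6")
        assert len(ts) == 6 and len(ts.matchable) == 6
        by_levels = {t.levels: t.label for t in ts.templates}
        assert by_levels[(1, 0, 0)] == "ES high"
        assert by_levels[(0, 1, 1)] == "OS and CSE high"
        assert by_levels[(1, 0, 1)] == "ES and CSE high"

    def test_ternary25_enumeration(self):
        ts = op.generate_templates("ternary25")
        assert len(ts) == 25
        assert len(ts.matchable) == 24
        degenerate = [t for t in ts.templates if t.degenerate]
        assert [t.levels for t in degenerate] == [(0.5, 0.5, 0.5)]

    def test_ternary_pearson_equivalence_classes(self):
        ts = op.generate_templates("ternary25")
        classes: list[list] = []
        for t in ts.matchable:
            for c in classes:
                if abs(pearson3(np.array(t.levels),
                                np.array(c[0].levels)) - 1) < 1e-12:
                    c.append(t)
                    break
            else:
                classes.append([t])
        assert len(classes) == 12


class TestAssignPattern:
    def test_exact_match(self):
        ts = op.generate_templates("binary6")
        t, r = op.assign_pattern([1, 0, 0], ts)
        assert t.label == "ES high" and r == 1.0

    def test_affine_equivalent_profile(self):
        ts = op.generate_templates("binary6")
        t, r = op.assign_pattern([10, 2, 2], ts)
        assert t.label == "ES high" and r == pytest.approx(1.0)

    def test_two_high_profile(self):
        ts = op.generate_templates("binary6")
        t, _ = op.assign_pattern([5, 5, 1], ts)
        assert t.label == "ES and OS high"

    def test_constant_profile_unassignable(self):
        ts = op.generate_templates("binary6")
        with pytest.raises(ValidationError, match="unassignable"):
            op.assign_pattern([3, 3, 3], ts)

    @pytest.mark.parametrize("mode", ["binary6", "ternary25"])
    def test_matches_brute_force_argmax(self, rng, mode):
        ts = op.generate_templates(mode)
        cand = ts.matchable
        for _ in range(300):
            m = rng.normal(size=3)
            if np.std(m) < 1e-9:
                continue
            t, r = op.assign_pattern(m, ts)
            rs = [pearson3(m, np.array(c.levels)) for c in cand]
            assert r == pytest.approx(max(rs), abs=1e-12)

    @given(st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
           st.floats(0.1, 10), st.floats(-20, 20))
    def test_affine_invariance(self, m, a, b):
        m = np.asarray(m)
        if np.std(m) < 1e-3:
            return
        ts = op.generate_templates("binary6")
        t1, _ = op.assign_pattern(m, ts)
        t2, _ = op.assign_pattern(a * m + b, ts)
        assert t1.name == t2.name

    def test_unique_graded_maximum_beats_binary(self):
        ts = op.generate_templates("ternary25")
        # a perfectly graded profile correlates at r=1 only with its own
        # graded template, which therefore wins over every binary one
        t, r = op.assign_pattern([2.0, 1.0, 0.0], ts)
        assert r == pytest.approx(1.0)
        assert t.levels == (1, 0.5, 0)

    def test_exact_tie_prefers_binary_template(self):
        ts = op.generate_templates("ternary25")
        # (10,2,2) has r=1 with the whole (1,0,0) equivalence class,
        # including graded (1,0.5,0.5) and (0.5,0,0); the binary member
        # wins the tie
        t, r = op.assign_pattern([10.0, 2.0, 2.0], ts)
        assert r == pytest.approx(1.0)
        assert t.levels == (1, 0, 0) and t.label == "ES high"


class TestFoldChange:
    def test_single_high_axis(self):
        assert op.fold_change([11.16, 0, 0], (1, 0, 0)) == pytest.approx(11.16)

    def test_two_high_axes(self):
        assert op.fold_change([3, 3, 1], (1, 1, 0)) == pytest.approx(2.0)

    def test_sign_symmetry_against_complement(self, rng):
        for _ in range(50):
            m = rng.normal(size=3)
            assert op.fold_change(m, (0, 1, 1)) == pytest.approx(
                -op.fold_change(m, (1, 0, 0)), rel=1e-12)

    def test_graded_axes_excluded(self):
        assert op.fold_change([4, 9, 0], (1, 0.5, 0)) == pytest.approx(4.0)

    def test_template_without_extremes_rejected(self):
        with pytest.raises(ValidationError, match="fold change"):
            op.fold_change([1, 2, 3], (0.5, 0.5, 1))


class TestClassifyAndGeneFilter:
    def test_recovery_and_partition_on_planted_data(self, small_run):
        results = small_run["results"]
        report = op.recovery_report(small_run["experiment"].truth,
                                    results.assignments)
        assert report.overall_recovery >= 0.95
        assert report.null_fp_rate <= 0.12
        assert report.complementary_confusions == 0
        assert results.group_counts().sum() == results.n_assigned

    def test_all_null_data_yields_few_significant(self):
        cfg = op.SimulationConfig(n_probes=3000, n_neg_controls=150,
                                  planted={}, unexpressed_fraction=0.0,
                                  seed=5)
        exp = op.simulate_experiment(cfg)
        m, ct = op.assemble_matrix(exp.scans, exp.sheet)
        log2m, _ = op.preprocess_pipeline(m, ct)
        res = op.ExpressionPatternModel(log2m, exp.sheet).fit()
        assert res.n_significant <= 0.01 * res.n_probes

    def test_summary_reports_counts(self, small_run):
        text = small_run["results"].summary()
        assert "significant probes" in text
        assert "ES high" in text

    @staticmethod
    def _assignment_row(probe, gene_q, fc, group="ES high"):
        return dict(probe_id=probe, mean_ES=1.0, mean_OS=0.0, mean_CSE=0.0,
                    F=10.0, p=1e-4, q=gene_q, significant=True,
                    assignable=True, template=group, r=1.0, log2_fc=fc,
                    group=group)

    def test_gene_filter_boundaries_are_strict(self):
        assignments = pd.DataFrame([
            self._assignment_row("p1", 0.04, 1.01),
            self._assignment_row("p2", 0.04, 1.00),
            self._assignment_row("p3", 0.05, 3.00),
        ])
        ann = op.AnnotationTable(pd.DataFrame({
            "probe_id": ["p1", "p2", "p3"],
            "gene_symbol": ["A", "B", "C"], "go_ids": ["", "", ""],
        }))
        tables = op.gene_level_filter(assignments, ann)
        kept = set(tables["ES high"]["gene_symbol"])
        assert kept == {"A"}        # fc 1.00 and q 0.05 both excluded

    def test_gene_collapsing_keeps_max_fc_probe(self):
        assignments = pd.DataFrame([
            self._assignment_row("p1", 0.01, 3.0),
            self._assignment_row("p2", 0.01, 5.0),
        ])
        ann = op.AnnotationTable(pd.DataFrame({
            "probe_id": ["p1", "p2"],
            "gene_symbol": ["A", "A"], "go_ids": ["", ""],
        }))
        tables = op.gene_level_filter(assignments, ann)
        table = tables["ES high"]
        assert len(table) == 1
        assert table.loc[0, "log2_fc"] == 5.0 and table.loc[0, "probe_id"] == "p2"

    def test_unannotated_probe_kept_under_probe_id(self):
        assignments = pd.DataFrame([self._assignment_row("pX", 0.01, 2.0)])
        ann = op.AnnotationTable(pd.DataFrame({
            "probe_id": ["p1"], "gene_symbol": ["A"], "go_ids": [""],
        }))
        tables = op.gene_level_filter(assignments, ann)
        assert list(tables["ES high"]["gene_symbol"]) == ["pX"]


class TestModelShape:
    def test_from_dataframe_constructor(self, rng):
        sheet = _sheet(2, 2, 2)
        df = pd.DataFrame(rng.normal(8, 1, size=(40, 6)),
                          index=[f"p{i}" for i in range(40)],
                          columns=sheet.sample_ids)
        results = op.ExpressionPatternModel.from_dataframe(df, sheet).fit()
        assert results.n_probes == 40
        assert {"F", "p", "q", "group"} <= set(results.assignments.columns)
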