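import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trnaterm.stats import (
    StatResult,
    build_counts_table,
    compare_groups,
    dunnett_critical_value,
    pmmr,
    write_report,
)


class TestPmmr:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(50, 1_000_000, 50.0), (0, 123, 0.0), (777, 777, 1e6)],
    )
    def test_values(self, count, total, expected):
        assert pmmr(count, total) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            pmmr(1, 0)

    def test_linearity(self, rng):
        for _ in range(20):
            a, b = rng.integers(0, 1000, size=2)
            t = int(rng.integers(1000, 10_000))
            assert pmmr(int(a) + int(b), t) == pytest.approx(
                pmmr(int(a), t) + pmmr(int(b), t))


def _tally_frame(rows):
    recs = []
    for cond, rep, key, n_cca, n_cc, n_other in rows:
        recs.append(dict(condition=cond, replicate=rep, level="group", key=key,
                         n_cca_added=n_cca, n_cc_terminating=n_cc,
                         n_other=n_other, n_total=n_cca + n_cc + n_other))
    return pd.DataFrame.from_records(recs)


class TestCountsTable:
    def test_single_library_percentages(self):
        t = _tally_frame([("c", 1, "OTHER", 95, 1, 4)])
        ct = build_counts_table(t, {("c", 1): 200})
        row = ct.iloc[0]
        assert row.pct_cca == pytest.approx(95.0)
        assert row.pct_cc == pytest.approx(1.0)
        assert row.pmmr_total == pytest.approx(1e6 * 100 / 200)

    def test_percentages_sum_to_100(self, rng):
        rows = [("c", r, g, *rng.integers(1, 500, size=3))
                for r in (1, 2) for g in ("CCA", "CC", "OTHER")]
        ct = build_counts_table(_tally_frame(rows), {("c", 1): 9999, ("c", 2): 888})
        assert np.allclose(ct.pct_cca + ct.pct_cc + ct.pct_other, 100.0)

    def test_scale_invariance_of_proportions(self):
        base = [("c", 1, "OTHER", 95, 1, 4)]
        doubled = [("c", 1, "OTHER", 190, 2, 8)]
        a = build_counts_table(_tally_frame(base), {("c", 1): 100})
        b = build_counts_table(_tally_frame(doubled), {("c", 1): 200})
        for col in ("pct_cca", "pct_cc", "pct_other"):
            assert a[col].iloc[0] == pytest.approx(b[col].iloc[0])

    def test_empty_group_is_null_not_zero(self):
        ct = build_counts_table(_tally_frame([("c", 1, "CC", 0, 0, 0)]),
                                {("c", 1): 10})
        assert np.isnan(ct.pct_cca.iloc[0])

    def test_label_collision_rejected(self):
        t = pd.concat([_tally_frame([("c", 1, "CC", 1, 1, 1)])] * 2)
        with pytest.raises(ValueError, match="collision"):
            build_counts_table(t, {("c", 1): 10})


class TestCompareGroups:
    def test_identical_groups_t_zero_p_one(self):
        res = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]}, "two_group")
        (r,) = res
        assert r.method == "t_test" and not r.adjusted
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_anova_f_matches_hand_computed_sums_of_squares(self):
        """Textbook three-group fixture: F from the direct SS decomposition."""
        groups = {"g1": [4.0, 5.0, 6.0], "g2": [6.0, 7.0, 8.0],
                  "g3": [9.0, 10.0, 14.0]}
        vals = np.concatenate(list(map(np.asarray, groups.values())))
        grand = vals.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2
                         for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                        for v in groups.values())
        f_hand = (ss_between / 2) / (ss_within / 6)
        res = compare_groups(groups, "vs_control", control="g1")
        anova = next(r for r in res if r.method == "anova")
        assert anova.statistic == pytest.approx(f_hand, abs=1e-10)

    def test_dunnett_adjusted_geq_unadjusted(self, rng):
        """Dunnett-adjusted p >= the unadjusted p of the same pooled-variance
        statistic, for every comparison (the price of simultaneity)."""
        for _ in range(5):
            groups = {
                "control": rng.normal(0, 1, 4),
                "t1": rng.normal(0.5, 1, 4),
                "t2": rng.normal(1.0, 1, 4),
            }
            res = compare_groups(groups, "vs_control", control="control")
            df = sum(len(v) for v in groups.values()) - len(groups)
            for r in res:
                if r.method != "dunnett":
                    continue
                p_raw = 2 * sps.t.sf(abs(r.statistic), df=df)
                assert r.adjusted
                assert r.p_value >= p_raw - 1e-9

    def test_tukey_kramer_all_pairs(self):
        groups = {"a": [1.0, 2, 3], "b": [2.0, 3, 4], "c": [8.0, 9, 10.5]}
        res = compare_groups(groups, "all_pairs")
        assert len(res) == 3
        assert all(r.method == "tukey_kramer" and r.adjusted for r in res)
        far = next(r for r in res if r.comparison == "a vs c")
        near = next(r for r in res if r.comparison == "a vs b")
        assert far.p_value < near.p_value

    @pytest.mark.parametrize(
        "groups,design,err",
        [
            ({"a": [1.0], "b": [1, 2]}, "two_group", "fewer than 2"),
            ({"a": [1.0, 1], "b": [2.0, 2]}, "two_group", "zero within-group"),
            ({"a": [1.0, 2], "b": [2.0, 3]}, "vs_control", "control"),
        ],
    )
    def test_input_validation(self, groups, design, err):
        with pytest.raises(ValueError, match=err):
            compare_groups(groups, design)

    def test_dunnett_critical_value_matches_scipy_pvalue(self, rng):
        """Dual route: at the critical value derived from the multivariate-t
        rectangle probability, scipy's Dunnett p-value is ~alpha."""
        c = dunnett_critical_value(n_treatment=2, n_per_group=3, alpha=0.05)
        # build a balanced dataset whose max |t| equals c: control mean 0,
        # one treatment shifted so its statistic is exactly c
        control = np.array([-1.0, 0.0, 1.0])
        s2 = 1.0  # pooled variance of three identical-shape groups
        shift = c * np.sqrt(s2 * 2 / 3)
        t1 = control + shift
        t2 = control.copy()
        res = sps.dunnett(t1, t2, control=control, rng=np.random.default_rng(0))
        assert min(res.pvalue) == pytest.approx(0.05, abs=0.005)


class TestWriteReport:
    def test_roundtrip_and_schema(self, tmp_path):
        ct = build_counts_table(
            _tally_frame([("c", 1, "OTHER", 95, 1, 4), ("c", 1, "CCA", 5, 1, 0),
                          ("t", 1, "OTHER", 80, 10, 10)]),
            {("c", 1): 1000, ("t", 1): 2000},
        )
        res = [StatResult("t_test", "c vs t", 1.5, 0.2, False)]
        paths = write_report(ct, res, tmp_path / "report")
        back = pd.read_csv(paths["counts"], sep="\t")
        pd.testing.assert_frame_equal(back, ct, check_dtype=False)
        with open(paths["summary"]) as fh:
            summary = json.load(fh)
        assert summary["schema_version"] == 1
        for cond, keys in summary["percent_triples"].items():
            for triple in keys.values():
                assert sum(triple.values()) == pytest.approx(100.0, abs=1e-9)
        assert summary["stat_results"][0]["method"] == "t_test"
        assert summary["stat_results"][0]["adjusted"] is False

    def test_p_value_bounds_enforced(self):
        with pytest.raises(ValueError):
            StatResult("t_test", "x", 0.0, 1.5, False)
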