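"""QC filtering rules and nonparametric statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliatrace import qc
from gliatrace._brute import dunn_z_brute, ecdf_ks_d


def _table(values, metric="total_filament_length_um", **extra):
    n = len(values)
    base = {
        "cell_id": [f"c{i}" for i in range(n)],
        "animal_id": ["a0"] * n,
        "group": ["g"] * n,
        "total_filament_length_um": 100.0,
        "sholl_sum": 50,
        "sphericity": 0.8,
        "hull_volume_um3": 1000.0,
        "nucleus_ok": True,
        "hull_degenerate": False,
    }
    df = pd.DataFrame(base)
    df[metric] = values
    for k, v in extra.items():
        df[k] = v
    return df


class TestPercentileFilter:
    def test_twenty_cell_fixture_retains_eighteen(self):
        # metric 1..20: interpolated P10 = 2.9, cells 1 and 2 strictly below
        df = _table(list(range(1, 21)))
        out = qc.percentile_filter(df)
        assert len(out) == 18
        assert set(out["total_filament_length_um"]) == set(range(3, 21))

    def test_identical_metrics_all_retained(self):
        df = _table([7.0] * 15)
        assert len(qc.percentile_filter(df)) == 15

    def test_nucleus_clipped_cells_always_excluded(self):
        df = _table(list(range(1, 21)), nucleus_ok=[False] * 2 + [True] * 18)
        out = qc.percentile_filter(df)
        assert not set(df.loc[~df.nucleus_ok, "cell_id"]) & set(out["cell_id"])

    def test_degenerate_hull_cells_excluded(self):
        df = _table([10.0] * 10, hull_degenerate=[True] + [False] * 9)
        out = qc.percentile_filter(df)
        assert "c0" not in set(out["cell_id"])

    def test_union_rule_across_metrics(self):
        # two metrics anti-correlated: union removes the low tail of each
        df = _table(list(range(1, 21)))
        df["sholl_sum"] = list(range(20, 0, -1))
        out = qc.percentile_filter(df)
        assert len(out) == 16  # 2 cells lost per metric, disjoint sets

    def test_scope_computes_cohort_cutoffs(self):
        df = pd.concat(
            [
                _table(list(range(1, 21)), model="m1", age="P10"),
                _table([x + 100 for x in range(1, 21)], model="m1", age="P18"),
            ],
            ignore_index=True,
        )
        out = qc.percentile_filter(df)
        # each cohort loses its own two lowest cells
        assert len(out) == 36

    def test_missing_metric_rejected(self):
        df = _table([1.0, 2.0]).drop(columns=["sholl_sum"])
        with pytest.raises(KeyError):
            qc.percentile_filter(df)

    def test_empty_table(self):
        df = _table([]).iloc[:0]
        assert qc.percentile_filter(df).empty

    def test_removal_fraction_bounds_on_continuous_data(self):
        rng = np.random.default_rng(0)
        n = 400
        df = _table(rng.normal(100, 10, n))
        df["sholl_sum"] = rng.normal(50, 5, n)
        df["sphericity"] = rng.uniform(0.5, 1.0, n)
        df["hull_volume_um3"] = rng.lognormal(7, 0.5, n)
        kept = len(qc.percentile_filter(df))
        removed = (n - kept) / n
        assert 0.10 <= removed <= 0.40
        # perfectly rank-correlated metrics: exactly the shared bottom 10%
        vals = np.sort(rng.normal(100, 10, n))
        df2 = _table(vals)
        for m in ("sholl_sum", "sphericity", "hull_volume_um3"):
            df2[m] = vals
        assert len(qc.percentile_filter(df2)) == n - int(np.ceil(0.10 * (n - 1)))


class TestPerAnimalSummary:
    def test_mean_of_two_cells(self):
        df = _table([10.0, 20.0])
        out = qc.per_animal_summary(df)
        assert len(out) == 1
        assert out.loc[0, "total_filament_length_um"] == pytest.approx(15.0)
        assert out.loc[0, "n_cells"] == 2

    def test_counts_match_rows(self):
        df = pd.concat(
            [_table([1.0] * 4), _table([2.0] * 7)], ignore_index=True
        )
        df.loc[4:, "animal_id"] = "a1"
        out = qc.per_animal_summary(df).set_index("animal_id")
        assert out.loc["a0", "n_cells"] == 4
        assert out.loc["a1", "n_cells"] == 7

    def test_one_row_per_animal_in_cohort(self):
        frames = []
        for g in ("sham", "treat"):
            for a in range(3):
                f = _table([float(a)] * 5)
                f["animal_id"] = f"{g}{a}"
                f["group"] = g
                frames.append(f)
        out = qc.per_animal_summary(pd.concat(frames, ignore_index=True))
        assert len(out) == 6
        assert sorted(out["group"].unique()) == ["sham", "treat"]


class TestMannWhitney:
    def test_disjoint_small_samples_exact(self):
        c = qc.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert c.statistic == 0.0
        assert c.p_value == pytest.approx(0.1)

    def test_identical_samples_symmetric(self):
        c = qc.mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert c.statistic == pytest.approx(8.0)  # n^2 / 2
        assert c.p_value >= 0.99

    def test_swap_antisymmetry(self):
        x, y = [1.0, 5.0, 9.0, 11.0], [2.0, 3.0, 12.0]
        a = qc.mann_whitney_u(x, y)
        b = qc.mann_whitney_u(y, x)
        assert a.p_value == pytest.approx(b.p_value)
        assert b.statistic == pytest.approx(len(x) * len(y) - a.statistic)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            qc.mann_whitney_u([], [1.0])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 99999))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(0.5, size=9)
        a = qc.mann_whitney_u(x, y)
        b = qc.mann_whitney_u(np.exp(x), np.exp(y))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        c = qc.kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        # rank sums {6, 15, 24}: H = 12/(9*10) * (36+225+576)/3 - 3*10 = 7.2
        assert c.statistic == pytest.approx(7.2)
        assert c.df == 2

    def test_two_groups_consistent_with_mann_whitney(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(0.7, size=25)
        kw = qc.kruskal_wallis({"x": x, "y": y})
        mw = qc.mann_whitney_u(x, y)
        assert kw.p_value == pytest.approx(mw.p_value, abs=0.01)

    def test_group_order_invariance(self):
        g = {"a": [1.0, 5.0], "b": [2.0, 9.0], "c": [3.0, 4.0]}
        h1 = qc.kruskal_wallis(g).statistic
        h2 = qc.kruskal_wallis(dict(reversed(list(g.items())))).statistic
        assert h1 == pytest.approx(h2)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            qc.kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0]})


class TestDunn:
    def test_identical_groups_z_zero_p_one(self):
        out = qc.dunn_posthoc(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, [("a", "b")]
        )
        assert out[0].statistic == pytest.approx(0.0)
        assert out[0].adjusted_p == 1.0

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(size=10) for k in "abcd"}
        pairs = list(itertools.combinations("abcd", 2))[:4]
        out = qc.dunn_posthoc(groups, pairs)
        for c in out:
            assert c.adjusted_p <= 1.0
            assert c.adjusted_p == pytest.approx(min(1.0, 4 * c.p_value))
            assert c.adjusted_p >= c.p_value

    def test_z_matches_brute_force_ranks(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        out = qc.dunn_posthoc(groups, [("a", "c")])
        pooled = [*groups["a"], *groups["b"], *groups["c"]]
        assert out[0].statistic == pytest.approx(
            dunn_z_brute(groups["a"], groups["c"], pooled)
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            qc.dunn_posthoc({"a": [1.0], "b": [2.0]}, [("a", "z")])


class TestKsSholl:
    def test_identical_profiles_d_zero(self):
        prof = [{1.0: 2, 2.0: 1}, {1.0: 1, 3.0: 4}]
        c = qc.ks_sholl(prof, [dict(p) for p in prof])
        assert c.statistic == 0.0

    def test_disjoint_supports_d_one(self):
        a = [{1.0: 3, 5.0: 2}]
        b = [{6.0: 1, 9.0: 4}]
        assert qc.ks_sholl(a, b).statistic == 1.0

    def test_matches_ecdf_oracle(self):
        a = [{1.0: 2, 2.0: 3, 4.0: 1}]
        b = [{1.0: 1, 3.0: 2, 4.0: 2, 6.0: 1}]
        xa = [1, 1, 2, 2, 2, 4]
        xb = [1, 3, 3, 4, 4, 6]
        assert qc.ks_sholl(a, b).statistic == pytest.approx(ecdf_ks_d(xa, xb))

    def test_zero_intersection_group_rejected(self):
        with pytest.raises(ValueError):
            qc.ks_sholl([{}], [{1.0: 1}])


class TestShollGroupCurve:
    def test_single_cell_curve_is_profile_with_zero_sem(self):
        prof = {1.0: 3, 2.0: 1, 4.0: 2}
        out = qc.sholl_group_curve([prof])
        assert list(out["radius_um"]) == [1.0, 2.0, 3.0, 4.0]
        assert list(out["mean"]) == [3, 1, 0, 2]
        assert (out["sem"] == 0).all()

    def test_two_identical_cells_zero_sem(self):
        prof = {1.0: 3, 2.0: 1}
        out = qc.sholl_group_curve([prof, dict(prof)])
        assert (out["sem"] == 0).all()
        assert list(out["mean"]) == [3, 1]

    def test_group_separation_on_synthetic_presets(self):
        from gliatrace.synthetic import morphology_preset, sample_tree
        from gliatrace.morphometry import sholl_profile

        rng = np.random.default_rng(4)
        amoe = [
            sholl_profile(sample_tree(morphology_preset("ameboid"), (30, 40, 40), rng))
            for _ in range(25)
        ]
        surv = [
            sholl_profile(
                sample_tree(morphology_preset("surveillance"), (30, 40, 40), rng)
            )
            for _ in range(25)
        ]
        ca = qc.sholl_group_curve(amoe).set_index("radius_um")["mean"]
        cs = qc.sholl_group_curve(surv).set_index("radius_um")["mean"]
        # surveillance cells keep branching far beyond the ameboid reach
        mid = [r for r in cs.index if 12 <= r <= 25]
        assert all(cs[r] > ca.get(r, 0.0) for r in mid)
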