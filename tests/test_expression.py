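"""Count normalisation, response calling and direct-target logic."""

import numpy as np
import pandas as pd
import pytest

from valleycall import simulate as sim
from valleycall.expression import (
    CountTable,
    classify_direct,
    enhancer_expression_test,
    normalize,
    respond,
    venn_overlap,
)


def build_table(endog, conditions=("CNT", "FGF"), reps=3, pos=500.0, hk=800.0, neg=5.0):
    """Hand-built table: ``endog`` maps probe -> {condition: mean count}."""
    samples, conds = [], []
    for c in conditions:
        for r in range(1, reps + 1):
            samples.append(f"{c}:{r}")
            conds.append(c)
    rows, classes = {}, {}
    for probe, per_cond in endog.items():
        rows[probe] = [float(per_cond[c]) for c in conds]
        classes[probe] = "endogenous"
    for i in range(3):
        rows[f"POS_{i}"] = [pos * (i + 1)] * len(samples)
        classes[f"POS_{i}"] = "positive"
        rows[f"NEG_{i}"] = [neg] * len(samples)
        classes[f"NEG_{i}"] = "negative"
        rows[f"HK_{i}"] = [hk] * len(samples)
        classes[f"HK_{i}"] = "housekeeping"
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return CountTable(
        counts,
        pd.Series(classes),
        pd.Series(conds, index=samples),
        pd.Series([int(s.split(":")[1]) for s in samples], index=samples),
    )


class TestCountTableIO:
    def test_tsv_round_trip(self, tmp_path):
        table, _ = sim.simulate_counts(seed=1)
        path = tmp_path / "c.tsv"
        table.to_tsv(path)
        back = CountTable.from_tsv(path)
        assert np.allclose(back.counts.values, table.counts.values)
        assert (back.probe_class == table.probe_class).all()
        assert (back.condition == table.condition).all()


class TestNormalize:
    def test_identical_samples_unchanged(self):
        t = build_table({"p1": {"CNT": 100, "FGF": 100}})
        n = normalize(t, background_subtraction=False)
        assert np.allclose(n.counts.values, t.counts.values)

    def test_doubled_sample_restored(self):
        t = build_table({"p1": {"CNT": 100, "FGF": 100}})
        doubled = t.counts.copy()
        doubled.iloc[:, 0] *= 2.0
        t2 = CountTable(doubled, t.probe_class, t.condition, t.replicate)
        n = normalize(t2, background_subtraction=False)
        # the doubled lane's combined factor is 0.5 -> equality restored
        assert np.allclose(n.counts.iloc[:, 0], n.counts.iloc[:, 1], rtol=1e-6)

    def test_missing_probe_class_named(self):
        t = build_table({"p1": {"CNT": 10, "FGF": 10}})
        stripped = CountTable(
            t.counts[~t.probe_class.eq("positive")],
            t.probe_class[~t.probe_class.eq("positive")],
            t.condition,
            t.replicate,
        )
        with pytest.raises(ValueError, match="positive"):
            normalize(stripped)

    def test_lane_effect_cv_reduced(self):
        table, _ = sim.simulate_counts(seed=3)
        hk = table.probes_of("housekeeping")
        before = (table.counts.loc[hk].std(axis=1) / table.counts.loc[hk].mean(axis=1)).mean()
        n = normalize(table, background_subtraction=False)
        after = (n.counts.loc[hk].std(axis=1) / n.counts.loc[hk].mean(axis=1)).mean()
        assert after < before


class TestRespond:
    def test_boundary_fold_change_inclusive(self):
        # FC exactly 1.5 with tiny within-group noise -> call up at p<=alpha
        t = build_table(
            {"p1": {"CNT": 1000, "FGF": 1500}},
        )
        noisy = t.counts.copy().astype(float)
        noisy.loc["p1"] = [1000.4, 1000.0, 999.6, 1500.6, 1500.0, 1499.4]
        t = CountTable(noisy, t.probe_class, t.condition, t.replicate)
        r = respond(t, "FGF", "CNT", preset="figure")
        assert r.table.loc["p1", "fold_change"] == pytest.approx(1.5)
        assert r.table.loc["p1", "call"] == "up"

    def test_zero_variance_equal_means_unchanged(self):
        t = build_table({"p1": {"CNT": 500, "FGF": 500}})
        r = respond(t, "FGF", "CNT")
        assert r.table.loc["p1", "p_value"] == 1.0
        assert r.table.loc["p1", "call"] == "unchanged"

    def test_antisymmetric_under_swap(self):
        table, _ = sim.simulate_counts(seed=4)
        n = normalize(table)
        fwd = respond(n, "FGF", "CNT", use_fc_thresholds=False)
        rev = respond(n, "CNT", "FGF", use_fc_thresholds=False)
        assert np.allclose(fwd.table["fold_change"], 1 / rev.table["fold_change"])
        assert np.allclose(fwd.table["p_value"], rev.table["p_value"])
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert (rev.table["call"] == fwd.table["call"].map(flip)).all()

    def test_unknown_preset_rejected(self):
        t = build_table({"p1": {"CNT": 10, "FGF": 10}})
        with pytest.raises(ValueError, match="preset"):
            respond(t, "FGF", "CNT", preset="nope")

    def test_planted_induction_called(self, rng):
        # 4-fold induction, n=3, CV ~20%
        base = 1000.0
        t = build_table({"p1": {"CNT": base, "FGF": base}})
        vals = np.concatenate([
            base * (1 + 0.2 * rng.standard_normal(3)),
            4 * base * (1 + 0.2 * rng.standard_normal(3)),
        ])
        counts = t.counts.copy()
        counts.loc["p1"] = vals
        r = respond(CountTable(counts, t.probe_class, t.condition, t.replicate), "FGF", "CNT")
        assert r.table.loc["p1", "call"] == "up"


class TestClassifyDirect:
    def _resp(self, calls, treated="FGF", control="CNT"):
        df = pd.DataFrame(
            {"fold_change": 1.0, "p_value": 1.0, "call": pd.Series(calls)}
        )
        from valleycall.expression import ResponseTable

        return ResponseTable(df, treated, control, 1.5, 0.25, 0.05)

    def test_all_branches(self):
        probes = [f"p{i}" for i in range(6)]
        plain = self._resp(dict(zip(probes, ["up", "up", "down", "down", "unchanged", "unchanged"])))
        chx = self._resp(dict(zip(probes, ["up", "unchanged", "down", "up", "up", "unchanged"])))
        cls = classify_direct(plain, chx)
        assert cls.classes.tolist() == [
            "direct_up", "indirect_up", "direct_down", "indirect_down",
            "unresponsive", "unresponsive",
        ]
        assert cls.chx_only == ["p4"]

    def test_mismatched_universe_rejected(self):
        a = self._resp({"p1": "up"})
        b = self._resp({"p2": "up"})
        with pytest.raises(ValueError):
            classify_direct(a, b)


class TestVenn:
    def test_identical_tables_full_overlap(self):
        t = TestClassifyDirect()
        r = t._resp({"p1": "up", "p2": "down", "p3": "unchanged"})
        v = venn_overlap(r, r)
        assert v == {
            "up_common": 1, "up_only_1": 0, "up_only_2": 0,
            "down_common": 1, "down_only_1": 0, "down_only_2": 0,
        }

    def test_matches_set_oracle(self, rng):
        t = TestClassifyDirect()
        probes = [f"p{i}" for i in range(50)]
        for _ in range(20):
            c1 = dict(zip(probes, rng.choice(["up", "down", "unchanged"], 50)))
            c2 = dict(zip(probes, rng.choice(["up", "down", "unchanged"], 50)))
            v = venn_overlap(t._resp(c1), t._resp(c2))
            for d in ("up", "down"):
                s1 = {p for p, c in c1.items() if c == d}
                s2 = {p for p, c in c2.items() if c == d}
                assert v[f"{d}_common"] == len(s1 & s2)
                assert v[f"{d}_only_1"] == len(s1 - s2)
                assert v[f"{d}_only_2"] == len(s2 - s1)
                # conservation of set sizes
                assert v[f"{d}_common"] + v[f"{d}_only_1"] == len(s1)


class TestEnhancerExpression:
    def test_all_tied_gives_half(self):
        expr = pd.Series(1.0, index=[f"p{i}" for i in range(10)])
        res = enhancer_expression_test(expr, {"p0", "p1"})
        assert res["p_value"] == 0.5

    def test_shifted_group_detected(self, rng):
        vals = {f"p{i}": float(v) for i, v in enumerate(rng.normal(5, 1, 250))}
        with_enh = [f"p{i}" for i in range(50)]
        for p in with_enh:
            vals[p] += 2.0
        res = enhancer_expression_test(pd.Series(vals), with_enh)
        assert res["p_value"] < 0.01
        assert res["median_with"] > res["median_without"]

    def test_null_p_is_uniformish(self, rng):
        ps = []
        for _ in range(200):
            vals = pd.Series(rng.normal(0, 1, 60), index=[f"p{i}" for i in range(60)])
            ps.append(enhancer_expression_test(vals, [f"p{i}" for i in range(20)])["p_value"])
        assert 0.35 < np.mean(ps) < 0.65

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            enhancer_expression_test(pd.Series({"a": 1.0}), set())
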