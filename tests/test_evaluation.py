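"""Tests for metrics, splits, diagnostics and the ranking pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sorptionlab as sl
from sorptionlab.errors import DegenerateInputError, SchemaError, UnidentifiableError
from sorptionlab.evaluation import (
    EvalConfig,
    anova_lsd,
    anova_residual_checks,
    aw_tercile_groups,
    compact_letters,
    levene,
    ljung_box,
    make_splits,
    mre,
    r2_adj,
    run_pipeline,
)
from sorptionlab.fitting import fit_global
from sorptionlab.synthetic import IsothermDataset, NoiseModel, generate_isotherm


class TestMakeSplits:
    def test_exact_75_25_division(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "aw": rng.uniform(0.1, 0.8, 100), "temperature_c": 25.0,
            "method": "wet", "branch": "desorption",
            "replicate": np.arange(100), "xe": rng.uniform(0.05, 0.3, 100),
        })
        ds = IsothermDataset(df, provenance="measured")
        plan = make_splits(ds, n_iterations=3, train_fraction=0.75, seed=1,
                           stratify=False)
        for tr, va in plan:
            assert len(tr) == 75 and len(va) == 25
            assert sorted(np.concatenate([tr, va])) == list(range(100))

    def test_seed_determinism(self, noisy_dataset):
        a = make_splits(noisy_dataset, n_iterations=5, seed=4)
        b = make_splits(noisy_dataset, n_iterations=5, seed=4)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va, vb)

    def test_every_record_validated_at_least_once(self, noisy_dataset):
        # P(a record never lands in validation) = 0.75^100 ~ 3e-13
        plan = make_splits(noisy_dataset, n_iterations=100, seed=2)
        seen = np.zeros(len(noisy_dataset), dtype=bool)
        for _, va in plan:
            seen[va] = True
        assert seen.all()

    def test_stratification_keeps_every_cell(self, noisy_dataset):
        plan = make_splits(noisy_dataset, n_iterations=10, seed=3)
        df = noisy_dataset.frame
        from sorptionlab.fitting import canonical_order
        df = canonical_order(df)
        cells = df.groupby(["method", "branch", "temperature_c"]).ngroups
        for tr, _ in plan:
            sub = df.iloc[tr]
            assert sub.groupby(["method", "branch", "temperature_c"]).ngroups == cells

    def test_bad_fraction(self, noisy_dataset):
        with pytest.raises(SchemaError):
            make_splits(noisy_dataset, train_fraction=1.0)

    def test_tiny_dataset_rejected(self):
        df = pd.DataFrame({
            "aw": [0.2, 0.3], "temperature_c": 25.0, "method": "wet",
            "branch": "desorption", "replicate": [1, 2], "xe": [0.1, 0.12]})
        with pytest.raises(SchemaError):
            make_splits(IsothermDataset(df, provenance="measured"))


class TestMre:
    def test_zero_for_identical(self):
        assert mre([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 0.0

    def test_hand_value(self):
        # (100/2) * (|0.1-0.11|/0.1 + |0.2-0.18|/0.2) = 50 * (0.1 + 0.1)
        assert mre([0.1, 0.2], [0.11, 0.18]) == pytest.approx(10.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(c=st.floats(1e-3, 1e3), seed=st.integers(0, 2**16))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0.05, 0.5, 20)
        p = y * rng.uniform(0.8, 1.2, 20)
        assert mre(c * y, c * p) == pytest.approx(mre(y, p), rel=1e-9)

    def test_zero_observation_rejected(self):
        with pytest.raises(DegenerateInputError):
            mre([0.1, 0.0], [0.1, 0.1])


class TestR2Adj:
    def test_perfect_prediction(self):
        r2, adj = r2_adj([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], m=2)
        assert r2 == 100.0 and adj == 100.0

    def test_hand_values(self):
        # SSE = 1, SST = 2 -> R2 = 50%; with M=2, N=3: adj = 100 - 2*50 = 0
        r2, adj = r2_adj([1, 2, 3], [1, 2, 4], m=1)
        assert r2 == pytest.approx(50.0, abs=1e-12)
        r2, adj = r2_adj([1, 2, 3], [1, 2, 4], m=2)
        assert r2 == pytest.approx(50.0, abs=1e-12)
        assert adj == pytest.approx(0.0, abs=1e-12)

    def test_adjusted_below_r2_for_m_above_one(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0.1, 0.4, 30)
        p = y + rng.normal(0, 0.01, 30)
        r2, adj = r2_adj(y, p, m=3)
        assert adj < r2

    def test_degrees_of_freedom_error(self):
        with pytest.raises(DegenerateInputError):
            r2_adj([1, 2], [1, 2], m=2)

    def test_as_printed_denominator(self):
        y = np.array([1.0, 2.0, 3.0])
        p = np.array([1.1, 2.2, 2.7])
        r2, _ = r2_adj(y, p, m=1, denominator="as_printed")
        sse = np.sum((y - p) ** 2)
        alt = np.sum((y.mean() - p) ** 2)
        assert r2 == pytest.approx(100 * (1 - sse / alt), abs=1e-12)


class TestLjungBox:
    def test_ar1_power(self):
        rejections = 0
        strong = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            e = rng.normal(0, 1, 200)
            x = np.zeros(200)
            for i in range(1, 200):
                x[i] = 0.9 * x[i - 1] + e[i]
            p = ljung_box(x)
            rejections += p < 0.05
            strong += p < 0.001
        assert strong >= 99

    def test_white_noise_size(self):
        hits = 0
        n_runs = 400
        for seed in range(n_runs):
            rng = np.random.default_rng(10_000 + seed)
            hits += ljung_box(rng.normal(0, 1, 500)) < 0.05
        assert 0.02 <= hits / n_runs <= 0.08

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ljung_box(np.zeros(100))

    def test_default_lag_rule(self):
        # min(10, N // 5) must keep tiny series workable
        rng = np.random.default_rng(0)
        assert 0 <= ljung_box(rng.normal(0, 1, 12)) <= 1


class TestLevene:
    def test_variance_ratio_power(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 3.0, 100)
        b = rng.normal(0, 1.0, 100)
        resid = np.concatenate([a, b])
        groups = np.array(["a"] * 100 + ["b"] * 100)
        assert levene(resid, groups) < 0.01

    def test_nominal_size(self):
        hits = 0
        n_runs = 400
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            resid = rng.normal(0, 1, 120)
            groups = np.repeat(["a", "b", "c"], 40)
            hits += levene(resid, groups) < 0.05
        assert 0.02 <= hits / n_runs <= 0.08

    def test_tiny_group_rejected(self):
        resid = np.arange(51, dtype=float)
        groups = np.array(["a"] + ["b"] * 50)
        with pytest.raises(DegenerateInputError):
            levene(resid, groups)

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            levene(np.arange(10, dtype=float), np.zeros(10))

    def test_tercile_grouping(self):
        aw = np.linspace(0.1, 0.85, 99)
        g = aw_tercile_groups(aw)
        assert set(g) == {"low", "mid", "high"}
        assert (g == "low").sum() == 33


def _metric_table(means, sd=0.2, n_iter=100, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for name, mu in means.items():
        for it in range(n_iter):
            rows.append({"model": name, "iteration": it, "subset": "validation",
                         "mre_pct": mu + rng.normal(0, sd),
                         "r2adj_pct": 100 - mu + rng.normal(0, sd)})
    return pd.DataFrame(rows)


class TestAnovaLsd:
    def test_identical_models_share_letter(self):
        base = _metric_table({"A": 3.0}, n_iter=50)
        dup = base.assign(model="B")
        ranking = anova_lsd(pd.concat([base, dup], ignore_index=True))
        t = ranking.table
        assert t.mre_pct_letter.nunique() == 1
        assert ranking.anova["mre_pct"]["model_F"] == pytest.approx(0.0, abs=1e-12)

    def test_large_offset_separates_letters(self):
        ranking = anova_lsd(_metric_table({"A": 3.0, "B": 8.0}, sd=0.2))
        t = ranking.table.set_index("model")
        assert t.loc["A", "mre_pct_letter"] != t.loc["B", "mre_pct_letter"]
        assert t.loc["A", "rank"] == 1

    def test_letters_match_brute_force_pairwise(self):
        # derived oracle: all-pairs LSD verdicts recomputed from scratch
        means = {"A": 3.0, "B": 3.05, "C": 3.5, "D": 5.0, "E": 5.02}
        metrics = _metric_table(means, sd=0.3, seed=7)
        ranking = anova_lsd(metrics)
        t = ranking.table.set_index("model")
        lsd = ranking.lsd["mre_pct"]
        series = {m: metrics[metrics.model == m].mre_pct.to_numpy() for m in means}
        for a in means:
            for b in means:
                if a >= b:
                    continue
                differ = abs(series[a].mean() - series[b].mean()) > lsd
                shared = set(t.loc[a, "mre_pct_letter"]) & set(t.loc[b, "mre_pct_letter"])
                assert differ == (not shared)

    def test_order_independence(self):
        metrics = _metric_table({"A": 3.0, "B": 4.0, "C": 3.2}, seed=3)
        shuffled = metrics.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = anova_lsd(metrics).table
        b = anova_lsd(shuffled).table
        pd.testing.assert_frame_equal(
            a.sort_values("model").reset_index(drop=True),
            b.sort_values("model").reset_index(drop=True))

    def test_aggregation_reproduces_raw_table(self):
        metrics = _metric_table({"A": 3.0, "B": 4.0}, seed=11)
        t = anova_lsd(metrics).table.set_index("model")
        for m in ("A", "B"):
            raw = metrics[metrics.model == m].mre_pct
            assert t.loc[m, "mre_pct_mean"] == pytest.approx(raw.mean())
            assert t.loc[m, "mre_pct_se"] == pytest.approx(
                raw.std(ddof=1) / np.sqrt(len(raw)))

    def test_single_model_rejected(self):
        with pytest.raises(SchemaError):
            anova_lsd(_metric_table({"A": 3.0}))

    def test_unbalanced_rejected(self):
        metrics = _metric_table({"A": 3.0, "B": 4.0})
        with pytest.raises(SchemaError):
            anova_lsd(metrics.iloc[:-1])

    def test_compact_letters_chain(self):
        # A~B, B~C significant only A vs C: expect letters ab / a b pattern
        means = np.array([0.0, 1.0, 2.0])
        sig = np.array([[False, False, True],
                        [False, False, False],
                        [True, False, False]])
        letters = compact_letters(means, sig, np.array([0, 1, 2]))
        assert set(letters[0]) & set(letters[1])
        assert set(letters[1]) & set(letters[2])
        assert not set(letters[0]) & set(letters[2])


class TestAnovaResidualChecks:
    def test_gaussian_null_passes(self):
        rng = np.random.default_rng(12)
        resid = rng.normal(0, 1, 400)
        factors = pd.DataFrame({"model": np.repeat(["A", "B", "C", "D"], 100),
                                "iteration": np.tile(np.arange(100), 4)})
        rep = anova_residual_checks(resid, factors=factors)
        assert rep["normal_ok"] and rep["independent_ok"] and rep["homoscedastic_ok"]

    def test_variance_trend_detected(self):
        rng = np.random.default_rng(13)
        scale = np.linspace(0.5, 3.0, 300)
        resid = rng.normal(0, 1, 300) * scale
        factors = pd.DataFrame({"iteration": np.arange(300, dtype=float)})
        rep = anova_residual_checks(resid, factors=factors)
        assert rep["mlr_p"] < 0.05
        assert not rep["homoscedastic_ok"]

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            anova_residual_checks(np.array([0.1, 0.2]))


class TestRunPipeline:
    def test_true_model_no_overfit_gap(self, sigmoid_truth):
        # triplicates (as in the DDI protocol) keep the in-sample optimism
        # of the correctly specified model well below the split noise
        from sorptionlab.synthetic import Design
        spec, truth = sigmoid_truth
        ds = generate_isotherm(spec, truth, Design(replicates=3),
                               NoiseModel(sd=0.002, seed=6))
        plan = make_splits(ds, n_iterations=20, seed=6)
        out = run_pipeline(ds, ["GAB", "Oswin"], plan)
        m = out["metrics"]
        gab = m[m.model == "GAB"]
        tr = gab[gab.subset == "train"].mre_pct
        va = gab[gab.subset == "validation"].mre_pct
        se = np.sqrt(tr.std(ddof=1) ** 2 / len(tr) + va.std(ddof=1) ** 2 / len(va))
        assert abs(tr.mean() - va.mean()) <= 2 * se

    def test_duplicated_model_shares_letter(self, sigmoid_truth):
        spec, truth = sigmoid_truth
        ds = generate_isotherm(spec, truth, noise=NoiseModel(sd=0.002, seed=8))
        plan = make_splits(ds, n_iterations=4, seed=8)
        out = run_pipeline(ds, ["GAB", "GAB"], plan)
        t = out["ranking"].table.set_index("model")
        assert set(t.index) == {"GAB", "GAB#2"}
        m = out["metrics"]
        a = m[m.model == "GAB"].sort_values(["iteration", "subset"]).mre_pct.to_numpy()
        b = m[m.model == "GAB#2"].sort_values(["iteration", "subset"]).mre_pct.to_numpy()
        np.testing.assert_array_equal(a, b)
        assert t.loc["GAB", "mre_pct_letter"] == t.loc["GAB#2", "mre_pct_letter"]

    def test_noise_free_true_family_tops(self, clean_dataset):
        plan = make_splits(clean_dataset, n_iterations=4, seed=1)
        out = run_pipeline(clean_dataset, ["GAB", "Oswin"], plan)
        t = out["ranking"].table.set_index("model")
        assert t.loc["GAB", "mre_pct_mean"] < 1e-4  # exact-fit limit
        top_letter = t.loc[t["rank"].idxmin() if "rank" not in t.columns else t.index[t["rank"] == 1][0],
                           "mre_pct_letter"]
        assert set(top_letter) & set(t.loc["GAB", "mre_pct_letter"])

    def test_unknown_model_rejected(self, noisy_dataset):
        plan = make_splits(noisy_dataset, n_iterations=2, seed=0)
        with pytest.raises(SchemaError, match="BET"):
            run_pipeline(noisy_dataset, ["GAB", "BET"], plan)

    def test_single_model_rejected(self, noisy_dataset):
        plan = make_splits(noisy_dataset, n_iterations=2, seed=0)
        with pytest.raises((SchemaError, UnidentifiableError)):
            run_pipeline(noisy_dataset, ["GAB"], plan)


class TestGapShrinksWithNoise:
    def test_monotone_overfit_gap(self, sigmoid_truth):
        spec, truth = sigmoid_truth
        gaps = []
        for sd in (0.004, 0.002, 0.001, 0.0):
            kind = "gaussian-additive" if sd else "none"
            ds = generate_isotherm(spec, truth,
                                   noise=NoiseModel(kind=kind, sd=sd, seed=14))
            plan = make_splits(ds, n_iterations=5, seed=14)
            diffs = []
            for tr_idx, va_idx in plan:
                train = ds.subset(ds.frame.index.isin(tr_idx))
                val = ds.subset(ds.frame.index.isin(va_idx))
                fit = fit_global(spec, train)
                from sorptionlab.models import evaluate_model
                pt = evaluate_model(spec, fit.params, train.frame.aw.to_numpy(),
                                    temperature_c=train.frame.temperature_c.to_numpy(),
                                    d1=train.d1(), d2=train.d2())
                pv = evaluate_model(spec, fit.params, val.frame.aw.to_numpy(),
                                    temperature_c=val.frame.temperature_c.to_numpy(),
                                    d1=val.d1(), d2=val.d2())
                diffs.append(abs(mre(train.frame.xe.to_numpy(), pt)
                                 - mre(val.frame.xe.to_numpy(), pv)))
            gaps.append(np.mean(diffs))
        assert gaps[-1] < 1e-8  # exact at zero noise
        assert gaps[-1] <= gaps[0]
        assert all(g < 1.0 for g in gaps)
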