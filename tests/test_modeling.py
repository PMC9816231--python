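"""Split arithmetic, standardization, redundancy filter, RFE, models."""

import numpy as np
import pandas as pd
import pytest

from fetrad.modeling import (
    StratificationError,
    assemble_variant,
    build_signature,
    fit_lr,
    pcc_filter,
    rfe_select,
    standardize,
    stratified_split,
    train_pipeline,
)


def labels_with(n, n_pos, seed=0):
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    return np.random.default_rng(seed).permutation(y)


class TestSplit:
    def test_cohort_141_with_40_events(self):
        y = labels_with(141, 40)
        split = stratified_split(y, seed=1)
        is_train = split == "train"
        assert is_train.sum() == 99 and (~is_train).sum() == 42
        assert y[is_train].sum() == 28 and y[~is_train].sum() == 12
        # training short-term-survivor rate 28/99 = 28.3%
        assert round(100 * y[is_train].mean(), 1) == 28.3

    def test_small_cohort_split(self):
        y = labels_with(10, 5)
        split = stratified_split(y, train_fraction=0.7, seed=0)
        assert (split == "train").sum() == 7 and (split == "test").sum() == 3

    def test_prevalence_balance_across_splits(self):
        """Train/test event rates stay close over repeated simulated
        141-patient cohorts (two-sided proportion test never near-significant
        in the typical case)."""
        from scipy.stats import norm

        diffs, pvals = [], []
        for seed in range(20):
            y = labels_with(141, 40, seed=seed)
            split = stratified_split(y, seed=seed)
            tr, te = y[split == "train"], y[split == "test"]
            p1, p2 = tr.mean(), te.mean()
            diffs.append(abs(p1 - p2))
            pool = y.mean()
            se = np.sqrt(pool * (1 - pool) * (1 / len(tr) + 1 / len(te)))
            z = (p1 - p2) / se
            pvals.append(2 * norm.sf(abs(z)))
        # largest-remainder allocation caps the rate difference structurally
        assert max(diffs) < 0.02
        assert min(pvals) > 0.5

    def test_single_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_split(np.ones(20, dtype=int))

    def test_deterministic_per_seed(self):
        y = labels_with(50, 15)
        assert np.array_equal(stratified_split(y, seed=3), stratified_split(y, seed=3))
        assert not np.array_equal(stratified_split(y, seed=3), stratified_split(y, seed=4))


class TestStandardize:
    def test_population_sd_convention(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        out, params = standardize(train, train)
        assert np.allclose(out["f"], [-1.224744871, 0.0, 1.224744871])
        assert params.sd["f"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_test_value_at_training_mean_is_zero(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        both = pd.DataFrame({"f": [1.0, 2.0, 3.0, 2.0]})
        out, _ = standardize(train, both)
        assert out["f"].iloc[3] == 0.0

    def test_affine_preserves_order(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"f": rng.random(30)})
        out, _ = standardize(train, train)
        assert np.array_equal(np.argsort(out["f"].values), np.argsort(train["f"].values))

    def test_constant_feature_dropped(self):
        train = pd.DataFrame({"f": [1.0, 2.0], "c": [5.0, 5.0]})
        out, params = standardize(train, train)
        assert "c" not in out.columns
        assert params.dropped == ("c",)


class TestPCCFilter:
    def test_duplicate_removed_keeps_first(self, rng):
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.random(50)})
        assert pcc_filter(df) == ["a", "c"]

    def test_independent_columns_kept(self, rng):
        df = pd.DataFrame(rng.random((200, 4)), columns=list("abcd"))
        assert pcc_filter(df) == list("abcd")

    def test_pcc_exactly_at_threshold_kept(self):
        # r(a, b) = 0.5 exactly; threshold 0.5 is strict "larger than"
        a = np.array([1.0, 2.0, 3.0, 4.0] * 5)
        b = np.array([1.0, 3.0, 2.0, 4.0] * 5)
        r = np.corrcoef(a, b)[0, 1]
        df = pd.DataFrame({"a": a, "b": b})
        assert pcc_filter(df, threshold=r) == ["a", "b"]
        assert pcc_filter(df, threshold=r - 1e-12) == ["a"]

    def test_anticorrelated_removed(self, rng):
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "b": -x})
        assert pcc_filter(df) == ["a"]


class TestRFE:
    @staticmethod
    def _table(n, seed, informative_beta=2.5, n_noise=14):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, n_noise + 1))
        logits = informative_beta * x[:, 0] - 1.0
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        cols = ["signal"] + [f"noise{i}" for i in range(n_noise)]
        return pd.DataFrame(x, columns=cols), y

    def test_informative_feature_recovered(self):
        """The single informative feature survives selection in >= 95% of
        20 independent simulations (n = 200, strong effect)."""
        hits = 0
        for seed in range(20):
            table, y = self._table(200, seed)
            sel = rfe_select(table, y, table.columns, seed=seed)
            hits += "signal" in sel.selected
        assert hits >= 19

    def test_all_noise_auc_near_half(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.standard_normal((150, 10)),
                             columns=[f"n{i}" for i in range(10)])
        y = rng.integers(0, 2, 150)
        sel = rfe_select(table, y, table.columns, seed=5)
        for k, auc in sel.cv_auc_by_k.items():
            assert abs(auc - 0.5) < 0.1, (k, auc)

    def test_chosen_k_is_argmax_smallest_on_ties(self):
        table, y = self._table(120, 3)
        sel = rfe_select(table, y, table.columns, seed=3)
        best = max(sel.cv_auc_by_k.values())
        assert sel.cv_auc_by_k[sel.chosen_k] == best
        assert all(k >= sel.chosen_k for k, v in sel.cv_auc_by_k.items() if v == best)
        assert len(sel.selected) == sel.chosen_k
        assert set(sel.selected) <= set(sel.retained_after_pcc)

    def test_k_range_truncated_to_feature_count(self):
        table, y = self._table(80, 1, n_noise=4)
        sel = rfe_select(table, y, table.columns, k_range=range(1, 16), seed=1)
        assert max(sel.cv_auc_by_k) == 5


class TestLogisticModel:
    def test_balanced_class_weights_formula(self):
        from sklearn.utils.class_weight import compute_class_weight

        y = labels_with(99, 28)
        w = compute_class_weight("balanced", classes=np.array([0, 1]), y=y)
        assert w[1] == pytest.approx(99 / (2 * 28))
        assert w[0] == pytest.approx(99 / (2 * 71))
        # the balance identity w+ * n+ == w- * n-
        assert w[1] * 28 == pytest.approx(w[0] * 71)

    def test_separating_feature_coefficient_sign(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        y = (x > 0).astype(int)
        m = fit_lr(pd.DataFrame({"f": x}), y)
        assert m.coef[0] > 0
        p = m.predict_proba(pd.DataFrame({"f": x}))
        assert np.all((p > 0) & (p < 1))

    def test_single_class_rejected(self):
        with pytest.raises(StratificationError):
            fit_lr(pd.DataFrame({"f": [1.0, 2.0]}), [1, 1])

    def test_signature_is_linear_predictor(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"f": rng.standard_normal(60)})
        y = (df["f"] + rng.standard_normal(60) * 0.5 > 0).astype(int)
        m = fit_lr(df, y)
        sig = build_signature(m, df)
        from scipy.special import expit

        assert np.allclose(expit(sig), m.predict_proba(df))
        # one feature, coefficient c, intercept b: signature = b + c * x
        assert sig[0] == pytest.approx(m.intercept + m.coef[0] * df["f"].iloc[0])

    def test_signature_separates_groups_on_effect_cohort(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(300)
        y = (rng.random(300) < 1 / (1 + np.exp(-2.0 * x))).astype(int)
        df = pd.DataFrame({"f": x})
        sig = build_signature(fit_lr(df, y), df)
        from scipy.stats import mannwhitneyu

        assert mannwhitneyu(sig[y == 1], sig[y == 0]).pvalue < 1e-6


class TestVariants:
    @staticmethod
    def _cohort(n=80, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "age": rng.normal(58, 13, n).round(1),
            "gender": rng.integers(0, 2, n),
            "kps": rng.choice(range(40, 101, 10), n),
            "who_grade": rng.choice([3, 4], n),
            "mgmt": rng.integers(0, 2, n),
            "tertp": rng.integers(0, 2, n),
        })
        for i in range(4):
            df[f"TBR_f{i}"] = rng.standard_normal(n)
            df[f"TTP_f{i}"] = rng.standard_normal(n)
        df["sts_label"] = (rng.random(n) < 1 / (1 + np.exp(-df["TTP_f0"]))).astype(int)
        return df

    def test_variant_column_counts(self):
        df = self._cohort()
        sig = np.zeros(len(df))
        assert assemble_variant("clinical", df).shape[1] == 6
        assert assemble_variant(
            "clinical-TBR-TTP", df, signature_tbr=sig, signature_ttp=sig).shape[1] == 8
        assert assemble_variant("clinical-TTP", df, signature_ttp=sig).shape[1] == 7
        assert assemble_variant("TBR-TTP", df, signature_tbr=sig,
                                signature_ttp=sig).shape[1] == 2
        assert assemble_variant("TTP", df, selected_ttp=["TTP_f0", "TTP_f1"]).shape[1] == 2

    def test_missing_signature_raises(self):
        from fetrad.modeling import SchemaError

        with pytest.raises(SchemaError):
            assemble_variant("clinical-TTP", self._cohort())

    def test_no_leakage_bit_identical(self):
        """Deleting the test rows before any fitting leaves every trained
        parameter bit-identical."""
        df = self._cohort(n=100, seed=7)
        split = stratified_split(df["sts_label"].to_numpy(), seed=7)
        full = train_pipeline(
            df, ttp_columns=[c for c in df if c.startswith("TTP_")],
            variants=("clinical", "TTP", "clinical-TTP"), seed=7, split=split,
            k_range=range(1, 5),
        )
        train_only = df.loc[split == "train"].reset_index(drop=True)
        reduced = train_pipeline(
            train_only, ttp_columns=[c for c in df if c.startswith("TTP_")],
            variants=("clinical", "TTP", "clinical-TTP"), seed=7,
            split=np.full(len(train_only), "train", dtype=object),
            k_range=range(1, 5),
        )
        assert full.selection["TTP"].selected == reduced.selection["TTP"].selected
        assert full.selection["TTP"].cv_auc_by_k == reduced.selection["TTP"].cv_auc_by_k
        for variant in ("clinical", "TTP", "clinical-TTP"):
            a, b = full.models[variant], reduced.models[variant]
            assert np.array_equal(a.coef, b.coef)
            assert a.intercept == b.intercept
        pd.testing.assert_series_equal(full.standardization.mean,
                                       reduced.standardization.mean)

    def test_pipeline_reproducible_per_seed(self):
        df = self._cohort(n=90, seed=3)
        kw = dict(ttp_columns=[c for c in df if c.startswith("TTP_")],
                  variants=("clinical", "TTP", "clinical-TTP"), k_range=range(1, 5))
        r1 = train_pipeline(df, seed=11, **kw)
        r2 = train_pipeline(df, seed=11, **kw)
        assert r1.selection["TTP"].selected == r2.selection["TTP"].selected
        for v in r1.models:
            assert np.array_equal(r1.models[v].coef, r2.models[v].coef)
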