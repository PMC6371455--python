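"""Splicing-category assignment, prediction, switches, and contrasts."""

import numpy as np
import pandas as pd
import pytest

from scsplice import categories as cat


class TestDispersionFit:
    def test_noiseless_scale_recovered(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 200)
        sd = 0.4 * np.sqrt(p * (1 - p))
        fit = cat.fit_expected_dispersion(p, sd)
        assert fit.scale == pytest.approx(0.4, abs=1e-6)

    def test_all_zero_sd_gives_zero_scale(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.25, 0.75, 50)
        fit = cat.fit_expected_dispersion(p, np.zeros(50))
        assert fit.scale == 0.0

    def test_normal_equations_satisfied(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 300)
        sd = 0.3 * np.sqrt(p * (1 - p)) + 0.05 * rng.normal(size=300)
        fit = cat.fit_expected_dispersion(p, sd)
        x = np.sqrt(p * (1 - p))
        resid = sd - fit.scale * x
        assert abs(np.sum(resid * x)) < 1e-8

    def test_too_few_intermediate_exons_rejected(self):
        p = np.array([0.05, 0.95, 0.5])
        with pytest.raises(ValueError):
            cat.fit_expected_dispersion(p, np.full(3, 0.1))


def _summary(bpsi, sd):
    return pd.DataFrame({"bpsi": bpsi, "psi_sd": sd},
                        index=[f"e{i}" for i in range(len(bpsi))])


@pytest.fixture(scope="module")
def reference_fit():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.25, 0.75, 100)
    sd = 0.4 * np.sqrt(p * (1 - p)) + 0.01 * rng.normal(size=100)
    return cat.fit_expected_dispersion(p, sd)


class TestAssignment:
    def test_mean_psi_bounds(self, reference_fit):
        out = cat.assign_categories(_summary([0.1, 0.9], [0.05, 0.05]),
                                    reference_fit)
        assert list(out["category"]) == ["excluded", "included"]

    def test_deviation_fences(self, reference_fit):
        fit = reference_fit
        base = 0.4 * np.sqrt(0.25)
        over_sd = base + fit.upper_threshold + 0.05
        under_sd = max(base + fit.lower_threshold - 0.05, 0.0)
        out = cat.assign_categories(
            _summary([0.5, 0.5, 0.5], [over_sd, under_sd, base]), fit)
        assert list(out["category"]) == ["overdispersed", "underdispersed",
                                         "multimodal"]

    def test_missing_sd_unassigned(self, reference_fit):
        out = cat.assign_categories(_summary([0.5], [np.nan]), reference_fit)
        assert out["category"].iloc[0] == "unassigned"

    def test_assignment_is_partition(self, reference_fit):
        rng = np.random.default_rng(4)
        out = cat.assign_categories(
            _summary(rng.uniform(0, 1, 500), rng.uniform(0, 0.5, 500)),
            reference_fit)
        assert set(out["category"]) <= set(cat.CATEGORIES) | {"unassigned"}
        assert out["category"].notna().all()

    def test_cell_model_exons_overdispersed_in_gene_background(self):
        """Exons whose SD follows the bimodal cell model stand out as
        overdispersed against a binomial-like background."""
        rng = np.random.default_rng(5)
        p_bg = rng.uniform(0.25, 0.75, 200)
        sd_bg = np.sqrt(p_bg * (1 - p_bg) / 20) + 0.01 * rng.normal(size=200)
        p_cm = rng.uniform(0.35, 0.65, 10)
        sd_cm = np.sqrt(p_cm * (1 - p_cm))
        p = np.concatenate([p_bg, p_cm])
        sd = np.clip(np.concatenate([sd_bg, sd_cm]), 0, None)
        fit = cat.fit_expected_dispersion(p, sd)
        out = cat.assign_categories(_summary(p, sd), fit)
        assert (out["category"].iloc[200:] == "overdispersed").all()


class TestClassifier:
    def _separable(self, n_per=40, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for k, category in enumerate(cat.CATEGORIES):
            for _ in range(n_per):
                rows.append(np.concatenate([[k + 0.05 * rng.normal()],
                                            rng.normal(size=4)]))
                labels.append(category)
        X = pd.DataFrame(rows, columns=[f"f{j}" for j in range(5)],
                         index=[f"e{i}" for i in range(len(rows))])
        return X, pd.Series(labels, index=X.index)

    def test_separable_categories_near_perfect_macro_auc(self):
        X, y = self._separable()
        res = cat.train_category_classifier(X, y, folds=5, repeats=2, seed=0)
        assert res.macro_auc >= 0.99

    def test_shuffled_labels_chance_macro_auc(self):
        X, y = self._separable(seed=1)
        rng = np.random.default_rng(2)
        y_shuf = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res = cat.train_category_classifier(X, y_shuf, folds=5, repeats=2, seed=0)
        assert res.macro_auc == pytest.approx(0.5, abs=0.05)

    def test_macro_is_unweighted_mean_of_per_category(self):
        X, y = self._separable(seed=3)
        res = cat.train_category_classifier(X, y, folds=5, repeats=2, seed=0)
        assert res.macro_auc == pytest.approx(
            res.per_category["auc_mean"].mean(), abs=1e-9)

    def test_binary_subproblem_reduction(self):
        X, y = self._separable(seed=4)
        keep = y.isin(["included", "excluded"])
        res = cat.train_category_classifier(X[keep], y[keep], folds=5,
                                            repeats=1, seed=0)
        aucs = res.per_category["auc_mean"]
        assert len(aucs) == 2
        # one-vs-rest of two classes collapses to the same binary problem
        assert aucs.iloc[0] == pytest.approx(aucs.iloc[1], abs=1e-9)

    def test_single_category_rejected(self):
        X, y = self._separable(seed=5)
        with pytest.raises(ValueError):
            cat.train_category_classifier(X, pd.Series("included", index=X.index))


def _assign(cats):
    return pd.DataFrame({"category": pd.Series(cats)})


class TestSwitchTable:
    def test_identical_assignments_fully_retained(self):
        a = _assign({f"e{i}": "included" for i in range(5)} |
                    {f"x{i}": "excluded" for i in range(5)})
        out = cat.category_switch_table(a, a)
        assert out["retained_fraction"] == 1.0
        t = out["table"].to_numpy()
        assert t.sum() - np.trace(t) == 0

    def test_two_switches_of_ten(self):
        a = _assign({f"e{i}": "multimodal" for i in range(10)})
        b_cats = {f"e{i}": "multimodal" for i in range(8)}
        b_cats["e8"] = "overdispersed"
        b_cats["e9"] = "included"
        out = cat.category_switch_table(a, _assign(b_cats))
        assert out["retained_fraction"] == pytest.approx(0.8)
        assert out["table"].to_numpy().sum() == out["n_shared"] == 10

    def test_empty_intersection_undefined(self):
        a = _assign({"e1": "included"})
        b = _assign({"x1": "included"})
        out = cat.category_switch_table(a, b)
        assert np.isnan(out["retained_fraction"])


class TestSwitchPrediction:
    def test_methylation_threshold_switching_is_learnable(self):
        rng = np.random.default_rng(6)
        n = 120
        meth = rng.uniform(0, 1, n)
        X = pd.DataFrame({
            "meth_mean_A": meth,
            **{f"g{j}": rng.normal(size=n) for j in range(5)},
        }, index=[f"e{i}" for i in range(n)])
        a = _assign({f"e{i}": "multimodal" for i in range(n)})
        b = _assign({f"e{i}": ("overdispersed" if meth[i] > 0.6 else "multimodal")
                     for i in range(n)})
        with_meth = cat.predict_category_switching(X, a, b, folds=5, repeats=2)
        without = cat.predict_category_switching(X.drop(columns="meth_mean_A"),
                                                 a, b, folds=5, repeats=2)
        assert with_meth.loc["multimodal", "auc_mean"] >= 0.9
        assert without.loc["multimodal", "auc_mean"] <= 0.7

    def test_shuffled_switch_labels_chance_auc(self):
        rng = np.random.default_rng(7)
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         index=[f"e{i}" for i in range(n)])
        a = _assign({f"e{i}": "multimodal" for i in range(n)})
        switch = rng.random(n) < 0.3
        b = _assign({f"e{i}": ("included" if switch[i] else "multimodal")
                     for i in range(n)})
        out = cat.predict_category_switching(X, a, b, folds=5, repeats=2)
        assert out.loc["multimodal", "auc_mean"] == pytest.approx(0.5, abs=0.12)

    def test_no_switchers_flagged_nan(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(20, 3)),
                         index=[f"e{i}" for i in range(20)])
        a = _assign({f"e{i}": "included" for i in range(20)})
        out = cat.predict_category_switching(X, a, a)
        assert np.isnan(out.loc["included", "auc_mean"])


class TestMethylationContrast:
    def _meth_table(self, n, seed, shift_rows=(), shift=0.0, ctx="C1"):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(n, 3)),
            columns=["C1", "A", "C2"],
            index=[f"e{i}" for i in range(n)])
        for r in shift_rows:
            df.loc[r, ctx] = np.clip(df.loc[r, ctx] + shift, 0, 1)
        return df

    def test_null_has_no_hits_beyond_chance(self):
        # category-vs-rest tests are dependent (complementary groups), so
        # allow for clustered false positives: the overall hit *rate* at
        # q < 0.05 stays near the nominal level across seeds
        hits = tests = 0
        for seed in range(5):
            meth = self._meth_table(100, seed)
            cats = pd.Series(
                np.repeat(["included", "excluded", "multimodal", "overdispersed"], 25),
                index=meth.index)
            out = cat.methylation_category_contrast(meth, _assign(cats.to_dict()))
            hits += int((out["q"] < 0.05).sum())
            tests += len(out)
        assert hits / tests <= 0.08

    def test_planted_shift_detected_with_sign(self):
        shift_rows = [f"e{i}" for i in range(50)]
        meth = self._meth_table(150, 9, shift_rows=shift_rows, shift=0.3, ctx="A")
        cats = {f"e{i}": ("underdispersed" if i < 50 else "multimodal")
                for i in range(150)}
        out = cat.methylation_category_contrast(meth, _assign(cats))
        hit = out[(out["category"] == "underdispersed") & (out["context"] == "A")]
        assert len(hit) == 1
        assert hit["q"].iloc[0] < 0.05
        assert hit["effect"].iloc[0] > 0

    def test_effect_antisymmetric_under_group_swap(self):
        meth = self._meth_table(60, 10, shift_rows=[f"e{i}" for i in range(30)],
                                shift=0.2, ctx="C1")
        cats_ab = {f"e{i}": ("included" if i < 30 else "excluded")
                   for i in range(60)}
        cats_ba = {f"e{i}": ("excluded" if i < 30 else "included")
                   for i in range(60)}
        out_ab = cat.methylation_category_contrast(meth, _assign(cats_ab))
        out_ba = cat.methylation_category_contrast(meth, _assign(cats_ba))

        def effect(out, category):
            sub = out[(out["category"] == category) & (out["context"] == "C1")]
            return sub["effect"].iloc[0]

        # swapping the group labels negates the included-vs-rest effect ...
        assert effect(out_ab, "included") == pytest.approx(
            -effect(out_ba, "included"))
        # ... and with two categories, excluded-vs-rest is its mirror image
        assert effect(out_ab, "included") == pytest.approx(
            -effect(out_ab, "excluded"))
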