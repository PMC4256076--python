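import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyver.benchmark_eval import (
    accuracy_auc,
    classify_outcomes,
    collapse_pattern,
    expression_dynamics_test,
    naive_min_anova,
    pca_anova,
    random_baseline,
    run_baseline,
    sensitivity_specificity,
    two_state_error_rate,
)
from dyver.dataset_io import ExpressionDataset, GenotypeMatrix
from dyver.synthetic_data import gen_collection


def _toy(y, codes, T=None):
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    geno = GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        [f"v{j}" for j in range(codes.shape[1])],
        codes.astype(np.uint8),
    )
    ds = ExpressionDataset(
        ["g"], list(geno.strain_ids), 10.0 * np.arange(y.shape[1]), y[None]
    )
    return ds, geno


class TestNaive:
    def test_identical_groups_p_near_one(self):
        y = np.tile([[1.0, 2.0]], (6, 1))
        ds, geno = _toy(y, np.array([[0]] * 3 + [[1]] * 3))
        _, p = naive_min_anova(ds, geno, "g")
        assert p > 0.99

    def test_matches_scipy_f_oneway_on_six_strain_toy(self, rng):
        y = rng.normal(size=(6, 3))
        codes = np.array([[0], [0], [0], [1], [1], [1]])
        ds, geno = _toy(y, codes)
        _, p = naive_min_anova(ds, geno, "g")
        expected = min(
            stats.f_oneway(y[:3, t], y[3:, t]).pvalue for t in range(3)
        )
        np.testing.assert_allclose(p, expected, rtol=1e-10)

    def test_strong_constant_effect_recovers_variant(self, rng):
        coll = gen_collection(
            "linear", T=5, h=2.0, n_genes=6, n_assoc=6, seed=2,
            n_strains=40, n_variants=8,
        )
        truth = coll.truth.set_index("gene")
        hits = 0
        for gene in coll.expression.gene_ids:
            v, _ = naive_min_anova(coll.expression, coll.genotypes, gene)
            hits += v == truth.loc[gene, "variant"]
        assert hits >= 4


class TestPca:
    def test_sign_flip_leaves_p_unchanged(self, rng):
        y = rng.normal(size=(12, 4))
        codes = rng.integers(0, 2, (12, 1))
        codes[:6], codes[6:] = 0, 1
        ds, geno = _toy(y, codes)
        _, p1 = pca_anova(ds, geno, "g")
        ds2, _ = _toy(-y, codes)
        _, p2 = pca_anova(ds2, geno, "g")
        np.testing.assert_allclose(p1, p2, rtol=1e-9)

    def test_rank_one_data_equals_anova_on_amplitudes(self, rng):
        profile = np.array([1.0, 2.0, -1.0, 0.5])
        amps = rng.normal(size=10)
        y = np.outer(amps, profile)
        codes = np.array([[0]] * 5 + [[1]] * 5)
        ds, geno = _toy(y, codes)
        _, p = pca_anova(ds, geno, "g")
        expected = stats.f_oneway(amps[:5], amps[5:]).pvalue
        np.testing.assert_allclose(p, expected, rtol=1e-8)

    def test_recovers_sustained_effect(self):
        coll = gen_collection(
            "sustained", T=9, h=0.75, n_genes=10, n_assoc=10, seed=4,
            n_strains=50, n_variants=10,
        )
        truth = coll.truth.set_index("gene")
        hits = sum(
            pca_anova(coll.expression, coll.genotypes, g)[0]
            == truth.loc[g, "variant"]
            for g in coll.expression.gene_ids
        )
        assert hits >= 7


class TestExpressionDynamics:
    def test_identical_groups_p_near_one(self):
        rngl = np.random.default_rng(0)
        base = rngl.normal(size=(1, 4))
        y = np.tile(base, (8, 1))
        ds, geno = _toy(y, np.array([[0]] * 4 + [[1]] * 4))
        _, p = expression_dynamics_test(ds, geno, "g")
        assert np.isnan(p) or p > 0.9

    def test_matches_rss_f_test_oracle(self, rng):
        y = rng.normal(size=(8, 5)) + np.linspace(0, 1, 5)
        y[:4] += np.linspace(0, 2, 5)
        codes = np.array([[0]] * 4 + [[1]] * 4)
        ds, geno = _toy(y, codes)
        _, p = expression_dynamics_test(ds, geno, "g")
        # independent oracle: explicit OLS residual sums of squares
        t = np.tile(10.0 * np.arange(5), 8)
        g01 = np.repeat(codes[:, 0], 5)
        yy = y.ravel()
        X1 = np.column_stack(
            [g01 == 0, g01 == 1, t * (g01 == 0), t * (g01 == 1)]
        ).astype(float)
        X0 = np.column_stack([np.ones_like(t), t])
        rss = lambda X: np.sum(
            (yy - X @ np.linalg.lstsq(X, yy, rcond=None)[0]) ** 2
        )
        f = ((rss(X0) - rss(X1)) / 2) / (rss(X1) / (40 - 4))
        expected = stats.f.sf(f, 2, 36)
        np.testing.assert_allclose(p, expected, rtol=1e-8)

    def test_linear_divergence_highly_significant(self, rng):
        T = 6
        y = rng.normal(0, 0.3, size=(20, T))
        y[:10] += np.linspace(0, 3, T)
        codes = np.array([[0]] * 10 + [[1]] * 10)
        ds, geno = _toy(y, codes)
        _, p = expression_dynamics_test(ds, geno, "g")
        assert p < 1e-8


def _truth(n_assoc=30, n_null=20):
    rows = [
        dict(gene=f"g{i}", is_associated=i < n_assoc,
             variant=f"v{i % 7}" if i < n_assoc else None)
        for i in range(n_assoc + n_null)
    ]
    return pd.DataFrame(rows)


class TestClassification:
    def test_perfect_predictor(self):
        truth = _truth()
        pred = pd.DataFrame(
            [
                dict(gene=r.gene, variant=r.variant, bonf_p=1e-6)
                for r in truth.itertuples()
                if r.is_associated
            ]
        )
        out = classify_outcomes(truth, pred, alpha=0.05)
        counts = out["call"].value_counts()
        assert counts["TP"] == 30 and counts["TN"] == 20
        sens, spec = sensitivity_specificity(out)
        assert sens == 1.0 and spec == 1.0

    def test_wrong_variant_is_false_positive_not_true_positive(self):
        truth = _truth(2, 1)
        pred = pd.DataFrame(
            [
                dict(gene="g0", variant="wrong", bonf_p=1e-6),
                dict(gene="g1", variant="v1", bonf_p=1e-6),
            ]
        )
        out = classify_outcomes(truth, pred, alpha=0.05).set_index("gene")
        assert out.loc["g0", "call"] == "FP"
        assert out.loc["g1", "call"] == "TP"

    def test_all_null_predictor(self):
        truth = _truth()
        pred = pd.DataFrame(
            [dict(gene=r.gene, variant="v0", bonf_p=1.0) for r in truth.itertuples()]
        )
        out = classify_outcomes(truth, pred, alpha=0.05)
        counts = out["call"].value_counts()
        assert counts["FN"] == 30 and counts["TN"] == 20

    def test_unknown_gene_rejected(self):
        truth = _truth(2, 0)
        pred = pd.DataFrame([dict(gene="mystery", variant="v0", bonf_p=0.1)])
        with pytest.raises(ValueError, match="absent"):
            classify_outcomes(truth, pred, alpha=0.05)

    def test_random_predictions_near_zero_sensitivity(self, rng):
        truth = _truth(60, 40)
        variants = [f"v{j}" for j in range(100)]
        pred = pd.DataFrame(
            [
                dict(gene=g, variant=variants[rng.integers(100)],
                     bonf_p=float(rng.uniform()))
                for g in truth["gene"]
            ]
        )
        out = classify_outcomes(truth, pred, alpha=0.9)
        sens, _ = sensitivity_specificity(out)
        assert sens < 0.1


class TestAccuracy:
    def test_perfect_predictor_area_one(self):
        truth = _truth()
        pred = pd.DataFrame(
            [
                dict(gene=r.gene, variant=r.variant if r.is_associated else "vx",
                     bonf_p=1e-8 if r.is_associated else 1.0)
                for r in truth.itertuples()
            ]
        )
        assert accuracy_auc(truth, pred) == pytest.approx(1.0, abs=1e-9)

    def test_random_predictor_area_near_zero(self, rng):
        truth = _truth(50, 50)
        pred = pd.DataFrame(
            [
                dict(gene=g, variant=f"v{rng.integers(100)}",
                     bonf_p=float(rng.uniform()))
                for g in truth["gene"]
            ]
        )
        assert accuracy_auc(truth, pred) < 0.1

    def test_dense_grid_agreement(self, rng):
        truth = _truth(40, 40)
        pred = pd.DataFrame(
            [
                dict(
                    gene=r.gene,
                    variant=r.variant if (r.is_associated and rng.uniform() < 0.7)
                    else "vx",
                    bonf_p=float(rng.beta(1, 8 if r.is_associated else 1)),
                )
                for r in truth.itertuples()
            ]
        )
        coarse = accuracy_auc(truth, pred, alphas=np.logspace(-6, 0, 200))
        dense = accuracy_auc(truth, pred, alphas=np.logspace(-6, 0, 20000))
        assert abs(coarse - dense) < 1e-3

    def test_requires_two_thresholds(self):
        with pytest.raises(ValueError):
            accuracy_auc(_truth(2, 2), pd.DataFrame(columns=["gene", "variant", "bonf_p"]), alphas=[0.5])


class TestErrorRates:
    def test_flexible_forgives_timing_but_not_order(self):
        assert collapse_pattern("LLHH") == collapse_pattern("LHHH") == "LH"
        assert (
            two_state_error_rate(["LLHH"], ["LHHH"], mode="stringent") == 1.0
        )
        assert two_state_error_rate(["LLHH"], ["LHHH"], mode="flexible") == 0.0

    def test_exact_match_zero_everywhere(self):
        pats = ["LLH", "HHL", "LHL"]
        for mode in ("stringent", "flexible"):
            assert two_state_error_rate(pats, list(pats), mode=mode) == 0.0

    def test_flexible_never_exceeds_stringent(self, rng):
        pats_t = ["".join(rng.choice(["L", "H"], 6)) for _ in range(200)]
        pats_f = ["".join(rng.choice(["L", "H"], 6)) for _ in range(200)]
        s = two_state_error_rate(pats_t, pats_f, mode="stringent")
        f = two_state_error_rate(pats_t, pats_f, mode="flexible")
        assert f <= s

    def test_empty_denominator_nan(self):
        assert np.isnan(
            two_state_error_rate(["LH"], ["LH"], mask=[False], mode="stringent")
        )

    def test_mask_restricts_denominator(self):
        rate = two_state_error_rate(
            ["LL", "HH", "LH"], ["LL", "LL", "LL"],
            mask=[True, True, False], mode="stringent",
        )
        assert rate == 0.5


class TestRunBaseline:
    def test_frame_shape_and_bonferroni(self, rng):
        coll = gen_collection(
            "sustained", T=5, h=1.0, n_genes=8, n_assoc=5, seed=6,
            n_strains=30, n_variants=6,
        )
        for method in ("naive", "pca", "dynamics", "random"):
            out = run_baseline(
                coll.expression, coll.genotypes, method, seed=0
            )
            assert set(out.columns) == {"gene", "variant", "p", "bonf_p"}
            K = out.attrs["n_testable_variants"]
            np.testing.assert_allclose(
                out["bonf_p"], np.minimum(1.0, out["p"] * K)
            )

    def test_random_baseline_uniform_p(self, rng):
        coll = gen_collection(
            "sustained", T=4, h=0.5, n_genes=3, n_assoc=2, seed=6,
            n_strains=20, n_variants=5,
        )
        v, p = random_baseline(coll.expression, coll.genotypes, "G0001", rng)
        assert v in coll.genotypes.variant_ids
        assert 0.0 <= p <= 1.0
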