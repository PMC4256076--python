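"""Baseline mapping methods and evaluation metrics for simulation studies.

Baselines map each gene to its best variant with an analytic p-value:

naive        per-time-point one-way genotype ANOVA, minimum p over times
pca          one-way genotype ANOVA on each strain's first-principal-
             component projection of its time profile
dynamics     F-test of a per-genotype intercept+slope linear time model
             against a shared intercept+slope null ("expression dynamics")
random       a uniformly drawn variant with a uniform p-value

Evaluation is variant-aware: a significant call only counts as a true
positive when the *correct* causal variant is predicted; a significant
wrong variant on an associated gene is a false positive.  The accuracy of
a method is the area under the resulting sensitivity vs (1 - specificity)
curve across significance thresholds: about 0 for random predictions
(variant-aware sensitivity stays near zero at any threshold) and 1 for
perfect ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import ExpressionDataset, GenotypeMatrix, align_strains

__all__ = [
    "naive_min_anova",
    "pca_anova",
    "expression_dynamics_test",
    "random_baseline",
    "run_baseline",
    "classify_outcomes",
    "sensitivity_specificity",
    "accuracy_auc",
    "collapse_pattern",
    "two_state_error_rate",
]


def _testable(geno: GenotypeMatrix) -> np.ndarray:
    n_a = (geno.codes == 0).sum(axis=0)
    n_b = (geno.codes == 1).sum(axis=0)
    return np.flatnonzero((n_a >= 2) & (n_b >= 2))


def _group_stats(Y: np.ndarray, members: np.ndarray):
    """Masked per-(variant, time) count/sum/sum-of-squares for one group.

    Y: (n, T) possibly with NaN; members: (n, K) 0/1 -> three (K, T) arrays.
    """
    obs = np.isfinite(Y)
    Y0 = np.where(obs, Y, 0.0)
    mt = members.T
    n = mt @ obs.astype(float)
    s1 = mt @ Y0
    s2 = mt @ (Y0 * Y0)
    return n, s1, s2


def _two_group_anova_p(na, s1a, s2a, nb, s1b, s2b):
    """One-way fixed-effect two-group F-test p (elementwise over arrays)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        n = na + nb
        ma = s1a / na
        mb = s1b / nb
        m = (s1a + s1b) / n
        ssw = np.maximum((s2a - na * ma**2) + (s2b - nb * mb**2), 0.0)
        ssb = na * (ma - m) ** 2 + nb * (mb - m) ** 2
        f = np.where(
            ssw > 0, ssb / (ssw / (n - 2)), np.where(ssb > 0, np.inf, 0.0)
        )
        p = stats.f.sf(f, 1, n - 2)
    bad = (na < 2) | (nb < 2) | np.isnan(f)
    return np.where(bad, np.nan, p)


def _naive_pvalues(Y, geno, testable_idx) -> np.ndarray:
    """Per-variant min-over-time ANOVA p for one gene. (K,)"""
    a = (geno.codes[:, testable_idx] == 0).astype(float)
    na, s1a, s2a = _group_stats(Y, a)
    nb, s1b, s2b = _group_stats(Y, 1.0 - a)
    p = _two_group_anova_p(na, s1a, s2a, nb, s1b, s2b)  # (K, T)
    with np.errstate(invalid="ignore"):
        return np.nanmin(p, axis=1)


def _pca_pvalues(Y, geno, testable_idx) -> np.ndarray:
    from sklearn.decomposition import PCA

    complete = np.isfinite(Y).all(axis=1)
    if complete.sum() < 3:
        return np.full(testable_idx.size, np.nan)
    scores = np.full(Y.shape[0], np.nan)
    scores[complete] = (
        PCA(n_components=1, svd_solver="full")
        .fit_transform(Y[complete])
        .ravel()
    )
    a = (geno.codes[:, testable_idx] == 0).astype(float)
    na, s1a, s2a = _group_stats(scores[:, None], a)
    nb, s1b, s2b = _group_stats(scores[:, None], 1.0 - a)
    return _two_group_anova_p(na, s1a, s2a, nb, s1b, s2b).ravel()


def _dynamics_pvalues(Y, geno, testable_idx, times) -> np.ndarray:
    """F-test of genotype-specific intercept and slope vs a shared line."""
    a = (geno.codes[:, testable_idx] == 0).astype(float)
    obs = np.isfinite(Y)
    Y0 = np.where(obs, Y, 0.0)
    t = np.asarray(times, dtype=float)

    def line_rss(members):
        mt = members.T
        n_kt = mt @ obs.astype(float)  # (K, T)
        s1 = mt @ Y0
        s2 = (mt @ (Y0 * Y0)).sum(axis=1)
        N = n_kt.sum(axis=1)
        St = n_kt @ t
        Stt = n_kt @ (t * t)
        Sy = s1.sum(axis=1)
        Sty = s1 @ t
        with np.errstate(divide="ignore", invalid="ignore"):
            sxx = Stt - St**2 / N
            sxy = Sty - St * Sy / N
            syy = s2 - Sy**2 / N
            rss = syy - np.where(sxx > 0, sxy**2 / np.where(sxx > 0, sxx, 1.0), 0.0)
        return N, rss

    na, rss_a = line_rss(a)
    nb, rss_b = line_rss(1.0 - a)
    npool, rss_0 = line_rss(np.ones_like(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_1 = rss_a + rss_b
        df2 = npool - 4.0
        f = ((rss_0 - rss_1) / 2.0) / (rss_1 / df2)
        p = stats.f.sf(f, 2, df2)
    bad = ~np.isfinite(f) | (df2 <= 0)
    return np.where(bad, np.nan, p)


def _best(p: np.ndarray, geno, testable_idx):
    if not np.isfinite(p).any():
        return None, np.nan
    j = int(np.nanargmin(p))
    return geno.variant_ids[testable_idx[j]], float(p[j])


def naive_min_anova(ds: ExpressionDataset, geno: GenotypeMatrix, gene):
    """Best variant by min-over-time-points one-way genotype ANOVA."""
    idx = _testable(geno)
    p = _naive_pvalues(ds.values[ds.gene_index(gene)], geno, idx)
    return _best(p, geno, idx)


def pca_anova(ds: ExpressionDataset, geno: GenotypeMatrix, gene):
    """Best variant by genotype ANOVA on first-principal-component scores."""
    idx = _testable(geno)
    p = _pca_pvalues(ds.values[ds.gene_index(gene)], geno, idx)
    return _best(p, geno, idx)


def expression_dynamics_test(ds: ExpressionDataset, geno: GenotypeMatrix, gene):
    """Best variant by the genotype-specific linear-time-trend F-test."""
    idx = _testable(geno)
    p = _dynamics_pvalues(
        ds.values[ds.gene_index(gene)], geno, idx, ds.time_points
    )
    return _best(p, geno, idx)


def random_baseline(ds, geno: GenotypeMatrix, gene, rng=None):
    rng = np.random.default_rng(rng)
    idx = _testable(geno)
    return geno.variant_ids[int(rng.choice(idx))], float(rng.random())


_METHODS = {
    "naive": _naive_pvalues,
    "pca": _pca_pvalues,
    "dynamics": _dynamics_pvalues,
}


def run_baseline(
    ds: ExpressionDataset,
    geno: GenotypeMatrix,
    method: str,
    genes=None,
    seed=None,
) -> pd.DataFrame:
    """Per-gene best variant and Bonferroni-corrected p for one baseline."""
    ds, geno = align_strains(ds, geno)
    if genes is None:
        genes = list(ds.gene_ids)
    idx = _testable(geno)
    K = idx.size
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        Y = ds.values[ds.gene_index(gene)]
        if method == "random":
            variant, p = random_baseline(ds, geno, gene, rng)
        elif method in _METHODS:
            args = (Y, geno, idx)
            if method == "dynamics":
                args = args + (ds.time_points,)
            variant, p = _best(_METHODS[method](*args), geno, idx)
        else:
            raise ValueError(f"unknown baseline method: {method!r}")
        if variant is None:
            continue
        rows.append(
            dict(gene=gene, variant=variant, p=p, bonf_p=min(1.0, p * K))
        )
    out = pd.DataFrame(rows)
    out.attrs["n_testable_variants"] = int(K)
    return out


# ---------------------------------------------------------------------------
# variant-aware outcome classification and accuracy


def classify_outcomes(
    truth: pd.DataFrame, predictions: pd.DataFrame, alpha: float
) -> pd.DataFrame:
    """TP/TN/FP/FN call per gene at significance threshold ``alpha``.

    ``truth`` needs columns (gene, is_associated, variant); ``predictions``
    needs (gene, variant, bonf_p).  A significant call is TP only when the
    predicted variant matches the causal one; a significant wrong variant
    (or any significant call on a non-associated gene) is FP; associated
    genes with no significant call are FN.
    """
    known = set(truth["gene"])
    unknown = set(predictions["gene"]) - known
    if unknown:
        raise ValueError(f"predictions contain genes absent from truth: {sorted(unknown)[:5]}")
    pred = predictions.set_index("gene")
    calls = []
    for rec in truth.itertuples():
        sig = False
        variant = None
        if rec.gene in pred.index:
            row = pred.loc[rec.gene]
            sig = bool(row["bonf_p"] <= alpha)
            variant = row["variant"]
        if rec.is_associated:
            if sig:
                call = "TP" if variant == rec.variant else "FP"
            else:
                call = "FN"
        else:
            call = "FP" if sig else "TN"
        calls.append(
            dict(
                gene=rec.gene,
                call=call,
                is_associated=bool(rec.is_associated),
                predicted_variant=variant if sig else None,
            )
        )
    return pd.DataFrame(calls)


def sensitivity_specificity(outcomes: pd.DataFrame) -> tuple:
    """(sensitivity, specificity): TP over all associated genes and TN over
    all non-associated genes."""
    n_assoc = int(outcomes["is_associated"].sum())
    n_null = int((~outcomes["is_associated"]).sum())
    tp = int(outcomes["call"].eq("TP").sum())
    tn = int(outcomes["call"].eq("TN").sum())
    sens = tp / n_assoc if n_assoc else float("nan")
    spec = tn / n_null if n_null else float("nan")
    return sens, spec


def accuracy_auc(
    truth: pd.DataFrame,
    predictions: pd.DataFrame,
    alphas=None,
) -> float:
    """Area under the variant-aware sensitivity vs (1 - specificity) curve."""
    if alphas is None:
        alphas = np.logspace(-6, 0, 200)
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size < 2:
        raise ValueError("need at least two thresholds")
    n_assoc = int(truth["is_associated"].sum())
    n_null = int((~truth["is_associated"]).sum())
    if n_assoc == 0 or n_null == 0:
        raise ValueError("truth must contain associated and non-associated genes")
    t = truth.set_index("gene")
    pred = predictions.copy()
    pred["correct"] = [
        t.loc[g, "is_associated"] and v == t.loc[g, "variant"]
        for g, v in zip(pred["gene"], pred["variant"])
    ]
    pred["null_gene"] = [not t.loc[g, "is_associated"] for g in pred["gene"]]
    xs, ys = [0.0], [0.0]
    for alpha in np.sort(alphas):
        sig = pred["bonf_p"].values <= alpha
        tp = int((sig & pred["correct"].values).sum())
        fp_null = int((sig & pred["null_gene"].values).sum())
        tn = n_null - fp_null
        xs.append(1.0 - tn / n_null)
        ys.append(tp / n_assoc)
    order = np.argsort(xs, kind="stable")
    return float(np.trapezoid(np.asarray(ys)[order], np.asarray(xs)[order]))


# ---------------------------------------------------------------------------
# two-state pattern error rates


def collapse_pattern(pattern: str) -> str:
    """Run-length collapse: 'LLHH' -> 'LH' (state order, timing ignored)."""
    out = []
    for c in pattern:
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def two_state_error_rate(
    truth_patterns,
    fitted_patterns,
    mask=None,
    mode: str = "stringent",
) -> float:
    """Fraction of wrong fitted patterns among significant correct calls.

    ``mask`` selects the denominator (significant, correctly mapped genes).
    stringent: exact pattern match required; flexible: patterns match when
    their run-length collapses agree (correct order of transitions, timing
    free).  Returns NaN when the denominator is empty.
    """
    if mode not in ("stringent", "flexible"):
        raise ValueError(f"unknown mode: {mode!r}")
    truth_patterns = np.asarray(truth_patterns, dtype=object)
    fitted_patterns = np.asarray(fitted_patterns, dtype=object)
    if mask is None:
        mask = np.ones(truth_patterns.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return float("nan")
    t = truth_patterns[mask]
    f = fitted_patterns[mask]
    if mode == "flexible":
        t = np.array([collapse_pattern(p) for p in t], dtype=object)
        f = np.array([collapse_pattern(p) for p in f], dtype=object)
    return float(np.mean(t != f))
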