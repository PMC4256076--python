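"""Association scoring: likelihood-ratio score, permutation p-values, scans.

The association statistic compares two hypotheses for a (gene, variant)
pair.  Under the null the cross-allele differences D and the same-allele
background differences B are exchangeable and one two-state model fits the
pooled sample; under the alternative D and B deserve separate models.  The
score is

    log Lambda = [max log L(D) + max log L(B)] - max log L(D u B)

with each term the maximized joint likelihood of the two-state model.
Significance is assessed empirically by permuting strain genotype labels
and recomputing the score, Bonferroni-corrected across variants, with a
Benjamini-Hochberg pass across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .dataset_io import (
    ExpressionDataset,
    GenotypeMatrix,
    StrainGroups,
    align_strains,
    split_by_allele,
    stabilize_variance,
)
from .effects import EffectObservations, effect_observations, suff_stats
from .two_state_model import FitResult, fit_two_state

__all__ = [
    "AssociationResult",
    "dyver_score",
    "permutation_pvalue",
    "scan_dataset",
    "gene_level_fdr",
    "dynamic_association_score",
    "gene_effects",
]


@dataclass
class AssociationResult:
    gene: object
    variant: object
    dyver_score: float
    perm_p: float
    bonf_p: float
    pattern: str
    dynamic_p: float
    mu_h: float
    mu_l: float


# ---------------------------------------------------------------------------
# reference (per-pair) path


def gene_effects(
    ds: ExpressionDataset,
    geno: GenotypeMatrix,
    gene,
    variant,
    groups: StrainGroups | None = None,
    stabilize: bool = True,
) -> EffectObservations:
    """Variance-stabilized D and B samples for one (gene, variant) pair."""
    if groups is None:
        groups = split_by_allele(geno, variant)
    if not groups.testable:
        raise ValueError(f"variant {variant!r} is monomorphic (untestable)")
    g = ds.gene_index(gene)
    single = ExpressionDataset(
        [gene], list(ds.strain_ids), ds.time_points, ds.values[g : g + 1]
    )
    if stabilize:
        single = _stabilize_for_groups(single, groups)
    return effect_observations(single, groups, gene)


def _stabilize_for_groups(ds: ExpressionDataset, groups: StrainGroups):
    geno1 = GenotypeMatrix(
        list(ds.strain_ids),
        [groups.variant_id],
        np.isin(np.arange(ds.n_strains), groups.group_b).astype(np.uint8)[:, None],
    )
    return stabilize_variance(ds, geno1, groups.variant_id)


def _fit_kwargs(kw):
    return {k: kw[k] for k in ("tol", "max_iter") if k in kw}


def dyver_score(effects, lam: float = 0.5, pi: float = 0.5, **fit_kw) -> float:
    """Likelihood-ratio association score of one (gene, variant) pair.

    The temporal two-state model is fitted on the observed effects D; with
    that state sequence held fixed, the score compares separate per-state
    Gaussian models for D and for the background B against a single model
    for the pooled sample (closed-form parameter maximization per term).
    ``effects`` is an EffectObservations carrying both samples (or a
    ``(D_effects, B_effects)`` pair on the same retained time grid).
    """
    if isinstance(effects, tuple):
        d_eff, b_eff = effects
        effects = EffectObservations(
            d_eff.variant_id, d_eff.time_points, d_eff.D, b_eff.B
        )
    if all(len(b) == 0 for b in effects.B):
        raise ValueError(
            "background sample is empty at every time point; at least two "
            "strains per allele group (a larger panel) are required"
        )
    nd, s1d, s2d = suff_stats(effects.D)
    nb, s1b, s2b = suff_stats(effects.B)
    fit = _engine.fit_batch(
        nd[None], s1d[None], s2d[None], lam=lam, pi=pi, **_fit_kwargs(fit_kw)
    )
    return float(
        _engine.score_given_path(
            fit["path"], (nd[None], s1d[None], s2d[None]),
            (nb[None], s1b[None], s2b[None]),
        )[0]
    )


def permutation_pvalue(
    ds: ExpressionDataset,
    geno: GenotypeMatrix,
    gene,
    variant,
    lam: float = 0.5,
    pi: float = 0.5,
    n_perm: int = 99,
    seed=None,
    **fit_kw,
) -> float:
    """Empirical p-value by permuting strain genotype labels.

    Reference implementation (recomputes stabilization and both difference
    samples per permutation); p uses add-one smoothing,
    ``(1 + #{permuted score >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    k = geno.variant_index(variant)
    col = geno.codes[:, k]
    obs = dyver_score(
        gene_effects(ds, geno, gene, variant), lam=lam, pi=pi, **fit_kw
    )
    exceed = 0
    for _ in range(n_perm):
        perm_col = col[rng.permutation(col.size)]
        groups = StrainGroups(
            variant, np.flatnonzero(perm_col == 0), np.flatnonzero(perm_col == 1)
        )
        eff = gene_effects(ds, geno, gene, variant, groups=groups)
        if dyver_score(eff, lam=lam, pi=pi, **fit_kw) >= obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def dynamic_association_score(effects: EffectObservations, pattern: str) -> float:
    """Welch t-test p between D pooled over H and over L time points.

    Undefined (NaN) for single-state patterns: without both states there is
    no temporal contrast to test.
    """
    if len(pattern) != effects.n_times:
        raise ValueError("pattern length must equal the retained time points")
    if "H" not in pattern or "L" not in pattern:
        return float("nan")
    h_pool = np.concatenate([d for d, s in zip(effects.D, pattern) if s == "H"])
    l_pool = np.concatenate([d for d, s in zip(effects.D, pattern) if s == "L"])
    return float(stats.ttest_ind(h_pool, l_pool, equal_var=False).pvalue)


def gene_level_fdr(pvalues, q: float = 0.06) -> np.ndarray:
    """Benjamini-Hochberg discovery flags over genes' best corrected p."""
    p = np.asarray(pvalues, dtype=float)
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(np.clip(p, 0.0, 1.0), alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# genome scan


def _permutation_blocks(total: int):
    """Split 1 + n_perm rows (row 0 = identity) into growing blocks."""
    edges, used, size = [], 0, 25
    while used < total:
        take = min(size, total - used)
        edges.append((used, used + take))
        used += take
        size = min(2 * size, 2000)
    return edges


def _scan_gene_complete(
    Y,
    codes,
    testable_idx,
    lam,
    pi,
    n_perm,
    rng,
    prune_max_exceed,
    em_tol,
    em_max_iter,
):
    """Observed scores and permutation exceedance counts for one gene.

    Returns (obs_scores (K,), counts (K,), seen (K,)) over testable
    variants.  When ``prune_max_exceed`` is set, variants whose exceedance
    count passes the bound stop accumulating permutations (their reported
    p is then based on the permutations seen, a conservative estimate for
    clearly non-significant variants; the set of variants reaching the
    strictest attainable p is unaffected).
    """
    n = Y.shape[0]
    all_rows = np.vstack(
        [np.arange(n)[None, :]]
        + [rng.permutation(n)[None, :] for _ in range(n_perm)]
    )
    K = testable_idx.size
    obs_scores = np.full(K, np.nan)
    counts = np.zeros(K, dtype=np.int64)
    seen = np.zeros(K, dtype=np.int64)
    active = np.arange(K)
    for lo, hi in _permutation_blocks(1 + n_perm):
        if active.size == 0:
            break
        Yp = Y[all_rows[lo:hi]]  # (Pb, n, T)
        a_ind = (codes[:, testable_idx[active]] == 0).astype(float)
        d, b, _pool = _engine.pair_suffstats(Yp, a_ind)
        Pb = hi - lo
        T = Y.shape[1]

        def flat(trip):
            return tuple(np.ascontiguousarray(x).reshape(-1, T) for x in trip)

        d_flat, b_flat = flat(d), flat(b)
        fit = _engine.fit_batch(
            *d_flat, lam=lam, pi=pi, tol=em_tol, max_iter=em_max_iter
        )
        scores = _engine.score_given_path(fit["path"], d_flat, b_flat).reshape(
            Pb, active.size
        )
        if lo == 0:
            obs_scores[active] = scores[0]
            perm_scores = scores[1:]
        else:
            perm_scores = scores
        counts[active] += (perm_scores >= obs_scores[active][None, :]).sum(axis=0)
        seen[active] += perm_scores.shape[0]
        if prune_max_exceed is not None:
            active = active[counts[active] <= prune_max_exceed]
    return obs_scores, counts, seen


def _scan_gene_masked(
    ds, geno, gene, testable_idx, lam, pi, n_perm, rng, em_tol, em_max_iter
):
    """Per-pair fallback for genes with missing observations."""
    K = testable_idx.size
    obs_scores = np.full(K, np.nan)
    counts = np.zeros(K, dtype=np.int64)
    seen = np.full(K, n_perm, dtype=np.int64)
    perms = [rng.permutation(geno.n_strains) for _ in range(n_perm)]
    for j, k in enumerate(testable_idx):
        variant = geno.variant_ids[k]
        col = geno.codes[:, k]
        try:
            obs_scores[j] = dyver_score(
                gene_effects(ds, geno, gene, variant),
                lam=lam,
                pi=pi,
                tol=em_tol,
                max_iter=em_max_iter,
            )
        except ValueError:
            continue
        for perm in perms:
            pc = col[perm]
            groups = StrainGroups(
                variant, np.flatnonzero(pc == 0), np.flatnonzero(pc == 1)
            )
            eff = gene_effects(ds, geno, gene, variant, groups=groups)
            s = dyver_score(eff, lam=lam, pi=pi, tol=em_tol, max_iter=em_max_iter)
            if s >= obs_scores[j]:
                counts[j] += 1
    return obs_scores, counts, seen


def _scan_one_gene(
    ds,
    geno,
    gene,
    testable_idx,
    seed_seq,
    lam,
    pi,
    n_perm,
    prune_max_exceed,
    em_tol,
    em_max_iter,
):
    """Best-variant association row for one gene (None when untestable)."""
    g = ds.gene_index(gene)
    Y = ds.values[g]
    rng = np.random.default_rng(seed_seq)
    if np.isfinite(Y).all():
        obs_scores, counts, seen = _scan_gene_complete(
            Y,
            geno.codes,
            testable_idx,
            lam,
            pi,
            n_perm,
            rng,
            prune_max_exceed,
            em_tol,
            em_max_iter,
        )
    else:
        obs_scores, counts, seen = _scan_gene_masked(
            ds, geno, gene, testable_idx, lam, pi, n_perm, rng, em_tol, em_max_iter
        )
    valid = np.isfinite(obs_scores)
    if not valid.any():
        return gene, None, None
    K = testable_idx.size
    perm_p = (1.0 + counts) / (1.0 + seen)
    bonf_p = np.minimum(1.0, perm_p * K)
    order = sorted(
        np.flatnonzero(valid), key=lambda j: (bonf_p[j], -obs_scores[j], j)
    )
    best = order[0]
    k = testable_idx[best]
    variant = geno.variant_ids[k]
    eff = gene_effects(ds, geno, gene, variant)
    fit = fit_two_state(eff, lam=lam, pi=pi)
    pattern = fit.model.pattern
    dyn_p = dynamic_association_score(eff, pattern)
    chrom = kb = np.nan
    if geno.positions is not None:
        pos = geno.positions.loc[variant]
        chrom, kb = pos["chrom"], pos["kb"]
    row = {
        "gene": gene,
        "variant": variant,
        "chrom": chrom,
        "kb": kb,
        "dyver_score": obs_scores[best],
        "perm_p": perm_p[best],
        "bonf_p": bonf_p[best],
        "n_exceed": int(counts[best]),
        "n_perm_seen": int(seen[best]),
        "pattern": pattern,
        "dynamic_p": dyn_p,
        "mu_H": fit.model.mu_h,
        "mu_L": fit.model.mu_l,
    }
    return gene, row, obs_scores


def scan_dataset(
    ds: ExpressionDataset,
    geno: GenotypeMatrix,
    genes=None,
    lam: float = 0.5,
    pi: float = 0.5,
    n_perm: int = 999,
    seed: int = 0,
    fdr_assoc: float = 0.06,
    fdr_dynamic: float = 0.15,
    prune_max_exceed: int | None = None,
    em_tol: float = 1e-4,
    em_max_iter: int = 200,
    n_jobs: int = 1,
    return_scores: bool = False,
):
    """Scan every (gene, variant) pair and report each gene's best association.

    Returns a DataFrame with one row per scanned gene: best variant,
    association score, permutation and Bonferroni-corrected p-values,
    gene-level BH discovery flag at ``fdr_assoc``, fitted H/L pattern,
    dynamic-association p with its BH flag at ``fdr_dynamic`` (computed
    among predicted associations), and the two state means.  With
    ``return_scores`` a (gene x variant) observed-score matrix is attached
    as ``.attrs['scores']``.
    """
    ds, geno = align_strains(ds, geno)
    if genes is None:
        genes = list(ds.gene_ids)
    n_a = (geno.codes == 0).sum(axis=0)
    n_b = (geno.codes == 1).sum(axis=0)
    testable_idx = np.flatnonzero((n_a >= 2) & (n_b >= 2))
    if testable_idx.size == 0:
        raise ValueError("no testable (polymorphic, >=2 strains per allele) variant")
    K = testable_idx.size
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(genes))

    scan_args = dict(
        lam=lam,
        pi=pi,
        n_perm=n_perm,
        prune_max_exceed=prune_max_exceed,
        em_tol=em_tol,
        em_max_iter=em_max_iter,
    )
    if n_jobs == 1:
        results = [
            _scan_one_gene(ds, geno, gene, testable_idx, children[gi], **scan_args)
            for gi, gene in enumerate(genes)
        ]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_scan_one_gene)(
                ds, geno, gene, testable_idx, children[gi], **scan_args
            )
            for gi, gene in enumerate(genes)
        )
    rows = []
    score_rows = {}
    for gene, row, scores in results:
        if row is not None:
            rows.append(row)
        if return_scores and scores is not None:
            score_rows[gene] = pd.Series(
                scores, index=[geno.variant_ids[k] for k in testable_idx]
            )
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr_pass"] = gene_level_fdr(result["bonf_p"].values, q=fdr_assoc)
        dyn_pass = np.zeros(len(result), dtype=bool)
        assoc = result["fdr_pass"].values & np.isfinite(result["dynamic_p"].values)
        if assoc.any():
            dyn_pass[assoc] = gene_level_fdr(
                result.loc[assoc, "dynamic_p"].values, q=fdr_dynamic
            )
        result["dynamic_pass"] = dyn_pass
    if return_scores:
        result.attrs["scores"] = pd.DataFrame(score_rows).T
    result.attrs["n_testable_variants"] = int(K)
    return result
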