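"""Reproducible simulation-study runners.

Each function generates its own synthetic inputs from a seed, runs the
mapping method(s) end to end (variance stabilization, effect samples,
two-state fitting, permutation scoring) and returns summary metrics.  The
problem sizes default to desk-scale reductions of the full benchmark grid;
they are parameters, so larger replications only change the arguments.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .association_scoring import (
    _scan_gene_complete,
    gene_effects,
    scan_dataset,
)
from .benchmark_eval import accuracy_auc, run_baseline, two_state_error_rate
from .synthetic_data import (
    gen_collection,
    gen_error_rate_dataset,
    gen_genotypes,
    waveform,
)
from .two_state_model import fit_two_state

__all__ = [
    "pattern_error_experiment",
    "impulse_sensitivity_experiment",
    "init_robustness_experiment",
    "null_calibration_experiment",
    "accuracy_comparison_experiment",
]


def pattern_error_experiment(
    n_genes: int = 150,
    T: int = 9,
    effect: float = 0.75,
    sigma: float = 1.0,
    lam_scan: float = 0.5,
    refit_lams: tuple = (0.5, 0.1, 0.01),
    cutoff: float = 1e-3,
    n_perm: int = 999,
    seed: int = 0,
    n_strains: int = 50,
    n_variants: int = 100,
) -> dict:
    """Two-state pattern error rates on the Markov-path sustained dataset.

    State paths are drawn from the sequence prior (transition probability
    0.5); genes are scanned with the permutation score and, among genes
    whose correct variant is called significant at ``cutoff`` (plain
    permutation proportion, Bonferroni over variants), the fraction of
    wrong fitted patterns is reported -- stringent (exact match) and
    flexible (run-length-collapsed match) -- re-fitting the model at each
    penalty in ``refit_lams``.
    """
    ss = np.random.SeedSequence(seed)
    gen_seed, scan_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    coll = gen_error_rate_dataset(
        T=T,
        lambda_true=0.5,
        mu_h=effect,
        sigma=sigma,
        n_genes=n_genes,
        seed=gen_seed,
        n_strains=n_strains,
        n_variants=n_variants,
    )
    scan = scan_dataset(
        coll.expression,
        coll.genotypes,
        lam=lam_scan,
        n_perm=n_perm,
        seed=scan_seed,
        prune_max_exceed=0,
    )
    truth = coll.truth.set_index("gene")
    merged = scan.set_index("gene")
    K = scan.attrs["n_testable_variants"]
    genes = merged.index
    correct = merged["variant"].values == truth.loc[genes, "variant"].values
    plain_corrected = np.minimum(
        1.0, merged["n_exceed"].values / merged["n_perm_seen"].values * K
    )
    denom = correct & (plain_corrected < cutoff)
    truth_patterns = truth.loc[genes, "pattern"].values[denom]
    sel_genes = genes[denom]

    out = {
        "n_genes": n_genes,
        "n_significant_correct": int(denom.sum()),
        "stringent": {},
        "flexible": {},
    }
    for lam in refit_lams:
        if lam == lam_scan:
            fitted = merged["pattern"].values[denom]
        else:
            fitted = np.array(
                [
                    fit_two_state(
                        gene_effects(
                            coll.expression,
                            coll.genotypes,
                            g,
                            merged.loc[g, "variant"],
                        ),
                        lam=lam,
                    ).model.pattern
                    for g in sel_genes
                ],
                dtype=object,
            )
        for mode in ("stringent", "flexible"):
            out[mode][lam] = two_state_error_rate(
                truth_patterns, fitted, mode=mode
            )
    return out


def impulse_sensitivity_experiment(
    T: int = 27,
    effect: float = 0.625,
    impulse_len: int = 5,
    n_genes: int = 100,
    sigma: float = 1.0,
    n_perm: int = 999,
    alpha: float = 0.1,
    seed: int = 0,
    n_strains: int = 50,
    n_variants: int = 100,
    methods: tuple = ("dyver", "pca"),
) -> dict:
    """Variant-aware sensitivity on an all-associated impulse collection.

    Sensitivity = fraction of genes whose best-scoring variant is the true
    causal one with Bonferroni-corrected p <= alpha.
    """
    ss = np.random.SeedSequence(seed)
    gen_seed, scan_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    coll = gen_collection(
        "impulse",
        T=T,
        h=effect,
        n_genes=n_genes,
        n_assoc=n_genes,
        sigma=sigma,
        seed=gen_seed,
        n_strains=n_strains,
        n_variants=n_variants,
        impulse_len=impulse_len,
    )
    truth = coll.truth.set_index("gene")
    out = {"n_genes": n_genes, "impulse_len": impulse_len}
    if "dyver" in methods:
        scan = scan_dataset(
            coll.expression,
            coll.genotypes,
            n_perm=n_perm,
            seed=scan_seed,
            prune_max_exceed=0,
        )
        hit = (
            (scan["variant"].values == truth.loc[scan["gene"], "variant"].values)
            & (scan["bonf_p"].values <= alpha)
        )
        out["dyver"] = float(hit.sum() / n_genes)
    if "pca" in methods:
        base = run_baseline(coll.expression, coll.genotypes, "pca")
        hit = (
            (base["variant"].values == truth.loc[base["gene"], "variant"].values)
            & (base["bonf_p"].values <= alpha)
        )
        out["pca"] = float(hit.sum() / n_genes)
    return out


def init_robustness_experiment(
    n_instances: int = 200,
    T: int = 9,
    effect: float = 0.5,
    sigma: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
    n_strains: int = 50,
    lam: float = 0.5,
    ll_tol: float = 1e-6,
) -> float:
    """Percent of fits where the single deterministic start attains the
    best likelihood found over ``n_restarts`` random initializations."""
    from .synthetic_data import _strain_expression

    rng = np.random.default_rng(seed)
    mu_t = waveform("sustained", T, effect)
    successes = 0
    for i in range(n_instances):
        while True:
            col = rng.integers(0, 2, size=n_strains)
            if 2 <= col.sum() <= n_strains - 2:
                break
        a_strains = np.flatnonzero(col == 0)
        y = _strain_expression(rng, n_strains, mu_t, a_strains, sigma)
        from .dataset_io import ExpressionDataset, GenotypeMatrix

        ds = ExpressionDataset(
            ["g"], [f"s{j}" for j in range(n_strains)], np.arange(T, dtype=float), y[None]
        )
        geno = GenotypeMatrix(
            [f"s{j}" for j in range(n_strains)], ["v"], col[:, None].astype(np.uint8)
        )
        eff = gene_effects(ds, geno, "g", "v")
        single = fit_two_state(eff, lam=lam)
        multi = fit_two_state(
            eff, lam=lam, restarts=n_restarts, seed=rng.integers(2**31)
        )
        if single.log_likelihood >= multi.log_likelihood - ll_tol:
            successes += 1
    return 100.0 * successes / n_instances


def null_calibration_experiment(
    n_genes: int = 500,
    T: int = 6,
    n_perm: int = 199,
    seed: int = 0,
    n_strains: int = 50,
    sigma: float = 1.0,
    lam: float = 0.5,
) -> dict:
    """Permutation p-values of one fixed variant on unassociated genes.

    Returns the p-values, their uniformity KS test p, and the
    genomic-control-style statistic log(median p) / log(0.5) (about 1 for
    a calibrated test).
    """
    ss = np.random.SeedSequence(seed)
    gen_seed, scan_seed = ss.spawn(2)
    geno = gen_genotypes(n_strains, 1, seed=gen_seed)
    rng = np.random.default_rng(scan_seed)
    testable = np.array([0])
    pvals = np.empty(n_genes)
    for i in range(n_genes):
        Y = rng.normal(0.0, sigma, size=(n_strains, T))
        _, counts, seen = _scan_gene_complete(
            Y,
            geno.codes,
            testable,
            lam,
            0.5,
            n_perm,
            rng,
            prune_max_exceed=None,
            em_tol=1e-4,
            em_max_iter=200,
        )
        pvals[i] = (1.0 + counts[0]) / (1.0 + seen[0])
    ks_p = float(stats.kstest(pvals, "uniform").pvalue)
    gc = float(np.log(np.median(pvals)) / np.log(0.5))
    return {"pvalues": pvals, "ks_p": ks_p, "genomic_control": gc}


def accuracy_comparison_experiment(
    kind: str,
    T: int = 6,
    effect: float = 0.75,
    n_genes: int = 30,
    n_assoc: int = 18,
    sigma: float = 1.0,
    n_perm: int = 99,
    seed: int = 0,
    n_strains: int = 40,
    n_variants: int = 15,
    methods: tuple = ("dyver", "naive", "pca", "dynamics"),
) -> dict:
    """Accuracy (area under the variant-aware curve) per mapping method."""
    ss = np.random.SeedSequence(seed)
    gen_seed, scan_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    coll = gen_collection(
        kind,
        T=T,
        h=effect,
        n_genes=n_genes,
        n_assoc=n_assoc,
        sigma=sigma,
        seed=gen_seed,
        n_strains=n_strains,
        n_variants=n_variants,
    )
    out = {}
    for method in methods:
        if method == "dyver":
            scan = scan_dataset(
                coll.expression,
                coll.genotypes,
                n_perm=n_perm,
                seed=scan_seed,
            )
            pred = scan[["gene", "variant", "bonf_p"]]
        else:
            pred = run_baseline(coll.expression, coll.genotypes, method, seed=scan_seed)
        out[method] = accuracy_auc(coll.truth, pred)
    return out
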