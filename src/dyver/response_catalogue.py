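"""Post-scan cataloguing of temporal response classes.

Takes a table of significant associations (gene, variant, fitted H/L
pattern) plus genomic positions and organises it: genes whose mean-effect
trajectory is essentially a straight line are filtered out, the remainder
are grouped by exact fitted pattern, genes sharing a *trans*-acting
variant form co-association modules, and pattern over-representation
within each module is tested hypergeometrically with a BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatternGroup",
    "CoassociationModule",
    "effect_trajectory",
    "filter_linear_like",
    "group_by_pattern",
    "build_modules",
    "pattern_enrichment",
]


@dataclass
class PatternGroup:
    pattern: str
    genes: list


@dataclass
class CoassociationModule:
    variant: object
    chrom: object
    kb: float
    genes: list
    enrichment: pd.DataFrame | None = None


def effect_trajectory(ds, geno, gene, variant) -> np.ndarray:
    """Mean observed effect per retained time point for one association."""
    from .association_scoring import gene_effects

    eff = gene_effects(ds, geno, gene, variant)
    return np.array([d.mean() if len(d) else np.nan for d in eff.D])


def filter_linear_like(
    trajectories: dict,
    r_threshold: float = 0.95,
    change_threshold: float = 0.05,
    eps: float = 1e-6,
) -> pd.Series:
    """Flag genes whose effect trajectory looks linear.

    A gene is linear-like when its trajectory correlates with the best-fit
    line at r > ``r_threshold`` AND the relative change between some pair
    of consecutive time points exceeds ``change_threshold`` (a flat line
    satisfies the correlation clause vacuously but shows no change, so it
    is retained).  Trajectories with fewer than 3 points cannot be
    assessed and are retained.
    """
    flags = {}
    for gene, traj in trajectories.items():
        traj = np.asarray(traj, dtype=float)
        traj = traj[np.isfinite(traj)]
        if traj.size < 3:
            flags[gene] = False
            continue
        t = np.arange(traj.size, dtype=float)
        if np.std(traj) < eps:
            r = 0.0
        else:
            r = abs(float(np.corrcoef(t, traj)[0, 1]))
        rel_change = np.abs(np.diff(traj)) / np.maximum(np.abs(traj[:-1]), eps)
        flags[gene] = bool(r > r_threshold and np.max(rel_change) > change_threshold)
    return pd.Series(flags, name="linear_like")


def group_by_pattern(catalogue: pd.DataFrame, min_size: int = 2):
    """Exact-pattern groups (>= ``min_size`` members) plus the singletons.

    ``catalogue`` needs (gene, pattern) columns.  Returns
    (list of PatternGroup, list of singleton genes).
    """
    groups, singletons = [], []
    if len(catalogue) == 0:
        return groups, singletons
    for pattern, sub in catalogue.groupby("pattern", sort=True):
        genes = sorted(sub["gene"])
        if len(genes) >= min_size:
            groups.append(PatternGroup(pattern, genes))
        else:
            singletons.extend(genes)
    return groups, sorted(singletons)


def _is_trans(gene_pos, var_pos, cis_window_kb: float) -> bool:
    if gene_pos is None or var_pos is None:
        return False
    g_chrom, g_kb = gene_pos
    v_chrom, v_kb = var_pos
    if g_chrom != v_chrom:
        return True
    return abs(float(g_kb) - float(v_kb)) > cis_window_kb


def build_modules(
    catalogue: pd.DataFrame,
    gene_positions: pd.DataFrame,
    variant_positions: pd.DataFrame,
    cis_window_kb: float = 50.0,
    min_size: int = 2,
) -> list:
    """Group genes sharing a trans-associated variant into modules.

    ``catalogue`` needs (gene, variant) columns; the position frames are
    indexed by gene/variant id with (chrom, kb) columns.  Associations
    within ``cis_window_kb`` of the gene on the same chromosome are cis
    and excluded; genes without positions are skipped.  Modules keep
    >= ``min_size`` members and are ordered by variant id.
    """
    members: dict = {}
    for rec in catalogue.itertuples():
        if rec.gene not in gene_positions.index or rec.variant not in variant_positions.index:
            continue
        g = gene_positions.loc[rec.gene]
        v = variant_positions.loc[rec.variant]
        if _is_trans((g["chrom"], g["kb"]), (v["chrom"], v["kb"]), cis_window_kb):
            members.setdefault(rec.variant, []).append(rec.gene)
    modules = []
    for variant in sorted(members, key=str):
        genes = sorted(members[variant])
        if len(genes) < min_size:
            continue
        v = variant_positions.loc[variant]
        modules.append(
            CoassociationModule(variant, v["chrom"], float(v["kb"]), genes)
        )
    return modules


def pattern_enrichment(
    module: CoassociationModule,
    catalogue: pd.DataFrame,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pattern inside a module.

    The catalogue (gene, pattern) is the background population; for each
    pattern present in the module, the upper-tail hypergeometric p of
    drawing at least the observed count is computed and BH-adjusted across
    the tested patterns.
    """
    cat = catalogue.set_index("gene")["pattern"]
    missing = [g for g in module.genes if g not in cat.index]
    if missing:
        raise ValueError(
            f"module genes absent from the catalogue background: {missing[:5]}"
        )
    M = len(cat)
    n = len(module.genes)
    module_patterns = cat.loc[module.genes]
    rows = []
    for pattern, k in module_patterns.value_counts().items():
        K = int((cat == pattern).sum())
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append(dict(pattern=pattern, in_module=int(k), in_background=K, p=p))
    out = pd.DataFrame(rows).sort_values("p", ignore_index=True)
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, *_ = multipletests(out["p"], alpha=fdr, method="fdr_bh")
    out["p_adj"] = p_adj
    out["enriched"] = reject
    return out
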