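"""Observed and background effect samples.

For a variant splitting the panel into allele groups A and B, the *observed
effect* of the variant on a gene at time t is the expression difference
``y_i^t - y_j^t`` between a strain i carrying A and a strain j carrying B.
The *background* sample collects differences between strains carrying the
same allele; under the null of no genetic effect the two samples come from
the same distribution, which is what the association score exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import ExpressionDataset, StrainGroups

__all__ = [
    "EffectObservations",
    "observed_effects",
    "background_effects",
    "effect_observations",
    "suff_stats",
]


@dataclass
class EffectObservations:
    """Per-time-point cross-allele (D) and same-allele (B) difference samples.

    Only *retained* time points appear: a time point is dropped (never
    imputed) when one allele group has no observed strain there.  Sign
    conventions: D is always (A strain) minus (B strain); within-group pairs
    use ascending strain index.
    """

    variant_id: object
    time_points: np.ndarray  # retained time points, strictly increasing
    D: list  # list of 1-D arrays, one per retained time point
    B: list  # same layout; may contain empty arrays

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    def d_counts(self) -> np.ndarray:
        return np.array([len(d) for d in self.D])

    def b_counts(self) -> np.ndarray:
        return np.array([len(b) for b in self.B])


def _gene_matrix(ds: ExpressionDataset, gene) -> np.ndarray:
    return ds.values[ds.gene_index(gene)]  # (N, T)


def _retained_times(ya: np.ndarray, yb: np.ndarray):
    obs_a = np.isfinite(ya).sum(axis=0)
    obs_b = np.isfinite(yb).sum(axis=0)
    return np.flatnonzero((obs_a > 0) & (obs_b > 0))


def observed_effects(
    ds: ExpressionDataset, groups: StrainGroups, gene
) -> EffectObservations:
    """Cross-allele differences D_t for every observed (A, B) strain pair."""
    y = _gene_matrix(ds, gene)
    ya, yb = y[groups.group_a], y[groups.group_b]
    keep = _retained_times(ya, yb)
    D = []
    for t in keep:
        a = ya[:, t][np.isfinite(ya[:, t])]
        b = yb[:, t][np.isfinite(yb[:, t])]
        D.append((a[:, None] - b[None, :]).ravel())
    return EffectObservations(
        groups.variant_id, ds.time_points[keep], D, [np.empty(0)] * len(keep)
    )


def background_effects(
    ds: ExpressionDataset, groups: StrainGroups, gene
) -> EffectObservations:
    """Same-allele differences B_t over unordered within-group pairs."""
    y = _gene_matrix(ds, gene)
    ya, yb = y[groups.group_a], y[groups.group_b]
    keep = _retained_times(ya, yb)
    B = []
    for t in keep:
        vals = []
        for grp in (ya[:, t], yb[:, t]):
            g = grp[np.isfinite(grp)]
            if g.size >= 2:
                i, j = np.triu_indices(g.size, k=1)
                vals.append(g[i] - g[j])
        B.append(np.concatenate(vals) if vals else np.empty(0))
    return EffectObservations(
        groups.variant_id, ds.time_points[keep], [np.empty(0)] * len(keep), B
    )


def effect_observations(
    ds: ExpressionDataset, groups: StrainGroups, gene
) -> EffectObservations:
    """Both samples at once, on the shared retained time grid."""
    d = observed_effects(ds, groups, gene)
    b = background_effects(ds, groups, gene)
    return EffectObservations(groups.variant_id, d.time_points, d.D, b.B)


def suff_stats(sample: list) -> tuple:
    """Per-time-point (count, sum, sum-of-squares) of a difference sample.

    These are sufficient for all Gaussian likelihood computations in the
    two-state model, which lets the genome scan avoid materializing the
    quadratic number of strain pairs.
    """
    n = np.array([len(x) for x in sample], dtype=float)
    s1 = np.array([x.sum() if len(x) else 0.0 for x in sample])
    s2 = np.array([(np.square(x)).sum() if len(x) else 0.0 for x in sample])
    return n, s1, s2
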