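"""Input containers and readers for genotype and time-course expression data.

The mapping population is a panel of homozygous (inbred/recombinant-inbred)
strains: every strain carries one of exactly two parental alleles at each
marker, so a variant partitions the panel into two allele groups.  Expression
is a log-scale genes x strains x time-points tensor; missing entries are
allowed and encoded as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionDataset",
    "StrainGroups",
    "read_genotype_table",
    "write_genotype_table",
    "read_expression_table",
    "stabilize_variance",
    "split_by_allele",
    "align_strains",
]


@dataclass
class GenotypeMatrix:
    """Strains x variants biallelic homozygous genotype matrix.

    ``codes`` holds 0 for the A allele and 1 for the B allele.  ``positions``
    is an optional frame indexed by variant id with ``chrom`` and ``kb``
    (1-based kilobase coordinate) columns.  ``allele_labels`` records the
    original two symbols mapped onto (A, B) for reporting.
    """

    strain_ids: list
    variant_ids: list
    codes: np.ndarray  # (n_strains, n_variants) uint8 in {0, 1}
    positions: pd.DataFrame | None = None
    allele_labels: tuple = ("A", "B")

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        n, k = self.codes.shape
        if len(self.strain_ids) != n or len(self.variant_ids) != k:
            raise ValueError("codes shape does not match strain/variant ids")
        if len(set(self.strain_ids)) != n:
            raise ValueError("duplicate strain identifiers")
        if len(set(self.variant_ids)) != k:
            raise ValueError("duplicate variant identifiers")
        if self.codes.size and self.codes.max() > 1:
            raise ValueError("genotype codes must be 0 (A) or 1 (B)")
        if self.positions is not None:
            self.positions = self.positions.loc[self.variant_ids]

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def variant_index(self, variant) -> int:
        try:
            return self.variant_ids.index(variant)
        except ValueError:
            raise KeyError(f"unknown variant: {variant!r}") from None

    def subset_strains(self, strain_ids) -> "GenotypeMatrix":
        idx = [self.strain_ids.index(s) for s in strain_ids]
        return GenotypeMatrix(
            list(strain_ids),
            list(self.variant_ids),
            self.codes[idx],
            self.positions,
            self.allele_labels,
        )


@dataclass
class ExpressionDataset:
    """Log-scale expression indexed by (gene, strain, time point).

    ``values`` has shape (n_genes, n_strains, n_times) with NaN marking
    unobserved entries; time points are strictly increasing minutes.
    """

    gene_ids: list
    strain_ids: list
    time_points: np.ndarray
    values: np.ndarray  # (G, N, T) float64, NaN = missing

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) == 0:
            raise ValueError("expression dataset contains no genes")
        if self.values.shape != (
            len(self.gene_ids),
            len(self.strain_ids),
            len(self.time_points),
        ):
            raise ValueError("values shape does not match ids/time points")
        if np.any(np.diff(self.time_points) <= 0):
            raise ValueError("time points must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    @property
    def observed_mask(self) -> np.ndarray:
        """(G, N, T) boolean presence indicator."""
        return np.isfinite(self.values)

    def gene_index(self, gene) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene: {gene!r}") from None

    def subset_strains(self, strain_ids) -> "ExpressionDataset":
        idx = [self.strain_ids.index(s) for s in strain_ids]
        return ExpressionDataset(
            list(self.gene_ids),
            list(strain_ids),
            self.time_points,
            self.values[:, idx, :],
        )


@dataclass
class StrainGroups:
    """Partition of strain indices into the two allele groups of a variant."""

    variant_id: object
    group_a: np.ndarray
    group_b: np.ndarray
    testable: bool = True

    def __post_init__(self) -> None:
        self.group_a = np.asarray(self.group_a, dtype=int)
        self.group_b = np.asarray(self.group_b, dtype=int)
        if np.intersect1d(self.group_a, self.group_b).size:
            raise ValueError("allele groups overlap")

    @property
    def n_a(self) -> int:
        return self.group_a.size

    @property
    def n_b(self) -> int:
        return self.group_b.size


# ---------------------------------------------------------------------------
# readers / writers


def read_genotype_table(
    path,
    positions_path=None,
    alleles: tuple | None = None,
    het_codes: tuple = ("H", "HET"),
):
    """Read a strains-in-rows, variants-in-columns tab-separated genotype table.

    ``alleles`` optionally declares the two-symbol alphabet mapped onto
    (A, B); by default the two symbols found in the table are used in sorted
    order.  A column with more than two distinct symbols, or any symbol in
    ``het_codes``, is rejected (the method is restricted to homozygous
    biallelic markers).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df = df.apply(lambda col: col.str.strip())
    symbols = pd.unique(df.values.ravel())
    for h in het_codes:
        if h in symbols:
            raise ValueError(
                f"heterozygous code {h!r} found; only homozygous biallelic "
                "genotypes are supported"
            )
    if alleles is None:
        if len(symbols) != 2:
            bad = _first_non_biallelic(df)
            raise ValueError(
                f"variant {bad!r} is not biallelic: expected exactly two "
                f"allele symbols, found {sorted(map(str, symbols))}"
            )
        alleles = tuple(sorted(symbols))
    unknown = set(symbols) - set(alleles)
    if unknown:
        rows, cols = np.nonzero(df.isin(unknown).values)
        where = ", ".join(
            f"{df.index[r]}/{df.columns[c]}" for r, c in zip(rows[:5], cols[:5])
        )
        raise ValueError(
            f"unknown allele symbols {sorted(map(str, unknown))} at {where}"
        )
    for col in df.columns:
        if df[col].nunique() > 2:
            raise ValueError(f"variant {col!r} has more than two allele codes")
    codes = (df.values == alleles[1]).astype(np.uint8)
    positions = None
    if positions_path is not None:
        positions = pd.read_csv(positions_path, sep="\t")
        positions = positions.set_index(positions.columns[0])
        positions.columns = ["chrom", "kb"][: len(positions.columns)]
    return GenotypeMatrix(
        list(df.index), list(df.columns), codes, positions, tuple(alleles)
    )


def _first_non_biallelic(df: pd.DataFrame):
    for col in df.columns:
        if df[col].nunique() > 2:
            return col
    return df.columns[0] if len(df.columns) else None


def write_genotype_table(geno: GenotypeMatrix, path, positions_path=None) -> None:
    labels = np.asarray(geno.allele_labels, dtype=object)
    df = pd.DataFrame(
        labels[geno.codes], index=geno.strain_ids, columns=geno.variant_ids
    )
    df.index.name = "strain"
    df.to_csv(path, sep="\t")
    if positions_path is not None and geno.positions is not None:
        geno.positions.to_csv(positions_path, sep="\t")


def read_expression_table(path, layout: str = "long", log2: bool = False):
    """Read expression data.

    ``layout='long'`` expects one file with columns (gene, strain, time_min,
    log_expr); ``layout='wide'`` expects a mapping {time_minutes: path} of
    per-time-point genes x strains tables.  Strain sets may differ between
    time points; absent combinations become NaN (missing).  ``log2`` applies
    a log2 transform on load for raw-scale inputs.
    """
    if layout == "long":
        df = pd.read_csv(path, sep="\t")
        df.columns = ["gene", "strain", "time_min", "log_expr"]
        df["log_expr"] = pd.to_numeric(df["log_expr"], errors="raise")
        dup = df.duplicated(["gene", "strain", "time_min"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                "duplicate record for "
                f"({first['gene']}, {first['strain']}, {first['time_min']})"
            )
        cube = df.pivot_table(
            index="gene", columns=["strain", "time_min"], values="log_expr"
        )
        genes = list(cube.index)
        strains = sorted({s for s, _ in cube.columns})
        times = np.array(sorted({t for _, t in cube.columns}), dtype=float)
        values = np.full((len(genes), len(strains), len(times)), np.nan)
        for (s, t), col in cube.items():
            values[:, strains.index(s), int(np.searchsorted(times, t))] = col.values
    elif layout == "wide":
        frames = {
            float(t): pd.read_csv(p, sep="\t", index_col=0).apply(
                pd.to_numeric, errors="raise"
            )
            for t, p in dict(path).items()
        }
        times = np.array(sorted(frames), dtype=float)
        genes = list(frames[times[0]].index)
        strains = sorted({s for f in frames.values() for s in f.columns})
        values = np.full((len(genes), len(strains), len(times)), np.nan)
        for j, t in enumerate(times):
            f = frames[t].reindex(index=genes, columns=strains)
            values[:, :, j] = f.values
    else:
        raise ValueError(f"unknown layout: {layout!r}")
    if log2:
        values = np.log2(values)
    return ExpressionDataset(genes, strains, times, values)


def align_strains(ds: ExpressionDataset, geno: GenotypeMatrix):
    """Restrict both inputs to their common strains, in genotype order."""
    common = [s for s in geno.strain_ids if s in set(ds.strain_ids)]
    if not common:
        raise ValueError("expression and genotype data share no strains")
    return ds.subset_strains(common), geno.subset_strains(common)


# ---------------------------------------------------------------------------
# per-variant preprocessing


def split_by_allele(geno: GenotypeMatrix, variant) -> StrainGroups:
    """Partition strains into the A and B allele groups of ``variant``.

    A monomorphic variant (an empty group) is returned with
    ``testable=False`` and is skipped by genome scans.
    """
    k = geno.variant_index(variant)
    col = geno.codes[:, k]
    group_a = np.flatnonzero(col == 0)
    group_b = np.flatnonzero(col == 1)
    testable = group_a.size > 0 and group_b.size > 0
    return StrainGroups(variant, group_a, group_b, testable=testable)


def stabilize_variance(
    ds: ExpressionDataset,
    geno: GenotypeMatrix,
    variant,
    target_variance: float | None = None,
) -> ExpressionDataset:
    """Equalize the within-(time point, allele group) variance of every gene.

    Each observed cell is rescaled as ``x -> m + (x - m) * (v / s)`` where
    ``m`` and ``s`` are the allele group's sample mean and standard
    deviation at that time point, so every group variance becomes ``v^2``
    while the means -- and hence the genetic effects -- are unchanged.
    By default ``v^2`` is the gene's average within-group variance across
    all (time point, allele) cells: the spread is equalized over time
    without altering the gene's overall noise scale, which would otherwise
    distort the effect-to-noise ratio.  Passing an explicit
    ``target_variance`` fixes an absolute constant instead.  Groups with
    zero variance are passed through unchanged with a warning.
    """
    groups = split_by_allele(geno, variant)
    out = ds.values.copy()
    degenerate = 0
    blocks = []
    for idx in (groups.group_a, groups.group_b):
        if idx.size == 0:
            continue
        block = out[:, idx, :]  # (G, n_g, T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(block, axis=1, keepdims=True)
            s = np.nanstd(block, axis=1, keepdims=True, ddof=1)
        blocks.append((idx, block, m, s))
    if target_variance is None:
        cells = np.concatenate(
            [s[:, 0, :] ** 2 for _, _, _, s in blocks], axis=1
        )  # (G, n_groups * T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            target = np.nanmean(cells, axis=1)[:, None, None]  # (G, 1, 1)
    else:
        target = np.full((ds.n_genes, 1, 1), float(target_variance))
    scale = np.sqrt(target)
    for idx, block, m, s in blocks:
        ok = s > 1e-12
        degenerate += int(np.sum(~ok & np.isfinite(s)))
        factor = np.where(ok, scale / np.where(ok, s, 1.0), 1.0)
        out[:, idx, :] = m + (block - m) * factor
    if degenerate:
        warnings.warn(
            f"{degenerate} zero-variance (time point, allele) groups left "
            "unscaled during variance stabilization",
            RuntimeWarning,
            stacklevel=2,
        )
    return replace(ds, values=out)
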