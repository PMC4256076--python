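"""Synthetic mapping panels with time-varying genetic effects.

The generator emulates a homozygous segregant panel: strains draw one of
two alleles with equal probability at each variant, and each *associated*
gene receives a temporal mean-effect curve mu(t) tied to one causal
variant -- strains carrying the A allele express N(mu(t), sigma) while B
strains express N(0, sigma), so the expected cross-allele effect equals
mu(t).  Four waveform families describe how the effect moves over time:

sustained  a sigmoid rise to the effect size h (single state transition)
impulse    a pulse of length l (product of two sigmoids, peak h)
complex    two impulses concatenated, one per half of the time course
linear     a steady ramp from 0 to h

The ground-truth two-state pattern calls a time point H when mu(t) > h/2.
A second dataset family samples the H/L state path itself from the
Markov-chain sequence prior and is used to measure pattern error rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .dataset_io import ExpressionDataset, GenotypeMatrix

__all__ = [
    "TruthRecord",
    "SyntheticCollection",
    "gen_genotypes",
    "waveform",
    "true_pattern",
    "gen_collection",
    "gen_error_rate_dataset",
    "sample_state_path",
    "apply_missingness",
    "write_collection",
    "read_truth_table",
    "EFFECT_SIZE_GRID",
    "TIME_POINT_GRID",
]

# the full benchmark grid: 8 effect sizes x 9 time-course lengths
EFFECT_SIZE_GRID = tuple(0.125 * k for k in range(1, 9))
TIME_POINT_GRID = tuple(range(3, 28, 3))


@dataclass
class TruthRecord:
    gene: str
    is_associated: bool
    variant: str | None = None
    pattern: str | None = None
    effect_size: float = np.nan
    waveform: str | None = None


@dataclass
class SyntheticCollection:
    genotypes: GenotypeMatrix
    expression: ExpressionDataset
    truth: pd.DataFrame  # one row per gene, TruthRecord fields
    seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def truth_records(self) -> list:
        return [TruthRecord(**row) for row in self.truth.to_dict("records")]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gen_genotypes(
    n_strains: int = 50,
    n_variants: int = 100,
    seed=None,
    variants_per_chrom: int = 20,
    spacing_kb: float = 25.0,
) -> GenotypeMatrix:
    """I.i.d. fair-coin biallelic genotypes on a synthetic genome."""
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 2, size=(n_strains, n_variants), dtype=np.uint8)
    strains = [f"S{i + 1:03d}" for i in range(n_strains)]
    variants = [f"V{k + 1:03d}" for k in range(n_variants)]
    positions = pd.DataFrame(
        {
            "chrom": [f"chr{k // variants_per_chrom + 1}" for k in range(n_variants)],
            "kb": [spacing_kb * (k % variants_per_chrom + 1) for k in range(n_variants)],
        },
        index=pd.Index(variants, name="variant"),
    )
    return GenotypeMatrix(strains, variants, codes, positions)


def waveform(
    kind: str,
    T: int,
    h: float,
    q: float = 0.5,
    v: float = 0.5,
    steepness: float = 10.0,
    impulse_len: int | None = None,
) -> np.ndarray:
    """Mean-effect curve mu(t) on the integer grid t = 1..T.

    sustained: ``h * sigmoid(q (t - v T))`` with q = v = 0.5 (half height at
    the midpoint).  impulse: product of rising and falling sigmoids --
    sharp transitions into and out of a high-effect steady state
    (``steepness`` controls how flat the plateau is) -- centred and
    spanning ``impulse_len`` grid points (default round(T/3)), peak
    normalized to h.  complex: two impulses, one per half of the course.
    linear: ramp 0 -> h.
    """
    if T < 2:
        raise ValueError("need at least 2 time points")
    if h < 0:
        raise ValueError("effect size must be non-negative")
    t = np.arange(1, T + 1, dtype=float)
    if kind == "sustained":
        return h * _sigmoid(q * (t - v * T))
    if kind == "impulse":
        l = int(round(T / 3)) if impulse_len is None else int(impulse_len)
        if l < 1 or l >= T:
            raise ValueError(f"impulse length {l} must be in [1, T)")
        t_on = (T - l + 1) / 2.0
        t_off = t_on + l
        raw = _sigmoid(steepness * (t - t_on)) * _sigmoid(-steepness * (t - t_off))
        return h * raw / raw.max()
    if kind == "complex":
        t1 = (T + 1) // 2
        t2 = T - t1
        halves = [
            waveform("impulse", ti, h, steepness=steepness) for ti in (t1, t2)
        ]
        return np.concatenate(halves)
    if kind == "linear":
        return h * (t - 1.0) / (T - 1.0)
    raise ValueError(f"unknown waveform kind: {kind!r}")


def true_pattern(mu: np.ndarray, h: float) -> str:
    """Ground-truth H/L pattern: H wherever the mean effect exceeds h/2."""
    return "".join("H" if m > h / 2.0 else "L" for m in np.asarray(mu))


def _strain_expression(rng, n_strains, mu_t, a_strains, sigma):
    """(n_strains, T) expression with the effect added to A-allele strains.

    ``sigma`` parameterizes the *observed effect*: the simulated
    cross-allele difference between two strains is marginally
    N(mu(t), sigma^2), so the per-strain expression noise is sigma/sqrt(2).
    """
    T = mu_t.size
    y = rng.normal(0.0, sigma / np.sqrt(2.0), size=(n_strains, T))
    y[a_strains] += mu_t[None, :]
    return y


def gen_collection(
    kind: str,
    T: int,
    h: float,
    n_genes: int = 500,
    n_assoc: int = 300,
    sigma: float = 1.0,
    seed=None,
    n_strains: int = 50,
    n_variants: int = 100,
    impulse_len: int | None = None,
    time_step_min: float = 10.0,
) -> SyntheticCollection:
    """One synthetic collection: genotyped panel + genes with waveform effects.

    The first ``n_assoc`` genes are associated, each with a uniformly drawn
    causal variant; the remainder are unassociated noise genes.
    """
    if n_assoc > n_genes:
        raise ValueError("n_assoc cannot exceed n_genes")
    ss = np.random.SeedSequence(seed)
    geno_seed, expr_seed = ss.spawn(2)
    geno = gen_genotypes(n_strains, n_variants, seed=geno_seed)
    rng = np.random.default_rng(expr_seed)
    mu_t = waveform(kind, T, h, impulse_len=impulse_len)
    pattern = true_pattern(mu_t, h)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    values = np.empty((n_genes, n_strains, T))
    truth_rows = []
    for i, gene in enumerate(genes):
        if i < n_assoc:
            k = int(rng.integers(n_variants))
            a_strains = np.flatnonzero(geno.codes[:, k] == 0)
            values[i] = _strain_expression(rng, n_strains, mu_t, a_strains, sigma)
            truth_rows.append(
                dict(
                    gene=gene,
                    is_associated=True,
                    variant=geno.variant_ids[k],
                    pattern=pattern,
                    effect_size=h,
                    waveform=kind,
                )
            )
        else:
            values[i] = _strain_expression(rng, n_strains, mu_t * 0.0, [], sigma)
            truth_rows.append(
                dict(
                    gene=gene,
                    is_associated=False,
                    variant=None,
                    pattern=None,
                    effect_size=np.nan,
                    waveform=None,
                )
            )
    expr = ExpressionDataset(
        genes,
        list(geno.strain_ids),
        time_step_min * np.arange(T),
        values,
    )
    return SyntheticCollection(
        geno,
        expr,
        pd.DataFrame(truth_rows),
        seed=seed,
        params=dict(kind=kind, T=T, h=h, sigma=sigma, impulse_len=impulse_len),
    )


def sample_state_path(T: int, lam: float, pi: float = 0.5, rng=None) -> np.ndarray:
    """Draw an H/L path (1/0 ints) from the Markov-chain sequence prior."""
    if not (0.0 < lam <= 0.5):
        raise ValueError("lam must be in (0, 0.5]")
    rng = np.random.default_rng(rng)
    path = np.empty(T, dtype=np.int8)
    path[0] = rng.random() < pi
    switches = rng.random(T - 1) < lam
    for t in range(1, T):
        path[t] = path[t - 1] ^ switches[t - 1]
    return path


def gen_error_rate_dataset(
    T: int = 9,
    lambda_true: float = 0.5,
    mu_h: float = 0.75,
    mu_l: float = 0.0,
    sigma: float = 1.0,
    n_genes: int = 150,
    seed=None,
    n_strains: int = 50,
    n_variants: int = 100,
    time_step_min: float = 10.0,
) -> SyntheticCollection:
    """Pattern-recovery dataset: state paths drawn from the sequence prior.

    Every gene is associated; its H/L path over the T time points is
    sampled from the Markov prior with transition probability
    ``lambda_true`` and its mean effect at time t is ``mu_h`` (H) or
    ``mu_l`` (L).
    """
    ss = np.random.SeedSequence(seed)
    geno_seed, expr_seed = ss.spawn(2)
    geno = gen_genotypes(n_strains, n_variants, seed=geno_seed)
    rng = np.random.default_rng(expr_seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    values = np.empty((n_genes, n_strains, T))
    truth_rows = []
    for i, gene in enumerate(genes):
        path = sample_state_path(T, lambda_true, rng=rng)
        mu_t = np.where(path == 1, mu_h, mu_l)
        k = int(rng.integers(n_variants))
        a_strains = np.flatnonzero(geno.codes[:, k] == 0)
        values[i] = _strain_expression(rng, n_strains, mu_t, a_strains, sigma)
        truth_rows.append(
            dict(
                gene=gene,
                is_associated=True,
                variant=geno.variant_ids[k],
                pattern="".join("H" if s else "L" for s in path),
                effect_size=mu_h,
                waveform="markov",
            )
        )
    expr = ExpressionDataset(
        genes, list(geno.strain_ids), time_step_min * np.arange(T), values
    )
    return SyntheticCollection(
        geno,
        expr,
        pd.DataFrame(truth_rows),
        seed=seed,
        params=dict(
            kind="markov", T=T, lambda_true=lambda_true, mu_h=mu_h,
            mu_l=mu_l, sigma=sigma,
        ),
    )


def apply_missingness(
    collection: SyntheticCollection, k_percent: float, seed=None
) -> SyntheticCollection:
    """Omit k% of strains, independently redrawn at every time point."""
    if not (0 <= k_percent < 100):
        raise ValueError("k_percent must be in [0, 100)")
    if k_percent == 0:
        return collection
    expr = collection.expression
    rng = np.random.default_rng(seed)
    n = expr.n_strains
    n_drop = int(round(k_percent / 100.0 * n))
    if n - n_drop < 4:
        warnings.warn(
            f"dropping {n_drop} of {n} strains may leave fewer than 2 "
            "strains per allele at some time points",
            RuntimeWarning,
            stacklevel=2,
        )
    values = expr.values.copy()
    for t in range(expr.n_times):
        dropped = rng.choice(n, size=n_drop, replace=False)
        values[:, dropped, t] = np.nan
    new_expr = replace(expr, values=values)
    return replace(
        collection,
        expression=new_expr,
        params={**collection.params, "missing_pct": k_percent},
    )


# ---------------------------------------------------------------------------
# plain-text round trip


def write_collection(collection: SyntheticCollection, out_dir) -> None:
    """Write genotype/positions/expression/truth TSVs into a directory."""
    from .dataset_io import write_genotype_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_table(
        collection.genotypes, out / "genotypes.tsv", out / "positions.tsv"
    )
    expr = collection.expression
    g, n, t = np.meshgrid(
        np.arange(expr.n_genes),
        np.arange(expr.n_strains),
        np.arange(expr.n_times),
        indexing="ij",
    )
    long = pd.DataFrame(
        {
            "gene": np.asarray(expr.gene_ids)[g.ravel()],
            "strain": np.asarray(expr.strain_ids)[n.ravel()],
            "time_min": expr.time_points[t.ravel()],
            "log_expr": expr.values.ravel(),
        }
    ).dropna(subset=["log_expr"])
    long.to_csv(out / "expression.tsv", sep="\t", index=False)
    collection.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_associated"] = df["is_associated"].astype(bool)
    for col in ("variant", "pattern", "waveform"):
        df[col] = df[col].where(df[col].notna(), None)
    return df
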