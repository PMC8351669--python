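"""Quality control, filtering and normalization of bulk RNA-seq count matrices.

This module hosts the shared core containers (:class:`CountMatrix`,
:class:`SampleTable`, :class:`ExpressionMatrix`, :class:`SampleQCReport`) and
the preprocessing chain applied before any modelling:

1. drop samples with shallow libraries (default < 4,000,000 reads),
2. drop outlier samples by standardized sample-network connectivity (z.K),
3. drop low-count genes,
4. median-of-ratios size factors and a closed-form negative-binomial
   variance-stabilizing transformation (VST),
5. PCA on the most variable genes.

The sample network used for outlier detection is the Oldham-style network:
pairwise Pearson correlation between sample expression columns, adjacency
``((1 + r) / 2) ** 2``, per-sample connectivity ``K_i = sum_{j != i} A_ij``,
standardized to z.K.  Samples with ``|z.K|`` above a threshold (default 2
standard deviations) are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_LIBRARY_SIZE = 4_000_000
DEFAULT_ZK_THRESHOLD = 2.0
DEFAULT_LOW_COUNT = 10
DEFAULT_N_TOP_PCA = 500

# floor used when a fitted NB dispersion intercept comes out non-positive
MIN_DISPERSION_A0 = 1e-8


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample integer count matrix with optional biotype labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    biotype: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if self.biotype is not None:
            self.biotype = pd.Series(self.biotype).reindex(self.gene_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_samples(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        if np.asarray(keep).dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            counts=self.counts[:, idx],
            biotype=self.biotype,
        )

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        if np.asarray(keep).dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        genes = [self.gene_ids[i] for i in idx]
        return CountMatrix(
            gene_ids=genes,
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
            biotype=None if self.biotype is None else self.biotype.loc[genes],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, biotype: pd.Series | None = None) -> "CountMatrix":
        return cls(
            gene_ids=list(df.index),
            sample_ids=list(df.columns),
            counts=df.to_numpy(),
            biotype=biotype,
        )

    @classmethod
    def read_tsv(cls, path, annotation_path=None) -> "CountMatrix":
        """Read a counts TSV (first column gene_id, header = sample ids)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        biotype = None
        if annotation_path is not None:
            ann = pd.read_csv(annotation_path, sep="\t").set_index("gene_id")
            biotype = ann["biotype"]
        return cls.from_frame(df, biotype=biotype)

    def write_tsv(self, path) -> None:
        self.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


@dataclass
class SampleTable:
    """Per-sample metadata: tissue, age in months, binary sex code (0=F, 1=M)."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "tissue", "age_months")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        t = self.table.copy()
        if "sex_code" not in t.columns:
            if "sex" not in t.columns:
                raise ValueError("metadata needs a 'sex' (F/M) or 'sex_code' column")
            t["sex_code"] = t["sex"].map({"F": 0, "M": 1})
        if not set(t["sex_code"].unique()) <= {0, 1}:
            raise ValueError("sex_code must be 0 (female) or 1 (male)")
        if (t["age_months"] <= 0).any():
            raise ValueError("age_months must be positive")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        self.table = t.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t"))

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing[:5]}")
        return t.loc[list(sample_ids)]

    def min_group_size(self, tissue: str | None = None) -> int:
        """Smallest number of samples at any observed age (within a tissue)."""
        t = self.table
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return int(t.groupby("age_months").size().min())


@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued matrix on the variance-stabilized scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, keep) -> "ExpressionMatrix":
        if np.asarray(keep).dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
        )

    def subset_genes(self, keep) -> "ExpressionMatrix":
        if np.asarray(keep).dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
        )


@dataclass
class SampleQCReport:
    """Per-sample QC: library size, depth pass flag, z.K, outlier flag."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "library_size", "depth_pass", "z_k", "outlier"]
        )
    )

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample-level filters
# ---------------------------------------------------------------------------

def filter_samples_by_depth(
    counts: CountMatrix, min_reads: int = DEFAULT_MIN_LIBRARY_SIZE
) -> tuple[CountMatrix, SampleQCReport]:
    """Drop samples whose library size is below ``min_reads``.

    The boundary is inclusive: a sample with exactly ``min_reads`` total
    reads is retained.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    lib = counts.library_sizes()
    keep = lib >= min_reads
    report = SampleQCReport(
        pd.DataFrame(
            {
                "sample_id": counts.sample_ids,
                "library_size": lib,
                "depth_pass": keep,
                "z_k": np.nan,
                "outlier": False,
            }
        )
    )
    if not keep.any():
        raise ValueError("no samples retained after depth filtering")
    return counts.subset_samples(keep), report


def detect_outlier_samples(
    expr: ExpressionMatrix, sd_threshold: float = DEFAULT_ZK_THRESHOLD
) -> SampleQCReport:
    """Flag outlier samples by standardized sample-network connectivity.

    Builds the sample correlation network (Pearson r between expression
    columns), adjacency ``((1+r)/2)**2``, connectivity ``K_i`` excluding the
    self-edge, and flags samples whose standardized connectivity z.K deviates
    from the mean by more than ``sd_threshold`` standard deviations (in
    absolute value).  A degenerate network (sd K = 0) flags nothing.
    """
    m = expr.n_samples
    if m < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    X = expr.values
    # Pearson correlation between sample columns; constant columns give r=0
    Xc = X - X.mean(axis=0, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=0))
    safe = np.where(norms > 0, norms, 1.0)
    R = (Xc / safe).T @ (Xc / safe)
    R[norms == 0, :] = 0.0
    R[:, norms == 0] = 0.0
    np.fill_diagonal(R, 1.0)
    A = ((1.0 + R) / 2.0) ** 2
    K = A.sum(axis=1) - np.diag(A)
    sd = K.std(ddof=1)
    # guard against fp noise on exactly-equal connectivities
    if sd > 1e-12 * max(1.0, abs(K.mean())):
        z = (K - K.mean()) / sd
    else:
        z = np.zeros_like(K)
    outlier = np.abs(z) > sd_threshold
    return SampleQCReport(
        pd.DataFrame(
            {
                "sample_id": expr.sample_ids,
                "library_size": np.nan,
                "depth_pass": True,
                "z_k": z,
                "outlier": outlier,
            }
        )
    )


# ---------------------------------------------------------------------------
# Gene-level filter
# ---------------------------------------------------------------------------

def filter_low_count_genes(
    counts: CountMatrix,
    min_count: int = DEFAULT_LOW_COUNT,
    min_samples: int = 1,
    mode: str = "per_sample",
) -> CountMatrix:
    """Keep genes with count strictly above ``min_count`` in >= ``min_samples``.

    ``mode='per_sample'`` requires ``count > min_count`` in at least
    ``min_samples`` individual samples; ``mode='row_total'`` instead requires
    the gene's total count across samples to exceed ``min_count``.
    """
    if min_samples > counts.n_samples:
        raise ValueError("min_samples exceeds the number of samples")
    if mode == "per_sample":
        keep = (counts.counts > min_count).sum(axis=1) >= min_samples
    elif mode == "row_total":
        keep = counts.counts.sum(axis=1) > min_count
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts.subset_genes(keep)


# ---------------------------------------------------------------------------
# Normalization: size factors + VST
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    Per gene, the geometric mean across samples is computed over genes with
    strictly positive counts in every sample; each sample's factor is the
    median across those genes of count / geometric mean.
    """
    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    all_pos = np.all(X > 0, axis=1)
    if not all_pos.any():
        raise ValueError("no gene with all-positive counts; cannot estimate size factors")
    Xp = X[all_pos].astype(float)
    geomean = np.exp(np.log(Xp).mean(axis=1, keepdims=True))
    factors = np.median(Xp / geomean, axis=0)
    return factors


def _fit_dispersion_trend(X: np.ndarray, size_factors: np.ndarray) -> tuple[float, float]:
    """Fit the mean-dispersion trend alpha(mu) = a1/mu + a0 robustly.

    Per-gene method-of-moments dispersions of normalized counts are regressed
    on 1/mean with a robust (Huber) linear fit; non-positive coefficients are
    clamped.
    """
    import statsmodels.api as sm

    q = X / size_factors[np.newaxis, :]
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    ok = mu > 0.5
    mu, var = mu[ok], var[ok]
    alpha = (var - mu) / mu**2
    use = alpha > 0
    if use.sum() < 10:
        return MIN_DISPERSION_A0, 0.0
    y = alpha[use]
    x = 1.0 / mu[use]
    design = sm.add_constant(x)
    fit = sm.RLM(y, design, M=sm.robust.norms.HuberT()).fit()
    a0, a1 = float(fit.params[0]), float(fit.params[1])
    if a0 <= 0:
        warnings.warn("fitted dispersion intercept non-positive; clamped to floor")
        a0 = MIN_DISPERSION_A0
    a1 = max(a1, 0.0)
    return a0, a1


def vst_transform(
    counts: CountMatrix,
    size_factors: np.ndarray | None = None,
    dispersion: tuple[float, float] | None = None,
    mode: str = "nb",
) -> ExpressionMatrix:
    """Variance-stabilizing transformation of normalized counts.

    For a negative-binomial mean-dispersion relation ``alpha(mu) = a1/mu + a0``
    the variance of a normalized count q is ``v(q) = (1 + a1) q + a0 q**2``;
    the closed-form antiderivative of ``1/sqrt(v)`` rescaled to base-2 is

        vst(q) = log2( (1 + a1 + 2 a0 q + 2 sqrt(a0 q (1 + a1 + a0 q)))
                       / (4 a0) )

    which approaches ``log2(q) + const`` for large q (and exactly the Poisson
    limit as a0 -> 0).  ``mode='log2p1'`` instead computes
    ``log2(count / size_factor + 1)``.
    """
    X = counts.counts.astype(float)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    q = X / size_factors[np.newaxis, :]
    if mode == "log2p1":
        vals = np.log2(q + 1.0)
    elif mode == "nb":
        if dispersion is None:
            a0, a1 = _fit_dispersion_trend(counts.counts, size_factors)
        else:
            a0, a1 = dispersion
            if a0 < 0 or a1 < 0:
                raise ValueError("dispersion parameters must be non-negative")
            if a0 == 0:
                a0 = MIN_DISPERSION_A0
        vals = np.log2(
            (1.0 + a1 + 2.0 * a0 * q + 2.0 * np.sqrt(a0 * q * (1.0 + a1 + a0 * q)))
            / (4.0 * a0)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=vals,
    )


# ---------------------------------------------------------------------------
# PCA on the most variable genes
# ---------------------------------------------------------------------------

def pca_top_variable(
    expr: ExpressionMatrix, n_top: int = DEFAULT_N_TOP_PCA, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples on the ``n_top`` genes with highest row variance.

    Genes are centered (optionally unit-scaled); returns sample scores
    (samples x components) and the percentage of variance per component.
    """
    if n_top > expr.n_genes:
        raise ValueError("n_top exceeds the number of genes")
    var = expr.values.var(axis=1, ddof=1)
    if np.all(var == 0):
        raise ValueError("expression matrix is constant; PCA undefined")
    top = np.argsort(var)[::-1][:n_top]
    M = expr.values[top, :]
    M = M - M.mean(axis=1, keepdims=True)
    if scale:
        sd = M.std(axis=1, ddof=1, keepdims=True)
        M = M / np.where(sd > 0, sd, 1.0)
    # samples as rows for the SVD: scores = U S of the samples x genes matrix
    U, S, _ = np.linalg.svd(M.T, full_matrices=False)
    scores = U * S
    var_pct = 100.0 * S**2 / (S**2).sum()
    return scores, var_pct
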