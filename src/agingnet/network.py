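"""Weighted gene co-expression network construction and module analysis.

The pipeline here follows the standard weighted-network recipe: a robust
biweight midcorrelation (bicor) matrix between genes, a signed soft-threshold
adjacency ``A_ij = ((1 + r_ij)/2) ** beta``, the topological overlap measure
(TOM) as the clustering similarity, average-linkage hierarchical clustering
of ``1 - TOM`` with a static branch cut, minimum module size filtering,
eigengene-based module merging, and module-trait statistics (module
eigengenes, module membership MM, gene significance GS, hub genes).

The branch-detection step is a static tree cut whose height is set by a
``deep_split`` preset in {0..4} (higher = more, smaller clusters); it is a
deliberate simplification of the hybrid dynamic tree cut algorithm and is
validated by recovery of planted modules, not by label identity with the R
implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

GREY = "grey"

DEFAULT_MIN_MODULE_SIZE = 50
DEFAULT_MERGE_HEIGHT = 0.15
DEFAULT_DEEP_SPLIT = 2
DEFAULT_R_MIN = 0.5
DEFAULT_FDR_ALPHA = 0.05
DEFAULT_MMGS_MIN = 0.5
DEFAULT_MMGS_ALPHA = 0.05
DEFAULT_HUB_GS = 0.2
DEFAULT_HUB_MM = 0.8

# Static-cut height as a fraction of the dendrogram's maximum merge height,
# indexed by deep_split (higher preset = lower cut = finer clusters).
DEEP_SPLIT_CUT = {0: 0.99, 1: 0.95, 2: 0.90, 3: 0.85, 4: 0.80}

# Fallback soft powers by sample count for signed networks, used when the
# scale-free fit index never reaches the target.
FALLBACK_POWERS = ((20, 16), (30, 14), (40, 12), (np.inf, 9))

# Soft powers used in the original study on GSE132040
STUDY_POWERS = {"brain": 7, "heart": 7, "liver": 5, "muscle": 6, "pancreas": 7}


# ---------------------------------------------------------------------------
# Biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_transform(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise biweight transform; returns (weighted deviations, zero-MAD mask)."""
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = (mad == 0).ravel()
    safe_mad = np.where(mad > 0, mad, 1.0)
    u = dev / (9.0 * safe_mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = dev * w
    return xt, zero_mad


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise biweight midcorrelation between the rows of X.

    For each row x: u_i = (x_i - med)/(9 MAD), weights (1-u^2)^2 on |u|<1,
    x~_i = (x_i - med) w_i, bicor(x, y) = <x~, y~>/(|x~||y~|).  Rows with zero
    MAD fall back to Pearson for every pair they participate in.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("bicor needs at least 3 samples")
    const = X.std(axis=1) == 0
    if const.any():
        raise ValueError("remove zero-variance genes before computing bicor")
    xt, zero_mad = _bicor_transform(X)
    norms = np.sqrt((xt**2).sum(axis=1, keepdims=True))
    xn = xt / np.where(norms > 0, norms, 1.0)
    R = xn @ xn.T
    if zero_mad.any():
        # per-variable Pearson fallback: any pair involving a zero-MAD row
        Xc = X - X.mean(axis=1, keepdims=True)
        pn = Xc / np.sqrt((Xc**2).sum(axis=1, keepdims=True))
        P = pn @ pn.T
        mask = zero_mad[:, None] | zero_mad[None, :]
        R = np.where(mask, P, R)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def bicor_pair(x: np.ndarray, y: np.ndarray) -> float:
    """bicor between two vectors (Pearson fallback on zero MAD)."""
    return float(bicor_matrix(np.vstack([x, y]))[0, 1])


# ---------------------------------------------------------------------------
# Soft threshold and adjacency
# ---------------------------------------------------------------------------

def adjacency_signed(cor: np.ndarray, beta: float) -> np.ndarray:
    """Signed adjacency A_ij = ((1 + r_ij)/2) ** beta, unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    A = ((1.0 + np.asarray(cor, dtype=float)) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned (~``n_bins`` bins over k); log10 frequency is
    regressed on log10 mean-k per bin.  Returns R^2 carrying the slope's
    sign, so a positive value means the distribution decays like a power law.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        return np.nan
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return np.nan
    slope, _, r, _, _ = stats.linregress(xs, ys)
    # positive index only for a decaying (negative-slope) distribution
    return float(-np.sign(slope) * r**2)


def _fallback_power(n_samples: int) -> int:
    for bound, power in FALLBACK_POWERS:
        if n_samples < bound:
            return power
    return FALLBACK_POWERS[-1][1]


def pick_soft_threshold(
    cor: np.ndarray,
    n_samples: int,
    powers: list[int] | None = None,
    target_fit: float = 0.8,
) -> tuple[pd.DataFrame, int]:
    """Scan soft powers for approximate scale-free topology.

    Returns the per-power table (fit index, mean connectivity) and the chosen
    power: the smallest whose signed fit index reaches ``target_fit``; if
    none does, a documented fallback keyed on the sample count applies.
    """
    if powers is None:
        powers = list(range(1, 21))
    if any(p < 1 for p in powers):
        raise ValueError("powers must be positive")
    rows = []
    chosen = None
    for beta in powers:
        A = adjacency_signed(cor, beta)
        k = A.sum(axis=1) - 1.0
        fit = scale_free_fit(k)
        rows.append({"power": beta, "fit_index": fit, "mean_k": float(k.mean())})
        if chosen is None and np.isfinite(fit) and fit >= target_fit:
            chosen = beta
    if chosen is None:
        chosen = _fallback_power(n_samples)
        warnings.warn(
            f"scale-free fit never reached {target_fit}; "
            f"falling back to power {chosen} for {n_samples} samples"
        )
    return pd.DataFrame(rows), chosen


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    L_ij = sum_{u != i,j} a_iu a_uj and k_i excludes the self-edge; unit
    diagonal.
    """
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    # (A0 @ A0)_ij = sum_u a_iu a_uj already excludes u=i and u=j (zero diagonal)
    L = A0 @ A0
    num = L + A0
    den = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(T, 1.0)
    return np.clip((T + T.T) / 2.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Module detection and eigengenes
# ---------------------------------------------------------------------------

@dataclass
class ModuleSet:
    """Per-gene module labels plus module eigengenes over samples."""

    gene_ids: list[str]
    labels: pd.Series  # gene_id -> module label ('grey' = unassigned)
    eigengenes: pd.DataFrame  # samples x modules, unit-norm columns

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def module_eigengenes(
    expr_values: np.ndarray, gene_ids: list[str], labels: pd.Series,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """First principal component of each module's z-scored expression.

    Unit-norm over samples, sign-oriented so the eigengene correlates
    positively with the module's mean z-profile.
    """
    idx = {g: i for i, g in enumerate(gene_ids)}
    mes = {}
    for module in sorted(set(labels) - {GREY}):
        members = [g for g in labels.index[labels == module]]
        rows = [idx[g] for g in members]
        M = expr_values[rows, :]
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, ddof=1, keepdims=True)
        Z = (M - mu) / np.where(sd > 0, sd, 1.0)
        if Z.shape[0] == 1:
            me = Z[0] / np.linalg.norm(Z[0])
        else:
            _, _, Vt = np.linalg.svd(Z, full_matrices=False)
            me = Vt[0]
        mean_profile = Z.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        mes[module] = me
    cols = sample_ids if sample_ids is not None else range(expr_values.shape[1])
    return pd.DataFrame(mes, index=list(cols))


def _merge_close_modules(
    expr_values: np.ndarray,
    gene_ids: list[str],
    labels: pd.Series,
    merge_height: float,
    sample_ids: list[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Iteratively merge modules whose eigengene dissimilarity < merge_height."""
    labels = labels.copy()
    while True:
        mes = module_eigengenes(expr_values, gene_ids, labels, sample_ids)
        mods = list(mes.columns)
        if len(mods) < 2:
            return labels, mes
        C = np.corrcoef(mes.to_numpy().T)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if 1.0 - C[i, j] < merge_height:
            a, b = mods[i], mods[j]
            labels[labels == b] = a
        else:
            return labels, mes


def detect_modules(
    tom: np.ndarray,
    expr_values: np.ndarray,
    gene_ids: list[str],
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    deep_split: int = DEFAULT_DEEP_SPLIT,
    merge_height: float = DEFAULT_MERGE_HEIGHT,
    sample_ids: list[str] | None = None,
    kme_min: float = 0.3,
) -> ModuleSet:
    """Cut the average-linkage tree of 1 - TOM into modules.

    Static cut at a ``deep_split``-preset fraction of the maximum merge
    height; clusters below ``min_size`` go to grey; genes whose correlation
    with their module eigengene falls below ``kme_min`` are released to grey
    (cohesion cleanup); eigengene-similar modules (dissimilarity <
    ``merge_height``) are merged until stable.  Modules are renamed M1, M2,
    ... in decreasing size order.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if deep_split not in DEEP_SPLIT_CUT:
        raise ValueError(f"deep_split must be one of {sorted(DEEP_SPLIT_CUT)}")
    D = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    cut = DEEP_SPLIT_CUT[deep_split] * Z[:, 2].max()
    assign = hierarchy.fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(
        [f"c{a}" for a in assign], index=gene_ids, dtype=object, name="module"
    )
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_size]
    labels[labels.isin(small)] = GREY
    if (labels == GREY).all():
        return ModuleSet(gene_ids, labels, pd.DataFrame(index=sample_ids or []))
    # cohesion cleanup: genes weakly correlated with their module eigengene
    if kme_min > 0:
        idx = {g: i for i, g in enumerate(gene_ids)}
        mes0 = module_eigengenes(expr_values, gene_ids, labels, sample_ids)
        for module in mes0.columns:
            me = mes0[module].to_numpy()
            for g in labels.index[labels == module]:
                x = expr_values[idx[g], :]
                if x.std() == 0 or np.corrcoef(x, me)[0, 1] < kme_min:
                    labels[g] = GREY
        sizes = labels[labels != GREY].value_counts()
        labels[labels.isin(sizes.index[sizes < min_size])] = GREY
        if (labels == GREY).all():
            return ModuleSet(gene_ids, labels, pd.DataFrame(index=sample_ids or []))
    labels, _ = _merge_close_modules(expr_values, gene_ids, labels, merge_height, sample_ids)
    # size-ordered final names
    sizes = labels[labels != GREY].value_counts()
    rename = {old: f"M{i + 1}" for i, old in enumerate(sizes.index)}
    labels = labels.map(lambda m: rename.get(m, GREY))
    mes = module_eigengenes(expr_values, gene_ids, labels, sample_ids)
    return ModuleSet(gene_ids, labels, mes)


# ---------------------------------------------------------------------------
# Module-trait statistics
# ---------------------------------------------------------------------------

def _cor_test_p(r: float, m: int) -> float:
    """Two-sided p for a correlation via the Student-t approximation."""
    if m < 3 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else 1.0
    tval = r * np.sqrt((m - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(tval), m - 2))


def module_trait_association(
    mes: pd.DataFrame,
    traits: pd.DataFrame,
    r_min: float = DEFAULT_R_MIN,
    alpha: float = DEFAULT_FDR_ALPHA,
) -> pd.DataFrame:
    """bicor of each module eigengene with each trait, with BH FDR per trait.

    A module is selected for a trait when |bicor| >= r_min and FDR < alpha.
    """
    from statsmodels.stats.multitest import multipletests

    m = len(mes)
    rows = []
    for trait in traits.columns:
        tv = traits[trait].to_numpy(dtype=float)
        if np.all(tv == tv[0]):
            raise ValueError(f"trait {trait!r} is constant; association undefined")
        for module in mes.columns:
            r = bicor_pair(mes[module].to_numpy(), tv)
            rows.append({"module": module, "trait": trait, "bicor": r,
                         "p": _cor_test_p(r, m)})
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for trait in traits.columns:
        sel = out["trait"] == trait
        if sel.any():
            out.loc[sel, "fdr"] = multipletests(out.loc[sel, "p"], method="fdr_bh")[1]
    out["selected"] = (out["bicor"].abs() >= r_min) & (out["fdr"] < alpha)
    return out


def gene_module_stats(
    expr_values: np.ndarray,
    gene_ids: list[str],
    labels: pd.Series,
    mes: pd.DataFrame,
    trait: np.ndarray,
    mmgs_min: float = DEFAULT_MMGS_MIN,
    mmgs_alpha: float = DEFAULT_MMGS_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene module membership (MM) and gene significance (GS).

    MM_g = cor(x_g, ME of g's module) (signed); GS_g = |cor(x_g, trait)|.
    Per module, the correlation of |MM| with GS and its p-value decide
    whether the module is retained (>= mmgs_min and p < mmgs_alpha).
    """
    idx = {g: i for i, g in enumerate(gene_ids)}
    trait = np.asarray(trait, dtype=float)
    gene_rows, mod_rows = [], []
    for module in mes.columns:
        members = [g for g in labels.index[labels == module]]
        me = mes[module].to_numpy()
        mm_abs, gs_all = [], []
        for g in members:
            x = expr_values[idx[g], :]
            mm = float(np.corrcoef(x, me)[0, 1]) if x.std() > 0 else 0.0
            gs = abs(float(np.corrcoef(x, trait)[0, 1])) if x.std() > 0 else 0.0
            gene_rows.append({"gene_id": g, "module": module, "MM": mm, "GS": gs})
            mm_abs.append(abs(mm))
            gs_all.append(gs)
        if len(members) < 3:
            warnings.warn(f"module {module} has < 3 genes; MM-GS correlation undefined")
            mod_rows.append({"module": module, "mmgs_r": np.nan, "mmgs_p": np.nan,
                             "retained": False})
            continue
        r = float(np.corrcoef(mm_abs, gs_all)[0, 1])
        p = _cor_test_p(r, len(members))
        mod_rows.append({"module": module, "mmgs_r": r, "mmgs_p": p,
                         "retained": bool(r >= mmgs_min and p < mmgs_alpha)})
    return pd.DataFrame(gene_rows), pd.DataFrame(mod_rows)


def hub_genes(
    gene_stats: pd.DataFrame,
    modules: list[str] | None = None,
    gs_min: float = DEFAULT_HUB_GS,
    mm_min: float = DEFAULT_HUB_MM,
) -> dict[str, list[str]]:
    """Per-module hub genes: GS strictly > gs_min and MM strictly > mm_min."""
    out: dict[str, list[str]] = {}
    mods = modules if modules is not None else sorted(gene_stats["module"].unique())
    for module in mods:
        sub = gene_stats[gene_stats["module"] == module]
        hits = sub[(sub["GS"] > gs_min) & (sub["MM"] > mm_min)]
        out[module] = sorted(hits["gene_id"])
    return out
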