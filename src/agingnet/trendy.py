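"""Per-gene segmented (piecewise-linear) regression over an age time course.

Each gene's expression is modelled as a continuous piecewise-linear function
of age with an additive binary sex covariate:

    y = b0 + b1 * t + sum_j d_j * (t - bp_j)_+ + g * sex + e

For every breakpoint count k in 0..max_k all admissible breakpoint
placements over the interior distinct observed ages are enumerated
exhaustively (subject to a minimum number of samples per segment); per k the
minimum-RSS placement is kept and the winning k is selected by BIC,
``n*ln(RSS/n) + p*ln(n)`` with p the number of fitted coefficients.  Segment
slopes are the cumulative sums ``s_j = b1 + d_1 + ... + d_j``, each tested
with a contrast t-test.

"Top dynamic" genes are those whose selected model exceeds an adjusted-R2
cutoff — calibrated by permutation so that under shuffled time labels fewer
than a target fraction (default 1%) of fits pass — and have at least one
segment slope with p below ``slope_alpha`` (default 0.1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MAX_K = 8
DEFAULT_SLOPE_ALPHA = 0.1
DEFAULT_PASS_FRACTION = 0.01
DEFAULT_N_PERM = 10

# Per-tissue constants used in the original study on GSE132040
STUDY_MIN_PER_SEGMENT = {"brain": 3, "heart": 4, "liver": 3, "muscle": 2, "pancreas": 2}
STUDY_R2_CUTOFFS = {"brain": 0.2, "heart": 0.2, "liver": 0.1, "muscle": 0.3, "pancreas": 0.3}

_RSS_FLOOR_REL = 1e-12


@dataclass
class SegmentedFit:
    """Chosen segmented model for one gene."""

    gene_id: str
    k: int
    breakpoints: tuple[float, ...]
    segment_slopes: np.ndarray
    slope_pvalues: np.ndarray
    segment_directions: tuple[str, ...]
    sex_coefficient: float
    adj_r2: float
    bic: float


@dataclass
class DynamicGeneCall:
    gene_id: str
    is_top_dynamic: bool
    cutoff_used: float
    overall_trend: str


@dataclass
class BreakpointSummary:
    histogram: dict[float, int]
    median_breakpoint: float | None
    fraction_before_reference: float | None
    fraction_per_k: dict[int, float]
    monotonic_fraction: float


# ---------------------------------------------------------------------------
# Breakpoint placement enumeration and design matrices
# ---------------------------------------------------------------------------

def _candidate_breakpoints(t: np.ndarray) -> np.ndarray:
    """Interior distinct observed times (breakpoints cannot sit at the ends)."""
    return np.unique(t)[1:-1]

def _segment_counts(t: np.ndarray, bps: tuple[float, ...]) -> list[int]:
    """Samples per segment; a sample at exactly a breakpoint joins the left segment."""
    edges = [-np.inf, *bps, np.inf]
    return [int(np.sum((t > lo) & (t <= hi))) for lo, hi in zip(edges[:-1], edges[1:])]

def enumerate_placements(
    t: np.ndarray, max_k: int, min_per_segment: int
) -> list[tuple[float, ...]]:
    """All admissible breakpoint placements for k = 0..max_k.

    Placements are ordered by increasing k so that BIC ties resolve to the
    simpler model.
    """
    cands = _candidate_breakpoints(t)
    placements: list[tuple[float, ...]] = [()]
    for k in range(1, max_k + 1):
        if k > len(cands):
            break
        for combo in itertools.combinations(cands, k):
            if min(_segment_counts(t, combo)) >= min_per_segment:
                placements.append(combo)
    return placements

def _design(t: np.ndarray, sex: np.ndarray | None, bps: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(t, dtype=float), t.astype(float)]
    for b in bps:
        cols.append(np.maximum(t - b, 0.0))
    if sex is not None:
        cols.append(sex.astype(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Vectorized all-genes fitting engine
# ---------------------------------------------------------------------------

def _fit_all_genes(
    Y: np.ndarray,
    t: np.ndarray,
    sex: np.ndarray | None,
    max_k: int = DEFAULT_MAX_K,
    min_per_segment: int = 2,
) -> dict:
    """Select (k, placement, RSS, adj R2, BIC) for every row of Y at once.

    For each placement the residual projector is formed once and applied to
    all genes; this is what makes the permutation calibration affordable.
    """
    Y = np.asarray(Y, dtype=float)
    n_genes, n = Y.shape
    if sex is not None and len(np.unique(sex)) < 2:
        sex = None  # constant covariate would be collinear with the intercept
    placements = enumerate_placements(t, max_k, min_per_segment)
    tss = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    floor = np.maximum(tss, 1.0) * _RSS_FLOOR_REL

    best_rss = {}
    best_idx = {}
    for i, bps in enumerate(placements):
        X = _design(t, sex, bps)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            continue  # degenerate placement (e.g. no points beyond a hinge)
        Q, _ = np.linalg.qr(X)
        Yt = Y.T
        resid = Yt - Q @ (Q.T @ Yt)
        rss = np.sum(resid**2, axis=0)
        k = len(bps)
        if k not in best_rss:
            best_rss[k] = rss
            best_idx[k] = np.full(n_genes, i)
        else:
            better = rss < best_rss[k]
            best_rss[k] = np.where(better, rss, best_rss[k])
            best_idx[k] = np.where(better, i, best_idx[k])

    ks = sorted(best_rss)
    n_cov = 0 if sex is None else 1
    bic_stack = np.empty((len(ks), n_genes))
    for row, k in enumerate(ks):
        p = 2 + k + n_cov
        rss_eff = np.maximum(best_rss[k], floor)
        bic_stack[row] = n * np.log(rss_eff / n) + p * np.log(n)
    # ks ascending: argmin resolves BIC ties to the smaller k
    sel_row = np.argmin(bic_stack, axis=0)
    sel_k = np.array(ks)[sel_row]
    sel_rss = np.choose(sel_row, [best_rss[k] for k in ks])
    sel_idx = np.choose(sel_row, [best_idx[k] for k in ks])
    sel_p = 2 + sel_k + n_cov
    with np.errstate(divide="ignore", invalid="ignore"):
        adj_r2 = np.where(
            (tss > 0) & (n - sel_p > 0),
            1.0 - (sel_rss / np.maximum(n - sel_p, 1)) / (tss / (n - 1)),
            0.0,
        )
    sel_bic = np.choose(sel_row, bic_stack)
    return {
        "placements": placements,
        "k": sel_k,
        "placement_idx": sel_idx,
        "rss": sel_rss,
        "adj_r2": adj_r2,
        "bic": sel_bic,
        "sex_used": sex is not None,
    }


def _segment_inference(
    y: np.ndarray,
    t: np.ndarray,
    sex: np.ndarray | None,
    bps: tuple[float, ...],
    slope_alpha: float,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], float]:
    """Slopes, contrast t-test p-values, direction calls, sex coefficient."""
    X = _design(t, sex, bps)
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df if df > 0 else 0.0
    XtX_inv = np.linalg.pinv(X.T @ X)
    k = len(bps)
    slopes = np.empty(k + 1)
    pvals = np.empty(k + 1)
    for j in range(k + 1):
        c = np.zeros(p)
        c[1] = 1.0
        c[2 : 2 + j] = 1.0  # cumulative hinge deltas
        slopes[j] = c @ beta
        se2 = sigma2 * float(c @ XtX_inv @ c)
        if se2 > 0:
            tval = slopes[j] / np.sqrt(se2)
            pvals[j] = 2.0 * stats.t.sf(abs(tval), df)
        else:
            pvals[j] = 0.0 if abs(slopes[j]) > 1e-12 else 1.0
    directions = tuple(
        "flat" if pv >= slope_alpha else ("up" if s > 0 else "down")
        for s, pv in zip(slopes, pvals)
    )
    sex_coef = float(beta[-1]) if sex is not None else 0.0
    return slopes, pvals, directions, sex_coef


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------

def fit_segmented(
    y: np.ndarray,
    t: np.ndarray,
    sex: np.ndarray | None = None,
    max_k: int = DEFAULT_MAX_K,
    min_per_segment: int = 2,
    slope_alpha: float = DEFAULT_SLOPE_ALPHA,
    gene_id: str = "gene",
) -> SegmentedFit:
    """Fit and select the segmented model for a single gene."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if sex is not None:
        sex = np.asarray(sex)
        if not (len(y) == len(t) == len(sex)):
            raise ValueError("y, t, sex must have equal length")
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time points")
    res = _fit_all_genes(y[np.newaxis, :], t, sex, max_k, min_per_segment)
    bps = res["placements"][int(res["placement_idx"][0])]
    sex_arr = sex if res["sex_used"] else None
    slopes, pvals, directions, sex_coef = _segment_inference(y, t, sex_arr, bps, slope_alpha)
    return SegmentedFit(
        gene_id=gene_id,
        k=int(res["k"][0]),
        breakpoints=tuple(float(b) for b in bps),
        segment_slopes=slopes,
        slope_pvalues=pvals,
        segment_directions=directions,
        sex_coefficient=sex_coef,
        adj_r2=float(res["adj_r2"][0]),
        bic=float(res["bic"][0]),
    )


def fit_segmented_all(
    Y: np.ndarray,
    t: np.ndarray,
    sex: np.ndarray | None,
    gene_ids: list[str],
    max_k: int = DEFAULT_MAX_K,
    min_per_segment: int = 2,
    slope_alpha: float = DEFAULT_SLOPE_ALPHA,
) -> list[SegmentedFit]:
    """Fit every gene (rows of Y); selection vectorized, inference per gene."""
    Y = np.asarray(Y, dtype=float)
    t = np.asarray(t, dtype=float)
    res = _fit_all_genes(Y, t, sex, max_k, min_per_segment)
    sex_arr = sex if res["sex_used"] else None
    fits = []
    for g in range(Y.shape[0]):
        bps = res["placements"][int(res["placement_idx"][g])]
        slopes, pvals, directions, sex_coef = _segment_inference(
            Y[g], t, sex_arr, bps, slope_alpha
        )
        fits.append(
            SegmentedFit(
                gene_id=gene_ids[g],
                k=int(res["k"][g]),
                breakpoints=tuple(float(b) for b in bps),
                segment_slopes=slopes,
                slope_pvalues=pvals,
                segment_directions=directions,
                sex_coefficient=sex_coef,
                adj_r2=float(res["adj_r2"][g]),
                bic=float(res["bic"][g]),
            )
        )
    return fits


# ---------------------------------------------------------------------------
# Permutation calibration of the adjusted-R2 cutoff
# ---------------------------------------------------------------------------

def permutation_r2_cutoff(
    Y: np.ndarray,
    t: np.ndarray,
    sex: np.ndarray | None,
    n_perm: int = DEFAULT_N_PERM,
    pass_fraction: float = DEFAULT_PASS_FRACTION,
    max_k: int = DEFAULT_MAX_K,
    min_per_segment: int = 2,
    seed: int = 0,
    return_null: bool = False,
):
    """Adjusted-R2 cutoff such that <= ``pass_fraction`` of null fits pass.

    The sample-to-time assignment is permuted globally (sex stays attached to
    its sample), every gene is refit, and the pooled null adjusted-R2 values
    give the (1 - pass_fraction) quantile.  The 'higher' quantile convention
    guarantees that the fraction of null fits strictly above the cutoff never
    exceeds ``pass_fraction``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0 < pass_fraction < 1):
        raise ValueError("pass_fraction must be in (0, 1)")
    Y = np.asarray(Y, dtype=float)
    n_genes = Y.shape[0]
    if n_perm * n_genes < 1.0 / pass_fraction:
        warnings.warn("too few permuted fits for a stable quantile at this pass_fraction")
    rng = np.random.default_rng(seed)
    t = np.asarray(t, dtype=float)
    pooled = []
    for _ in range(n_perm):
        perm = rng.permutation(len(t))
        res = _fit_all_genes(Y, t[perm], sex, max_k, min_per_segment)
        pooled.append(res["adj_r2"])
    pooled = np.concatenate(pooled)
    cutoff = float(np.quantile(pooled, 1.0 - pass_fraction, method="higher"))
    if return_null:
        return cutoff, pooled
    return cutoff


def select_top_dynamic(
    fits: list[SegmentedFit],
    cutoff: float,
    slope_alpha: float = DEFAULT_SLOPE_ALPHA,
) -> tuple[list[DynamicGeneCall], int, float]:
    """Flag top dynamic genes: adj R2 > cutoff and min slope p < slope_alpha.

    Returns the calls, the number selected, and the percentage of the fitted
    (expressed) genes rounded to one decimal.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if not (0 < slope_alpha < 1):
        raise ValueError("slope_alpha must be in (0, 1)")
    calls = []
    for f in fits:
        selected = f.adj_r2 > cutoff and float(np.min(f.slope_pvalues)) < slope_alpha
        signs = {d for d in f.segment_directions if d != "flat"}
        if signs == {"up"}:
            trend = "increasing"
        elif signs == {"down"}:
            trend = "decreasing"
        else:
            trend = "mixed"
        calls.append(DynamicGeneCall(f.gene_id, selected, cutoff, trend))
    n_sel = sum(c.is_top_dynamic for c in calls)
    pct = round(100.0 * n_sel / len(fits), 1) if fits else 0.0
    return calls, n_sel, pct


# ---------------------------------------------------------------------------
# Breakpoint summaries and group comparisons
# ---------------------------------------------------------------------------

def dynamic_percentage(n_dynamic: int, n_expressed: int) -> float:
    """Percentage of expressed genes called dynamic, to one decimal."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    return round(100.0 * n_dynamic / n_expressed, 1)


def summarize_breakpoints(
    fits: list[SegmentedFit],
    selected_ids: set[str],
    reference_age: float = 15.0,
) -> BreakpointSummary:
    """Pool breakpoints of the selected genes and summarize their timing."""
    fitted_ids = {f.gene_id for f in fits}
    if not selected_ids <= fitted_ids:
        raise ValueError("selected genes must be a subset of fitted genes")
    sel = [f for f in fits if f.gene_id in selected_ids]
    bps = np.array([b for f in sel for b in f.breakpoints])
    hist: dict[float, int] = {}
    for b in bps:
        hist[float(b)] = hist.get(float(b), 0) + 1
    n_sel = len(sel)
    per_k: dict[int, int] = {}
    for f in sel:
        per_k[f.k] = per_k.get(f.k, 0) + 1
    return BreakpointSummary(
        histogram=dict(sorted(hist.items())),
        median_breakpoint=float(np.median(bps)) if bps.size else None,
        fraction_before_reference=float(np.mean(bps <= reference_age)) if bps.size else None,
        fraction_per_k={k: v / n_sel for k, v in sorted(per_k.items())} if n_sel else {},
        monotonic_fraction=(per_k.get(0, 0) / n_sel) if n_sel else 0.0,
    )


def compare_breakpoint_distributions(
    groups: dict[str, np.ndarray], adjust: str = "holm"
) -> dict:
    """Kruskal-Wallis across tissues plus Dunn's pairwise post-hoc test.

    Dunn's z uses mean ranks over the pooled sample with the tie-corrected
    standard error; pairwise p-values are multiplicity-adjusted (Holm by
    default, configurable to any statsmodels method such as 'fdr_bh').
    """
    from statsmodels.stats.multitest import multipletests

    names = list(groups)
    if len(names) < 2 or any(len(groups[g]) < 1 for g in names):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*samples)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    # tie correction term for Dunn's SE
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    mean_ranks, sizes = {}, {}
    start = 0
    for g, s in zip(names, samples):
        mean_ranks[g] = ranks[start : start + len(s)].mean()
        sizes[g] = len(s)
        start += len(s)
    pairs, zs, ps = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se2 = (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(se2) if se2 > 0 else 0.0
            pairs.append((a, b))
            zs.append(z)
            ps.append(2.0 * stats.norm.sf(abs(z)))
    adj = multipletests(ps, method=adjust)[1] if ps else np.array([])
    return {
        "H": float(H),
        "p": float(p),
        "pairs": pd.DataFrame(
            {
                "group_a": [a for a, _ in pairs],
                "group_b": [b for _, b in pairs],
                "z": zs,
                "p": ps,
                "p_adj": adj,
            }
        ),
    }


def biotype_enrichment(
    selected: set[str],
    reference: set[str],
    biotype: pd.Series,
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-biotype 2x2 enrichment of the selected genes against the reference.

    Two-sided Fisher exact test (sample odds ratio) by default; a chi-squared
    mode is available for comparison.  BH adjustment across biotypes.
    """
    from statsmodels.stats.multitest import multipletests

    if not selected <= reference:
        raise ValueError("selected genes must be a subset of the reference")
    unlabeled = reference - set(biotype.dropna().index)
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} reference genes lack a biotype label")
    ref = sorted(reference)
    labels = biotype.loc[ref]
    rows = []
    for bt in sorted(labels.unique()):
        in_bt = set(labels.index[labels == bt])
        a = len(selected & in_bt)
        b = len(selected) - a
        c = len(in_bt) - a
        d = len(reference) - len(selected) - c
        table = np.array([[a, b], [c, d]])
        if method == "fisher":
            _, pval = stats.fisher_exact(table, alternative="two-sided")
        elif method == "chi2":
            pval = stats.chi2_contingency(table, correction=True)[1]
        else:
            raise ValueError(f"unknown method {method!r}")
        odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else 0.0)
        rows.append({"biotype": bt, "selected": a, "reference": len(in_bt),
                     "odds_ratio": odds, "p": pval})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def fits_to_frame(fits: list[SegmentedFit]) -> pd.DataFrame:
    """Tabular export of segmented fits (breakpoints comma-joined)."""
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "k": [f.k for f in fits],
            "breakpoints": [",".join(str(b) for b in f.breakpoints) for f in fits],
            "slopes": [",".join(f"{s:.6g}" for s in f.segment_slopes) for f in fits],
            "slope_pvalues": [",".join(f"{p:.4g}" for p in f.slope_pvalues) for f in fits],
            "directions": [",".join(f.segment_directions) for f in fits],
            "sex_coef": [f.sex_coefficient for f in fits],
            "adj_r2": [f.adj_r2 for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
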