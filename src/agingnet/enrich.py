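"""Hypergeometric over-representation analysis (ORA) of gene signatures.

Gene sets come in as a GMT file; the universe is the tissue's expressed
(post-filter) gene list.  For each term with K members in the universe and a
signature of n genes containing k term members, the upper-tail
hypergeometric p-value P[X >= k] is computed, with Benjamini-Hochberg FDR
across the tested terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_SET_SIZE = 10
DEFAULT_MAX_SET_SIZE = 500
DEFAULT_ALPHA = 0.05


@dataclass
class GeneSetCollection:
    """term_id -> (name, member gene ids)."""

    sets: dict[str, tuple[str, set[str]]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term_id: str) -> set[str]:
        return self.sets[term_id][1]

    def name(self, term_id: str) -> str:
        return self.sets[term_id][0]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (term, description, tab-separated member genes)."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (< 3 fields)")
            term, desc = fields[0], fields[1]
            if term in sets:
                raise ValueError(f"{path}: duplicate term {term!r} at line {lineno}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"{path}: term {term!r} has no members (line {lineno})")
            sets[term] = (desc, members)
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    signature: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Over-representation of the signature in each gene set.

    Term memberships are first intersected with the universe; terms whose
    within-universe size falls outside [min_size, max_size] are skipped.
    Signature genes outside the universe are dropped with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    stray = signature - universe
    if stray:
        warnings.warn(f"{len(stray)} signature genes outside the universe were dropped")
        signature = signature & universe
    if not signature:
        warnings.warn("empty signature; no enrichment computed")
        return pd.DataFrame(
            columns=["term_id", "name", "k", "K", "n", "N", "p", "fdr",
                     "significant", "hits"]
        )
    N = len(universe)
    n = len(signature)
    rows = []
    for term_id, (name, members) in sets.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if not (min_size <= K <= max_size):
            continue
        hits = signature & in_universe
        k = len(hits)
        rows.append({
            "term_id": term_id, "name": name, "k": k, "K": K, "n": n, "N": N,
            "p": hypergeom_upper_tail(k, N, K, n), "hits": ",".join(sorted(hits)),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] < alpha
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["fdr"] = np.nan
        out["significant"] = False
    return out
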