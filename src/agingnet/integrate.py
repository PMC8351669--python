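"""Set intersections between dynamic-gene, module, and hub gene lists.

Per tissue, the signature carried to functional enrichment is the
intersection of the top dynamic (segmented-regression) genes with the hub
genes of each selected module; upset-style exclusive regions are reported for
the three-set diagram and for cross-tissue comparisons of genes or enriched
terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations


@dataclass
class OverlapReport:
    """Exclusive intersection regions of named sets, plus the signature set."""

    regions: dict[frozenset[str], set[str]]  # set-name combination -> members
    signature: set[str]  # trendy & hub

    def region_sizes(self) -> dict[tuple[str, ...], int]:
        return {tuple(sorted(k)): len(v) for k, v in self.regions.items()}


def exclusive_regions(named_sets: dict[str, set[str]]) -> dict[frozenset[str], set[str]]:
    """Partition the union of the sets into exclusive membership regions."""
    universe = set().union(*named_sets.values()) if named_sets else set()
    regions: dict[frozenset[str], set[str]] = {}
    for el in universe:
        key = frozenset(name for name, s in named_sets.items() if el in s)
        regions.setdefault(key, set()).add(el)
    return regions


def intersect_gene_sets(
    trendy: set[str], module: set[str], hub: set[str]
) -> OverlapReport:
    """Three-set overlap of dynamic, module, and hub genes.

    Hub genes are by construction a subset of module genes; violating that
    indicates an upstream bug and raises.  The signature (dynamic AND hub) is
    the gene list carried to over-representation analysis.
    """
    if not hub <= module:
        raise ValueError("hub genes must be a subset of module genes")
    regions = exclusive_regions({"trendy": trendy, "module": module, "hub": hub})
    return OverlapReport(regions=regions, signature=trendy & hub)


def cross_tissue_overlap(
    sets_by_tissue: dict[str, set[str]]
) -> dict[frozenset[str], set[str]]:
    """Upset-style exclusive intersections of gene or term sets across tissues.

    The region keyed by exactly {'heart', 'liver'} holds elements present in
    the heart and liver lists and in no other tissue's list.
    """
    if len(sets_by_tissue) < 2:
        raise ValueError("need at least 2 tissues")
    return exclusive_regions(sets_by_tissue)


def pairwise_exclusive(
    sets_by_tissue: dict[str, set[str]]
) -> dict[tuple[str, str], set[str]]:
    """Elements shared by exactly one pair of tissues, per pair."""
    regions = cross_tissue_overlap(sets_by_tissue)
    out = {}
    for a, b in combinations(sorted(sets_by_tissue), 2):
        out[(a, b)] = regions.get(frozenset({a, b}), set())
    return out


def regions_to_json(regions: dict[frozenset[str], set[str]]) -> dict:
    """JSON-serializable view: '+'.joined sorted set names -> size + members."""
    return {
        "+".join(sorted(k)): {"size": len(v), "members": sorted(v)}
        for k, v in sorted(regions.items(), key=lambda kv: "+".join(sorted(kv[0])))
    }
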