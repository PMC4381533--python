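"""Gene-list overlap statistics and Venn-style set accounting.

The significance of an overlap between two gene lists drawn from a stated
universe is the hypergeometric upper-tail probability
P(X >= observed overlap) with parameters (universe size, |A|, |B|). The
universe must be supplied explicitly — it is the set of genes that could
have appeared in either list (e.g. the genes measured on both platforms)
and silently defaulting it is the classic way to overstate significance.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass
class GeneOverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    p_upper: float
    overlap: frozenset


def hypergeom_overlap(list_a, list_b, universe) -> GeneOverlapResult:
    """Upper-tail hypergeometric significance of a two-list overlap."""
    set_a, set_b, uni = set(list_a), set(list_b), set(universe)
    outside = (set_a | set_b) - uni
    if outside:
        raise ValueError(
            f"list elements outside the universe: {sorted(outside)[:10]}"
        )
    inter = set_a & set_b
    k = len(inter)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(set_a), len(set_b)))
    return GeneOverlapResult(
        n_a=len(set_a), n_b=len(set_b), n_overlap=k, n_universe=len(uni),
        p_upper=min(p, 1.0), overlap=frozenset(inter),
    )


def venn_counts(*lists) -> dict[str, int]:
    """Disjoint-region counts for 2 or 3 gene sets.

    Region keys are binary membership patterns, e.g. ``"110"`` = in set 1
    and set 2 but not set 3 (``"10"``/``"01"``/``"11"`` for two sets).
    """
    if not 2 <= len(lists) <= 3:
        raise ValueError(f"venn_counts supports 2-3 sets, got {len(lists)}")
    sets = [set(l) for l in lists]
    union = set().union(*sets)
    counts: dict[str, int] = {}
    k = len(sets)
    for pattern in range(1, 2**k):
        key = format(pattern, f"0{k}b")
        region = union.copy()
        for i, bit in enumerate(key):
            region = region & sets[i] if bit == "1" else region - sets[i]
        counts[key] = len(region)
    return counts
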