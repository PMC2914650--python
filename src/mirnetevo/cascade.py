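"""Regulatory-cascade ordering: upstream vs. downstream evolutionary rates.

A regulator A is *upstream* of a same-class regulator B when a directed path
A ⇝ B exists over edges of any relation type and no return path B ⇝ A exists
(mutually reachable pairs are excluded rather than counted in both
orientations).  For each ordered pair the rates are compared; the headline
statistic is the fraction of comparable pairs in which the upstream node has
the strictly lower evolutionary rate, computed separately for TFs and miRNAs
and contrasted with Fisher's exact test.

Shortest paths use unit edge weights, where Dijkstra's algorithm reduces to
breadth-first search.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .evorate import RateTable
from .netio import RegNetwork
from .stats import ContingencyResult, ContingencyTable2x2, fisher_exact_2x2


class CascadeError(ValueError):
    pass


@dataclass(frozen=True)
class CascadePairSummary:
    """Upstream-vs-downstream rate comparison for one regulator class.

    ``fraction_upstream_lower`` = n_upstream_lower / (n_pairs - n_ties), or
    None when no comparable pairs remain; ``n_dropped`` counts pairs excluded
    because a member lacks a rate.
    """

    node_class: str
    n_pairs: int
    n_upstream_lower: int
    n_ties: int
    n_dropped: int
    fraction_upstream_lower: float | None

    @property
    def n_comparable(self) -> int:
        return self.n_pairs - self.n_ties


def shortest_path_lengths(net: RegNetwork, source: str) -> dict[str, int]:
    """Directed shortest-path lengths (unit weights) from ``source``.

    Unreachable nodes are absent from the map; the source maps to 0.
    """
    if source not in net.nodes:
        raise CascadeError(f"unknown source node {source!r}")
    g = net.to_networkx()
    return dict(nx.single_source_shortest_path_length(g, source))


def enumerate_ordered_pairs(
    net: RegNetwork, node_class: str
) -> list[tuple[str, str]]:
    """All (upstream, downstream) pairs of one regulator class.

    (A, B) is emitted iff both are of ``node_class``, A ≠ B, A reaches B by a
    directed path over any edge types, and B does not reach A.  The result is
    antisymmetric and sorted for reproducibility.
    """
    if node_class not in ("TF", "miRNA"):
        raise CascadeError(f"node_class must be TF or miRNA, got {node_class!r}")
    members = net.nodes_of_class(node_class)
    g = net.to_networkx()
    reach: dict[str, set[str]] = {
        m: nx.descendants(g, m) & set(members) for m in members
    }
    pairs = [
        (a, b)
        for a in members
        for b in sorted(reach[a])
        if a not in reach[b]
    ]
    return sorted(pairs)


def upstream_conservation_fraction(
    pairs: list[tuple[str, str]],
    rates: RateTable,
    node_class: str = "TF",
) -> CascadePairSummary:
    """Count ordered pairs whose upstream member evolves strictly slower.

    Pairs with a member missing from the rate table are dropped (and counted);
    rate ties are excluded from the fraction's denominator because "lower" is
    strict.
    """
    n_pairs = 0
    n_lower = 0
    n_ties = 0
    n_dropped = 0
    for up, down in sorted(pairs):
        r_up = rates.get(up)
        r_down = rates.get(down)
        if r_up is None or r_down is None:
            n_dropped += 1
            continue
        n_pairs += 1
        if r_up == r_down:
            n_ties += 1
        elif r_up < r_down:
            n_lower += 1
    comparable = n_pairs - n_ties
    fraction = n_lower / comparable if comparable > 0 else None
    return CascadePairSummary(
        node_class=node_class,
        n_pairs=n_pairs,
        n_upstream_lower=n_lower,
        n_ties=n_ties,
        n_dropped=n_dropped,
        fraction_upstream_lower=fraction,
    )


def compare_class_fractions(
    tf_summary: CascadePairSummary, mirna_summary: CascadePairSummary
) -> ContingencyResult:
    """Fisher's exact contrast of upstream-lower fractions between classes.

    Table rows are TF / miRNA pairs, columns upstream-lower yes / no (ties
    excluded, consistent with the fraction's denominator).
    """
    for s in (tf_summary, mirna_summary):
        if s.n_comparable <= 0:
            raise CascadeError(
                f"no comparable {s.node_class} pairs for class contrast"
            )
    table = ContingencyTable2x2(
        a=tf_summary.n_upstream_lower,
        b=tf_summary.n_comparable - tf_summary.n_upstream_lower,
        c=mirna_summary.n_upstream_lower,
        d=mirna_summary.n_comparable - mirna_summary.n_upstream_lower,
    )
    return fisher_exact_2x2(table)
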