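"""Signed TF–miRNA regulatory network: data model, I/O and topology summaries.

The network is a directed, typed, signed graph over three node classes —
transcription factors (TF), microRNAs (miRNA) and protein-coding genes — with
three relation types:

* ``TF-gene``      TF → gene (or TF → TF, transcriptional autoregulation and
                   TF–TF regulation are carried under this relation type),
* ``TF-miRNA``     TF → miRNA,
* ``miRNA-target`` miRNA → gene or miRNA → TF; always repressive.

Node classes are inferred from the relation-type column of the edge list, not
declared per node; an id whose implied classes conflict (e.g. used both as a
TF source and as a TF-miRNA target) is a hard validation error.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

logger = logging.getLogger("mirnetevo")

NODE_CLASSES = ("TF", "miRNA", "gene")
RELATION_TYPES = ("TF-gene", "TF-miRNA", "miRNA-target")
SIGNS = ("activation", "repression", "unknown")

#: endpoint classes permitted per relation type: (source classes, target classes)
_ENDPOINT_RULES = {
    "TF-gene": ({"TF"}, {"gene", "TF"}),
    "TF-miRNA": ({"TF"}, {"miRNA"}),
    "miRNA-target": ({"miRNA"}, {"gene", "TF"}),
}


class NetworkValidationError(ValueError):
    """Raised when an edge list violates the network's structural invariants."""


class NetworkParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""


@dataclass(frozen=True)
class NodeRecord:
    id: str
    node_class: str  # "TF" | "miRNA" | "gene"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("node id must be non-empty")
        if self.node_class not in NODE_CLASSES:
            raise NetworkValidationError(f"unknown node class {self.node_class!r}")


@dataclass(frozen=True, order=True)
class SignedEdge:
    source: str
    target: str
    relation_type: str  # "TF-gene" | "TF-miRNA" | "miRNA-target"
    sign: str  # "activation" | "repression" | "unknown"

    def __post_init__(self) -> None:
        if self.relation_type not in RELATION_TYPES:
            raise NetworkValidationError(
                f"unknown relation type {self.relation_type!r}"
            )
        if self.sign not in SIGNS:
            raise NetworkValidationError(f"unknown sign token {self.sign!r}")
        if self.relation_type == "miRNA-target" and self.sign != "repression":
            raise NetworkValidationError(
                f"miRNA-target edge {self.source}->{self.target} must be "
                f"repression, got {self.sign!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.relation_type)


@dataclass
class RegNetwork:
    """Validated signed regulatory network.

    ``nodes`` maps node id → node class; ``edges`` is kept in a deterministic
    sorted order so that every downstream seeded computation is reproducible.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: list[SignedEdge] = field(default_factory=list)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[SignedEdge],
        extra_nodes: Iterable[NodeRecord] = (),
    ) -> "RegNetwork":
        """Build a network, inferring node classes from edge context."""
        edges = sorted(set(edges))
        declared = {rec.id: rec.node_class for rec in extra_nodes}
        nodes = _infer_node_classes(edges, declared)
        net = cls(nodes=nodes, edges=edges)
        net.validate()
        return net

    def validate(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        signs_by_pair: dict[tuple[str, str, str], str] = {}
        for e in self.edges:
            if e.key in seen:
                raise NetworkValidationError(f"duplicate edge {e.key}")
            seen.add(e.key)
            prev_sign = signs_by_pair.get(e.key)
            if prev_sign is not None and prev_sign != e.sign:
                raise NetworkValidationError(
                    f"conflicting signs for edge {e.key}: {prev_sign} vs {e.sign}"
                )
            signs_by_pair[e.key] = e.sign
            for node in (e.source, e.target):
                if node not in self.nodes:
                    raise NetworkValidationError(
                        f"edge endpoint {node!r} missing from node table"
                    )
            src_ok, tgt_ok = _ENDPOINT_RULES[e.relation_type]
            if self.nodes[e.source] not in src_ok:
                raise NetworkValidationError(
                    f"{e.relation_type} edge {e.source}->{e.target}: source is "
                    f"{self.nodes[e.source]}, expected one of {sorted(src_ok)}"
                )
            if self.nodes[e.target] not in tgt_ok:
                raise NetworkValidationError(
                    f"{e.relation_type} edge {e.source}->{e.target}: target is "
                    f"{self.nodes[e.target]}, expected one of {sorted(tgt_ok)}"
                )
            if e.source == e.target and e.relation_type != "TF-gene":
                raise NetworkValidationError(
                    f"self-loop only permitted for TF-gene autoregulation: {e.key}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes_of_class(self, node_class: str) -> list[str]:
        return sorted(n for n, c in self.nodes.items() if c == node_class)

    def edges_of_type(self, relation_type: str) -> list[SignedEdge]:
        return [e for e in self.edges if e.relation_type == relation_type]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node, cls_ in self.nodes.items():
            g.add_node(node, node_class=cls_)
        for e in self.edges:
            g.add_edge(e.source, e.target, relation_type=e.relation_type, sign=e.sign)
        return g


def _infer_node_classes(
    edges: Iterable[SignedEdge], declared: dict[str, str] | None = None
) -> dict[str, str]:
    """Infer node classes from edge context.

    Sources of TF-* edges are TFs, sources of miRNA-target edges and targets
    of TF-miRNA edges are miRNAs; remaining endpoints default to "gene".
    A node pinned to two different classes is a conflict.  ``declared``
    seeds the inference with externally known classes (same conflict rule).
    """
    classes: dict[str, str] = dict(declared or {})

    def pin(node: str, cls_: str, why: str) -> None:
        prev = classes.get(node)
        if prev is not None and prev != cls_:
            raise NetworkValidationError(
                f"node {node!r} implied both {prev} and {cls_} ({why})"
            )
        classes[node] = cls_

    for e in edges:
        if e.relation_type in ("TF-gene", "TF-miRNA"):
            pin(e.source, "TF", f"source of {e.relation_type}")
        else:
            pin(e.source, "miRNA", "source of miRNA-target")
        if e.relation_type == "TF-miRNA":
            pin(e.target, "miRNA", "target of TF-miRNA")
    # second pass: untyped targets of TF-gene / miRNA-target edges are genes
    for e in edges:
        if e.relation_type in ("TF-gene", "miRNA-target"):
            classes.setdefault(e.target, "gene")
            if classes[e.target] == "miRNA":
                raise NetworkValidationError(
                    f"{e.relation_type} edge {e.source}->{e.target} targets a "
                    "miRNA; miRNAs may only be targets of TF-miRNA edges"
                )
    return classes


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_HEADER = ["source", "target", "relation_type", "sign"]


def read_network(path) -> RegNetwork:
    """Read a 4-column signed edge-list TSV (header required) into a network.

    ``#``-prefixed lines are comments; malformed rows raise
    :class:`NetworkParseError` naming the line number.
    """
    edges: list[SignedEdge] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields] != _HEADER:
                    expected = "\t".join(_HEADER)
                    raise NetworkParseError(
                        f"{path}:{lineno}: expected header "
                        f"{expected!r}, got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            src, tgt, rel, sign = (f.strip() for f in fields)
            try:
                edges.append(SignedEdge(src, tgt, rel, sign))
            except NetworkValidationError as exc:
                raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
        if not header_seen:
            raise NetworkParseError(f"{path}: missing header row")
    return RegNetwork.from_edges(edges)


def write_network(net: RegNetwork, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_HEADER)
        for e in net.edges:
            w.writerow([e.source, e.target, e.relation_type, e.sign])


def write_sif(net: RegNetwork, path) -> None:
    """Export to SIF (source, interaction, target) for graph viewers."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for e in net.edges:
            fh.write(f"{e.source}\t{e.relation_type}\t{e.target}\n")


def read_gmt(path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set file: name, description, members..."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: GMT rows need name, description and "
                    "at least one member"
                )
            name = fields[0]
            if name in sets:
                raise NetworkParseError(f"{path}:{lineno}: duplicate set {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise NetworkParseError(f"{path}:{lineno}: empty set {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, frozenset[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


# ---------------------------------------------------------------------------
# topology summaries
# ---------------------------------------------------------------------------


def connected_components(net: RegNetwork) -> list[set[str]]:
    """Weakly connected components (edge direction ignored), largest first.

    Ties in size are broken by the smallest member id so the order is
    deterministic.
    """
    g = net.to_networkx()
    comps = [set(c) for c in nx.weakly_connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def degree_summary(net: RegNetwork) -> pd.DataFrame:
    """Per-node out-degree split by relation type.

    Returns a DataFrame indexed by node id with one column per relation type
    plus ``node_class`` and ``out_total``; column sums over all nodes equal
    the edge count.
    """
    counts = {n: dict.fromkeys(RELATION_TYPES, 0) for n in net.nodes}
    for e in net.edges:
        counts[e.source][e.relation_type] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    df.index.name = "node"
    df.insert(0, "node_class", [net.nodes[n] for n in df.index])
    df["out_total"] = df[list(RELATION_TYPES)].sum(axis=1)
    return df
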