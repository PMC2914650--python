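"""Pathway co-regulation: do activating TF–miRNA pairs share signaling
pathways more often than repressing pairs?

A TF–miRNA pair "regulates a common pathway" when at least one pathway set
contains both members; pathway membership is an annotation input (GMT), not
something computed here.  The contrast is a 2x2 Fisher test of sign
(activation / repression) against common-pathway yes/no.

Two counting units are supported because the unit is ambiguous in analyses of
this kind: with ``counting_unit="pair"`` each signed TF–miRNA pair is one
observation; with ``"pair_pathway"`` each (pair, pathway regulated by either
member) combination is one observation, "yes" when the pathway contains both.
The default is ``pair``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .netio import RegNetwork, read_gmt, write_gmt
from .stats import ContingencyResult, ContingencyTable2x2, fisher_exact_2x2


class PathwayError(ValueError):
    pass


@dataclass
class PathwaySet:
    """Named, non-empty membership sets (TFs, miRNAs and genes)."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not name:
                raise PathwayError("pathway name must be non-empty")
            if not members:
                raise PathwayError(f"pathway {name!r} has no members")
        # inverted index: member id -> set of pathway names
        self._index: dict[str, set[str]] = {}
        for name, members in self.sets.items():
            for m in members:
                self._index.setdefault(m, set()).add(name)

    def __len__(self) -> int:
        return len(self.sets)

    def pathways_of(self, member: str) -> set[str]:
        return self._index.get(member, set())

    @classmethod
    def from_gmt(cls, path) -> "PathwaySet":
        return cls(read_gmt(path))

    def to_gmt(self, path) -> None:
        write_gmt(self.sets, path)


def common_pathway_flag(pair: tuple[str, str], pathways: PathwaySet) -> bool:
    """True iff at least one pathway contains both members of the pair."""
    a, b = pair
    return bool(pathways.pathways_of(a) & pathways.pathways_of(b))


@dataclass(frozen=True)
class CoregulationReport:
    table: ContingencyTable2x2
    fisher: ContingencyResult
    counting_unit: str
    pct_common_activating: float  # 0-100 scale
    pct_common_repressing: float


def coregulation_contingency(
    net: RegNetwork,
    pathways: PathwaySet,
    counting_unit: str = "pair",
) -> CoregulationReport:
    """Sign × common-pathway contingency over signed TF-miRNA pairs.

    Row 1 of the table is the activating stratum, row 2 the repressing one;
    column 1 counts "common pathway" observations.
    """
    if counting_unit not in ("pair", "pair_pathway"):
        raise PathwayError(f"unknown counting unit {counting_unit!r}")
    if len(pathways) == 0:
        raise PathwayError("empty pathway set")
    pairs = {
        (e.source, e.target): e.sign
        for e in net.edges_of_type("TF-miRNA")
        if e.sign in ("activation", "repression")
    }
    if not pairs:
        raise PathwayError("no signed TF-miRNA edges in network")
    counts = {("activation", True): 0, ("activation", False): 0,
              ("repression", True): 0, ("repression", False): 0}
    for (tf, mirna), sign in sorted(pairs.items()):
        if counting_unit == "pair":
            counts[sign, common_pathway_flag((tf, mirna), pathways)] += 1
        else:
            for pw in sorted(pathways.pathways_of(tf) | pathways.pathways_of(mirna)):
                both = pw in pathways.pathways_of(tf) and pw in pathways.pathways_of(mirna)
                counts[sign, both] += 1
    table = ContingencyTable2x2(
        a=counts["activation", True],
        b=counts["activation", False],
        c=counts["repression", True],
        d=counts["repression", False],
    )
    return report_from_table(table, counting_unit)


def report_from_table(
    table: ContingencyTable2x2, counting_unit: str = "pair"
) -> CoregulationReport:
    """Build the co-regulation report from a pre-tabulated 2x2 table."""
    n_act = table.a + table.b
    n_rep = table.c + table.d
    return CoregulationReport(
        table=table,
        fisher=fisher_exact_2x2(table),
        counting_unit=counting_unit,
        pct_common_activating=100.0 * table.a / n_act if n_act else float("nan"),
        pct_common_repressing=100.0 * table.c / n_rep if n_rep else float("nan"),
    )
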