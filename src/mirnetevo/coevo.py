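"""Sign-stratified coevolution analyses.

The central question: do regulators and the partners they regulate have
correlated evolutionary rates, and does the answer depend on the sign of the
regulation?  Four operations:

* :func:`stratify_edges_by_sign` — partition rated edges of one relation type
  into activation / repression / unknown groups.
* :func:`coevolution_correlation` — Spearman correlation of regulator vs.
  partner rates within a group; each edge is one observation (a regulator with
  k edges contributes k pairs, so pseudo-replication across shared regulators
  is accepted, matching the per-pair framing of the analysis).
* :func:`median_split_comparison` — split a group's pairs into equal low/high
  halves by one member's rate and compare the other member's rates with the
  Wilcoxon rank-sum test.
* :func:`signal_preference` — do rapidly evolving TFs prefer activating over
  repressing their miRNA targets?  2x2 (rate half × sign) with Fisher's test.

Also here: expression-based sign inference for TF-gene edges whose sign is
not curated (positive expression correlation → activation, negative →
repression).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evorate import RateTable
from .netio import RegNetwork, SignedEdge
from .stats import (
    ContingencyResult,
    ContingencyTable2x2,
    CorrelationResult,
    GroupComparisonResult,
    fisher_exact_2x2,
    spearman,
    wilcoxon_rank_sum,
)

logger = logging.getLogger("mirnetevo")


class CoevoError(ValueError):
    pass


@dataclass
class EdgeGroup:
    """Rated regulator–partner pairs of one relation type and sign."""

    relation_type: str
    sign: str
    pairs: list[tuple[str, str]] = field(default_factory=list)
    regulator_rates: list[float] = field(default_factory=list)
    partner_rates: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def stratify_edges_by_sign(
    net: RegNetwork,
    relation_type: str,
    rates_regulator: RateTable,
    rates_partner: RateTable,
) -> dict[str, EdgeGroup]:
    """Partition rated edges of ``relation_type`` by sign.

    Edges whose regulator or partner lacks a rate are dropped (count logged);
    unknown-sign edges form their own group.  Only non-empty groups appear in
    the returned map.
    """
    edges = net.edges_of_type(relation_type)
    if not edges:
        logger.warning("no %s edges in network", relation_type)
        return {}
    groups: dict[str, EdgeGroup] = {}
    n_dropped = 0
    for e in edges:
        r_reg = rates_regulator.get(e.source)
        r_par = rates_partner.get(e.target)
        if r_reg is None or r_par is None:
            n_dropped += 1
            continue
        g = groups.setdefault(e.sign, EdgeGroup(relation_type, e.sign))
        g.pairs.append((e.source, e.target))
        g.regulator_rates.append(r_reg)
        g.partner_rates.append(r_par)
    if n_dropped:
        logger.info(
            "%s: dropped %d of %d edges lacking rates",
            relation_type,
            n_dropped,
            len(edges),
        )
    return groups


def coevolution_correlation(group: EdgeGroup) -> CorrelationResult:
    """Spearman correlation of regulator vs. partner rates over a group."""
    if len(group) < 3:
        raise CoevoError(
            f"{group.relation_type}/{group.sign}: need >= 3 rated pairs, "
            f"got {len(group)}"
        )
    return spearman(group.regulator_rates, group.partner_rates)


def _median_split_order(group: EdgeGroup, split_on: str) -> tuple[list[int], list[int]]:
    """Indices of the low and high halves, sorted by the split member's rate.

    Equal rates are broken by lexicographic (regulator, partner) edge id so the
    split is deterministic; with an odd count the middle pair goes to the low
    half.
    """
    if split_on not in ("regulator", "partner"):
        raise CoevoError(f"split_on must be regulator or partner, got {split_on!r}")
    key_rates = (
        group.regulator_rates if split_on == "regulator" else group.partner_rates
    )
    order = sorted(
        range(len(group)), key=lambda i: (key_rates[i], group.pairs[i])
    )
    n_low = (len(order) + 1) // 2
    return order[:n_low], order[n_low:]


def median_split_comparison(
    group: EdgeGroup, split_on: str = "regulator"
) -> GroupComparisonResult:
    """Compare the non-split member's rates between low and high halves.

    Pairs are sorted by the ``split_on`` member's rate and divided into two
    (near-)equal halves; the Wilcoxon rank-sum test is applied to the OTHER
    member's rates.  ``median_a`` is the low half, ``median_b`` the high half.
    """
    if len(group) < 4:
        raise CoevoError(f"need >= 4 pairs for a median split, got {len(group)}")
    low, high = _median_split_order(group, split_on)
    other = group.partner_rates if split_on == "regulator" else group.regulator_rates
    return wilcoxon_rank_sum(
        [other[i] for i in low], [other[i] for i in high]
    )


@dataclass(frozen=True)
class SignalPreferenceResult:
    """Sign composition of TF-miRNA edges by TF-rate half.

    ``table`` rows are the high / low TF-rate halves, columns activation /
    repression counts.  Percentages are activation shares per half (on the
    0-100 scale).
    """

    table: ContingencyTable2x2
    fisher: ContingencyResult
    pct_activation_high: float
    pct_activation_low: float


def signal_preference(net: RegNetwork, tf_rates: RateTable) -> SignalPreferenceResult:
    """Test whether rapidly evolving TFs preferentially activate miRNAs.

    Signed (activation/repression) TF-miRNA edges with a rated TF are split
    into two equal halves by TF rate using the same convention as
    :func:`median_split_comparison`; Fisher's exact test is applied to the
    half × sign table.
    """
    edges = [
        e
        for e in net.edges_of_type("TF-miRNA")
        if e.sign in ("activation", "repression") and e.source in tf_rates
    ]
    if not edges:
        raise CoevoError("no signed TF-miRNA edges with rated TFs")
    group = EdgeGroup("TF-miRNA", "any")
    for e in edges:
        group.pairs.append((e.source, e.target))
        group.regulator_rates.append(tf_rates[e.source])
        group.partner_rates.append(math.nan)  # unused for the split
    low, high = _median_split_order(group, "regulator")
    signs = [e.sign for e in edges]
    table = signal_preference_table(
        [signs[i] for i in high], [signs[i] for i in low]
    )
    return _signal_preference_from_table(table)


def signal_preference_table(
    high_signs: list[str], low_signs: list[str]
) -> ContingencyTable2x2:
    return ContingencyTable2x2(
        a=sum(s == "activation" for s in high_signs),
        b=sum(s == "repression" for s in high_signs),
        c=sum(s == "activation" for s in low_signs),
        d=sum(s == "repression" for s in low_signs),
    )


def _signal_preference_from_table(
    table: ContingencyTable2x2,
) -> SignalPreferenceResult:
    n_high = table.a + table.b
    n_low = table.c + table.d
    return SignalPreferenceResult(
        table=table,
        fisher=fisher_exact_2x2(table),
        pct_activation_high=100.0 * table.a / n_high if n_high else math.nan,
        pct_activation_low=100.0 * table.c / n_low if n_low else math.nan,
    )


def signal_preference_from_counts(table: ContingencyTable2x2) -> SignalPreferenceResult:
    """Signal-preference summary from pre-tabulated counts."""
    return _signal_preference_from_table(table)


# ---------------------------------------------------------------------------
# expression-based sign inference
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values; all rows share the sample axis."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 3:
            raise CoevoError("expression matrix needs >= 3 samples per gene")
        if self.values.index.has_duplicates:
            raise CoevoError("duplicate gene ids in expression matrix")

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)


def read_expression(path) -> ExpressionMatrix:
    """Read a genes × samples TSV (header row of sample names required)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


@dataclass(frozen=True)
class InferredSign:
    edge: SignedEdge
    correlation: float  # NaN when undefined or an endpoint is missing
    missing_endpoint: bool


def infer_sign_from_expression(
    expr: ExpressionMatrix,
    edges: list[SignedEdge],
    min_abs_correlation: float = 0.0,
    method: str = "spearman",
) -> list[InferredSign]:
    """Assign signs to TF-gene edges from expression-profile correlation.

    Positive correlation → activation, negative → repression; exactly zero,
    undefined (constant profile), below ``min_abs_correlation`` in magnitude,
    or a missing endpoint → unknown.  The correlation value is retained.
    """
    if method not in ("spearman", "pearson"):
        raise CoevoError(f"unknown correlation method {method!r}")
    out: list[InferredSign] = []
    for e in edges:
        if e.source not in expr or e.target not in expr:
            out.append(
                InferredSign(
                    SignedEdge(e.source, e.target, e.relation_type, "unknown"),
                    math.nan,
                    missing_endpoint=True,
                )
            )
            continue
        x = expr.profile(e.source)
        y = expr.profile(e.target)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho = math.nan
        elif method == "spearman":
            rho = spearman(x, y).rho
        else:
            rho = float(np.corrcoef(x, y)[0, 1])
        if not math.isfinite(rho) or rho == 0 or abs(rho) < min_abs_correlation:
            sign = "unknown"
        elif rho > 0:
            sign = "activation"
        else:
            sign = "repression"
        out.append(
            InferredSign(
                SignedEdge(e.source, e.target, e.relation_type, sign),
                rho,
                missing_endpoint=False,
            )
        )
    return out
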