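"""Synthetic regulatory networks with planted, recoverable structure.

Every analysis in this package is exercised on generated data whose
statistical structure mirrors the curated human TF–miRNA network the method
was designed for:

* a tri-partite signed network (default composition 425 TFs / 150 miRNAs /
  1700 genes with 2655 TF-gene, 210 TF-miRNA and 1433 miRNA-target edges)
  with heavy-tailed regulator out-degrees,
* ~78% of TF-originating edges activating, all miRNA-target edges repressive,
* a planted Spearman correlation between regulator and partner rates on
  activating edges only (Gaussian-copula rank blending), a planted negative
  association on miRNA-target pairs,
* opposite per-depth rate gradients for TFs and miRNAs along the cascade
  (positive gradient = deeper nodes evolve faster),
* pathway co-membership enriched for activating TF–miRNA pairs at a planted
  odds ratio,
* expression profiles whose pairwise correlation sign matches each TF-gene
  edge's sign, and
* pairwise alignment blocks with i.i.d. per-site substitutions.

Each generator draws from its own seed-derived stream, so artifacts are
reproducible independently of generation order; the same seed yields
byte-identical emitted files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .coevo import ExpressionMatrix
from .evorate import (
    AlignmentBlock,
    GenomicInterval,
    RateTable,
    write_axt,
    write_bed,
    write_rate_table,
)
from .netio import NodeRecord, RegNetwork, SignedEdge, write_network
from .pathways import PathwaySet

logger = logging.getLogger("mirnetevo")

_BASES = np.array(list("ACGT"))


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror the curated network's composition.

    ``cascade_gradient_*`` is the additive rate change per unit cascade depth
    (positive: deeper regulators evolve faster, so upstream members of ordered
    pairs tend to have the lower rate).  ``rho_*`` are target Spearman
    correlations between regulator and partner rates per edge sign.
    """

    n_tf: int = 425
    n_mirna: int = 150
    n_gene: int = 1700
    n_tf_gene: int = 2655
    n_tf_mirna: int = 210
    n_mirna_target: int = 1433
    p_activation: float = 0.78
    p_tf_target: float = 0.1  # share of TF-gene edges whose target is a TF
    p_mirna_targets_tf: float = 0.1  # share of miRNA-target edges hitting a TF
    degree_skew: float = 1.0  # power-law-like exponent for out-degree weights
    rho_activating: float = 0.6
    rho_repressing: float = 0.0
    rho_mirna_target: float = -0.3
    cascade_gradient_tf: float = 0.006
    cascade_gradient_mirna: float = -0.006
    cascade_depth_cap: int = 6  # gradient saturates beyond this depth
    pathway_or: float = 2.0
    common_pathway_base: float = 0.12  # repressing-pair common-pathway rate
    n_pathways: int = 183
    memberships_per_node: int = 2
    subst_prob: float = 0.05
    gap_prob: float = 0.02
    mirna_length: int = 80
    alignment_flank: int = 10
    n_expression_samples: int = 20
    expression_noise: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_activation": self.p_activation,
            "p_tf_target": self.p_tf_target,
            "p_mirna_targets_tf": self.p_mirna_targets_tf,
            "common_pathway_base": self.common_pathway_base,
            "subst_prob": self.subst_prob,
            "gap_prob": self.gap_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SyntheticConfigError(f"{name}={p} outside [0, 1]")
        for name in ("rho_activating", "rho_repressing", "rho_mirna_target"):
            if abs(getattr(self, name)) > 1.0:
                raise SyntheticConfigError(f"|{name}| must be <= 1")
        for name in (
            "n_tf", "n_mirna", "n_gene", "n_tf_gene", "n_tf_mirna",
            "n_mirna_target", "n_pathways", "mirna_length",
        ):
            if getattr(self, name) < 1:
                raise SyntheticConfigError(f"{name} must be positive")
        if self.n_expression_samples < 3:
            raise SyntheticConfigError("need >= 3 expression samples")
        if self.n_tf_mirna > self.n_tf * self.n_mirna:
            raise SyntheticConfigError("n_tf_mirna exceeds possible distinct pairs")
        if self.n_tf_gene > self.n_tf * (self.n_tf + self.n_gene):
            raise SyntheticConfigError("n_tf_gene exceeds possible distinct pairs")
        if self.n_mirna_target > self.n_mirna * (self.n_gene + self.n_tf):
            raise SyntheticConfigError(
                "n_mirna_target exceeds possible distinct pairs"
            )

    def _stream(self, label: int) -> np.random.Generator:
        return np.random.default_rng([abs(self.seed) % (2**31), label])


def _spearman_to_pearson_weight(rho_s: float) -> float:
    """Gaussian-copula latent correlation giving Spearman ``rho_s``."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def generate_network(cfg: SyntheticConfig) -> RegNetwork:
    """Tri-partite signed network with skewed regulator out-degrees."""
    cfg.validate()
    rng = cfg._stream(1)
    tfs = [f"TF{i:04d}" for i in range(cfg.n_tf)]
    mirnas = [f"mir{i:04d}" for i in range(cfg.n_mirna)]
    genes = [f"g{i:05d}" for i in range(cfg.n_gene)]

    def skew_weights(n: int) -> np.ndarray:
        w = (np.arange(1, n + 1)) ** (-cfg.degree_skew)
        rng.shuffle(w)
        return w / w.sum()

    tf_w = skew_weights(cfg.n_tf)
    mir_w = skew_weights(cfg.n_mirna)
    edges: set[SignedEdge] = set()
    taken: set[tuple[str, str, str]] = set()

    def draw_sign() -> str:
        return "activation" if rng.random() < cfg.p_activation else "repression"

    def sample(relation: str, n: int) -> None:
        attempts = 0
        added = 0
        while added < n:
            attempts += 1
            if attempts > 200 * n + 1000:
                raise SyntheticConfigError(
                    f"could not place {n} distinct {relation} edges"
                )
            if relation == "TF-gene":
                src = tfs[rng.choice(cfg.n_tf, p=tf_w)]
                if rng.random() < cfg.p_tf_target:
                    tgt = tfs[rng.integers(cfg.n_tf)]
                else:
                    tgt = genes[rng.integers(cfg.n_gene)]
                sign = draw_sign()
            elif relation == "TF-miRNA":
                src = tfs[rng.choice(cfg.n_tf, p=tf_w)]
                tgt = mirnas[rng.integers(cfg.n_mirna)]
                sign = draw_sign()
            else:  # miRNA-target
                src = mirnas[rng.choice(cfg.n_mirna, p=mir_w)]
                if rng.random() < cfg.p_mirna_targets_tf:
                    tgt = tfs[rng.integers(cfg.n_tf)]
                else:
                    tgt = genes[rng.integers(cfg.n_gene)]
                sign = "repression"
            if (src, tgt, relation) in taken:
                continue
            taken.add((src, tgt, relation))
            edges.add(SignedEdge(src, tgt, relation, sign))
            added += 1

    sample("TF-gene", cfg.n_tf_gene)
    sample("TF-miRNA", cfg.n_tf_mirna)
    sample("miRNA-target", cfg.n_mirna_target)
    extra = (
        [NodeRecord(t, "TF") for t in tfs]
        + [NodeRecord(m, "miRNA") for m in mirnas]
        + [NodeRecord(g, "gene") for g in genes]
    )
    return RegNetwork.from_edges(edges, extra_nodes=extra)


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------


def node_depths(net: RegNetwork) -> dict[str, int]:
    """Cascade depth: longest-path position in the condensation DAG.

    Strongly connected components are contracted and each component's depth is
    the longest path from any source component.  This makes depth strictly
    monotone along the upstream/downstream ordered-pair relation (if A reaches
    B but not vice versa, depth(A) < depth(B)), so a per-depth rate gradient
    expresses the planted cascade direction deterministically — a plain BFS
    distance from root regulators does not guarantee this in dense networks.
    """
    import networkx as nx

    g = net.to_networkx()
    cond = nx.condensation(g)
    depth: dict[int, int] = {}
    for scc in nx.topological_sort(cond):
        preds = list(cond.predecessors(scc))
        depth[scc] = 1 + max((depth[p] for p in preds), default=-1)
    mapping = cond.graph["mapping"]  # node -> scc index
    return {n: depth[mapping[n]] for n in net.nodes}


def _blend_latent(
    rng: np.random.Generator,
    regulator_latents: list[float],
    rho_target: float,
) -> float:
    """Latent for a partner node: standard normal with per-edge latent
    correlation ≈ the copula weight for ``rho_target`` against each regulator.

    With k independent regulators the shared component is their normalized sum;
    the blend weight is scaled by sqrt(k) (capped at 1) so that the per-edge
    correlation stays near the target for small k and degrades gracefully as
    1/sqrt(k) for hub-regulated partners.
    """
    k = len(regulator_latents)
    if k == 0 or rho_target == 0.0:
        return float(rng.standard_normal())
    w_edge = _spearman_to_pearson_weight(rho_target)
    w_eff = max(-1.0, min(1.0, w_edge * math.sqrt(k)))
    shared = sum(regulator_latents) / math.sqrt(k)
    return float(w_eff * shared + math.sqrt(1.0 - w_eff**2) * rng.standard_normal())


def generate_rates(
    net: RegNetwork, cfg: SyntheticConfig
) -> tuple[RateTable, RateTable]:
    """Evolutionary rates with planted sign-dependent coevolution and cascade
    gradients.

    Returns (protein rate table for TFs and genes, miRNA divergence table).
    Base rates are right-skewed (gamma marginals via a Gaussian copula, dN-like
    scale for proteins, divergence-like scale for miRNAs); latent blending
    plants the per-sign correlations, then per-depth gradients shift TF and
    miRNA rates, clipped to valid ranges.
    """
    cfg.validate()
    rng = cfg._stream(2)
    latent: dict[str, float] = {}
    for tf in net.nodes_of_class("TF"):
        latent[tf] = float(rng.standard_normal())

    act_regs: dict[str, list[str]] = {}
    rep_regs: dict[str, list[str]] = {}
    mir_regs: dict[str, list[str]] = {}
    for e in net.edges:
        if e.relation_type in ("TF-gene", "TF-miRNA"):
            bucket = act_regs if e.sign == "activation" else rep_regs
            bucket.setdefault(e.target, []).append(e.source)
        else:
            mir_regs.setdefault(e.target, []).append(e.source)

    for m in net.nodes_of_class("miRNA"):
        if m in act_regs and cfg.rho_activating != 0.0:
            latent[m] = _blend_latent(
                rng, [latent[t] for t in sorted(act_regs[m])], cfg.rho_activating
            )
        elif m in rep_regs and cfg.rho_repressing != 0.0:
            latent[m] = _blend_latent(
                rng, [latent[t] for t in sorted(rep_regs[m])], cfg.rho_repressing
            )
        else:
            latent[m] = float(rng.standard_normal())

    for g in net.nodes_of_class("gene"):
        # miRNA regulation takes precedence: miRNA-target anti-coevolution is
        # the planted feature; otherwise activating TFs drive the gene latent.
        if g in mir_regs and cfg.rho_mirna_target != 0.0:
            latent[g] = _blend_latent(
                rng, [latent[m] for m in sorted(mir_regs[g])], cfg.rho_mirna_target
            )
        elif g in act_regs and cfg.rho_activating != 0.0:
            latent[g] = _blend_latent(
                rng, [latent[t] for t in sorted(act_regs[g])], cfg.rho_activating
            )
        elif g in rep_regs and cfg.rho_repressing != 0.0:
            latent[g] = _blend_latent(
                rng, [latent[t] for t in sorted(rep_regs[g])], cfg.rho_repressing
            )
        else:
            latent[g] = float(rng.standard_normal())

    depths = node_depths(net)
    n_clipped = 0
    protein: dict[str, float] = {}
    mirna: dict[str, float] = {}
    for node, cls_ in sorted(net.nodes.items()):
        u = float(sps.norm.cdf(latent[node]))
        u = min(max(u, 1e-12), 1.0 - 1e-12)
        eff_depth = min(depths[node], cfg.cascade_depth_cap)
        if cls_ == "miRNA":
            rate = float(sps.gamma.ppf(u, a=1.2, scale=0.035))
            rate += cfg.cascade_gradient_mirna * eff_depth
            if rate < 0.0 or rate > 1.0:
                n_clipped += 1
            mirna[node] = min(max(rate, 0.0), 1.0)
        else:
            rate = float(sps.gamma.ppf(u, a=1.5, scale=0.04))
            if cls_ == "TF":
                rate += cfg.cascade_gradient_tf * eff_depth
            if rate < 0.0:
                n_clipped += 1
            protein[node] = max(rate, 0.0)
    if n_clipped:
        logger.warning("generate_rates: clipped %d rates to valid range", n_clipped)
    return RateTable(protein), RateTable(mirna)


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------


def generate_pathways(net: RegNetwork, cfg: SyntheticConfig) -> PathwaySet:
    """Pathway sets with planted co-membership enrichment for activating pairs.

    Each signed TF-miRNA pair is flagged "common pathway" with probability
    derived from ``common_pathway_base`` (repressing pairs) and ``pathway_or``
    (activating pairs); flagged pairs share one randomly chosen pathway.  All
    nodes additionally receive ``memberships_per_node`` random memberships as
    annotation noise.
    """
    cfg.validate()
    rng = cfg._stream(3)
    p_rep = cfg.common_pathway_base
    odds_act = cfg.pathway_or * p_rep / (1.0 - p_rep)
    p_act = odds_act / (1.0 + odds_act)
    names = [f"P{i:03d}" for i in range(cfg.n_pathways)]
    members: dict[str, set[str]] = {n: set() for n in names}
    pairs = sorted(
        (e.source, e.target, e.sign)
        for e in net.edges_of_type("TF-miRNA")
        if e.sign in ("activation", "repression")
    )
    for tf, mir, sign in pairs:
        p = p_act if sign == "activation" else p_rep
        if rng.random() < p:
            pw = names[rng.integers(cfg.n_pathways)]
            members[pw].update((tf, mir))
    for node in sorted(net.nodes):
        for idx in rng.choice(cfg.n_pathways, cfg.memberships_per_node, replace=False):
            members[names[idx]].add(node)
    return PathwaySet(
        {n: frozenset(m) for n, m in members.items() if m}
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(net: RegNetwork, cfg: SyntheticConfig) -> ExpressionMatrix:
    """Expression profiles whose correlation signs reflect TF-gene edge signs.

    Each TF gets an independent standard-normal profile; each gene's profile
    is the signed sum of its regulators' profiles plus noise, so the per-edge
    expression correlation carries the edge's sign (with multiple discordant
    regulators, individual edges may be diluted — documented limitation).
    """
    cfg.validate()
    import pandas as pd

    rng = cfg._stream(4)
    n = cfg.n_expression_samples
    tfs = net.nodes_of_class("TF")
    genes = net.nodes_of_class("gene")
    profiles: dict[str, np.ndarray] = {}
    for tf in tfs:
        profiles[tf] = rng.standard_normal(n)
    tf_regs: dict[str, list[tuple[str, str]]] = {}
    for e in net.edges_of_type("TF-gene"):
        tf_regs.setdefault(e.target, []).append((e.source, e.sign))
    for g in genes:
        base = np.zeros(n)
        for tf, sign in sorted(tf_regs.get(g, [])):
            if sign == "activation":
                base = base + profiles[tf]
            elif sign == "repression":
                base = base - profiles[tf]
        profiles[g] = base + cfg.expression_noise * rng.standard_normal(n)
    ids = sorted(profiles)
    frame = pd.DataFrame(
        np.vstack([profiles[i] for i in ids]),
        index=pd.Index(ids, name="id"),
        columns=[f"s{j:02d}" for j in range(n)],
    )
    return ExpressionMatrix(frame)


# ---------------------------------------------------------------------------
# intervals and alignments
# ---------------------------------------------------------------------------


def generate_intervals(net: RegNetwork, cfg: SyntheticConfig) -> list[GenomicInterval]:
    """One genomic interval per miRNA on a synthetic chromosome."""
    spacing = cfg.mirna_length + 2 * cfg.alignment_flank + 100
    return [
        GenomicInterval(
            id=m,
            chrom="chrS",
            start=100 + i * spacing,
            end=100 + i * spacing + cfg.mirna_length,
            strand="+" if i % 2 == 0 else "-",
        )
        for i, m in enumerate(net.nodes_of_class("miRNA"))
    ]


def generate_alignments(
    intervals: list[GenomicInterval],
    cfg: SyntheticConfig,
    rates: RateTable | None = None,
) -> list[AlignmentBlock]:
    """One alignment block per interval with i.i.d. per-site substitutions.

    The substitution probability is the interval's planted rate when ``rates``
    is given, else ``subst_prob``; query-deletion and insertion gap columns
    appear with probability ``gap_prob`` each.
    """
    cfg.validate()
    rng = cfg._stream(5)
    blocks: list[AlignmentBlock] = []
    for iv in intervals:
        p_sub = cfg.subst_prob
        if rates is not None and iv.id in rates:
            p_sub = min(rates[iv.id], 1.0)
        start = max(iv.start - cfg.alignment_flank, 0)
        end = iv.end + cfg.alignment_flank
        ref_cols: list[str] = []
        qry_cols: list[str] = []
        for _ in range(start, end):
            if rng.random() < cfg.gap_prob:  # insertion in the query
                ref_cols.append("-")
                qry_cols.append(str(rng.choice(_BASES)))
            base = str(rng.choice(_BASES))
            ref_cols.append(base)
            if rng.random() < cfg.gap_prob:  # deletion in the query
                qry_cols.append("-")
            elif rng.random() < p_sub:
                others = [b for b in "ACGT" if b != base]
                qry_cols.append(others[rng.integers(3)])
            else:
                qry_cols.append(base)
        blocks.append(
            AlignmentBlock(
                ref_chrom=iv.chrom,
                ref_start=start,
                ref_aln="".join(ref_cols),
                query_aln="".join(qry_cols),
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


def write_bundle(outdir, cfg: SyntheticConfig) -> dict[str, str]:
    """Generate every artifact and write it in the format the pipeline reads.

    Emits the edge TSV, protein and miRNA rate TSVs, BED coordinates, AXT
    alignments (substitutions driven by the planted per-miRNA rates), GMT
    pathways, the expression TSV and a manifest JSON recording the planted
    parameters.  Byte-identical for a fixed config.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = generate_network(cfg)
    protein, mirna = generate_rates(net, cfg)
    pathways = generate_pathways(net, cfg)
    expr = generate_expression(net, cfg)
    intervals = generate_intervals(net, cfg)
    blocks = generate_alignments(intervals, cfg, rates=mirna)

    paths = {
        "network": str(outdir / "network.tsv"),
        "rates_protein": str(outdir / "rates_protein.tsv"),
        "rates_mirna": str(outdir / "rates_mirna.tsv"),
        "mirna_bed": str(outdir / "mirnas.bed"),
        "alignments": str(outdir / "alignments.axt"),
        "pathways": str(outdir / "pathways.gmt"),
        "expression": str(outdir / "expression.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_network(net, paths["network"])
    write_rate_table(protein, paths["rates_protein"])
    write_rate_table(mirna, paths["rates_mirna"])
    write_bed(intervals, paths["mirna_bed"])
    write_axt(blocks, paths["alignments"])
    pathways.to_gmt(paths["pathways"])
    from .coevo import write_expression

    write_expression(expr, paths["expression"])
    manifest = {
        "planted": dataclasses.asdict(cfg),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
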