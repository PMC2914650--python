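"""Robustness of the headline statistics to network incompleteness.

Curated regulatory networks are incomplete: some true links are missing and
some recorded links are spurious.  The sensitivity analysis simulates this by
removing a fraction of edges uniformly at random and simultaneously adding
the same-order fraction of class-compatible false edges, then re-running every
analysis on each perturbed replicate.  A finding is robust when its sign and
significance verdict survive in (nearly) all replicates.

Replicates are seeded from (seed, replicate index), so any subset of
replicates can be recomputed independently and execution order never affects
results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import cascade as casc
from . import coevo
from .evorate import RateTable
from .netio import RegNetwork, SignedEdge
from .pathways import PathwaySet

logger = logging.getLogger("mirnetevo")


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class PerturbationConfig:
    remove_frac: float = 0.05
    add_frac: float = 0.05
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("remove_frac", self.remove_frac), ("add_frac", self.add_frac)):
            if not 0.0 <= v < 1.0:
                raise SensitivityError(f"{name}={v} outside [0, 1)")
        if self.n_reps < 1:
            raise SensitivityError("n_reps must be >= 1")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


_PAIR_SPACES = {
    # relation type -> (source class, target classes)
    "TF-gene": ("TF", ("TF", "gene")),
    "TF-miRNA": ("TF", ("miRNA",)),
    "miRNA-target": ("miRNA", ("TF", "gene")),
}


def perturb_network(
    net: RegNetwork, cfg: PerturbationConfig, rep_index: int
) -> RegNetwork:
    """One perturbed replicate: remove true links, add false ones.

    Removes ``round(remove_frac * |E|)`` uniformly chosen edges and adds
    ``round(add_frac * |E|)`` edges absent from the original network, sampled
    uniformly over class-compatible (source, target) pairs and typed by their
    endpoint classes.  Added TF-gene / TF-miRNA edges draw their sign from the
    original sign frequencies of that relation type; added miRNA-target edges
    are repression.  The node set is unchanged.  Deterministic given
    (cfg.seed, rep_index).
    """
    rng = np.random.default_rng([abs(cfg.seed) % (2**31), rep_index])
    edges = sorted(net.edges)
    n_remove = _round_half_up(cfg.remove_frac * len(edges))
    n_add = _round_half_up(cfg.add_frac * len(edges))

    keep_mask = np.ones(len(edges), dtype=bool)
    if n_remove:
        keep_mask[rng.choice(len(edges), size=n_remove, replace=False)] = False
    kept = [e for e, k in zip(edges, keep_mask) if k]

    by_class: dict[str, list[str]] = {
        "TF": net.nodes_of_class("TF"),
        "miRNA": net.nodes_of_class("miRNA"),
        "gene": net.nodes_of_class("gene"),
    }
    spaces: list[tuple[str, str, str, int]] = []  # (relation, src_class, tgt_class, size)
    for rel, (src_cls, tgt_classes) in _PAIR_SPACES.items():
        for tgt_cls in tgt_classes:
            size = len(by_class[src_cls]) * len(by_class[tgt_cls])
            if size:
                spaces.append((rel, src_cls, tgt_cls, size))
    total_space = sum(s[3] for s in spaces)
    original_keys = {e.key for e in edges}
    if n_add > total_space - len(original_keys):
        raise SensitivityError(
            f"cannot add {n_add} edges: complement holds at most "
            f"{total_space - len(original_keys)}"
        )
    sign_pool: dict[str, tuple[list[str], list[float]]] = {}
    for rel in ("TF-gene", "TF-miRNA"):
        rel_signs = [e.sign for e in edges if e.relation_type == rel]
        if rel_signs:
            tokens = sorted(set(rel_signs))
            freqs = [rel_signs.count(t) / len(rel_signs) for t in tokens]
            sign_pool[rel] = (tokens, freqs)
        else:
            sign_pool[rel] = (["activation"], [1.0])

    probs = np.array([s[3] for s in spaces], dtype=float)
    probs /= probs.sum()
    added: list[SignedEdge] = []
    added_keys: set[tuple[str, str, str]] = set()
    guard = 0
    while len(added) < n_add:
        guard += 1
        if guard > 1000 * max(n_add, 1) + 10_000:
            raise SensitivityError("edge addition failed to find free pairs")
        rel, src_cls, tgt_cls, _ = spaces[rng.choice(len(spaces), p=probs)]
        src = by_class[src_cls][rng.integers(len(by_class[src_cls]))]
        tgt = by_class[tgt_cls][rng.integers(len(by_class[tgt_cls]))]
        if src == tgt and rel != "TF-gene":
            continue
        key = (src, tgt, rel)
        if key in original_keys or key in added_keys:
            continue
        if rel == "miRNA-target":
            sign = "repression"
        else:
            tokens, freqs = sign_pool[rel]
            sign = tokens[rng.choice(len(tokens), p=freqs)]
        added_keys.add(key)
        added.append(SignedEdge(src, tgt, rel, sign))

    from .netio import NodeRecord

    extra = [NodeRecord(n, c) for n, c in sorted(net.nodes.items())]
    return RegNetwork.from_edges(kept + added, extra_nodes=extra)


# ---------------------------------------------------------------------------
# replicate analyses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisStat:
    """One analysis outcome on one network: a signed statistic and optionally
    its p-value (cascade fractions are reported as fraction - 0.5, no p)."""

    value: float
    p_value: float | None


def _analysis_suite(
    net: RegNetwork,
    protein_rates: RateTable,
    mirna_rates: RateTable,
) -> dict[str, AnalysisStat]:
    out: dict[str, AnalysisStat] = {}
    tfmir = coevo.stratify_edges_by_sign(net, "TF-miRNA", protein_rates, mirna_rates)
    tfgene = coevo.stratify_edges_by_sign(net, "TF-gene", protein_rates, protein_rates)
    for label, groups in (("tf_mirna", tfmir), ("tf_gene", tfgene)):
        for sign in ("activation", "repression"):
            name = f"coevolution_{label}_{sign}"
            group = groups.get(sign)
            if group is None or len(group) < 3:
                continue
            r = coevo.coevolution_correlation(group)
            if r.defined:
                out[name] = AnalysisStat(r.rho, r.p_value)
    mt = coevo.stratify_edges_by_sign(net, "miRNA-target", mirna_rates, protein_rates)
    group = mt.get("repression")
    if group is not None and len(group) >= 4:
        cmp_ = coevo.median_split_comparison(group, split_on="regulator")
        out["mirna_target_median_split"] = AnalysisStat(
            cmp_.median_a - cmp_.median_b, cmp_.p_value
        )
    for node_class in ("TF", "miRNA"):
        rates = protein_rates if node_class == "TF" else mirna_rates
        pairs = casc.enumerate_ordered_pairs(net, node_class)
        summary = casc.upstream_conservation_fraction(pairs, rates, node_class)
        if summary.fraction_upstream_lower is not None:
            out[f"cascade_{node_class.lower()}_fraction"] = AnalysisStat(
                summary.fraction_upstream_lower - 0.5, None
            )
    return out


@dataclass
class SensitivityReport:
    """Baseline statistics plus per-replicate re-computations.

    ``replicates[name]`` holds one entry per replicate (None when that
    analysis was unavailable on that replicate, e.g. a stratum vanished);
    ``preserved_share(name)`` is the share of replicates keeping the baseline
    sign and, where a p-value exists, the baseline significance verdict at
    alpha = 0.05.
    """

    config: PerturbationConfig
    baseline: dict[str, AnalysisStat]
    replicates: dict[str, list[AnalysisStat | None]] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def median_value(self, name: str) -> float:
        vals = [s.value for s in self.replicates.get(name, []) if s is not None]
        return float(np.median(vals)) if vals else math.nan

    def preserved_share(self, name: str) -> float:
        base = self.baseline.get(name)
        reps = self.replicates.get(name, [])
        if base is None or not reps:
            return math.nan
        n_ok = 0
        for s in reps:
            if s is None:
                continue
            same_sign = math.copysign(1, s.value) == math.copysign(1, base.value)
            if base.p_value is not None and s.p_value is not None:
                same_sig = (s.p_value < self.alpha) == (base.p_value < self.alpha)
            else:
                same_sig = True
            if same_sign and same_sig:
                n_ok += 1
        return n_ok / len(reps)

    def summary_rows(self) -> list[dict]:
        rows = []
        for name in sorted(self.baseline):
            base = self.baseline[name]
            rows.append(
                {
                    "analysis": name,
                    "baseline_value": base.value,
                    "baseline_p": base.p_value,
                    "median_value": self.median_value(name),
                    "preserved_share": self.preserved_share(name),
                    "n_reps": len(self.replicates.get(name, [])),
                }
            )
        return rows

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.summary_rows()).to_csv(path, sep="\t", index=False)


def run_sensitivity(
    net: RegNetwork,
    protein_rates: RateTable,
    mirna_rates: RateTable,
    cfg: PerturbationConfig,
    pathways: PathwaySet | None = None,
) -> SensitivityReport:
    """Re-run the coevolution, median-split and cascade analyses on perturbed
    replicates and summarize stability against the unperturbed baseline.

    Per-replicate failures of individual analyses are recorded, not fatal.
    ``pathways`` is accepted for interface symmetry with the full pipeline but
    the pathway contrast is not perturbed here (membership annotations, not
    network links, drive it).
    """
    baseline = _analysis_suite(net, protein_rates, mirna_rates)
    report = SensitivityReport(config=cfg, baseline=baseline)
    report.replicates = {name: [] for name in baseline}
    for rep in range(cfg.n_reps):
        try:
            pnet = perturb_network(net, cfg, rep)
            stats = _analysis_suite(pnet, protein_rates, mirna_rates)
        except Exception as exc:  # analysis failures are per-replicate data
            report.errors.append(f"replicate {rep}: {exc}")
            stats = {}
        for name in baseline:
            report.replicates[name].append(stats.get(name))
    return report
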