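import math

import numpy as np
import pandas as pd
import pytest

from mirnetevo.coevo import (
    CoevoError,
    EdgeGroup,
    ExpressionMatrix,
    coevolution_correlation,
    infer_sign_from_expression,
    median_split_comparison,
    read_expression,
    signal_preference,
    signal_preference_from_counts,
    stratify_edges_by_sign,
    write_expression,
)
from mirnetevo.evorate import RateTable
from mirnetevo.netio import RegNetwork, SignedEdge
from mirnetevo.stats import ContingencyTable2x2
from mirnetevo.synthetic import SyntheticConfig, generate_network, generate_rates


def _rated_net():
    net = RegNetwork.from_edges(
        [
            SignedEdge("TF1", "mir1", "TF-miRNA", "activation"),
            SignedEdge("TF1", "mir2", "TF-miRNA", "activation"),
            SignedEdge("TF2", "mir1", "TF-miRNA", "repression"),
        ]
    )
    tf_rates = RateTable({"TF1": 0.1, "TF2": 0.2})
    mir_rates = RateTable({"mir1": 0.03, "mir2": 0.06})
    return net, tf_rates, mir_rates


class TestStratify:
    def test_group_sizes_by_sign(self):
        net, tf_rates, mir_rates = _rated_net()
        groups = stratify_edges_by_sign(net, "TF-miRNA", tf_rates, mir_rates)
        assert len(groups["activation"]) == 2
        assert len(groups["repression"]) == 1

    def test_missing_rate_dropped(self):
        net, tf_rates, _ = _rated_net()
        groups = stratify_edges_by_sign(
            net, "TF-miRNA", tf_rates, RateTable({"mir1": 0.03})
        )
        assert len(groups["activation"]) == 1  # mir2 unrated -> dropped

    def test_absent_relation_type_gives_empty_map(self):
        net, tf_rates, mir_rates = _rated_net()
        assert stratify_edges_by_sign(net, "miRNA-target", mir_rates, tf_rates) == {}

    def test_group_sizes_sum_to_rated_edges(self, small_cfg):
        net = generate_network(small_cfg)
        prot, mir = generate_rates(net, small_cfg)
        groups = stratify_edges_by_sign(net, "TF-miRNA", prot, mir)
        n_rated = sum(
            1
            for e in net.edges_of_type("TF-miRNA")
            if e.source in prot and e.target in mir
        )
        assert sum(len(g) for g in groups.values()) == n_rated


class TestCorrelation:
    def test_monotone_pairs_give_rho_one(self):
        g = EdgeGroup("TF-miRNA", "activation",
                      pairs=[("a", "x"), ("b", "y"), ("c", "z")],
                      regulator_rates=[0.1, 0.2, 0.3],
                      partner_rates=[0.01, 0.02, 0.03])
        assert coevolution_correlation(g).rho == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        g = EdgeGroup("TF-miRNA", "activation", [("a", "x")], [0.1], [0.2])
        with pytest.raises(CoevoError):
            coevolution_correlation(g)

    def test_planted_correlation_recovered(self):
        rhos = []
        for seed in range(5):
            cfg = SyntheticConfig(
                seed=seed, n_tf=100, n_mirna=140, n_gene=200, n_tf_gene=250,
                n_tf_mirna=200, n_mirna_target=200,
                cascade_gradient_tf=0.0, cascade_gradient_mirna=0.0,
            )
            net = generate_network(cfg)
            prot, mir = generate_rates(net, cfg)
            g = stratify_edges_by_sign(net, "TF-miRNA", prot, mir)["activation"]
            rhos.append(coevolution_correlation(g).rho)
        assert 0.4 < np.mean(rhos) < 0.75

    def test_permuted_partner_rates_kill_correlation(self):
        cfg = SyntheticConfig(
            seed=2, n_tf=200, n_mirna=500, n_gene=300, n_tf_gene=300,
            n_tf_mirna=650, n_mirna_target=300,
            cascade_gradient_tf=0.0, cascade_gradient_mirna=0.0,
        )
        net = generate_network(cfg)
        prot, mir = generate_rates(net, cfg)
        g = stratify_edges_by_sign(net, "TF-miRNA", prot, mir)["activation"]
        rng = np.random.default_rng(0)
        g.partner_rates = list(rng.permutation(g.partner_rates))
        assert abs(coevolution_correlation(g).rho) < 0.1


class TestMedianSplit:
    def test_low_and_high_half_medians(self):
        g = EdgeGroup("TF-miRNA", "activation",
                      pairs=[("a", "w"), ("b", "x"), ("c", "y"), ("d", "z")],
                      regulator_rates=[1, 2, 3, 4],
                      partner_rates=[0.1, 0.1, 0.9, 0.9])
        res = median_split_comparison(g, "regulator")
        assert (res.median_a, res.median_b) == (0.1, 0.9)
        assert res.n_a == res.n_b == 2

    def test_equal_partner_rates_give_p_one(self):
        g = EdgeGroup("TF-miRNA", "activation",
                      pairs=[(c, c) for c in "abcd"],
                      regulator_rates=[1, 2, 3, 4],
                      partner_rates=[0.5] * 4)
        assert median_split_comparison(g, "regulator").p_value == 1.0

    def test_odd_count_middle_goes_to_low_half(self):
        g = EdgeGroup("TF-miRNA", "activation",
                      pairs=[(c, c) for c in "abcde"],
                      regulator_rates=[1, 2, 3, 4, 5],
                      partner_rates=[0.1, 0.2, 0.3, 0.4, 0.5])
        res = median_split_comparison(g, "regulator")
        assert (res.n_a, res.n_b) == (3, 2)

    def test_group_sizes_differ_by_at_most_one(self, small_cfg):
        net = generate_network(small_cfg)
        prot, mir = generate_rates(net, small_cfg)
        g = stratify_edges_by_sign(net, "miRNA-target", mir, prot)["repression"]
        res = median_split_comparison(g, "regulator")
        assert abs(res.n_a - res.n_b) <= 1

    def test_planted_anticorrelation_direction_on_mirna_targets(self):
        """Conserved miRNAs regulate faster-evolving targets: the low-rate
        half's targets have the higher median."""
        diffs = []
        for seed in range(5):
            cfg = SyntheticConfig(seed=seed)
            net = generate_network(cfg)
            prot, mir = generate_rates(net, cfg)
            g = stratify_edges_by_sign(net, "miRNA-target", mir, prot)["repression"]
            res = median_split_comparison(g, "regulator")
            diffs.append(res.median_a - res.median_b)
        assert np.mean(diffs) > 0


class TestSignalPreference:
    def test_printed_counts_reproduce_percentages(self):
        res = signal_preference_from_counts(ContingencyTable2x2(76, 13, 82, 32))
        assert round(res.pct_activation_high, 1) == 85.4
        assert round(res.pct_activation_low, 1) == 71.9

    def test_all_activation_degenerate_column(self):
        res = signal_preference_from_counts(ContingencyTable2x2(5, 0, 5, 0))
        assert math.isnan(res.fisher.odds_ratio)
        assert res.fisher.p_value == pytest.approx(1.0)

    def test_split_uses_tf_rate_halves(self):
        net, tf_rates, _ = _rated_net()
        res = signal_preference(net, tf_rates)
        # 3 signed edges: low half holds 2 (TF1 edges), high half 1 (TF2)
        assert res.table.a + res.table.b == 1
        assert res.table.c + res.table.d == 2

    def test_null_p_values_roughly_uniform(self):
        """With signs independent of TF rate the Fisher p is null-distributed
        (discrete, hence only roughly uniform)."""
        ps = []
        for seed in range(60):
            cfg = SyntheticConfig(
                seed=seed, n_tf=80, n_mirna=120, n_gene=100, n_tf_gene=150,
                n_tf_mirna=250, n_mirna_target=150, p_activation=0.5,
            )
            net = generate_network(cfg)
            prot, _ = generate_rates(net, cfg)
            ps.append(signal_preference(net, prot).fisher.p_value)
        ps = np.asarray(ps)
        # no excess of small p-values, and p spreads over the unit interval
        assert (ps < 0.05).mean() <= 0.10
        assert np.median(ps) > 0.25


class TestSignInference:
    def _expr(self, rows):
        return ExpressionMatrix(pd.DataFrame(rows).T)

    def test_identical_profiles_activation(self):
        expr = self._expr({"TF1": [1, 2, 3, 4], "g1": [1, 2, 3, 4]})
        edges = [SignedEdge("TF1", "g1", "TF-gene", "unknown")]
        out = infer_sign_from_expression(expr, edges)
        assert out[0].edge.sign == "activation" and out[0].correlation == 1.0

    def test_negated_profile_repression_and_antisymmetry(self):
        expr = self._expr({"TF1": [1, 2, 3, 4], "g1": [4, 3, 2, 1]})
        out = infer_sign_from_expression(
            expr, [SignedEdge("TF1", "g1", "TF-gene", "unknown")]
        )
        assert out[0].edge.sign == "repression" and out[0].correlation == -1.0

    def test_constant_profile_unknown(self):
        expr = self._expr({"TF1": [1, 1, 1, 1], "g1": [1, 2, 3, 4]})
        out = infer_sign_from_expression(
            expr, [SignedEdge("TF1", "g1", "TF-gene", "unknown")]
        )
        assert out[0].edge.sign == "unknown" and math.isnan(out[0].correlation)

    def test_missing_endpoint_flagged(self):
        expr = self._expr({"TF1": [1, 2, 3]})
        out = infer_sign_from_expression(
            expr, [SignedEdge("TF1", "g9", "TF-gene", "unknown")]
        )
        assert out[0].missing_endpoint and out[0].edge.sign == "unknown"

    def test_expression_round_trip(self, tmp_path, small_cfg):
        from mirnetevo.synthetic import generate_expression, generate_network

        net = generate_network(small_cfg)
        expr = generate_expression(net, small_cfg)
        path = tmp_path / "expr.tsv"
        write_expression(expr, path)
        back = read_expression(path)
        assert np.allclose(back.values.to_numpy(), expr.values.to_numpy())

    def test_generated_expression_signs_match_edges(self, small_cfg):
        from mirnetevo.synthetic import generate_expression, generate_network

        net = generate_network(small_cfg)
        expr = generate_expression(net, small_cfg)
        edges = net.edges_of_type("TF-gene")
        out = infer_sign_from_expression(expr, edges)
        known = [
            (o.edge.sign, e.sign)
            for o, e in zip(out, edges)
            if e.sign in ("activation", "repression") and not o.missing_endpoint
        ]
        agree = sum(a == b for a, b in known) / len(known)
        assert agree > 0.8  # hubs with discordant co-regulators dilute a few
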