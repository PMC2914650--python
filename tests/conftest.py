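import pytest

from mirnetevo.netio import RegNetwork, SignedEdge
from mirnetevo.synthetic import SyntheticConfig


@pytest.fixture
def tiny_network() -> RegNetwork:
    """Hand-built 3-layer cascade: TFs -> miRNAs -> targets (incl. a TF)."""
    return RegNetwork.from_edges(
        [
            SignedEdge("TF1", "g1", "TF-gene", "activation"),
            SignedEdge("TF1", "mir1", "TF-miRNA", "activation"),
            SignedEdge("TF1", "mir2", "TF-miRNA", "repression"),
            SignedEdge("TF2", "g2", "TF-gene", "repression"),
            SignedEdge("mir1", "g1", "miRNA-target", "repression"),
            SignedEdge("mir1", "TF2", "miRNA-target", "repression"),
            SignedEdge("mir2", "g2", "miRNA-target", "repression"),
        ]
    )


@pytest.fixture
def small_cfg() -> SyntheticConfig:
    """Desk-scale generator configuration used across module tests."""
    return SyntheticConfig(
        n_tf=40,
        n_mirna=30,
        n_gene=120,
        n_tf_gene=200,
        n_tf_mirna=90,
        n_mirna_target=120,
        n_pathways=30,
        seed=0,
    )
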