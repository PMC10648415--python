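import numpy as np
import pytest

from circernet.cernet import CeRNANetwork, CeRNATriple, SignedFeature
from circernet.tabio import Layer

# The published sponge table this package's summary math is checked against:
# five circRNAs, their interacting miRNAs, and per-circRNA interaction counts.
SPONGE_TABLE = {
    "circANKRD17": (("hsa-miR-7-5p", "hsa-miR-182-3p", "hsa-miR-182-5p"), 124),
    "circBPTF": (("hsa-let-7a-5p", "hsa-miR-18a-3p", "hsa-miR-126-5p",
                  "hsa-miR-146b-5p", "hsa-miR-196b-5p"), 220),
    "circHIPK3": (("hsa-miR-551b-3p",), 50),
    "circPVT1": (("hsa-miR-30a-5p", "hsa-miR-30d-5p"), 155),
    "circSLC8A1": (("hsa-miR-338-3p", "hsa-miR-338-5p"), 113),
}


def build_tripartite_network(per_circ, circ_sign=1):
    """Expand a {circ: (miRNAs, n_interactions)} spec into a full network.

    Interactions are distributed round-robin over each circRNA's miRNAs and
    each triple gets its own mRNA, so distinct-mRNA count equals the
    interaction total.
    """
    triples = []
    gene_counter = 0
    for circ, (mirnas, count) in per_circ.items():
        circ_feat = SignedFeature(circ, Layer.CIRCRNA, circ_sign * 1.5, 0.001)
        for i in range(count):
            mirna = mirnas[i % len(mirnas)]
            mirna_feat = SignedFeature(mirna, Layer.MIRNA, -circ_sign * 1.0,
                                       0.01)
            gene_counter += 1
            mrna_feat = SignedFeature(f"TGT{gene_counter:04d}", Layer.MRNA,
                                      circ_sign * 0.8, 0.005)
            triples.append(CeRNATriple(circ=circ_feat, mirna=mirna_feat,
                                       mrna=mrna_feat,
                                       circ_mir_sources=frozenset({"encori"}),
                                       mm_resource_count=7))
    return CeRNANetwork(triples=frozenset(triples))


@pytest.fixture(scope="session")
def sponge_table_network():
    return build_tripartite_network(SPONGE_TABLE)


def random_small_network(rng: np.random.Generator, max_nodes: int = 5):
    """A random valid (sign-consistent) network for property tests.

    Every node carries one fixed sign, so shared nodes are attribute-
    consistent across triples.
    """
    circs = [f"c{i}" for i in range(1, max_nodes + 1)]
    mirnas = [f"m{i}" for i in range(1, max_nodes + 1)]
    genes = [f"g{i}" for i in range(1, max_nodes + 1)]
    sign = {x: int(rng.choice([-1, 1])) for x in circs + mirnas + genes}
    candidates = [(c, m, g) for c in circs for m in mirnas for g in genes
                  if sign[m] == -sign[c] and sign[g] == sign[c]]
    n = int(rng.integers(0, min(11, len(candidates) + 1)))
    idx = rng.choice(len(candidates), size=n, replace=False) if n else []
    triples = set()
    for i in np.asarray(idx, dtype=int):
        c, m, g = candidates[i]
        triples.add(CeRNATriple(
            circ=SignedFeature(c, Layer.CIRCRNA, sign[c] * 2.0, 0.01),
            mirna=SignedFeature(m, Layer.MIRNA, sign[m] * 1.0, 0.01),
            mrna=SignedFeature(g, Layer.MRNA, sign[g] * 1.0, 0.001),
            circ_mir_sources=frozenset({"encori", "circatlas"}),
            mm_resource_count=int(rng.integers(1, 20)),
        ))
    return CeRNANetwork(triples=frozenset(triples))
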