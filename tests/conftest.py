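import numpy as np
import pytest

from triwalk import (CompositeNetwork, build_composite, edge_list_from_pairs)


def make_net(gg=(), pp=(), mm=(), gm=(), pg=(), pm=()) -> CompositeNetwork:
    """Build a composite network from in-memory (u, v, w) triples."""
    return build_composite(
        edge_list_from_pairs("gene", "gene", list(gg)),
        edge_list_from_pairs("phenotype", "phenotype", list(pp)),
        edge_list_from_pairs("metabolite", "metabolite", list(mm)),
        edge_list_from_pairs("gene", "metabolite", list(gm)),
        edge_list_from_pairs("phenotype", "gene", list(pg)),
        edge_list_from_pairs("phenotype", "metabolite", list(pm)),
    )


def random_composite(rng: np.random.Generator, max_layer: int = 15) -> CompositeNetwork:
    """Random small composite network spanning the absent-block cases.

    Layer sizes may be zero (at most two empty layers), whole sub-networks are
    dropped at random, and nodes may end up isolated, so the transition
    builder's fallback rules (absent cross block, absent within block,
    dangling node) are all exercised.
    """
    while True:
        sizes = rng.integers(0, max_layer + 1, size=3)
        if sizes.sum() > 0:
            break
    genes = [f"g{i}" for i in range(sizes[0])]
    phens = [f"p{i}" for i in range(sizes[1])]
    mets = [f"m{i}" for i in range(sizes[2])]

    def within(ids):
        if len(ids) < 2 or rng.random() < 0.3:  # sometimes drop the block
            return []
        density = rng.uniform(0.05, 0.6)
        out = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if rng.random() < density:
                    out.append((ids[i], ids[j], float(rng.uniform(0.05, 1.0))))
        return out

    def cross(rows, cols):
        if not rows or not cols or rng.random() < 0.3:
            return []
        density = rng.uniform(0.05, 0.5)
        return [(r, c, float(rng.uniform(0.05, 1.0)))
                for r in rows for c in cols if rng.random() < density]

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-blocks-empty draws are retried
        net = make_net(gg=within(genes), pp=within(phens), mm=within(mets),
                       gm=cross(genes, mets), pg=cross(phens, genes),
                       pm=cross(phens, mets))
    if net.n_nodes == 0:
        return random_composite(rng, max_layer)
    return net


def add_isolated_metabolite(net: CompositeNetwork, mid: str) -> CompositeNetwork:
    """Return a copy of the network with one extra edge-less metabolite node."""
    ng, np_, nm = net.layer_sizes
    mm = net.mm.copy()
    mm.resize((nm + 1, nm + 1))
    gm = net.gm.copy()
    gm.resize((ng, nm + 1))
    pm = net.pm.copy()
    pm.resize((np_, nm + 1))
    return CompositeNetwork(net.genes, net.phenotypes, net.metabolites + [mid],
                            net.gg, net.pp, mm, gm, net.pg, pm)


@pytest.fixture
def toy4() -> CompositeNetwork:
    """Two genes, one phenotype, one metabolite: g1-g2, p1-g1, p1-m1."""
    return make_net(gg=[("g1", "g2", 1.0)],
                    pg=[("p1", "g1", 1.0)],
                    pm=[("p1", "m1", 1.0)])
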