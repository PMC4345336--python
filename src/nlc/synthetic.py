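"""Packaged example networks and a planted hybrid-structure simulator.

Two deterministic fixtures ship as edge-list TSVs: a 14-node network of
three 5-cliques (two sharing a node, the third attached by a bridge edge)
whose known best description is a mixture of two link communities and one
node community, and Zachary's 34-node karate-club network.  For systematic
testing, :func:`planted_hybrid_network` plants a chain of clique blocks —
node-community blocks on fresh nodes and link-community blocks sharing a
node with their predecessor — plus Bernoulli inter-block noise, and returns
the network together with its ground-truth typed structure and node cover.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .inference import HybridStructure
from .mapeq import NodeCover, induced_cover
from .network import Network

__all__ = [
    "fixture_toy14",
    "fixture_karate",
    "planted_hybrid_network",
    "chain_spec",
]


def _load_fixture(name: str) -> Network:
    from .io import read_graph

    with resources.as_file(resources.files("nlc") / "data" / name) as p:
        return read_graph(p, format="edgelist")


def fixture_toy14() -> tuple[Network, HybridStructure, NodeCover]:
    """Three overlapping 5-cliques on 14 nodes (31 edges).

    Cliques sit on nodes {1..5}, {5..9} and {10..14}; node 5 is shared by
    the first two and the edge (9, 10) bridges to the third.  Ground truth:
    the two node-sharing cliques are link communities (their shared node
    belongs to both), the third clique is a node community, and the bridge
    edge belongs with the third block.  Returns (network, typed structure,
    induced node cover).
    """
    net = _load_fixture("toy14.tsv")
    c1 = [str(i) for i in range(1, 6)]
    c2 = [str(i) for i in range(5, 10)]
    c3 = [str(i) for i in range(10, 15)]

    def clique_edges(nodes):
        return frozenset(
            tuple(sorted((u, v))) for a, u in enumerate(nodes) for v in nodes[a + 1 :]
        )

    communities = [
        ("link", clique_edges(c1)),
        ("link", clique_edges(c2)),
        ("node", frozenset(c3)),
    ]
    structure = HybridStructure(
        communities, frozenset(), frozenset({tuple(sorted(("9", "10")))})
    )
    return net, structure, induced_cover(structure, net)


def fixture_karate() -> Network:
    """Zachary's karate-club network: 34 nodes, 78 edges, unweighted."""
    return _load_fixture("karate.tsv")


def chain_spec(
    n_blocks: int = 8, n_nodes: int = 100, n_link_blocks: int = 2
) -> list[dict]:
    """Block specification for a chain of clique communities.

    ``n_link_blocks`` of the blocks are link communities, each sharing one
    node with the preceding block (creating genuine overlap); the rest are
    node communities on fresh nodes.  Sizes are as equal as possible given
    ``n_nodes`` distinct nodes in total.
    """
    if n_blocks < 1 or n_link_blocks >= n_blocks:
        raise ValueError("need at least one node block")
    kinds = ["node"] * n_blocks
    # spread link blocks through the chain, never first (they share backwards)
    for t in range(n_link_blocks):
        kinds[(t + 1) * n_blocks // (n_link_blocks + 1)] = "link"
    total = n_nodes + n_link_blocks  # shared nodes counted once
    sizes = [total // n_blocks] * n_blocks
    for t in range(total - sum(sizes)):
        sizes[t] += 1
    if min(sizes) < 3:
        raise ValueError("blocks must have at least 3 nodes")
    return [{"kind": k, "size": s} for k, s in zip(kinds, sizes)]


def planted_hybrid_network(
    blocks: list[dict] | None = None,
    inter_p: float = 0.02,
    seed: int | np.random.Generator | None = None,
    max_resample: int = 20,
) -> tuple[Network, HybridStructure, NodeCover]:
    """Planted chain of clique blocks with Bernoulli inter-block noise.

    Each block is a clique.  A ``"node"`` block occupies fresh nodes; a
    ``"link"`` block shares its first node with the preceding block, so that
    the shared node genuinely belongs to two communities and the block is
    best described by its links.  Every cross-block node pair is then joined
    independently with probability ``inter_p``.  If noise makes some planted
    node block no denser inside than at its boundary, the noise is
    resampled (up to ``max_resample`` times).

    Returns (network, ground-truth typed structure, ground-truth cover).
    """
    if blocks is None:
        blocks = chain_spec()
    rng = np.random.default_rng(seed)
    block_nodes: list[list[str]] = []
    next_id = 0
    for b, spec in enumerate(blocks):
        size = int(spec["size"])
        if size < 3:
            raise ValueError("block sizes must be >= 3")
        nodes = []
        if spec["kind"] == "link":
            if b == 0:
                raise ValueError("a link block needs a predecessor to share a node with")
            nodes.append(block_nodes[b - 1][-1])
        while len(nodes) < size:
            nodes.append(str(next_id))
            next_id += 1
        block_nodes.append(nodes)
    labels = [str(i) for i in range(next_id)]
    clique_edges = []
    for nodes in block_nodes:
        for a, u in enumerate(nodes):
            for v in nodes[a + 1 :]:
                clique_edges.append((u, v, 1.0))
    members = [set(nodes) for nodes in block_nodes]

    for _ in range(max_resample):
        noise = []
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                u, v = labels[a], labels[b]
                if any(u in s and v in s for s in members):
                    continue
                if rng.random() < inter_p:
                    noise.append((u, v, 1.0))
        net = Network.from_edges(clique_edges + noise, node_labels=labels)
        if _blocks_dense(net, blocks, block_nodes):
            break
    else:
        raise ValueError("could not plant dense-enough blocks; lower inter_p")

    communities = []
    for spec, nodes in zip(blocks, block_nodes):
        if spec["kind"] == "node":
            communities.append(("node", frozenset(nodes)))
        else:
            communities.append(
                (
                    "link",
                    frozenset(
                        tuple(sorted((u, v)))
                        for a, u in enumerate(nodes)
                        for v in nodes[a + 1 :]
                    ),
                )
            )
    structure = HybridStructure(communities, frozenset(), frozenset())
    return net, structure, induced_cover(structure, net)


def _blocks_dense(net: Network, blocks, block_nodes) -> bool:
    """Every planted node block strictly denser inside than at its boundary."""
    for spec, nodes in zip(blocks, block_nodes):
        if spec["kind"] != "node":
            continue
        idx = np.asarray([net.index_of(u) for u in nodes], dtype=np.intp)
        inside = float(net.W[idx, :][:, idx].sum())  # 2 * internal weight
        total = float(net.degrees[idx].sum())
        if inside <= total - inside:  # internal <= boundary weight
            return False
    return True
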