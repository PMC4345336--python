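"""Model/Results front end.

:class:`NodeLinkCommunities` wraps a network and the detection settings the
way a statistical model wraps its data; :meth:`~NodeLinkCommunities.fit`
returns the :class:`~nlc.inference.NLCResults` object carrying parameter
estimates, soft memberships, the typed hard structure, the description
length and a text ``summary()``.

>>> import nlc
>>> net, _, truth = nlc.fixture_toy14()
>>> res = nlc.NodeLinkCommunities(net, c=3).fit(seed=0)
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .inference import NLCResults, detect_communities
from .network import Network
from .selection import SweepResult, sweep_c

__all__ = ["NodeLinkCommunities", "select_communities"]


class NodeLinkCommunities:
    """Degree-allocation community model for an undirected network.

    Parameters
    ----------
    network
        A :class:`~nlc.network.Network`, a networkx graph, or anything
        :meth:`Network.from_edges` accepts (an iterable of edge tuples).
    c
        Number of communities.
    scheme
        ``"hybrid"`` (search node/link type per community), ``"node"`` or
        ``"link"``.
    """

    def __init__(self, network, c: int, scheme: str = "hybrid"):
        self.net = self._coerce(network)
        if c < 1:
            raise ValueError("need at least one community")
        self.c = int(c)
        self.scheme = scheme

    @staticmethod
    def _coerce(network) -> Network:
        if isinstance(network, Network):
            return network
        if isinstance(network, nx.Graph):
            return Network.from_networkx(network)
        return Network.from_edges(network)

    @classmethod
    def from_file(cls, path, c: int, scheme: str = "hybrid", format: str = "auto"):
        from .io import read_graph

        return cls(read_graph(path, format=format), c=c, scheme=scheme)

    def fit(
        self,
        method: str = "em",
        restarts: int = 10,
        max_iter: int = 500,
        tol: float = 1e-8,
        seed: int | None = None,
    ) -> NLCResults:
        """Fit the model and infer the hard typed community structure."""
        return detect_communities(
            self.net,
            self.c,
            scheme=self.scheme,
            method=method,
            restarts=restarts,
            max_iter=max_iter,
            tol=tol,
            seed=seed,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"NodeLinkCommunities(n={self.net.n_nodes}, c={self.c}, "
            f"scheme={self.scheme!r})"
        )


def select_communities(
    network,
    c_min: int = 1,
    c_max: int = 10,
    scheme: str = "hybrid",
    method: str = "em",
    seed: int | None = None,
    **opts,
) -> SweepResult:
    """Sweep the community count and return the shortest-description result."""
    net = NodeLinkCommunities._coerce(network)
    return sweep_c(net, c_min, c_max, scheme=scheme, method=method, seed=seed, **opts)
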