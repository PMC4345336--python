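"""Graph readers, cover readers and result (de)serialization.

Supported graph formats: GML, Pajek NET and plain TSV edge lists (two or
three whitespace-separated columns ``src dst [weight]``; lines starting with
``#`` are comments).  Duplicate edges are summed into the pair weight and a
self-loop of weight s is stored as ``W_ii = 2 s``.  Ground-truth covers are
text files with one community per line of whitespace-separated node labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .inference import NLCResults
from .mapeq import NodeCover
from .network import Network

__all__ = [
    "read_graph",
    "read_cover",
    "write_cover",
    "write_structure",
    "read_structure",
]

FORMAT_VERSION = 1


class GraphParseError(ValueError):
    pass


def _read_edgelist(path: Path) -> Network:
    edges = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 2:
            edges.append((parts[0], parts[1], 1.0))
        elif len(parts) == 3:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise GraphParseError(f"{path}:{ln}: bad weight {parts[2]!r}") from exc
            edges.append((parts[0], parts[1], w))
        else:
            raise GraphParseError(f"{path}:{ln}: expected 2 or 3 columns, got {len(parts)}")
    return Network.from_edges(edges)


def _read_gml(path: Path) -> nx.Graph:
    try:
        return nx.read_gml(path, label="label")
    except nx.NetworkXError as exc:
        msg = str(exc).lower()
        if "duplicated" in msg or "multigraph" in msg:
            # repeated edges without a multigraph flag: reparse as a
            # multigraph so the duplicates accumulate into weights
            text = path.read_text()
            text = text.replace("graph [", "graph [\n  multigraph 1", 1)
            try:
                return nx.parse_gml(text, label="label")
            except nx.NetworkXError as exc2:  # pragma: no cover
                raise GraphParseError(f"{path}: {exc2}") from exc2
        raise GraphParseError(f"{path}: {exc}") from exc


def read_graph(path, format: str = "auto", symmetrize: bool = False) -> Network:
    """Read an undirected network from GML / Pajek NET / TSV edge list.

    Directed input raises unless ``symmetrize=True`` (arcs then summed with
    their reverses).  Format is chosen by extension when ``"auto"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        ext = path.suffix.lower()
        format = {"": "edgelist", ".gml": "gml", ".net": "pajek", ".paj": "pajek"}.get(
            ext, "edgelist"
        )
    if format == "edgelist":
        return _read_edgelist(path)
    if format == "gml":
        g = _read_gml(path)
    elif format == "pajek":
        try:
            g = nx.read_pajek(path)
        except Exception as exc:
            raise GraphParseError(f"{path}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {format!r}")
    if g.is_directed():
        if not symmetrize:
            raise GraphParseError(
                f"{path}: directed graph; pass symmetrize=True to fold arcs"
            )
        g = g.to_undirected(reciprocal=False)
    return Network.from_networkx(g)


def read_cover(path) -> NodeCover:
    """One community per line, whitespace-separated node labels."""
    modules = []
    for line in Path(path).read_text().splitlines():
        labels = line.split()
        if labels:
            modules.append(frozenset(labels))
    if not modules:
        raise ValueError(f"{path}: no communities found")
    return NodeCover(modules)


def write_cover(cover: NodeCover, path) -> None:
    with open(path, "w") as fh:
        for m in cover.modules:
            fh.write(" ".join(sorted(m)) + "\n")


def write_structure(result: NLCResults, path, include_soft: bool = False) -> None:
    """Serialize a detection result to JSON (lossless round-trip)."""
    net = result.net
    doc = {
        "version": FORMAT_VERSION,
        "c": result.n_communities,
        "scheme": result.scheme,
        "method": result.method,
        "seed": result.seed,
        "mdl": result.mdl,
        "log_likelihood": result.log_likelihood,
        "node_labels": net.node_labels,
        "edges": [
            [net.node_labels[i], net.node_labels[j], float(w)]
            for i, j, w in zip(net.edge_i, net.edge_j, net.edge_w)
        ],
        "types": result.types,
        "communities": [
            {"type": t, "members": sorted(map(list, m)) if t == "link" else sorted(m)}
            for t, m in result.structure.communities
        ],
        "background_nodes": sorted(result.structure.background_nodes),
        "background_links": sorted(map(list, result.structure.background_links)),
        "D": result.model.D.tolist(),
    }
    if include_soft:
        doc["S"] = result.S.tolist()
        doc["R"] = result.R.tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_structure(path) -> NLCResults:
    """Load a result written by :func:`write_structure`."""
    import numpy as np

    from .inference import HybridStructure, link_memberships, node_memberships
    from .mapeq import induced_cover
    from .model import DegreeModel, log_likelihood

    with open(path) as fh:
        doc = json.load(fh)
    required = {"version", "c", "scheme", "method", "mdl", "node_labels", "edges",
                "types", "communities", "D"}
    missing = required - doc.keys()
    if missing:
        raise ValueError(f"{path}: missing required keys {sorted(missing)}")
    net = Network.from_edges(
        [(u, v, w) for u, v, w in doc["edges"]], node_labels=doc["node_labels"]
    )
    model = DegreeModel(np.asarray(doc["D"], dtype=float))
    communities = []
    for entry in doc["communities"]:
        if entry["type"] == "link":
            members = frozenset(tuple(e) for e in entry["members"])
        else:
            members = frozenset(entry["members"])
        communities.append((entry["type"], members))
    structure = HybridStructure(
        communities,
        frozenset(doc.get("background_nodes", [])),
        frozenset(tuple(e) for e in doc.get("background_links", [])),
    )
    return NLCResults(
        net=net,
        model=model,
        S=node_memberships(model),
        R=link_memberships(net, model),
        types=doc["types"],
        structure=structure,
        cover=induced_cover(structure, net),
        mdl=float(doc["mdl"]),
        log_likelihood=float(doc.get("log_likelihood", log_likelihood(net, model))),
        scheme=doc["scheme"],
        method=doc["method"],
        seed=doc.get("seed"),
    )
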