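"""Phenotype co-occurrence networks ("bubble charts") and edge replication.

Two graphs over the six phenotype categories are compared:

* the *reference* graph — the clinically/epidemiologically established
  relationships between the phenotypes, supplied as a config edge list
  (default: the complete 6-clique), with unweighted 0/1 edges;
* the *genetic* graph — an edge between two phenotypes wherever their
  positional gene sets intersect, weighted by the intersection size, with
  node sizes proportional to each phenotype's share of studied genes.

An edge of the reference graph is *replicated* when the genetic graph also
contains it.  The canonical artifact is the serialized graph (GraphML, DOT,
JSON summary); rendering is optional and never load-bearing.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .config import PHENOTYPES
from .overlap import PhenotypeGeneSet


def build_genetic_graph(
    sets: dict[str, PhenotypeGeneSet], denominator: str = "multiplicity"
) -> nx.Graph:
    """Genetic overlap graph from the six phenotype gene sets.

    Node attribute ``size_fraction`` is the phenotype's share of studied
    genes.  With ``denominator='multiplicity'`` (default) the denominator is
    the sum of per-phenotype list sizes, so a shared gene is attributed to
    every phenotype it touches; ``'distinct'`` divides by the number of
    distinct genes instead.  Edges join phenotypes with a non-empty pairwise
    intersection; ``weight`` is the intersection size.
    """
    if denominator not in ("multiplicity", "distinct"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    labels = [p for p in PHENOTYPES if p in sets]
    if denominator == "multiplicity":
        denom = sum(sets[p].size for p in labels)
    else:
        denom = len(set().union(*(sets[p].genes for p in labels))) if labels else 0
    g = nx.Graph(kind="genetic")
    for p in labels:
        g.add_node(p, size_fraction=(sets[p].size / denom) if denom else 0.0)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            inter = sets[a].genes & sets[b].genes
            if inter:
                g.add_edge(a, b, weight=len(inter), genes=";".join(sorted(inter)))
    return g


def reference_graph(
    edges: list[tuple[str, str]] | None = None,
    nodes: tuple[str, ...] = PHENOTYPES,
) -> nx.Graph:
    """Reference (epidemiological) network with unweighted 0/1 edges.

    ``edges=None`` yields the complete graph on the six phenotypes; a
    supplied edge list is validated against the node universe and
    deduplicated (edges are unordered pairs).
    """
    g = nx.Graph(kind="reference")
    g.add_nodes_from(nodes)
    if edges is None:
        edge_iter = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
    else:
        edge_iter = edges
        for a, b in edge_iter:
            if a not in g or b not in g:
                raise ValueError(f"reference edge ({a}, {b}) names an unknown phenotype")
    for a, b in edge_iter:
        g.add_edge(a, b, weight=1)
    return g


@dataclass
class EdgeReplication:
    replicated: set[frozenset]
    missing: set[frozenset]
    fraction: float

    def replicated_pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.replicated)

    def missing_pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.missing)


def replicated_edges(genetic: nx.Graph, reference: nx.Graph) -> EdgeReplication:
    """Which reference edges the genetic graph reproduces.

    An edge is replicated iff present in both graphs (as an unordered pair);
    the fraction is |replicated| / |reference edges|, 0 when the reference is
    edgeless.
    """
    if set(genetic.nodes) != set(reference.nodes):
        raise ValueError("graphs must share the same node universe")
    ref = {frozenset(e) for e in reference.edges}
    gen = {frozenset(e) for e in genetic.edges}
    rep = ref & gen
    return EdgeReplication(
        replicated=rep,
        missing=ref - gen,
        fraction=(len(rep) / len(ref)) if ref else 0.0,
    )


# --------------------------------------------------------------------------
# serialization

def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT serialization (nodes with size_fraction, weighted edges)."""
    lines = ["graph phenotypes {"]
    for n, data in graph.nodes(data=True):
        attrs = ", ".join(f'{k}="{v}"' for k, v in data.items())
        lines.append(f'  "{n}" [{attrs}];' if attrs else f'  "{n}";')
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1)
        lines.append(f'  "{a}" -- "{b}" [weight="{w}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def graph_summary(
    genetic: nx.Graph, reference: nx.Graph | None = None
) -> dict:
    """JSON-ready summary: nodes with fractions, edges with weights, and the
    replication report when a reference graph is given."""
    out = {
        "nodes": [
            {"phenotype": n, "size_fraction": data.get("size_fraction", 0.0)}
            for n, data in genetic.nodes(data=True)
        ],
        "edges": [
            {"phenotypes": sorted((a, b)), "weight": data.get("weight", 1)}
            for a, b, data in genetic.edges(data=True)
        ],
    }
    if reference is not None:
        rep = replicated_edges(genetic, reference)
        out["replication"] = {
            "replicated": [list(e) for e in rep.replicated_pairs()],
            "missing": [list(e) for e in rep.missing_pairs()],
            "fraction": rep.fraction,
        }
    return out


def plot_network(graph: nx.Graph, ax=None, seed: int = 7):
    """Render the bubble chart: node area tracks size_fraction, edge width
    tracks intersection count.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.circular_layout(graph)
    fracs = [graph.nodes[n].get("size_fraction", 1 / max(len(graph), 1)) for n in graph]
    sizes = [300 + 12_000 * f for f in fracs]
    widths = [graph.edges[e].get("weight", 1) for e in graph.edges]
    nx.draw_networkx_nodes(graph, pos, node_size=sizes, node_color="#76a5d4", ax=ax)
    nx.draw_networkx_labels(graph, pos, ax=ax)
    if widths:
        nx.draw_networkx_edges(graph, pos, width=widths, alpha=0.6, ax=ax)
    ax.set_axis_off()
    return ax
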