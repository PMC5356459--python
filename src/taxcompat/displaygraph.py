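"""The display graph of a fully labeled profile.

Gluing the input trees at shared labels yields an undirected graph on the
label universe: vertices are labels (one per label, since trees are fully
and singularly labeled) and there is an edge between two labels whenever
one is the parent of the other in some input tree.  Parallel edges are
merged.  The graph has at most M_P vertices plus edges, where M_P is the
total number of nodes and edges in the profile.

Connected components of the display graph correspond to label-disjoint
sub-profiles that can be solved independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .sltree import Profile, TreeError


@dataclass
class DisplayGraph:
    """Undirected graph on labels plus per-label tree multiplicities k_l."""

    graph: nx.Graph
    multiplicity: dict[str, int]

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors(self, label: str) -> set[str]:
        return set(self.graph[label])

    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_display_graph(profile: Profile) -> DisplayGraph:
    """Glue the trees of a fully and singularly labeled profile at shared labels.

    Also counts, per label, the number of input trees containing it (k_l);
    a label is semi-universal in a position exactly when its singleton
    frontier count reaches k_l.
    """
    g = nx.Graph()
    mult: dict[str, int] = {}
    for idx, t in enumerate(profile.trees):
        seen: set[str] = set()
        for u, ch in t.children.items():
            labs = t.labels_of[u]
            if not labs:
                raise TreeError(
                    f"tree {idx}: node {u} is unlabeled; apply "
                    "add_distinct_labels before building the display graph")
            if len(labs) > 1:
                raise TreeError(f"tree {idx}: node {u} has multiple labels; "
                                "input trees must be singularly labeled")
            (lab,) = labs
            if lab in seen:
                raise TreeError(f"tree {idx}: label {lab!r} on two nodes")
            seen.add(lab)
        for lab in seen:
            mult[lab] = mult.get(lab, 0) + 1
            g.add_node(lab)
        for u, ch in t.children.items():
            (pl,) = t.labels_of[u]
            for c in ch:
                (cl,) = t.labels_of[c]
                g.add_edge(pl, cl)
    return DisplayGraph(graph=g, multiplicity=mult)


def static_components(graph: DisplayGraph) -> list[frozenset[str]]:
    """Partition of the label set into connected components."""
    return [frozenset(c) for c in nx.connected_components(graph.graph)]


def edge_list_text(graph: DisplayGraph) -> str:
    """Debug export: one edge per line, endpoints sorted."""
    lines = sorted(
        "\t".join(sorted((u, v))) for u, v in graph.graph.edges
    )
    return "\n".join(lines) + ("\n" if lines else "")
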