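"""Candidate physical-interaction subnetwork extraction.

A candidate gene is retained when its product physically interacts with
at least one other candidate's product either directly or through at
most one bridging node (a non-candidate adjacent to both).  Paths with
two or more intermediates never qualify.  Edge weights are ignored for
retention (the criterion is purely topological) but carried through for
display.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .datatypes import InteractionGraph

__all__ = ["CandidateSubnetwork", "extract_candidate_subnetwork"]


@dataclass
class CandidateSubnetwork:
    """Retained candidates, their bridges, and the induced edges."""

    candidates: set[str]
    bridges: set[str]
    edges: list[tuple[str, str, float]]

    @property
    def n_connected_candidates(self) -> int:
        return len(self.candidates)


def _to_networkx(graph: InteractionGraph) -> nx.Graph:
    g = nx.Graph()
    for a, b, w in graph.edges():
        g.add_edge(a, b, weight=w)
    return g


def extract_candidate_subnetwork(candidates: set[str],
                                 graph: InteractionGraph) -> CandidateSubnetwork:
    """Apply the one-bridge retention rule.

    Candidate u is retained iff some candidate v != u is a direct
    neighbor, or some non-candidate b is adjacent to both u and a
    candidate v != u.  Bridges are the non-candidates that mediate at
    least one retained pair; the output keeps every edge among retained
    nodes (candidate or bridge).
    """
    candidates = set(candidates)
    g = _to_networkx(graph)
    present = candidates & set(g.nodes)

    retained: set[str] = set()
    bridges: set[str] = set()
    for u in present:
        nbrs = set(g.neighbors(u))
        if nbrs & (candidates - {u}):
            retained.add(u)
            continue
        for b in nbrs - candidates:
            if set(g.neighbors(b)) & (candidates - {u}):
                retained.add(u)
                break
    for u in retained:
        for b in set(g.neighbors(u)) - candidates:
            partners = set(g.neighbors(b)) & (retained - {u})
            if partners:
                bridges.add(b)

    kept_nodes = retained | bridges
    edges = [(a, b, w) for a, b, w in graph.edges() if a in kept_nodes and b in kept_nodes]
    return CandidateSubnetwork(candidates=retained, bridges=bridges, edges=edges)
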