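"""Raw rating networks, rule-derived networks, and SNA metrics.

The raw network is a directed graph with one arc per roster rating
(rater -> ratee, weight 1-5). A derived network applies a tie rule to every
unordered within-network dyad, yielding an undirected graph (the rule's
reciprocity and dichotomization make ties symmetric); isolates are kept so
that node sets stay comparable across rules. Per-edge explanation traces are
stored with the graph.

Metrics are the standard unweighted ones: degree (in/out on the raw
directed graph), betweenness and closeness centrality (shortest-path based,
normalized; an isolate's closeness is 0 by convention), connected
components, density and the raw-arc reciprocity rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .definitions import Explanation, TieRule, evaluate_tie
from .errors import ValidationError
from .questionnaire import ResponseSet

logger = logging.getLogger(__name__)

#: How to treat an unanswered roster item for a within-classroom dyad:
#: "floor"  — score it as weight 1 ("We never spend time together"),
#: "strict" — treat that direction as absent (fails reciprocity).
MISSING_POLICIES = ("floor", "strict")


def build_raw_network(
    responses: ResponseSet, classroom: str | None = None
) -> nx.DiGraph:
    """Directed weighted rating network mirroring the DyadRatings one-to-one.

    ``classroom`` restricts to one classroom; by default the whole study is
    included (classroom membership is a node attribute either way).
    """
    g = nx.DiGraph(kind="raw", classroom=classroom)
    for ind in responses.individuals.values():
        if classroom is not None and ind.classroom_id != classroom:
            continue
        g.add_node(ind.id, gender=ind.gender, classroom=ind.classroom_id)
    for (rater, ratee), rating in responses.ratings.items():
        if rater in g and ratee in g:
            g.add_edge(rater, ratee, weight=rating.weight)
    return g


def derive_network(
    raw: nx.DiGraph, rule: TieRule, missing_policy: str = "floor"
) -> nx.Graph:
    """Apply a tie rule to every unordered dyad of the raw network.

    An undirected edge {a, b} exists iff ``evaluate_tie(rule, w(a->b),
    w(b->a))`` is true. Dyads crossing classrooms are only evaluated when the
    raw network actually contains cross-classroom arcs. Under the default
    ``"floor"`` policy an unanswered direction of a within-classroom dyad is
    scored as weight 1 (the scale's "never spend time together" floor);
    ``"strict"`` leaves it absent. The node set (isolates included) equals
    the raw node set; the rule and per-edge explanations are stored on the
    graph (``g.graph["tie_rule"]``, ``g.graph["explanations"]``).
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValidationError(f"missing_policy must be one of {MISSING_POLICIES}")
    derived = nx.Graph(kind="derived", rule_name=rule.name)
    derived.graph["tie_rule"] = rule
    explanations: dict[tuple[str, str], Explanation] = {}
    derived.graph["explanations"] = explanations
    derived.add_nodes_from(raw.nodes(data=True))

    cross_ok = any(
        raw.nodes[u]["classroom"] != raw.nodes[v]["classroom"] for u, v in raw.edges
    )
    missing_filled = 0
    nodes = sorted(raw.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            same_room = raw.nodes[a]["classroom"] == raw.nodes[b]["classroom"]
            if not same_room and not cross_ok:
                continue
            w_ab = raw.edges[a, b]["weight"] if raw.has_edge(a, b) else None
            w_ba = raw.edges[b, a]["weight"] if raw.has_edge(b, a) else None
            if missing_policy == "floor" and same_room:
                if w_ab is None:
                    w_ab, missing_filled = 1, missing_filled + 1
                if w_ba is None:
                    w_ba, missing_filled = 1, missing_filled + 1
            verdict, expl = evaluate_tie(rule, w_ab, w_ba, subject=(a, b))
            if verdict:
                derived.add_edge(a, b, weight=rule.edge_weight(w_ab, w_ba))
                explanations[(a, b)] = expl
    if missing_filled:
        logger.warning(
            "rule %r: %d unanswered roster directions scored as weight 1",
            rule.name,
            missing_filled,
        )
    return derived


@dataclass
class MetricTable:
    """Per-node metrics as a DataFrame (index: node id) plus graph-level stats."""

    nodes: pd.DataFrame
    graph: dict[str, float]

    def to_csv(self, path: str | Path) -> None:
        self.nodes.to_csv(path, index_label="id")

    def node_metrics(self, node: str) -> dict[str, float]:
        return self.nodes.loc[node].to_dict()


def _reciprocity_rate(g: nx.DiGraph) -> float:
    """Fraction of directed arcs whose reverse arc also exists (1.0 if no arcs)."""
    if g.number_of_edges() == 0:
        return 1.0
    mutual = sum(1 for u, v in g.edges if g.has_edge(v, u))
    return mutual / g.number_of_edges()


def compute_metrics(net: nx.Graph | nx.DiGraph) -> MetricTable:
    """Standard node- and graph-level SNA measures.

    Betweenness and closeness use unweighted shortest paths with the usual
    normalizations (closeness is scaled by the reachable fraction, so an
    isolate scores 0). On a directed raw network in/out-degree are the arc
    counts and components are weak components; on an undirected derived
    network in_degree and out_degree are reported equal to the undirected
    degree (every tie is mutual by construction).
    """
    directed = net.is_directed()
    n = net.number_of_nodes()
    und = net.to_undirected(as_view=False) if directed else net
    comps = sorted(nx.connected_components(und), key=lambda c: (-len(c), min(c)))
    comp_id = {node: i for i, comp in enumerate(comps) for node in comp}

    betweenness = nx.betweenness_centrality(net, normalized=True)
    closeness = nx.closeness_centrality(net, wf_improved=True)

    rows = {}
    for node in net.nodes:
        deg = und.degree(node)
        rows[node] = {
            "in_degree": net.in_degree(node) if directed else deg,
            "out_degree": net.out_degree(node) if directed else deg,
            "degree": deg,
            "betweenness": betweenness[node],
            "closeness": closeness[node],
            "component": comp_id[node],
        }
    nodes_df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    nodes_df.index.name = "id"

    m = net.number_of_edges()
    graph_stats = {
        "n_nodes": n,
        "n_edges": m,
        "density": nx.density(net) if n > 1 else 0.0,
        "reciprocity": _reciprocity_rate(net) if directed else 1.0,
        "n_components": len(comps),
    }
    return MetricTable(nodes=nodes_df, graph=graph_stats)


# ---------------------------------------------------------------------------
# exports


def _scalar_attrs(data: dict) -> dict:
    return {k: v for k, v in data.items() if isinstance(v, (str, int, float, bool))}


def _exportable(net: nx.Graph) -> nx.Graph:
    """Copy with only scalar attributes (GraphML/GEXF cannot carry objects)."""
    g = net.__class__()
    g.graph.update(_scalar_attrs(net.graph))
    for node, data in net.nodes(data=True):
        g.add_node(node, **_scalar_attrs(data))
    for u, v, data in net.edges(data=True):
        g.add_edge(u, v, **_scalar_attrs(data))
    return g


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(_exportable(net), path)


def write_gexf(net: nx.Graph, path: str | Path) -> None:
    nx.write_gexf(_exportable(net), path)


def write_edgelist_csv(net: nx.Graph, path: str | Path) -> None:
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1)}
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)
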