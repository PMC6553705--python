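"""Weekly communication networks and per-node structural features.

Calls and texts are pooled into one undirected, unweighted graph per week.
An edge between two ids is admitted at all only if the pair communicated at
least ``edge_min_events`` times over the whole study window (the spam /
spurious-connection filter, applied globally); it is then present in week *w*
iff the pair has at least one event that week.  Two variants are built:

* **whole** — all ids (participants and external contacts active that week);
* **participant** — restricted to the enrolled roster; isolated roster
  members remain as degree-0 nodes so every participant-week has a feature
  vector.

Per node and week, five structural features are computed: degree, number of
triangles, local clustering coefficient, betweenness centrality (normalized
by (n-1)(n-2)/2) and Wasserman–Faust component-scaled closeness centrality.
Weekly graphs are typically disconnected; the scaled centrality variants keep
all features in [0, 1].
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .data_model import CommEvent, StudyConfig, assign_week

logger = logging.getLogger("netwell")

STRUCTURE_METRICS = ("degree", "triangles", "clustering", "betweenness", "closeness")
NETWORK_VARIANTS = ("participant", "whole")


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical undirected pair key: lexicographically ordered, never a loop."""
    if a == b:
        raise ValueError(f"self-loop edge ({a!r}, {b!r})")
    return (a, b) if a < b else (b, a)


@dataclasses.dataclass(frozen=True)
class NodeStructuralFeatures:
    degree: int
    triangles: int
    clustering: float
    betweenness: float
    closeness: float


def filter_spurious_edges(
    events: Iterable[CommEvent], min_events: int
) -> set[tuple[str, str]]:
    """Pairs whose total event count (both channels, both directions, whole
    window) reaches ``min_events``; pairs below the threshold are dropped."""
    counts: dict[tuple[str, str], int] = {}
    for e in events:
        k = edge_key(e.source, e.target)
        counts[k] = counts.get(k, 0) + 1
    retained = {k for k, c in counts.items() if c >= min_events}
    logger.info(
        "edge filter: retained %d of %d pairs (min_events=%d)",
        len(retained), len(counts), min_events,
    )
    return retained


def build_weekly_graphs(
    events: Sequence[CommEvent],
    retained: set[tuple[str, str]],
    variant: str,
    config: StudyConfig,
) -> dict[int, nx.Graph]:
    """One undirected, unweighted graph per week from the retained pairs.

    ``variant='participant'`` keeps only edges with both endpoints on the
    roster and uses the roster as the node set; ``variant='whole'`` also
    includes external ids active (incident to an edge) that week.
    """
    if variant not in NETWORK_VARIANTS:
        raise ValueError(f"unknown network variant {variant!r}")
    roster = config.roster
    weekly_edges: dict[int, set[tuple[str, str]]] = {w: set() for w in range(config.n_weeks)}
    n_late = 0
    for e in events:
        w = assign_week(e.timestamp, config)
        if w >= config.n_weeks:
            n_late += 1
            continue
        k = edge_key(e.source, e.target)
        if k not in retained:
            continue
        if variant == "participant" and not (k[0] in roster and k[1] in roster):
            continue
        weekly_edges[w].add(k)
    if n_late:
        logger.warning("build_weekly_graphs: ignored %d event(s) past week %d",
                       n_late, config.n_weeks - 1)

    graphs: dict[int, nx.Graph] = {}
    for w in range(config.n_weeks):
        g = nx.Graph(week=w, variant=variant)
        g.add_nodes_from(roster)
        g.add_edges_from(weekly_edges[w])
        graphs[w] = g
    return graphs


def node_structural_features(graph: nx.Graph, node: str) -> NodeStructuralFeatures:
    """The five structural features of one node (see module docstring)."""
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    deg = graph.degree(node)
    tri = nx.triangles(graph, node)
    clus = nx.clustering(graph, node)
    betw = nx.betweenness_centrality(graph, normalized=True)[node]
    clos = nx.closeness_centrality(graph, wf_improved=True)[node]
    return NodeStructuralFeatures(int(deg), int(tri), float(clus), float(betw), float(clos))


def _graph_feature_frame(graph: nx.Graph, nodes: Iterable[str]) -> pd.DataFrame:
    nodes = list(nodes)
    tri = nx.triangles(graph)
    clus = nx.clustering(graph)
    betw = nx.betweenness_centrality(graph, normalized=True)
    clos = nx.closeness_centrality(graph, wf_improved=True)
    return pd.DataFrame(
        {
            "participant": nodes,
            "degree": [graph.degree(n) for n in nodes],
            "triangles": [tri[n] for n in nodes],
            "clustering": [clus[n] for n in nodes],
            "betweenness": [betw[n] for n in nodes],
            "closeness": [clos[n] for n in nodes],
        }
    )


def structural_feature_table(
    events: Sequence[CommEvent], config: StudyConfig
) -> pd.DataFrame:
    """Long table of the five features for every roster member, week and
    variant: columns (participant, week, variant, degree, triangles,
    clustering, betweenness, closeness)."""
    retained = filter_spurious_edges(events, config.edge_min_events)
    frames = []
    for variant in NETWORK_VARIANTS:
        graphs = build_weekly_graphs(events, retained, variant, config)
        for w, g in graphs.items():
            df = _graph_feature_frame(g, sorted(config.roster))
            df.insert(1, "week", w)
            df.insert(2, "variant", variant)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def structure_wide(features: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long feature table to one row per participant-week with the
    10 structure columns ``{metric}_{variant}``."""
    wide = features.pivot_table(
        index=["participant", "week"],
        columns="variant",
        values=list(STRUCTURE_METRICS),
        aggfunc="first",
    )
    wide.columns = [f"{metric}_{variant}" for metric, variant in wide.columns]
    return wide.reset_index()


def write_edge_lists(graphs: Mapping[int, nx.Graph], path) -> None:
    """Weekly edges as TSV (week, a, b)."""
    rows = [
        {"week": w, "a": a, "b": b}
        for w, g in sorted(graphs.items())
        for a, b in sorted(g.edges())
    ]
    pd.DataFrame(rows, columns=["week", "a", "b"]).to_csv(path, sep="\t", index=False)


def write_graphml(graphs: Mapping[int, nx.Graph], directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for w, g in graphs.items():
        nx.write_graphml(g, directory / f"week{w:02d}_{g.graph['variant']}.graphml")
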