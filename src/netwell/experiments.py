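"""Reusable validation experiments: brute-force oracles and seeded
Monte-Carlo studies of the synthetic cohort.

These back both the test suite and the reproduction script; each experiment
is deterministic given the seeds it is handed.
"""

from __future__ import annotations

import itertools
from collections import deque
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .behavior_features import weekly_behavior_table
from .correlation_analysis import cohort_pair_matrix, count_pairs, high_low_tests
from .network_builder import (
    filter_spurious_edges,
    structural_feature_table,
    structure_wide,
)
from .synthetic_cohort import GeneratorConfig, generate_cohort, generate_comm_log, generate_daily_table
from .wellness_prediction import run_prediction
from .data_model import survey_frame


# ---------------------------------------------------------------------------
# brute-force graph-metric oracle
# ---------------------------------------------------------------------------

def brute_force_features(edges: Sequence[tuple], nodes: Sequence) -> dict:
    """Exhaustive-enumeration structural features for every node of a small
    undirected graph, independent of any graph library.

    Degree and triangles by direct counting; betweenness by enumerating all
    shortest paths with breadth-first search from every source (normalized by
    (n-1)(n-2)/2); closeness in the component-scaled Wasserman–Faust form
    ((r-1)/(n-1)) * ((r-1)/sum of distances), 0 for isolated nodes.
    """
    nodes = list(nodes)
    n = len(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    # all-pairs shortest-path distances and path counts via BFS
    dist = {v: {} for v in nodes}
    sigma = {v: {} for v in nodes}
    for s in nodes:
        dist[s][s] = 0
        sigma[s][s] = 1
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist[s]:
                    dist[s][w] = dist[s][u] + 1
                    sigma[s][w] = 0
                    queue.append(w)
                if dist[s][w] == dist[s][u] + 1:
                    sigma[s][w] += sigma[s][u]

    out = {}
    for v in nodes:
        deg = len(adj[v])
        tri = sum(
            1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]
        )
        clus = 2.0 * tri / (deg * (deg - 1)) if deg >= 2 else 0.0

        betw = 0.0
        for s, t in itertools.combinations(nodes, 2):
            if s == v or t == v or t not in dist[s]:
                continue
            if v in dist[s] and t in dist[v] and dist[s][v] + dist[v][t] == dist[s][t]:
                betw += sigma[s][v] * sigma[v][t] / sigma[s][t]
        if n > 2:
            betw /= (n - 1) * (n - 2) / 2.0

        reach = dist[v]  # includes v itself
        r = len(reach)
        total = sum(reach.values())
        clos = 0.0
        if r > 1 and total > 0:
            clos = ((r - 1) / (n - 1)) * ((r - 1) / total)
        out[v] = {
            "degree": deg,
            "triangles": tri,
            "clustering": clus,
            "betweenness": betw,
            "closeness": clos,
        }
    return out


def random_graph(n_nodes: int, rng: np.random.Generator) -> tuple[list, list]:
    nodes = list(range(n_nodes))
    p = rng.uniform(0.15, 0.7)
    edges = [e for e in itertools.combinations(nodes, 2) if rng.random() < p]
    return nodes, edges


def graph_oracle_max_error(n_trials: int = 200, max_nodes: int = 8, seed: int = 0) -> float:
    """Largest absolute disagreement between the production graph metrics and
    the brute-force oracle over random graphs (integers must agree exactly)."""
    from .network_builder import node_structural_features

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        nodes, edges = random_graph(int(rng.integers(2, max_nodes + 1)), rng)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        expected = brute_force_features(edges, nodes)
        for v in nodes:
            got = node_structural_features(g, v)
            if got.degree != expected[v]["degree"] or got.triangles != expected[v]["triangles"]:
                return float("inf")
            worst = max(
                worst,
                abs(got.clustering - expected[v]["clustering"]),
                abs(got.betweenness - expected[v]["betweenness"]),
                abs(got.closeness - expected[v]["closeness"]),
            )
    return worst


# ---------------------------------------------------------------------------
# synthetic-study runners
# ---------------------------------------------------------------------------

def synthetic_feature_table(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a study and build the merged participant-week feature table."""
    study = config.study_config()
    profiles, surveys = generate_cohort(config)
    events = generate_comm_log(profiles, config)
    daily = generate_daily_table(profiles, config)
    weekly = weekly_behavior_table(daily, study)
    structure = structure_wide(structural_feature_table(events, study))
    table = weekly.merge(structure, on=["participant", "week"], how="outer")
    return table.merge(survey_frame(surveys), on="participant", how="left")


def correlation_recovery(
    seeds: Sequence[int], coupling_rho: float, **config_kwargs
) -> pd.DataFrame:
    """Per seed: the cohort degree–steps correlation (participant network)
    and the number of the 60 pairs with |r| >= 0.5."""
    rows = []
    for seed in seeds:
        config = GeneratorConfig(seed=int(seed), coupling_rho=coupling_rho, **config_kwargs)
        matrix = cohort_pair_matrix(synthetic_feature_table(config))
        deg_steps = matrix.loc[
            (matrix["structure_feature"] == "degree_participant")
            & (matrix["behavior_feature"] == "steps_mean"),
            "r",
        ].iloc[0]
        rows.append(
            {
                "seed": int(seed),
                "degree_steps_r": float(deg_steps),
                "n_pairs_ge_0.5": count_pairs(matrix, 0.5),
            }
        )
    return pd.DataFrame(rows)


def null_fdr_experiment(seeds: Sequence[int], **config_kwargs) -> pd.DataFrame:
    """Fraction of the 60 high/low tests called significant (BH, alpha=0.05)
    per seed under the fully-null generator (no coupling, no label effects)."""
    rows = []
    for seed in seeds:
        config = GeneratorConfig(
            seed=int(seed),
            coupling_rho=0.0,
            label_beta_behavior=0.0,
            label_beta_network=0.0,
            **config_kwargs,
        )
        tests = high_low_tests(synthetic_feature_table(config))
        n_sig = sum(t.significant for t in tests)
        rows.append({"seed": int(seed), "n_tests": len(tests),
                     "fraction_significant": n_sig / len(tests) if tests else 0.0})
    return pd.DataFrame(rows)


def headline_experiment(
    seeds: Sequence[int],
    label_beta_network: float,
    attribute: str = "stress",
    grid: str = "none",
    **config_kwargs,
) -> pd.DataFrame:
    """Per seed: ensemble macro F1 with baseline (gender+behavior) features vs
    full features, on the default synthetic study."""
    rows = []
    for seed in seeds:
        config = GeneratorConfig(
            seed=int(seed), label_beta_network=label_beta_network, **config_kwargs
        )
        table = synthetic_feature_table(config)
        f1 = {}
        for fs in ("baseline", "full"):
            res = run_prediction(table, attribute, fs, seed=int(seed), grid=grid)
            f1[fs] = res.report.overall
        rows.append({"seed": int(seed), "f1_baseline": f1["baseline"], "f1_full": f1["full"]})
    return pd.DataFrame(rows)


def spurious_filter_counts(events, min_events: int = 3) -> dict:
    """Pair totals and the retained set, for bookkeeping checks."""
    retained = filter_spurious_edges(events, min_events)
    return {"retained": retained}
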