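"""PPI subnetwork assembly, differential overlays and enrichment.

The graph is the subgraph of a scored edge list induced on the analysis
proteins (typically LDA descriptors union differentially expressed
proteins), with the score filter applied and self-loops, duplicate pairs and
isolated nodes removed.  Subnetwork memberships are user-supplied functional
annotations; enrichment of a candidate set in each subnetwork is tested with
the exact upper-tail hypergeometric probability, Benjamini-Hochberg
corrected across subnetworks.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError
from .io import dedupe_edges
from .stats import hypergeom_tail

log = logging.getLogger(__name__)

__all__ = ["build_graph", "overlay_differential", "subnetwork_enrichment", "SCORE_MIN"]

SCORE_MIN = 0.15


def build_graph(
    edges: pd.DataFrame,
    node_set: Iterable[str] | None = None,
    score_min: float = SCORE_MIN,
) -> nx.Graph:
    """Induced, score-filtered PPI graph.

    Keeps edges with combined_score > score_min whose endpoints both lie in
    ``node_set`` (all edge-list nodes if None); drops self-loops, duplicate
    unordered pairs (max score kept) and isolated nodes.  An empty result is
    returned as an empty graph with ``graph['status'] == 'empty'``, not an
    exception.
    """
    clean = dedupe_edges(edges.copy(), score_min=score_min)
    if node_set is not None:
        nodes = set(node_set)
        clean = clean[
            clean["protein_a"].isin(nodes) & clean["protein_b"].isin(nodes)
        ]
    graph: nx.Graph = nx.Graph()
    for row in clean.itertuples():
        graph.add_edge(row.protein_a, row.protein_b, combined_score=row.combined_score)
    graph.graph["status"] = "empty" if graph.number_of_nodes() == 0 else "ok"
    log.info(
        "build_graph: %d nodes, %d edges (score > %s)",
        graph.number_of_nodes(),
        graph.number_of_edges(),
        score_min,
    )
    return graph


def overlay_differential(
    graph: nx.Graph,
    differential_tables: Mapping[str, pd.DataFrame] | None = None,
    remodeling: pd.DataFrame | None = None,
    spc_star: pd.DataFrame | None = None,
    max_missing_fraction: float = 0.5,
) -> nx.Graph:
    """Annotate graph nodes with DAve per condition pair, remodeling class
    and SpC* per condition.

    ``differential_tables`` maps a pair label (e.g. 'native_vs_preEVLP') to a
    differential table indexed like the graph's node identifiers.  Nodes
    absent from every table are annotated ``no_data``.  If more than
    ``max_missing_fraction`` of graph nodes are missing from all overlays a
    hard error suggests an identifier mapping table.
    """
    nodes = list(graph.nodes)
    if not nodes:
        return graph
    covered: set[str] = set()
    for pair, table in (differential_tables or {}).items():
        for node in nodes:
            if node in table.index:
                graph.nodes[node][f"dave_{pair}"] = float(table.at[node, "dave"])
                covered.add(node)
    if remodeling is not None:
        for node in nodes:
            if node in remodeling.index:
                graph.nodes[node]["remodel_class"] = str(
                    remodeling.at[node, "remodel_class"]
                )
                covered.add(node)
    if spc_star is not None:
        for node in nodes:
            if node in spc_star.index:
                for cond in spc_star.columns:
                    graph.nodes[node][f"spc_star_{cond}"] = float(
                        spc_star.at[node, cond]
                    )
                covered.add(node)
    any_overlay = differential_tables or remodeling is not None or spc_star is not None
    if any_overlay:
        missing = [n for n in nodes if n not in covered]
        if len(missing) > max_missing_fraction * len(nodes):
            raise ValidationError(
                f"{len(missing)}/{len(nodes)} graph nodes missing from every "
                "overlay table; the node identifier spaces probably differ — "
                "supply an accession-to-symbol mapping table"
            )
        for node in missing:
            graph.nodes[node]["no_data"] = True
    return graph


def subnetwork_enrichment(
    universe: Iterable[str] | nx.Graph,
    memberships: pd.DataFrame | Mapping[str, Iterable[str]],
    candidate_set: Iterable[str],
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a candidate set in each subnetwork.

    ``universe`` is the analysis graph (its nodes) or an explicit node set;
    ``memberships`` is either a frame with columns (node, subnetwork) or a
    mapping subnetwork -> member nodes (many-to-many allowed).  Candidates
    outside the universe are trimmed with a warning.  Returns one row per
    subnetwork with overlap k, subnetwork size m, candidate total n, universe
    N, hypergeometric p and Benjamini-Hochberg q; enriched = q <= q_max.
    """
    nodes = set(universe.nodes) if isinstance(universe, nx.Graph) else set(universe)
    if isinstance(memberships, pd.DataFrame):
        mapping: dict[str, set] = {
            str(sub): set(group["node"])
            for sub, group in memberships.groupby("subnetwork")
        }
    else:
        mapping = {str(sub): set(members) for sub, members in memberships.items()}
    candidates = set(candidate_set)
    outside = candidates - nodes
    if outside:
        log.warning(
            "%d candidate proteins outside the universe were trimmed", len(outside)
        )
        candidates &= nodes
    N = len(nodes)
    n = len(candidates)
    rows = []
    for sub in sorted(mapping):
        members = mapping[sub] & nodes
        m = len(members)
        k = len(members & candidates)
        p = 1.0 if n == 0 or m == 0 else hypergeom_tail(k, m, n, N)
        rows.append({"subnetwork": sub, "k": k, "m": m, "n": n, "N": N, "p": p})
    result = pd.DataFrame(rows).set_index("subnetwork")
    if len(result):
        result["q"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    else:
        result["q"] = []
    result["enriched"] = result["q"] <= q_max
    return result
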