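"""Disease subnetwork assembly and hub statistics.

A disease subnetwork is the induced subgraph of seed proteins over a
physical-interaction edge database, optionally expanded by the
highest-degree database neighbors.  Bait interactome edges from an IAP-MS
experiment can be merged on top (edge provenance is tracked per edge in a
``sources`` set, so a pair supported by both the database and the pulldown
keeps a single edge with both tags).  Hubs are ranked by degree D and exact
shortest-path betweenness centrality C_B normalized by (n−1)(n−2)/2, the
convention under which a star center scores 1.

Gene symbols are uppercased for matching throughout: the seed lists come
from human genetics while the proteins are mouse, and symbol case is the
only systematic difference.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GeneSetCollection
from .enrich import hypergeom_enrich

__all__ = [
    "normalize_symbol",
    "build_subnetwork",
    "merge_interactome",
    "centrality",
    "hub_prediction",
]


def normalize_symbol(s: str) -> str:
    return str(s).strip().upper()


def build_subnetwork(seeds: Iterable[str],
                     database_edges: Iterable[tuple[str, str]],
                     expansion_k: int = 0) -> nx.Graph:
    """Induced subgraph of the seed proteins over a physical-interaction database.

    ``expansion_k`` optionally adds up to that many non-seed database
    neighbors of the subnetwork, chosen by descending degree within the
    database (ties broken lexicographically).  Self-loops are dropped.
    Reports component structure in ``G.graph``: ``component_sizes`` and
    ``n_isolated_seeds``.
    """
    seed_set = {normalize_symbol(s) for s in seeds}
    if not seed_set:
        raise ValueError("seed list is empty")
    db = nx.Graph()
    for u, v in database_edges:
        u, v = normalize_symbol(u), normalize_symbol(v)
        if u != v:
            db.add_edge(u, v, sources={"database"})
    present = seed_set & set(db.nodes)
    if not present:
        raise ValueError("no seed appears in the interaction database")

    nodes = set(present)
    if expansion_k > 0:
        neighbors = set()
        for s in present:
            neighbors.update(db.neighbors(s))
        neighbors -= seed_set
        ranked = sorted(neighbors, key=lambda n: (-db.degree(n), n))
        nodes |= set(ranked[:expansion_k])

    g = nx.Graph(db.subgraph(nodes).copy())
    # seeds that never matched the database stay out of the graph; matched
    # seeds without retained partners appear as isolates
    g.add_nodes_from(present - set(g.nodes))
    for n in g.nodes:
        g.nodes[n]["is_seed"] = n in seed_set
    comp_sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    g.graph["component_sizes"] = comp_sizes
    g.graph["n_isolated_seeds"] = sum(1 for n in g.nodes
                                      if g.degree(n) == 0 and g.nodes[n]["is_seed"])
    return g


def merge_interactome(g: nx.Graph, bait: str, iap_partners: Iterable[str],
                      add_new_nodes: bool = True) -> nx.Graph:
    """Merge bait–partner pulldown edges into a subnetwork.

    The bait node is added if absent (flagged ``is_bait``).  Each partner
    gains an edge to the bait tagged ``iap``; partners not already in the
    graph are added only when ``add_new_nodes``.  An existing database edge
    for the same pair is kept as one edge with ``sources`` unioned.
    """
    out = g.copy()
    b = normalize_symbol(bait)
    if b not in out:
        out.add_node(b)
    out.nodes[b]["is_bait"] = True
    for p in {normalize_symbol(x) for x in iap_partners}:
        if p == b:
            continue
        if p not in out:
            if not add_new_nodes:
                continue
            out.add_node(p)
        if out.has_edge(b, p):
            out.edges[b, p].setdefault("sources", set()).add("iap")
        else:
            out.add_edge(b, p, sources={"iap"})
    return out


def centrality(g: nx.Graph) -> pd.DataFrame:
    """Degree and normalized betweenness centrality for every node.

    Betweenness is the exact Brandes accumulation over all shortest paths,
    normalized by (n−1)(n−2)/2 so values lie in [0, 1]; unreachable pairs
    in disconnected graphs contribute 0.  Ranks are 1-based, descending,
    with lexicographic tie-break on the node name.

    Columns: ``node, degree, betweenness, rank_by_degree,
    rank_by_betweenness``, sorted by ``rank_by_betweenness``.
    """
    if g.number_of_nodes() < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    bc = nx.betweenness_centrality(g, normalized=True)
    rows = pd.DataFrame(
        {
            "node": list(g.nodes),
            "degree": [g.degree(n) for n in g.nodes],
            "betweenness": [bc[n] for n in g.nodes],
        }
    )
    for col, rank_col in (("degree", "rank_by_degree"), ("betweenness", "rank_by_betweenness")):
        order = rows.sort_values([col, "node"], ascending=[False, True]).index
        ranks = pd.Series(np.arange(1, len(rows) + 1), index=order)
        rows[rank_col] = ranks
    return rows.sort_values("rank_by_betweenness", ignore_index=True)


def hub_prediction(locus_genes: Sequence[str],
                   coexpr_sets: GeneSetCollection,
                   subnetwork_proteins: Iterable[str],
                   universe: Iterable[str] | None = None,
                   annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Prioritize candidate subnetwork drivers among locus genes.

    For each locus gene, its brain co-expression set is tested for
    over-representation of subnetwork proteins (hypergeometric, over the
    declared universe).  Gene-level annotations (pLI constraint scores,
    disease flags, proteome Z-ratios) are attached verbatim — the
    combination of evidence is left qualitative, no composite score is
    computed.  Genes lacking a co-expression set get a flagged row rather
    than being dropped.  Rows are sorted by p (missing last).
    """
    raw_uni = set(universe) if universe is not None else coexpr_sets.universe
    uni = {normalize_symbol(g) for g in raw_uni}
    sub = {normalize_symbol(s) for s in subnetwork_proteins} & uni
    norm_sets = {normalize_symbol(name): {normalize_symbol(g) for g in members}
                 for name, members in coexpr_sets.sets.items()}
    rows = []
    for gene in locus_genes:
        row: dict = {"locus_gene": gene, "missing_coexpr_set": False}
        members = norm_sets.get(normalize_symbol(gene))
        if not members:
            row.update({"missing_coexpr_set": True, "coexpr_set_size": 0,
                        "overlap_with_subnetwork": np.nan, "fold": np.nan, "p": np.nan})
        else:
            r = hypergeom_enrich(members, sub, uni, set_name=gene)
            row.update({"coexpr_set_size": r.n_query, "overlap_with_subnetwork": r.k,
                        "fold": r.fold, "p": r.p})
        if annotations is not None:
            idx = gene if gene in annotations.index else normalize_symbol(gene)
            if idx in annotations.index:
                for col in annotations.columns:
                    row[col] = annotations.loc[idx, col]
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("p", na_position="last", ignore_index=True)
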