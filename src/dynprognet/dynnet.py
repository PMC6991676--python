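"""Dynamic interaction network: background merging, DL mapping, hubs.

The background is the union of several interaction edge tables (protein
interaction databases, regulatory edges, pathway-derived links).  Dynamic
differentially co-expressed links are mapped onto it — by default an edge
survives only if the same unordered pair is itself a background interaction
— and the surviving graph is analysed for hub genes by degree.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .iolib import EdgeTable, _canon

logger = logging.getLogger("dynprognet")


def merge_backgrounds(tables: list[EdgeTable]) -> EdgeTable:
    """Union of several edge tables; source tags concatenate per edge."""
    if not tables:
        raise ValueError("need at least one background table")
    out = EdgeTable()
    for t in tables:
        for (a, b), conf in t.edges.items():
            for tag in (t.sources[(a, b)] or [""]):
                out.add(a, b, conf, tag)
    if len(out) == 0:
        raise ValueError("merged background is empty")
    logger.info("merge_backgrounds: %d tables -> %d edges over %d nodes",
                len(tables), len(out), len(out.nodes()))
    return out


def map_dls_to_ppi(dl_table: pd.DataFrame, background: EdgeTable,
                   mode: str = "edges",
                   node_attrs: pd.DataFrame | None = None) -> nx.Graph:
    """Restrict dynamic DLs to the background interaction network.

    mode="edges": a DL becomes a network edge iff that unordered pair is a
    background edge (edge-intersection semantics).  mode="nodes": a DL is
    kept when both endpoints occur anywhere in the background.  Isolated
    nodes are dropped in both modes.

    ``node_attrs`` (index=gene) attaches per-gene attributes such as stage
    means and DEG flags to the surviving nodes.
    """
    if mode not in ("edges", "nodes"):
        raise ValueError("mode must be 'edges' or 'nodes'")
    sub = dl_table[dl_table["is_dynamic_dl"]]
    bg_nodes = background.nodes()
    g = nx.Graph()
    for row in sub.itertuples(index=False):
        a, b = _canon(row.geneA, row.geneB)
        if mode == "edges":
            keep = (a, b) in background
        else:
            keep = a in bg_nodes and b in bg_nodes
        if not keep:
            continue
        sources = "|".join(background.sources.get((a, b), []))
        g.add_edge(a, b, dpcc1=float(row.dpcc1), dpcc2=float(row.dpcc2),
                   sources=sources)
    if node_attrs is not None:
        for n in g.nodes():
            if n in node_attrs.index:
                for k, v in node_attrs.loc[n].items():
                    g.nodes[n][k] = v
    logger.info("map_dls_to_ppi(mode=%s): %d dynamic DLs -> %d network edges, "
                "%d nodes", mode, len(sub), g.number_of_edges(),
                g.number_of_nodes())
    return g


def shared_neighbour_score(background: EdgeTable, a: str, b: str
                           ) -> tuple[int, float] | None:
    """Common-neighbour count and Jaccard overlap of two genes' background
    neighbourhoods.

    Jaccard = |N(a) ∩ N(b)| / |N(a) ∪ N(b) minus {a, b}|.  Returns None
    when either gene is absent from the background.
    """
    nodes = background.nodes()
    if a not in nodes or b not in nodes:
        return None
    na: set[str] = set()
    nb: set[str] = set()
    for (u, v) in background.edges:
        if u == a:
            na.add(v)
        elif v == a:
            na.add(u)
        if u == b:
            nb.add(v)
        elif v == b:
            nb.add(u)
    inter = na & nb
    union = (na | nb) - {a, b}
    jac = len(inter) / len(union) if union else 0.0
    return len(inter), jac


def annotate_shared_neighbours(g: nx.Graph, background: EdgeTable) -> nx.Graph:
    """Attach shared-neighbour count and Jaccard to every edge of ``g``."""
    bg = background.to_graph()
    for a, b in g.edges():
        if a in bg and b in bg:
            na, nb = set(bg[a]), set(bg[b])
            inter = na & nb
            union = (na | nb) - {a, b}
            g.edges[a, b]["shared_neighbours"] = len(inter)
            g.edges[a, b]["shared_jaccard"] = (
                len(inter) / len(union) if union else 0.0)
        else:
            g.edges[a, b]["shared_neighbours"] = None
            g.edges[a, b]["shared_jaccard"] = None
    return g


def hub_ranking(g: nx.Graph, top_k: int | None = None,
                restrict_to: set[str] | None = None) -> pd.DataFrame:
    """Degree-ranked gene table, ties broken lexicographically.

    ``restrict_to`` limits the ranking to a node subset, e.g. the strict
    dynamic DEGs, as in the study's hub table.
    """
    nodes = [n for n in g.nodes()
             if restrict_to is None or n in restrict_to]
    rows = sorted(((n, g.degree(n)) for n in nodes),
                  key=lambda r: (-r[1], r[0]))
    if top_k is not None:
        rows = rows[:top_k]
    return pd.DataFrame(rows, columns=["gene", "degree"])


def network_gene_overlap(g1: nx.Graph, g2: nx.Graph) -> tuple[int, set[str]]:
    """Count and identity of genes shared by two networks' node sets."""
    shared = set(g1.nodes()) & set(g2.nodes())
    return len(shared), shared
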