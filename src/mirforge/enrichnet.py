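"""Hypergeometric GO/KEGG enrichment and miRNA-centric bipartite networks.

Enrichment is the classic over-representation test: for a term annotating
K of N background genes, observing k annotated genes among n targets has
upper-tail probability P(X >= k) with X ~ Hypergeometric(N, K, n).
Benjamini-Hochberg adjustment is applied within each ontology family.

Networks are bipartite miRNA-vs-gene (or term) graphs built on
``networkx``; hubs are ranked by degree with lexicographic tie-breaks.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


class EnrichmentError(ValueError):
    pass


def enrich_terms(
    targets: list[str] | set[str],
    background: list[str] | set[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Term-level over-representation of ``targets`` within ``background``.

    ``annotation`` needs columns gene, term_id, term_name, ontology.
    Only terms with at least one target gene are tested; BH q-values are
    computed within each ontology family.  Result is sorted by ascending
    p (ties by term_id).
    """
    target_set = set(targets)
    bg_set = set(background)
    stray = target_set - bg_set
    if stray:
        raise EnrichmentError(
            f"target genes absent from background: {sorted(stray)[:10]}")
    if not target_set:
        return pd.DataFrame(columns=["term_id", "term_name", "ontology",
                                     "k", "K", "n", "N", "p", "q"])
    ann = annotation[annotation["gene"].isin(bg_set)]
    N, n = len(bg_set), len(target_set)
    rows = []
    for (term_id, term_name, ontology), sub in ann.groupby(
            ["term_id", "term_name", "ontology"], sort=True):
        genes = set(sub["gene"])
        K = len(genes)
        k = len(genes & target_set)
        if k < 1:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term_id=term_id, term_name=term_name,
                         ontology=ontology, k=k, K=K, n=n, N=N,
                         p=min(p, 1.0)))
    out = pd.DataFrame(rows)
    if out.empty:
        out["p"] = []
        out["q"] = []
        return out
    out["q"] = 1.0
    for ont in out["ontology"].unique():
        mask = out["ontology"] == ont
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return (out.sort_values(["p", "term_id"], kind="mergesort")
               .reset_index(drop=True))


def build_bipartite_network(
    edges: list[tuple[str, str]],
    min_left_per_right: int = 1,
) -> nx.Graph:
    """Bipartite miRNA (left) vs gene/term (right) network.

    Duplicate pairs collapse to a single edge.  Right-hand nodes kept
    only when connected to at least ``min_left_per_right`` distinct
    miRNAs -- used for pathway networks restricted to pathways
    co-regulated by a minimum number of miRNAs.
    """
    g = nx.Graph()
    uniq = sorted(set(edges))
    lefts = sorted({a for a, _ in uniq})
    rights = sorted({b for _, b in uniq})
    g.add_nodes_from(lefts, bipartite=0)
    g.add_nodes_from(rights, bipartite=1)
    g.add_edges_from(uniq)
    if min_left_per_right > 1:
        drop = [r for r in rights if g.degree(r) < min_left_per_right]
        g.remove_nodes_from(drop)
        g.remove_nodes_from([l for l in lefts if g.degree(l) == 0])
    return g


def rank_hubs(network: nx.Graph, top_n: int) -> list[tuple[str, int]]:
    """miRNA-side nodes by descending degree, ties alphabetical."""
    if top_n <= 0:
        return []
    lefts = [n for n, d in network.nodes(data=True) if d.get("bipartite") == 0]
    ranked = sorted(lefts, key=lambda n: (-network.degree(n), n))
    return [(n, network.degree(n)) for n in ranked[:top_n]]


def network_to_edgelist(network: nx.Graph) -> pd.DataFrame:
    left = {n for n, d in network.nodes(data=True) if d.get("bipartite") == 0}
    rows = [{"mirna": a if a in left else b, "partner": b if a in left else a}
            for a, b in sorted(network.edges())]
    return pd.DataFrame(rows)
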