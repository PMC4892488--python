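"""Per-module graph export and differential betweenness centrality.

A module is turned into an undirected, unweighted graph by thresholding
the TOM (or adjacency) submatrix.  Betweenness centrality

    BC(v) = sum_{s != v != t} sigma_st(v) / sigma_st

counts, over every unordered pair of other nodes, the fraction of
shortest paths passing through v (unnormalized; disconnected pairs
contribute nothing).  Genes whose betweenness changes sharply between
the reference- and test-condition module graphs are candidate switch
points of the module's information flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import CoexpressionNetwork

__all__ = [
    "ModuleGraph",
    "build_module_graph",
    "density_threshold",
    "betweenness",
    "differential_bc",
    "write_graphml",
    "write_edge_list",
]


@dataclass
class ModuleGraph:
    """Undirected unweighted graph over a module's genes."""

    graph: nx.Graph
    source: str       # "tom" or "adjacency"
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_module_graph(
    network: CoexpressionNetwork,
    module_genes,
    source: str = "tom",
    threshold: float = 0.1,
) -> ModuleGraph:
    """Edge (i, j) iff the source matrix entry >= threshold; isolated nodes kept."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if source not in ("tom", "adjacency"):
        raise ValueError(f"source must be 'tom' or 'adjacency', got {source!r}")
    genes = list(module_genes)
    idx = network.index_of(genes)
    mat = network.tom if source == "tom" else network.adjacency
    sub = mat[np.ix_(idx, idx)]
    g = nx.Graph()
    g.add_nodes_from(genes)
    m = len(genes)
    for i in range(m):
        for j in range(i + 1, m):
            if sub[i, j] >= threshold:
                g.add_edge(genes[i], genes[j])
    return ModuleGraph(graph=g, source=source, threshold=float(threshold))


def density_threshold(
    network: CoexpressionNetwork,
    module_genes,
    source: str = "tom",
    max_density: float = 0.15,
) -> float:
    """Smallest threshold keeping edge density at or below ``max_density``.

    Computed from the module's off-diagonal values: the threshold is the
    smallest matrix entry such that edges-with-value >= it number at most
    ``max_density`` of all pairs.  Used as the default per-module export
    policy when no absolute threshold is configured.
    """
    genes = list(module_genes)
    idx = network.index_of(genes)
    mat = network.tom if source == "tom" else network.adjacency
    sub = mat[np.ix_(idx, idx)]
    iu = np.triu_indices(len(genes), k=1)
    vals = np.sort(sub[iu])[::-1]
    limit = int(np.floor(max_density * len(vals)))
    if limit <= 0:
        t = float(vals[0]) + 1e-12 if len(vals) else 0.5
    else:
        t = float(vals[limit - 1])
        # back off ties that would push density above the limit
        while limit < len(vals) and (vals >= t).sum() > limit:
            t = float(np.nextafter(t, 1.0))
    return float(min(max(t, np.nextafter(0, 1)), np.nextafter(1, 0)))


def betweenness(graph: ModuleGraph | nx.Graph) -> pd.Series:
    """Unnormalized betweenness, each unordered pair counted once."""
    g = graph.graph if isinstance(graph, ModuleGraph) else graph
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(bc, name="bc").sort_index()


def _ranks(values: pd.Series) -> pd.Series:
    """Rank 1 = highest value; ties broken by gene id (deterministic)."""
    order = sorted(values.index, key=lambda g: (-values[g], g))
    return pd.Series({g: r for r, g in enumerate(order, start=1)}, name="rank")


def differential_bc(ref_bc: pd.Series, test_bc: pd.Series) -> pd.DataFrame:
    """Cross-condition betweenness table sorted by |delta_bc| descending.

    Genes absent from one condition's module graph score 0 there and are
    flagged; delta_rank = rank_reference - rank_test (positive = the gene
    became relatively more central in the test condition).
    """
    genes = sorted(set(ref_bc.index) | set(test_bc.index))
    ref = ref_bc.reindex(genes)
    test = test_bc.reindex(genes)
    absent_ref = ref.isna()
    absent_test = test.isna()
    ref = ref.fillna(0.0)
    test = test.fillna(0.0)
    rank_ref = _ranks(ref)
    rank_test = _ranks(test)
    df = pd.DataFrame(
        {
            "bc_reference": ref,
            "bc_test": test,
            "rank_reference": rank_ref,
            "rank_test": rank_test,
            "delta_bc": test - ref,
            "delta_rank": rank_ref - rank_test,
            "absent_reference": absent_ref,
            "absent_test": absent_test,
        }
    )
    df = df.sort_values(
        by=["delta_bc"], key=lambda s: -s.abs(), kind="stable"
    )
    df = df.loc[sorted(df.index, key=lambda g: (-abs(df.loc[g, "delta_bc"]), g))]
    df.index.name = "gene_id"
    return df


def write_graphml(mg: ModuleGraph, path) -> None:
    g = mg.graph.copy()
    g.graph["source_matrix"] = mg.source
    g.graph["edge_threshold"] = mg.threshold
    nx.write_graphml(g, path)


def write_edge_list(mg: ModuleGraph, path) -> None:
    """Plain gene<TAB>gene pairs (VisANT-compatible)."""
    with open(path, "w") as fh:
        for u, v in sorted(mg.graph.edges()):
            fh.write(f"{u}\t{v}\n")
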