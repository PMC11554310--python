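"""All-by-all Spearman solubility-correlation networks.

Proteins whose solubility responds consistently to the same compounds —
complex subunits, paralogous kinases, shared off-targets — show correlated
fold-change profiles across a screen even when the individual changes are
too small to pass hit-calling cutoffs.  Rank-based (Spearman) correlation is
used to blunt the influence of the few very large thermal shifts.  Edges are
kept above an absolute-rho threshold (default 0.35, roughly the top 5% of
pair magnitudes at library scale) or by an explicit quantile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "KINOME_GROUPS",
    "build_profile_matrix",
    "comparison_count",
    "all_by_all_spearman",
    "filter_edges",
    "build_network",
    "extract_subgraph",
    "write_edge_list",
    "write_graphml",
]

#: Standard kinome group vocabulary plus the non-protein kinase class.
KINOME_GROUPS = (
    "AGC", "Atypical", "CAMK", "CK1", "CMGC", "STE", "TK", "TKL",
    "Other", "non-protein kinase",
)

DEFAULT_RHO_THRESHOLD = 0.35
DEFAULT_MIN_PAIRS = 10


def build_profile_matrix(log2fc: pd.DataFrame) -> pd.DataFrame:
    """Proteins x treatments matrix of replicate-averaged log2 fold changes.

    Vehicle pseudo-treatments are dropped; treatments are ordered
    deterministically (sorted).  Missing measurements stay missing.
    """
    tbl = log2fc[~log2fc["is_vehicle"].astype(bool)]
    mat = tbl.pivot_table(index="protein_id", columns="treatment_id",
                          values="log2fc", aggfunc="mean", dropna=False)
    return mat.sort_index(axis=0).sort_index(axis=1)


def comparison_count(n_proteins: int) -> int:
    """Total all-by-all comparison count, P^2 for P proteins.

    The convention counts self-pairs and both orders (the square of the
    protein count); the edge list itself stores each unordered pair once.
    """
    return int(n_proteins) * int(n_proteins)


def all_by_all_spearman(
    profile: pd.DataFrame, min_pairs: int = DEFAULT_MIN_PAIRS
) -> pd.DataFrame:
    """Spearman rho over pairwise-complete treatments for every protein pair.

    Ranks use average tie handling and are recomputed per pair over the
    treatments both proteins were measured in; pairs with fewer than
    ``min_pairs`` complete observations are dropped.  Returns an edge table
    (protein_a, protein_b, rho, n_pairs) for each unordered pair, with the
    total P^2 comparison count attached as ``.attrs['total_comparisons']``.
    """
    if min_pairs < 3:
        raise ValueError("min_pairs must be >= 3")
    if profile.shape[0] < 2:
        raise ValueError("need at least two proteins to correlate")
    corr = profile.T.corr(method="spearman", min_periods=min_pairs)
    present = (~profile.isna()).to_numpy().astype(np.int64)
    npairs = present @ present.T
    prot = profile.index.to_numpy()
    iu, ju = np.triu_indices(len(prot), k=1)
    rho = corr.to_numpy()[iu, ju]
    n = npairs[iu, ju]
    keep = ~np.isnan(rho) & (n >= min_pairs)
    edges = pd.DataFrame(
        {
            "protein_a": prot[iu][keep],
            "protein_b": prot[ju][keep],
            "rho": rho[keep],
            "n_pairs": n[keep].astype(int),
        }
    )
    edges.attrs["total_comparisons"] = comparison_count(len(prot))
    return edges


def filter_edges(
    edges: pd.DataFrame, mode: str = "threshold", value: float = DEFAULT_RHO_THRESHOLD
) -> pd.DataFrame:
    """Flag edges passing a magnitude filter.

    ``threshold`` keeps |rho| > value; ``quantile`` keeps the top ``value``
    fraction of edges by |rho| (ties broken deterministically by protein
    ids).  The returned copy carries ``passes_filter`` plus summary attrs:
    the kept fraction, and for quantile mode the implied threshold.
    """
    out = edges.copy()
    absr = out["rho"].abs()
    if mode == "threshold":
        out["passes_filter"] = absr > value
        out.attrs["kept_fraction"] = float(out["passes_filter"].mean()) if len(out) else 0.0
    elif mode == "quantile":
        if not 0.0 < value < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        k = int(round(value * len(out)))
        order = out.assign(_a=absr).sort_values(
            ["_a", "protein_a", "protein_b"], ascending=[False, True, True]
        ).index
        flag = pd.Series(False, index=out.index)
        flag.loc[order[:k]] = True
        out["passes_filter"] = flag
        kept = absr[flag]
        out.attrs["implied_threshold"] = float(kept.min()) if k else np.nan
        out.attrs["kept_fraction"] = k / len(out) if len(out) else 0.0
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    out.attrs.setdefault("total_comparisons", edges.attrs.get("total_comparisons"))
    return out


def build_network(
    edges: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    nodes: list[str] | None = None,
) -> nx.Graph:
    """Undirected graph from filtered edges, with kinome-group node labels.

    ``nodes`` fixes the node universe (isolated proteins included); by
    default it is every protein appearing in the edge table.  ``annotations``
    is a DataFrame with ``protein_id`` and ``group`` columns; unannotated
    nodes are labelled ``"unknown"``.  Edge weights carry rho.
    """
    if nodes is None:
        nodes = sorted(set(edges["protein_a"]) | set(edges["protein_b"]))
    groups: dict[str, str] = {}
    if annotations is not None:
        bad = set(annotations["group"]) - set(KINOME_GROUPS)
        if bad:
            raise ValueError(f"unknown kinome groups: {sorted(bad)}")
        groups = dict(zip(annotations["protein_id"], annotations["group"]))
    g = nx.Graph()
    for n in nodes:
        g.add_node(n, group=groups.get(n, "unknown"))
    passing = edges[edges["passes_filter"]] if "passes_filter" in edges else edges
    for row in passing.itertuples(index=False):
        if row.protein_a in g and row.protein_b in g:
            g.add_edge(row.protein_a, row.protein_b,
                       weight=float(row.rho), rho=float(row.rho),
                       n_pairs=int(row.n_pairs))
    return g


def extract_subgraph(
    graph: nx.Graph, nodes: list[str] | None = None, group: str | None = None
) -> nx.Graph:
    """Induced subgraph by explicit node set and/or kinome group filter."""
    selected = set(graph.nodes) if nodes is None else {n for n in nodes if n in graph}
    if group is not None:
        selected = {n for n in selected if graph.nodes[n].get("group") == group}
    if not selected:
        import warnings

        warnings.warn("subgraph selection is empty", stacklevel=2)
    return graph.subgraph(selected).copy()


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
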