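"""Downstream prioritization: term scoring, interaction scaling, and
visualization-network sparsification.

Module significance of an annotation term is the mean module membership
(kME) of the term's genes inside the module times (1 - p) for the term's
enrichment p-value; term significance additionally weights by the genes'
mean absolute gene significance for a chosen behavioural trait.  Protein
interaction edges (confidence >= 0.9 only) are ranked by one of four
scaling metrics combining connectivity, differential connectivity, and
gene significance.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "module_significance",
    "term_significance",
    "scale_interactions",
    "cross_module_filter",
    "sparsify_for_viz",
    "edge_width",
    "HIGH_CONFIDENCE",
]

HIGH_CONFIDENCE = 0.9


def _annotated_in_module(term_genes, module_genes) -> pd.Index:
    term_idx = pd.Index(term_genes)
    return term_idx.intersection(pd.Index(module_genes))


def module_significance(term_genes, p_value: float, module_genes, kme_own: pd.Series) -> float:
    """MS = mean kME of the term's genes inside the module x (1 - p).

    NaN when no annotated gene falls inside the module.
    """
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("p_value must lie in [0, 1]")
    inside = _annotated_in_module(term_genes, module_genes)
    if len(inside) == 0:
        return np.nan
    return float(kme_own.loc[inside].mean() * (1.0 - p_value))


def term_significance(
    term_genes,
    p_value: float,
    module_genes,
    kme_own: pd.Series,
    gs_trait: pd.Series,
    signed: bool = False,
) -> float:
    """TS = MS x mean |gene significance| of the annotated module genes.

    ``signed=True`` uses the signed mean instead of the absolute mean.
    """
    ms = module_significance(term_genes, p_value, module_genes, kme_own)
    if np.isnan(ms):
        return np.nan
    inside = _annotated_in_module(term_genes, module_genes)
    gs = gs_trait.loc[inside]
    weight = gs.mean() if signed else gs.abs().mean()
    return float(ms * weight)


def score_terms(
    terms: pd.DataFrame,
    labels: pd.Series,
    kme_own: pd.Series,
    gs_trait: pd.Series | None = None,
) -> pd.DataFrame:
    """Module/term significance for every (term, module) pair with overlap.

    ``terms`` columns: term_id, category, p_value, gene_ids (comma-separated).
    """
    rows = []
    modules = [m for m in labels.unique() if m != "grey"]
    for _, rec in terms.iterrows():
        term_genes = pd.Index(str(rec["gene_ids"]).split(","))
        for m in modules:
            module_genes = labels.index[labels == m]
            inside = _annotated_in_module(term_genes, module_genes)
            if len(inside) == 0:
                continue
            ms = module_significance(term_genes, rec["p_value"], module_genes, kme_own)
            row = {
                "term_id": rec["term_id"],
                "category": rec.get("category", ""),
                "module": m,
                "n_genes_in_module": len(inside),
                "module_significance": ms,
            }
            if gs_trait is not None:
                row["term_significance"] = term_significance(
                    term_genes, rec["p_value"], module_genes, kme_own, gs_trait
                )
            rows.append(row)
    return pd.DataFrame(rows)


def scale_interactions(
    edges: pd.DataFrame,
    stats: pd.DataFrame,
    metric: int,
    confidence_threshold: float = HIGH_CONFIDENCE,
) -> pd.DataFrame:
    """Rank high-confidence interactions by one of four scaling metrics.

    ``stats`` is indexed by gene id with columns among kIN, dk (differential
    within-module connectivity between conditions), gs (gene significance).

    metric 1: conf x kIN_i x kIN_j           (juvenile network hubs)
    metric 2: conf x dk_i x dk_j             (juvenile-specific hubs)
    metric 3: conf x gs_i x gs_j             (behaviour-correlated genes)
    metric 4: conf x (kIN_i gs_i) x (kIN_j gs_j)

    Edges below the confidence threshold are excluded first; edges with a
    missing statistic are dropped with a warning.  Ties in score break
    lexicographically by (gene_i, gene_j).
    """
    need = {1: ["kIN"], 2: ["dk"], 3: ["gs"], 4: ["kIN", "gs"]}[metric]
    kept = edges.loc[edges["confidence"] >= confidence_threshold].copy()
    have = kept["gene_i"].isin(stats.index) & kept["gene_j"].isin(stats.index)
    for col in need:
        have &= (
            kept["gene_i"].map(stats[col]).notna() & kept["gene_j"].map(stats[col]).notna()
        )
    n_dropped = int((~have).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} edge(s) with missing statistics")
    kept = kept.loc[have]

    def _factor(genes: pd.Series) -> np.ndarray:
        if metric == 1:
            return genes.map(stats["kIN"]).to_numpy()
        if metric == 2:
            return genes.map(stats["dk"]).to_numpy()
        if metric == 3:
            return genes.map(stats["gs"]).to_numpy()
        return (genes.map(stats["kIN"]) * genes.map(stats["gs"])).to_numpy()

    kept["score"] = kept["confidence"].to_numpy() * _factor(kept["gene_i"]) * _factor(
        kept["gene_j"]
    )
    kept = kept.sort_values(
        ["score", "gene_i", "gene_j"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return kept


def cross_module_filter(
    edges: pd.DataFrame,
    labels: pd.Series,
    source_modules,
    target_modules,
) -> pd.DataFrame:
    """Keep edges linking a source-class module to a target-class module.

    Within-class edges (both endpoints in the source set, or both in the
    target set) are dropped, as are edges touching genes outside either
    class.
    """
    src = set(source_modules)
    tgt = set(target_modules)
    mi = edges["gene_i"].map(labels)
    mj = edges["gene_j"].map(labels)
    keep = (mi.isin(src) & mj.isin(tgt)) | (mi.isin(tgt) & mj.isin(src))
    return edges.loc[keep].reset_index(drop=True)


def sparsify_for_viz(
    weighted_edges: pd.DataFrame, keep_fraction: float = 0.02
) -> nx.Graph:
    """Three-stage sparsification for network plots.

    Retain the top ``keep_fraction`` of edges by weight (ties at the cutoff
    all retained), drop nodes left without edges, and keep only the largest
    connected component (equal-size ties broken by smallest lexicographic
    node id).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if len(weighted_edges) == 0:
        raise ValueError("no edges survive; increase keep_fraction")
    w = weighted_edges["weight"].to_numpy(dtype=float)
    n_keep = max(1, int(np.ceil(keep_fraction * len(w))))
    cutoff = np.sort(w)[::-1][n_keep - 1]
    kept = weighted_edges.loc[w >= cutoff]
    g = nx.Graph()
    for _, e in kept.iterrows():
        g.add_edge(e["gene_i"], e["gene_j"], weight=float(e["weight"]))
    if g.number_of_nodes() == 0:
        raise ValueError("no edges survive; increase keep_fraction")
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    main = components[0]
    return g.subgraph(main).copy()


def edge_width(conf, kin_i, kin_j):
    """Display width of an interaction edge: confidence x kIN_i x kIN_j."""
    conf = np.asarray(conf, dtype=float)
    ki = np.asarray(kin_i, dtype=float)
    kj = np.asarray(kin_j, dtype=float)
    if np.any(conf < 0) or np.any(ki < 0) or np.any(kj < 0):
        raise ValueError("inputs must be non-negative")
    out = conf * ki * kj
    return out.item() if out.ndim == 0 else out


def export_gexf(graph: nx.Graph, path, kin: pd.Series | None = None) -> None:
    """GEXF export with node size = kIN (fallback: degree)."""
    g = graph.copy()
    for node in g.nodes:
        size = float(kin.get(node, g.degree(node))) if kin is not None else g.degree(node)
        g.nodes[node]["size"] = size
    nx.write_gexf(g, path)
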