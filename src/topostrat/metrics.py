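"""Node centralities on positive-weight undirected graphs.

Strength (weighted degree), shortest-path betweenness with the 1/weight
length transform, and PageRank with damping 0.85.  Graphs are the positive
parts of subject connectivity matrices (see
:func:`topostrat.connectome.positive_graph`).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd


def strength_centrality(G: nx.Graph) -> dict:
    """s_i = sum of connection weights incident to node i."""
    return {n: float(w) for n, w in G.degree(weight="weight")}


def betweenness_centrality(G: nx.Graph, normalized: bool = False) -> dict:
    """Weighted shortest-path betweenness with edge length 1/weight.

    A stronger correlation is a shorter path; equal-length path ties are
    counted fractionally.  Unnormalized pair counts by default.
    """
    lengths = {(u, v): 1.0 / d["weight"] for u, v, d in G.edges(data=True)}
    nx.set_edge_attributes(G, lengths, "_length")
    try:
        return nx.betweenness_centrality(G, weight="_length", normalized=normalized)
    finally:
        for u, v in lengths:
            del G[u][v]["_length"]


@dataclass
class PageRankConfig:
    """Damped random-walk parameters; alpha = 0.85 is the study value."""

    alpha: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def pagerank(G: nx.Graph, cfg: PageRankConfig | None = None) -> dict:
    """Stationary vector of the damped walk with transitions A_ij / s_i.

    Each undirected edge acts as two directed arcs; dangling (isolated)
    nodes jump uniformly.  Values sum to 1.
    """
    cfg = cfg or PageRankConfig()
    try:
        return nx.pagerank(
            G, alpha=cfg.alpha, tol=cfg.tol, max_iter=cfg.max_iter, weight="weight"
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"PageRank failed to reach tol={cfg.tol} in {cfg.max_iter} "
            "iterations"
        ) from exc


def centrality_table(
    graphs: dict, measure: str = "degree", **kwargs
) -> pd.DataFrame:
    """Per-subject x per-ROI table of one centrality measure.

    ``graphs`` maps subject id -> positive-weight graph; ``measure`` is
    "degree" (strength), "betweenness" or "pagerank".
    """
    fns = {
        "degree": strength_centrality,
        "betweenness": betweenness_centrality,
        "pagerank": pagerank,
    }
    if measure not in fns:
        raise ValueError(f"unknown measure {measure!r}")
    if measure == "pagerank" and kwargs:
        kwargs = {"cfg": PageRankConfig(**kwargs)}
    rows = {sid: fns[measure](g, **kwargs) for sid, g in graphs.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
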