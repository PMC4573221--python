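"""Topological analysis of state-specific networks.

Computes the four classic node properties — degree, betweenness
centrality, clustering coefficient and PageRank — on an SSN, writes them
back as node attributes, and reports how each correlates with node
abundance (Pearson and Spearman, two-sided p-values).

Conventions: degree is in-degree + out-degree on the directed graph;
betweenness and PageRank respect edge direction; the clustering
coefficient is computed on the undirected projection (a directed triangle
census would split into seven motif classes, which is not what a plain
triangle count means).  PageRank uses the conventional damping 0.85 with
uniform teleport and uniform redistribution of dangling mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericError, ValidationError
from .reference_model import MetabolicNetwork

logger = logging.getLogger(__name__)

METRICS = ("degree", "betweenness", "clustering", "pagerank")


class CorrelationStats(NamedTuple):
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float


@dataclass
class TopologyResult:
    """Per-node topology metrics plus their correlation with abundance.

    ``frame`` is indexed by KO with columns degree, betweenness (pair-count
    normalized), betweenness_raw, clustering, pagerank and abundance.
    ``correlations[metric]`` holds Pearson/Spearman statistics of metric vs
    abundance, NaN when undefined (< 3 nodes or a constant vector).
    """

    frame: pd.DataFrame
    correlations: dict[str, CorrelationStats] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "ko"
        out.to_csv(path, sep="\t")


def node_degree(net: MetabolicNetwork) -> dict[str, int]:
    """Total degree (in + out; a self-loop counts twice)."""
    return {n: int(d) for n, d in net.graph.degree()}


def betweenness_centrality(
    net: MetabolicNetwork, normalized: bool = True
) -> dict[str, float]:
    """Directed shortest-path betweenness, endpoints excluded.

    ``normalized`` divides by the (n-1)(n-2) ordered pairs that could route
    through a node; shortest-path multiplicity is shared fractionally.
    """
    return {
        n: float(v)
        for n, v in nx.betweenness_centrality(net.graph, normalized=normalized).items()
    }


def clustering_coefficient(net: MetabolicNetwork) -> dict[str, float]:
    """Local clustering on the undirected projection (self-loops dropped)."""
    und = nx.Graph(net.graph)
    und.remove_edges_from(nx.selfloop_edges(und))
    return {n: float(v) for n, v in nx.clustering(und).items()}


def pagerank(
    net: MetabolicNetwork,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> dict[str, float]:
    """PageRank by power iteration on the directed graph.

    Uniform teleport with probability ``1 - damping``; a dangling node's
    mass is redistributed uniformly.  Convergence is declared when the L1
    change of the rank vector drops below ``tol``.

    Raises
    ------
    ValidationError
        Empty network.
    NumericError
        No convergence within ``max_iter`` iterations (the message reports
        the iteration count).
    """
    nodes = list(net.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValidationError("pagerank of an empty network is undefined")
    index = {v: i for i, v in enumerate(nodes)}
    out_nbrs: list[list[int]] = [
        [index[w] for w in net.graph.successors(v)] for v in nodes
    ]
    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for _ in range(max_iter):
        new = np.full(n, teleport)
        dangling_mass = 0.0
        for i, nbrs in enumerate(out_nbrs):
            if nbrs:
                share = damping * x[i] / len(nbrs)
                for j in nbrs:
                    new[j] += share
            else:
                dangling_mass += x[i]
        new += damping * dangling_mass / n
        if np.abs(new - x).sum() < tol:
            return {v: float(new[index[v]]) for v in nodes}
        x = new
    raise NumericError(
        f"pagerank did not converge within {max_iter} iterations (L1 tol {tol:g})"
    )


def _correlate(x: np.ndarray, y: np.ndarray) -> CorrelationStats:
    nan = float("nan")
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return CorrelationStats(nan, nan, nan, nan)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationStats(
        float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue)
    )


def analyze_topology(ssn: MetabolicNetwork) -> TopologyResult:
    """Compute all metrics on an SSN and attach them as node attributes.

    The SSN must carry ``abundance`` node attributes.  Correlations between
    abundance and each metric are reported with two-sided p-values; with
    fewer than 3 nodes, or a zero-variance vector (e.g. equal abundances),
    the corresponding statistics are NaN.
    """
    nodes = list(ssn.graph.nodes)
    if not nodes:
        frame = pd.DataFrame(
            columns=[
                "degree",
                "betweenness",
                "betweenness_raw",
                "clustering",
                "pagerank",
                "abundance",
            ]
        )
        return TopologyResult(frame=frame, correlations={})
    missing = [n for n in nodes if "abundance" not in ssn.graph.nodes[n]]
    if missing:
        raise ValidationError(
            f"{len(missing)} nodes lack an 'abundance' attribute (e.g. {missing[0]!r})"
        )

    deg = node_degree(ssn)
    btw = betweenness_centrality(ssn, normalized=True)
    btw_raw = betweenness_centrality(ssn, normalized=False)
    clu = clustering_coefficient(ssn)
    pr = pagerank(ssn)

    for n in nodes:
        ssn.graph.nodes[n].update(
            degree=deg[n],
            betweenness=btw[n],
            betweenness_raw=btw_raw[n],
            clustering=clu[n],
            pagerank=pr[n],
        )

    frame = pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "betweenness_raw": [btw_raw[n] for n in nodes],
            "clustering": [clu[n] for n in nodes],
            "pagerank": [pr[n] for n in nodes],
            "abundance": [ssn.graph.nodes[n]["abundance"] for n in nodes],
        },
        index=nodes,
    )
    abund = frame["abundance"].to_numpy()
    correlations = {
        m: _correlate(abund, frame[m].to_numpy(dtype=float)) for m in METRICS
    }
    for m, c in correlations.items():
        if math.isnan(c.spearman_r):
            logger.info("correlation abundance~%s undefined (constant input or n<3)", m)
    return TopologyResult(frame=frame, correlations=correlations)


def plot_topology(result: TopologyResult, path: str | Path) -> None:
    """Scatter abundance against each metric (2x2 grid) into an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    for ax, m in zip(axes.ravel(), METRICS):
        ax.scatter(result.frame[m], result.frame["abundance"], s=12)
        ax.set_xlabel(m)
        ax.set_ylabel("relative abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
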