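"""Bipartite network views of fitted GRNs and HITS centrality comparison.

Each phenotype's incidence matrix becomes a directed bipartite graph with
driver -> target edges carrying the signed fitted weight.  Kleinberg's HITS
scores are computed on the absolute weights (HITS needs a non-negative
adjacency; signs stay on the edges for reporting): drivers accumulate hub
mass, targets authority mass, and both vectors are rescaled to unit
maximum.  Authority shifts between two phenotypes are assessed with a
paired two-sided Wilcoxon signed-rank test across genes, with
Benjamini-Hochberg correction when several score types are tested together.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .inference import IncidenceMatrixSet
from .scoring import RegulonFilter

__all__ = [
    "BipartiteGRN",
    "CentralityReport",
    "build_bipartite_graph",
    "authority_hub_scores",
    "compare_centrality",
    "write_graphml",
]


@dataclass
class BipartiteGRN:
    """Weighted directed bipartite driver -> target graph for one phenotype."""

    graph: nx.DiGraph
    driver_ids: list[str]
    target_ids: list[str]
    phenotype: str

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"driver": u, "target": v, "weight": d["weight"], "sign": int(np.sign(d["weight"]))}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["driver", "target", "weight", "sign"])


@dataclass
class CentralityReport:
    """Per-gene centralities for two phenotypes plus the paired-test verdict."""

    table: pd.DataFrame  # gene, role, score_a, score_b, delta, p_value, q_value
    statistic: float
    p_value: float
    significant: bool
    alpha: float


def build_bipartite_graph(
    W_set_or_W,
    phenotype: str | None = None,
    filt: RegulonFilter | None = None,
    weight_tol: float = 1e-8,
) -> BipartiteGRN:
    """Build the signed bipartite graph of one phenotype's retained edges.

    Accepts either an :class:`IncidenceMatrixSet` plus a phenotype label, or
    a bare ``(m + 1, n)`` array (bias row dropped) with generated ids.  One
    edge is added per retained entry with ``|w| > weight_tol``.
    """
    if isinstance(W_set_or_W, IncidenceMatrixSet):
        if phenotype is None:
            raise ValueError("phenotype label required with an IncidenceMatrixSet")
        W = W_set_or_W.weights(phenotype)
        drivers, targets = W_set_or_W.driver_ids, W_set_or_W.target_ids
    else:
        W = np.asarray(W_set_or_W, dtype=float)[:-1, :]
        drivers = [f"d{i}" for i in range(W.shape[0])]
        targets = [f"t{j}" for j in range(W.shape[1])]
        phenotype = phenotype or ""

    keep = np.abs(W) > weight_tol
    if filt is not None:
        keep &= filt.driver_mask[phenotype] & filt.kept_targets(W.shape[1])[None, :]

    g = nx.DiGraph()
    g.add_nodes_from(drivers, role="driver")
    g.add_nodes_from(targets, role="target")
    for i, j in zip(*np.nonzero(keep)):
        g.add_edge(drivers[i], targets[j], weight=float(W[i, j]))
    return BipartiteGRN(graph=g, driver_ids=list(drivers), target_ids=list(targets),
                        phenotype=phenotype)


def authority_hub_scores(g: BipartiteGRN, tol: float = 1e-10, max_iter: int = 1000) -> pd.DataFrame:
    """HITS authority and hub scores on absolute edge weights, max-normalised.

    Returns a frame indexed by gene with columns ``role``, ``authority`` and
    ``hub``.  In a driver -> target bipartite graph the targets carry the
    authority mass and the drivers the hub mass.
    """
    if g.n_edges == 0:
        raise ValueError("empty graph: no edges to score")
    # deterministic HITS power iteration on |weights| (uniform start); the
    # library routine delegates to ARPACK with a random start, which breaks
    # byte-identical reruns
    m, n = len(g.driver_ids), len(g.target_ids)
    didx = {d: i for i, d in enumerate(g.driver_ids)}
    tidx = {t: j for j, t in enumerate(g.target_ids)}
    A = np.zeros((m, n))
    for u, v, d in g.graph.edges(data=True):
        A[didx[u], tidx[v]] = abs(d["weight"])
    a = np.ones(n)
    for _ in range(max_iter):
        a_new = A.T @ (A @ a)
        s = a_new.sum()
        if s == 0:
            a_new = np.zeros(n)
            break
        a_new /= s
        if np.abs(a_new - a).sum() < tol:
            a = a_new
            break
        a = a_new
    h = A @ a

    def rescale(v: np.ndarray) -> np.ndarray:
        mx = v.max()
        return v / mx if mx > 0 else np.zeros_like(v)

    a, h = rescale(a), rescale(h)
    auths = {**{d: 0.0 for d in g.driver_ids},
             **{t: float(a[tidx[t]]) for t in g.target_ids}}
    hubs = {**{d: float(h[didx[d]]) for d in g.driver_ids},
            **{t: 0.0 for t in g.target_ids}}
    genes = g.driver_ids + g.target_ids
    return pd.DataFrame(
        {
            "role": ["driver"] * len(g.driver_ids) + ["target"] * len(g.target_ids),
            "authority": [auths[x] for x in genes],
            "hub": [hubs[x] for x in genes],
        },
        index=pd.Index(genes, name="gene"),
    )


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired signed-rank test; identical vectors give (0, 1)."""
    diff = b - a
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    res = wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_centrality(
    report_a: pd.DataFrame,
    report_b: pd.DataFrame,
    alpha: float = 0.05,
    scores: tuple[str, ...] = ("authority", "hub"),
) -> CentralityReport:
    """Compare per-gene centralities of two phenotypes.

    Genes are paired across the two reports (shared genes only; at least
    two required).  For each score type a two-sided Wilcoxon signed-rank
    test is run across genes, and the p-values of the tested score types
    are Benjamini-Hochberg adjusted.  Each gene row carries its score
    type's p and q value; the global verdict is whether the authority shift
    is significant at ``alpha`` after correction.
    """
    shared = [gene for gene in report_a.index if gene in set(report_b.index)]
    if len(shared) < 2:
        raise ValueError("need at least two shared genes to compare")
    a = report_a.loc[shared]
    b = report_b.loc[shared]

    stats: dict[str, tuple[float, float]] = {
        s: _paired_wilcoxon(a[s].to_numpy(), b[s].to_numpy()) for s in scores
    }
    pvals = np.array([stats[s][1] for s in scores])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    q_of = dict(zip(scores, qvals))

    rows = []
    for s in scores:
        for gene in shared:
            rows.append(
                {
                    "gene": gene,
                    "score": s,
                    "role": a.loc[gene, "role"],
                    "value_a": a.loc[gene, s],
                    "value_b": b.loc[gene, s],
                    "delta": b.loc[gene, s] - a.loc[gene, s],
                    "p_value": stats[s][1],
                    "q_value": q_of[s],
                }
            )
    table = pd.DataFrame(rows)
    stat, p = stats[scores[0]]
    return CentralityReport(
        table=table,
        statistic=stat,
        p_value=p,
        significant=bool(q_of[scores[0]] < alpha),
        alpha=alpha,
    )


def write_graphml(g: BipartiteGRN, path) -> None:
    """Simple GraphML export of one phenotype's network."""
    nx.write_graphml(g.graph, path)
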