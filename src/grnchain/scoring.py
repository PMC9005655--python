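"""Per-cell regulon activity, regulon filtering and regulatory dissimilarity.

A *regulon* is one driver (TF) together with its weighted edges to target
genes.  For a single cell, the regulon's activity is the normalised area
under the cumulative sum of its (normalised) weights, visited in the order
of the cell's target expression: if the strongly weighted targets are the
highly expressed ones, weight accumulates early and the area approaches 1;
if they are the least expressed, it approaches its minimum.  The score is
always in [0, 1].

Because raw incidence weights are comparable across drivers for a fixed
target but not across targets, each weight is first divided by the Euclidean
norm of its target's expression over the cells of the state at hand
(:func:`normalize_weights`).  Ordering and accumulation use weight
magnitudes — the [0, 1] guarantee fails for signed weights — with edge signs
reported separately in the network outputs; ``signed=True`` gives the raw
signed variant.  Targets are ranked by descending expression by default so
that the weights of highly expressed targets accumulate first;
``ascending=True`` gives the opposite reading.

Shifts in a regulon's activity between phenotypes are quantified by the
total-variation distance between the per-phenotype empirical score
distributions, generalised to K >= 2 phenotypes by the minmax form
(1/K) * sum_bins (max_i P_i - min_j P_j), which equals plain total
variation when K = 2 and lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .inference import NONZERO_TOL, FitReport, IncidenceMatrixSet

__all__ = [
    "NormalizedWeights",
    "ActivityScoreSet",
    "ScoreDistribution",
    "DissimilarityTable",
    "RegulonFilter",
    "normalize_weights",
    "activity_score",
    "activity_matrix",
    "filter_regulons",
    "drop_poor_targets",
    "score_distribution",
    "total_variation",
    "minmax_tv",
    "dissimilarity_table",
]

#: sentinel returned for a cell/driver pair whose regulon is empty
EMPTY_REGULON = float("nan")


@dataclass
class NormalizedWeights:
    """Driver x target weights with each column scaled by 1 / ||Y_j||_2."""

    W_hat: np.ndarray
    driver_ids: list[str]
    target_ids: list[str]
    phenotype: str


@dataclass
class ActivityScoreSet:
    """Per-phenotype cells x drivers activity matrices, entries in [0, 1]."""

    scores: dict[str, pd.DataFrame]  # phenotype -> cells x drivers
    phenotype_order: list[str]

    def all_scores(self) -> pd.DataFrame:
        """Concatenated cells x drivers frame across phenotypes (chain order)."""
        return pd.concat([self.scores[ph] for ph in self.phenotype_order], axis=0)


@dataclass
class ScoreDistribution:
    """Histogram of activity scores over [0, 1], normalised to sum 1."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    descriptor: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.size != self.bin_edges.size - 1:
            raise ValueError("need one probability per bin")
        if np.any(self.probabilities < 0) or abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")


@dataclass
class DissimilarityTable:
    """Drivers x clusters minmax total-variation scores in [0, 1] (NaN = missing)."""

    table: pd.DataFrame


@dataclass
class RegulonFilter:
    """Kept-driver masks (one m x n boolean matrix per phenotype) and a target mask.

    For each target, drivers are sorted by decreasing squared weight and the
    shortest prefix whose cumulative squared-weight share reaches the
    variance fraction is kept, so each kept set is a prefix of the
    weight-sorted driver list.
    """

    driver_mask: dict[str, np.ndarray]  # phenotype -> (m, n) boolean
    target_mask: np.ndarray | None = None  # (n,) boolean, from goodness of fit

    def kept_targets(self, n: int) -> np.ndarray:
        return np.ones(n, dtype=bool) if self.target_mask is None else self.target_mask


def normalize_weights(W: np.ndarray, Y: np.ndarray, driver_ids=None, target_ids=None,
                      phenotype: str = "") -> NormalizedWeights:
    """Scale each column j of the (bias-free) weight matrix by 1 / ||Y_j||_2.

    ``Y`` holds the target expression of the cells of the state at hand
    (cells x targets).  Zero-norm targets get a zero column with a warning.
    """
    W = np.asarray(W, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if W.shape[1] != Y.shape[1]:
        raise ValueError("W and Y disagree on the number of targets")
    norms = np.linalg.norm(Y, axis=0)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-norm target(s); their columns set to 0",
                      stacklevel=2)
    safe = np.where(zero, 1.0, norms)
    W_hat = W / safe
    W_hat[:, zero] = 0.0
    m, n = W.shape
    return NormalizedWeights(
        W_hat=W_hat,
        driver_ids=list(driver_ids) if driver_ids is not None else [f"d{i}" for i in range(m)],
        target_ids=list(target_ids) if target_ids is not None else [f"t{j}" for j in range(n)],
        phenotype=phenotype,
    )


def activity_score(cell_expr, regulon_weights, ascending: bool = False,
                   signed: bool = False) -> float:
    """Normalised area under the cumulative sum of expression-ordered weights.

    ``cell_expr`` is the cell's expression over the regulon's targets and
    ``regulon_weights`` the matching normalised weights.  Targets are ranked
    by descending expression (ties broken by index), weights — magnitudes by
    default — are accumulated in that order, and the score is

        sum_t (cumsum_t / T) / sum_t w_t ,   t = 1..T,

    which lies in [0, 1] and equals 1 when all weight sits on the most
    expressed target.  Returns NaN for an empty (all-zero-weight) regulon.
    """
    x = np.asarray(cell_expr, dtype=float).ravel()
    w = np.asarray(regulon_weights, dtype=float).ravel()
    if x.shape != w.shape:
        raise ValueError("expression and weight vectors disagree in length")
    if not signed:
        w = np.abs(w)
    if not np.any(w != 0):
        return EMPTY_REGULON
    T = w.size  # zero-weight members still count toward T
    order = np.lexsort((np.arange(T), -x if not ascending else x))
    w_ord = w[order]
    cums = np.cumsum(w_ord)
    return float(cums.sum() / (T * cums[-1]))


def _regulon_members(mask_col: np.ndarray) -> np.ndarray:
    return np.flatnonzero(mask_col)


def activity_matrix(
    ds: ExpressionDataset,
    W_set: IncidenceMatrixSet,
    filt: RegulonFilter | None = None,
    ascending: bool = False,
    signed: bool = False,
) -> ActivityScoreSet:
    """Cells x drivers activity matrix for every phenotype.

    For each phenotype k the incidence matrix W^k (bias dropped) is
    normalised with that state's cells, optionally masked by a
    :class:`RegulonFilter` (dropped edges and poorly fitted targets are
    excluded from every regulon), and the activity score is evaluated per
    cell and driver.
    """
    if W_set.driver_ids != ds.driver_ids or W_set.target_ids != ds.target_ids:
        raise ValueError("gene indexing mismatch")
    m, n = len(ds.driver_ids), len(ds.target_ids)
    out: dict[str, pd.DataFrame] = {}
    for k, ph in enumerate(ds.phenotype_order):
        cells = ds.cells_of_phenotype(ph)
        if not cells:
            raise ValueError(f"phenotype {ph!r} has no cells")
        Y = ds.target_block(ph, cells)
        W = W_set.W_list[k][:-1, :].copy()
        if filt is not None:
            keep = filt.driver_mask[ph] & filt.kept_targets(n)[None, :]
            W = np.where(keep, W, 0.0)
        nw = normalize_weights(W, Y, ds.driver_ids, ds.target_ids, ph)
        # keep zero-weight targets in the ranking: a regulon's score reflects
        # where its weighted targets sit among all (retained) targets
        kept = filt.kept_targets(n) if filt is not None else np.ones(n, dtype=bool)
        A = np.empty((len(cells), m))
        for c in range(len(cells)):
            expr = Y[c, kept]
            for i in range(m):
                A[c, i] = activity_score(expr, nw.W_hat[i, kept],
                                         ascending=ascending, signed=signed)
        out[ph] = pd.DataFrame(A, index=cells, columns=ds.driver_ids)
    return ActivityScoreSet(scores=out, phenotype_order=list(ds.phenotype_order))


def filter_regulons(W_set: IncidenceMatrixSet, variance_fraction: float = 0.9) -> RegulonFilter:
    """Per target, keep the smallest prefix of squared-weight-sorted drivers
    whose cumulative squared-weight share reaches ``variance_fraction``.

    All-zero target columns yield an empty kept set for that target.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must be in (0, 1]")
    masks: dict[str, np.ndarray] = {}
    for ph, W_full in zip(W_set.phenotype_order, W_set.W_list):
        W = W_full[:-1, :]
        m, n = W.shape
        mask = np.zeros((m, n), dtype=bool)
        sq = W**2
        for j in range(n):
            tot = sq[:, j].sum()
            if tot <= NONZERO_TOL**2:
                continue  # empty driver set; target flagged by all-False column
            order = np.argsort(-sq[:, j], kind="stable")
            share = np.cumsum(sq[order, j]) / tot
            # smallest prefix reaching the fraction (+eps guards roundoff at 1.0)
            i_keep = int(np.searchsorted(share, variance_fraction - 1e-12) + 1)
            mask[order[:i_keep], j] = True
        masks[ph] = mask
    return RegulonFilter(driver_mask=masks)


def drop_poor_targets(report: FitReport, threshold: float = 0.7) -> np.ndarray:
    """Boolean mask of targets whose held-out adjusted R^2 reaches ``threshold``."""
    if report.adjusted_r2_pooled is None:
        raise ValueError("FitReport has no held-out adjusted R^2; run assess_fit first")
    r2 = report.adjusted_r2_pooled.to_numpy()
    mask = np.nan_to_num(r2, nan=-np.inf) >= threshold
    if not mask.any():
        warnings.warn("no target gene reached the goodness-of-fit threshold", stacklevel=2)
    return mask


def score_distribution(scores, n_bins: int = 100, descriptor: str = "") -> ScoreDistribution:
    """Equal-width histogram of activity scores over [0, 1], normalised to sum 1.

    NaN scores (empty regulons) are ignored; an effectively empty input is an
    error.  The last bin is closed on the right so a score of exactly 1
    counts.
    """
    s = np.asarray(scores, dtype=float).ravel()
    s = s[~np.isnan(s)]
    if s.size == 0:
        raise ValueError("no scores to bin")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(s, bins=edges)  # numpy's last bin is right-closed
    return ScoreDistribution(edges, counts / counts.sum(), descriptor)


def _check_same_bins(dists: list[ScoreDistribution]) -> None:
    e0 = dists[0].bin_edges
    for d in dists[1:]:
        if d.bin_edges.size != e0.size or not np.allclose(d.bin_edges, e0):
            raise ValueError("distributions have mismatched binning")


def total_variation(P: ScoreDistribution, Q: ScoreDistribution) -> float:
    """Total-variation distance 1/2 * sum |P - Q| over shared bins, in [0, 1]."""
    _check_same_bins([P, Q])
    return float(0.5 * np.abs(P.probabilities - Q.probabilities).sum())


def minmax_tv(dists: list[ScoreDistribution]) -> float:
    """Minmax total variation (1/K) * sum_bins (max_i P_i - min_j P_j).

    Degenerates to :func:`total_variation` for K = 2.
    """
    if len(dists) < 2:
        raise ValueError("need at least two distributions")
    _check_same_bins(dists)
    P = np.stack([d.probabilities for d in dists])
    return float(np.sum(P.max(axis=0) - P.min(axis=0)) / len(dists))


def dissimilarity_table(
    act: ActivityScoreSet,
    clusters: dict[str, str] | None = None,
    n_bins: int = 100,
) -> DissimilarityTable:
    """Drivers x clusters table of across-phenotype regulatory dissimilarity.

    For each driver and cluster, one activity-score distribution is built per
    phenotype from that cluster's cells and the minmax total variation across
    the K distributions is reported.  With no cluster map a single pseudo-
    cluster ``"all"`` is used.  A cluster with no scored cells in some
    phenotype yields a missing (NaN) entry with a warning, not 0.
    """
    phenos = act.phenotype_order
    if len(phenos) < 2:
        raise ValueError("dissimilarity needs at least two phenotypes")
    drivers = list(act.scores[phenos[0]].columns)

    def cluster_of(cell: str) -> str:
        return "all" if clusters is None else clusters[cell]

    cluster_names = sorted({cluster_of(c) for ph in phenos for c in act.scores[ph].index})
    out = pd.DataFrame(np.nan, index=drivers, columns=cluster_names)
    for cl in cluster_names:
        per_ph = {}
        ok = True
        for ph in phenos:
            frame = act.scores[ph]
            rows = [c for c in frame.index if cluster_of(c) == cl]
            if not rows:
                warnings.warn(
                    f"cluster {cl!r} has no cells in phenotype {ph!r}; entries left missing",
                    stacklevel=2,
                )
                ok = False
                break
            per_ph[ph] = frame.loc[rows]
        if not ok:
            continue
        for drv in drivers:
            dists = []
            valid = True
            for ph in phenos:
                vals = per_ph[ph][drv].to_numpy()
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    valid = False
                    break
                dists.append(score_distribution(vals, n_bins, f"{drv}|{ph}|{cl}"))
            if valid:
                out.loc[drv, cl] = minmax_tv(dists)
    return DissimilarityTable(table=out)
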