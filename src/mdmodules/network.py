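"""Differential co-expression network (DCN) construction.

One weighted, undirected network is built per disease condition.  Edge
presence is decided by a first-order partial Pearson correlation screen
on that condition's expression matrix; edge weights come from the
differential-expression p-values of the two endpoint genes:

    w_ij = sqrt(-log p_i - log p_j) / sqrt(2 * max_l |log p_l|)

(natural log), so w_ij is in (0, 1] and reaches 1 exactly when both
endpoints attain the global minimum p-value.  The stack of per-condition
networks over a common gene set realizes a genes x genes x conditions
weight tensor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DEPValueTable, ExpressionPanel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DCN",
    "CorrelationScreen",
    "partial_correlation_screen",
    "edge_weight",
    "build_dcn",
    "select_delta",
]

#: denominators below this are treated as numerically collinear and skipped
COLLINEAR_EPS = 1e-12
#: above this many genes, exhaustive first-order conditioning becomes cubic
#: and the conditioning set is capped (most-correlated genes only)
EXACT_CONDITIONING_LIMIT = 2000
DEFAULT_CONDITIONING_CAP = 200


@dataclass
class DCN:
    """A weighted differential co-expression network for one condition.

    ``adjacency`` is a dense symmetric n x n array over ``genes`` (0 =
    no edge, no self-loops).  ``neg_log_p`` caches -log p per gene for
    reporting.
    """

    condition: str
    genes: list[str]
    adjacency: np.ndarray
    delta: float
    neg_log_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.shape != (len(self.genes), len(self.genes)):
            raise ValidationError("adjacency shape does not match gene list")
        if not np.allclose(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.diagonal(A).any():
            raise ValidationError("self-loops are not allowed")
        if (A < 0).any() or (A > 1).any():
            raise ValidationError("edge weights must lie in [0, 1]")
        self.adjacency = A

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree per gene."""
        return self.adjacency.sum(axis=1)

    def connected_genes(self) -> np.ndarray:
        """Boolean mask of genes with at least one incident edge."""
        return self.degrees > 0

    def edge_list(self) -> pd.DataFrame:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return pd.DataFrame(
            {
                "gene_a": [self.genes[i] for i in iu],
                "gene_b": [self.genes[j] for j in ju],
                "weight": self.adjacency[iu, ju],
            }
        )

    def induced(self, genes: list[str]) -> np.ndarray:
        idx = [self.genes.index(g) for g in genes]
        return self.adjacency[np.ix_(idx, idx)]


@dataclass
class CorrelationScreen:
    """Marginal and minimum first-order partial correlations per pair.

    ``partial_min`` is NaN for pairs whose marginal correlation never
    reached the screening threshold (the partial is not computed there).
    """

    genes: list[str]
    marginal: np.ndarray
    partial_min: np.ndarray
    delta: float
    n_skipped_collinear: int = 0

    def passed(self, delta: float | None = None) -> np.ndarray:
        """Symmetric boolean matrix of pairs passing the screen at
        ``delta`` (defaults to the screening threshold)."""
        d = self.delta if delta is None else delta
        with np.errstate(invalid="ignore"):
            ok = (self.marginal >= d) & (self.partial_min >= d)
        np.fill_diagonal(ok, False)
        return ok


def _pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Signed Pearson correlation between rows of X (genes x samples)."""
    R = np.corrcoef(X)
    return np.clip(R, -1.0, 1.0)


def partial_correlation_screen(
    expr: pd.DataFrame,
    delta: float,
    conditioning_cap: int | None = None,
) -> CorrelationScreen:
    """Screen all gene pairs of one condition's matrix.

    A pair (i, j) passes when its absolute Pearson correlation is >=
    ``delta`` and the minimum over conditioning genes z of the absolute
    first-order partial correlation

        (r_ij - r_iz r_jz) / sqrt((1 - r_iz^2)(1 - r_jz^2))

    also stays >= ``delta`` — removing correlation that a single third
    gene fully explains.  Near-collinear conditioning genes (denominator
    below ``COLLINEAR_EPS``) are skipped and counted.

    Parameters
    ----------
    expr : genes x samples DataFrame (>= 3 samples, no zero-variance rows)
    delta : screening threshold in (0, 1)
    conditioning_cap : condition only on this many genes (those most
        correlated with either endpoint); ``None`` = all genes.
    """
    if not 0 < delta <= 1:
        raise ValidationError(f"delta must lie in (0, 1], got {delta}")
    X = expr.to_numpy(dtype=float)
    n, m = X.shape
    if m < 3:
        raise ValidationError("at least 3 samples are required for correlation")
    variances = X.var(axis=1)
    if (variances <= 0).any():
        bad = [expr.index[i] for i in np.nonzero(variances <= 0)[0][:5]]
        raise ValidationError(f"zero-variance gene(s) present, e.g. {bad}; exclude them upstream")

    R = _pearson_matrix(X)
    absR = np.abs(R)
    partial_min = np.full((n, n), np.nan)
    n_skipped = 0

    iu, ju = np.nonzero(np.triu(absR >= delta, k=1))
    for i, j in zip(iu, ju):
        ri, rj = R[i], R[j]
        if conditioning_cap is not None and n - 2 > conditioning_cap:
            relevance = np.maximum(np.abs(ri), np.abs(rj))
            relevance[[i, j]] = -np.inf
            z_idx = np.argpartition(relevance, -conditioning_cap)[-conditioning_cap:]
        else:
            z_idx = np.arange(n)
            z_idx = z_idx[(z_idx != i) & (z_idx != j)]
        num = R[i, j] - ri[z_idx] * rj[z_idx]
        den_sq = (1.0 - ri[z_idx] ** 2) * (1.0 - rj[z_idx] ** 2)
        den = np.sqrt(np.maximum(den_sq, 0.0))
        usable = den >= COLLINEAR_EPS
        n_skipped += int((~usable).sum())
        if not usable.any():
            # every conditioning gene is collinear; fall back to marginal
            q = absR[i, j]
        else:
            q = float(np.min(np.abs(num[usable] / den[usable])))
            q = min(q, 1.0)
        partial_min[i, j] = partial_min[j, i] = q

    if n_skipped:
        logger.info("partial screen skipped %d near-collinear conditioning genes", n_skipped)
    return CorrelationScreen(
        genes=list(expr.index),
        marginal=absR,
        partial_min=partial_min,
        delta=delta,
        n_skipped_collinear=n_skipped,
    )


def edge_weight(p_i: float, p_j: float, p_floor_log: float) -> float:
    """Differential-expression edge weight in (0, 1].

    ``p_floor_log`` is max_l |log p_l| over all genes of the network, so
    the weight is 1 exactly when both endpoints carry the globally most
    significant p-value, and 0 when both p-values are 1.
    """
    for p in (p_i, p_j):
        if p <= 0 or p > 1:
            raise ValidationError(f"p-values must lie in (0, 1], got {p}")
    if p_floor_log <= 0:
        raise ValidationError("all p-values equal 1; the network would carry zero weight")
    w = np.sqrt(-np.log(p_i) - np.log(p_j)) / np.sqrt(2.0 * p_floor_log)
    return float(w)


def build_dcn(
    expr: pd.DataFrame,
    de_pvalues: pd.Series,
    delta: float,
    condition: str = "",
    conditioning_cap: int | None = None,
    log_transform: bool = False,
    screen: CorrelationScreen | None = None,
) -> DCN:
    """Build the weighted DCN of one condition.

    Edges are exactly the pairs passing :func:`partial_correlation_screen`
    at ``delta``; each edge carries :func:`edge_weight` computed with the
    normalizing max |log p| taken once over all genes.  Genes with zero
    expression variance are kept in the node set but excluded from the
    screen (isolated, with a warning).  An edge whose weight is exactly 0
    (both endpoint p-values equal 1) is treated as absent, matching the
    weight formula's second branch.
    """
    genes = list(expr.index)
    de = de_pvalues.reindex(genes)
    if de.isna().any():
        missing = list(de.index[de.isna()])[:5]
        raise ValidationError(f"p-values missing for genes, e.g. {missing}")
    pvals = np.clip(de.to_numpy(dtype=float), DEPValueTable.P_CLAMP, 1.0)

    variances = expr.to_numpy(dtype=float).var(axis=1)
    keep = variances > 0
    if not keep.all():
        logger.warning(
            "condition %s: excluding %d zero-variance gene(s) from the screen",
            condition,
            int((~keep).sum()),
        )

    X = expr.loc[keep]
    if log_transform:
        X = np.log2(X + 1.0)
    if conditioning_cap is None and int(keep.sum()) > EXACT_CONDITIONING_LIMIT:
        conditioning_cap = DEFAULT_CONDITIONING_CAP
    if screen is None:
        screen = partial_correlation_screen(X, delta, conditioning_cap)

    neg_log_p = -np.log(pvals)
    p_floor_log = float(neg_log_p.max())
    if p_floor_log <= 0:
        raise ValidationError("all differential-expression p-values equal 1")

    n = len(genes)
    A = np.zeros((n, n))
    pass_mask = screen.passed(delta)
    sub_idx = np.nonzero(keep)[0]
    iu, ju = np.nonzero(np.triu(pass_mask, k=1))
    for si, sj in zip(iu, ju):
        gi, gj = sub_idx[si], sub_idx[sj]
        w = np.sqrt(neg_log_p[gi] + neg_log_p[gj]) / np.sqrt(2.0 * p_floor_log)
        if w > 0:
            A[gi, gj] = A[gj, gi] = min(float(w), 1.0)

    dcn = DCN(condition=condition, genes=genes, adjacency=A, delta=delta, neg_log_p=neg_log_p)
    if dcn.n_edges == 0:
        logger.warning("condition %s: DCN has no edges at delta=%.3g", condition, delta)
    return dcn


def select_delta(panel: ExpressionPanel, grid: list[float]) -> float:
    """Pick the correlation threshold from a grid.

    Returns the largest delta maximizing the number of genes connected
    (degree >= 1) simultaneously in every condition's network; ties are
    broken toward larger delta (sparser networks).  Only the screen
    matters for connectivity, so p-values are not needed here.
    """
    if not grid:
        raise ValidationError("delta grid must be non-empty")
    for d in grid:
        if not 0 < d < 1:
            raise ValidationError(f"grid deltas must lie in (0, 1), got {d}")
    dmin = min(grid)
    screens = []
    for cond in panel.conditions:
        expr = panel.condition_matrix(cond)
        variances = expr.to_numpy(dtype=float).var(axis=1)
        screens.append((variances > 0, partial_correlation_screen(expr.loc[variances > 0], dmin)))

    best_delta, best_count = None, -1
    for d in sorted(grid):
        connected_all = np.ones(panel.n_genes, dtype=bool)
        for keep, screen in screens:
            conn = np.zeros(panel.n_genes, dtype=bool)
            conn[np.nonzero(keep)[0]] = screen.passed(d).any(axis=1)
            connected_all &= conn
        count = int(connected_all.sum())
        if count >= best_count:  # >= biases ties toward the larger delta
            best_delta, best_count = d, count
    return float(best_delta)
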