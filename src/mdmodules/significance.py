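"""Empirical module significance via degree-preserved network randomization.

The null model rewires every network of a subset by double-edge swaps
(preserving each gene's unweighted degree exactly), randomly permutes
the multiset of edge weights over the rewired edge set, reruns the full
module search with identical parameters, and pools the entropy scores of
the modules found.  A real module's empirical p-value is the add-one
estimate of the probability of a null module scoring as low or lower;
Benjamini-Hochberg correction controls the FDR across modules.
"""

from __future__ import annotations

import logging

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datatypes import MDM, ValidationError
from .network import DCN

logger = logging.getLogger(__name__)

__all__ = [
    "degree_preserving_shuffle",
    "null_score_pool",
    "mdm_significance",
    "bh_adjust",
]


def degree_preserving_shuffle(
    dcn: DCN, rng: np.random.Generator, swaps_per_edge: int = 10
) -> DCN:
    """Randomize a network's topology while conserving every gene's
    unweighted degree and the multiset of edge weights.

    ``swaps_per_edge * |E|`` double-edge swaps are attempted (the
    standard mixing heuristic); the edge weights are then randomly
    permuted over the rewired edge set.  Graphs too small to admit a
    legal swap are returned with only their weights permuted.
    """
    A0 = dcn.adjacency
    iu, ju = np.nonzero(np.triu(A0, k=1))
    n_edges = iu.size
    weights = A0[iu, ju].copy()
    if n_edges < 2:
        logger.warning("network %s has fewer than 2 edges; only weights permuted", dcn.condition)
    u = iu.copy()
    v = ju.copy()
    if n_edges >= 2:
        # classic double-edge swap on a uniformly chosen edge pair:
        # (a,b),(c,d) -> (a,d),(c,b) unless a self-loop or multi-edge
        # would result
        ul = [int(x) for x in u]
        vl = [int(x) for x in v]
        present = set(zip(ul, vl))
        target = n_edges * swaps_per_edge
        max_tries = max(100 * n_edges, target + 1)
        swaps = tries = 0
        pairs1 = rng.integers(0, n_edges, size=max_tries).tolist()
        pairs2 = rng.integers(0, n_edges, size=max_tries).tolist()
        orient = rng.integers(0, 2, size=max_tries).tolist()
        while swaps < target and tries < max_tries:
            e1 = pairs1[tries]
            e2 = pairs2[tries]
            flip = orient[tries]
            tries += 1
            if e1 == e2:
                continue
            a, b = ul[e1], vl[e1]
            c, d = (ul[e2], vl[e2]) if flip else (vl[e2], ul[e2])
            if a == c or a == d or b == c or b == d:
                continue
            n1 = (a, d) if a < d else (d, a)
            n2 = (c, b) if c < b else (b, c)
            if n1 in present or n2 in present:
                continue
            present.discard((a, b) if a < b else (b, a))
            present.discard((c, d) if c < d else (d, c))
            present.add(n1)
            present.add(n2)
            ul[e1], vl[e1] = n1
            ul[e2], vl[e2] = n2
            swaps += 1
        u = np.array(ul)
        v = np.array(vl)
        if swaps < target:
            logger.debug(
                "network %s: %d/%d swaps achieved (few legal swaps exist)",
                dcn.condition,
                swaps,
                target,
            )
    rng.shuffle(weights)
    A = np.zeros_like(A0)
    A[u, v] = weights
    A[v, u] = weights
    return DCN(
        condition=dcn.condition,
        genes=dcn.genes,
        adjacency=A,
        delta=dcn.delta,
        neg_log_p=dcn.neg_log_p,
    )


def null_score_pool(
    dcns: list[DCN],
    n_rand: int = 100,
    rng: np.random.Generator | None = None,
    fraction: float = 0.10,
    min_size: int = 5,
    jaccard: float = 0.5,
    swaps_per_edge: int = 10,
) -> np.ndarray:
    """Entropy scores of modules discovered on randomized networks.

    Every network of the subset is shuffled independently ``n_rand``
    times and the full search is rerun each time with the same
    parameters.  Scores of all expanded candidates are pooled (before
    the minimum-size drop and Jaccard merging; at small problem sizes
    the refined catalog of a randomized network is empty almost surely,
    which would leave no null distribution at all).
    """
    from .search import search_subset

    if rng is None:
        rng = np.random.default_rng()
    subset = tuple(d.condition for d in dcns)
    scores: list[float] = []
    for _ in range(n_rand):
        shuffled = [degree_preserving_shuffle(d, rng, swaps_per_edge) for d in dcns]
        _, raw = search_subset(
            shuffled, subset, fraction=fraction, min_size=min_size, jaccard=jaccard
        )
        scores.extend(c.entropy for c in raw)
    return np.asarray(scores, dtype=float)


def mdm_significance(
    mdms: list[MDM],
    dcns: list[DCN],
    n_rand: int = 100,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    fraction: float = 0.10,
    min_size: int = 5,
    jaccard: float = 0.5,
    swaps_per_edge: int = 10,
) -> list[MDM]:
    """Attach empirical and BH-adjusted p-values to a module list.

    All modules are assumed to have been discovered on the given (real)
    networks.  The empirical p-value of a module with entropy H is
    (1 + #{null scores <= H}) / (1 + #null scores) — low entropy is the
    extreme direction.  An empty null pool degenerates every p-value to
    1 with a prominent warning.
    """
    if rng is None:
        rng = np.random.default_rng()
    null_scores = null_score_pool(
        dcns,
        n_rand=n_rand,
        rng=rng,
        fraction=fraction,
        min_size=min_size,
        jaccard=jaccard,
        swaps_per_edge=swaps_per_edge,
    )
    if null_scores.size == 0:
        logger.warning("EMPTY null score pool: no module was ever found on randomized networks")
    out = []
    for m in mdms:
        p = (1.0 + float((null_scores <= m.entropy + 1e-12).sum())) / (1.0 + null_scores.size)
        out.append(m.with_pvalues(min(p, 1.0), adj=np.nan, alpha=alpha))
    adj = bh_adjust([m.p_value for m in out])
    return [m.with_pvalues(m.p_value, float(a), alpha) for m, a in zip(out, adj)]


def bh_adjust(pvals: list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
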