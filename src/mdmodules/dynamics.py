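"""Connectivity dynamics of shared modules (MCDS).

A module found in two or more networks has one induced weighted
adjacency matrix per network.  The Module Connectivity Dynamic Score
compares them:

    Delta_ij = || A_i^C - A_j^C ||_2 / |C|

with the matrix 2-norm (largest singular value) by default, averaged
over network pairs.  Large scores mean the module's internal wiring is
rewired between conditions ("dynamic"); a score of 0 means the induced
matrices are identical ("static").  Significance comes from size-matched
random gene sets drawn from the connected genes.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import MCDSResult, MDM, ValidationError
from .network import DCN
from .significance import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["component_adjacency", "mcds", "mcds_significance"]


def component_adjacency(mdm_genes: list[str], dcn: DCN) -> np.ndarray:
    """Induced weighted adjacency of a module in one network, with rows
    and columns in sorted gene order (canonical across networks)."""
    order = sorted(mdm_genes)
    missing = [g for g in order if g not in dcn.genes]
    if missing:
        raise ValidationError(f"module genes absent from network: {missing[:5]}")
    return dcn.induced(order)


def _pair_delta(A: np.ndarray, B: np.ndarray, norm: str) -> float:
    D = A - B
    if norm == "spectral":
        return float(np.linalg.norm(D, 2))
    if norm == "frobenius":
        return float(np.linalg.norm(D))
    raise ValidationError(f"unknown norm {norm!r}")


def mcds(
    mdm: MDM,
    dcns: list[DCN],
    norm: str = "spectral",
    pairing: str = "allpairs",
) -> MCDSResult:
    """Score the connectivity dynamics of one shared module.

    ``pairing='allpairs'`` averages the normalized difference norm over
    all unordered network pairs; ``'adjacent'`` averages over consecutive
    pairs in input order (both coincide for two networks).
    """
    if len(dcns) < 2:
        raise ValidationError("MCDS is defined only for modules shared by >= 2 networks")
    genes = list(mdm.genes)
    mats = [component_adjacency(genes, d) for d in dcns]
    size = len(genes)
    pairwise: dict[tuple[str, str], float] = {}
    if pairing == "allpairs":
        pairs = [(i, j) for i in range(len(dcns)) for j in range(i + 1, len(dcns))]
    elif pairing == "adjacent":
        pairs = [(i, i + 1) for i in range(len(dcns) - 1)]
    else:
        raise ValidationError(f"unknown pairing {pairing!r}")
    deltas = []
    for i, j in pairs:
        d = _pair_delta(mats[i], mats[j], norm) / size
        pairwise[(dcns[i].condition, dcns[j].condition)] = d
        deltas.append(d)
    return MCDSResult(
        module_id=mdm.module_id,
        genes=mdm.genes,
        subset=tuple(d.condition for d in dcns),
        score=float(np.mean(deltas)),
        pairwise=pairwise,
    )


def mcds_significance(
    results: list[MCDSResult],
    dcns_by_condition: dict[str, DCN],
    n_rand: int = 100,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    norm: str = "spectral",
    pairing: str = "allpairs",
) -> list[MCDSResult]:
    """Flag dynamic modules against size-matched random gene sets.

    For each module, ``n_rand`` gene sets of the same size are drawn
    uniformly from the genes connected in at least one of the module's
    networks, their MCDS computed, and the one-sided (large = dynamic)
    add-one empirical p-value taken; BH correction is applied across all
    modules and the dynamic flag set at adjusted p <= alpha.
    """
    if rng is None:
        rng = np.random.default_rng()
    out: list[MCDSResult] = []
    for res in results:
        dcns = [dcns_by_condition[c] for c in res.subset]
        active = np.zeros(dcns[0].n_genes, dtype=bool)
        for d in dcns:
            active |= d.connected_genes()
        pool = [dcns[0].genes[i] for i in np.nonzero(active)[0]]
        size = len(res.genes)
        if size > len(pool):
            raise ValidationError(
                f"module {res.module_id} is larger than the connected gene pool"
            )
        null = np.empty(n_rand)
        for r in range(n_rand):
            draw = list(rng.choice(len(pool), size=size, replace=False))
            fake = MDM(
                module_id="null",
                genes=tuple(pool[i] for i in draw),
                subset=res.subset,
                entropy=np.nan,
            )
            null[r] = mcds(fake, dcns, norm=norm, pairing=pairing).score
        p = (1.0 + float((null >= res.score - 1e-12).sum())) / (1.0 + n_rand)
        out.append(
            MCDSResult(
                module_id=res.module_id,
                genes=res.genes,
                subset=res.subset,
                score=res.score,
                pairwise=res.pairwise,
                p_value=min(p, 1.0),
            )
        )
    if out:
        adj = bh_adjust([r.p_value for r in out])
        for r, a in zip(out, adj):
            r.adj_p_value = float(a)
            r.dynamic = bool(a <= alpha)
    return out
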