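"""Multi-network module discovery by graph-entropy seed expansion.

Genes are first ranked in every network by a propagation importance (the
principal eigenvector of the degree-normalized weighted adjacency,
computed per connected component and weighted by each component's share
of total edge weight).  Per-network importances are z-scored over the
active gene set, averaged across networks, and the top fraction become
seeds.  Each seed is expanded greedily: the gene whose addition most
decreases the module's graph entropy

    H(C) = sum_k sum_{i in C} h(p_ik) / |C|,
    p_ik = L_k(i) / (L_k(i) + Lbar_k(i)),   h = binary entropy (nats)

is added until no addition decreases H.  Low entropy means each member's
edge weight is sharply concentrated inside the module, simultaneously in
every network searched.  Candidates smaller than a minimum size are
dropped and overlapping candidates are merged by Jaccard index.

Searching every non-empty subset S of the M networks and keeping, per
module, only the maximal subset for which it is significant yields the
final catalog: modules at level m = |S| are those found in exactly m
conditions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import replace

import numpy as np

from .datatypes import MDM, ModuleCandidate, ValidationError, jaccard_index
from .network import DCN

logger = logging.getLogger(__name__)

__all__ = [
    "node_importance",
    "combine_rankings",
    "module_entropy",
    "expand_seed",
    "refine_candidates",
    "discover_mdms",
    "search_subset",
    "active_gene_mask",
]

POWER_TOL = 1e-10
POWER_MAXITER = 10_000
#: strictness margin for "the objective decreased"
DESCENT_EPS = 1e-12
MAX_NETWORKS = 6


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    out = np.zeros_like(p)
    mask = (p > 0) & (p < 1)
    pm = p[mask]
    out[mask] = -pm * np.log(pm) - (1 - pm) * np.log(1 - pm)
    return out


def _connected_components(A: np.ndarray) -> list[np.ndarray]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(csr_matrix(A != 0), directed=False)
    return [np.nonzero(labels == c)[0] for c in range(n_comp)]


def _power_iteration(M: np.ndarray) -> np.ndarray:
    """Leading eigenvector of a symmetric non-negative matrix with
    spectrum in [-1, 1], unit-sum.

    Iterates on (M + I)/2, which shares M's eigenvectors but maps the
    spectrum into [0, 1]; a bipartite component's -1 eigenvalue would
    otherwise make plain power iteration oscillate forever.
    """
    n = M.shape[0]
    M = (M + np.eye(n)) / 2.0
    v = np.full(n, 1.0 / n)
    for _ in range(POWER_MAXITER):
        w = M @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValidationError("power iteration collapsed to zero")
        w /= norm
        if np.linalg.norm(w - v) <= POWER_TOL * np.linalg.norm(v):
            v = w
            break
        v = w
    else:
        raise ValidationError(
            f"power iteration did not converge in {POWER_MAXITER} steps (n={n})"
        )
    v = np.abs(v)
    return v / v.sum()


def node_importance(dcn: DCN) -> np.ndarray:
    """Propagation importance of every gene in one network.

    For each connected component, the importance is the principal
    eigenvector of the symmetrically degree-normalized weighted adjacency
    A' = D^-1/2 A D^-1/2 (the fixed point of the propagation g = A'g),
    scaled by the component's share of the network's total edge weight.
    On a connected network this is exactly the global principal
    eigenvector; on a fragmented one every component contributes
    importance mass proportional to its strength instead of all but the
    largest being zeroed out.  Isolated genes get importance 0.  The
    result is non-negative with unit sum.
    """
    A = dcn.adjacency
    if not (A > 0).any():
        raise ValidationError(f"network {dcn.condition!r} has no edges")
    n = A.shape[0]
    g = np.zeros(n)
    total_weight = A.sum()
    for comp in _connected_components(A):
        if comp.size < 2:
            continue
        sub = A[np.ix_(comp, comp)]
        mass = sub.sum() / total_weight
        d = sub.sum(axis=1)
        dinv = 1.0 / np.sqrt(d)
        M = sub * dinv[:, None] * dinv[None, :]
        if comp.size <= 500:
            # dense solve: exact and faster than iterating through the
            # tiny spectral gaps of weakly coupled components
            evals, evecs = np.linalg.eigh(M)
            v = np.abs(evecs[:, -1])
            v /= v.sum()
        else:  # pragma: no cover - large-network path
            v = _power_iteration(M)
        g[comp] = v * mass
    return g / g.sum()


def active_gene_mask(dcns: list[DCN]) -> np.ndarray:
    """Genes with degree >= 1 in at least one of the networks."""
    mask = np.zeros(dcns[0].n_genes, dtype=bool)
    for dcn in dcns:
        mask |= dcn.connected_genes()
    return mask


def combine_rankings(
    rankings: list[np.ndarray],
    fraction: float = 0.10,
    active: np.ndarray | None = None,
    genes: list[str] | None = None,
) -> list[int]:
    """Cross-network seed selection by averaged z-scores.

    Each network's importance vector is z-scored over the active gene
    set, the z-scores are averaged per gene across networks, and the top
    ceil(fraction * n_active) genes are returned (indices into the gene
    list).  A network whose importances are all equal contributes zero to
    every gene, with a warning.  Ties are broken by gene order.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"seed fraction must lie in (0, 1], got {fraction}")
    n = rankings[0].shape[0]
    if active is None:
        active = np.zeros(n, dtype=bool)
        for g in rankings:
            active |= g > 0
    idx_active = np.nonzero(active)[0]
    if idx_active.size == 0:
        return []
    zsum = np.zeros(idx_active.size)
    for g in rankings:
        vals = g[idx_active]
        sd = vals.std(ddof=0)
        if sd == 0:
            logger.warning("a network has constant importances; it does not rank genes")
            continue
        zsum += (vals - vals.mean()) / sd
    zavg = zsum / len(rankings)
    n_seeds = math.ceil(fraction * idx_active.size)
    if genes is not None:
        tie = np.array([genes[i] for i in idx_active])
        order = np.lexsort((tie, -zavg))
    else:
        order = np.lexsort((idx_active, -zavg))
    return [int(idx_active[k]) for k in order[:n_seeds]]


def module_entropy(member_idx: np.ndarray, adjacencies: list[np.ndarray]) -> float:
    """Graph entropy H(C) of a gene set over the networks of a subset.

    For each network and member gene, p = in-module weight / total
    weighted degree (0 when the gene is isolated); the per-gene binary
    entropies are summed over members and networks and divided by |C|.
    """
    member_idx = np.asarray(member_idx, dtype=int)
    if member_idx.size < 2:
        raise ValidationError("module entropy requires at least 2 genes")
    total = 0.0
    for A in adjacencies:
        deg = A.sum(axis=1)[member_idx]
        lin = A[np.ix_(member_idx, member_idx)].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(deg > 0, lin / np.where(deg > 0, deg, 1.0), 0.0)
        total += _binary_entropy(p).sum()
    return float(total / member_idx.size)


def expand_seed(
    seed_idx: int,
    adjacencies: list[np.ndarray],
    genes: list[str],
    subset: tuple[str, ...],
    max_size: int | None = None,
    csr: list | None = None,
) -> ModuleCandidate | None:
    """Grow one module from a seed by steepest entropy descent.

    The module is initialized as the seed's closed neighborhood (the
    seed plus every gene adjacent to it in at least one network of the
    subset) and repeatedly adds, among genes adjacent to the current
    module in at least one network, the gene whose addition decreases H
    the most, stopping when no addition strictly decreases it.

    The closed-neighborhood start matters: binary entropy peaks at
    in-module weight fraction 1/2, so from a bare seed pair inside a
    densely interconnected gene group every addition *raises* the
    objective (each member's in-fraction climbs toward 1/2 from below)
    and strict descent could never leave the pair.  Starting from the
    neighborhood places the search on the far side of that entropy
    barrier, where descent sharpens the module boundary instead.

    Returns None for a seed isolated in every network of the subset.
    """
    n = adjacencies[0].shape[0]
    summed = sum(A[seed_idx] for A in adjacencies)
    summed[seed_idx] = 0.0
    if summed.max() <= 0:
        logger.warning("seed %s is isolated in all networks of the subset; skipped", genes[seed_idx])
        return None
    neighbors = np.nonzero(summed > 0)[0]
    if max_size is not None and neighbors.size + 1 > max_size:
        order = np.lexsort((np.array(genes)[neighbors], -summed[neighbors]))
        neighbors = neighbors[order[: max_size - 1]]
    members = [seed_idx] + [int(i) for i in neighbors]

    degs = [A.sum(axis=1) for A in adjacencies]
    # lin[k][v] = total weight between gene v and the current module in network k
    lins = [A[:, members].sum(axis=1) for A in adjacencies]
    member_mask = np.zeros(n, dtype=bool)
    member_mask[members] = True

    def current_entropy() -> float:
        total = 0.0
        for lin, deg in zip(lins, degs):
            p = np.where(deg[members] > 0, lin[members] / np.where(deg[members] > 0, deg[members], 1.0), 0.0)
            total += _binary_entropy(p).sum()
        return float(total / len(members))

    H = current_entropy()
    trace = [("<init>", H)]

    if csr is None:
        from scipy.sparse import csr_matrix

        csr = [csr_matrix(A) for A in adjacencies]
    csr_arrays = [(S.indptr, S.indices, S.data) for S in csr]
    # member_pos[g] = position of gene g in the member list, else -1
    member_pos = np.full(n, -1, dtype=np.int64)
    member_pos[members] = np.arange(len(members))

    gene_order = np.array(genes)
    while True:
        adjacent = np.zeros(n, dtype=bool)
        for lin in lins:
            adjacent |= lin > 0
        adjacent &= ~member_mask
        cand = np.nonzero(adjacent)[0]
        if cand.size == 0 or (max_size is not None and len(members) >= max_size):
            break
        # H after adding each candidate.  Only members actually adjacent
        # to a candidate change their entropy term, so the update walks
        # the candidates' sparse rows: start from the current member
        # entropy sum and correct the affected (member, candidate) pairs.
        newH = np.zeros(cand.size)
        midx = np.array(members)
        for (indptr, indices, data), lin, deg in zip(csr_arrays, lins, degs):
            dm = deg[midx]
            safe_dm = np.where(dm > 0, dm, 1.0)
            p_old = np.where(dm > 0, lin[midx] / safe_dm, 0.0)
            h_old = _binary_entropy(p_old)
            contrib = np.full(cand.size, h_old.sum())
            starts = indptr[cand]
            counts = indptr[cand + 1] - starts
            total = int(counts.sum())
            if total:
                # flat positions of all candidate-row entries in the CSR
                base = np.repeat(starts, counts)
                excl = np.concatenate(([0], np.cumsum(counts[:-1])))
                flat = base + (np.arange(total) - np.repeat(excl, counts))
                mcols = member_pos[indices[flat]]
                hit = mcols >= 0
                if hit.any():
                    rows_h = np.repeat(np.arange(cand.size), counts)[hit]
                    mcols_h = mcols[hit]
                    w_h = data[flat][hit]
                    p_new = np.where(
                        dm[mcols_h] > 0, (lin[midx][mcols_h] + w_h) / safe_dm[mcols_h], 0.0
                    )
                    np.add.at(contrib, rows_h, _binary_entropy(p_new) - h_old[mcols_h])
            newH += contrib
            dc = deg[cand]
            pc = np.where(dc > 0, lin[cand] / np.where(dc > 0, dc, 1.0), 0.0)
            newH += _binary_entropy(pc)
        newH /= len(members) + 1
        order = np.lexsort((gene_order[cand], newH))
        pick = order[0]
        if newH[pick] >= H - DESCENT_EPS:
            break
        chosen = int(cand[pick])
        members.append(chosen)
        member_mask[chosen] = True
        member_pos[chosen] = len(members) - 1
        for k, A in enumerate(adjacencies):
            lins[k] = lins[k] + A[:, chosen]
        H = float(newH[pick])
        trace.append((genes[chosen], H))

    module_genes = tuple(sorted(genes[i] for i in members))
    return ModuleCandidate(
        genes=module_genes, subset=subset, entropy=H, seed=genes[seed_idx], trace=trace
    )


def refine_candidates(
    candidates: list[ModuleCandidate],
    adjacencies: list[np.ndarray],
    genes: list[str],
    min_size: int = 5,
    jaccard: float = 0.5,
) -> list[ModuleCandidate]:
    """Drop undersized candidates, then merge overlapping ones.

    The pair with the highest Jaccard index >= the threshold is merged
    (set union, entropy recomputed) repeatedly until no pair qualifies.
    Ties are broken by candidate input order, so the result is
    deterministic.
    """
    gene_index = {g: i for i, g in enumerate(genes)}
    pool = [c for c in candidates if c.size >= min_size]
    # deduplicate identical gene sets up front
    seen: dict[tuple[str, ...], ModuleCandidate] = {}
    for c in pool:
        seen.setdefault(c.genes, c)
    pool = list(seen.values())

    while len(pool) > 1:
        best_pair, best_j = None, jaccard
        for a, b in itertools.combinations(range(len(pool)), 2):
            j = jaccard_index(pool[a].genes, pool[b].genes)
            if j > best_j or (best_pair is None and j >= best_j):
                best_pair, best_j = (a, b), j
        if best_pair is None:
            break
        a, b = best_pair
        union = tuple(sorted(set(pool[a].genes) | set(pool[b].genes)))
        idx = np.array([gene_index[g] for g in union])
        merged = ModuleCandidate(
            genes=union,
            subset=pool[a].subset,
            entropy=module_entropy(idx, adjacencies),
            seed=pool[a].seed,
            trace=pool[a].trace + pool[b].trace,
        )
        pool = [c for k, c in enumerate(pool) if k not in (a, b)] + [merged]
    return pool


def _has_edges_everywhere(member_idx: np.ndarray, adjacencies: list[np.ndarray]) -> bool:
    """A module counts as present in a subset only if its induced
    subgraph is non-empty in every network of the subset (a gene set
    with no internal edges in some network is not a module there)."""
    for A in adjacencies:
        if not A[np.ix_(member_idx, member_idx)].any():
            return False
    return True


def search_subset(
    dcns: list[DCN],
    subset: tuple[str, ...],
    fraction: float = 0.10,
    min_size: int = 5,
    jaccard: float = 0.5,
    active: np.ndarray | None = None,
    max_size: int | None = None,
) -> tuple[list[ModuleCandidate], list[ModuleCandidate]]:
    """Run seed ranking + expansion + refinement on one network subset.

    Returns (refined candidates, raw expanded candidates).  Both lists
    are restricted to candidates whose induced subgraph has at least one
    edge in every network of the subset.

    Unless overridden, module size is bounded by half the active gene
    set: the entropy objective is exactly 0 for any union of whole
    connected components, so without a scale bound the degenerate answer
    "absorb everything reachable" would score as a perfect module (on
    randomized networks especially, where the active genes typically
    form one blob).  A gene set spanning most of the network is not a
    module; the same bound applies to real and null searches.
    """
    from scipy.sparse import csr_matrix

    genes = dcns[0].genes
    adjacencies = [d.adjacency for d in dcns]
    rankings = [node_importance(d) for d in dcns]
    if active is None:
        active = active_gene_mask(dcns)
    if max_size is None:
        max_size = max(2, math.ceil(0.5 * int(active.sum())))
    seeds = combine_rankings(rankings, fraction=fraction, active=active, genes=genes)

    csr = [csr_matrix(A) for A in adjacencies]
    raw: list[ModuleCandidate] = []
    seen: set[tuple[str, ...]] = set()
    gene_index = {g: i for i, g in enumerate(genes)}
    for s in seeds:
        cand = expand_seed(s, adjacencies, genes, subset, max_size=max_size, csr=csr)
        if cand is None:
            continue
        idx = np.array([gene_index[g] for g in cand.genes])
        if not _has_edges_everywhere(idx, adjacencies):
            continue
        if cand.genes not in seen:
            seen.add(cand.genes)
            raw.append(cand)
    refined = refine_candidates(raw, adjacencies, genes, min_size=min_size, jaccard=jaccard)
    refined = [
        c
        for c in refined
        if _has_edges_everywhere(np.array([gene_index[g] for g in c.genes]), adjacencies)
    ]
    return refined, raw


def discover_mdms(
    dcns: list[DCN],
    fraction: float = 0.10,
    min_size: int = 5,
    jaccard: float = 0.5,
    n_rand: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    swaps_per_edge: int = 10,
) -> list[MDM]:
    """Discover significant modules at every level across M networks.

    Every non-empty subset S of the networks is searched; each subset's
    candidates get empirical p-values against module scores found on
    degree-preserved randomizations of the subset's networks
    (:mod:`mdmodules.significance`); Benjamini-Hochberg correction is
    applied jointly across all subsets; and each surviving module is
    assigned to its maximal subset — a module significant for S is
    discarded when a module significant for a strict superset of S
    matches it at the Jaccard threshold.
    """
    from .significance import bh_adjust, null_score_pool

    M = len(dcns)
    if M < 1:
        raise ValidationError("at least one network is required")
    if M > MAX_NETWORKS:
        raise ValidationError(f"subset enumeration is guarded at {MAX_NETWORKS} networks")
    if rng is None:
        rng = np.random.default_rng()
    genes = dcns[0].genes
    for d in dcns:
        if d.genes != genes:
            raise ValidationError("all networks must share one ordered gene set")

    records: list[MDM] = []  # provisional modules across all subsets
    counter = 0
    for size in range(M, 0, -1):
        for combo in itertools.combinations(range(M), size):
            sub_dcns = [dcns[k] for k in combo]
            if any(d.n_edges == 0 for d in sub_dcns):
                logger.warning(
                    "subset %s skipped: a network has no edges",
                    tuple(dcns[k].condition for k in combo),
                )
                continue
            subset = tuple(dcns[k].condition for k in combo)
            refined, _ = search_subset(
                sub_dcns, subset, fraction=fraction, min_size=min_size, jaccard=jaccard
            )
            if not refined:
                continue
            null_scores = null_score_pool(
                sub_dcns,
                n_rand=n_rand,
                rng=rng,
                fraction=fraction,
                min_size=min_size,
                jaccard=jaccard,
                swaps_per_edge=swaps_per_edge,
            )
            if null_scores.size == 0:
                logger.warning(
                    "subset %s: empty null score pool; p-values degenerate to 1", subset
                )
            for cand in refined:
                p = (1.0 + float((null_scores <= cand.entropy + DESCENT_EPS).sum())) / (
                    1.0 + null_scores.size
                )
                records.append(
                    MDM(
                        module_id=f"M{counter:04d}",
                        genes=cand.genes,
                        subset=subset,
                        entropy=cand.entropy,
                        p_value=min(p, 1.0),
                        provenance=(cand.seed,),
                    )
                )
                counter += 1

    if not records:
        return []
    adj = bh_adjust([m.p_value for m in records])
    records = [
        replace(m, adj_p_value=float(a), significant=bool(a <= alpha))
        for m, a in zip(records, adj)
    ]
    significant = [m for m in records if m.significant]

    # maximal-subset level assignment
    kept: list[MDM] = []
    for m in significant:
        shadowed = False
        for other in significant:
            if set(m.subset) < set(other.subset) and jaccard_index(m.genes, other.genes) >= jaccard:
                shadowed = True
                break
        if not shadowed:
            kept.append(m)
    kept.sort(key=lambda m: (-m.level, m.module_id))
    return kept
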