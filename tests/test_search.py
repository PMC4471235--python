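"""Seed ranking, graph entropy, greedy expansion and refinement."""

import math

import numpy as np
import pytest

from mdmodules.datatypes import ModuleCandidate, ValidationError
from mdmodules.search import (
    combine_rankings,
    expand_seed,
    module_entropy,
    node_importance,
    refine_candidates,
    search_subset,
)
from tests.conftest import clique_adjacency, make_dcn


class TestNodeImportance:
    def test_star_hub_exceeds_leaves(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1.0
        g = node_importance(make_dcn(A))
        assert g[0] > g[1]
        assert np.allclose(g[1:], g[1])
        assert g.sum() == pytest.approx(1.0)

    def test_two_equal_triangles_share_importance(self):
        A = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            A[a, b] = A[b, a] = 0.6
        g = node_importance(make_dcn(A))
        # automorphism forces equality within (and here across) components
        assert np.allclose(g, g[0])

    def test_matches_dense_eigensolver_on_connected_graph(self):
        rng = np.random.default_rng(0)
        n = 10
        A = np.zeros((n, n))
        for i in range(1, n):  # random spanning tree keeps it connected
            j = rng.integers(0, i)
            A[i, j] = A[j, i] = rng.uniform(0.2, 1.0)
        for _ in range(8):
            i, j = rng.integers(0, n, 2)
            if i != j:
                w = rng.uniform(0.2, 1.0)
                A[i, j] = A[j, i] = w
        g = node_importance(make_dcn(A))
        d = A.sum(axis=1)
        M = A / np.sqrt(np.outer(d, d))
        evals, evecs = np.linalg.eigh(M)
        lead = np.abs(evecs[:, np.argmax(evals)])
        assert np.allclose(g, lead / lead.sum(), atol=1e-8)

    def test_isolated_genes_get_zero(self, clique_factory):
        A = clique_factory(8, 5)
        g = node_importance(make_dcn(A))
        assert (g[5:] == 0).all()
        assert (g[:5] > 0).all()

    def test_edgeless_network_is_fatal(self):
        with pytest.raises(ValidationError):
            node_importance(make_dcn(np.zeros((4, 4))))


class TestCombineRankings:
    def test_single_network_preserves_importance_order(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0.01, 1, 20)
        g /= g.sum()
        seeds = combine_rankings([g], fraction=0.5, active=np.ones(20, bool))
        assert seeds == list(np.argsort(-g)[:10])

    def test_seed_count_is_ceil_of_fraction(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(0.01, 1, 60)
        active = np.ones(60, bool)
        assert len(combine_rankings([g], fraction=0.10, active=active)) == 6
        assert len(combine_rankings([g], fraction=0.10, active=np.arange(60) < 55)) == math.ceil(5.5)

    def test_dominant_gene_is_first_seed(self):
        rng = np.random.default_rng(3)
        rankings = []
        for _ in range(3):
            g = rng.uniform(0.0, 0.1, 30)
            g[7] = 1.0
            rankings.append(g / g.sum())
        seeds = combine_rankings(rankings, fraction=0.1, active=np.ones(30, bool))
        assert seeds[0] == 7


class TestModuleEntropy:
    def test_isolated_clique_has_zero_entropy(self, clique_factory):
        A = clique_factory(10, 6)
        assert module_entropy(np.arange(6), [A]) == pytest.approx(0.0)

    def test_half_split_gene_contributes_log_two(self):
        # gene 0: one edge inside the module, one of equal weight outside
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 0.4
        A[0, 2] = A[2, 0] = 0.4
        H = module_entropy(np.array([0, 1]), [A])
        # gene 0 term = log 2, gene 1 term = 0 (all weight inside)
        assert H == pytest.approx(np.log(2) / 2)

    def test_brute_force_oracle_on_toy_graph(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(0, 1, (6, 6))
        A = np.triu(A, 1) * (rng.uniform(size=(6, 6)) < 0.7)
        A = A + A.T
        B = rng.uniform(0, 1, (6, 6))
        B = np.triu(B, 1) * (rng.uniform(size=(6, 6)) < 0.7)
        B = B + B.T
        C = np.array([0, 2, 5])
        total = 0.0
        for M in (A, B):
            for i in C:
                lin = sum(M[i, j] for j in C if j != i)
                lbar = sum(M[i, j] for j in range(6) if j not in C)
                denom = lin + lbar
                p = lin / denom if denom > 0 else 0.0
                if 0 < p < 1:
                    total += -p * np.log(p) - (1 - p) * np.log(1 - p)
        assert module_entropy(C, [A, B]) == pytest.approx(total / 3, abs=1e-12)

    def test_entropy_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mats = [
                (lambda X: (np.triu(X, 1) + np.triu(X, 1).T))(rng.uniform(0, 1, (8, 8)))
                for _ in range(3)
            ]
            C = rng.choice(8, size=4, replace=False)
            H = module_entropy(C, mats)
            assert 0.0 <= H <= 3 * np.log(2) + 1e-12


class TestExpandSeed:
    def test_recovers_planted_near_clique(self, clique_factory):
        rng = np.random.default_rng(6)
        A = clique_factory(30, 10, weight=0.9)
        # weak background ring among the remaining genes
        for i in range(10, 29):
            A[i, i + 1] = A[i + 1, i] = 0.15
        genes = [f"g{i:02d}" for i in range(30)]
        cand = expand_seed(3, [A], genes, ("c1",))
        planted = set(genes[:10])
        assert len(planted & set(cand.genes)) >= 8

    def test_steps_match_exhaustive_reevaluation(self):
        # replay the greedy trace, recomputing every candidate's entropy
        # from scratch with module_entropy at each step
        rng = np.random.default_rng(7)
        n = 9
        A = np.triu(rng.uniform(0.1, 1, (n, n)) * (rng.uniform(size=(n, n)) < 0.5), 1)
        A = A + A.T
        genes = [f"g{i}" for i in range(n)]
        cand = expand_seed(0, [A], genes, ("c1",))
        if cand is None:
            pytest.skip("seed isolated in this draw")
        gi = {g: k for k, g in enumerate(genes)}
        summed = A[0].copy()
        current = {0} | {int(i) for i in np.nonzero(summed > 0)[0]}
        for gene, recorded_H in cand.trace[1:]:
            candidates = {
                v
                for v in range(n)
                if v not in current and A[list(current), v].sum() > 0
            }
            best = None
            for v in sorted(candidates, key=lambda v: genes[v]):
                H = module_entropy(np.array(sorted(current | {v})), [A])
                if best is None or H < best[1] - 1e-15:
                    best = (v, H)
            assert best is not None
            assert genes[best[0]] == gene
            assert recorded_H == pytest.approx(best[1], abs=1e-9)
            current.add(gi[gene])
        assert set(cand.genes) == {genes[i] for i in current}

    def test_trace_strictly_decreases(self, small_dcns):
        subset = tuple(d.condition for d in small_dcns)
        _, raw = search_subset(small_dcns, subset)
        assert raw
        for cand in raw:
            hs = [h for _, h in cand.trace]
            assert all(b < a for a, b in zip(hs, hs[1:]))

    def test_never_crosses_between_components(self, clique_factory):
        A = clique_factory(12, 5) + clique_factory(12, 5, offset=6)
        genes = [f"g{i:02d}" for i in range(12)]
        cand = expand_seed(0, [A], genes, ("c1",))
        assert set(cand.genes) <= set(genes[:5])

    def test_isolated_seed_returns_none(self):
        A = np.zeros((4, 4))
        A[1, 2] = A[2, 1] = 0.5
        assert expand_seed(0, [A], ["a", "b", "c", "d"], ("c1",)) is None


class TestRefineCandidates:
    def _cand(self, genes, subset=("c1",), H=0.1):
        return ModuleCandidate(genes=tuple(sorted(genes)), subset=subset, entropy=H, seed=genes[0])

    def test_identical_candidates_merge_to_one(self, clique_factory):
        A = clique_factory(10, 6)
        genes = [f"g{i:02d}" for i in range(10)]
        cands = [self._cand(genes[:6]), self._cand(genes[:6])]
        out = refine_candidates(cands, [A], genes)
        assert len(out) == 1

    def test_low_jaccard_pair_not_merged(self):
        genes = [f"g{i:02d}" for i in range(12)]
        A = np.zeros((12, 12))
        a = self._cand(genes[0:6])
        b = self._cand(genes[3:12])  # overlap 3, union 12 -> J = 0.25
        out = refine_candidates([a, b], [A + A.T], genes, min_size=5, jaccard=0.5)
        assert len(out) == 2

    def test_undersized_candidate_removed(self):
        genes = [f"g{i:02d}" for i in range(8)]
        out = refine_candidates([self._cand(genes[:4])], [np.zeros((8, 8))], genes, min_size=5)
        assert out == []

    def test_merge_recomputes_entropy(self, clique_factory):
        A = clique_factory(10, 6, weight=0.9)
        genes = [f"g{i:02d}" for i in range(10)]
        a = self._cand(genes[0:5], H=0.3)
        b = self._cand(genes[1:6], H=0.3)
        out = refine_candidates([a, b], [A], genes)
        assert len(out) == 1
        assert out[0].genes == tuple(genes[:6])
        assert out[0].entropy == pytest.approx(module_entropy(np.arange(6), [A]))


class TestRelabelingEquivariance:
    def test_order_preserving_relabel_permutes_output(self, clique_factory):
        rng = np.random.default_rng(8)
        n = 20
        A = clique_factory(n, 7, weight=0.9)
        for _ in range(10):
            i, j = rng.integers(0, n, 2)
            if i != j and A[i, j] == 0:
                A[i, j] = A[j, i] = rng.uniform(0.1, 0.5)
        genes = [f"g{i:02d}" for i in range(n)]
        # reverse the vertex storage order and rename g<k> -> x<k>; the
        # renaming preserves lexicographic gene order, so documented
        # tie-breaks behave identically and outputs must map exactly
        perm = np.arange(n)[::-1]
        A2 = A[np.ix_(perm, perm)]
        genes2 = [f"x{perm[k]:02d}" for k in range(n)]
        r1, _ = search_subset([make_dcn(A, genes=genes)], ("c1",))
        r2, _ = search_subset([make_dcn(A2, genes=genes2)], ("c1",))
        mapped = [tuple(sorted("x" + g[1:] for g in c.genes)) for c in r1]
        assert sorted(mapped) == sorted(c.genes for c in r2)
        for c1, c2 in zip(sorted(r1, key=lambda c: c.entropy), sorted(r2, key=lambda c: c.entropy)):
            assert c1.entropy == pytest.approx(c2.entropy, abs=1e-10)
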