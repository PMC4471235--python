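"""Module-level statistics: activity, regulation, phenotype correlation,
enrichment and rewiring exports."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mdmodules as md
from mdmodules.datatypes import MDM, GeneSetCollection, PhenotypeTable
from mdmodules.modstats import (
    edge_delta_export,
    fisher_significant_fraction,
    hypergeometric_enrichment,
    mean_edge_weight,
    module_activity,
    phenotype_correlation,
    regulation_call,
)
from tests.conftest import clique_adjacency, make_dcn


def _mdm(genes, subset=("c1",)):
    return MDM(module_id="m", genes=tuple(genes), subset=tuple(subset), entropy=0.0)


def _panel(data, conditions, times, reps, baseline="ctrl"):
    cols = pd.MultiIndex.from_tuples(
        [(c, t, f"r{k}") for c in conditions for t in times for k in range(reps)],
        names=["condition", "time", "replicate"],
    )
    genes = [f"g{i:02d}" for i in range(data.shape[0])]
    return md.ExpressionPanel(
        values=pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=cols),
        baseline=baseline,
    )


class TestMeanEdgeWeight:
    def test_constant_weights(self):
        dcn = make_dcn(clique_adjacency(8, 5, weight=0.5))
        assert mean_edge_weight(_mdm(dcn.genes[:5]), dcn) == pytest.approx(0.5)

    def test_hand_mean(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 0.2
        A[1, 2] = A[2, 1] = 0.4
        dcn = make_dcn(A)
        assert mean_edge_weight(_mdm(dcn.genes[:3]), dcn) == pytest.approx(0.3)

    def test_no_edges_is_missing_not_zero(self):
        dcn = make_dcn(np.zeros((4, 4)))
        assert np.isnan(mean_edge_weight(_mdm(dcn.genes[:3]), dcn))

    def test_dense_mean_includes_absent_pairs(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 0.6
        dcn = make_dcn(A)
        assert mean_edge_weight(_mdm(dcn.genes[:3]), dcn, dense=True) == pytest.approx(0.2)


class TestModuleActivity:
    def test_single_gene_module_is_its_mean_z(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 5, (3, 12))
        panel = _panel(data, ("ctrl", "dis"), ("t1", "t2"), 3)
        prof = module_activity(_mdm(["g00"]), panel)
        z = (data[0] - data[0].mean()) / data[0].std(ddof=1)
        expected = z[:3].mean()  # first (condition, time) cell
        assert prof.activity.iloc[0] == pytest.approx(expected)

    def test_mirror_profiles_cancel(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(-1, 1, 12)
        data = np.vstack([5 + base, 5 - base])
        panel = _panel(data, ("ctrl", "dis"), ("t1", "t2"), 3)
        prof = module_activity(_mdm(["g00", "g01"]), panel)
        assert np.allclose(prof.activity.to_numpy(), 0.0, atol=1e-12)

    def test_matches_two_step_averaging_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(1, 9, (5, 16))
        panel = _panel(data, ("ctrl", "dis"), ("t1", "t2"), 4)
        prof = module_activity(_mdm([f"g{i:02d}" for i in range(5)]), panel)
        z = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, ddof=1, keepdims=True)
        for k, (cond, time) in enumerate(prof.activity.index):
            cols = [
                j
                for j, (c, t, _) in enumerate(panel.values.columns)
                if c == cond and t == time
            ]
            assert prof.activity.iloc[k] == pytest.approx(z[:, cols].mean(axis=1).mean())


class TestRegulationCall:
    def _shifted_panel(self, shift):
        rng = np.random.default_rng(3)
        n = 10
        base = rng.uniform(5, 6, (n, 8))
        dis = base[:, :8].copy() + shift
        data = np.hstack([base, dis])
        return _panel(data, ("ctrl", "dis"), ("t1", "t2"), 4)

    def test_upshift_called_up(self):
        panel = self._shifted_panel(+2.0)
        call, p = regulation_call(_mdm([f"g{i:02d}" for i in range(10)]), panel, "dis", "t1")
        assert call == "up" and p < 0.01

    def test_downshift_called_down(self):
        panel = self._shifted_panel(-2.0)
        call, p = regulation_call(_mdm([f"g{i:02d}" for i in range(10)]), panel, "dis", "t1")
        assert call == "down" and p < 0.01

    def test_identical_groups_called_none(self):
        panel = self._shifted_panel(0.0)
        call, _ = regulation_call(_mdm([f"g{i:02d}" for i in range(10)]), panel, "dis", "t1")
        assert call == "none"


class TestPhenotypeCorrelation:
    def _profile_and_pheno(self, transform):
        rng = np.random.default_rng(4)
        idx = pd.MultiIndex.from_product(
            [["c1", "c2"], ["t1", "t2", "t3"]], names=["condition", "time"]
        )
        activity = pd.Series(rng.standard_normal(6), index=idx, name="m")
        pheno = PhenotypeTable(pd.DataFrame({"meas": transform(activity.to_numpy())}, index=idx))
        from mdmodules.modstats import ModuleActivityProfile

        return ModuleActivityProfile("m", activity), pheno

    def test_self_correlation_is_one(self):
        prof, pheno = self._profile_and_pheno(lambda a: a.copy())
        assert phenotype_correlation(prof, pheno, "meas") == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        prof, pheno = self._profile_and_pheno(lambda a: -a)
        assert phenotype_correlation(prof, pheno, "meas") == pytest.approx(-1.0)

    def test_affine_invariance(self):
        prof, pheno = self._profile_and_pheno(lambda a: 3.0 * a - 7.0)
        assert phenotype_correlation(prof, pheno, "meas") == pytest.approx(1.0)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(5)
        prof, pheno = self._profile_and_pheno(lambda a: a + rng.standard_normal(a.size))
        r = phenotype_correlation(prof, pheno, "meas")
        expected = stats.pearsonr(prof.activity.to_numpy(), pheno.measures["meas"].to_numpy()).statistic
        assert r == pytest.approx(expected)

    def test_too_few_cells_is_missing(self):
        prof, pheno = self._profile_and_pheno(lambda a: a.copy())
        short = PhenotypeTable(pheno.measures.iloc[:2])
        assert np.isnan(phenotype_correlation(prof, short, "meas"))

    def test_condition_restriction(self):
        prof, pheno = self._profile_and_pheno(lambda a: a.copy())
        r = phenotype_correlation(prof, pheno, "meas", conditions=["c1"])
        assert r == pytest.approx(1.0)


class TestEnrichment:
    def test_identical_module_hits_closed_form(self):
        universe = [f"g{i:04d}" for i in range(1000)]
        coll = GeneSetCollection(sets={"ref": universe[:10]}, universe=universe)
        res = hypergeometric_enrichment([_mdm(universe[:10])], coll)
        expected = 1.0 / comb(1000, 10)
        assert res.table["p_value"].iloc[0] == pytest.approx(expected, rel=1e-6)
        assert res.specificity == 1.0 and res.sensitivity == 1.0

    def test_disjoint_module_contributes_nothing(self):
        universe = [f"g{i:04d}" for i in range(100)]
        coll = GeneSetCollection(sets={"ref": universe[:10]}, universe=universe)
        res = hypergeometric_enrichment([_mdm(universe[50:60])], coll)
        assert res.specificity == 0.0

    def test_tail_probability_decreases_with_overlap(self):
        N, K, n = 100, 20, 10
        ps = [stats.hypergeom.sf(k - 1, N, K, n) for k in range(0, n + 1)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_fisher_matches_exact_enumeration(self):
        # 8/10 vs 2/10 significant, one-sided toward group A
        p = fisher_significant_fraction(8, 10, 2, 10)
        total = sum(
            stats.hypergeom.pmf(k, 20, 10, 10) for k in range(8, 11)
        )
        assert p == pytest.approx(total, rel=1e-10)


class TestEdgeDeltaExport:
    def test_identical_networks_export_nothing(self, clique_factory):
        A = clique_factory(6, 4, weight=0.5)
        d1, d2 = make_dcn(A, "c1"), make_dcn(A.copy(), "c2")
        out = edge_delta_export(_mdm(d1.genes[:4], ("c1", "c2")), d1, d2, min_delta=0.01)
        assert out.empty

    def test_single_changed_edge_detected(self, clique_factory):
        A = clique_factory(6, 4, weight=0.5)
        B = A.copy()
        B[0, 1] = B[1, 0] = 0.8
        d1, d2 = make_dcn(A, "c1"), make_dcn(B, "c2")
        out = edge_delta_export(_mdm(d1.genes[:4], ("c1", "c2")), d1, d2, min_delta=0.2)
        assert len(out) == 1
        assert out["delta"].iloc[0] == pytest.approx(0.3)

    def test_deltas_match_matrix_subtraction(self):
        rng = np.random.default_rng(6)
        X = np.triu(rng.uniform(0, 1, (5, 5)), 1)
        A = X + X.T
        Y = np.triu(rng.uniform(0, 1, (5, 5)), 1)
        B = Y + Y.T
        d1, d2 = make_dcn(A, "c1"), make_dcn(B, "c2")
        genes = sorted(d1.genes)
        out = edge_delta_export(_mdm(genes, ("c1", "c2")), d1, d2, min_delta=0.0)
        from mdmodules.dynamics import component_adjacency

        D = component_adjacency(genes, d2) - component_adjacency(genes, d1)
        for a, b, wa, wb, delta in out.itertuples(index=False):
            i, j = genes.index(a), genes.index(b)
            assert delta == pytest.approx(D[i, j])
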