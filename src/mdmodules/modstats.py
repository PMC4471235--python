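"""Module-level downstream statistics.

Differential activity (mean edge weight), per-time-point up/down
regulation calls, module activity and its correlation with phenotype
measures, hypergeometric enrichment against reference gene sets with
collection-level specificity/sensitivity, and the per-edge weight-change
export behind rewiring displays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    MDM,
    ExpressionPanel,
    GeneSetCollection,
    PhenotypeTable,
    ValidationError,
)
from .network import DCN
from .significance import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "mean_edge_weight",
    "ModuleActivityProfile",
    "module_activity",
    "regulation_call",
    "phenotype_correlation",
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "fisher_significant_fraction",
    "edge_delta_export",
]


def mean_edge_weight(mdm: MDM, dcn: DCN, dense: bool = False) -> float:
    """Average weight of the module's internal edges in one network.

    The edge weight measures how differentially expressed the endpoint
    genes are, so this average is a per-network differential-activity
    summary of the module.  By default only edges actually present are
    averaged (absent pairs carry weight 0 by construction and would
    conflate sparsity with activity); ``dense=True`` averages over all
    gene pairs instead.  A module with no internal edges yields NaN.
    """
    sub = dcn.induced(sorted(mdm.genes))
    iu = np.triu_indices(sub.shape[0], k=1)
    weights = sub[iu]
    if dense:
        return float(weights.mean()) if weights.size else float("nan")
    present = weights[weights > 0]
    if present.size == 0:
        logger.warning("module %s has no internal edges in %s", mdm.module_id, dcn.condition)
        return float("nan")
    return float(present.mean())


@dataclass
class ModuleActivityProfile:
    """Mean z-scored expression of a module per (condition, time)."""

    module_id: str
    activity: pd.Series  # MultiIndex (condition, time)
    regulation: pd.DataFrame = field(default_factory=pd.DataFrame)


def _zscore_panel(panel: ExpressionPanel) -> pd.DataFrame:
    """Per-gene z-score across all samples of all conditions; genes with
    zero variance are dropped with a warning."""
    vals = panel.values
    sd = vals.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance gene(s) excluded from activity", int(flat.sum()))
    vals = vals.loc[~flat]
    return vals.sub(vals.mean(axis=1), axis=0).div(sd[~flat], axis=0)


def module_activity(mdm: MDM, panel: ExpressionPanel) -> ModuleActivityProfile:
    """Module activity: average normalized expression of member genes.

    Expression is z-scored per gene across all samples; within every
    (condition, time) cell the replicate values are averaged per gene
    and then averaged over member genes.
    """
    missing = [g for g in mdm.genes if g not in panel.values.index]
    if missing:
        raise ValidationError(f"module genes absent from panel: {missing[:5]}")
    z = _zscore_panel(panel)
    members = [g for g in mdm.genes if g in z.index]
    zmod = z.loc[members]
    # average replicates within each (condition, time) cell, then genes
    cell_means = zmod.T.groupby(level=["condition", "time"], sort=False).mean().T
    activity = cell_means.mean(axis=0)
    activity.name = mdm.module_id
    return ModuleActivityProfile(module_id=mdm.module_id, activity=activity)


def regulation_call(
    mdm: MDM,
    panel: ExpressionPanel,
    condition: str,
    time: str,
    p_cut: float = 0.01,
    unit: str = "gene",
) -> tuple[str, float]:
    """Up/down/none regulation of a module at one (condition, time).

    With the default gene-level unit, each member gene contributes its
    mean expression difference (condition minus baseline, averaged over
    replicates) and a two-sided one-sample t-test asks whether these
    per-gene differences center at zero.  ``unit='replicate'`` pools all
    gene x replicate values into a two-sample Welch test instead.
    Returns (call, p-value); the call is 'up' or 'down' only when
    p < ``p_cut``.
    """
    cond_vals = panel.cell_matrix(condition, time).loc[list(mdm.genes)]
    base_vals = panel.cell_matrix(panel.baseline, time).loc[list(mdm.genes)]
    if cond_vals.shape[1] == 0 or base_vals.shape[1] == 0:
        return "none", float("nan")
    if unit == "gene":
        diffs = cond_vals.mean(axis=1) - base_vals.mean(axis=1)
        if len(diffs) < 2:
            return "none", float("nan")
        tstat, p = stats.ttest_1samp(diffs.to_numpy(), 0.0)
        direction = float(diffs.mean())
    elif unit == "replicate":
        a = cond_vals.to_numpy().ravel()
        b = base_vals.to_numpy().ravel()
        if a.size < 2 or b.size < 2:
            return "none", float("nan")
        tstat, p = stats.ttest_ind(a, b, equal_var=False)
        direction = float(a.mean() - b.mean())
    else:
        raise ValidationError(f"unknown test unit {unit!r}")
    if np.isnan(p) or p >= p_cut:
        return "none", float(p)
    return ("up" if direction > 0 else "down"), float(p)


def phenotype_correlation(
    profile: ModuleActivityProfile,
    pheno: PhenotypeTable,
    measure: str,
    conditions: list[str] | None = None,
    fs_invert: list[str] | None = None,
) -> float:
    """Pearson correlation between module activity and one phenotype
    measure across matched (condition, time) cells.

    ``conditions`` restricts to the conditions the module was derived
    from.  ``fs_invert`` lists fraction-type measures to replace by
    1 - value (with per-measure z-scoring) before correlating, for
    measures whose clinical polarity is inverted.  Returns NaN with
    fewer than 3 matched cells.
    """
    table = pheno.transformed(invert=fs_invert) if fs_invert else pheno
    series = table.measures[measure]
    act = profile.activity
    if conditions is not None:
        act = act[act.index.get_level_values("condition").isin(conditions)]
    act_idx = {(str(c), str(t)): v for (c, t), v in act.items()}
    pairs = [
        (act_idx[(str(c), str(t))], v)
        for (c, t), v in series.items()
        if (str(c), str(t)) in act_idx and np.isfinite(v)
    ]
    if len(pairs) < 3:
        return float("nan")
    a, b = np.array(pairs).T
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class EnrichmentResult:
    """Per (module, gene set) hypergeometric overlap tests plus the
    collection-level specificity and sensitivity."""

    table: pd.DataFrame
    specificity: float
    sensitivity: float
    alpha: float


def hypergeometric_enrichment(
    mdms: list[MDM], collection: GeneSetCollection, alpha: float = 0.05
) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap of every module against every
    reference set, BH-corrected over all pairs.

    Specificity is the fraction of modules significantly overlapping at
    least one reference set; sensitivity is the fraction of reference
    sets hit by at least one module.
    """
    universe = set(collection.universe)
    if not universe:
        raise ValidationError("background universe is empty")
    N = len(universe)
    rows = []
    for m in mdms:
        mod = set(m.genes) & universe
        for name, ref in collection.sets.items():
            refset = set(ref)
            k = len(mod & refset)
            p = stats.hypergeom.sf(k - 1, N, len(refset), len(mod)) if mod else 1.0
            rows.append((m.module_id, name, k, float(p)))
    table = pd.DataFrame(rows, columns=["module_id", "gene_set", "overlap", "p_value"])
    if len(table):
        table["adj_p_value"] = bh_adjust(table["p_value"].tolist())
        table["significant"] = table["adj_p_value"] <= alpha
    else:
        table["adj_p_value"] = []
        table["significant"] = []
    sig = table[table["significant"]] if len(table) else table
    specificity = (
        sig["module_id"].nunique() / len(mdms) if mdms else float("nan")
    )
    sensitivity = (
        sig["gene_set"].nunique() / len(collection.sets) if collection.sets else float("nan")
    )
    return EnrichmentResult(table=table, specificity=specificity, sensitivity=sensitivity, alpha=alpha)


def fisher_significant_fraction(
    n_sig_a: int, n_tot_a: int, n_sig_b: int, n_tot_b: int
) -> float:
    """One-sided Fisher exact p that group A's significant fraction
    exceeds group B's — the comparison used to benchmark two module
    catalogs against each other."""
    table = [[n_sig_a, n_tot_a - n_sig_a], [n_sig_b, n_tot_b - n_sig_b]]
    return float(stats.fisher_exact(table, alternative="greater").pvalue)


def edge_delta_export(
    mdm: MDM, dcn_a: DCN, dcn_b: DCN, min_delta: float = 0.0
) -> pd.DataFrame:
    """Within-module edges whose weight changes by at least ``min_delta``
    between two networks, signed as (b - a), sorted by |delta| descending
    — the data behind module rewiring displays."""
    genes = sorted(mdm.genes)
    A = dcn_a.induced(genes)
    B = dcn_b.induced(genes)
    D = B - A
    iu, ju = np.triu_indices(len(genes), k=1)
    rows = []
    for i, j in zip(iu, ju):
        if abs(D[i, j]) >= min_delta and (A[i, j] > 0 or B[i, j] > 0):
            rows.append((genes[i], genes[j], A[i, j], B[i, j], D[i, j]))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight_a", "weight_b", "delta"])
    return df.reindex(df["delta"].abs().sort_values(ascending=False).index).reset_index(drop=True)
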