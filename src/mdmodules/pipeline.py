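"""End-to-end pipeline: networks -> modules -> significance -> dynamics
-> module statistics -> report.

All randomness flows from one configured seed, split deterministically
per stage, so identical configuration yields a byte-identical module
table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .datatypes import MDM, ValidationError
from .dynamics import mcds, mcds_significance
from .modstats import (
    hypergeometric_enrichment,
    mean_edge_weight,
    module_activity,
    phenotype_correlation,
    regulation_call,
)
from .network import build_dcn, select_delta
from .search import discover_mdms

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "build_networks"]


class ConfigError(ValidationError):
    pass


@dataclass
class RunConfig:
    """Run configuration; ``delta`` has no default on purpose — the
    correlation threshold is a modeling decision the user must make
    (or delegate to ``delta_grid`` selection)."""

    expression: str = ""
    de_pvalues: str = ""
    out_dir: str = "results"
    delta: float | None = None
    delta_grid: list[float] = field(default_factory=list)
    phenotype: str | None = None
    gene_sets: str | None = None
    seed: int = 0
    seed_fraction: float = 0.10
    min_size: int = 5
    jaccard: float = 0.5
    n_rand: int = 100
    alpha: float = 0.05
    mcds_n_rand: int = 100
    mcds_alpha: float = 0.05
    norm: str = "spectral"
    pairing: str = "allpairs"
    swaps_per_edge: int = 10
    p_cut: float = 0.01
    min_delta: float = 0.1
    fs_invert: list[str] = field(default_factory=list)
    log_transform: bool = False
    conditioning_cap: int | None = None
    impute_missing: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.expression:
            raise ConfigError("configuration must name an expression file")
        if not self.de_pvalues:
            raise ConfigError("configuration must name a DE p-value file")
        if self.delta is None and not self.delta_grid:
            raise ConfigError("configuration must set delta (or a delta_grid to select from)")
        if self.delta is not None and not 0 < self.delta < 1:
            raise ConfigError(f"delta must lie in (0, 1), got {self.delta}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_networks(panel, de, config: RunConfig):
    """Build one DCN per non-baseline condition at the configured (or
    grid-selected) threshold."""
    delta = config.delta
    if delta is None:
        delta = select_delta(panel, config.delta_grid)
        logger.info("selected delta=%.3g from grid", delta)
    de.check_covers(panel.genes)
    dcns = []
    for cond in panel.conditions:
        dcns.append(
            build_dcn(
                panel.condition_matrix(cond),
                de.for_condition(cond),
                delta,
                condition=cond,
                conditioning_cap=config.conditioning_cap,
                log_transform=config.log_transform,
            )
        )
    return dcns


def run_pipeline(config: RunConfig) -> int:
    """Execute the full two-step pipeline and write the report.

    Stage failures propagate as exceptions whose message names the
    stage.  Returns 0 on success.
    """
    config.validate()
    seed_seq = np.random.SeedSequence(config.seed)
    search_rng, mcds_rng = (np.random.default_rng(s) for s in seed_seq.spawn(2))

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load inputs")
        panel = mio.load_expression_panel(config.expression, impute_missing=config.impute_missing)
        de = mio.load_de_table(config.de_pvalues)
        pheno = mio.load_phenotype_table(config.phenotype) if config.phenotype else None
        gene_sets = (
            mio.load_gmt(config.gene_sets, universe=panel.genes) if config.gene_sets else None
        )
    except Exception as exc:
        raise ValidationError(f"[load] {exc}") from exc

    try:
        stage("build networks")
        dcns = build_networks(panel, de, config)
    except Exception as exc:
        raise ValidationError(f"[dcn_builder] {exc}") from exc

    try:
        stage("module discovery + significance")
        mdms = discover_mdms(
            dcns,
            fraction=config.seed_fraction,
            min_size=config.min_size,
            jaccard=config.jaccard,
            n_rand=config.n_rand,
            alpha=config.alpha,
            rng=search_rng,
            swaps_per_edge=config.swaps_per_edge,
        )
    except Exception as exc:
        raise ValidationError(f"[module_search/significance] {exc}") from exc

    try:
        stage("connectivity dynamics")
        by_condition = {d.condition: d for d in dcns}
        shared = [m for m in mdms if m.level >= 2]
        mcds_results = [
            mcds(m, [by_condition[c] for c in m.subset], norm=config.norm, pairing=config.pairing)
            for m in shared
        ]
        mcds_results = mcds_significance(
            mcds_results,
            by_condition,
            n_rand=config.mcds_n_rand,
            rng=mcds_rng,
            alpha=config.mcds_alpha,
            norm=config.norm,
            pairing=config.pairing,
        )
    except Exception as exc:
        raise ValidationError(f"[dynamics] {exc}") from exc

    try:
        stage("module statistics")
        stats_tables = module_statistics(mdms, dcns, panel, pheno, config)
    except Exception as exc:
        raise ValidationError(f"[module_stats] {exc}") from exc

    try:
        stage("write report")
        out = Path(config.out_dir)
        mio.write_mdm_report(mdms, mcds_results, out, dcns=dcns, manifest=config.to_dict())
        for name, df in stats_tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        if gene_sets is not None and mdms:
            enr = hypergeometric_enrichment(mdms, gene_sets, alpha=config.alpha)
            enr.table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            with (out / "enrichment_summary.tsv").open("w") as fh:
                fh.write("specificity\tsensitivity\n")
                fh.write(f"{enr.specificity!r}\t{enr.sensitivity!r}\n")
    except Exception as exc:
        raise ValidationError(f"[report] {exc}") from exc

    logger.info("pipeline finished: %d modules", len(mdms))
    return 0


def module_statistics(mdms: list[MDM], dcns, panel, pheno, config: RunConfig) -> dict:
    """Activity, regulation calls, mean edge weights and phenotype
    correlations for a module catalog, as flat tables."""
    by_condition = {d.condition: d for d in dcns}
    activity_rows, regulation_rows, weight_rows, corr_rows = [], [], [], []
    for m in mdms:
        profile = module_activity(m, panel)
        for (cond, time), val in profile.activity.items():
            activity_rows.append((m.module_id, cond, time, float(val)))
        for cond in m.subset:
            weight_rows.append((m.module_id, cond, mean_edge_weight(m, by_condition[cond])))
            for time in panel.time_points:
                call, p = regulation_call(m, panel, cond, time, p_cut=config.p_cut)
                regulation_rows.append((m.module_id, cond, time, call, p))
        if pheno is not None:
            for measure in pheno.names:
                corr = phenotype_correlation(
                    profile,
                    pheno,
                    measure,
                    conditions=list(m.subset),
                    fs_invert=config.fs_invert or None,
                )
                corr_rows.append((m.module_id, measure, corr))
    return {
        "activity": pd.DataFrame(
            activity_rows, columns=["module_id", "condition", "time", "activity"]
        ),
        "regulation": pd.DataFrame(
            regulation_rows, columns=["module_id", "condition", "time", "call", "p_value"]
        ),
        "mean_edge_weight": pd.DataFrame(
            weight_rows, columns=["module_id", "condition", "mean_edge_weight"]
        ),
        "phenotype_correlation": pd.DataFrame(
            corr_rows, columns=["module_id", "measure", "correlation"]
        ),
    }
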