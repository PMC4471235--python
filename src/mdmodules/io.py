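"""Readers and writers for every external format.

All formats are tab-separated text chosen for diffability: expression
panels with metadata header lines, differential-expression p-value
tables, phenotype tables, GMT gene sets, weighted edge lists and the
module report (module table + per-network edge lists + JSON manifest).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MDM,
    DEPValueTable,
    ExpressionPanel,
    GeneSetCollection,
    MCDSResult,
    PhenotypeTable,
    ValidationError,
)
from .network import DCN

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression_panel",
    "write_expression_panel",
    "load_de_table",
    "write_de_table",
    "load_phenotype_table",
    "write_phenotype_table",
    "load_gmt",
    "write_network",
    "read_network",
    "write_mdm_report",
    "read_mdm_report",
]

_META_KEYS = ("baseline", "condition", "time", "replicate")


def load_expression_panel(path: str | Path, impute_missing: bool = False) -> ExpressionPanel:
    """Load a genes x samples expression TSV.

    The file starts with ``#baseline``, ``#condition``, ``#time`` and
    ``#replicate`` metadata lines mapping each sample column, followed by
    a header row (first column = gene id) and one row per gene.  Missing
    values are rejected unless ``impute_missing`` enables per-gene mean
    imputation.
    """
    path = Path(path)
    meta: dict[str, list[str]] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, *vals = line[1:].split("\t")
                meta[key] = vals
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(line.split("\t"))
    for key in _META_KEYS:
        if key not in meta:
            raise ValidationError(f"expression file lacks required #{key} metadata line")
    if header is None or not rows:
        raise ValidationError("expression file has no data rows")
    baseline = meta["baseline"][0]
    n_samples = len(header) - 1
    for key in ("condition", "time", "replicate"):
        if len(meta[key]) != n_samples:
            raise ValidationError(
                f"#{key} lists {len(meta[key])} entries for {n_samples} sample columns"
            )
    columns = pd.MultiIndex.from_arrays(
        [meta["condition"], meta["time"], meta["replicate"]],
        names=["condition", "time", "replicate"],
    )
    genes = [r[0] for r in rows]
    data = np.empty((len(rows), n_samples))
    for i, r in enumerate(rows):
        if len(r) != n_samples + 1:
            raise ValidationError(f"row for gene {r[0]!r} has {len(r) - 1} values, expected {n_samples}")
        for j, cell in enumerate(r[1:]):
            if cell in ("", "NA", "NaN", "nan"):
                data[i, j] = np.nan
                continue
            try:
                data[i, j] = float(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"non-numeric value {cell!r} at gene {r[0]!r}, sample column {j + 1}"
                ) from exc
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=columns)
    if df.isna().to_numpy().any():
        if not impute_missing:
            raise ValidationError(
                "expression file contains missing values (enable imputation to fill per-gene means)"
            )
        logger.warning("imputing %d missing value(s) with per-gene means", int(df.isna().sum().sum()))
        df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
    return ExpressionPanel(values=df, baseline=baseline)


def write_expression_panel(panel: ExpressionPanel, path: str | Path) -> None:
    path = Path(path)
    cols = panel.values.columns
    with path.open("w") as fh:
        fh.write(f"#baseline\t{panel.baseline}\n")
        for level in ("condition", "time", "replicate"):
            fh.write("#" + level + "\t" + "\t".join(map(str, cols.get_level_values(level))) + "\n")
        names = [f"{c}.{t}.{r}" for c, t, r in cols]
        fh.write("gene\t" + "\t".join(names) + "\n")
        for gene, row in zip(panel.values.index, panel.values.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_de_table(path: str | Path) -> DEPValueTable:
    """Load a gene x condition table of differential-expression p-values.

    Zeros are rejected; values below the clamp floor are clamped with a
    warning so downstream -log p stays finite.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy(dtype=float)
    if (arr == 0).any():
        raise ValidationError("p-value of exactly 0 encountered; clamp upstream or fix the input")
    n_clamped = int((arr < DEPValueTable.P_CLAMP).sum())
    if n_clamped:
        logger.warning("clamping %d p-value(s) below %.1e", n_clamped, DEPValueTable.P_CLAMP)
        df = df.clip(lower=DEPValueTable.P_CLAMP)
    return DEPValueTable(pvalues=df)


def write_de_table(table: DEPValueTable, path: str | Path) -> None:
    table.pvalues.rename_axis("gene").to_csv(path, sep="\t")


def load_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str, "time": str})
    for col in ("condition", "time"):
        if col not in df.columns:
            raise ValidationError(f"phenotype table lacks a {col!r} column")
    df = df.set_index(["condition", "time"])
    return PhenotypeTable(measures=df.astype(float))


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    table.measures.to_csv(path, sep="\t")


def load_gmt(path: str | Path, universe: list[str]) -> GeneSetCollection:
    """Load GMT gene sets (name, description, genes...); genes outside
    the universe are dropped with a warning."""
    sets: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    coll = GeneSetCollection(sets=sets, universe=list(universe))
    if coll.n_dropped:
        logger.warning("dropped %d gene(s) outside the universe from gene sets", coll.n_dropped)
    return coll


# -- networks ------------------------------------------------------------


def write_network(dcn: DCN, path: str | Path, graphml: bool = False) -> None:
    """Write a weighted edge list with enough metadata to reconstruct
    the network, optionally alongside a GraphML twin for viewers."""
    path = Path(path)
    edges = dcn.edge_list()
    with path.open("w") as fh:
        fh.write(f"#condition\t{dcn.condition}\n")
        fh.write(f"#delta\t{dcn.delta!r}\n")
        fh.write("#genes\t" + ",".join(dcn.genes) + "\n")
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in edges.itertuples(index=False):
            fh.write(f"{a}\t{b}\t{float(w)!r}\n")
    if graphml:
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(dcn.genes)
        for a, b, w in edges.itertuples(index=False):
            G.add_edge(a, b, weight=float(w))
        nx.write_graphml(G, path.with_suffix(path.suffix + ".graphml"))


def read_network(path: str | Path) -> DCN:
    meta: dict[str, str] = {}
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                meta[key] = val
            elif line and not line.startswith("gene_a"):
                rows.append(line.split("\t"))
    genes = meta["genes"].split(",")
    index = {g: i for i, g in enumerate(genes)}
    A = np.zeros((len(genes), len(genes)))
    for a, b, w in rows:
        A[index[a], index[b]] = A[index[b], index[a]] = float(w)
    return DCN(condition=meta["condition"], genes=genes, adjacency=A, delta=float(meta["delta"]))


# -- module report -------------------------------------------------------

_MODULE_COLUMNS = [
    "module_id",
    "level",
    "conditions",
    "n_genes",
    "entropy",
    "p_value",
    "adj_p_value",
    "significant",
    "mcds",
    "mcds_p_value",
    "mcds_adj_p_value",
    "dynamic",
    "genes",
]


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_mdm_report(
    mdms: list[MDM],
    mcds_results: list[MCDSResult],
    out_dir: str | Path,
    dcns: list[DCN] | None = None,
    manifest: dict | None = None,
) -> Path:
    """Emit the machine-readable module catalog.

    Writes ``modules.tsv`` (one row per module with scores, p-values and
    the gene list), one weighted edge list per (module, network) pair
    under ``modules/``, and ``manifest.json`` with configuration, seed
    and library versions.  Returns the module-table path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mcds_by_id = {r.module_id: r for r in mcds_results}
    table_path = out / "modules.tsv"
    with table_path.open("w") as fh:
        fh.write("\t".join(_MODULE_COLUMNS) + "\n")
        for m in mdms:
            r = mcds_by_id.get(m.module_id)
            fh.write(
                "\t".join(
                    [
                        m.module_id,
                        str(m.level),
                        "|".join(m.subset),
                        str(m.size),
                        _fmt(m.entropy),
                        _fmt(m.p_value),
                        _fmt(m.adj_p_value),
                        _fmt(m.significant),
                        _fmt(r.score if r else None),
                        _fmt(r.p_value if r else None),
                        _fmt(r.adj_p_value if r else None),
                        _fmt(r.dynamic if r else None),
                        ",".join(m.genes),
                    ]
                )
                + "\n"
            )
    if dcns is not None:
        mod_dir = out / "modules"
        mod_dir.mkdir(exist_ok=True)
        by_condition = {d.condition: d for d in dcns}
        for m in mdms:
            genes = sorted(m.genes)
            for cond in m.subset:
                dcn = by_condition[cond]
                sub = dcn.induced(genes)
                with (mod_dir / f"{m.module_id}.{cond}.edges.tsv").open("w") as fh:
                    fh.write("gene_a\tgene_b\tweight\n")
                    iu, ju = np.nonzero(np.triu(sub, k=1))
                    for i, j in zip(iu, ju):
                        fh.write(f"{genes[i]}\t{genes[j]}\t{sub[i, j]!r}\n")

    versions = {}
    for modname in ("numpy", "scipy", "pandas", "networkx", "statsmodels"):
        try:
            versions[modname] = __import__(modname).__version__
        except Exception:  # pragma: no cover
            versions[modname] = "unknown"
    from . import __version__

    payload = {
        "package_version": __version__,
        "library_versions": versions,
        "config": manifest or {},
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return table_path


def _parse(val: str, cast):
    if val == "NA":
        return None
    if cast is bool:
        return bool(int(val))
    return cast(val)


def read_mdm_report(out_dir: str | Path) -> tuple[list[MDM], list[MCDSResult]]:
    """Re-parse a written module table into MDM / MCDSResult records."""
    table_path = Path(out_dir) / "modules.tsv"
    mdms: list[MDM] = []
    mcds_results: list[MCDSResult] = []
    with table_path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MODULE_COLUMNS:
            raise ValidationError("unrecognized module table header")
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            genes = tuple(vals["genes"].split(","))
            subset = tuple(vals["conditions"].split("|"))
            mdms.append(
                MDM(
                    module_id=vals["module_id"],
                    genes=genes,
                    subset=subset,
                    entropy=float(vals["entropy"]),
                    p_value=_parse(vals["p_value"], float),
                    adj_p_value=_parse(vals["adj_p_value"], float),
                    significant=_parse(vals["significant"], bool),
                )
            )
            if vals["mcds"] != "NA":
                mcds_results.append(
                    MCDSResult(
                        module_id=vals["module_id"],
                        genes=genes,
                        subset=subset,
                        score=float(vals["mcds"]),
                        p_value=_parse(vals["mcds_p_value"], float),
                        adj_p_value=_parse(vals["mcds_adj_p_value"], float),
                        dynamic=_parse(vals["dynamic"], bool),
                    )
                )
    return mdms, mcds_results
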