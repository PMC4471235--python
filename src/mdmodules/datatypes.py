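"""Core in-memory containers shared across the pipeline stages.

Expression data are held as pandas DataFrames with a (condition, time,
replicate) MultiIndex on the sample axis; networks are dense symmetric
weight matrices over a fixed, ordered gene list.  Modules and their
statistics are plain dataclass records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionPanel",
    "DEPValueTable",
    "PhenotypeTable",
    "GeneSetCollection",
    "ModuleCandidate",
    "MDM",
    "MCDSResult",
]

SAMPLE_LEVELS = ("condition", "time", "replicate")


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass
class ExpressionPanel:
    """Genes x samples expression values for all conditions of a study.

    ``values`` has the gene identifiers as its index (file order is
    preserved) and a three-level (condition, time, replicate) MultiIndex
    on the columns.  Exactly one condition is the healthy/baseline
    reference; all others are disease conditions for which a differential
    co-expression network can be built.
    """

    values: pd.DataFrame
    baseline: str

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValidationError("sample columns must be a (condition, time, replicate) MultiIndex")
        self.values.columns = self.values.columns.set_names(list(SAMPLE_LEVELS))
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def all_conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond in self.values.columns.get_level_values("condition"):
            seen.setdefault(cond, None)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        """Non-baseline conditions, in column order."""
        return [c for c in self.all_conditions if c != self.baseline]

    @property
    def time_points(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.values.columns.get_level_values("time"):
            seen.setdefault(str(t), None)
        return list(seen)

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        """All samples (every time point and replicate) of one condition."""
        mask = self.values.columns.get_level_values("condition") == condition
        if not mask.any():
            raise KeyError(f"unknown condition {condition!r}")
        return self.values.loc[:, mask]

    def cell_matrix(self, condition: str, time: str) -> pd.DataFrame:
        cols = self.values.columns
        mask = (cols.get_level_values("condition") == condition) & (
            cols.get_level_values("time").astype(str) == str(time)
        )
        return self.values.loc[:, mask]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicated gene identifier(s): {', '.join(map(str, dupes))}")
        if self.baseline not in self.all_conditions:
            raise ValidationError(f"baseline condition {self.baseline!r} absent from panel")
        if self.values.isna().to_numpy().any():
            raise ValidationError("expression panel contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        for cond in self.conditions:
            n = self.condition_matrix(cond).shape[1]
            if n < 3:
                raise ValidationError(
                    f"condition {cond!r} has {n} samples; at least 3 are required for correlation"
                )

    def equals(self, other: "ExpressionPanel") -> bool:
        return (
            self.baseline == other.baseline
            and self.values.index.equals(other.values.index)
            and list(self.values.columns) == list(other.values.columns)
            and np.allclose(self.values.to_numpy(), other.values.to_numpy())
        )


@dataclass
class DEPValueTable:
    """Per-condition differential-expression p-values, one column per
    non-baseline condition, indexed by gene.

    Values must lie in (0, 1]; exact zeros are rejected at load time and
    p-values below ``P_CLAMP`` are clamped there so edge weights stay
    finite.
    """

    pvalues: pd.DataFrame

    P_CLAMP = 1e-300

    def __post_init__(self) -> None:
        arr = self.pvalues.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("p-value table contains missing values")
        if (arr <= 0).any() or (arr > 1).any():
            raise ValidationError("differential-expression p-values must lie in (0, 1]")

    @property
    def conditions(self) -> list[str]:
        return list(self.pvalues.columns)

    def for_condition(self, condition: str) -> pd.Series:
        return self.pvalues[condition]

    def check_covers(self, genes: Sequence[str]) -> None:
        missing = [g for g in genes if g not in self.pvalues.index]
        if missing:
            raise ValidationError(
                f"p-value table is missing {len(missing)} gene(s), e.g. {missing[:5]}"
            )


@dataclass
class PhenotypeTable:
    """Numeric phenotype measures per (condition, time point).

    ``measures`` is indexed by a (condition, time) MultiIndex with one
    column per measure (e.g. fractional shortening).
    """

    measures: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.issubdtype(self.measures.to_numpy().dtype, np.number):
            raise ValidationError("phenotype measures must be numeric")
        self.measures.index = self.measures.index.set_names(["condition", "time"])

    @property
    def names(self) -> list[str]:
        return list(self.measures.columns)

    def transformed(self, invert: Sequence[str] = ()) -> "PhenotypeTable":
        """Return a copy with selected fraction-type measures replaced by
        1 - value, then every measure z-scored — making measures with
        opposite clinical polarity comparable."""
        df = self.measures.copy()
        for name in invert:
            if name in df.columns:
                df[name] = 1.0 - df[name]
        df = (df - df.mean()) / df.std(ddof=1)
        return PhenotypeTable(df)


@dataclass
class GeneSetCollection:
    """Named reference gene sets over a background universe."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        cleaned: dict[str, list[str]] = {}
        self.n_dropped = 0
        for name, genes in self.sets.items():
            kept = [g for g in genes if g in uni]
            self.n_dropped += len(genes) - len(kept)
            if not kept:
                continue
            cleaned[name] = kept
        if not cleaned:
            raise ValidationError("gene-set collection is empty after universe filtering")
        self.sets = cleaned

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ModuleCandidate:
    """A greedily expanded module before refinement.

    ``trace`` records (gene added, entropy after the step) starting with
    the two-gene initialization, so the strict-descent property of the
    expansion can be audited after the fact.
    """

    genes: tuple[str, ...]
    subset: tuple[str, ...]
    entropy: float
    seed: str
    trace: list[tuple[str, float]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class MDM:
    """A multiple differential module: a gene set discovered in the
    networks of ``subset``, with its entropy score and significance."""

    module_id: str
    genes: tuple[str, ...]
    subset: tuple[str, ...]
    entropy: float
    p_value: float | None = None
    adj_p_value: float | None = None
    significant: bool | None = None
    provenance: tuple[str, ...] = ()

    @property
    def level(self) -> int:
        return len(self.subset)

    @property
    def size(self) -> int:
        return len(self.genes)

    def jaccard(self, other_genes: Sequence[str]) -> float:
        a, b = set(self.genes), set(other_genes)
        return len(a & b) / len(a | b)

    def with_pvalues(self, p: float, adj: float, alpha: float) -> "MDM":
        return replace(self, p_value=p, adj_p_value=adj, significant=bool(adj <= alpha))


@dataclass
class MCDSResult:
    """Connectivity-dynamics score of a shared module.

    ``pairwise`` maps unordered network pairs to their normalized
    adjacency-difference norms; ``score`` aggregates them.
    """

    module_id: str
    genes: tuple[str, ...]
    subset: tuple[str, ...]
    score: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    p_value: float | None = None
    adj_p_value: float | None = None
    dynamic: bool | None = None


def jaccard_index(a: Sequence[str], b: Sequence[str]) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
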