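"""Synthetic multi-condition expression panels with planted modules.

The generator emulates the statistical design the method targets: M
disease conditions plus a baseline, T time points, R replicates, with
planted gene modules that are co-expressed and differentially expressed
in chosen condition subsets, optional connectivity rewiring between
conditions, and a phenotype coupled to the activity of the rewired
("dynamic") modules.

Co-expression model.  Each planted module spans a rank-2 latent factor
plane: member gene g of a module active in condition c takes

    x_g = baseline_g + beta * (cos(theta_gc) f1 + sin(theta_gc) f2)
          + effect_c(t) + sigma * eps

with f1, f2 ~ N(0,1) drawn fresh per sample and per module.  Pairwise
correlation between members is then ~cos(theta_i - theta_j), so a
compact angular arc plants a near-clique at a 0.8 correlation threshold
while a wide arc plants a band graph.  Two latent dimensions (rather
than one) are essential: genes driven by a single shared factor are
conditionally independent given any other member, so a first-order
partial-correlation screen would (correctly) delete every within-module
edge — with two factors the first-order partial stays near +-1 whatever
single gene is conditioned on.  The within-module noise sigma is kept
very small because a conditioning gene nearly collinear with an endpoint
otherwise drags the sampled partial correlation below the threshold.

Rewiring.  A rewired module re-assigns the member angles (a random
permutation) per condition, changing which pairs fall within the
correlation threshold while keeping the module coherent in every
condition of its subset.

Differential expression.  effect_c(t) is a linear ramp over time points
("progressive" modules, emulating disease progression) or a constant
shift; the internal stand-in for a DE tool is a per-gene Welch t-test of
all condition samples against all baseline samples.

Phenotype.  Each phenotype measure is a weighted sum of the per-cell
activity of the phenotype-driver modules (the dynamic ones by default)
plus noise, so dynamic-module activity correlates with phenotype by
construction and static-module activity does not.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DEPValueTable,
    ExpressionPanel,
    PhenotypeTable,
    ValidationError,
)
from .network import DCN

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedModule",
    "SyntheticTruth",
    "simulate_panel",
    "default_fixture",
    "rewiring_fixture",
    "random_dcn",
]


@dataclass
class PlantedModule:
    """Specification and realized parameters of one planted module."""

    name: str
    size: int
    subset: tuple[str, ...]
    beta: float = 1.0
    arc_degrees: float = 25.0
    effect: float = 3.0
    progressive: bool = True
    rewired: bool = False
    phenotype_driver: bool = False
    #: decoy clusters are small DE-less co-expressed background groups;
    #: they are not planted truth and recovery tests skip them
    decoy: bool = False
    genes: tuple[str, ...] = ()
    #: per-condition gene -> angle (degrees), filled during simulation
    angles: dict = field(default_factory=dict)

    def effect_at(self, t_index: int, n_times: int) -> float:
        if self.progressive:
            return self.effect * (t_index + 1) / n_times
        return self.effect * 0.8


@dataclass
class SyntheticTruth:
    """Full specification of a synthetic study; the recovery oracle.

    Together with an RNG seed this determines the generated panel
    exactly; every planted parameter is recorded so tests can compare
    recovered modules against the planted ones.
    """

    n_genes: int
    conditions: tuple[str, ...]
    baseline: str = "ctrl"
    time_points: int = 4
    replicates: int = 4
    modules: list[PlantedModule] = field(default_factory=list)
    noise_sd: float = 0.002
    background_sd: float = 1.0
    phenotype_noise_sd: float = 0.2
    baseline_low: float = 30.0
    baseline_high: float = 60.0

    def validate(self) -> None:
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ValidationError(
                f"planted modules need {total} genes but the panel has {self.n_genes}"
            )
        for m in self.modules:
            unknown = set(m.subset) - set(self.conditions)
            if unknown:
                raise ValidationError(f"module {m.name} references unknown conditions {unknown}")

    def manifest(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True, default=list)
            fh.write("\n")


def _assign_genes(truth: SyntheticTruth) -> None:
    width = max(4, len(str(truth.n_genes)))
    cursor = 0
    for mod in truth.modules:
        mod.genes = tuple(f"g{idx:0{width}d}" for idx in range(cursor, cursor + mod.size))
        cursor += mod.size


def _module_angles(mod: PlantedModule, truth: SyntheticTruth, rng: np.random.Generator) -> None:
    mod.angles = {}
    if not mod.rewired:
        base = np.linspace(0.0, mod.arc_degrees, mod.size)
        for cond in mod.subset:
            mod.angles[cond] = base.tolist()
        return
    # Rewired modules model sub-pathways that split and merge across
    # conditions: each half occupies a tight arc of its own (so every
    # within-half correlation sits far above the threshold whatever the
    # condition); the two arcs are well separated (no cross edges) in
    # even-indexed conditions and overlap (dense cross edges) in
    # odd-indexed ones, so the induced adjacency difference is a
    # structured cross-block between the halves.
    half_a = mod.size // 2
    half_b = mod.size - half_a
    arc = mod.arc_degrees
    split = np.concatenate(
        [np.linspace(0.0, arc, half_a), np.linspace(0.0, arc, half_b) + arc + 45.0]
    )
    # one evenly spaced band; even spacing avoids duplicate angles, which
    # would make a gene's near-twin annihilate its partial correlations
    merged = np.linspace(0.0, 1.5 * arc, mod.size)
    for k, cond in enumerate(mod.subset):
        mod.angles[cond] = (split if k % 2 == 0 else merged).tolist()


def simulate_panel(
    truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[ExpressionPanel, DEPValueTable, PhenotypeTable, SyntheticTruth]:
    """Generate (panel, DE p-values, phenotype, realized truth).

    The same truth object and generator state produce an identical panel;
    the returned truth carries the realized gene assignments and angle
    maps for oracle comparisons.
    """
    truth.validate()
    _assign_genes(truth)
    width = max(4, len(str(truth.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(truth.n_genes)]
    all_conditions = [truth.baseline, *truth.conditions]
    times = [f"w{t + 1}" for t in range(truth.time_points)]
    columns = pd.MultiIndex.from_tuples(
        [
            (c, t, f"r{r + 1}")
            for c in all_conditions
            for t in times
            for r in range(truth.replicates)
        ],
        names=["condition", "time", "replicate"],
    )
    baselines = rng.uniform(truth.baseline_low, truth.baseline_high, truth.n_genes)
    data = baselines[:, None] + truth.background_sd * rng.standard_normal(
        (truth.n_genes, len(columns))
    )
    gene_pos = {g: i for i, g in enumerate(genes)}

    for mod in truth.modules:
        _module_angles(mod, truth, rng)
        idx = np.array([gene_pos[g] for g in mod.genes])
        for cond in mod.subset:
            theta = np.deg2rad(np.asarray(mod.angles[cond]))
            col_mask = columns.get_level_values("condition") == cond
            cols = np.nonzero(col_mask)[0]
            t_labels = columns.get_level_values("time")[col_mask]
            factors = rng.standard_normal((2, cols.size))
            signal = mod.beta * (
                np.cos(theta)[:, None] * factors[0] + np.sin(theta)[:, None] * factors[1]
            )
            effects = np.array(
                [mod.effect_at(times.index(t), truth.time_points) for t in t_labels]
            )
            noise = truth.noise_sd * rng.standard_normal((idx.size, cols.size))
            data[np.ix_(idx, cols)] = baselines[idx][:, None] + signal + effects[None, :] + noise

    data = np.maximum(data, 0.0)  # expression values are non-negative
    panel = ExpressionPanel(
        values=pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=columns),
        baseline=truth.baseline,
    )

    # internal DE stand-in: per-gene Welch t-test vs baseline
    pcols = {}
    base = panel.condition_matrix(truth.baseline).to_numpy()
    for cond in truth.conditions:
        vals = panel.condition_matrix(cond).to_numpy()
        res = stats.ttest_ind(vals, base, axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        pcols[cond] = np.clip(p, DEPValueTable.P_CLAMP, 1.0)
    de = DEPValueTable(pvalues=pd.DataFrame(pcols, index=pd.Index(genes, name="gene")))

    pheno = _phenotype_from_activity(panel, truth, rng)
    return panel, de, pheno, truth


def _phenotype_from_activity(
    panel: ExpressionPanel, truth: SyntheticTruth, rng: np.random.Generator
) -> PhenotypeTable:
    z = panel.values
    sd = z.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = z.sub(z.mean(axis=1), axis=0).div(sd, axis=0)
    cell_means = z.T.groupby(level=["condition", "time"], sort=False).mean().T
    drivers = [m for m in truth.modules if m.phenotype_driver]
    signal = np.zeros(cell_means.shape[1])
    for mod in drivers:
        signal += cell_means.loc[list(mod.genes)].mean(axis=0).to_numpy()
    measures = {}
    for name, rel_noise in (("measure_a", 1.0), ("measure_b", 1.5)):
        noise = truth.phenotype_noise_sd * rel_noise * rng.standard_normal(signal.size)
        measures[name] = signal + noise
    df = pd.DataFrame(measures, index=cell_means.columns)
    return PhenotypeTable(measures=df)


def default_fixture(scale: str = "small", beta: float = 1.0) -> SyntheticTruth:
    """Standard study designs at three problem sizes.

    ``tiny`` (60 genes, 2 time points, 3 replicates) runs end-to-end in
    seconds; ``small`` (300 genes, 4 x 4 design) is the planted-recovery
    benchmark; ``large`` (2000 genes, 3 conditions x 4 time
    points x 4 replicates) mirrors the shape of a real study at desk
    scale.  Three modules are planted, one per level: condition-specific,
    shared-by-two, and shared-by-all, with distinct sizes so that no two
    network components tie.  Small DE-less decoy co-expression clusters
    keep the active gene set at a realistic size (so the top-10% seed
    rule yields enough seeds to cover every module, as it does at real
    network scale).  ``beta=0`` removes all planted co-expression (the
    null design).
    """
    conditions = ("cond1", "cond2", "cond3")
    if scale == "tiny":
        n_genes, tps, reps, sizes, decoys = 60, 2, 3, (14, 12, 10), 5
    elif scale == "small":
        n_genes, tps, reps, sizes, decoys = 300, 4, 4, (14, 12, 10), 30
    elif scale == "large":
        n_genes, tps, reps, sizes, decoys = 2000, 4, 4, (30, 24, 18), 100
    else:
        raise ValidationError(f"unknown scale {scale!r}")
    modules = [
        PlantedModule(
            name="mod_level1", size=sizes[0], subset=("cond1",), beta=beta, phenotype_driver=False
        ),
        PlantedModule(
            name="mod_level2",
            size=sizes[1],
            subset=("cond1", "cond2"),
            beta=beta,
            phenotype_driver=True,
        ),
        PlantedModule(
            name="mod_level3",
            size=sizes[2],
            subset=("cond1", "cond2", "cond3"),
            beta=beta,
            phenotype_driver=True,
        ),
    ]
    modules.extend(_decoy_clusters(decoys, conditions))
    for m in modules:
        if m.decoy:
            m.beta = beta
    return SyntheticTruth(
        n_genes=n_genes,
        conditions=conditions,
        time_points=tps,
        replicates=reps,
        modules=modules,
    )


def rewiring_fixture(n_genes: int = 240, beta: float = 1.0) -> SyntheticTruth:
    """Design for connectivity-dynamics evaluation.

    Two rewired ("dynamic") shared modules carry time-ramped effects
    (disease progression) and drive the phenotype; two static shared
    modules carry time-constant effects and do not.  The ramp makes a
    dynamic module's activity vary strongly across its own
    (condition, time) cells, so its correlation with the phenotype it
    generates is identifiable even though the other driver module's
    on/off contrast across conditions also feeds the phenotype.  Each
    module occupies a different condition subset so each has an
    unambiguous search home.
    """
    modules = [
        PlantedModule(
            name="dyn_a",
            size=13,
            subset=("cond1", "cond2"),
            beta=beta,
            arc_degrees=20.0,
            rewired=True,
            progressive=True,
            phenotype_driver=True,
        ),
        PlantedModule(
            name="stat_a",
            size=11,
            subset=("cond1", "cond3"),
            beta=beta,
            arc_degrees=25.0,
            rewired=False,
            progressive=False,
            phenotype_driver=False,
        ),
        PlantedModule(
            name="dyn_b",
            size=14,
            subset=("cond2", "cond3"),
            beta=beta,
            arc_degrees=20.0,
            rewired=True,
            progressive=True,
            phenotype_driver=True,
        ),
        PlantedModule(
            name="stat_b",
            size=10,
            subset=("cond1", "cond2", "cond3"),
            beta=beta,
            arc_degrees=25.0,
            rewired=False,
            progressive=False,
            phenotype_driver=False,
        ),
    ]
    modules.extend(_decoy_clusters(30, ("cond1", "cond2", "cond3")))
    # a longer time course than the recovery fixtures: phenotype
    # correlations are computed across (condition, time) cells, and with
    # fewer than ~12 cells the magnitude of a pure-noise correlation
    # would swamp the planted contrast
    return SyntheticTruth(
        n_genes=n_genes,
        conditions=("cond1", "cond2", "cond3"),
        time_points=6,
        replicates=4,
        modules=modules,
        phenotype_noise_sd=0.15,
    )


def _decoy_clusters(count: int, conditions: tuple[str, ...], size: int = 4) -> list[PlantedModule]:
    """Small co-expressed background clusters without differential
    expression.  Real co-expression networks keep many genes connected
    through such groups; they enlarge the active gene set (and hence the
    10% seed count) without competing with the planted modules, whose
    seeds rank far above them."""
    return [
        PlantedModule(
            name=f"decoy{i:02d}",
            size=size,
            subset=conditions,
            effect=0.0,
            progressive=False,
            decoy=True,
        )
        for i in range(count)
    ]


def random_dcn(
    n_genes: int,
    n_edges: int,
    rng: np.random.Generator,
    condition: str = "noise",
    delta: float = 0.8,
) -> DCN:
    """A pure-noise network: uniformly random edges with weights drawn
    from the edge-weight model under uniform p-values.  Used for null
    calibration of the significance machinery."""
    width = max(4, len(str(n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]
    max_pairs = n_genes * (n_genes - 1) // 2
    if n_edges > max_pairs:
        raise ValidationError("more edges requested than gene pairs available")
    chosen = rng.choice(max_pairs, size=n_edges, replace=False)
    iu, ju = np.triu_indices(n_genes, k=1)
    neg_log_p = -np.log(rng.uniform(1e-6, 1.0, n_genes))
    floor = neg_log_p.max()
    A = np.zeros((n_genes, n_genes))
    for k in chosen:
        i, j = int(iu[k]), int(ju[k])
        w = np.sqrt(neg_log_p[i] + neg_log_p[j]) / np.sqrt(2 * floor)
        A[i, j] = A[j, i] = min(float(w), 1.0)
    return DCN(condition=condition, genes=genes, adjacency=A, delta=delta, neg_log_p=neg_log_p)
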