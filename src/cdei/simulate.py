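"""Synthetic three-condition expression datasets with known ground truth.

The generator emulates the experimental design the scoring pipeline is
built for: a pool of control replicates, a pool of untreated (pathological)
replicates in which pathway root genes are induced by a known log2 effect
δ, and one pool of treated replicates per simulated drug, in which the
induction is scaled down by that drug's restoration fraction ρ — the
treated mean multiplier is ``2^((1 - ρ) δ)``, so ρ = 1 restores the
control mean structure exactly and ρ = 0 leaves the perturbation intact.
ρ = -1 models an "anti-drug" that doubles the perturbation.

Counts are negative-binomial (mean μ per gene, variance μ + α μ²), the
field-standard overdispersed noise model for RNA-seq; all randomness flows
from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .expression import (
    CONTROL,
    TREATED,
    UNTREATED,
    ExpressionMatrix,
    SampleDesign,
    write_design,
    write_expression,
)
from .pathway import Pathway, write_pathways


def _default_drugs() -> dict[str, float]:
    return {"drug_r000": 0.0, "drug_r050": 0.5, "drug_r100": 1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults mirror the study design the pipeline targets: 241 pathways,
    triplicate control/untreated/treated pools of a standardized tissue
    model (tight negative-binomial dispersion, well-expressed panel genes),
    and a modest coherent induction (δ = 0.6, ~1.5-fold) of pathway root
    genes in the untreated state.  The operating point matters: the index
    compares t magnitudes, which saturate once the pathway-level signal
    dwarfs count noise, so partial restoration is only resolvable when the
    residual signal and the noise floor are of comparable size (see the
    methods documentation).

    Parameters
    ----------
    n_pathways, genes_per_pathway : int
        Library size and pathway size.
    edge_probability : float
        Probability of a directed edge from a lower- to a higher-index gene
        (pathways are acyclic by construction).
    inhibition_fraction : float
        Probability that an edge is inhibitory (-1) rather than activating.
    n_control, n_untreated, n_treated : int
        Replicates per pool (n_treated applies to each drug).
    baseline_mean : float
        Median baseline expected count per gene; per-gene baselines are
        log-normal around this value.
    dispersion : float
        Negative-binomial dispersion α (variance μ + α μ²).
    perturbation_effect : float
        δ, the log2 induction applied to root-gene means in the untreated
        state.
    drugs : mapping drug label -> restoration fraction ρ ∈ [-1, 1]
        ρ = 1 full restoration, ρ = 0 no effect, ρ < 0 amplification.
    seed : int
        Single seed for every random draw.
    """

    n_pathways: int = 241
    genes_per_pathway: int = 20
    edge_probability: float = 0.15
    inhibition_fraction: float = 0.2
    n_control: int = 3
    n_untreated: int = 3
    n_treated: int = 3
    baseline_mean: float = 500.0
    dispersion: float = 0.01
    perturbation_effect: float = 0.6
    drugs: Mapping[str, float] = field(default_factory=_default_drugs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1 or self.genes_per_pathway < 1:
            raise UsageError("pathway counts must be >= 1")
        if not (0.0 <= self.edge_probability <= 1.0):
            raise UsageError("edge_probability must lie in [0, 1]")
        if not (0.0 <= self.inhibition_fraction <= 1.0):
            raise UsageError("inhibition_fraction must lie in [0, 1]")
        if min(self.n_control, self.n_untreated, self.n_treated) < 1 or self.n_control < 2:
            raise UsageError("need >= 2 controls and >= 1 replicate per case pool")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise UsageError("baseline_mean must be > 0 and dispersion >= 0")
        if not np.isfinite(self.perturbation_effect):
            raise UsageError("perturbation_effect must be finite")
        for drug, rho in self.drugs.items():
            if not (-1.0 <= rho <= 1.0):
                raise UsageError(f"drug {drug!r}: restoration fraction {rho} outside [-1, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually did: perturbed (root) genes per pathway
    and each drug's restoration fraction."""

    perturbed_genes: Mapping[str, tuple[str, ...]]
    restoration: Mapping[str, float]
    perturbation_effect: float


def generate_pathway_library(config: SimulationConfig) -> list[Pathway]:
    """Random acyclic signed pathway library, deterministic for a fixed seed.

    Edges run only from lower to higher gene index, so every pathway is a
    DAG and the index order is already topological.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_pathways))
    library = []
    for k in range(config.n_pathways):
        pw_id = f"P{k + 1:0{width}d}"
        n = config.genes_per_pathway
        genes = tuple(f"{pw_id}_G{j:03d}" for j in range(n))
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < config.edge_probability:
                    sign = -1 if rng.random() < config.inhibition_fraction else 1
                    edges.append((genes[i], genes[j], sign))
        library.append(Pathway(id=pw_id, name=pw_id, genes=genes, edges=tuple(edges)))
    return library


def _root_genes(pathway: Pathway) -> tuple[str, ...]:
    indeg = {g: 0 for g in pathway.genes}
    for _src, dst, _sign in pathway.edges:
        indeg[dst] += 1
    return tuple(g for g in pathway.genes if indeg[g] == 0)


def generate_dataset(
    config: SimulationConfig, library: Sequence[Pathway] | None = None
) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth]:
    """Simulate counts for the full three-condition design over a library.

    Pathway root genes (in-degree 0) carry the induction: untreated means
    are multiplied by ``2^δ`` and each drug's treated means by
    ``2^((1 - ρ) δ)``.  Perturbation of downstream genes is *not* injected
    directly — it is the scoring pipeline's job to recover the propagated
    signal from the topology.
    """
    if library is None:
        library = generate_pathway_library(config)
    # independent stream from the library's so passing a prebuilt library
    # does not shift the count draws
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes: list[str] = []
    seen = set()
    for pw in library:
        for g in pw.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    perturbed = {pw.id: _root_genes(pw) for pw in library}
    perturbed_set = {g for roots in perturbed.values() for g in roots}

    baselines = config.baseline_mean * rng.lognormal(
        mean=0.0, sigma=0.5, size=len(genes)
    )
    delta = config.perturbation_effect
    induced = np.array([g in perturbed_set for g in genes])

    conditions: dict[str, str] = {}
    drug_of: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}

    def draw(mean: np.ndarray) -> np.ndarray:
        if config.dispersion == 0.0:
            return rng.poisson(mean).astype(float)
        size = 1.0 / config.dispersion
        return rng.negative_binomial(size, size / (size + mean)).astype(float)

    for r in range(config.n_control):
        s = f"C{r + 1:02d}"
        conditions[s] = CONTROL
        columns[s] = draw(baselines)
    u_mean = np.where(induced, baselines * 2.0**delta, baselines)
    for r in range(config.n_untreated):
        s = f"U{r + 1:02d}"
        conditions[s] = UNTREATED
        columns[s] = draw(u_mean)
    for drug, rho in config.drugs.items():
        t_mean = np.where(induced, baselines * 2.0 ** ((1.0 - rho) * delta), baselines)
        for r in range(config.n_treated):
            s = f"T_{drug}_{r + 1:02d}"
            conditions[s] = TREATED
            drug_of[s] = drug
            columns[s] = draw(t_mean)

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=pd.Index(genes, name="gene")))
    design = SampleDesign(conditions=conditions, drug_of=drug_of)
    truth = GroundTruth(
        perturbed_genes=perturbed,
        restoration=dict(config.drugs),
        perturbation_effect=delta,
    )
    return matrix, design, truth


def write_dataset(
    outdir: str | Path,
    matrix: ExpressionMatrix,
    design: SampleDesign,
    truth: GroundTruth,
    library: Sequence[Pathway],
) -> dict[str, Path]:
    """Write a complete, immediately scoreable dataset to ``outdir``.

    Emits expression.tsv, design.csv, pathways.tsv, panel.txt (all simulated
    genes) and ground_truth.tsv; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.csv",
        "pathways": outdir / "pathways.tsv",
        "panel": outdir / "panel.txt",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_expression(matrix, paths["expression"])
    write_design(design, paths["design"])
    write_pathways(library, paths["pathways"])
    with open(paths["panel"], "w", encoding="utf-8") as fh:
        fh.write("# all simulated genes\n")
        for g in matrix.genes:
            fh.write(g + "\n")
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        fh.write("record\tkey\tvalue\n")
        fh.write(f"effect\tdelta_log2\t{truth.perturbation_effect}\n")
        for drug, rho in truth.restoration.items():
            fh.write(f"drug\t{drug}\t{rho}\n")
        for pw_id, roots in truth.perturbed_genes.items():
            fh.write(f"perturbed\t{pw_id}\t{','.join(roots)}\n")
    return paths
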