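"""Per-gene perturbation factors and per-pathway perturbation scores.

Each gene's perturbation factor combines its own expression change with the
sign-weighted, out-degree-normalized perturbation of its direct upstream
regulators:

    PF(g) = dE(g) + sum over upstream u of  beta(u,g) * PF(u) / n_down(u)

The purely propagated part, Acc(g) = PF(g) - dE(g), satisfies the closed
form ``Acc = B (I - B)^-1 dE`` with B the out-degree-normalized signed
adjacency matrix; the pathway's perturbation score is the sum of Acc over
its genes — positive for an upregulated pathway, negative for a
downregulated one.

Two independent routes are provided: the matrix closed form (production
path, works for any pathway with invertible I - B) and direct evaluation of
the recursion in topological order (oracle, acyclic pathways only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PathwaySingularError, UsageError
from .expression import DeltaEVector
from .pathway import BetaMatrix, Pathway, compute_beta_matrix, topological_order

log = logging.getLogger(__name__)

#: reciprocal-condition threshold below which (I - B) is treated as singular
RCOND_SINGULAR = 1e-10


@dataclass(frozen=True)
class PerturbationResult:
    """PF and Acc per gene, and the scalar pathway score, for one sample."""

    pathway_id: str
    sample_id: str
    pf: pd.Series = field(repr=False)
    acc: pd.Series = field(repr=False)
    spia_score: float


def _as_vector(delta_e: DeltaEVector | pd.Series, order: Sequence[str]) -> np.ndarray:
    values = delta_e.values if isinstance(delta_e, DeltaEVector) else delta_e
    vec = values.reindex(order).fillna(0.0).to_numpy(dtype=float)
    if not np.isfinite(vec).all():
        raise UsageError("ΔE contains non-finite values")
    return vec


def accuracies_matrix(
    beta: BetaMatrix, delta_e: DeltaEVector | pd.Series, sample_id: str | None = None
) -> PerturbationResult:
    """Accuracy vector via the closed form, solving (I - B) y = ΔE.

    ``Acc = B y``, ``PF = Acc + ΔE``; the score is the sum of Acc.  The
    solve is a linear system (never an explicit inverse); (I - B) with
    reciprocal condition below ``RCOND_SINGULAR`` raises
    :class:`PathwaySingularError` so the caller can apply its skip policy.
    """
    if sample_id is None:
        sample_id = delta_e.sample_id if isinstance(delta_e, DeltaEVector) else "<vector>"
    de = _as_vector(delta_e, beta.order)
    i_minus_b = np.eye(beta.n) - beta.values
    # 1-norm rcond estimate, same convention as LAPACK's gecon
    cond = np.linalg.cond(i_minus_b, 1)
    if not np.isfinite(cond) or 1.0 / cond < RCOND_SINGULAR:
        raise PathwaySingularError(beta.pathway_id)
    y = np.linalg.solve(i_minus_b, de)
    acc = beta.values @ y
    pf = acc + de
    index = pd.Index(beta.order)
    return PerturbationResult(
        pathway_id=beta.pathway_id,
        sample_id=sample_id,
        pf=pd.Series(pf, index=index),
        acc=pd.Series(acc, index=index),
        spia_score=float(acc.sum()),
    )


def accuracies_recursive(
    pathway: Pathway, delta_e: DeltaEVector | pd.Series, sample_id: str | None = None
) -> PerturbationResult:
    """Accuracy vector by direct evaluation of the PF recursion.

    Genes are processed in topological order, so every upstream PF is final
    when consumed.  Only defined for acyclic pathways; serves as the
    independent oracle for :func:`accuracies_matrix`.
    """
    if sample_id is None:
        sample_id = delta_e.sample_id if isinstance(delta_e, DeltaEVector) else "<vector>"
    try:
        order = topological_order(pathway)
    except Exception as exc:
        raise UsageError(
            f"pathway {pathway.id!r} is cyclic; the recursive evaluation "
            "requires a topological order"
        ) from exc
    de = _as_vector(delta_e, pathway.genes)
    de_of = dict(zip(pathway.genes, de))
    n_down = pathway.out_degrees()
    upstream: dict[str, list[tuple[str, int]]] = {g: [] for g in pathway.genes}
    for src, dst, sign in pathway.edges:
        upstream[dst].append((src, sign))
    pf: dict[str, float] = {}
    for g in order:
        pf[g] = de_of[g] + sum(
            sign * pf[u] / n_down[u] for u, sign in upstream[g]
        )
    index = pd.Index(pathway.genes)
    pf_series = pd.Series([pf[g] for g in pathway.genes], index=index)
    acc_series = pf_series - pd.Series(de, index=index)
    return PerturbationResult(
        pathway_id=pathway.id,
        sample_id=sample_id,
        pf=pf_series,
        acc=acc_series,
        spia_score=float(acc_series.sum()),
    )


@dataclass(frozen=True)
class ScoreTable:
    """Dense (pathway x case sample) table of pathway perturbation scores.

    ``scores``: DataFrame, pathways in rows, samples in columns.
    ``excluded``: pathway_id -> reason, for pathways dropped dataset-wide
    (singular I - B); exclusions apply uniformly to every sample so each
    condition's summary runs over an identical pathway set.
    """

    scores: pd.DataFrame
    excluded: Mapping[str, str]


def score_all(
    pathways: Sequence[Pathway],
    beta_matrices: Mapping[str, BetaMatrix] | None,
    delta_e_by_sample: Mapping[str, pd.Series],
) -> ScoreTable:
    """Score every pathway for every case sample.

    ``delta_e_by_sample`` maps sample id to a ΔE Series over the measured
    genes; pathway genes missing from a Series contribute ΔE = 0.  Singular
    pathways are excluded for all samples and logged; if every pathway is
    singular the dataset cannot be scored.
    """
    if beta_matrices is None:
        beta_matrices = {pw.id: compute_beta_matrix(pw) for pw in pathways}
    samples = list(delta_e_by_sample)
    rows: dict[str, list[float]] = {}
    excluded: dict[str, str] = {}
    for pw in pathways:
        beta = beta_matrices[pw.id]
        try:
            rows[pw.id] = [
                accuracies_matrix(beta, delta_e_by_sample[s], sample_id=s).spia_score
                for s in samples
            ]
        except PathwaySingularError:
            excluded[pw.id] = "singular (I - B)"
            rows.pop(pw.id, None)
    if excluded:
        log.info("excluded %d singular pathway(s): %s", len(excluded), sorted(excluded))
    if not rows:
        raise UsageError("all pathways are singular; nothing to score")
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return ScoreTable(scores=scores, excluded=excluded)


def write_scores(table: ScoreTable, path: str | Path) -> None:
    """Write the score table as TSV: pathway_id, sample_id, spia_score."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tsample_id\tspia_score\n")
        for pw_id, row in table.scores.iterrows():
            for sample_id, score in row.items():
                fh.write(f"{pw_id}\t{sample_id}\t{score:.10g}\n")
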