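"""End-to-end orchestration: files in, ranked drug-efficiency report out.

``run_score`` executes the full chain — read expression and design,
optionally normalize raw counts, optionally restrict to a gene panel,
compute ΔE per case sample, score every pathway, summarize each dataset
with the one-sample t-test and rank the drugs — and writes three outputs
to the run directory:

* ``report.tsv`` — one row per condition, the human-readable table
  (t, p, index at reporting precision);
* ``summary.yaml`` — the machine-readable run summary at full precision
  (pathway counts, exclusions, t statistics, ranking, size factors);
* ``scores.tsv`` — the raw (pathway x sample) score table.

``run_simulate`` writes a complete synthetic dataset that ``run_score``
can consume unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import expression as ex
from . import scoring, simulate, spia
from .errors import CdeiError, UsageError
from .pathway import compute_beta_matrix, load_pathways

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs of one scoring run."""

    expression: Path
    design: Path
    pathways: Path
    out: Path
    gene_list: Path | None = None
    normalize: bool = False
    pseudocount: float = 1.0
    report_decimals: int = 2


@dataclass(frozen=True)
class RunResult:
    """Everything a scoring run computed, at full precision."""

    untreated: scoring.DatasetTStat
    per_drug: tuple[scoring.CdeiResult, ...]
    treated_stats: Mapping[str, scoring.DatasetTStat]
    n_pathways_used: int
    excluded_pathways: Mapping[str, str]
    size_factors: Mapping[str, float] | None
    n_profiles: Mapping[str, int] = field(default_factory=dict)


def score(
    matrix: ex.ExpressionMatrix,
    design: ex.SampleDesign,
    pathways_list,
    pseudocount: float = 1.0,
) -> tuple[RunResult, spia.ScoreTable]:
    """Library entry point: score an in-memory dataset end to end."""
    if not design.untreated_samples:
        raise UsageError("design has no untreated samples; t_U is undefined")
    if not design.drugs:
        raise UsageError("design has no treated samples; nothing to rank")
    betas = {pw.id: compute_beta_matrix(pw) for pw in pathways_list}
    delta = ex.delta_e_table(matrix, design, pseudocount=pseudocount)
    table = spia.score_all(
        pathways_list, betas, {s: delta[s] for s in delta.columns}
    )
    t_u = scoring.summarize_dataset(table.scores, design, ex.UNTREATED)
    treated_stats: dict[str, scoring.DatasetTStat] = {}
    results = []
    for drug in design.drugs:
        t_t = scoring.summarize_dataset(table.scores, design, ex.TREATED, drug=drug)
        treated_stats[drug] = t_t
        results.append(
            scoring.CdeiResult(
                drug=drug,
                abs_t_untreated=abs(t_u.t),
                abs_t_treated=abs(t_t.t),
                cdei=scoring.cdei_score(t_u.t, t_t.t),
                n_profiles=len(design.treated_samples(drug)),
            )
        )
    ranked = tuple(scoring.rank_drugs(results))
    n_profiles = {"control": len(design.control_samples),
                  "untreated": len(design.untreated_samples)}
    n_profiles.update({r.drug: r.n_profiles or 0 for r in ranked})
    result = RunResult(
        untreated=t_u,
        per_drug=ranked,
        treated_stats=treated_stats,
        n_pathways_used=len(table.scores),
        excluded_pathways=table.excluded,
        size_factors=None,
        n_profiles=n_profiles,
    )
    return result, table


def _format_sig(p: float, sig: int = 2) -> str:
    return f"{p:.{sig}g}"


def write_report(result: RunResult, path: Path, decimals: int = 2) -> None:
    """Human-readable per-condition table (control row carries no statistics)."""
    rnd = scoring.round_half_away
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("dataset\tsample_class\tn_profiles\tt_value\tp_value\tcdei\n")
        fh.write(f"control\tControl (C)\t{result.n_profiles.get('control', '')}\t-\t-\t-\n")
        t_u = result.untreated
        fh.write(
            f"untreated\tUntreated (U)\t{result.n_profiles.get('untreated', '')}\t"
            f"{rnd(t_u.t, decimals)}\t{_format_sig(t_u.p)}\t0.0\n"
        )
        for r in result.per_drug:
            t_t = result.treated_stats[r.drug]
            fh.write(
                f"{r.drug}\tTreated (T)\t{r.n_profiles or ''}\t"
                f"{rnd(t_t.t, decimals)}\t{_format_sig(t_t.p)}\t{rnd(r.cdei, decimals)}\n"
            )


def write_summary(result: RunResult, path: Path) -> None:
    """Full-precision machine-readable run summary (YAML)."""
    doc = {
        "n_pathways_used": result.n_pathways_used,
        "degrees_of_freedom": result.untreated.df,
        "excluded_pathways": dict(result.excluded_pathways),
        "size_factors": dict(result.size_factors) if result.size_factors else None,
        "untreated": {"t": result.untreated.t, "p": result.untreated.p},
        "treated": {
            drug: {"t": s.t, "p": s.p} for drug, s in result.treated_stats.items()
        },
        "ranking": [
            {
                "rank": r.rank,
                "drug": r.drug,
                "cdei": r.cdei,
                "abs_t_untreated": r.abs_t_untreated,
                "abs_t_treated": r.abs_t_treated,
            }
            for r in result.per_drug
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def run_score(config: RunConfig) -> RunResult:
    """File-based scoring run; writes report.tsv, summary.yaml, scores.tsv.

    On any component error the partially written outputs are removed and
    the error propagates to the caller (the CLI maps it to a nonzero exit).
    """
    for label, p in (
        ("expression", config.expression),
        ("design", config.design),
        ("pathways", config.pathways),
    ):
        if not Path(p).exists():
            raise UsageError(f"{label} file not found: {p}")
    if config.gene_list is not None and not Path(config.gene_list).exists():
        raise UsageError(f"gene list file not found: {config.gene_list}")

    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = [outdir / "report.tsv", outdir / "summary.yaml", outdir / "scores.tsv"]
    try:
        matrix = ex.read_expression(config.expression)
        design = ex.read_design(config.design)
        pathways_list = load_pathways(config.pathways)
        if not pathways_list:
            raise UsageError(f"no pathways in {config.pathways}")
        sf = None
        if config.normalize:
            sf = ex.size_factors(matrix)
            matrix = ex.median_of_ratios_normalize(matrix)
        if config.gene_list is not None:
            panel = ex.read_gene_list(config.gene_list)
            matrix = ex.restrict_to_gene_list(matrix, panel)
        result, table = score(matrix, design, pathways_list, config.pseudocount)
        if sf is not None:
            result = RunResult(
                untreated=result.untreated,
                per_drug=result.per_drug,
                treated_stats=result.treated_stats,
                n_pathways_used=result.n_pathways_used,
                excluded_pathways=result.excluded_pathways,
                size_factors={k: float(v) for k, v in sf.items()},
                n_profiles=result.n_profiles,
            )
        write_report(result, outputs[0], config.report_decimals)
        write_summary(result, outputs[1])
        spia.write_scores(table, outputs[2])
        log.info(
            "scored %d pathways (df=%d), %d excluded",
            result.n_pathways_used,
            result.untreated.df,
            len(result.excluded_pathways),
        )
        return result
    except CdeiError:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise


def run_simulate(config: simulate.SimulationConfig, out: Path) -> dict[str, Path]:
    """Generate and write a synthetic dataset ready for :func:`run_score`."""
    library = simulate.generate_pathway_library(config)
    matrix, design, truth = simulate.generate_dataset(config, library)
    return simulate.write_dataset(out, matrix, design, truth, library)
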