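"""Expression matrices, sample designs, normalization and ΔE vectors.

The scoring pipeline consumes a normalized gene-by-sample expression matrix
and a design table that assigns every sample to one of three conditions:
control (the healthy/unperturbed state), untreated case (the pathological
state), or a treated case, one group per drug or extract.  Each case sample
is compared against the mean of the control pool by a signed log2
fold-change, the ΔE vector that drives pathway perturbation scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

log = logging.getLogger(__name__)

CONTROL = "control"
UNTREATED = "untreated"
TREATED = "treated"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative gene-by-sample expression values.

    ``data`` is a pandas DataFrame with unique gene symbols as the index and
    unique sample identifiers as columns; values are finite and >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(values).all():
            gene, sample = _first_offender(df, ~np.isfinite(values))
            raise FormatError(f"non-finite value at gene {gene!r}, sample {sample!r}")
        if (values < 0).any():
            gene, sample = _first_offender(df, values < 0)
            raise FormatError(f"negative value at gene {gene!r}, sample {sample!r}")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _first_offender(df: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return str(df.index[i]), str(df.columns[j])


@dataclass(frozen=True)
class SampleDesign:
    """Assignment of each sample to control / untreated / treated:<drug>.

    ``conditions`` maps sample id to one of the condition constants;
    ``drugs`` maps sample id to a drug label for treated samples only.
    Drug order follows first appearance in the design file so reports are
    deterministic.
    """

    conditions: Mapping[str, str]
    drug_of: Mapping[str, str]

    def __post_init__(self) -> None:
        for sample, cond in self.conditions.items():
            if cond not in (CONTROL, UNTREATED, TREATED):
                raise FormatError(f"sample {sample!r}: unknown condition {cond!r}")
            if cond == TREATED and sample not in self.drug_of:
                raise FormatError(f"treated sample {sample!r} has no drug label")
            if cond != TREATED and sample in self.drug_of:
                raise FormatError(f"non-treated sample {sample!r} carries a drug label")
        if len(self.control_samples) < 2:
            raise FormatError("at least 2 control samples are required for the pool")
        for drug in self.drugs:
            if not self.treated_samples(drug):
                raise FormatError(f"drug {drug!r} has no samples")

    @property
    def control_samples(self) -> list[str]:
        return [s for s, c in self.conditions.items() if c == CONTROL]

    @property
    def untreated_samples(self) -> list[str]:
        return [s for s, c in self.conditions.items() if c == UNTREATED]

    def treated_samples(self, drug: str) -> list[str]:
        return [
            s
            for s, c in self.conditions.items()
            if c == TREATED and self.drug_of[s] == drug
        ]

    @property
    def case_samples(self) -> list[str]:
        """Every non-control sample, in design order."""
        return [s for s, c in self.conditions.items() if c != CONTROL]

    @property
    def drugs(self) -> list[str]:
        seen: list[str] = []
        for s, c in self.conditions.items():
            if c == TREATED and self.drug_of[s] not in seen:
                seen.append(self.drug_of[s])
        return seen


@dataclass(frozen=True)
class DeltaEVector:
    """Per-gene signed log2 fold-change of one case sample vs. the control pool.

    ``values`` is indexed by the pathway gene order it was computed for;
    genes absent from the measured panel carry exactly 0.
    """

    sample_id: str
    values: pd.Series
    pseudocount: float


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column ``gene``, then sample ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise FormatError(f"{path}: cannot parse expression matrix: {exc}") from exc
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric values in column(s) {non_numeric}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_design(path: str | Path) -> SampleDesign:
    """Read a design CSV with header ``sample,condition,drug``.

    ``condition`` is control/untreated/treated; ``drug`` is non-empty exactly
    for treated rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["sample", "condition", "drug"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected header {','.join(expected)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"{path}: duplicate sample(s) {dups}")
    conditions: dict[str, str] = {}
    drug_of: dict[str, str] = {}
    for _, row in df.iterrows():
        conditions[row["sample"]] = row["condition"]
        if row["drug"]:
            drug_of[row["sample"]] = row["drug"]
    return SampleDesign(conditions=conditions, drug_of=drug_of)


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample,condition,drug\n")
        for sample, cond in design.conditions.items():
            drug = design.drug_of.get(sample, "")
            fh.write(f"{sample},{cond},{drug}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene panel, one symbol per line, '#' comments."""
    panel: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#") and sym not in panel:
                panel.append(sym)
    return panel


def median_of_ratios_normalize(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization of a raw count matrix.

    The per-gene reference is the geometric mean of counts across samples,
    restricted to genes with a positive count in every sample; each sample's
    size factor is the median over reference genes of count / reference, and
    each column is divided by its size factor.  Size factors are logged.

    Raises
    ------
    UsageError
        If no gene has all-positive counts (no reference can be formed);
        pre-normalized input should be supplied instead.
    """
    counts = raw.data
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise UsageError(
            "no gene has positive counts in every sample; cannot form the "
            "geometric-mean reference — supply pre-normalized expression instead"
        )
    ref = np.exp(np.log(counts.loc[positive]).mean(axis=1))
    size_factors = counts.loc[positive].div(ref, axis=0).median(axis=0)
    log.info("size factors: %s", size_factors.round(4).to_dict())
    return ExpressionMatrix(counts.div(size_factors, axis=1))


def size_factors(raw: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (the per-sample divisors used by
    :func:`median_of_ratios_normalize`)."""
    counts = raw.data
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise UsageError("no gene has positive counts in every sample")
    ref = np.exp(np.log(counts.loc[positive]).mean(axis=1))
    return counts.loc[positive].div(ref, axis=0).median(axis=0)


def restrict_to_gene_list(
    matrix: ExpressionMatrix, panel: Sequence[str]
) -> ExpressionMatrix:
    """Restrict the matrix to panel genes, in panel order.

    Panel genes absent from the matrix are dropped (their count is logged);
    an empty intersection is an error.
    """
    if not panel:
        raise UsageError("gene panel is empty")
    measured = [g for g in panel if g in matrix.data.index]
    if not measured:
        raise UsageError("no panel gene is present in the expression matrix")
    dropped = len(panel) - len(measured)
    if dropped:
        log.info("%d panel gene(s) not measured; dropped", dropped)
    return ExpressionMatrix(matrix.data.loc[measured])


def compute_delta_e(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    sample_id: str,
    pathway_genes: Sequence[str],
    pseudocount: float = 1.0,
) -> DeltaEVector:
    """ΔE for one case sample over a pathway's genes.

    For each measured pathway gene g,
    ``ΔE(g) = log2((x[g, sample] + c) / (mean_controls(x[g]) + c))`` with
    pseudocount c; pathway genes absent from the matrix carry ΔE = 0.
    """
    if sample_id not in design.conditions:
        raise UsageError(f"sample {sample_id!r} not in design")
    if design.conditions[sample_id] == CONTROL:
        raise UsageError(f"sample {sample_id!r} is a control; ΔE is defined for case samples")
    table = delta_e_table(matrix, design, samples=[sample_id], pseudocount=pseudocount)
    values = table[sample_id].reindex(pathway_genes).fillna(0.0)
    return DeltaEVector(sample_id=sample_id, values=values, pseudocount=pseudocount)


def delta_e_table(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    samples: Iterable[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """ΔE for every measured gene (rows) of each case sample (columns).

    Batch form of :func:`compute_delta_e` over the full measured gene set;
    pathway-specific zero-filling happens downstream.
    """
    controls = design.control_samples
    if len(controls) < 2:
        raise UsageError("at least 2 control samples are required")
    case = list(samples) if samples is not None else design.case_samples
    missing = [s for s in case if s not in matrix.data.columns]
    if missing:
        raise UsageError(f"sample(s) {missing} not in the expression matrix")
    control_mean = matrix.data[controls].mean(axis=1)
    return np.log2(
        matrix.data[case].add(pseudocount, axis=0)
    ).sub(np.log2(control_mean + pseudocount), axis=0)
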