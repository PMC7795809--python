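"""Aggregation of pathway scores into per-dataset t statistics and the
drug-efficiency index.

For each pathway, the case-sample scores are summarized by a
sign-consistency weight w_p (the fraction of case samples whose score
shares the sign of the pathway mean) and the adjusted mean
``SPIA_mu = mean(scores) * w_p``.  The SPIA_mu vector over pathways is
tested against zero with a one-sample Student t-test, once for the
untreated dataset (t_U) and once per drug (t_T).  The drug-efficiency
index is

    CDEI = 2 * (|t_U| / (|t_T| + |t_U|) - 0.5)

which lies in [-1, 1]: 1 when the treatment fully restores a control-like
pathway profile (|t_T| = 0), 0 when it changes nothing (|t_T| = |t_U|),
negative when it pushes the transcriptome further from control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError, UsageError
from .expression import SampleDesign, TREATED, UNTREATED


@dataclass(frozen=True)
class PathwaySummary:
    """Per-pathway summary of case-sample scores for one condition."""

    pathway_id: str
    condition: str
    scores: tuple[float, ...]
    mean_score: float
    weight: float
    spia_mu: float


@dataclass(frozen=True)
class DatasetTStat:
    """One-sample t statistic of the SPIA_mu vector of one dataset vs. 0."""

    condition: str
    t: float
    p: float
    df: int
    n_pathways: int


@dataclass(frozen=True)
class CdeiResult:
    """Drug-efficiency index of one drug, with the t magnitudes behind it."""

    drug: str
    abs_t_untreated: float
    abs_t_treated: float
    cdei: float
    rank: int | None = None
    n_profiles: int | None = None


def pathway_weight(case_scores: Sequence[float]) -> float:
    """Sign-consistency weight w_p of one pathway's case-sample scores.

    Positive pathway mean: fraction of strictly positive scores; negative
    mean: fraction of strictly negative scores.  Zeros count toward neither
    numerator; a mean of exactly 0 (measure-zero tie) uses the positive
    branch.
    """
    scores = np.asarray(case_scores, dtype=float)
    if scores.size == 0:
        raise UsageError("pathway weight requires at least one score")
    if scores.mean() < 0:
        return float((scores < 0).sum() / scores.size)
    return float((scores > 0).sum() / scores.size)


def weighted_mean(case_scores: Sequence[float]) -> float:
    """Adjusted pathway mean ``SPIA_mu = mean(scores) * w_p``."""
    scores = np.asarray(case_scores, dtype=float)
    if scores.size == 0:
        raise UsageError("weighted mean requires at least one score")
    return float(scores.mean() * pathway_weight(scores))


def student_t_pvalue(t: float, df: int) -> float:
    """Two-sided tail probability of Student's t with ``df`` degrees of freedom."""
    return float(2.0 * stats.t.sf(abs(t), df))


def one_sample_t(spia_mu: Sequence[float], condition: str = "") -> DatasetTStat:
    """One-sample t-test of the per-pathway SPIA_mu vector against zero.

    ``t = mean / (sd / sqrt(N))`` with the sample (N-1) standard deviation;
    df = N - 1; two-sided p.
    """
    values = np.asarray(spia_mu, dtype=float)
    n = values.size
    if n < 2:
        raise UsageError("one-sample t-test requires at least 2 pathways")
    sd = values.std(ddof=1)
    if sd == 0.0:
        raise DegenerateStatisticError(
            f"SPIA_mu vector is constant ({values[0]}); t statistic undefined"
        )
    t = float(values.mean() / (sd / math.sqrt(n)))
    return DatasetTStat(
        condition=condition, t=t, p=student_t_pvalue(t, n - 1), df=n - 1, n_pathways=n
    )


def cdei_score(t_untreated: float, t_treated: float) -> float:
    """Drug-efficiency index from the two t statistics (signs are dropped).

    ``2 * (|t_U| / (|t_T| + |t_U|) - 0.5)``; defined as 0 when both
    magnitudes vanish (no signal, no claimed efficiency).
    """
    tu, tt = abs(t_untreated), abs(t_treated)
    if tu + tt == 0.0:
        return 0.0
    return 2.0 * (tu / (tt + tu) - 0.5)


def rank_drugs(results: Sequence[CdeiResult]) -> list[CdeiResult]:
    """Order drugs by descending index, ties broken by drug label; ranks 1..n."""
    if not results:
        raise UsageError("no drugs to rank")
    ordered = sorted(results, key=lambda r: (-r.cdei, r.drug))
    return [replace(r, rank=i) for i, r in enumerate(ordered, start=1)]


def summarize_pathways(
    scores: pd.DataFrame, samples: Sequence[str], condition: str
) -> list[PathwaySummary]:
    """Per-pathway w_p and SPIA_mu over the given case samples."""
    missing = [s for s in samples if s not in scores.columns]
    if missing:
        raise UsageError(f"sample(s) {missing} missing from the score table")
    if not samples:
        raise UsageError(f"condition {condition!r} has no samples")
    out = []
    for pw_id, row in scores[list(samples)].iterrows():
        vals = tuple(float(v) for v in row)
        out.append(
            PathwaySummary(
                pathway_id=str(pw_id),
                condition=condition,
                scores=vals,
                mean_score=float(np.mean(vals)),
                weight=pathway_weight(vals),
                spia_mu=weighted_mean(vals),
            )
        )
    return out


def summarize_dataset(
    scores: pd.DataFrame,
    design: SampleDesign,
    condition: str,
    drug: str | None = None,
) -> DatasetTStat:
    """t statistic of one dataset: ``condition`` is 'untreated', or 'treated'
    with a ``drug`` label.

    The control condition is never summarized — its SPIA_mu values are
    identically 0 by construction.
    """
    if condition == UNTREATED:
        samples, label = design.untreated_samples, "U"
    elif condition == TREATED:
        if drug is None:
            raise UsageError("summarizing a treated dataset requires a drug label")
        samples, label = design.treated_samples(drug), f"T:{drug}"
    else:
        raise UsageError(
            f"cannot summarize condition {condition!r}; expected 'untreated' or 'treated'"
        )
    summaries = summarize_pathways(scores, samples, label)
    stat = one_sample_t([s.spia_mu for s in summaries], condition=label)
    return stat


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.005 -> 0.01, -0.005 -> -0.01).

    Matches conventional table formatting; Python's round() is banker's
    rounding and would disagree on exact midpoints.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
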