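"""Published benchmark t statistics for three inflammation experiments.

Three-condition studies on standardized 3D human tissue models — EpiDermFT
skin (UVC-induced inflammation), EpiOral oral epithelium and EpiIntestinal
intestinal epithelium (both TNFα-induced) — each treated with a panel of
cannabis extracts.  For every dataset the published per-dataset one-sample
t statistic (241 pathways, df = 240) and the resulting drug-efficiency
index are recorded here.  These values serve as reference inputs for
regression tests of the index formula and the Student-t tail probability;
they are not recomputed from raw sequencing data, which was never
deposited.

Each experiment maps to ``(t_untreated, p_untreated, rows)`` where rows are
``(extract_label, t_treated, p_treated, published_index)`` tuples.
"""

from __future__ import annotations

from typing import NamedTuple


class TreatedRow(NamedTuple):
    extract: str
    t: float
    p: float
    cdei: float


class Experiment(NamedTuple):
    name: str
    t_untreated: float
    p_untreated: float
    treated: tuple[TreatedRow, ...]
    #: the published untreated p is inconsistent with its own t for this
    #: dataset (0.23 printed where df=240 gives 0.30); excluded from p checks
    untreated_p_reliable: bool = True


EPIDERM_FT = Experiment(
    name="EpiDermFT",
    t_untreated=1.04,
    p_untreated=0.23,
    untreated_p_reliable=False,
    treated=(
        TreatedRow("Extract #4", 0.67, 0.50, 0.22),
        TreatedRow("Extract #12", 2.06, 0.04, -0.33),
        TreatedRow("Extract #8", -0.19, 0.85, 0.69),
        TreatedRow("Extract #13", -1.04, 0.30, 0.00),
    ),
)

EPI_ORAL = Experiment(
    name="EpiOral",
    t_untreated=-2.78,
    p_untreated=0.006,
    treated=(
        TreatedRow("Extract #1", 0.86, 0.39, 0.53),
        TreatedRow("Extract #7", 0.19, 0.85, 0.87),
        TreatedRow("Extract #9", -0.03, 0.98, 0.98),
        TreatedRow("Extract #45", -2.02, 0.04, 0.16),
        TreatedRow("Extract #115", -0.15, 0.88, 0.90),
        TreatedRow("Extract #129", -0.63, 0.53, 0.63),
        TreatedRow("Extract #157", -0.29, 0.77, 0.81),
        TreatedRow("Extract #167", -2.27, 0.02, 0.10),
        TreatedRow("Extract #169", -0.17, 0.86, 0.88),
    ),
)

EPI_INTESTINAL = Experiment(
    name="EpiIntestinal",
    t_untreated=2.43,
    p_untreated=0.016,
    treated=(
        TreatedRow("Extract #1", -1.37, 0.17, 0.28),
        TreatedRow("Extract #7", 1.15, 0.25, 0.36),
        TreatedRow("Extract #9", 1.43, 0.15, 0.26),
        TreatedRow("Extract #45", 1.02, 0.31, 0.41),
        TreatedRow("Extract #115", 0.21, 0.84, 0.84),
        TreatedRow("Extract #129", -0.56, 0.58, 0.63),
        TreatedRow("Extract #130", 1.56, 0.12, 0.22),
        TreatedRow("Extract #169", 1.75, 0.08, 0.16),
        TreatedRow("Extract #274", 0.99, 0.32, 0.42),
    ),
)

EXPERIMENTS: tuple[Experiment, ...] = (EPIDERM_FT, EPI_ORAL, EPI_INTESTINAL)

#: pathway count behind the published t statistics (df = 240)
N_PATHWAYS = 241
DF = N_PATHWAYS - 1
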