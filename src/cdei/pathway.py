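"""Signed pathway graphs and the matrix quantities derived from them.

A pathway is a directed graph over gene symbols in which every edge carries a
sign: +1 for activation, -1 for inhibition.  From the graph we derive the
B matrix whose entry (i, j) is the sign of the j -> i interaction divided by
gene j's out-degree; the closed form ``Acc = B (I - B)^-1 dE`` (see
:mod:`cdei.spia`) propagates expression changes through this matrix.

File dialect: tab-separated, four columns
``pathway_id<TAB>source<TAB>target<TAB>interaction`` with interaction in
{activation, inhibition}; ``#`` lines are comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as _Path
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import FormatError

_SIGN_BY_KEYWORD = {"activation": 1, "inhibition": -1}
_KEYWORD_BY_SIGN = {1: "activation", -1: "inhibition"}

HEADER = "pathway_id\tsource\ttarget\tinteraction"


@dataclass(frozen=True)
class Pathway:
    """A signed directed gene-interaction graph for one pathway.

    Parameters
    ----------
    id : str
        Short identifier, unique within a library.
    name : str
        Free-text name (may equal ``id``).
    genes : tuple of str
        Ordered unique gene symbols; this order fixes the row/column order
        of every vector and matrix derived from the pathway.
    edges : tuple of (str, str, int)
        ``(source, target, sign)`` triples with sign +1 (activation) or
        -1 (inhibition).  At most one edge per (source, target) pair.
    """

    id: str
    name: str
    genes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise FormatError(f"pathway {self.id!r}: at least one gene required")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"pathway {self.id!r}: duplicate gene symbols")
        gene_set = set(self.genes)
        seen_pairs: set[tuple[str, str]] = set()
        for src, dst, sign in self.edges:
            if src not in gene_set or dst not in gene_set:
                raise FormatError(
                    f"pathway {self.id!r}: edge ({src}, {dst}) references unknown gene"
                )
            if sign not in (1, -1):
                raise FormatError(
                    f"pathway {self.id!r}: edge ({src}, {dst}) has sign {sign}; must be +1 or -1"
                )
            if (src, dst) in seen_pairs:
                raise FormatError(
                    f"pathway {self.id!r}: duplicate edge ({src}, {dst})"
                )
            seen_pairs.add((src, dst))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_digraph(self) -> nx.DiGraph:
        """Return the pathway as a networkx DiGraph with a ``sign`` edge attribute."""
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for src, dst, sign in self.edges:
            g.add_edge(src, dst, sign=sign)
        return g

    def out_degrees(self) -> dict[str, int]:
        """Number of direct downstream targets (n_down) per gene."""
        deg = {g: 0 for g in self.genes}
        for src, _dst, _sign in self.edges:
            deg[src] += 1
        return deg


@dataclass(frozen=True)
class BetaMatrix:
    """The out-degree-normalized signed adjacency matrix B of a pathway.

    ``values[i, j] = sign(g_j -> g_i) / n_down(g_j)`` when gene ``g_j``
    directly regulates ``g_i``, else 0.  Columns of genes with no targets
    are identically zero.
    """

    pathway_id: str
    order: tuple[str, ...]
    n_down: tuple[int, ...]
    values: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.order)


def compute_beta_matrix(pathway: Pathway) -> BetaMatrix:
    """Build the B matrix of a pathway in the pathway's gene order.

    Each declared edge ``src -> dst`` with sign s contributes the entry
    ``B[dst, src] = s / n_down(src)``.  Genes with zero out-degree get an
    all-zero column (they never act as upstream regulators).
    """
    idx = {g: i for i, g in enumerate(pathway.genes)}
    n = pathway.n_genes
    deg = pathway.out_degrees()
    values = np.zeros((n, n))
    for src, dst, sign in pathway.edges:
        values[idx[dst], idx[src]] = sign / deg[src]
    return BetaMatrix(
        pathway_id=pathway.id,
        order=pathway.genes,
        n_down=tuple(deg[g] for g in pathway.genes),
        values=values,
    )


@dataclass(frozen=True)
class PathwayDiagnostics:
    """Validation report for one pathway: invertibility of (I - B),
    acyclicity (which enables the recursive oracle), and isolated genes."""

    pathway_id: str
    invertible: bool
    acyclic: bool
    isolated_genes: tuple[str, ...]
    condition_number: float


def validate_pathway(
    pathway: Pathway, beta: BetaMatrix, condition_threshold: float = 1e10
) -> PathwayDiagnostics:
    """Diagnose a pathway before the accuracy-vector solve.

    (I - B) is reported invertible when its condition number stays below
    ``condition_threshold``.  For acyclic pathways B is nilpotent, so
    (I - B) is always invertible; cycles may put an eigenvalue of B at 1.
    Pure query; never raises on a singular pathway.
    """
    if beta.pathway_id != pathway.id:
        raise ValueError("beta matrix does not belong to this pathway")
    n = pathway.n_genes
    i_minus_b = np.eye(n) - beta.values
    cond = float(np.linalg.cond(i_minus_b))
    graph = pathway.to_digraph()
    isolated = tuple(g for g in pathway.genes if graph.degree(g) == 0)
    return PathwayDiagnostics(
        pathway_id=pathway.id,
        invertible=bool(np.isfinite(cond) and cond < condition_threshold),
        acyclic=nx.is_directed_acyclic_graph(graph),
        isolated_genes=isolated,
        condition_number=cond,
    )


def load_pathways(path: str | _Path) -> list[Pathway]:
    """Parse a signed edge-list file into a list of pathways.

    One :class:`Pathway` per distinct ``pathway_id``, in first-seen order;
    within a pathway the gene order is the first-seen order of edge
    endpoints.  An empty file yields an empty list.

    Raises
    ------
    FormatError
        On a malformed row (naming the line number), an unknown interaction
        keyword, or a (pathway, source, target) pair declared with
        conflicting signs.
    """
    path = _Path(path)
    genes_by_pw: dict[str, list[str]] = {}
    edges_by_pw: dict[str, dict[tuple[str, str], int]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and [f.strip() for f in fields] == HEADER.split("\t"):
                continue
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            pw_id, src, dst, keyword = (f.strip() for f in fields)
            if keyword not in _SIGN_BY_KEYWORD:
                raise FormatError(
                    f"{path}:{lineno}: unknown interaction {keyword!r} "
                    f"(expected 'activation' or 'inhibition')"
                )
            sign = _SIGN_BY_KEYWORD[keyword]
            genes = genes_by_pw.setdefault(pw_id, [])
            edges = edges_by_pw.setdefault(pw_id, {})
            for gene in (src, dst):
                if gene not in genes:  # pathways are small; linear scan is fine
                    genes.append(gene)
            if (src, dst) in edges and edges[(src, dst)] != sign:
                raise FormatError(
                    f"{path}:{lineno}: conflicting signs for edge "
                    f"({pw_id}, {src}, {dst})"
                )
            edges[(src, dst)] = sign
    return [
        Pathway(
            id=pw_id,
            name=pw_id,
            genes=tuple(genes_by_pw[pw_id]),
            edges=tuple((s, d, sg) for (s, d), sg in edges_by_pw[pw_id].items()),
        )
        for pw_id in genes_by_pw
    ]


def write_pathways(pathways: Iterable[Pathway], path: str | _Path) -> None:
    """Write pathways in the same edge-list dialect :func:`load_pathways` reads.

    Genes without any edge cannot be represented in an edge list and are
    silently dropped on round-trip; pathways written from a loaded file
    round-trip exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(HEADER + "\n")
        for pw in pathways:
            for src, dst, sign in pw.edges:
                fh.write(f"{pw.id}\t{src}\t{dst}\t{_KEYWORD_BY_SIGN[sign]}\n")


def topological_order(pathway: Pathway) -> list[str]:
    """Topological gene order of an acyclic pathway (raises on cycles)."""
    return list(nx.topological_sort(pathway.to_digraph()))
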