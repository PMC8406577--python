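"""Readers, writers and in-memory containers for the three input formats.

The package consumes three plain-text inputs:

* an association edge list (``disease<TAB>miRNA``, one known association per
  line, ``#`` comments allowed), turned into a binary disease x miRNA matrix;
* a labelled square similarity matrix (first row and first column carry the
  identifiers), the carrier for a precomputed miRNA functional-similarity
  matrix;
* a disease-ontology edge list (``parent<TAB>child``) describing the
  MeSH-style directed acyclic graph used for semantic similarity.

Predicted scores are written back as a long-format TSV.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "DiseaseDAG",
    "SimilarityMatrix",
    "FormatError",
    "load_associations",
    "save_associations",
    "load_similarity_matrix",
    "save_similarity_matrix",
    "load_disease_dag",
    "save_disease_dag",
    "write_scores",
    "read_scores",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for x in ids:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {kind} identifiers: {dupes[:5]}")


@dataclasses.dataclass
class AssociationMatrix:
    """Binary disease x miRNA association matrix with identifier lists.

    Row ``i`` is the interaction profile of disease ``disease_ids[i]``;
    column ``j`` is the interaction profile of miRNA ``mirna_ids[j]``.
    Entries are exactly 0 or 1.
    """

    disease_ids: list[str]
    mirna_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape != (len(self.disease_ids), len(self.mirna_ids)):
            raise ValueError(
                f"X shape {self.X.shape} does not match id lists "
                f"({len(self.disease_ids)}, {len(self.mirna_ids)})"
            )
        if not np.all(np.isin(self.X, (0.0, 1.0))):
            raise ValueError("association matrix entries must be 0 or 1")
        _check_unique(self.disease_ids, "disease")
        _check_unique(self.mirna_ids, "miRNA")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.disease_ids), list(self.mirna_ids), self.X.copy()
        )

    def sparsity(self) -> dict:
        """Sparsity report: counts of known (1) and unknown (0) entries."""
        n_ones = int(self.X.sum())
        total = self.n_diseases * self.n_mirnas
        return {
            "n_diseases": self.n_diseases,
            "n_mirnas": self.n_mirnas,
            "n_known": n_ones,
            "n_zeros": total - n_ones,
            "density": n_ones / total if total else float("nan"),
        }


@dataclasses.dataclass
class DiseaseDAG:
    """Directed acyclic graph of disease terms (edges point parent -> child)."""

    graph: nx.DiGraph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "DiseaseDAG":
        g = nx.DiGraph()
        for parent, child in edges:
            if parent == child:
                raise FormatError(f"self-edge on node {parent!r}")
            g.add_edge(parent, child)
        for n in extra_nodes:
            g.add_node(n)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"graph contains a cycle: {cycle}")
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.in_degree(n) == 0}

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def ancestors(self, node: str) -> set[str]:
        """All strict ancestors of ``node`` (nodes with a directed path to it)."""
        return nx.ancestors(self.graph, node)


@dataclasses.dataclass
class SimilarityMatrix:
    """Labelled square similarity matrix with an availability mask.

    ``available[i, j]`` marks entries where the underlying measure is
    defined; integration uses it to decide when to fall back to the
    Gaussian interaction-profile kernel.
    """

    ids: list[str]
    S: np.ndarray
    available: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.available = np.asarray(self.available, dtype=bool)
        n = len(self.ids)
        if self.S.shape != (n, n) or self.available.shape != (n, n):
            raise ValueError("similarity matrix must be square and match ids")
        _check_unique(self.ids, "similarity")
        if not np.array_equal(self.available, self.available.T):
            raise ValueError("availability mask must be symmetric")
        both = self.available & self.available.T
        if not np.allclose(self.S[both], self.S.T[both], atol=1e-8):
            raise ValueError("similarity values must be symmetric where available")

    def copy(self) -> "SimilarityMatrix":
        return SimilarityMatrix(list(self.ids), self.S.copy(), self.available.copy())


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def load_associations(path: str | Path, order: str = "first-seen") -> AssociationMatrix:
    """Read a two-column association edge list into a binary matrix.

    Identifier order is first-appearance order by default (reproducible from
    the same file); pass ``order="sorted"`` for lexicographic order.
    Duplicate lines collapse to a single 1 — the matrix is binary.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'disease<TAB>miRNA', got {line!r}")
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise FormatError(f"{path}: no associations")
    diseases = list(dict.fromkeys(d for d, _ in pairs))
    mirnas = list(dict.fromkeys(m for _, m in pairs))
    if order == "sorted":
        diseases, mirnas = sorted(diseases), sorted(mirnas)
    elif order != "first-seen":
        raise ValueError(f"unknown order {order!r}")
    di = {d: i for i, d in enumerate(diseases)}
    mi = {m: j for j, m in enumerate(mirnas)}
    X = np.zeros((len(diseases), len(mirnas)))
    for d, m in pairs:
        X[di[d], mi[m]] = 1.0
    return AssociationMatrix(diseases, mirnas, X)


def save_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the association matrix back as an edge list (1-entries only)."""
    lines = ["# disease\tmiRNA"]
    for i, d in enumerate(assoc.disease_ids):
        for j in np.flatnonzero(assoc.X[i]):
            lines.append(f"{d}\t{assoc.mirna_ids[j]}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_similarity_matrix(
    path: str | Path, mask_path: str | Path | None = None
) -> SimilarityMatrix:
    """Read a labelled square text matrix.

    The availability mask defaults to ``S > 0`` (zero meaning "not measured",
    the convention of published functional-similarity files); pass
    ``mask_path`` pointing at a 0/1 matrix of the same shape when zeros are
    legitimate measured values. Slightly asymmetric input (common in
    published matrices) is symmetrized by averaging, with a warning when the
    asymmetry exceeds 1e-8.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error paths vary
        raise FormatError(f"{path}: cannot parse similarity matrix: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: matrix body is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"{path}: row labels do not match column labels")
    try:
        S = df.to_numpy(dtype=float)
    except ValueError as exc:
        bad = df.map(lambda v: not np.isreal(pd.to_numeric(v, errors="coerce")))
        cells = list(zip(*np.nonzero(bad.to_numpy())))
        raise FormatError(f"{path}: non-numeric cell at {cells[:3]}") from exc
    if np.isnan(S).any():
        cells = list(zip(*np.nonzero(np.isnan(S))))
        raise FormatError(f"{path}: non-numeric cell at (row, col) index {cells[:3]}")
    asym = float(np.abs(S - S.T).max())
    if asym > 1e-8:
        warnings.warn(
            f"{path}: similarity matrix asymmetric (max |S - S^T| = {asym:.3g}); "
            "symmetrized by averaging",
            stacklevel=2,
        )
    S = (S + S.T) / 2.0
    ids = [str(c) for c in df.columns]
    if mask_path is not None:
        mdf = pd.read_csv(Path(mask_path), sep=r"\s+", index_col=0, comment="#")
        available = mdf.to_numpy(dtype=float) > 0
        available = available & available.T
    else:
        available = S > 0
    return SimilarityMatrix(ids, S, available)


def save_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.S, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def load_disease_dag(path: str | Path) -> DiseaseDAG:
    """Read a parent->child edge list into a DiseaseDAG (cycle-checked)."""
    path = Path(path)
    edges = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'parent<TAB>child', got {line!r}")
        edges.append((fields[0], fields[1]))
    return DiseaseDAG.from_edges(edges)


def save_disease_dag(dag: DiseaseDAG, path: str | Path) -> None:
    lines = ["# parent\tchild"]
    lines += [f"{p}\t{c}" for p, c in sorted(dag.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_scores(scores, path: str | Path, known: np.ndarray | None = None) -> None:
    """Write predicted scores as long-format TSV.

    Columns: disease, miRNA, score, known_flag. Rows are grouped by disease
    (input order) and sorted by descending score, ties broken by miRNA label
    so output is deterministic. Scores round-trip at 10 significant digits.
    """
    if not np.all(np.isfinite(scores.S_hat)):
        raise ValueError("scores must be finite")
    if known is None:
        known = np.zeros_like(scores.S_hat, dtype=int)
    rows = []
    for i, d in enumerate(scores.disease_ids):
        order = sorted(
            range(len(scores.mirna_ids)),
            key=lambda j: (-scores.S_hat[i, j], scores.mirna_ids[j]),
        )
        for j in order:
            rows.append(
                f"{d}\t{scores.mirna_ids[j]}\t{scores.S_hat[i, j]:.10g}\t{int(known[i, j])}"
            )
    header = "# disease\tmiRNA\tscore\tknown"
    Path(path).write_text("\n".join([header] + rows) + "\n")


def read_scores(path: str | Path):
    """Read a score TSV written by :func:`write_scores`."""
    from .core import ScoreMatrix  # local import to avoid a cycle

    df = pd.read_csv(
        Path(path), sep="\t", comment="#",
        names=["disease", "mirna", "score", "known"],
    )
    diseases = list(dict.fromkeys(df["disease"]))
    mirnas = sorted(set(df["mirna"]))
    di = {d: i for i, d in enumerate(diseases)}
    mi = {m: j for j, m in enumerate(mirnas)}
    S = np.zeros((len(diseases), len(mirnas)))
    K = np.zeros_like(S, dtype=int)
    for row in df.itertuples(index=False):
        S[di[row.disease], mi[row.mirna]] = row.score
        K[di[row.disease], mi[row.mirna]] = row.known
    return ScoreMatrix(diseases, mirnas, S), K
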