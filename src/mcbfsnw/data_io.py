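"""Reading and writing expression matrices, labels, gene rankings and edge lists.

All downstream modules consume the container types defined here:
:class:`ExpressionDataset` (a labeled samples x genes matrix),
:class:`GeneRanking` (an ordered list of genes with scores) and
:class:`InteractionNetwork` (a simple undirected graph).

No normalization happens at load time; transforms are explicit and opt-in
(see :func:`mcbfsnw.mcbfs.standardize_values`).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GeneRanking",
    "InteractionNetwork",
    "read_expression",
    "write_expression",
    "read_labels",
    "read_edge_list",
    "write_edge_list",
    "read_ranking",
    "write_ranking",
]


@dataclass
class ExpressionDataset:
    """Labeled expression matrix, stored samples x genes.

    Parameters
    ----------
    values : (s, p) float array
        Expression values, one row per sample.
    sample_ids, gene_ids : unique string identifiers.
    labels : length-s class labels (arbitrary strings), >= 2 distinct values,
        every class non-empty.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.labels = [str(x) for x in self.labels]
        s, p = self.values.shape
        if s < 2 or p < 1:
            raise ValueError(f"need >= 2 samples and >= 1 gene, got {s} x {p}")
        if len(self.sample_ids) != s:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match matrix columns")
        if len(self.labels) != s:
            raise ValueError(
                f"label count ({len(self.labels)}) does not match sample count ({s})"
            )
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != p:
            dup = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if len(self.classes) < 2:
            raise ValueError("need >= 2 classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        """Distinct labels in order of first appearance (class index 0..c-1)."""
        seen: dict[str, None] = {}
        for y in self.labels:
            seen.setdefault(y, None)
        return list(seen)

    @property
    def class_indices(self) -> np.ndarray:
        """Integer class index per sample (by first appearance of its label)."""
        order = {y: i for i, y in enumerate(self.classes)}
        return np.array([order[y] for y in self.labels], dtype=int)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given genes, preserving the requested order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        cols = [idx[g] for g in gene_ids]
        return ExpressionDataset(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            gene_ids=list(gene_ids),
            labels=list(self.labels),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and self.labels == other.labels
            and np.allclose(self.values, other.values)
        )


@dataclass
class GeneRanking:
    """Ordered gene list, best first, with non-increasing scores."""

    gene_ids: list[str]
    weights: list[float]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.weights = [float(w) for w in self.weights]
        if len(self.gene_ids) != len(self.weights):
            raise ValueError("gene_ids and weights must have the same length")
        w = np.asarray(self.weights)
        if w.size and np.any(np.diff(w) > 1e-12):
            raise ValueError("ranking weights must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> "GeneRanking":
        if not 1 <= k <= len(self):
            raise ValueError(f"k={k} out of range [1, {len(self)}]")
        return GeneRanking(self.gene_ids[:k], self.weights[:k])

    def rank_of(self, gene_id: str) -> int:
        """1-based rank of a gene."""
        return self.gene_ids.index(gene_id) + 1


@dataclass
class InteractionNetwork:
    """Simple undirected graph: no self-loops, no parallel edges."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                logger.warning("dropping self-loop on node %r", a)
                continue
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


def _sep_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if os.path.splitext(str(path))[1].lower() == ".csv" else "\t"


def _numeric_matrix(df: pd.DataFrame, path: str) -> np.ndarray:
    """Convert a DataFrame body to floats, naming the first bad cell."""
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna()
        bad |= df[col].isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric or empty cell at row {df.index[i]!r}, "
                f"column {col!r}"
            )
        out[:, j] = converted.to_numpy()
    return out


def read_labels(path: str, delimiter: str | None = None) -> list[str] | dict[str, str]:
    """Read sample labels from a sidecar file.

    One column: positional labels (one per sample, matrix order).
    Two columns: sample_id -> label mapping. A header line ``sample<tab>label``
    is skipped if present.
    """
    sep = _sep_for(path, delimiter)
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            rows.append([c.strip() for c in line.split(sep)])
    if not rows:
        raise ValueError(f"{path}: empty label file")
    if rows[0][:2] in (["sample", "label"],):
        rows = rows[1:]
    widths = {len(r) for r in rows}
    if widths == {1}:
        return [r[0] for r in rows]
    if widths == {2}:
        return {r[0]: r[1] for r in rows}
    raise ValueError(f"{path}: label file must have 1 or 2 columns throughout")


def read_expression(
    path: str,
    orientation: str = "genes_as_rows",
    label_source: str | Sequence[str] | Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Load a delimited expression matrix plus labels into an ExpressionDataset.

    ``orientation`` is ``genes_as_rows`` (default, the common convention for
    expression text dumps) or ``samples_as_rows``; internally everything is
    normalized to samples x genes. ``label_source`` is a label file path, an
    in-memory list (positional) or mapping (by sample id).
    """
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = _numeric_matrix(df, str(path))
    if orientation == "genes_as_rows":
        gene_ids = list(df.index)
        sample_ids = list(df.columns)
        values = values.T
    else:
        sample_ids = list(df.index)
        gene_ids = list(df.columns)

    if label_source is None:
        raise ValueError("labels are required (path, list or mapping)")
    if isinstance(label_source, (str, os.PathLike)):
        label_source = read_labels(str(label_source), delimiter)
    if isinstance(label_source, Mapping):
        missing = [s for s in sample_ids if s not in label_source]
        if missing:
            raise ValueError(f"no label for samples: {missing[:5]}")
        labels = [label_source[s] for s in sample_ids]
    else:
        labels = [str(x) for x in label_source]
        if len(labels) != len(sample_ids):
            raise ValueError(
                f"label count ({len(labels)}) does not match sample count "
                f"({len(sample_ids)})"
            )
    return ExpressionDataset(values, sample_ids, gene_ids, labels)


def write_expression(
    data: ExpressionDataset,
    path: str,
    orientation: str = "genes_as_rows",
    delimiter: str | None = None,
) -> None:
    sep = _sep_for(path, delimiter)
    df = pd.DataFrame(data.values.T, index=data.gene_ids, columns=data.sample_ids)
    if orientation == "samples_as_rows":
        df = df.T
    elif orientation != "genes_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=sep)


def read_edge_list(path: str, dialect: str = "tsv_pairs") -> InteractionNetwork:
    """Read an undirected edge list (two-column TSV or SIF).

    Repeated/reversed pairs collapse to one edge; self-loops are dropped with
    a warning; blank node names are an error. SIF lines are
    ``node relation node [node ...]`` and fan out to one edge per target.
    """
    if dialect not in ("tsv_pairs", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p.strip() for p in parts]
            if dialect == "tsv_pairs":
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(f"{path}:{lineno}: need two non-blank node names")
                edges.append((parts[0], parts[1]))
            else:  # SIF: source relation target...
                if len(parts) == 1 and parts[0]:
                    continue  # isolated node declaration
                if len(parts) < 3 or any(not p for p in parts):
                    raise ValueError(f"{path}:{lineno}: malformed SIF line")
                src = parts[0]
                for tgt in parts[2:]:
                    edges.append((src, tgt))
    return InteractionNetwork.from_edges(edges)


def write_edge_list(net: InteractionNetwork, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")


RANKING_HEADER = "gene\tweight"


def write_ranking(ranking: GeneRanking, path: str) -> None:
    """Write a two-column TSV (gene, weight), order preserved."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(RANKING_HEADER + "\n")
        for g, w in zip(ranking.gene_ids, ranking.weights):
            fh.write(f"{g}\t{w!r}\n")


def read_ranking(path: str) -> GeneRanking:
    genes: list[str] = []
    weights: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if lineno == 1 or line == RANKING_HEADER:
                if line.split("\t")[0] == "gene":
                    continue
            g, w = line.split("\t")
            genes.append(g)
            weights.append(float(w))
    return GeneRanking(genes, weights)
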