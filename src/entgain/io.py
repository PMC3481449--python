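"""Core data model and text I/O.

Two in-memory containers are shared by every other module:

:class:`ExpressionMatrix`
    A genes x time-points table. Values are real numbers before
    preprocessing, or ternary codes {-1, 0, +1} plus an explicit
    not-observed code (3 by default) after quantization.

:class:`Network`
    A set of unordered gene pairs over a gene universe. Gold standards,
    prior-knowledge networks and inferred networks all share this shape;
    self-pairs are excluded because auto-regulatory relationships are
    outside the method's scope.

On-disk formats are plain text: an expression matrix is one row per gene
(gene id followed by T numeric fields, tab- or whitespace-separated); a
network is a two-column edge list. An edge list cannot represent isolated
genes, so the writer optionally emits a sidecar ``.genes`` file with one
gene id per line, and the reader picks it up when present.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DuplicateGeneError, FormatError

logger = logging.getLogger(__name__)

#: Default code marking a not-observed time point in quantized matrices.
MISSING_CODE = 3

TERNARY = (-1, 0, 1)


@dataclass
class ExpressionMatrix:
    """Genes x time-points expression table.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers.
    values
        Array of shape (n_genes, T). Float for raw data; integer codes
        {-1, 0, +1, missing_code} once quantized.
    quantized
        True iff every non-missing value is a ternary code.
    missing_code
        Integer code marking a not-observed measurement.
    """

    gene_ids: list[str]
    values: np.ndarray
    quantized: bool = False
    missing_code: int = MISSING_CODE
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D array")
        if len(self.gene_ids) != self.values.shape[0]:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if self.values.shape[1] < 2:
            raise FormatError("an expression matrix needs at least 2 time points")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        if len(self._index) != len(self.gene_ids):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise DuplicateGeneError(f"duplicate gene id {g!r}")
                seen.add(g)
        if self.quantized:
            ok = np.isin(self.values, TERNARY + (self.missing_code,))
            if not ok.all():
                bad = self.values[~ok].flat[0]
                raise FormatError(
                    f"quantized matrix contains non-ternary value {bad!r}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_timepoints(self) -> int:
        return int(self.values.shape[1])

    def series(self, gene: str) -> np.ndarray:
        """Return the time series of one gene (1-D view)."""
        from .errors import LookupError_

        try:
            return self.values[self._index[gene]]
        except KeyError:
            raise LookupError_(f"gene {gene!r} not in expression matrix") from None

    def observed_mask(self) -> np.ndarray:
        """Boolean array, True where a value was observed."""
        if self.quantized:
            return self.values != self.missing_code
        return ~np.isnan(self.values)

    def n_observed(self) -> np.ndarray:
        """Per-gene count of observed time points."""
        return self.observed_mask().sum(axis=1)

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Rows for ``genes``, preserving this matrix's gene order."""
        keep = set(genes)
        rows = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in rows],
            self.values[rows],
            quantized=self.quantized,
            missing_code=self.missing_code,
        )


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Network:
    """Undirected network: a gene universe and a set of unordered pairs.

    Edges are stored canonically as sorted 2-tuples; self-pairs are
    rejected and both endpoints of every edge must be in ``genes``.
    Isolated genes (in ``genes`` but in no edge) are permitted — gold
    standard gene counts include them when a sidecar gene list exists.
    """

    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @staticmethod
    def build(
        edges: Iterable[tuple[str, str]], genes: Iterable[str] = ()
    ) -> "Network":
        """Canonicalize pairs, drop self-pairs, close the gene universe."""
        eset: set[tuple[str, str]] = set()
        gset: set[str] = set(genes)
        for a, b in edges:
            if a == b:
                logger.warning("dropping self-pair (%s, %s)", a, b)
                gset.add(a)
                continue
            eset.add(_canonical_edge(a, b))
            gset.add(a)
            gset.add(b)
        return Network(frozenset(gset), frozenset(eset))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _canonical_edge(a, b) in self.edges

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.genes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def read_expression(path: str | Path, missing_code: int = MISSING_CODE) -> ExpressionMatrix:
    """Read a gene-per-row expression matrix from a text file.

    Each non-empty row holds a gene id followed by T numeric fields,
    separated by tabs or runs of spaces. The matrix is flagged quantized
    iff every non-missing value is in {-1, 0, +1}.
    """
    path = Path(path)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    width: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            gene, *fields = tokens
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected gene id + >=2 values, got {len(fields)}"
                )
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(fields)} values, expected {width}"
                )
            if gene in gene_ids:
                raise DuplicateGeneError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            gene_ids.append(gene)
    if not rows:
        raise FormatError(f"{path}: empty expression file")
    values = np.asarray(rows)
    nonmissing = values[values != missing_code]
    is_ternary = bool(
        np.isin(nonmissing, TERNARY).all() and np.equal(np.mod(values, 1), 0).all()
    )
    if is_ternary:
        values = values.astype(int)
    return ExpressionMatrix(
        gene_ids, values, quantized=is_ternary, missing_code=missing_code
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the row-per-gene text format (tab separators)."""
    path = Path(path)
    with path.open("w") as fh:
        for gene, row in zip(matrix.gene_ids, matrix.values):
            if matrix.quantized:
                fields = "\t".join(str(int(v)) for v in row)
            else:
                fields = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{gene}\t{fields}\n")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".genes")


def read_network(path: str | Path) -> Network:
    """Read a two-column edge list; accepts a ``.genes`` sidecar.

    Self-pairs are dropped with a warning and duplicate pairs (either
    order) collapse to a single canonical edge.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 gene ids, got {len(tokens)}"
                )
            edges.append((tokens[0], tokens[1]))
    genes: list[str] = []
    sidecar = _sidecar(path)
    if sidecar.exists():
        genes = [t for t in sidecar.read_text().split() if t]
    return Network.build(edges, genes)


def write_network(net: Network, path: str | Path, sidecar_genes: bool = True) -> None:
    """Write one canonical pair per line; isolated genes go to a sidecar.

    ``read_network(write_network(n)) == n`` holds whenever
    ``sidecar_genes`` is left on (an edge list alone cannot carry
    isolated genes).
    """
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
    isolated = net.genes - {g for e in net.edges for g in e}
    if sidecar_genes and isolated:
        _sidecar(path).write_text("\n".join(sorted(net.genes)) + "\n")


def n_pairs(n: int) -> int:
    """Number of unordered pairs of distinct items among n."""
    return math.comb(n, 2)
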