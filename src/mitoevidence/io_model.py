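"""Domain containers and TSV readers/writers shared by the whole pipeline.

The pipeline consumes five kinds of tabular input: a gold-standard protein
catalog (experimentally verified mitochondrial positives and non-mitochondrial
negatives), a protein x predictor matrix of binary localization calls, gene x
sample expression matrices, an undirected protein-interaction edge list, and a
protein -> GO-term annotation table restricted to a configured set of GO
levels.  All formats are header-bearing TSV; protein identifiers are opaque,
case-sensitive tokens (AGI symbols in the motivating data).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("mitoevidence")

#: token written/read for a missing predictor call
MISSING_TOKEN = "NA"


class ParseError(ValueError):
    """A file does not conform to its declared tabular format."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ProteinCatalog:
    """Protein ids with gold-standard localization labels.

    ``entries`` is a list of ``(protein_id, label, source)`` tuples.  Ids must
    be unique and the positive and negative sets are disjoint by construction
    (each id carries exactly one label).
    """

    entries: list[tuple[str, Label, str]]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate protein ids in catalog")
        for _, label, _ in self.entries:
            if not isinstance(label, Label):
                raise ValidationError(f"invalid label {label!r}")

    @property
    def protein_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def labels(self) -> dict[str, Label]:
        return {pid: lab for pid, lab, _ in self.entries}

    def ids_with_label(self, label: Label) -> set[str]:
        return {pid for pid, lab, _ in self.entries if lab is label}

    @property
    def positives(self) -> set[str]:
        return self.ids_with_label(Label.POSITIVE)

    @property
    def negatives(self) -> set[str]:
        return self.ids_with_label(Label.NEGATIVE)

    @property
    def unknowns(self) -> set[str]:
        return self.ids_with_label(Label.UNKNOWN)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FeatureMatrix:
    """Protein x predictor binary calls; missing calls stored as NaN."""

    protein_ids: list[str]
    predictor_ids: list[str]
    calls: np.ndarray  # float array, entries in {0.0, 1.0, nan}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError("duplicate protein ids in feature matrix")
        if len(set(self.predictor_ids)) != len(self.predictor_ids):
            raise ValidationError("duplicate predictor ids in feature matrix")
        if self.calls.shape != (len(self.protein_ids), len(self.predictor_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.predictor_ids)} predictors"
            )
        finite = self.calls[~np.isnan(self.calls)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValidationError("calls must be 0, 1 or missing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.protein_ids, columns=self.predictor_ids
        )

    def column(self, predictor_id: str) -> np.ndarray:
        try:
            j = self.predictor_ids.index(predictor_id)
        except ValueError:
            raise ValidationError(f"unknown predictor id {predictor_id!r}") from None
        return self.calls[:, j]


@dataclass
class ExpressionDataset:
    """One normalized expression matrix (genes x samples), unitless."""

    dataset_id: str
    gene_ids: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"duplicate gene ids in dataset {self.dataset_id}")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValidationError(
                f"dataset {self.dataset_id}: value matrix shape mismatch"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"dataset {self.dataset_id}: non-finite values")


class InteractionNetwork:
    """Undirected, unweighted protein-interaction network.

    Thin wrapper over :class:`networkx.Graph` enforcing no self-loops and no
    duplicate edges.
    """

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if u not in g or v not in g:
                raise ValidationError(f"edge ({u!r}, {v!r}) endpoint not in node set")
            g.add_edge(u, v)
        self._g = g

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "InteractionNetwork":
        net = cls.__new__(cls)
        if any(u == v for u, v in g.edges):
            raise ValidationError("graph contains self-loops")
        net._g = nx.Graph(g)
        return net

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, p: str) -> set[str]:
        if p not in self._g:
            raise ValidationError(f"unknown protein {p!r}")
        return set(self._g.neighbors(p))

    def __contains__(self, p: str) -> bool:
        return p in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass
class AnnotationMap:
    """Protein -> function-term records, each tagged with a GO level."""

    records: frozenset  # of (protein_id, term_id, level)

    def __post_init__(self) -> None:
        self.records = frozenset(self.records)
        for rec in self.records:
            if len(rec) != 3 or not isinstance(rec[2], int):
                raise ValidationError(f"malformed annotation record {rec!r}")
        self._by_protein: dict[str, set[str]] = {}
        for pid, term, _ in self.records:
            self._by_protein.setdefault(pid, set()).add(term)

    def terms_of(self, protein_id: str) -> set[str]:
        return set(self._by_protein.get(protein_id, set()))

    @property
    def annotated_proteins(self) -> set[str]:
        return set(self._by_protein)

    @property
    def terms(self) -> set[str]:
        return {t for _, t, _ in self.records}

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [ln for ln in text.splitlines() if ln.strip()]


def read_catalog(path: str | Path) -> ProteinCatalog:
    """Read a gold-standard TSV with columns protein_id, label[, source]."""
    lines = _read_lines(path)
    if not lines:
        raise ValidationError(f"{path}: empty catalog file")
    header = lines[0].split("\t")
    if header[0] != "protein_id":
        raise ParseError(f"{path}: expected 'protein_id' header, got {header[0]!r}")
    entries = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) < 2:
            raise ParseError(f"{path}: line {i}: expected >= 2 columns")
        pid, lab = cells[0], cells[1]
        try:
            label = Label(lab)
        except ValueError:
            raise ParseError(f"{path}: line {i}: unknown label {lab!r}") from None
        source = cells[2] if len(cells) > 2 else ""
        entries.append((pid, label, source))
    return ProteinCatalog(entries)


def read_feature_table(path: str | Path, missing_token: str = MISSING_TOKEN) -> FeatureMatrix:
    """Read a protein x predictor TSV of {1, 0, missing} calls.

    First row holds predictor ids, first column protein ids.  Malformed rows
    raise :class:`ParseError` naming the line; duplicate protein ids raise
    :class:`ValidationError`.
    """
    lines = _read_lines(path)
    if not lines:
        raise ValidationError(f"{path}: empty feature table")
    header = lines[0].split("\t")
    predictor_ids = header[1:]
    ncol = len(header)
    protein_ids: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != ncol:
            raise ParseError(
                f"{path}: line {i}: expected {ncol} columns, found {len(cells)}"
            )
        protein_ids.append(cells[0])
        row = []
        for j, cell in enumerate(cells[1:]):
            if cell == missing_token:
                row.append(float("nan"))
            elif cell in ("0", "1"):
                row.append(float(cell))
            else:
                raise ParseError(
                    f"{path}: line {i}: invalid call {cell!r} for predictor "
                    f"{predictor_ids[j]!r}"
                )
        rows.append(row)
    if len(set(protein_ids)) != len(protein_ids):
        raise ValidationError(f"{path}: duplicate protein ids")
    return FeatureMatrix(protein_ids, predictor_ids, np.array(rows, dtype=float))


#: header written by write_edge_list and recognised (and skipped) on read
_EDGE_HEADERS = {("protein_a", "protein_b"), ("source", "target")}


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Read a two-column TSV edge list into an undirected network.

    Reciprocal and duplicate lines collapse silently; self-loops are dropped
    with a logged count.  An empty file is a validation error.
    """
    lines = _read_lines(path)
    if not lines:
        raise ValidationError(f"{path}: empty edge list")
    start = 0
    first = tuple(lines[0].split("\t")[:2])
    if first in _EDGE_HEADERS:
        start = 1
    nodes: set[str] = set()
    edges: set[frozenset] = set()
    n_self = 0
    for i, ln in enumerate(lines[start:], start=start + 1):
        cells = ln.split("\t")
        if len(cells) < 2:
            raise ParseError(f"{path}: line {i}: expected 2 columns")
        u, v = cells[0], cells[1]
        nodes.add(u)
        nodes.add(v)
        if u == v:
            n_self += 1
            continue
        edges.add(frozenset((u, v)))
    if n_self:
        logger.info("read_edge_list(%s): dropped %d self-loop line(s)", path, n_self)
    return InteractionNetwork(nodes, [tuple(sorted(e)) for e in edges])


def read_annotations(path: str | Path, allowed_levels: set[int] = frozenset({4, 5})) -> AnnotationMap:
    """Read a three-column TSV (protein_id, term_id, level).

    Records outside ``allowed_levels`` are dropped with a logged count;
    duplicates collapse.  A non-integer level raises :class:`ParseError`.
    """
    lines = _read_lines(path)
    records: set[tuple[str, str, int]] = set()
    n_dropped = 0
    start = 0
    if lines and lines[0].split("\t")[0] == "protein_id":
        start = 1
    for i, ln in enumerate(lines[start:], start=start + 1):
        cells = ln.split("\t")
        if len(cells) < 3:
            raise ParseError(f"{path}: line {i}: expected 3 columns")
        pid, term, lev = cells[0], cells[1], cells[2]
        try:
            level = int(lev)
        except ValueError:
            raise ParseError(f"{path}: line {i}: non-integer level {lev!r}") from None
        if level not in allowed_levels:
            n_dropped += 1
            continue
        records.add((pid, term, level))
    if n_dropped:
        logger.info(
            "read_annotations(%s): dropped %d record(s) outside levels %s",
            path, n_dropped, sorted(allowed_levels),
        )
    return AnnotationMap(frozenset(records))


def read_expression_table(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a genes x samples TSV into an :class:`ExpressionDataset`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if dataset_id is None:
        dataset_id = Path(path).stem
    return ExpressionDataset(
        dataset_id=dataset_id,
        gene_ids=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Writers (exact inverses of the readers above)
# ---------------------------------------------------------------------------

def write_catalog(catalog: ProteinCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tlabel\tsource\n")
        for pid, label, source in catalog.entries:
            fh.write(f"{pid}\t{label.value}\t{source}\n")


def write_feature_table(
    fm: FeatureMatrix, path: str | Path, missing_token: str = MISSING_TOKEN
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\t" + "\t".join(fm.predictor_ids) + "\n")
        for pid, row in zip(fm.protein_ids, fm.calls):
            cells = [
                missing_token if np.isnan(x) else str(int(x)) for x in row
            ]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for e in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
    # isolated nodes are not representable in an edge list; callers that need
    # the full node set persist the catalog alongside.


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tterm_id\tlevel\n")
        for pid, term, level in sorted(ann.records):
            fh.write(f"{pid}\t{term}\t{level}\n")


def write_expression_table(ds: ExpressionDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.samples)
    df.to_csv(path, sep="\t", index_label="gene_id")
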