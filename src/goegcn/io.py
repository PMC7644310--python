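"""Readers, writers and the core data model for expression pipelines.

Canonical on-disk dialect is TSV with a header row (comma fallback via
``sep=","``). Gene and sample identifiers are opaque, case-sensitive
strings; no symbol/ID mapping is attempted. Readers preserve file order
and never silently reorder genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
EXPERIMENT = "experiment"


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicates, negatives, ...)."""


class ParseError(ValueError):
    """A file could not be parsed into the expected shape."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of nonnegative expression values.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers, in file/construction order.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        FPKM-like or count values. Must be finite; nonnegative when
        ``scale_tag == "linear"``.
    scale_tag : {"linear", "log2"}
        Whether values are on the raw or log2 scale.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale_tag not in ("linear", "log2"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene id {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.scale_tag == "linear" and (self.values < 0).any():
            raise ValidationError("linear-scale expression values must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Row-subset in the given order; unknown genes raise KeyError."""
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[rows, :], self.scale_tag)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = self.sample_index()
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples),
                                self.values[:, cols], self.scale_tag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (self.gene_ids == other.gene_ids
                and self.sample_ids == other.sample_ids
                and self.scale_tag == other.scale_tag
                and np.array_equal(self.values, other.values))


@dataclass
class GroupDesign:
    """Binary control/experiment assignment of samples.

    ``labels`` maps sample id -> ``"control"`` or ``"experiment"``. Both
    labels must occur at least twice.
    """

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {CONTROL, EXPERIMENT}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        counts = self.counts()
        for lab in (CONTROL, EXPERIMENT):
            if counts[lab] < 2:
                raise ValidationError(f"group {lab!r} has {counts[lab]} samples; need >= 2")

    def counts(self) -> dict[str, int]:
        c = {CONTROL: 0, EXPERIMENT: 0}
        for v in self.labels.values():
            c[v] += 1
        return c

    def group_samples(self, label: str, sample_order: list[str] | None = None) -> list[str]:
        """Samples in the group, in ``sample_order`` if given (else insertion order)."""
        if sample_order is None:
            return [s for s, v in self.labels.items() if v == label]
        return [s for s in sample_order if self.labels.get(s) == label]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = set(self.labels) - set(expr.sample_ids)
        if missing:
            raise ValidationError(f"labelled samples absent from matrix: {sorted(missing)[:5]}")


@dataclass
class GeneSetAnnotation:
    """Gene-set annotation (GO terms, pathways, ...) as flat sets.

    ``terms`` maps term_id -> (term_name, frozenset of gene ids); every
    term has at least one gene.
    """

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if len(genes) == 0:
                raise ValidationError(f"term {tid!r} has no genes")

    def __len__(self) -> int:
        return len(self.terms)

    def term_ids(self) -> list[str]:
        return list(self.terms)

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path, rows_are_genes: bool = True, sep: str = "\t",
                    scale_tag: str = "linear") -> ExpressionMatrix:
    """Read an expression TSV: header row of sample ids, first column gene ids.

    Set ``rows_are_genes=False`` for a transposed (samples x genes) file.
    Non-numeric cells and duplicated gene ids are rejected with the
    offending row/column named.
    """
    df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str,
                     keep_default_na=False)
    if not rows_are_genes:
        df = df.T
    values = np.empty(df.shape, dtype=float)
    cols = list(df.columns)
    for j, col in enumerate(cols):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(f"non-numeric value at row {bad!r}, column {col!r} in {path}")
    genes = [str(g) for g in df.index]
    dup = _first_duplicate(genes)
    if dup is not None:
        raise ValidationError(f"duplicate gene id {dup!r} in {path}")
    return ExpressionMatrix(genes, [str(c) for c in cols], values, scale_tag)


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_group_design(path, sep: str = "\t") -> GroupDesign:
    """Read a two-column sample_id <tab> label file (header optional).

    Labels must be 'control' or 'experiment'; a header line of the form
    'sample_id<tab>label' is skipped.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            sid, lab = parts[0].strip(), parts[1].strip()
            if lineno == 1 and lab not in (CONTROL, EXPERIMENT):
                continue  # header
            if sid in labels:
                raise ValidationError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            labels[sid] = lab
    return GroupDesign(labels)


def write_group_design(design: GroupDesign, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"sample_id{sep}label\n")
        for sid, lab in design.labels.items():
            fh.write(f"{sid}{sep}{lab}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetAnnotation:
    """Read a GMT file: term_id <tab> description <tab> gene1 <tab> gene2 ...

    Blank lines are skipped; a line with fewer than 3 fields is a parse
    error (a term must annotate at least one gene).
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(parts)}")
            tid, name = parts[0], parts[1]
            if tid in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {tid!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {tid!r} lists no genes")
            terms[tid] = (name, genes)
    return GeneSetAnnotation(terms)


def write_gmt(annotation: GeneSetAnnotation, path) -> None:
    with open(path, "w") as fh:
        for tid, (name, genes) in annotation.terms.items():
            fh.write("\t".join([tid, name] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# regulatory edge lists


def read_edge_list(path, sep: str = "\t"):
    """Read a regulator <tab> target edge list into a :class:`RegulatoryNetwork`.

    Duplicate edges are collapsed; self-loops are dropped with a warning
    (self-regulation has no meaning in the weight fixed point).
    """
    from .regnet import RegulatoryNetwork  # local import to avoid a cycle

    edges: list[tuple[str, str]] = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(f"{path}:{lineno}: expected 'regulator{sep}target'")
            reg, tgt = parts[0].strip(), parts[1].strip()
            if lineno == 1 and (reg, tgt) == ("regulator", "target"):
                continue  # header
            if reg == tgt:
                n_self += 1
                continue
            edges.append((reg, tgt))
    if n_self:
        msg = f"dropped {n_self} self-loop(s) while reading {path}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return RegulatoryNetwork.from_edges(edges)


def write_edge_list(net, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for reg, tgt in sorted(net.edges):
            fh.write(f"{reg}{sep}{tgt}\n")


# ---------------------------------------------------------------------------
# SIF export for coexpression edges


def write_sif(edges, path, relation: str = "pp") -> None:
    """Write unordered gene pairs as SIF lines ``geneA pp geneB``."""
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
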