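"""Per-group Pearson coexpression networks and differential-edge extraction.

Each group's network is the upper triangle of the gene-gene Pearson
correlation matrix, pruned at a hard threshold. Comparing the two
pruned structures yields three disjoint edge classes: *inhibited*
couples (present only in the control network), *activated* couples
(present only in the experiment network) and *shared* couples. Only
edge presence matters in the comparison, not the correlation value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, ValidationError

Edge = tuple[str, str]  # unordered pair stored with i < j in network gene order


@dataclass
class CoexpressionNetwork:
    """Pruned upper-triangular coexpression network for one group."""

    genes: list[str]
    edges: dict[Edge, float]  # (gene_i, gene_j) with index(i) < index(j) -> PCC
    threshold: float
    mode: str = "signed"
    group: str = ""

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[Edge]:
        return set(self.edges)


@dataclass
class DifferentialEdgeSets:
    """Disjoint partition of two pruned networks' edges."""

    inhibited: set[Edge]  # control-only
    activated: set[Edge]  # experiment-only
    shared: set[Edge]

    def __post_init__(self) -> None:
        if (self.inhibited & self.activated or self.inhibited & self.shared
                or self.activated & self.shared):
            raise ValidationError("differential edge sets must be pairwise disjoint")


def pearson_matrix(expr_log: ExpressionMatrix, genes=None, samples=None) -> np.ndarray:
    """Gene-gene Pearson correlation across a sample subset.

    Returns a symmetric matrix with unit diagonal, rows/cols in the
    order of ``genes`` (defaults to all genes). Zero-variance genes have
    undefined correlations; those entries are set to 0 with a warning so
    they can never form an edge.
    """
    sub = expr_log
    if genes is not None:
        sub = sub.subset_genes(list(genes))
    if samples is not None:
        sub = sub.subset_samples(list(samples))
    if sub.n_samples < 3:
        raise ValidationError(f"need >= 3 samples to correlate, got {sub.n_samples}")
    x = sub.values
    sd = x.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.atleast_2d(corr)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); their correlations set to 0",
            stacklevel=2)
        corr[flat, :] = 0.0
        corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def prune_network(corr: np.ndarray, genes, threshold: float = 0.3,
                  mode: str = "signed", group: str = "") -> CoexpressionNetwork:
    """Keep upper-triangular pairs meeting the correlation cutoff.

    ``signed`` mode retains PCC >= threshold (the default reading of the
    hard-threshold rule); ``absolute`` retains |PCC| >= threshold. The
    diagonal is never retained.
    """
    genes = list(genes)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (len(genes), len(genes)):
        raise ValidationError("correlation matrix shape does not match gene list")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    vals = corr if mode == "signed" else np.abs(corr)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = vals[iu, ju] >= threshold
    edges = {(genes[i], genes[j]): float(corr[i, j])
             for i, j in zip(iu[keep], ju[keep])}
    return CoexpressionNetwork(genes, edges, threshold, mode, group)


def differential_edges(control_net: CoexpressionNetwork,
                       experiment_net: CoexpressionNetwork) -> DifferentialEdgeSets:
    """Partition the two networks' edges into inhibited / activated / shared.

    Edge identity is the unordered gene pair; both networks must share
    the same gene list and order so pairs are directly comparable.
    """
    if control_net.genes != experiment_net.genes:
        raise ValidationError("paired networks must share the same gene list and order")
    c, e = control_net.edge_set(), experiment_net.edge_set()
    return DifferentialEdgeSets(inhibited=c - e, activated=e - c, shared=c & e)


def group_networks(expr_log: ExpressionMatrix, genes, control_samples,
                   experiment_samples, threshold: float = 0.3,
                   mode: str = "signed") -> tuple[CoexpressionNetwork, CoexpressionNetwork]:
    """Convenience: build both pruned group networks over one gene list."""
    cn = prune_network(pearson_matrix(expr_log, genes, control_samples),
                       genes, threshold, mode, group="control")
    en = prune_network(pearson_matrix(expr_log, genes, experiment_samples),
                       genes, threshold, mode, group="experiment")
    return cn, en
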