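"""Gene weights on a directed regulatory network.

A gene's weight measures how many targets it (transitively) regulates:
weight flows from targets back to their regulators through the damped
fixed point

    W(g_i) = (1 - d)/N + d * sum_{g_j in T(g_i)} W(g_j) / L(g_j)

where T(g_i) is the target set of g_i and L(g_j) the number of
regulators of g_j. This is the printed recurrence as-is — no dangling
redistribution and no renormalisation, so weights need not sum to 1.
The iteration always contracts: the update matrix has unit column sums
at most, so its spectral radius is <= 1 and the damped map is a
contraction with factor d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegulatoryNetwork:
    """Directed regulator -> target network over a fixed gene universe."""

    genes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        universe = set(self.genes)
        if len(universe) != len(self.genes):
            raise ValueError("gene universe contains duplicates")
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"self-loop {reg!r} -> {tgt!r} not allowed")
            if reg not in universe or tgt not in universe:
                raise ValueError(f"edge ({reg!r}, {tgt!r}) endpoint outside gene universe")

    @classmethod
    def from_edges(cls, edges, genes=None) -> "RegulatoryNetwork":
        """Build from an iterable of (regulator, target) pairs.

        Duplicates collapse; the universe defaults to all endpoint genes
        (insertion order) unless ``genes`` is given explicitly.
        """
        edge_set = {(r, t) for r, t in edges if r != t}
        if genes is None:
            seen: dict[str, None] = {}
            for r, t in edges:
                seen.setdefault(r)
                seen.setdefault(t)
            genes = list(seen)
        return cls(list(genes), edge_set)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {g: [] for g in self.genes}
        for reg, tgt in self.edges:
            out[reg].append(tgt)
        return out

    def regulator_counts(self) -> dict[str, int]:
        """In-degree L(g): how many regulators each gene has."""
        out = {g: 0 for g in self.genes}
        for _, tgt in self.edges:
            out[tgt] += 1
        return out


@dataclass
class GeneWeightVector:
    """Fixed-point weights with the damping and convergence residual used."""

    weights: dict[str, float]
    damping: float
    residual: float

    def __getitem__(self, gene: str) -> float:
        return self.weights[gene]


def compute_weights(net: RegulatoryNetwork, d: float = 0.85, tol: float = 1e-10,
                    max_iter: int = 1000) -> GeneWeightVector:
    """Iterate the damped regulatory recurrence to its fixed point.

    Starts from the uniform vector 1/N and stops when the max absolute
    update falls below ``tol``; raises if ``max_iter`` sweeps do not
    reach it. Deterministic: gene order follows the network's universe.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"damping must be in (0,1), got {d}")
    n = net.n_genes
    if n < 1:
        raise ValueError("network must contain at least one gene")
    index = {g: i for i, g in enumerate(net.genes)}
    in_deg = np.zeros(n)
    for _, tgt in net.edges:
        in_deg[index[tgt]] += 1
    # sparse-ish propagation: rows regulators, cols targets, value 1/L(target)
    regs = np.fromiter((index[r] for r, _ in net.edges), dtype=np.intp, count=len(net.edges))
    tgts = np.fromiter((index[t] for _, t in net.edges), dtype=np.intp, count=len(net.edges))
    inv_l = 1.0 / in_deg[tgts] if len(net.edges) else np.zeros(0)

    w = np.full(n, 1.0 / n)
    base = (1.0 - d) / n
    residual = 0.0
    for _ in range(max_iter):
        acc = np.zeros(n)
        np.add.at(acc, regs, w[tgts] * inv_l)
        w_new = base + d * acc
        residual = float(np.max(np.abs(w_new - w)))
        w = w_new
        if residual <= tol:
            break
    else:
        raise RuntimeError(
            f"weight iteration did not converge in {max_iter} sweeps (residual {residual:.3e})")
    return GeneWeightVector({g: float(w[index[g]]) for g in net.genes}, d, residual)


def rank_top_m(weights: GeneWeightVector, m: int) -> list[str]:
    """Top ``m`` genes by descending weight, ties broken by ascending gene id."""
    if m < 1:
        raise ValueError("m must be >= 1")
    ranked = sorted(weights.weights, key=lambda g: (-weights.weights[g], g))
    return ranked[:m]


def weighted_degs(degs: set[str], top_genes) -> list[str]:
    """Intersection of the DEG set with a top-weight ranking, sorted by gene id.

    The sorted order makes downstream edge sets and reports reproducible.
    An empty intersection is legal but flagged with a warning.
    """
    inter = sorted(set(degs) & set(top_genes))
    if not inter:
        warnings.warn("weighted-DEG intersection is empty", stacklevel=2)
    return inter
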