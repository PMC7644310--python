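"""Synthetic data with the statistical structure the pipeline assumes.

Four generators, each deterministic under an explicit seed:

* negative-binomial counts with planted log2 fold changes between a
  control and an experiment group (baseline means log-normal, variance
  mu + dispersion * mu^2);
* group-specific latent-factor coexpression modules: a shared factor
  added to member genes only in the samples of the active group(s), so
  within-module correlation appears there and nowhere else;
* a sparse directed regulatory network grown by out-degree preferential
  attachment, giving hub regulators;
* gene-set annotations partially aligned with the planted modules.

Every generator records what it planted in a :class:`SyntheticTruth` so
recovery can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CONTROL, EXPERIMENT, ExpressionMatrix, GeneSetAnnotation, GroupDesign
from .regnet import RegulatoryNetwork


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: what was planted, and where."""

    seed: int
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2 FC
    modules: list[dict] = field(default_factory=list)  # {genes, activity}
    aligned_terms: dict[str, int] = field(default_factory=dict)  # term_id -> module index
    hub_genes: list[str] = field(default_factory=list)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        offset = len(self.modules)
        return SyntheticTruth(
            seed=self.seed,
            de_genes={**self.de_genes, **other.de_genes},
            modules=self.modules + other.modules,
            aligned_terms={**self.aligned_terms,
                           **{t: i + offset for t, i in other.aligned_terms.items()}},
            hub_genes=self.hub_genes + other.hub_genes,
        )


def simulate_counts(n_genes: int, n_control: int, n_experiment: int,
                    de_fraction: float = 0.1, lfc_magnitude: float = 2.0,
                    dispersion: float = 0.1, rng_seed: int = 0,
                    mean_log2: float = 5.0, mean_sd_log2: float = 1.5,
                    de_genes: list[str] | None = None
                    ) -> tuple[ExpressionMatrix, GroupDesign, SyntheticTruth]:
    """Negative-binomial counts with planted fold changes.

    Baseline means are log-normal (log2 mean ``mean_log2``, sd
    ``mean_sd_log2``). A ``de_fraction`` of genes (or the explicit
    ``de_genes`` list) shifts its experiment-group mean by
    +/- ``lfc_magnitude`` on the log2 scale, sign chosen at random.
    Counts have variance mu + dispersion * mu^2; ``dispersion=0`` gives
    Poisson counts.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0,1]")
    rng = np.random.default_rng(rng_seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"c{i:03d}" for i in range(n_control)] + \
              [f"e{i:03d}" for i in range(n_experiment)]
    base_mu = 2.0 ** rng.normal(mean_log2, mean_sd_log2, size=n_genes)

    if de_genes is None:
        n_de = int(round(de_fraction * n_genes))
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
    else:
        gindex = {g: i for i, g in enumerate(genes)}
        de_idx = np.array([gindex[g] for g in de_genes], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=len(de_idx))
    lfc = np.zeros(n_genes)
    lfc[de_idx] = signs * lfc_magnitude

    mu = np.tile(base_mu[:, None], (1, len(samples)))
    mu[:, n_control:] *= 2.0 ** lfc[:, None]
    counts = _nb_draw(rng, mu, dispersion)

    design = GroupDesign({s: CONTROL for s in samples[:n_control]}
                         | {s: EXPERIMENT for s in samples[n_control:]})
    truth = SyntheticTruth(seed=rng_seed,
                           de_genes={genes[i]: float(lfc[i]) for i in de_idx})
    return ExpressionMatrix(genes, samples, counts.astype(float), "linear"), design, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion  # NB shape: var = mu + mu^2/size
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_modules(expr_log: ExpressionMatrix, design: GroupDesign,
                     modules: list[tuple[list[str], str]], factor_strength: float = 2.0,
                     rng_seed: int = 0) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Overlay latent-factor coexpression modules on a log-scale matrix.

    Each entry of ``modules`` is (member gene list, activity) with
    activity one of ``control``, ``experiment`` or ``both``. For each
    module a standard-normal factor f_j is drawn per sample of the
    active group(s) and lambda_g * f_j is added to each member gene,
    with loadings lambda_g = factor_strength * Uniform(0.5, 1), sign
    positive. Modules must be disjoint; sizes must be >= 3.
    """
    rng = np.random.default_rng(rng_seed)
    seen: set[str] = set()
    for genes, activity in modules:
        if len(genes) < 3:
            raise ValueError("module size must be >= 3")
        if activity not in (CONTROL, EXPERIMENT, "both"):
            raise ValueError(f"unknown module activity {activity!r}")
        overlap = seen & set(genes)
        if overlap:
            raise ValueError(f"modules overlap on {sorted(overlap)[:3]}")
        seen |= set(genes)
    values = expr_log.values.copy()
    gidx = expr_log.gene_index()
    sidx = expr_log.sample_index()
    truth = SyntheticTruth(seed=rng_seed)
    for genes, activity in modules:
        active = [s for s in expr_log.sample_ids
                  if s in design.labels and
                  (activity == "both" or design.labels[s] == activity)]
        cols = [sidx[s] for s in active]
        loadings = factor_strength * rng.uniform(0.5, 1.0, size=len(genes))
        factor = rng.normal(0.0, 1.0, size=len(cols))
        for lam, g in zip(loadings, genes):
            values[gidx[g], cols] += lam * factor
        truth.modules.append({"genes": list(genes), "activity": activity})
    out = ExpressionMatrix(list(expr_log.gene_ids), list(expr_log.sample_ids),
                           values, expr_log.scale_tag)
    return out, truth


def simulate_dataset(n_genes: int = 1000, n_per_group: int = 50,
                     module_layout: tuple[tuple[str, int], ...] = (
                         ("both", 15), ("both", 15), ("both", 15),
                         ("experiment", 15), ("control", 15)),
                     factor_strength: float = 2.0, de_fraction: float = 0.12,
                     lfc_magnitude: float = 2.0, dispersion: float = 0.1,
                     n_background_terms: int = 50, n_regulatory_edges: int = 3000,
                     hub_bias: float = 1.0, rng_seed: int = 0):
    """Compose all four generators into one study-shaped dataset.

    Produces a linear-scale count-like matrix with planted fold changes
    and latent-factor coexpression modules, a hub-biased regulatory
    network, and an annotation holding ``n_background_terms`` random
    terms plus one aligned term per module. Module genes are always
    planted as differentially expressed so they survive the DEG gate;
    the shared ("both") modules give the two group networks common
    structure, while group-specific modules create the differential
    edges the enrichment stage is meant to find. The coexpression
    overlay is applied on the log2 scale and mapped back to the linear
    scale (clipped at zero), so a pipeline that log2-transforms the
    counts recovers the planted correlation.

    Returns ``(expr, design, regnet, annotation, truth)``.
    """
    rng = np.random.default_rng(rng_seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)
    genes = [f"g{i:05d}" for i in range(n_genes)]

    n_module_genes = sum(size for _, size in module_layout)
    n_de = max(int(round(de_fraction * n_genes)), n_module_genes)
    chosen = rng.choice(n_genes, size=n_de, replace=False)
    de_genes = [genes[i] for i in chosen]
    modules: list[tuple[list[str], str]] = []
    cursor = 0
    for activity, size in module_layout:
        modules.append((de_genes[cursor:cursor + size], activity))
        cursor += size

    expr, design, truth = simulate_counts(
        n_genes, n_per_group, n_per_group, lfc_magnitude=lfc_magnitude,
        dispersion=dispersion, rng_seed=int(sub_seeds[0]), de_genes=de_genes)

    if factor_strength > 0 and modules:
        logm = ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                                np.log2(expr.values + 1.0), "log2")
        logm, mod_truth = simulate_modules(logm, design, modules, factor_strength,
                                           rng_seed=int(sub_seeds[1]))
        linear = np.clip(2.0 ** logm.values - 1.0, 0.0, None)
        expr = ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                                linear, "linear")
        truth = truth.merge(mod_truth)
    else:
        truth = truth.merge(SyntheticTruth(seed=int(sub_seeds[1]),
                                           modules=[{"genes": g, "activity": a}
                                                    for g, a in modules]))

    regnet = simulate_regulatory_network(genes, n_regulatory_edges, hub_bias,
                                         rng_seed=int(sub_seeds[2]))
    annotation, ann_truth = simulate_annotation(
        genes, n_background_terms, modules=truth.modules, rng_seed=int(sub_seeds[3]))
    truth.aligned_terms = ann_truth.aligned_terms
    return expr, design, regnet, annotation, truth


def simulate_regulatory_network(gene_ids: list[str], n_edges: int,
                                hub_bias: float = 1.0, rng_seed: int = 0
                                ) -> RegulatoryNetwork:
    """Directed network grown by out-degree preferential attachment.

    Each new edge picks its regulator with probability proportional to
    (current out-degree)^``hub_bias`` + 1 and a uniform random distinct
    target; ``hub_bias = 0`` gives uniform regulator choice. Duplicate
    edges are re-drawn, self-loops never occur.
    """
    n = len(gene_ids)
    if n_edges > n * (n - 1):
        raise ValueError("n_edges exceeds the number of possible directed edges")
    rng = np.random.default_rng(rng_seed)
    out_deg = np.zeros(n)
    edges: set[tuple[int, int]] = set()
    while len(edges) < n_edges:
        weights = out_deg ** hub_bias + 1.0 if hub_bias > 0 else np.ones(n)
        weights[out_deg >= n - 1] = 0.0  # regulator has every possible target
        probs = weights / weights.sum()
        reg = int(rng.choice(n, p=probs))
        for _ in range(20):  # fast path: rejection-sample the target
            tgt = int(rng.integers(0, n - 1))
            if tgt >= reg:
                tgt += 1
            if (reg, tgt) not in edges:
                break
        else:  # near-saturated regulator: draw from its unused targets
            free = [t for t in range(n) if t != reg and (reg, t) not in edges]
            tgt = free[int(rng.integers(0, len(free)))]
        edges.add((reg, tgt))
        out_deg[reg] += 1
    return RegulatoryNetwork(list(gene_ids),
                             {(gene_ids[r], gene_ids[t]) for r, t in edges})


def simulate_annotation(gene_ids: list[str], n_terms: int,
                        size_range: tuple[int, int] = (10, 40),
                        modules: list[dict] | None = None,
                        padding: int = 15, rng_seed: int = 0
                        ) -> tuple[GeneSetAnnotation, SyntheticTruth]:
    """Random gene-set annotation with one aligned term per planted module.

    Background terms draw their genes uniformly from the universe with
    sizes uniform in ``size_range``. For each module (dicts with a
    ``genes`` key, e.g. from :class:`SyntheticTruth`) one aligned term is
    appended containing the full module plus ``padding`` random
    non-member genes. Alignment is recorded in the returned truth.
    """
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(gene_ids):
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= universe size")
    rng = np.random.default_rng(rng_seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    truth = SyntheticTruth(seed=rng_seed)
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        tid = f"TERM:{i:04d}"
        terms[tid] = (f"background term {i}", frozenset(gene_ids[j] for j in members))
    for mi, mod in enumerate(modules or []):
        mod_genes = set(mod["genes"])
        pool = [g for g in gene_ids if g not in mod_genes]
        pad = rng.choice(len(pool), size=min(padding, len(pool)), replace=False)
        tid = f"TERM:M{mi:02d}"
        terms[tid] = (f"module-aligned term {mi}",
                      frozenset(mod_genes | {pool[j] for j in pad}))
        truth.aligned_terms[tid] = mi
        truth.modules.append(dict(mod))
    return GeneSetAnnotation(terms), truth
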