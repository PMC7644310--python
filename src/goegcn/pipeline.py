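"""End-to-end orchestration of the two analysis branches.

The enrichment branch chains: gene filter -> log2 -> moderated DE ->
regulatory weighting -> weighted-DEG intersection -> per-group Pearson
networks -> differential edges -> edge-level term enrichment. The
classification branch shares the front half and hands the weighted DEGs
to the cross-validation harness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .classify import GaussianNBClassifier, MetricsReport, repeated_stratified_cv
from .coexpression import (CoexpressionNetwork, DifferentialEdgeSets,
                           differential_edges, group_networks)
from .config import PipelineConfig
from .diffexp import DEResult, filter_genes, log2_normalize, moderated_de, select_degs
from .enrichment import EnrichmentRecord, goegcn, initial_ora
from .io import (CONTROL, EXPERIMENT, ExpressionMatrix, GeneSetAnnotation,
                 GroupDesign)
from .regnet import RegulatoryNetwork, compute_weights, rank_top_m, weighted_degs


@dataclass
class EnrichmentRunResult:
    """Everything the enrichment branch computed, for inspection or export."""

    de: DEResult
    degs: set[str]
    weighted_degs: list[str]
    control_net: CoexpressionNetwork
    experiment_net: CoexpressionNetwork
    diffs: DifferentialEdgeSets
    ora_terms: list[str]
    records: list[EnrichmentRecord]


def run_enrichment(expr: ExpressionMatrix, design: GroupDesign,
                   regnet: RegulatoryNetwork, annotation: GeneSetAnnotation,
                   config: PipelineConfig | None = None) -> EnrichmentRunResult:
    """Run the full enrichment branch on linear-scale expression input."""
    cfg = config or PipelineConfig()
    design.validate_against(expr)
    filtered = filter_genes(expr, cfg.mean_min, cfg.var_min)
    logm = log2_normalize(filtered, cfg.pseudocount)
    de = moderated_de(logm, design)
    degs = select_degs(de, cfg.lfc_min, cfg.deg_alpha)
    wvec = compute_weights(regnet, cfg.damping, cfg.weight_tol, cfg.weight_max_iter)
    top = rank_top_m(wvec, cfg.top_m_enrichment)
    wdegs = weighted_degs(degs, top)

    ctrl = design.group_samples(CONTROL, logm.sample_ids)
    expt = design.group_samples(EXPERIMENT, logm.sample_ids)
    cn, en = group_networks(logm, wdegs, ctrl, expt,
                            cfg.pcc_threshold, cfg.pcc_mode)
    diffs = differential_edges(cn, en)

    universe = annotation.all_genes() & set(filtered.gene_ids)
    query = set(wdegs) & universe
    terms, _ = initial_ora(query, annotation, universe, cfg.ora_alpha)
    records = goegcn(terms, annotation, cn, en, diffs, cfg.goegcn_alpha,
                     cfg.background, cfg.point_mass)
    return EnrichmentRunResult(de=de, degs=degs, weighted_degs=wdegs,
                               control_net=cn, experiment_net=en, diffs=diffs,
                               ora_terms=terms, records=records)


def run_classification(expr: ExpressionMatrix, design: GroupDesign,
                       regnet: RegulatoryNetwork | None = None,
                       config: PipelineConfig | None = None,
                       classifier_factory=GaussianNBClassifier) -> MetricsReport:
    """Run the classification branch: weighted DEGs as features, CV metrics out.

    Without a regulatory network the feature set is the plain DEG list
    (the weighting step is skipped).
    """
    cfg = config or PipelineConfig()
    design.validate_against(expr)
    filtered = filter_genes(expr, cfg.mean_min, cfg.var_min)
    logm = log2_normalize(filtered, cfg.pseudocount)
    de = moderated_de(logm, design)
    degs = select_degs(de, cfg.lfc_min, cfg.deg_alpha)
    if regnet is not None:
        wvec = compute_weights(regnet, cfg.damping, cfg.weight_tol, cfg.weight_max_iter)
        features = weighted_degs(degs, rank_top_m(wvec, cfg.top_m_classification))
    else:
        features = sorted(degs)
    if not features:
        raise ValueError("no weighted DEGs available as classifier features")
    sub = logm.subset_genes(features)
    X = sub.values.T  # samples x genes
    y = np.array([1 if design.labels[s] == EXPERIMENT else 0 for s in sub.sample_ids])
    return repeated_stratified_cv(X, y, classifier_factory, cfg.cv_folds,
                                  cfg.cv_repeats, cfg.use_smote, cfg.smote_k,
                                  cfg.rng_seed)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: PipelineConfig, inputs: dict[str, str],
                   stage: str) -> None:
    """Record config, seed, package version and input checksums as JSON."""
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "inputs": {name: sha256_of(p) for name, p in sorted(inputs.items())},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
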