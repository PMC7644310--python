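"""Pipeline configuration: every threshold the method uses, in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and sizes for the full weighted-DEG / enrichment pipeline.

    Attributes
    ----------
    mean_min, var_min : float
        Gene filter: keep genes with mean >= ``mean_min`` and variance >=
        ``var_min`` across all samples (linear scale).
    lfc_min, deg_alpha : float
        DEG rule: |log2 fold change| >= ``lfc_min`` and BH-adjusted
        p <= ``deg_alpha``.
    top_m_classification, top_m_enrichment : int
        How many top-weighted genes to intersect with the DEGs for the
        classification and enrichment branches, respectively.
    pcc_threshold : float
        Pearson-correlation cutoff for retaining a coexpression edge.
    pcc_mode : {"signed", "absolute"}
        Whether the cutoff applies to the signed coefficient or |PCC|.
    ora_alpha, goegcn_alpha : float
        BH-adjusted significance levels for the initial gene-level
        over-representation screen and the edge-level recalculation.
    background : {"full", "differential"}
        Edge background for the enrichment recalculation: all retained
        edges of the group network, or its differential subset only.
    point_mass : bool
        Use the hypergeometric point probability P(X = k) instead of the
        upper tail P(X >= k).
    damping : float
        Damping factor d of the regulatory-weight fixed point, in (0, 1).
    pseudocount : float
        Added before the log2 transform.
    cv_folds, cv_repeats, smote_k : int
        Cross-validation layout and SMOTE neighbourhood size.
    rng_seed : int
        Seed for every stochastic step.
    """

    mean_min: float = 0.2
    var_min: float = 2.0
    lfc_min: float = 0.5
    deg_alpha: float = 0.01
    top_m_classification: int = 1000
    top_m_enrichment: int = 3000
    pcc_threshold: float = 0.3
    pcc_mode: str = "signed"
    ora_alpha: float = 0.05
    goegcn_alpha: float = 0.05
    background: str = "full"
    point_mass: bool = False
    damping: float = 0.85
    pseudocount: float = 1.0
    weight_tol: float = 1e-10
    weight_max_iter: int = 1000
    cv_folds: int = 5
    cv_repeats: int = 100
    smote_k: int = 5
    use_smote: bool = True
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError(f"damping must be in (0,1), got {self.damping}")
        for name in ("deg_alpha", "ora_alpha", "goegcn_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("mean_min", "var_min", "lfc_min", "pcc_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pcc_mode not in ("signed", "absolute"):
            raise ValueError(f"pcc_mode must be 'signed' or 'absolute', got {self.pcc_mode!r}")
        if self.background not in ("full", "differential"):
            raise ValueError(f"background must be 'full' or 'differential', got {self.background!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
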