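"""Gene filtering, log2 normalisation and moderated differential expression.

The differential-expression engine is an empirical-Bayes moderated t on
log2 values: per-gene pooled residual variances are shrunk toward a
common prior estimated by moment matching on the log variances, and the
moderated statistic is referred to a t distribution with the prior plus
residual degrees of freedom. Any external DE table can be substituted
downstream; the rest of the pipeline only consumes the gene list defined
by the |log2FC| / adjusted-p rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CONTROL, EXPERIMENT, ExpressionMatrix, GroupDesign, ValidationError


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    ``table`` is indexed by gene id with columns ``log_fc`` (experiment
    minus control), ``t``, ``p_value``, ``adj_p_value``, ``mean_control``,
    ``mean_experiment``. ``df_prior`` and ``s2_prior`` record the fitted
    empirical-Bayes prior (``df_prior`` may be ``inf``).
    """

    table: pd.DataFrame
    df_prior: float
    s2_prior: float

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def filter_genes(expr: ExpressionMatrix, mean_min: float = 0.2,
                 var_min: float = 2.0, spread: str = "variance") -> ExpressionMatrix:
    """Keep genes with mean >= ``mean_min`` and variance >= ``var_min``.

    Both statistics are taken across all samples on the linear scale.
    ``spread="sd"`` applies the second cutoff to the standard deviation
    instead of the variance.
    """
    if expr.scale_tag != "linear":
        raise ValidationError("filter_genes expects linear-scale values")
    if spread not in ("variance", "sd"):
        raise ValueError(f"spread must be 'variance' or 'sd', got {spread!r}")
    means = expr.values.mean(axis=1)
    spreads = expr.values.var(axis=1, ddof=1) if expr.n_samples > 1 else np.zeros(expr.n_genes)
    if spread == "sd":
        spreads = np.sqrt(spreads)
    keep = (means >= mean_min) & (spreads >= var_min)
    if not keep.any():
        raise ValidationError(
            f"gene filter (mean >= {mean_min}, {spread} >= {var_min}) removed every gene")
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(expr.sample_ids), expr.values[keep, :], "linear")


def log2_normalize(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return log2(value + pseudocount) with ``scale_tag`` set to ``log2``."""
    if expr.scale_tag != "linear":
        raise ValidationError("log2_normalize expects linear-scale values")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (expr.values < 0).any():
        raise ValidationError("negative values cannot be log2-transformed")
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                            np.log2(expr.values + pseudocount), "log2")


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x).copy()
    y = 0.5 + 1.0 / x  # good starting point: trigamma(y) ~ 1/y + 1/(2y^2)
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-12 * y):
            break
    return float(y[0]) if scalar else y


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Works on z = log(s2): under the hierarchical model z - digamma(df/2)
    + log(df/2) has mean log(s0^2) + log(d0/2) - digamma(d0/2) and excess
    variance trigamma(d0/2) beyond trigamma(df/2). Returns (d0, s0^2);
    d0 = inf when the observed spread is no larger than expected under a
    single common variance.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        # no variance heterogeneity beyond sampling noise: one common variance
        return np.inf, float(s2[ok].mean())
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderated_de(expr_log: ExpressionMatrix, design: GroupDesign) -> DEResult:
    """Empirical-Bayes moderated two-group differential expression.

    Per gene g: logFC = mean(experiment) - mean(control); the pooled
    residual variance s_g^2 on d_g = n_c + n_e - 2 df is shrunk to
    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g), the moderated
    t = logFC / (s~_g * sqrt(1/n_c + 1/n_e)) is two-sided against
    t(d0 + d_g), and p-values are BH-adjusted across all tested genes.

    Genes with zero variance in both groups get p = 1 (their logFC is
    still reported); they stay in the multiple-testing denominator.
    """
    if expr_log.scale_tag != "log2":
        raise ValidationError("moderated_de expects log2-scale values")
    design.validate_against(expr_log)
    ctrl = design.group_samples(CONTROL, expr_log.sample_ids)
    expt = design.group_samples(EXPERIMENT, expr_log.sample_ids)
    if len(ctrl) < 2 or len(expt) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got control={len(ctrl)}, experiment={len(expt)}")
    sidx = expr_log.sample_index()
    xc = expr_log.values[:, [sidx[s] for s in ctrl]]
    xe = expr_log.values[:, [sidx[s] for s in expt]]
    n_c, n_e = xc.shape[1], xe.shape[1]

    mean_c = xc.mean(axis=1)
    mean_e = xe.mean(axis=1)
    log_fc = mean_e - mean_c
    df_resid = float(n_c + n_e - 2)
    ss = ((xc - mean_c[:, None]) ** 2).sum(axis=1) + ((xe - mean_e[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    df_prior, s2_prior = _fit_f_dist(s2, df_resid)
    if np.isinf(df_prior):
        s2_post = np.full_like(s2, s2_prior)
    else:
        s2_post = (df_prior * s2_prior + df_resid * s2) / (df_prior + df_resid)
    # cap the reference df at the total residual df available across genes
    df_total = min(df_prior + df_resid, expr_log.n_genes * df_resid)

    se = np.sqrt(s2_post * (1.0 / n_c + 1.0 / n_e))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log_fc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    zero_var = se == 0
    p = np.where(zero_var, 1.0, p)
    t = np.where(zero_var, 0.0, t)

    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "t": t,
            "p_value": p,
            "adj_p_value": bh_adjust(p),
            "mean_control": mean_c,
            "mean_experiment": mean_e,
        },
        index=pd.Index(expr_log.gene_ids, name="gene_id"),
    )
    return DEResult(table=table, df_prior=float(df_prior), s2_prior=float(s2_prior))


def select_degs(de: DEResult, lfc_min: float = 0.5, alpha: float = 0.01) -> set[str]:
    """Genes with |logFC| >= ``lfc_min`` and adjusted p <= ``alpha`` (both inclusive)."""
    t = de.table
    mask = (t["log_fc"].abs() >= lfc_min) & (t["adj_p_value"] <= alpha)
    return set(t.index[mask])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def write_de_table(de: DEResult, path, sep: str = "\t") -> None:
    de.table.to_csv(path, sep=sep, index_label="gene_id")


def read_de_table(path, sep: str = "\t") -> DEResult:
    """Load an externally produced DE table (same columns as :func:`write_de_table`)."""
    table = pd.read_csv(path, sep=sep, index_col="gene_id")
    required = {"log_fc", "adj_p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return DEResult(table=table, df_prior=float("nan"), s2_prior=float("nan"))
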