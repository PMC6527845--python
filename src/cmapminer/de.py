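"""Two-group differential expression with an empirical-Bayes moderated t.

Per gene, the statistic is a pooled-variance two-sample t whose variance
estimate is shrunk toward a prior fitted across genes: log sample
variances are moment-matched to a scaled F distribution, yielding prior
degrees of freedom d0 and prior variance s0^2; the moderated variance is

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d),    d = n1 + n2 - 2,

and the moderated t is referenced to a t distribution on d0 + d degrees
of freedom. With d0 = 0 this is exactly the classical equal-variance
two-sample t; with d0 = inf every gene uses the common prior variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DEResult",
    "CONTRASTS",
    "moderated_ttest",
    "differential_expression",
    "significant_genes",
    "fit_variance_prior",
]

logger = logging.getLogger(__name__)

#: contrast name -> (metadata column, group1 label, group2 label)
CONTRASTS = {
    "tumor_vs_normal": ("group", "tumor", "normal"),
    "hpv_pos_vs_neg": ("hpv", "positive", "negative"),
    "smoker_vs_non": ("smoking", "smoker", "non-smoker"),
}


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float
    t_stat: float
    p_value: float
    n1: int
    n2: int


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic starting value x ~ 0.5 + 1/y and the update on
    1/x implied by trigamma's convexity; converges in a handful of
    steps for any positive y.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    x = np.where(y < 1e-6, 1.0 / y, x)
    interior = (y >= 1e-6) & (y <= 1e7)
    for _ in range(50):
        tri = special.polygamma(1, x[interior])
        dif = tri * (1.0 - tri / y[interior]) / special.polygamma(
            2, x[interior]
        )
        x[interior] = x[interior] + dif
        if np.max(-dif / x[interior], initial=0.0) < 1e-8:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) by moment-matching log sample variances.

    If s^2 ~ s0^2 * F(df, d0), then e = log(s^2) - digamma(df/2)
    + log(df/2) has mean log(s0^2) + digamma(d0/2) - log(d0/2) and
    variance trigamma(df/2) + trigamma(d0/2); solving the variance
    equation for d0 (via the trigamma inverse) and back-substituting
    gives s0^2. A sample variance of the e's at or below trigamma(df/2)
    means no excess spread across genes: d0 = inf and s0^2 = mean(s^2).
    Zero variances are offset to 1e-5 times the median before taking
    logs.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 0.0)
    if s2.size < 2:
        return 0.0, float(np.mean(s2)) if s2.size else 1.0
    m = float(np.median(s2))
    if m == 0:
        m = 1.0
    s2 = np.maximum(s2, 1e-5 * m)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid <= 0:
        return float("inf"), float(np.mean(s2))
    d0 = float(2.0 * _trigamma_inverse(resid)[0])
    s0_2 = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0_2


def moderated_ttest(
    x1: np.ndarray, x2: np.ndarray, prior_df: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated two-sample t for each row of two genes x samples blocks.

    ``prior_df=None`` estimates the prior from the data;
    ``prior_df=0`` gives the classical pooled-variance t. Returns
    ``(log2fc, t, p)`` arrays. Genes whose moderated variance is zero
    get t = 0, p = 1 (no evidence either way).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    d = n1 + n2 - 2
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    diff = m1 - m2
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, d)
    else:
        d0 = float(prior_df)
        s0_2 = float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
    # total df capped at the pooled residual df over all genes
    df_total = min(d0 + d, len(s2) * d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    nz = se > 0
    t[nz] = diff[nz] / se[nz]
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), df_total)
    np.clip(p, np.finfo(float).tiny, 1.0, out=p)
    return diff, t, p


def differential_expression(
    ds,
    contrast: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Run one two-group contrast on a normalized, log2, gene-level dataset.

    ``contrast`` is one of ``tumor_vs_normal``, ``hpv_pos_vs_neg``,
    ``smoker_vs_non``. Samples with labels other than the two contrast
    levels (e.g. "unknown") are excluded, with the count logged. The
    result table has one row per gene: log2fc (group1 minus group2
    means), moderated t, raw two-sided p, Benjamini-Hochberg FDR and the
    group sizes. Raw p values are what the significance threshold is
    applied to; the FDR column is informational.
    """
    if contrast not in CONTRASTS:
        raise ValueError(
            f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}"
        )
    column, level1, level2 = CONTRASTS[contrast]
    if column not in ds.metadata.columns:
        raise ValueError(f"contrast {contrast}: metadata lacks column {column!r}")
    labels = ds.metadata.loc[ds.matrix.columns, column]
    g1 = labels.index[labels == level1]
    g2 = labels.index[labels == level2]
    n_excluded = len(labels) - len(g1) - len(g2)
    if n_excluded:
        logger.info(
            "contrast %s: excluded %d samples with labels outside {%s, %s}",
            contrast, n_excluded, level1, level2,
        )
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"contrast {contrast}: needs >= 2 samples per group "
            f"(got {len(g1)} {level1}, {len(g2)} {level2})"
        )
    x1 = ds.matrix[g1].to_numpy(dtype=float)
    x2 = ds.matrix[g2].to_numpy(dtype=float)
    log2fc, t, p = moderated_ttest(x1, x2, prior_df=prior_df)
    fdr = stats.false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {
            "gene_id": ds.matrix.index,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "n1": len(g1),
            "n2": len(g2),
        }
    ).set_index("gene_id", drop=False)


def significant_genes(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Genes with raw p strictly below ``alpha``."""
    return results[results["p"] < alpha]
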