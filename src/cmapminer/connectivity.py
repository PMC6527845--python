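"""Drug-gene connectivity scores from literature co-occurrence and
expression correlation.

For gene g and drug d the connectivity score is a regularized log-odds
of abstract-level co-occurrence, scaled up when the drug's annotated
target genes co-express with g::

    theta_gd = ln( (df_gd * P + lambda) / (df_g * df_d + lambda) )
               * (1 + Corr_gd)

df_gd, df_g, df_d are the numbers of abstracts mentioning both terms,
the gene, and the drug; P is the corpus size; lambda (default 1) guards
the degenerate zero-count cases; Corr_gd is the average absolute
Pearson correlation between g and the drug's targets across the
expression datasets. The log term is positive when the pair co-occurs
more often than independence predicts; a high Corr_gd amplifies
whichever sign the literature evidence has.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import AbstractAnnotation

__all__ = [
    "ConnectivityScore",
    "cooccurrence_counts",
    "target_correlation",
    "connectivity_score",
    "build_connectivity_matrix",
]


@dataclass(frozen=True)
class ConnectivityScore:
    gene_id: str
    drug_id: str
    df_gd: int
    df_g: int
    df_d: int
    p_total: int
    corr_gd: float
    lam: float
    theta: float


def _presence_sets(
    annotations: Sequence[AbstractAnnotation], category: str
) -> dict[str, set[int]]:
    """entity id -> indices of the abstracts mentioning it."""
    out: dict[str, set[int]] = {}
    for i, ann in enumerate(annotations):
        for entity in ann.entity_ids(category):
            out.setdefault(entity, set()).add(i)
    return out


def cooccurrence_counts(
    annotations: Sequence[AbstractAnnotation], gene_id: str, drug_id: str
) -> tuple[int, int, int, int]:
    """Document-level counts (df_gd, df_g, df_d, P) for one pair.

    Presence is abstract-level (any mention anywhere in the abstract),
    not sentence-level.
    """
    gene_docs = {
        i for i, a in enumerate(annotations) if gene_id in a.entity_ids("gene")
    }
    drug_docs = {
        i for i, a in enumerate(annotations) if drug_id in a.entity_ids("drug")
    }
    return (
        len(gene_docs & drug_docs),
        len(gene_docs),
        len(drug_docs),
        len(annotations),
    )


def target_correlation(
    gene_id: str,
    targets: set[str],
    datasets: Sequence[pd.DataFrame],
    min_samples: int = 3,
) -> float:
    """Average absolute Pearson correlation of a gene with a drug's targets.

    The mean runs over all (target, dataset) pairs in which both genes
    are measured with nonzero variance; a target identical to the gene
    contributes |r| = 1 (the direct-target case). With no annotated
    targets or no valid pair the fallback is 0.
    """
    if not targets:
        return 0.0
    values: list[float] = []
    for matrix in datasets:
        if gene_id not in matrix.index:
            continue
        g = matrix.loc[gene_id].to_numpy(dtype=float)
        for target in sorted(targets):
            if target == gene_id:
                values.append(1.0)
                continue
            if target not in matrix.index:
                continue
            t = matrix.loc[target].to_numpy(dtype=float)
            ok = np.isfinite(g) & np.isfinite(t)
            if ok.sum() < min_samples:
                continue
            if np.std(g[ok]) == 0 or np.std(t[ok]) == 0:
                continue
            r, _ = stats.pearsonr(g[ok], t[ok])
            values.append(abs(float(r)))
    return float(np.mean(values)) if values else 0.0


def connectivity_score(
    df_gd: int,
    df_g: int,
    df_d: int,
    p_total: int,
    corr_gd: float,
    lam: float = 1.0,
) -> float:
    """theta for one gene-drug pair. ``lam`` must be positive."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if not 0 <= df_gd <= min(df_g, df_d) <= p_total:
        raise ValueError(
            f"inconsistent counts: df_gd={df_gd}, df_g={df_g}, "
            f"df_d={df_d}, P={p_total}"
        )
    if not 0.0 <= corr_gd <= 1.0:
        raise ValueError("corr_gd must lie in [0, 1]")
    log_odds = math.log((df_gd * p_total + lam) / (df_g * df_d + lam))
    return log_odds * (1.0 + corr_gd)


def build_connectivity_matrix(
    annotations: Sequence[AbstractAnnotation],
    gene_list: Sequence[str],
    drug_list: Sequence[str],
    drug_targets: Mapping[str, set[str]],
    datasets: Sequence[pd.DataFrame],
    lam: float = 1.0,
) -> pd.DataFrame:
    """Score every gene x drug pair; genes are rows, drugs columns.

    Returns a long-format frame with one row per pair carrying every
    component (counts, correlation, theta) for audit. Use
    :func:`theta_matrix` for the wide theta matrix.
    """
    if not gene_list or not drug_list:
        raise ValueError("gene_list and drug_list must be nonempty")
    gene_docs = _presence_sets(annotations, "gene")
    drug_docs = _presence_sets(annotations, "drug")
    p_total = len(annotations)
    corr_cache: dict[str, dict[str, float]] = {}
    rows = []
    for drug_id in drug_list:
        targets = set(drug_targets.get(drug_id, set()))
        d_docs = drug_docs.get(drug_id, set())
        cache = corr_cache.setdefault(drug_id, {})
        for gene_id in gene_list:
            g_docs = gene_docs.get(gene_id, set())
            if gene_id not in cache:
                cache[gene_id] = target_correlation(gene_id, targets, datasets)
            corr = cache[gene_id]
            df_gd = len(g_docs & d_docs)
            theta = connectivity_score(
                df_gd, len(g_docs), len(d_docs), p_total, corr, lam
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "drug_id": drug_id,
                    "df_gd": df_gd,
                    "df_g": len(g_docs),
                    "df_d": len(d_docs),
                    "P": p_total,
                    "corr_gd": corr,
                    "lambda": lam,
                    "theta": theta,
                }
            )
    return pd.DataFrame(rows)


def theta_matrix(long_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format connectivity table to genes x drugs theta."""
    return long_table.pivot(index="gene_id", columns="drug_id", values="theta")


def read_drug_targets(path) -> dict[str, set[str]]:
    """Read a drug->target table (TSV columns drug_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug_id", "gene_id"} <= set(df.columns):
        raise ValueError("drug-target TSV needs columns drug_id, gene_id")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["drug_id"], set()).add(row["gene_id"])
    return out
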