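"""Robust rank aggregation of per-dataset differential-expression rankings.

Each dataset contributes a normalized rank in (0, 1] per gene (rank of
its log2 fold change divided by the number of genes in that dataset).
Under the null that a gene is unremarkable, its normalized ranks are
i.i.d. uniform; the aggregation score (rho, the "AR score") asks how
surprisingly small the k-th smallest rank is for the best k, via the
Beta(k, n-k+1) order-statistic distribution, with a Bonferroni factor n
for having scanned all k. Small rho = consistently top-ranked across
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AggregatedRank",
    "normalized_ranks",
    "rra_score",
    "aggregate_datasets",
]


@dataclass(frozen=True)
class AggregatedRank:
    gene_id: str
    direction: str  # "up" or "down"
    rho: float
    per_dataset_ranks: dict
    n_datasets_measured: int


def normalized_ranks(
    de_tables: Mapping[str, pd.DataFrame], direction: str
) -> pd.DataFrame:
    """Per-dataset normalized ranks of every gene, by log2 fold change.

    ``direction="up"`` ranks descending (largest fold change gets rank
    1), ``"down"`` ascending. Ties get average ranks. The normalized
    rank is rank / N_dataset, in (0, 1]. Returns a genes x datasets
    frame with NaN where a gene is not measured.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    cols = {}
    for dataset_id, table in de_tables.items():
        fc = pd.Series(
            table["log2fc"].to_numpy(), index=table["gene_id"].to_numpy()
        )
        ranks = fc.rank(method="average", ascending=(direction == "down"))
        cols[dataset_id] = ranks / len(ranks)
    return pd.DataFrame(cols)


def rra_score(ranks: Sequence[float], n: int | None = None) -> float:
    """Aggregation score for one gene's normalized ranks.

    With r(1) <= ... <= r(n) the sorted ranks, returns

        rho = min(1, n * min_k  P[Beta(k, n-k+1) <= r(k)])

    the Bonferroni-corrected minimum of the order-statistic beta
    probabilities. Ranks must lie in (0, 1].
    """
    r = np.sort(np.asarray(ranks, dtype=float))
    if n is None:
        n = len(r)
    if len(r) != n:
        raise ValueError("n must equal the number of ranks")
    if n == 0:
        raise ValueError("at least one rank is required")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    k = np.arange(1, n + 1)
    p = stats.beta.cdf(r, k, n - k + 1)
    return float(min(1.0, n * p.min()))


def aggregate_datasets(
    de_tables: Mapping[str, pd.DataFrame], direction: str
) -> pd.DataFrame:
    """Aggregate per-dataset DE tables into one ranked gene list.

    Per gene, rho is computed from its normalized ranks in the datasets
    where it is measured (n is per-gene, so platform coverage
    differences are not penalized). The display meta-score is
    -log10(rho), signed positive for direction "up" and negative for
    "down" — a labeled convention, the raw rho is always kept. Output is
    sorted ascending by rho, ties broken by gene id.
    """
    rank_frame = normalized_ranks(de_tables, direction)
    if rank_frame.empty:
        import warnings

        warnings.warn("no genes found in any DE table", stacklevel=2)
        return pd.DataFrame(
            columns=["gene_id", "direction", "rho", "meta_score",
                     "n_datasets_measured"]
        )
    records = []
    for gene_id, row in rank_frame.iterrows():
        r = row.dropna().to_numpy()
        rho = rra_score(r)
        sign = 1.0 if direction == "up" else -1.0
        records.append(
            {
                "gene_id": gene_id,
                "direction": direction,
                "rho": rho,
                "meta_score": sign * -np.log10(rho) if rho > 0 else np.inf,
                "n_datasets_measured": len(r),
            }
        )
    out = pd.DataFrame(records).sort_values(
        ["rho", "gene_id"], kind="mergesort"
    )
    return out.set_index("gene_id", drop=False)
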