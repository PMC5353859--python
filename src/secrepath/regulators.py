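"""Regulator screening by summed Spearman correlation to a seed cluster.

Every transcriptome gene is scored by the sum over seed-cluster genes of
its Spearman correlation (and squared correlation) with them; high summed
correlation nominates co-regulated candidates, strongly negative summed
correlation with high summed squared correlation nominates inversely
correlated candidates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


class RegulatorScreenError(ValueError):
    """Raised on invalid screening inputs."""


def summed_correlation_scores(
    values: pd.DataFrame,
    seed_genes: list[str],
) -> pd.DataFrame:
    """Score every gene by summed Spearman correlation to the seed set.

    Returns a frame indexed by gene with columns ``sum_rho``,
    ``sum_rho_sq``, ``n_seed``, ``is_seed``, ``rank_pos``, ``rank_neg``.
    Seed members are scored too (flagged, not silently dropped) so the
    seed's internal coherence is inspectable. Constant genes get NaN
    scores and no ranks. Positive ranks order by sum_rho descending,
    negative ranks ascending; ties break by gene id.

    Raises
    ------
    RegulatorScreenError
        On an empty seed set, missing seed genes, or < 4 samples.
    """
    if not seed_genes:
        raise RegulatorScreenError("seed set is empty")
    missing = [g for g in seed_genes if g not in values.index]
    if missing:
        raise RegulatorScreenError(f"seed genes absent from matrix: {missing[:10]}")
    if values.shape[1] < 4:
        raise RegulatorScreenError("need >= 4 samples")

    arr = values.to_numpy(dtype=float)
    ranks = rankdata(arr, axis=1, method="average")
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0

    seed_idx = [values.index.get_loc(g) for g in seed_genes]
    seed_centered = centered[seed_idx]
    seed_norms = norms[seed_idx]

    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ seed_centered.T) / np.outer(norms, seed_norms)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant] = np.nan
    rho[:, seed_norms == 0] = np.nan

    sum_rho = np.nansum(rho, axis=1)
    sum_rho_sq = np.nansum(rho**2, axis=1)
    sum_rho[constant] = np.nan
    sum_rho_sq[constant] = np.nan

    out = pd.DataFrame(
        {
            "sum_rho": sum_rho,
            "sum_rho_sq": sum_rho_sq,
            "n_seed": len(seed_genes),
            "is_seed": values.index.isin(seed_genes),
        },
        index=values.index,
    )
    scored = out.loc[out["sum_rho"].notna()].sort_index(kind="stable")
    order_pos = scored.sort_values("sum_rho", ascending=False, kind="stable")
    out["rank_pos"] = pd.Series(np.arange(1, len(order_pos) + 1), index=order_pos.index)
    order_neg = scored.sort_values("sum_rho", ascending=True, kind="stable")
    out["rank_neg"] = pd.Series(np.arange(1, len(order_neg) + 1), index=order_neg.index)
    return out


def rank_regulator_candidates(
    scores: pd.DataFrame,
    k: int = 10,
    *,
    exclude_seed: bool = True,
    negative_by: str = "sum_rho",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k positively and negatively scored candidate regulators.

    ``negative_by="sum_rho"`` ranks the negative list by most negative
    summed correlation; ``"sum_rho_sq"`` ranks by highest summed squared
    correlation among genes with negative sum_rho (inverse but strongly
    coupled profiles). Ties break by gene id; seed members are dropped
    when ``exclude_seed``.
    """
    if negative_by not in ("sum_rho", "sum_rho_sq"):
        raise RegulatorScreenError(f"invalid negative_by {negative_by!r}")
    pool = scores[scores["sum_rho"].notna()]
    if exclude_seed:
        pool = pool[~pool["is_seed"]]
    pool = pool.sort_index(kind="stable")

    positive = pool.sort_values("sum_rho", ascending=False, kind="stable").head(k)
    if negative_by == "sum_rho":
        negative = pool.sort_values("sum_rho", ascending=True, kind="stable").head(k)
    else:
        anti = pool[pool["sum_rho"] < 0]
        negative = anti.sort_values(
            "sum_rho_sq", ascending=False, kind="stable"
        ).head(k)
    return positive, negative
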