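"""Gene-phenotype correlation with an adaptive two-SD significance rule.

Each gene's expression profile is correlated (Spearman for monotone,
Pearson for linear relationships) against a per-sample phenotype vector
such as specific growth rate or specific productivity. A gene is flagged
significant when its correlation lies more than two standard deviations
from the mean of all measured correlations for that statistic; the
thresholds are data-driven, never hard-coded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


class PhenotypeError(ValueError):
    """Raised on invalid phenotype-correlation inputs."""


@dataclass(frozen=True)
class ThresholdRecord:
    """Mean +/- 2 SD bounds for one correlation statistic."""

    mean: float
    sd: float
    lower: float
    upper: float


def _corr_columns(arr: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``arr`` with vector ``y``."""
    xc = arr - arr.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xnorm = np.sqrt((xc**2).sum(axis=1))
    ynorm = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (xnorm * ynorm)
    r[xnorm == 0] = np.nan
    if ynorm == 0:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlate_to_phenotype(
    values: pd.DataFrame,
    phenotype: pd.Series,
) -> pd.DataFrame:
    """Spearman and Pearson correlation of every gene with a phenotype.

    ``values`` is genes x samples; ``phenotype`` must cover the matrix
    samples (extra entries are ignored; missing phenotype values drop
    those samples). Constant genes or a constant phenotype yield NaN with
    a warning.

    Raises
    ------
    PhenotypeError
        If sample ids are misaligned or < 4 usable samples remain.
    """
    missing = [s for s in values.columns if s not in phenotype.index]
    if missing:
        raise PhenotypeError(f"phenotype missing for samples: {missing[:10]}")
    pheno = phenotype.reindex(values.columns).astype(float)
    usable = pheno.notna()
    if usable.sum() < 4:
        raise PhenotypeError("need >= 4 samples with a phenotype value")
    sub = values.loc[:, usable.to_numpy()]
    y = pheno[usable].to_numpy()

    arr = sub.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("constant phenotype: all correlations are undefined")
    n_constant = int((np.ptp(arr, axis=1) == 0).sum())
    if n_constant:
        warnings.warn(f"{n_constant} constant gene(s): correlations undefined")

    r_pearson = _corr_columns(arr, y)
    rho = _corr_columns(
        rankdata(arr, axis=1, method="average"),
        rankdata(y, method="average"),
    )
    return pd.DataFrame(
        {"rho_spearman": rho, "r_pearson": r_pearson}, index=values.index
    )


def adaptive_threshold(correlations: pd.Series | np.ndarray) -> ThresholdRecord:
    """Mean +/- 2 sample-SD bounds over the non-missing correlations.

    Bounds are clipped to [-1, 1]. Requires >= 2 non-missing values.
    """
    arr = np.asarray(correlations, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise PhenotypeError("need >= 2 non-missing correlations")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return ThresholdRecord(
        mean=mean,
        sd=sd,
        lower=max(mean - 2.0 * sd, -1.0),
        upper=min(mean + 2.0 * sd, 1.0),
    )


def classify_targets(
    corrs: pd.DataFrame,
    thresholds: dict[str, ThresholdRecord] | None = None,
    known_targets: pd.Series | None = None,
) -> pd.DataFrame:
    """Flag genes beyond the two-SD bounds and attach target categories.

    ``corrs`` is the output of :func:`correlate_to_phenotype` (or several
    such frames concatenated with suffixed columns). ``thresholds`` maps
    column name -> :class:`ThresholdRecord`; missing entries are computed
    from the data. ``known_targets`` maps gene -> category label (e.g.
    folding_UPR, apoptosis, generic) and is carried into the output for
    scatter plotting.
    """
    out = corrs.copy()
    thresholds = dict(thresholds or {})
    for column in corrs.columns:
        if not np.issubdtype(corrs[column].dtype, np.number):
            continue
        record = thresholds.get(column)
        if record is None:
            record = adaptive_threshold(corrs[column])
            thresholds[column] = record
        vals = corrs[column]
        out[f"significant_{column}"] = (
            vals.notna() & ((vals > record.upper) | (vals < record.lower))
        )
    if known_targets is not None:
        out["category"] = known_targets.reindex(out.index).fillna("")
    else:
        out["category"] = ""
    out.attrs["thresholds"] = thresholds
    return out
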