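"""Count-matrix normalisation, expression filtering, DE thresholding,
and culture growth metrics.

Counts are handled as pandas DataFrames (genes x samples). Normalisation
offers plain library-size CPM and TMM (trimmed mean of M-values) effective
library sizes. Differential-expression statistics are consumed as
(gene, log2FC, p) tables; this module performs Benjamini-Hochberg
adjustment and threshold flagging only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DE_STATUSES = ("up", "down", "de_below_fold", "not_significant", "not_expressed")


class ExpressionError(ValueError):
    """Raised on invalid count/expression inputs."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with normalisation provenance."""

    values: pd.DataFrame
    scale: str = "cpm"  # cpm | log2cpm
    normalization: str = "libsize"  # libsize | tmm
    scaling_factors: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.columns.duplicated().any():
        raise ExpressionError("duplicate sample ids in count matrix")
    arr = counts.to_numpy()
    if arr.size and ((arr < 0).any() or not np.allclose(arr, np.round(arr))):
        raise ExpressionError("counts must be non-negative integers")


def tmm_factors(
    counts: pd.DataFrame,
    *,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile (of nonzero-scaled
    counts) is closest to the mean upper-quartile. For each sample, genes
    with zero counts in either sample are removed, the most extreme 30% of
    log-ratios (M) and 5% of average log-intensities (A) are trimmed, and
    the factor is the precision-weighted mean of the remaining M values.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ExpressionError(f"all-zero sample(s): {bad}")
    frac = counts.to_numpy(dtype=float) / lib.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.array(
            [np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0 for col in frac.T]
        )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    n_genes, n_samples = frac.shape
    log_factors = np.zeros(n_samples)
    ref = frac[:, ref_idx]
    ref_counts = counts.to_numpy(dtype=float)[:, ref_idx]
    obs_counts_all = counts.to_numpy(dtype=float)
    for s in range(n_samples):
        if s == ref_idx:
            continue
        obs = frac[:, s]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            continue
        m = np.log2(obs[keep] / ref[keep])
        a = 0.5 * np.log2(obs[keep] * ref[keep])
        # asymptotic precision weights (delta method on binomial counts)
        w = 1.0 / (
            (lib.iloc[s] - obs_counts_all[keep, s]) / (lib.iloc[s] * obs_counts_all[keep, s])
            + (lib.iloc[ref_idx] - ref_counts[keep]) / (lib.iloc[ref_idx] * ref_counts[keep])
        )
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        trimmed = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not trimmed.any() or np.isclose(w[trimmed].sum(), 0):
            continue
        log_factors[s] = np.average(m[trimmed], weights=w[trimmed])
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def compute_cpm(
    counts: pd.DataFrame,
    normalization: str = "libsize",
    *,
    log2: bool = False,
    prior: float = 1.0,
) -> ExpressionMatrix:
    """Counts-per-million matrix under plain or TMM-effective library sizes.

    With ``normalization="libsize"`` each column of the CPM matrix sums to
    1e6. With ``"tmm"`` the library sizes are multiplied by TMM factors
    first. ``log2=True`` returns log2(CPM + prior).

    Raises
    ------
    ExpressionError
        If a sample has zero total counts, or no samples are present.
    """
    if counts.shape[1] == 0:
        raise ExpressionError("count matrix has no samples")
    _check_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ExpressionError(f"all-zero sample(s): {bad}")
    if normalization == "libsize":
        factors = pd.Series(1.0, index=counts.columns)
    elif normalization == "tmm":
        factors = tmm_factors(counts)
    else:
        raise ExpressionError(f"unknown normalization {normalization!r}")
    eff_lib = lib * factors
    cpm = counts.div(eff_lib, axis=1) * 1e6
    if log2:
        cpm = np.log2(cpm + prior)
    return ExpressionMatrix(
        values=cpm,
        scale="log2cpm" if log2 else "cpm",
        normalization=normalization,
        scaling_factors=factors,
    )


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_removed: int
    min_cpm: float
    min_samples: int


def filter_expressed(
    expr: ExpressionMatrix,
    min_cpm: float = 1.0,
    min_samples: int = 2,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    if expr.scale != "cpm":
        raise ExpressionError("filter_expressed requires a cpm-scale matrix")
    n_samples = expr.values.shape[1]
    if expr.values.shape[0] and min_samples > n_samples:
        raise ExpressionError(
            f"min_samples={min_samples} exceeds sample count {n_samples}"
        )
    mask = (expr.values >= min_cpm).sum(axis=1) >= min_samples
    kept = expr.values.loc[mask]
    report = FilterReport(
        n_input=expr.values.shape[0],
        n_kept=int(mask.sum()),
        n_removed=int((~mask).sum()),
        min_cpm=min_cpm,
        min_samples=min_samples,
    )
    logger.info(
        "expression filter kept %d/%d genes (CPM >= %g in >= %d samples)",
        report.n_kept,
        report.n_input,
        min_cpm,
        min_samples,
    )
    return (
        ExpressionMatrix(kept, expr.scale, expr.normalization, expr.scaling_factors),
        report,
    )


def benjamini_hochberg(p: np.ndarray | pd.Series) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values with monotonisation."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ExpressionError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def adjust_and_flag_de(
    raw: pd.DataFrame,
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """BH-adjust a (gene, log2FC, p) table and flag DE status.

    Status rules: ``up`` if log2FC >= fc_cut with FDR < fdr_cut and
    p < p_cut; ``down`` symmetrically; ``de_below_fold`` if FDR < fdr_cut
    (and p < p_cut) but |log2FC| < fc_cut; else ``not_significant``.
    """
    for column in ("gene", "log2FC", "p"):
        if column not in raw.columns:
            raise ExpressionError(f"DE table missing column {column!r}")
    out = raw.loc[:, ["gene", "log2FC", "p"]].copy()
    out["FDR"] = benjamini_hochberg(out["p"].to_numpy())

    significant = (out["FDR"] < fdr_cut) & (out["p"] < p_cut)
    status = np.full(len(out), "not_significant", dtype=object)
    status[significant & (out["log2FC"] >= fc_cut)] = "up"
    status[significant & (out["log2FC"] <= -fc_cut)] = "down"
    status[significant & (out["log2FC"].abs() < fc_cut)] = "de_below_fold"
    out["status"] = status
    return out


# -- culture growth metrics ------------------------------------------------


@dataclass
class GrowthRecord:
    """Time course of a batch culture.

    time in hours (strictly increasing), viable_density in cells/mL,
    titer in mg/L (optional, NaN where unmeasured).
    """

    time: np.ndarray
    viable_density: np.ndarray
    titer: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.viable_density = np.asarray(self.viable_density, dtype=float)
        if self.titer is not None:
            self.titer = np.asarray(self.titer, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.viable_density):
            raise ExpressionError("time and viable_density must align")
        if len(self.time) > 1 and not (np.diff(self.time) > 0).all():
            raise ExpressionError("time points must be strictly increasing")
        if (self.viable_density < 0).any():
            raise ExpressionError("viable densities must be >= 0")


def doubling_time(mu: float) -> float:
    """Doubling time t_d = ln(2) / mu, hours, for mu > 0."""
    if mu <= 0:
        raise ExpressionError(f"growth rate must be positive, got {mu}")
    return math.log(2.0) / mu


def fit_growth_rate(
    record: GrowthRecord,
    window: tuple[float, float] | None = None,
) -> float:
    """Specific growth rate: least-squares slope of ln(density) vs time.

    Only points inside ``window`` (inclusive) with positive density are
    used; at least two are required.
    """
    t = record.time
    x = record.viable_density
    mask = x > 0
    if window is not None:
        lo, hi = window
        mask &= (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise ExpressionError("need >= 2 positive-density points in window")
    slope, _ = np.polyfit(t[mask], np.log(x[mask]), 1)
    return float(slope)


def specific_productivity(record: GrowthRecord) -> float:
    """Cell-specific productivity q_P in pg/cell/h.

    q_P = (P_end - P_start) / integral of viable density over time, with a
    trapezoidal integral. Titer is mg/L and density cells/mL, so the ratio
    (mg/L) / (cells/mL * h) equals pg/cell/h directly.
    """
    if record.titer is None:
        raise ExpressionError("record has no titer measurements")
    mask = ~np.isnan(record.titer)
    if mask.sum() < 2:
        raise ExpressionError("need >= 2 titer timepoints")
    t = record.time[mask]
    x = record.viable_density[mask]
    p = record.titer[mask]
    delta_p = p[-1] - p[0]
    integral = np.trapezoid(x, t)  # cells/mL * h
    if integral <= 0:
        raise ExpressionError("non-positive cell-time integral")
    q_p = float(delta_p / integral * 1e6)  # mg/L -> pg/mL
    if q_p < 0:
        warnings.warn("titer decreased over the record; q_P is negative")
    return q_p


def load_counts(path, metadata_path=None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a genes x samples count TSV (first column = gene id) and
    optional sample metadata TSV (first column = sample id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    _check_counts(counts)
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        missing = [s for s in counts.columns if s not in meta.index]
        if missing:
            raise ExpressionError(f"samples missing from metadata: {missing}")
    return counts, meta
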