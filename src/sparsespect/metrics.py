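"""Image-quality metrics and results aggregation.

Reduced-view reconstructions are evaluated against the unfiltered full-view
(60-view) reconstruction of the same acquisition:

* MAPE  = |μ_ref − μ_reduced| / μ_ref × 100  on an ROI mean,
* NRMSE = Σ(x_reduced − x_ref)² / Σ(x_ref − μ)²   (no square root by
  default — that is the formula as defined for this metric suite; a sqrt
  variant is available),
* PSNR  = 10 log10( max(x_reduced)² / Σ(x_reduced − x_ref)² )  — note the
  peak is taken over the *reduced* image and the error term is the total
  (not mean) squared norm; a conventional variant (peak over reference,
  MSE) is available,
* NB    = (μ_ref − μ_reduced) / var(ref | ROI1)  with the population
  variance convention (divide by N),
* percent change PC = (x₂ − x₁) / x₁ × 100 between filter conditions,
* ICC   = (MSB − MSE) / (MSB + (K−1)·MSE)  from a one-way subjects ANOVA
  of a complete cases × raters score table.

``aggregate_results`` reproduces the two distinct "improvement" summaries
used for such studies: the maximum |PC| per metric between filter
conditions, and the maximum percentage-point difference for MAPE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import ROIMask
from .reconstruction import ReconVolume

METRICS_COLUMNS = [
    "case_id",
    "n_views",
    "filter",
    "mape_roi1",
    "mape_roi2",
    "nrmse",
    "psnr",
    "nb_roi1",
]


class InfinitePSNR(ArithmeticError):
    """Raised when reduced == reference exactly (zero error, PSNR → ∞)."""


def _vals(x: ReconVolume | np.ndarray) -> np.ndarray:
    return x.values if isinstance(x, ReconVolume) else np.asarray(x, dtype=float)


def roi_mean(vol: ReconVolume | np.ndarray, mask: ROIMask | np.ndarray) -> float:
    """Arithmetic mean of voxel values under a boolean ROI mask."""
    v = _vals(vol)
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if v.shape != m.shape:
        raise ValueError(f"volume shape {v.shape} != mask shape {m.shape}")
    if not m.any():
        raise ValueError("empty ROI mask")
    return float(v[m].mean())


def mape(mu_ref: float, mu_reduced: float) -> float:
    """Mean absolute percentage error between two ROI means, in percent."""
    if mu_ref == 0:
        raise ValueError("MAPE undefined for a zero reference mean")
    return abs((mu_ref - mu_reduced) / mu_ref) * 100.0


def nrmse(ref: ReconVolume | np.ndarray, reduced: ReconVolume | np.ndarray, sqrt: bool = False) -> float:
    """Normalized (root) mean square error relative to reference variance.

    Default is the ratio of sums Σ(x_red − x_ref)² / Σ(x_ref − μ)² without
    a square root; ``sqrt=True`` returns its square root.
    """
    r, q = _vals(ref), _vals(reduced)
    if r.shape != q.shape:
        raise ValueError("volumes must share a shape")
    denom = float(np.sum((r - r.mean()) ** 2))
    if denom == 0:
        raise ValueError("NRMSE undefined for a constant reference image")
    val = float(np.sum((q - r) ** 2)) / denom
    return float(np.sqrt(val)) if sqrt else val


def psnr(ref: ReconVolume | np.ndarray, reduced: ReconVolume | np.ndarray, standard: bool = False) -> float:
    """Peak signal-to-noise ratio.

    Default: 10·log10(max(x_reduced)² / Σ(x_red − x_ref)²) — peak over the
    reduced image, total squared error.  ``standard=True`` uses the textbook
    convention (peak over the reference, mean squared error).  Raises
    :class:`InfinitePSNR` when the images are identical.
    """
    r, q = _vals(ref), _vals(reduced)
    if r.shape != q.shape:
        raise ValueError("volumes must share a shape")
    err = float(np.sum((q - r) ** 2))
    if err == 0:
        raise InfinitePSNR("reduced equals reference; PSNR is infinite")
    if standard:
        peak = float(r.max())
        err = err / r.size
    else:
        peak = float(q.max())
    return 10.0 * float(np.log10(peak**2 / err))


def nb(ref_roi_values: np.ndarray, reduced_roi_mean: float) -> float:
    """Normalized bias: (μ_ref − μ_reduced) / var(ref values in ROI1).

    Signed (positive means the reduced image underestimates the ROI mean);
    population variance (divide by N).
    """
    v = np.asarray(ref_roi_values, dtype=float).ravel()
    var = float(v.var())  # population convention
    if var == 0:
        raise ValueError("NB undefined for zero reference ROI variance")
    return (float(v.mean()) - float(reduced_roi_mean)) / var


def percent_change(x1: float, x2: float) -> float:
    """Signed percent change (x₂ − x₁)/x₁ × 100 from initial x₁ to final x₂."""
    if x1 == 0:
        raise ValueError("percent change undefined for a zero initial value")
    return (x2 - x1) / x1 * 100.0


def icc(scores: pd.DataFrame) -> float:
    """Inter-rater intraclass correlation from a complete two-way score table.

    ``scores`` needs columns ``case_id``, ``rater`` and ``score`` (an extra
    ``filter`` column, if present, is folded into the case identity so each
    rated image is one subject).  Computes a one-way subjects ANOVA:
    MSB (between-subject mean square, df n−1) and MSE (within-subject mean
    square, df n(K−1)), then (MSB − MSE)/(MSB + (K−1)·MSE).
    """
    df = scores.copy()
    required = {"case_id", "rater", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    if "filter" in df.columns:
        df["case_id"] = df["case_id"].astype(str) + "/" + df["filter"].astype(str)
    wide = df.pivot_table(index="case_id", columns="rater", values="score", aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("incomplete layout: every case must be rated by every rater")
    n, k = wide.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 cases and >= 2 raters")
    x = wide.to_numpy(dtype=float)
    grand = x.mean()
    row_means = x.mean(axis=1)
    msb = k * float(np.sum((row_means - grand) ** 2)) / (n - 1)
    mse = float(np.sum((x - row_means[:, None]) ** 2)) / (n * (k - 1))
    denom = msb + (k - 1) * mse
    if denom == 0:
        return 0.0
    return (msb - mse) / denom


# ---------------------------------------------------------------------------
# results tables and aggregation


@dataclass(frozen=True)
class MetricRecord:
    """One evaluated (case, view count, filter) combination."""

    case_id: str
    n_views: int
    filter: str
    mape_roi1: float
    mape_roi2: float
    nrmse: float
    psnr: float
    nb_roi1: float


def records_to_table(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=METRICS_COLUMNS)


def _require_complete(table: pd.DataFrame, n_views: int, filters: list[str]) -> pd.DataFrame:
    sub = table[table["n_views"] == n_views]
    missing = [f for f in filters if f not in set(sub["filter"])]
    if missing:
        raise ValueError(f"missing filter conditions at {n_views} views: {missing}")
    return sub


def mean_mape(table: pd.DataFrame, n_views: int, roi: str = "roi1", filter_kind: str = "none") -> float:
    """Mean MAPE over cases for one (view count, ROI, filter) cell."""
    col = f"mape_{roi}"
    sub = _require_complete(table, n_views, [filter_kind])
    sub = sub[sub["filter"] == filter_kind]
    if sub[col].isna().any():
        raise ValueError(f"missing {col} values at {n_views} views / {filter_kind}")
    return float(sub[col].mean())


def _paired(table: pd.DataFrame, metric: str, n_views: int, filter_from: str, filter_to: str) -> pd.DataFrame:
    sub = _require_complete(table, n_views, [filter_from, filter_to])
    a = sub[sub["filter"] == filter_from].set_index("case_id")[metric]
    b = sub[sub["filter"] == filter_to].set_index("case_id")[metric]
    pair = pd.DataFrame({"from": a, "to": b}).dropna()
    if pair.empty:
        raise ValueError("no complete case pairs for the requested comparison")
    return pair


def max_percent_change(
    table: pd.DataFrame, metric: str, n_views: int, filter_from: str, filter_to: str
) -> tuple[float, str]:
    """Maximum |percent change| of a metric between two filter conditions.

    Returns (magnitude in %, case id attaining it).  This is the
    "improvement up to X%" summary for NRMSE/PSNR/NB.
    """
    pair = _paired(table, metric, n_views, filter_from, filter_to)
    pc = pair.apply(lambda row: percent_change(row["from"], row["to"]), axis=1)
    case = pc.abs().idxmax()
    return float(abs(pc.loc[case])), str(case)


def max_point_difference(
    table: pd.DataFrame, metric: str, n_views: int, filter_from: str, filter_to: str
) -> tuple[float, str]:
    """Maximum raw difference (from − to) of a metric between conditions.

    For MAPE this is the percentage-point reduction (e.g. 5.94 → 1.47 is a
    4.47-point improvement), the second "improvement" definition.
    """
    pair = _paired(table, metric, n_views, filter_from, filter_to)
    diff = pair["from"] - pair["to"]
    case = diff.idxmax()
    return float(diff.loc[case]), str(case)


def aggregate_results(table: pd.DataFrame) -> dict:
    """Aggregate a complete metrics table into the study's summary numbers.

    Returns a dict with: ``mean_mape`` (per view count × ROI × filter),
    ``max_abs_percent_change`` (per metric × view count × filter pair) and
    ``max_mape_point_reduction`` (per ROI × view count × filter pair).
    """
    out: dict = {"mean_mape": {}, "max_abs_percent_change": {}, "max_mape_point_reduction": {}}
    view_counts = sorted(table["n_views"].unique(), reverse=True)
    filters = [f for f in ("none", "gaussian", "nlm") if f in set(table["filter"])]
    for nv in view_counts:
        for roi in ("roi1", "roi2"):
            for f in filters:
                sub = table[(table["n_views"] == nv) & (table["filter"] == f)]
                if sub.empty or sub[f"mape_{roi}"].isna().all():
                    continue
                out["mean_mape"][(nv, roi, f)] = float(sub[f"mape_{roi}"].mean())
    pairs = [(a, b) for a in filters for b in filters if a != b and b == "nlm"]
    for nv in view_counts:
        for metric in ("nrmse", "psnr", "nb_roi1"):
            for a, b in pairs:
                try:
                    val, case = max_percent_change(table, metric, nv, a, b)
                except ValueError:
                    continue
                out["max_abs_percent_change"][(metric, nv, a, b)] = (val, case)
        for roi in ("roi1", "roi2"):
            for a, b in pairs:
                try:
                    val, case = max_point_difference(table, f"mape_{roi}", nv, a, b)
                except ValueError:
                    continue
                out["max_mape_point_reduction"][(roi, nv, a, b)] = (val, case)
    return out
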