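"""Corpus-level statistics of per-piece feature frequencies.

Aggregates a per-piece feature table into sliding-window time series
(default 100-year windows shifted by 25 years), per-composer summaries,
and per-era beta fits.  Throughout, pieces whose frequency is exactly
zero are excluded before computing statistics — rare-event frequencies
of short pieces pile up at zero and would otherwise dominate — and the
sample (n-1) standard deviation is used.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import fit_beta
from .errors import FittingError, InvalidParameterError

__all__ = ["window_series", "composer_stats", "era_beta_fit", "filter_pieces"]


def _feature_column(features: pd.DataFrame, feature: str) -> pd.Series:
    if feature not in features.columns:
        raise InvalidParameterError(
            f"unknown feature {feature!r}; available: {sorted(features.columns)}"
        )
    return features[feature]


def filter_pieces(features: pd.DataFrame) -> pd.DataFrame:
    """Drop pieces flagged short (< 100 notes), if the flag is present."""
    if "short" in features.columns:
        return features[~features["short"].astype(bool)]
    return features


def _nonzero(values: pd.Series) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    return x[np.isfinite(x) & (x != 0.0)]


def window_series(
    features: pd.DataFrame,
    feature: str,
    *,
    width: float = 100.0,
    step: float = 25.0,
    origin: Optional[float] = None,
) -> pd.DataFrame:
    """Sliding-window mean/sd series of a feature frequency.

    Windows are half-open intervals [y, y + width) stepped by ``step``
    from ``origin`` (default: the minimum year rounded down to a step
    multiple) across the year span.  Zero-frequency pieces are excluded
    within each window; windows with fewer than 2 surviving pieces get
    NaN sd (and NaN mean when empty).

    Returns columns window_start, window_end, n, mean, sd, ratio.
    """
    if width <= 0 or step <= 0:
        raise InvalidParameterError("width and step must be positive")
    _feature_column(features, feature)
    years = features["year"].to_numpy(dtype=float)
    if years.size == 0:
        raise InvalidParameterError("empty feature table")
    lo, hi = float(np.nanmin(years)), float(np.nanmax(years))
    if origin is None:
        origin = math.floor(lo / step) * step
    rows = []
    start = origin
    while start < hi + 1e-9:
        in_win = features[(years >= start) & (years < start + width)]
        x = _nonzero(in_win[feature])
        n = x.size
        mean = float(x.mean()) if n >= 1 else float("nan")
        sd = float(x.std(ddof=1)) if n >= 2 else float("nan")
        rows.append(
            {
                "window_start": start,
                "window_end": start + width,
                "n": n,
                "mean": mean,
                "sd": sd,
                "ratio": sd / mean if n >= 2 and mean > 0 else float("nan"),
            }
        )
        start += step
    return pd.DataFrame(rows)


def composer_stats(features: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Per-composer mean/sd of a feature frequency, zero-excluded.

    Composers whose pieces all have zero frequency appear with n = 0
    and NaN statistics (flagged, not dropped), so the grouping still
    partitions the corpus.
    """
    _feature_column(features, feature)
    rows = []
    for composer, group in features.groupby("composer", sort=True):
        x = _nonzero(group[feature])
        rows.append(
            {
                "composer": composer,
                "n": x.size,
                "n_total": len(group),
                "mean": float(x.mean()) if x.size >= 1 else float("nan"),
                "sd": float(x.std(ddof=1)) if x.size >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def era_beta_fit(
    features: pd.DataFrame,
    feature: str,
    era_edges: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Best-fit beta parameters per era.

    Eras are [edge_i, edge_{i+1}) bins; by default century bins spanning
    the data.  Within each era, zero frequencies are excluded and
    :func:`musevol.distributions.fit_beta` (MLE) is applied to the rest.
    Per-era failures (too few points, zero variance) are reported in the
    ``error`` column without aborting the other eras.
    """
    _feature_column(features, feature)
    years = features["year"].to_numpy(dtype=float)
    if era_edges is None:
        lo = math.floor(float(np.nanmin(years)) / 100.0) * 100.0
        hi = math.ceil((float(np.nanmax(years)) + 1e-9) / 100.0) * 100.0
        era_edges = np.arange(lo, hi + 1, 100.0)
    era_edges = list(era_edges)
    rows = []
    for lo_e, hi_e in zip(era_edges, era_edges[1:]):
        in_era = features[(years >= lo_e) & (years < hi_e)]
        x = _nonzero(in_era[feature])
        x = x[x < 1.0]  # beta support is open; saturated pieces cannot be fitted
        row = {"era_start": lo_e, "era_end": hi_e, "n": x.size, "a": float("nan"), "b": float("nan"), "error": None}
        try:
            fitted = fit_beta(x)
            row["a"], row["b"] = fitted.a, fitted.b
        except FittingError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
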