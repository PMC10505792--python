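"""Binary SMAD2/3-positive calls and per-colony positive fractions.

A nucleus is positive when its (mean, by default) nuclear intensity lies
strictly above a threshold; ties are negative. Because the original
readout relied on a manually chosen cutoff, two reproducible estimators
are provided and the threshold actually used is always recorded next to
the fractions it produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class ThresholdSuggestion:
    value: float
    mode: str  # "otsu" | "bimodal-midpoint"
    degenerate: bool = False  # distribution too unimodal to trust the split


def classify_positive(
    records: pd.DataFrame,
    threshold: float,
    intensity_column: str = "mean_intensity",
) -> tuple[pd.DataFrame, float]:
    """Call each nucleus positive/negative and return the positive fraction.

    Returns
    -------
    calls : DataFrame
        One row per nucleus: label, intensity, threshold, positive.
    fraction : float
        Percentage of positive nuclei among all (size-filtered) nuclei.
    """
    if len(records) == 0:
        raise ValueError("no nucleus records to classify")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    v = records[intensity_column].to_numpy(dtype=float)
    positive = v > threshold  # strict: ties are negative
    calls = pd.DataFrame(
        {
            "colony_id": records.get("colony_id", ""),
            "label": records["label"] if "label" in records else np.arange(len(v)),
            "intensity": v,
            "threshold": threshold,
            "positive": positive,
        }
    )
    return calls, 100.0 * positive.sum() / len(v)


def _two_means_1d(v: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Deterministic 1-D two-means: Lloyd iterations from the extremes."""
    c0, c1 = float(v.min()), float(v.max())
    for _ in range(max_iter):
        mid = (c0 + c1) / 2.0
        lo, hi = v[v <= mid], v[v > mid]
        if len(lo) == 0 or len(hi) == 0:
            break
        n0, n1 = float(lo.mean()), float(hi.mean())
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    return c0, c1


def suggest_threshold(
    records: pd.DataFrame,
    mode: str = "otsu",
    intensity_column: str = "mean_intensity",
) -> ThresholdSuggestion:
    """Reproducible stand-ins for a manual cutoff, fit on control colonies.

    ``otsu`` thresholds the pooled nucleus-intensity histogram;
    ``bimodal-midpoint`` returns the midpoint of the two cluster centers of
    a 1-D two-means fit. A degenerate flag is raised when the two centers
    sit within 5% of the intensity range (no usable bimodality).
    """
    if len(records) == 0:
        raise ValueError("no records to estimate a threshold from")
    v = records[intensity_column].to_numpy(dtype=float)
    rng_width = float(v.max() - v.min())
    if rng_width == 0:
        return ThresholdSuggestion(float(v[0]), mode, degenerate=True)
    if mode == "otsu":
        thr = float(threshold_otsu(v))
        c0, c1 = _two_means_1d(v)
    elif mode == "bimodal-midpoint":
        c0, c1 = _two_means_1d(v)
        thr = (c0 + c1) / 2.0
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    degenerate = abs(c1 - c0) < 0.05 * rng_width
    return ThresholdSuggestion(thr, mode, degenerate)


def positive_fraction_table(
    per_colony: dict[str, pd.DataFrame],
    threshold: float,
    mode: str,
    intensity_column: str = "mean_intensity",
) -> pd.DataFrame:
    """`positives.csv` layout: per-colony counts and percentage."""
    rows = []
    for cid, rec in per_colony.items():
        _, frac = classify_positive(rec, threshold, intensity_column)
        n = len(rec)
        rows.append((cid, n, int(round(frac * n / 100.0)), frac, threshold, mode))
    return pd.DataFrame(
        rows,
        columns=[
            "colony_id",
            "n_total",
            "n_positive",
            "pct_positive",
            "threshold",
            "threshold_mode",
        ],
    )
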