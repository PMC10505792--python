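"""Radial profiles of nuclear marker intensity and center/edge band summaries.

A radial profile bins nuclei by their distance to the colony center
(half-open 10 µm bins by default) and averages the per-nucleus median
intensities within each bin; profiles are normalised to their maximum so
colonies of different staining strength are comparable. Band summaries
average raw per-nucleus intensities inside a center band (10–25 µm) and an
edge band (175–225 µm), one value pair per colony, which is the unit used
for group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DEFAULT_CENTER_BAND = (10.0, 25.0)
DEFAULT_EDGE_BAND = (175.0, 225.0)


@dataclass(frozen=True)
class RadialProfile:
    bin_edges: np.ndarray  # (k+1,) µm; bin i is [edges[i], edges[i+1])
    bin_means: np.ndarray  # (k,) a.u.; NaN marks an empty bin
    bin_counts: np.ndarray  # (k,) nuclei per bin
    normalized: bool = False
    colony_id: str = ""
    overflow_count: int = 0  # nuclei beyond max_radius, excluded from means

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass(frozen=True)
class BandSummary:
    colony_id: str
    center_band: tuple[float, float]
    edge_band: tuple[float, float]
    center_mean: float  # NaN when the band holds no nucleus
    edge_mean: float
    center_n: int
    edge_n: int


@dataclass(frozen=True)
class AggregateProfile:
    """Across-colony mean profile with per-bin dispersion."""

    bin_edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray  # contributing colonies per bin


def radial_profile(
    records: pd.DataFrame,
    bin_width: float = 10.0,
    max_radius: float = 250.0,
    intensity_column: str = "median_intensity",
    colony_id: str | None = None,
) -> RadialProfile:
    """Bin per-nucleus intensities by distance to the colony center.

    Nuclei at distance >= ``max_radius`` land in an overflow count and do
    not contribute to any bin mean.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(records) == 0:
        raise ValueError("no nucleus records")
    d = records["distance_um"].to_numpy(dtype=float)
    v = records[intensity_column].to_numpy(dtype=float)
    edges = np.arange(0.0, max_radius + bin_width, bin_width)
    if edges[-1] > max_radius:
        edges = edges[edges <= max_radius]
    k = len(edges) - 1
    idx = np.floor(d / bin_width).astype(int)
    in_range = (d >= 0) & (idx < k)
    counts = np.bincount(idx[in_range], minlength=k)
    sums = np.bincount(idx[in_range], weights=v[in_range], minlength=k)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    cid = colony_id
    if cid is None:
        cid = str(records["colony_id"].iloc[0]) if "colony_id" in records else ""
    return RadialProfile(
        edges, means, counts, False, cid, int((~in_range).sum())
    )


def normalize_profile(profile: RadialProfile) -> RadialProfile:
    """Divide every bin mean by the profile maximum (idempotent)."""
    finite = np.isfinite(profile.bin_means)
    if not finite.any():
        raise ValueError("profile has no non-empty bin")
    peak = np.nanmax(profile.bin_means)
    if peak <= 0:
        raise ValueError("degenerate profile: maximum bin mean is not positive")
    if profile.normalized:
        return replace(profile)
    return replace(profile, bin_means=profile.bin_means / peak, normalized=True)


def band_summary(
    records: pd.DataFrame,
    center_band: tuple[float, float] = DEFAULT_CENTER_BAND,
    edge_band: tuple[float, float] = DEFAULT_EDGE_BAND,
    intensity_column: str = "median_intensity",
    colony_id: str | None = None,
) -> BandSummary:
    """Per-colony mean nuclear intensity inside the center and edge bands.

    Bands are half-open ``[lo, hi)`` on the distance to the colony center
    and must not overlap. Means are over raw per-nucleus intensities, not
    over binned profile values.
    """
    (c0, c1), (e0, e1) = center_band, edge_band
    if not (c0 < c1 and e0 < e1):
        raise ValueError("bands must be ascending (lo, hi) pairs")
    if max(c0, e0) < min(c1, e1):
        raise ValueError("center and edge bands overlap")
    d = records["distance_um"].to_numpy(dtype=float)
    v = records[intensity_column].to_numpy(dtype=float)
    in_c = (d >= c0) & (d < c1)
    in_e = (d >= e0) & (d < e1)
    cid = colony_id
    if cid is None:
        cid = str(records["colony_id"].iloc[0]) if "colony_id" in records else ""
    return BandSummary(
        cid,
        center_band,
        edge_band,
        float(v[in_c].mean()) if in_c.any() else float("nan"),
        float(v[in_e].mean()) if in_e.any() else float("nan"),
        int(in_c.sum()),
        int(in_e.sum()),
    )


def aggregate_profiles(profiles: list[RadialProfile]) -> AggregateProfile:
    """Mean and SD per bin across colonies, ignoring each colony's empty
    bins. SD is the sample (n-1) deviation, 0 where a single colony
    contributes."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if len(p.bin_edges) != len(edges) or not np.allclose(p.bin_edges, edges):
            raise ValueError("profiles have mismatched bin grids")
    stack = np.vstack([p.bin_means for p in profiles])
    n = np.isfinite(stack).sum(axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(n > 0, np.nanmean(stack, axis=0), np.nan)
        sd = np.where(n > 1, np.nanstd(stack, axis=0, ddof=1), np.nan)
    sd = np.where(n == 1, 0.0, sd)
    return AggregateProfile(edges, mean, sd, n)


def profiles_to_frame(profiles: list[RadialProfile]) -> pd.DataFrame:
    """Tidy table (colony_id, bin_lo, bin_hi, mean, n) for CSV export."""
    rows = []
    for p in profiles:
        for i in range(len(p.bin_means)):
            rows.append(
                (
                    p.colony_id,
                    p.bin_edges[i],
                    p.bin_edges[i + 1],
                    p.bin_means[i],
                    int(p.bin_counts[i]),
                    p.normalized,
                )
            )
    return pd.DataFrame(
        rows, columns=["colony_id", "bin_lo", "bin_hi", "mean", "n", "normalized"]
    )


def bands_to_frame(bands: list[BandSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                b.colony_id,
                b.center_mean,
                b.edge_mean,
                b.center_n,
                b.edge_n,
            )
            for b in bands
        ],
        columns=["colony_id", "center_mean", "edge_mean", "center_n", "edge_n"],
    )
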