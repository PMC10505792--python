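"""Synthetic micropattern colony and neuruloid generator with known ground truth.

Emulates the two assay geometries this package quantifies:

* **Activin assay colonies** — 500 µm circular micropatterned hESC colonies
  of ~2000 nuclei imaged in DAPI + SMAD2/3. Phenotype presets control where
  SMAD2/3 is nuclear: edge-restricted (WT), patchy central activation (HET),
  or near/fully uniform activation (HD, KO).
* **Neuruloids** — day-7 endpoint structures with a DAPI disc, central PAX6
  and N-CAD discs and a peripheral SOX10 annulus, whose analytic area
  fractions serve as ground truth for the domain quantification.

Every generated sample is bit-reproducible from ``(parameters, seed)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .io import MultiChannelImage

__all__ = [
    "ColonyLayout",
    "NoiseParams",
    "PhenotypeParams",
    "NeuruloidGroundTruth",
    "SyntheticSample",
    "ACTIVIN_PRESETS",
    "NEURULOID_PRESETS",
    "generate_colony_layout",
    "assign_activation",
    "render_colony_image",
    "render_neuruloid_image",
    "nucleus_records_from_truth",
    "write_sample",
]

#: arbitrary-unit DAPI intensity inside a nucleus
DAPI_INTENSITY = 100.0


class InfeasiblePackingError(ValueError):
    """Requested nucleus count cannot fit in the disc at the separation."""


@dataclass
class ColonyLayout:
    """Positions and sizes of nuclei in one circular colony (µm)."""

    nucleus_centers: np.ndarray  # (n, 2) µm, (x, y)
    nucleus_radii: np.ndarray  # (n,) µm
    colony_center: tuple[float, float]
    colony_radius: float
    min_separation: float
    shortfall: bool = False  # True if placement fell >5% short of target

    @property
    def n(self) -> int:
        return len(self.nucleus_radii)

    def distances_to_center(self) -> np.ndarray:
        return np.hypot(
            self.nucleus_centers[:, 0] - self.colony_center[0],
            self.nucleus_centers[:, 1] - self.colony_center[1],
        )

    def validate(self) -> None:
        if np.any(self.distances_to_center() > self.colony_radius + 1e-9):
            raise ValueError("nucleus center outside colony disc")
        if self.n > 1:
            tree = cKDTree(self.nucleus_centers)
            d, _ = tree.query(self.nucleus_centers, k=2)
            if d[:, 1].min() < self.min_separation - 1e-9:
                raise ValueError("minimum separation violated")

    def translated(self, dx: float, dy: float) -> "ColonyLayout":
        return ColonyLayout(
            self.nucleus_centers + np.array([dx, dy]),
            self.nucleus_radii,
            (self.colony_center[0] + dx, self.colony_center[1] + dy),
            self.colony_radius,
            self.min_separation,
            self.shortfall,
        )


@dataclass(frozen=True)
class NoiseParams:
    """Additive imaging noise: flat background + Gaussian readout, optional shot noise."""

    background: float = 5.0  # a.u. (5% of the default on-intensity)
    sigma: float = 2.0  # a.u.
    poisson: bool = False

    @classmethod
    def off(cls) -> "NoiseParams":
        return cls(background=0.0, sigma=0.0, poisson=False)


@dataclass(frozen=True)
class PhenotypeParams:
    """Spatial activation rule for the SMAD2/3 channel.

    A nucleus whose distance to the colony center is at least
    ``colony_radius - edge_band_width`` is an *edge* nucleus and is activated
    with probability ``p_edge``; interior nuclei activate with probability
    ``p_center``, in spatially correlated patches of characteristic size
    ``patchiness`` (µm) when that is positive.
    """

    phenotype_name: str
    edge_band_width: float = 75.0
    p_edge: float = 1.0
    p_center: float = 0.0
    patchiness: float = 0.0
    intensity_on: float = 100.0
    intensity_off: float = 20.0
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_edge <= 1.0 and 0.0 <= self.p_center <= 1.0):
            raise ValueError("activation probabilities must lie in [0, 1]")
        if self.intensity_on <= self.intensity_off:
            raise ValueError("intensity_on must exceed intensity_off")
        if self.edge_band_width <= 0:
            raise ValueError("edge_band_width must be positive")


#: Default activin-assay phenotype presets. WT responds only at the rim,
#: HET shows patchy partial central activation, HD is near-uniform and the
#: knockout fully uniform.
ACTIVIN_PRESETS: dict[str, PhenotypeParams] = {
    "WT": PhenotypeParams("WT", p_edge=1.0, p_center=0.0),
    "HET": PhenotypeParams("HET", p_edge=1.0, p_center=0.4, patchiness=40.0),
    "HD": PhenotypeParams("HD", p_edge=1.0, p_center=0.95),
    "KO": PhenotypeParams("KO", p_edge=1.0, p_center=1.0),
}


@dataclass(frozen=True)
class NeuruloidGroundTruth:
    """Concentric endpoint geometry of one synthetic neuruloid (µm)."""

    dapi_disc_radius: float = 250.0
    pax6_radius: float = 140.0
    ncad_radius: float = 90.0
    sox10_inner_radius: float = 180.0
    sox10_outer_radius: float = 240.0

    def __post_init__(self) -> None:
        ok = (
            0
            < self.ncad_radius
            <= self.pax6_radius
            <= self.sox10_outer_radius
            <= self.dapi_disc_radius
        ) and 0 <= self.sox10_inner_radius <= self.sox10_outer_radius
        if not ok:
            raise ValueError(
                "radii must nest: ncad <= pax6 <= sox10_outer <= dapi and "
                "sox10_inner <= sox10_outer"
            )

    @property
    def true_fractions(self) -> dict[str, float]:
        R2 = self.dapi_disc_radius**2
        return {
            "PAX6": self.pax6_radius**2 / R2,
            "NCAD": self.ncad_radius**2 / R2,
            "SOX10": (self.sox10_outer_radius**2 - self.sox10_inner_radius**2) / R2,
        }


#: Neuruloid presets: the HD-like phenotypes have an enlarged neuroectodermal
#: core (PAX6, N-CAD) and a contracted neural-crest (SOX10) ring.
NEURULOID_PRESETS: dict[str, NeuruloidGroundTruth] = {
    "WT": NeuruloidGroundTruth(250.0, 140.0, 90.0, 180.0, 240.0),
    "HET": NeuruloidGroundTruth(250.0, 165.0, 115.0, 200.0, 240.0),
    "HD": NeuruloidGroundTruth(250.0, 190.0, 140.0, 215.0, 240.0),
    "KO": NeuruloidGroundTruth(250.0, 210.0, 160.0, 225.0, 240.0),
}


@dataclass
class SyntheticSample:
    """A rendered image plus the ground truth that produced it."""

    image: MultiChannelImage
    layout: ColonyLayout | None
    activation: np.ndarray | None  # (n,) bool per-nucleus truth
    label_image: np.ndarray | None  # int labels, 0 = background
    params: dict
    seed: int

    @property
    def truth_table(self) -> pd.DataFrame:
        """Per-nucleus sidecar: id, position (µm), radius, activation."""
        if self.layout is None:
            return pd.DataFrame()
        return pd.DataFrame(
            {
                "nucleus_id": np.arange(1, self.layout.n + 1),
                "x_um": self.layout.nucleus_centers[:, 0],
                "y_um": self.layout.nucleus_centers[:, 1],
                "radius_um": self.layout.nucleus_radii,
                "activated": self.activation.astype(int),
            }
        )


def _max_hex_count(radius: float, sep: float) -> int:
    """Hexagonal-packing upper bound on points with pairwise distance >= sep."""
    return max(1, int(2 * math.pi * radius**2 / (math.sqrt(3) * sep**2)))


def generate_colony_layout(
    colony_radius: float,
    target_count: int,
    min_separation: float = 8.0,
    seed: int = 0,
    radius_range: tuple[float, float] = (3.5, 5.5),
    max_rounds: int = 600,
) -> ColonyLayout:
    """Place ``target_count`` nucleus centers in a disc with a hard minimum
    pairwise separation, by batched dart-throwing (random sequential
    adsorption with a kd-tree reject step).

    Raises
    ------
    InfeasiblePackingError
        If the hexagonal-packing bound shows the count cannot fit; the error
        message names the maximum feasible count.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    cap = _max_hex_count(colony_radius, min_separation)
    if target_count > cap:
        raise InfeasiblePackingError(
            f"cannot place {target_count} nuclei with separation "
            f"{min_separation} µm in a {colony_radius} µm disc; "
            f"maximum feasible count is about {cap}"
        )
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 2))
    batch = max(256, 2 * target_count)
    for _ in range(max_rounds):
        if len(pts) >= target_count:
            break
        u = rng.random(batch)
        theta = rng.random(batch) * 2 * np.pi
        r = colony_radius * np.sqrt(u)
        cand = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        if len(pts):
            d, _ = cKDTree(pts).query(cand, k=1)
            cand = cand[d >= min_separation]
        if not len(cand):
            continue
        # greedy admission within the batch
        pairs = cKDTree(cand).query_pairs(min_separation, output_type="ndarray")
        adj: list[list[int]] = [[] for _ in range(len(cand))]
        for i, j in pairs:
            adj[i].append(j)
            adj[j].append(i)
        bad = np.zeros(len(cand), bool)
        keep = []
        for i in range(len(cand)):
            if not bad[i]:
                keep.append(i)
                bad[adj[i]] = True
        pts = np.vstack([pts, cand[keep]])
    pts = pts[:target_count]
    shortfall = len(pts) < 0.95 * target_count
    radii = rng.uniform(*radius_range, size=len(pts))
    layout = ColonyLayout(
        pts, radii, (0.0, 0.0), colony_radius, min_separation, shortfall
    )
    layout.validate()
    return layout


def assign_activation(
    layout: ColonyLayout, pheno: PhenotypeParams, seed: int = 0
) -> np.ndarray:
    """Draw per-nucleus SMAD2/3 activation labels under a phenotype rule.

    Edge-band nuclei are independent Bernoulli(``p_edge``). Interior nuclei
    are Bernoulli(``p_center``); when ``patchiness`` > 0 the interior labels
    come from thresholding a Gaussian random field smoothed to that
    correlation length, so activated cells form spatial patches while the
    marginal activation fraction stays at ``p_center``.
    """
    if pheno.edge_band_width >= layout.colony_radius:
        raise ValueError("edge_band_width must be smaller than the colony radius")
    rng = np.random.default_rng(seed)
    d = layout.distances_to_center()
    edge = d >= layout.colony_radius - pheno.edge_band_width
    active = np.zeros(layout.n, dtype=bool)
    active[edge] = rng.random(edge.sum()) < pheno.p_edge

    interior = ~edge
    n_int = int(interior.sum())
    if n_int:
        if pheno.p_center <= 0.0:
            pass
        elif pheno.p_center >= 1.0:
            active[interior] = True
        elif pheno.patchiness <= 0.0:
            active[interior] = rng.random(n_int) < pheno.p_center
        else:
            # smooth field on a coarse grid, thresholded at the empirical
            # quantile so the realised interior fraction matches p_center
            step = 4.0  # µm
            R = layout.colony_radius
            ng = int(np.ceil(2 * R / step)) + 1
            fieldg = gaussian_filter(
                rng.standard_normal((ng, ng)), sigma=pheno.patchiness / step
            )
            xi = np.clip(
                ((layout.nucleus_centers[:, 0] - layout.colony_center[0] + R) / step)
                .astype(int),
                0,
                ng - 1,
            )
            yi = np.clip(
                ((layout.nucleus_centers[:, 1] - layout.colony_center[1] + R) / step)
                .astype(int),
                0,
                ng - 1,
            )
            vals = fieldg[yi, xi][interior]
            thr = np.quantile(vals, 1.0 - pheno.p_center)
            active[interior] = vals > thr
    return active


def _paint_nuclei(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    radii_px: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (antialiased center-bright coverage, nearest-nucleus labels).

    Each nucleus renders as a radial dome (brightest at its center, half
    intensity at the rim), mimicking real DAPI texture; the per-nucleus
    intensity maxima are what lets the watershed resolve confluent colonies.
    """
    cov = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)
    score = np.full(shape, np.inf)  # d/r priority; nearest-normalised wins
    h, w = shape
    for k in range(len(radii_px)):
        cx, cy, r = centers_px[k, 0], centers_px[k, 1], radii_px[k]
        x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
        y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - cx, yy - cy)
        patch_cov = np.clip(r - d + 0.5, 0.0, 1.0)
        patch_cov *= 1.0 - 0.4 * np.clip(d / r, 0.0, 1.0) ** 2
        sub = cov[y0:y1, x0:x1]
        np.maximum(sub, patch_cov, out=sub)
        inside = d <= r
        rel = d / r
        ssub = score[y0:y1, x0:x1]
        take = inside & (rel < ssub)
        ssub[take] = rel[take]
        labels[y0:y1, x0:x1][take] = k + 1
    return cov, labels


def _apply_noise(
    img: np.ndarray, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    out = img + noise.background
    if noise.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if noise.sigma > 0:
        out = out + rng.normal(0.0, noise.sigma, size=img.shape)
    return np.clip(out, 0.0, None)


def render_colony_image(
    layout: ColonyLayout,
    activation: np.ndarray,
    pheno: PhenotypeParams,
    pixel_size: float = 1.0,
    seed: int = 0,
    margin: float = 10.0,
    max_dim: int = 8192,
) -> SyntheticSample:
    """Rasterise a colony into DAPI + SMAD2/3 channels.

    DAPI renders each nucleus as a lightly blurred antialiased disc; the
    SMAD2/3 channel takes ``intensity_on`` inside activated nuclei and
    ``intensity_off`` inside inactive ones (no blur, so noiseless medians
    equal the set intensity exactly), then phenotype noise is added.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    side_um = 2 * (layout.colony_radius + margin)
    n_px = int(np.ceil(side_um / pixel_size))
    if n_px > max_dim:
        raise ValueError(f"image dimension {n_px} px exceeds cap {max_dim}")
    offset = layout.colony_radius + margin  # µm shift putting center mid-image
    shifted = layout.translated(
        offset - layout.colony_center[0], offset - layout.colony_center[1]
    )
    centers_px = shifted.nucleus_centers / pixel_size
    radii_px = shifted.nucleus_radii / pixel_size

    rng = np.random.default_rng(seed)
    cov, labels = _paint_nuclei((n_px, n_px), centers_px, radii_px)
    dapi = gaussian_filter(cov * DAPI_INTENSITY, sigma=0.7 / pixel_size)
    smad = np.zeros_like(cov)
    inten = np.where(activation, pheno.intensity_on, pheno.intensity_off)
    inten = np.concatenate([[0.0], inten])  # label 0 = background
    smad = inten[labels]

    dapi = _apply_noise(dapi, pheno.noise, rng)
    smad = _apply_noise(smad, pheno.noise, rng)
    img = MultiChannelImage({"DAPI": dapi, "SMAD23": smad}, pixel_size)
    params = {
        "kind": "colony",
        "phenotype": pheno.phenotype_name,
        "colony_radius_um": layout.colony_radius,
        "n_nuclei": layout.n,
        "pixel_size_um": pixel_size,
        "margin_um": margin,
        "pheno": _pheno_dict(pheno),
        "seed": seed,
    }
    return SyntheticSample(img, shifted, activation, labels, params, seed)


def render_neuruloid_image(
    truth: NeuruloidGroundTruth,
    pixel_size: float = 1.0,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    margin: float = 10.0,
    intensity: float = 100.0,
) -> SyntheticSample:
    """Rasterise a neuruloid: DAPI/PAX6/N-CAD discs and a SOX10 annulus."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    R = truth.dapi_disc_radius
    side_um = 2 * (R + margin)
    n_px = int(np.ceil(side_um / pixel_size))
    c = (R + margin) / pixel_size
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    d = np.hypot(xx - c, yy - c) * pixel_size  # µm from structure center

    def disc(r: float) -> np.ndarray:
        return np.clip((r - d) / pixel_size + 0.5, 0.0, 1.0) * intensity

    rng = np.random.default_rng(seed)
    channels = {
        "DAPI": disc(R),
        "PAX6": disc(truth.pax6_radius),
        "NCAD": disc(truth.ncad_radius),
        "SOX10": np.clip(
            disc(truth.sox10_outer_radius) - disc(truth.sox10_inner_radius),
            0.0,
            intensity,
        ),
    }
    channels = {k: _apply_noise(v, noise, rng) for k, v in channels.items()}
    img = MultiChannelImage(channels, pixel_size)
    params = {
        "kind": "neuruloid",
        "radii_um": asdict(truth),
        "true_fractions": truth.true_fractions,
        "pixel_size_um": pixel_size,
        "margin_um": margin,
        "noise": asdict(noise),
        "seed": seed,
    }
    return SyntheticSample(img, None, None, None, params, seed)


def nucleus_records_from_truth(
    layout: ColonyLayout,
    activation: np.ndarray,
    pheno: PhenotypeParams,
    colony_id: str = "synthetic",
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth nucleus measurement table, bypassing rasterisation.

    Emulates what segmentation + intensity measurement would recover from a
    rendered image: per-nucleus intensity = on/off level + background +
    Gaussian measurement noise. Used for fast statistical simulations where
    the imaging steps themselves are not under test.
    """
    rng = np.random.default_rng(seed)
    inten = np.where(activation, pheno.intensity_on, pheno.intensity_off).astype(float)
    inten = inten + pheno.noise.background
    if pheno.noise.sigma > 0:
        inten = inten + rng.normal(0.0, pheno.noise.sigma, size=layout.n)
    d = layout.distances_to_center()
    return pd.DataFrame(
        {
            "colony_id": colony_id,
            "label": np.arange(1, layout.n + 1),
            "x_um": layout.nucleus_centers[:, 0],
            "y_um": layout.nucleus_centers[:, 1],
            "area_um2": np.pi * layout.nucleus_radii**2,
            "median_intensity": inten,
            "mean_intensity": inten,
            "distance_um": d,
        }
    )


def _pheno_dict(pheno: PhenotypeParams) -> dict:
    d = asdict(pheno)
    return d


def write_sample(sample: SyntheticSample, outdir, stem: str) -> dict[str, str]:
    """Write TIFF + ground-truth CSV + parameter JSON; returns written paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tif = outdir / f"{stem}.tif"
    sample.image.save_tiff(tif)
    paths["image"] = str(tif)
    truth = sample.truth_table
    if len(truth):
        csv = outdir / f"{stem}_truth.csv"
        truth.to_csv(csv, index=False)
        paths["truth"] = str(csv)
    js = outdir / f"{stem}_params.json"
    js.write_text(json.dumps(sample.params, indent=2, sort_keys=True, default=float))
    paths["params"] = str(js)
    return paths
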