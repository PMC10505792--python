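"""End-to-end runs: synthesize or ingest images -> detect -> segment ->
quantify -> statistics -> plots, with full provenance.

Every numeric output is a deterministic function of (config, seed); CSVs
are written with a fixed float format so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import positive_fraction_table, suggest_threshold
from .colonies import detect_colonies, extract_colony
from .domains import MarkerSegmentationParams, domains_to_frame, quantify_neuruloid
from .io import MultiChannelImage
from .nuclei import SegmentationParams, segment_and_measure
from .radial import (
    aggregate_profiles,
    band_summary,
    bands_to_frame,
    normalize_profile,
    profiles_to_frame,
    radial_profile,
)
from .stats import comparison_to_frame, dunnett_test, tukey_hsd
from .synthetic import (
    ACTIVIN_PRESETS,
    NEURULOID_PRESETS,
    assign_activation,
    generate_colony_layout,
    render_colony_image,
    render_neuruloid_image,
    write_sample,
)

log = logging.getLogger("mpq")

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Every field that affects a numeric result is recorded in the emitted
    provenance JSON; unknown keys in a config file are rejected.
    """

    assay: str  # "activin" | "neuruloid"
    outdir: str
    seed: int = 0
    mode: str = "synth"  # "synth" | "ingest"
    input_dir: str | None = None
    conditions: dict[str, int] = field(
        default_factory=lambda: {"WT": 15, "HET": 15, "HD": 15, "KO": 15}
    )
    control: str = "WT"
    stats_method: str = "dunnett"  # "dunnett" | "tukey"
    pixel_size: float = 1.0
    channel_map: dict[str, str] = field(default_factory=dict)
    # colony / synthesis geometry
    expected_diameter: float = 500.0
    n_nuclei: int = 1800
    min_separation: float = 8.0
    # quantification parameters
    bin_width: float = 10.0
    max_radius: float = 250.0
    center_band: tuple[float, float] = (10.0, 25.0)
    edge_band: tuple[float, float] = (175.0, 225.0)
    min_nucleus_area: float = 30.0
    max_nucleus_area: float = 300.0
    threshold_mode: str = "otsu"
    crop_margin: float = 10.0
    make_plots: bool = True
    save_images: bool = False  # synth mode: also write the TIFFs + sidecars

    def __post_init__(self) -> None:
        if self.assay not in ("activin", "neuruloid"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.mode not in ("synth", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest" and not self.input_dir:
            raise ValueError("ingest mode requires input_dir")
        if self.stats_method not in ("dunnett", "tukey"):
            raise ValueError(f"unknown stats method {self.stats_method!r}")
        defaults = (
            {"dapi": "DAPI", "smad": "SMAD23"}
            if self.assay == "activin"
            else {"dapi": "DAPI", "pax6": "PAX6", "ncad": "NCAD", "sox10": "SOX10"}
        )
        cm = dict(defaults)
        cm.update(self.channel_map)
        self.channel_map = cm
        bad = [k for k in defaults if not cm.get(k)]
        if bad:
            raise ValueError(f"channel_map missing channels for: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("center_band", "edge_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["center_band"] = list(self.center_band)
        d["edge_band"] = list(self.edge_band)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    """Bundle of a completed run: every table plus where it was written."""

    config: RunConfig
    tables: dict[str, pd.DataFrame]
    paths: dict[str, str]
    notices: list[str] = field(default_factory=list)


def _child_seed(base_seed: int, *idx: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *map(int, idx)])
    return int(ss.generate_state(1)[0] % (2**31))


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return str(path)


def _provenance(config: RunConfig, outdir: Path, extra: dict) -> str:
    rec = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "software": {"package": "mpq", "version": __version__},
        **extra,
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(rec, indent=2, sort_keys=True))
    return str(path)


def _iter_colony_images(config: RunConfig):
    """Yield (condition, image_stem, MultiChannelImage, synth_truth|None)."""
    if config.mode == "synth":
        presets = ACTIVIN_PRESETS
        for ci, (cond, n) in enumerate(sorted(config.conditions.items())):
            if cond not in presets:
                raise ValueError(f"no activin preset named {cond!r}")
            pheno = presets[cond]
            for i in range(n):
                lay = generate_colony_layout(
                    config.expected_diameter / 2.0,
                    config.n_nuclei,
                    config.min_separation,
                    seed=_child_seed(config.seed, 0, ci, i),
                )
                act = assign_activation(
                    lay, pheno, seed=_child_seed(config.seed, 1, ci, i)
                )
                sample = render_colony_image(
                    lay,
                    act,
                    pheno,
                    pixel_size=config.pixel_size,
                    seed=_child_seed(config.seed, 2, ci, i),
                )
                yield cond, f"{cond}_{i:03d}", sample.image, sample
    else:
        root = Path(config.input_dir)
        conds = sorted(p.name for p in root.iterdir() if p.is_dir())
        if not conds:
            raise ValueError(f"no condition directories under {root}")
        for cond in conds:
            for tif in sorted((root / cond).glob("*.tif")):
                yield cond, tif.stem, MultiChannelImage.load_tiff(tif), None


def run_activin(config: RunConfig) -> RunResult:
    """Activin-assay pipeline: radial profiles, band summaries, positive
    fractions, and group statistics over per-colony values."""
    if config.assay != "activin":
        raise ValueError("config.assay must be 'activin'")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dapi_name = config.channel_map["dapi"]
    smad_name = config.channel_map["smad"]
    seg = SegmentationParams()

    colony_rows, nuclei_frames, profiles, bands = [], [], [], []
    per_colony_records: dict[str, pd.DataFrame] = {}
    colony_condition: dict[str, str] = {}
    counts_by_condition: dict[str, int] = {}
    t_start = time.time()
    for cond, stem, image, sample in _iter_colony_images(config):
        if config.mode == "synth" and config.save_images:
            write_sample(sample, outdir / "images" / cond, stem)
        det = detect_colonies(
            image[dapi_name],
            config.expected_diameter,
            image.pixel_size,
            source_image=stem,
        )
        log.info(
            "%s: %d colonies accepted, %d rejected", stem, len(det), len(det.rejects)
        )
        for rej in det.rejects:
            colony_rows.append(
                (rej.colony_id, cond, rej.center_um[0], rej.center_um[1],
                 rej.area_um2, False, rej.reject_reason)
            )
        for region in det:
            cid = region.colony_id
            colony_rows.append(
                (cid, cond, region.center_um[0], region.center_um[1],
                 region.area_um2, True, "")
            )
            crop = extract_colony(image, region, margin=config.crop_margin)
            rec = segment_and_measure(
                crop.image[dapi_name],
                crop.image[smad_name],
                crop.region.center_um,
                image.pixel_size,
                colony_id=cid,
                min_area=config.min_nucleus_area,
                max_area=config.max_nucleus_area,
                params=seg,
            )
            if not len(rec):
                continue
            nuclei_frames.append(rec)
            per_colony_records[cid] = rec
            colony_condition[cid] = cond
            counts_by_condition[cond] = counts_by_condition.get(cond, 0) + 1
            profiles.append(
                normalize_profile(
                    radial_profile(rec, config.bin_width, config.max_radius)
                )
            )
            bands.append(
                band_summary(rec, config.center_band, config.edge_band)
            )
    for cond in config.conditions if config.mode == "synth" else set(
        colony_condition.values()
    ):
        if counts_by_condition.get(cond, 0) == 0:
            raise RuntimeError(f"no colonies detected in condition {cond!r}")

    nuclei = pd.concat(nuclei_frames, ignore_index=True)
    colonies = pd.DataFrame(
        colony_rows,
        columns=["colony_id", "condition", "center_x_um", "center_y_um",
                 "area_um2", "accepted", "reject_reason"],
    )
    bands_df = bands_to_frame(bands)
    bands_df.insert(1, "condition", bands_df["colony_id"].map(colony_condition))
    profiles_df = profiles_to_frame(profiles)
    profiles_df.insert(
        1, "condition", profiles_df["colony_id"].map(colony_condition)
    )

    # one global threshold per batch, estimated on the pooled control nuclei
    control_ids = [c for c, k in colony_condition.items() if k == config.control]
    pooled = (
        nuclei[nuclei["colony_id"].isin(control_ids)] if control_ids else nuclei
    )
    thr = suggest_threshold(pooled, mode=config.threshold_mode)
    positives = positive_fraction_table(
        per_colony_records, thr.value, thr.mode
    )
    positives.insert(1, "condition", positives["colony_id"].map(colony_condition))

    tables = {
        "colonies": colonies,
        "nuclei": nuclei,
        "profiles": profiles_df,
        "bands": bands_df,
        "positives": positives,
    }
    notices = []
    if thr.degenerate:
        notices.append("threshold estimate degenerate (unimodal intensities)")

    stats_frames = []
    n_conditions = bands_df["condition"].nunique()
    if n_conditions < 2:
        notices.append("single group; statistics skipped")
    else:
        for readout, source, col in (
            ("center_mean", bands_df, "center_mean"),
            ("edge_mean", bands_df, "edge_mean"),
            ("pct_positive", positives, "pct_positive"),
        ):
            groups = {
                cond: sub[col].dropna().to_numpy()
                for cond, sub in source.groupby("condition")
            }
            comp = (
                dunnett_test(groups, config.control)
                if config.stats_method == "dunnett"
                else tukey_hsd(groups)
            )
            stats_frames.append(comparison_to_frame(comp, readout))
        tables["stats"] = pd.concat(stats_frames, ignore_index=True)

    paths = {name: _write(df, outdir / f"{name}.csv") for name, df in tables.items()}
    if config.make_plots:
        from . import plotting

        agg = {
            cond: aggregate_profiles([p for p in profiles
                                      if colony_condition[p.colony_id] == cond])
            for cond in sorted(set(colony_condition.values()))
        }
        paths["profiles_plot"] = plotting.save_profile_plot(
            agg, outdir / "profiles.png"
        )
        paths["bands_plot"] = plotting.save_band_scatter(
            bands_df, outdir / "bands.png"
        )
    paths["provenance"] = _provenance(
        config,
        outdir,
        {
            "colonies_per_condition": counts_by_condition,
            "notices": notices,
            "threshold": {"value": thr.value, "mode": thr.mode},
            "runtime_s": round(time.time() - t_start, 2),
        },
    )
    return RunResult(config, tables, paths, notices)


def run_neuruloid(config: RunConfig) -> RunResult:
    """Neuruloid pipeline: marker-domain fractions and group statistics."""
    if config.assay != "neuruloid":
        raise ValueError("config.assay must be 'neuruloid'")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm = config.channel_map
    markers = {"PAX6": cm["pax6"], "NCAD": cm["ncad"], "SOX10": cm["sox10"]}
    params = MarkerSegmentationParams()
    records, conditions = [], {}
    t_start = time.time()
    if config.mode == "synth":
        for ci, (cond, n) in enumerate(sorted(config.conditions.items())):
            if cond not in NEURULOID_PRESETS:
                raise ValueError(f"no neuruloid preset named {cond!r}")
            truth = NEURULOID_PRESETS[cond]
            for i in range(n):
                sample = render_neuruloid_image(
                    truth,
                    pixel_size=config.pixel_size,
                    seed=_child_seed(config.seed, 3, ci, i),
                )
                cid = f"{cond}_{i:03d}"
                if config.save_images:
                    write_sample(sample, outdir / "images" / cond, cid)
                img = sample.image
                rec = quantify_neuruloid(
                    img,
                    marker_channels=tuple(markers),
                    dapi_channel="DAPI",
                    params=params,
                    colony_id=cid,
                )
                records.append(rec)
                conditions[cid] = cond
    else:
        root = Path(config.input_dir)
        conds = sorted(p.name for p in root.iterdir() if p.is_dir())
        for cond in conds:
            for tif in sorted((root / cond).glob("*.tif")):
                img = MultiChannelImage.load_tiff(tif)
                for key, ch in {**markers, "DAPI": cm["dapi"]}.items():
                    if ch not in img.channels:
                        raise ValueError(
                            f"{tif.name}: channel {ch!r} ({key}) missing"
                        )
                rec = quantify_neuruloid(
                    img,
                    marker_channels=tuple(markers.values()),
                    dapi_channel=cm["dapi"],
                    params=params,
                    colony_id=tif.stem,
                )
                records.append(rec)
                conditions[tif.stem] = cond
    if not records:
        raise RuntimeError("no neuruloids quantified")
    domains = domains_to_frame(records)
    domains.insert(1, "condition", domains["colony_id"].map(conditions))
    tables = {"domains": domains}
    notices = []
    frac_cols = [c for c in domains.columns if c.endswith("_frac")]
    if domains["condition"].nunique() < 2:
        notices.append("single group; statistics skipped")
    else:
        frames = []
        for col in frac_cols:
            groups = {
                cond: sub[col].to_numpy() for cond, sub in domains.groupby("condition")
            }
            comp = (
                dunnett_test(groups, config.control)
                if config.stats_method == "dunnett"
                else tukey_hsd(groups)
            )
            frames.append(comparison_to_frame(comp, col))
        tables["stats"] = pd.concat(frames, ignore_index=True)
    paths = {name: _write(df, outdir / f"{name}.csv") for name, df in tables.items()}
    if config.make_plots:
        from . import plotting

        paths["domains_plot"] = plotting.save_domain_plot(
            domains, frac_cols, outdir / "domains.png"
        )
    paths["provenance"] = _provenance(
        config,
        outdir,
        {
            "neuruloids_per_condition": pd.Series(list(conditions.values()))
            .value_counts()
            .to_dict(),
            "notices": notices,
            "runtime_s": round(time.time() - t_start, 2),
        },
    )
    return RunResult(config, tables, paths, notices)
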