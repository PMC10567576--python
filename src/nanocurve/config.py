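"""Run configuration and the stage-dispatching pipeline."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, NanocurveError
from .io import read_image
from .registration import (
    average_windows,
    derive_bar_rois,
    derive_pillar_rois,
    detect_lattice,
    tile_windows,
)
from .ratiometric import (
    background_level,
    classify_enriched,
    end_side_ratios,
    pillar_ratios,
    spearman_at_pillars,
)
from .dynamics import extract_traces, group_by_intensity, temporal_sd
from .fret import fret_ratios, segment_and_classify
from .coloc import adhesion_census
from .matrix3d import cell_depths, estimate_surface, segment_cells_3d

log = logging.getLogger(__name__)

TASKS = ("bars", "pillars", "spearman", "dynamics", "fret", "coloc", "depth")

#: analysis defaults, centralised so every run logs them
DEFAULTS = {
    "pitch_band_um": (2.0, 10.0),
    "r_in_px": 9,
    "r_out_px": 20,
    "min_coloc_2d_px": 10,
    "min_coloc_3d_vox": 25,
    "min_cell_volume_vox": 500,
    "surface_blur_px": 50.0,
    "enrichment_threshold": 1.5,
    "flank_width_px": 2,
}


@dataclass
class RunConfig:
    task: str
    input: str
    out_dir: str
    roles: tuple[str, ...] | None = None
    pixel_size_um: float | None = None
    voxel_size_um: tuple[float, float, float] | None = None
    cell_mask: str | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigError(f"unknown task {self.task!r}; expected one of {TASKS}")
        for key in ("pixel_size_um",):
            v = getattr(self, key)
            if v is not None and v <= 0:
                raise ConfigError(f"{key} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config YAML must be a mapping")
        if "roles" in raw and raw["roles"] is not None:
            raw["roles"] = tuple(raw["roles"])
        if "voxel_size_um" in raw and raw["voxel_size_um"] is not None:
            raw["voxel_size_um"] = tuple(raw["voxel_size_um"])
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def param(self, key: str):
        return self.params.get(key, DEFAULTS.get(key))


def _load_cell_mask(cfg: RunConfig):
    if cfg.cell_mask is None:
        return None
    return read_image(cfg.cell_mask).data.astype(bool)


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute one configured analysis; write CSVs and a JSON run log.

    Deterministic: the same config (and seed) produces byte-identical
    outputs.  Any stage failure aborts with the stage name and cause.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = read_image(cfg.input, roles=cfg.roles, pixel_size_um=cfg.pixel_size_um)
    results: dict[str, pd.DataFrame] = {}
    stage = "setup"
    try:
        if cfg.task == "bars":
            stage = "lattice"
            px = img.require_pixel_size()
            lat = detect_lattice(img.channel("registration"), cfg.param("pitch_band_um"), px)
            cell = _load_cell_mask(cfg)
            stage = "windows"
            mem = img.channel("membrane")
            itg = img.channel("integrin")
            wins = tile_windows(lat, mem.shape, cell)
            stage = "rois"
            avg = average_windows(mem, wins)
            rois = derive_bar_rois(
                avg,
                bar_width_px=cfg.params.get("bar_width_px"),
                flank_width=cfg.param("flank_width_px"),
            )
            stage = "ratios"
            bg = (
                (background_level(itg, cell), background_level(mem, cell))
                if cell is not None
                else (0.0, 0.0)
            )
            res = end_side_ratios(itg, mem, wins, rois, background=bg)
            results["per_bar"] = res.per_bar
            results["per_cell"] = pd.DataFrame(
                [{"cell_id": res.cell_id, "mean_ratio_norm": res.per_cell_mean,
                  "n_bars": len(res.per_bar)}]
            )

        elif cfg.task in ("pillars", "spearman"):
            stage = "lattice"
            px = img.require_pixel_size()
            mem = img.channel("membrane")
            lat = detect_lattice(mem, cfg.param("pitch_band_um"), px)
            cell = _load_cell_mask(cfg)
            stage = "windows"
            wins = tile_windows(lat, mem.shape, cell)
            rois = derive_pillar_rois(wins.side, cfg.param("r_in_px"), cfg.param("r_out_px"))
            itg = img.channel("integrin")
            stage = "ratios"
            res = pillar_ratios(itg, mem, wins, rois)
            results["per_roi"] = res.per_roi
            if cfg.task == "pillars":
                flags, frac = classify_enriched(
                    res.pillar_norm_ratios, cfg.param("enrichment_threshold")
                )
                results["summary"] = pd.DataFrame(
                    [{"cell_id": res.cell_id, "enriched_fraction": frac,
                      "n_pillars": len(flags)}]
                )
            else:
                stage = "spearman"
                sp = spearman_at_pillars(img.channel("poi"), itg, mem, wins, rois)
                results["spearman"] = pd.DataFrame(
                    [{"cell_id": sp.cell_id, "rho": sp.rho, "n_pillars": sp.n}]
                )

        elif cfg.task == "dynamics":
            stage = "lattice"
            px = img.require_pixel_size()
            if "T" not in img.axes:
                raise ConfigError("dynamics task requires a time axis")
            mem0 = img.channel("membrane")[0]
            lat = detect_lattice(mem0, cfg.param("pitch_band_um"), px)
            wins = tile_windows(lat, mem0.shape, _load_cell_mask(cfg))
            rois = derive_pillar_rois(wins.side, cfg.param("r_in_px"), cfg.param("r_out_px"))
            stage = "traces"
            traces = extract_traces(img.channel("poi"), wins, rois)
            itg0 = img.channel("integrin")[0]
            ref = np.array(
                [itg0[wins.window_slice(k)][rois["pillar"]].mean()
                 for k in wins.in_cell_indices()]
            )
            labels = group_by_intensity(ref, cfg.params.get("scheme", "top25_bottom75"))
            sds = temporal_sd(traces)
            results["traces"] = pd.DataFrame(
                {tr.pillar_id: tr.normalized for tr in traces}
            )
            results["sds"] = pd.DataFrame(
                {
                    "pillar_id": [tr.pillar_id for tr in traces],
                    "group": labels,
                    "temporal_sd": sds,
                }
            )

        elif cfg.task == "fret":
            stage = "lattice"
            px = img.require_pixel_size()
            lat = detect_lattice(img.channel("registration"), cfg.param("pitch_band_um"), px)
            stage = "segment"
            don = img.channel("donor")
            masks = segment_and_classify(don, lat, r_in=cfg.param("r_in_px"))
            stage = "ratios"
            res = fret_ratios(img.channel("acceptor"), don, masks, _load_cell_mask(cfg))
            results["fret"] = pd.DataFrame(
                [{"curved_ratio": res.curved_ratio, "focal_ratio": res.focal_ratio,
                  "cellwide_ratio": res.cellwide_ratio, "mode": res.mode}]
            )

        elif cfg.task == "coloc":
            stage = "census"
            curved_role = cfg.params.get("curved_partner_role", "poi")
            focal_role = cfg.params.get("focal_partner_role", "donor")
            arr = img.channel("integrin")
            min_size = cfg.params.get("min_size")
            results["census"] = adhesion_census(
                arr,
                img.channel(curved_role),
                img.channel(focal_role),
                min_size=min_size,
            )

        elif cfg.task == "depth":
            stage = "segment"
            if img.voxel_size_um is None and cfg.voxel_size_um is None:
                raise ConfigError("depth task needs voxel_size_um (metadata or config)")
            vox = cfg.voxel_size_um or img.voxel_size_um
            cells = segment_cells_3d(
                img.channel("cell"), vox, cfg.param("min_cell_volume_vox")
            )
            stage = "surface"
            surf = estimate_surface(img.channel("fibre"), vox, cfg.param("surface_blur_px"))
            stage = "depths"
            depths = cell_depths(cells, surf)
            results["cells"] = pd.DataFrame(
                [
                    {
                        "cell_id": c.id,
                        "volume_voxels": c.volume_voxels,
                        "x_um": c.centroid_um[0],
                        "y_um": c.centroid_um[1],
                        "z_um": c.centroid_um[2],
                        "depth_um": d,
                    }
                    for c, d in zip(cells, depths)
                ]
            )
    except NanocurveError as e:
        raise NanocurveError(f"stage {stage!r} failed: {e}") from e

    for name, df in results.items():
        df.to_csv(out / f"{name}.csv", index=False)
    logdict = {
        "config": {**asdict(cfg)},
        "defaults": {k: list(v) if isinstance(v, tuple) else v for k, v in DEFAULTS.items()},
        "nanocurve_version": __version__,
        "numpy_version": np.__version__,
    }
    (out / "run_log.json").write_text(json.dumps(logdict, indent=1, default=str))
    return results
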