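"""End-to-end pipeline: image -> lanes -> bands -> weights -> matching -> trees.

Mirrors the six-step workflow as a single call. Every intermediate is
persisted as a text artifact so a user can stop after any stage, hand-edit
the TSV (the programmatic stand-in for interactive adjustment), and resume
with the individual CLI subcommands. A JSON manifest records all artifacts
and the parameters that produced them, which suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import io as gio
from .band_detection import BandDetectionParams, detect_bands, lane_profile
from .band_matching import (MatchingParams, clustering_matrix, dice_similarity,
                            distance_from_similarity, match_bands)
from .errors import NotFoundError, PipelineError
from .gel_image import crop, load_image, rotate_quarter, save_image
from .lane_detection import (LaneDetectionParams, column_max_profile, detect_lanes,
                             subtract_background)
from .phylogeny import METHODS, build_tree, write_newick
from .weight_calibration import assign_weights, fit_migration_model, read_marker

logger = logging.getLogger("gelphylo")


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters for a full run. ``marker_lanes`` are excluded from band
    matching and tree building by default (set ``include_markers`` to keep
    them); ``standard`` names a ``.marker`` file in ``standards_dir`` (or is
    a direct path)."""

    image: str
    out_dir: str = "."
    crop_box: Optional[tuple[int, int, int, int]] = None  # top, bottom, left, right
    rotate_turns: int = 0
    lane_params: LaneDetectionParams = field(default_factory=LaneDetectionParams)
    band_params: BandDetectionParams = field(default_factory=BandDetectionParams)
    marker_lanes: tuple[int, ...] = ()
    standard: Optional[str] = None
    standards_dir: str = "standards"
    include_markers: bool = False
    matching: MatchingParams = field(default_factory=MatchingParams)
    methods: tuple[str, ...] = ("nj",)
    seed: int = 0

    def __post_init__(self):
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown tree methods {sorted(bad)}; choose from {METHODS}")


def _params_dict(obj) -> dict:
    return dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else obj


def resolve_standard(name: str, standards_dir: str):
    """Find a marker standard by direct path or by name in ``standards_dir``."""
    candidates = [name]
    if not name.endswith(".marker"):
        candidates.append(name + ".marker")
    candidates += [os.path.join(standards_dir, c) for c in list(candidates)]
    for cand in candidates:
        if os.path.isfile(cand):
            return read_marker(cand)
    raise NotFoundError(f"marker standard '{name}' not found "
                        f"(searched {standards_dir!r} and direct paths)")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest (also written as JSON).

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts written before the failure are kept.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {"config": {
        "image": cfg.image, "crop_box": cfg.crop_box, "rotate_turns": cfg.rotate_turns,
        "lane_params": _params_dict(cfg.lane_params),
        "band_params": _params_dict(cfg.band_params),
        "marker_lanes": list(cfg.marker_lanes), "standard": cfg.standard,
        "include_markers": cfg.include_markers,
        "matching": _params_dict(cfg.matching), "methods": list(cfg.methods),
        "seed": cfg.seed,
    }, "artifacts": {}}

    def emit(key: str, filename: str) -> str:
        path = os.path.join(cfg.out_dir, filename)
        manifest["artifacts"][key] = path
        logger.info("%s -> %s", key, path)
        return path

    def finish() -> dict:
        path = os.path.join(cfg.out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest

    stage = "prepare"
    try:
        img = load_image(cfg.image)
        if cfg.crop_box is not None:
            img = crop(img, *cfg.crop_box)
        if cfg.rotate_turns:
            img = rotate_quarter(img, cfg.rotate_turns)
        save_image(img, emit("prepared_image", "prepared.png"))

        stage = "lanes"
        lanes = detect_lanes(column_max_profile(img), cfg.lane_params)
        gio.write_lanes_tsv(lanes, emit("lanes", "lanes.tsv"))
        subtracted = subtract_background(img, lanes)
        save_image(subtracted, emit("background_subtracted", "subtracted.png"))

        stage = "bands"
        bands = []
        for lane in lanes:
            bands.extend(detect_bands(lane_profile(subtracted, lane), lane,
                                      cfg.band_params))
        gio.write_bands_tsv(bands, emit("bands", "bands.tsv"))

        stage = "weights"
        if cfg.standard is not None:
            if not cfg.marker_lanes:
                raise NotFoundError("a standard is configured but no marker lane is")
            std = resolve_standard(cfg.standard, cfg.standards_dir)
            marker_rows = sorted(b.migration_distance for b in bands
                                 if b.lane_id == cfg.marker_lanes[0])
            model = fit_migration_model(marker_rows, std)
            bands = assign_weights(bands, model)
            manifest["calibration"] = {"alpha": model.alpha, "beta": model.beta}
            gio.write_bands_tsv(bands, emit("bands_weighted", "bands_weighted.tsv"))

        stage = "match"
        if cfg.include_markers:
            kept_ids = [ln.id for ln in lanes]
        else:
            kept_ids = [ln.id for ln in lanes if ln.id not in cfg.marker_lanes]
        remap = {lane_id: k for k, lane_id in enumerate(kept_ids)}
        labels = [f"lane{lane_id}" for lane_id in kept_ids]
        kept_bands = [dataclasses.replace(b, lane_id=remap[b.lane_id])
                      for b in bands if b.lane_id in remap]
        clusters = match_bands(kept_bands, img.height, cfg.matching)
        matrix = clustering_matrix(clusters, n_lanes=len(kept_ids))
        gio.write_matrix_tsv(matrix, emit("matrix", "matrix.tsv"), lane_labels=labels)
        similarity = dice_similarity(matrix)
        distance = distance_from_similarity(similarity)
        gio.write_phylip(distance, labels, emit("distance", "dist.phy"))

        stage = "tree"
        for method in cfg.methods:
            tree = build_tree(distance, labels, method)
            with open(emit(f"tree_{method}", f"tree_{method}.nwk"), "w") as fh:
                fh.write(write_newick(tree) + "\n")
    except Exception as exc:
        finish()  # keep partial artifacts for inspection
        raise PipelineError(stage, exc) from exc

    return finish()
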