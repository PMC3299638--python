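"""Synthetic gel images with known ground truth.

Emulates UV photographs of ethidium-bromide-stained agarose gels: bright
lanes on a dark background, each band a Gaussian intensity bump in the row
direction spanning the lane's columns, over a smooth (optionally tilted)
background with additive Gaussian noise. Band rows are placed by inverting
the log-linear migration law, row = (ln(weight) - beta) / alpha, so every
downstream stage — lane detection, band detection, weight calibration,
matching, trees — can be checked against exact ground truth.

Not modelled (out of scope): lane smiling, smearing from overloaded wells,
saturation blooming, degradation artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import SceneError
from .gel_image import GelImage
from .weight_calibration import CalibrationModel, MarkerStandard


@dataclass(frozen=True)
class GelScene:
    """Full description of a synthetic gel.

    ``fragments`` holds one list of molecular weights per lane; ``model``
    is the generating migration model mapping weight to band row.
    """

    fragments: tuple[tuple[float, ...], ...]
    model: CalibrationModel
    lane_width: int = 20
    lane_gap: int = 8
    image_height: int = 500
    band_sigma: float = 2.0
    band_amplitude: float = 180.0
    background_level: float = 10.0
    background_tilt: float = 0.0  # intensity per row
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "fragments",
                           tuple(tuple(float(w) for w in lane) for lane in self.fragments))
        if self.n_lanes < 1:
            raise SceneError("a scene needs at least one lane")
        if self.band_sigma <= 0:
            raise SceneError("band_sigma must be positive")
        if any(w <= 0 for lane in self.fragments for w in lane):
            raise SceneError("fragment weights must be positive")

    @property
    def n_lanes(self) -> int:
        return len(self.fragments)

    @property
    def image_width(self) -> int:
        return self.lane_gap + self.n_lanes * (self.lane_width + self.lane_gap)

    def lane_interval(self, lane_id: int) -> tuple[int, int]:
        start = self.lane_gap + lane_id * (self.lane_width + self.lane_gap)
        return start, start + self.lane_width

    def band_row(self, weight: float) -> float:
        """Invert the migration law: row = (ln(weight) - beta) / alpha."""
        return (math.log(weight) - self.model.beta) / self.model.alpha


@dataclass(frozen=True)
class GroundTruth:
    """True lane intervals and true (lane, row, weight) band positions."""

    lanes: tuple[tuple[int, int], ...]
    bands: tuple[tuple[int, float, float], ...]  # (lane_id, row, weight)


def render_gel(scene: GelScene) -> tuple[GelImage, GroundTruth]:
    """Render the scene; deterministic for a fixed seed."""
    height, width = scene.image_height, scene.image_width
    rows = np.arange(height, dtype=float)
    canvas = np.tile((scene.background_level + scene.background_tilt * rows)[:, None],
                     (1, width))

    truth_bands: list[tuple[int, float, float]] = []
    for lane_id, weights in enumerate(scene.fragments):
        a, b = scene.lane_interval(lane_id)
        for w in weights:
            row = scene.band_row(w)
            if not 0 <= row < height:
                raise SceneError(
                    f"fragment of weight {w:g} in lane {lane_id} maps to row "
                    f"{row:.1f}, outside the {height}-row image")
            profile = scene.band_amplitude * np.exp(
                -0.5 * ((rows - row) / scene.band_sigma) ** 2)
            canvas[:, a:b] += profile[:, None]
            truth_bands.append((lane_id, row, w))

    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        canvas = canvas + rng.normal(0.0, scene.noise_sigma, size=canvas.shape)

    truth = GroundTruth(
        lanes=tuple(scene.lane_interval(k) for k in range(scene.n_lanes)),
        bands=tuple(truth_bands))
    return GelImage(np.clip(canvas, 0.0, 255.0)), truth


def scene_from_fingerprints(matrix, cluster_weights, model: CalibrationModel,
                            **geometry) -> GelScene:
    """Build a scene realizing a presence/absence fingerprint.

    ``matrix`` is a clusters x lanes 0/1 grid; ``cluster_weights`` gives the
    molecular weight of each cluster row; lane l receives the weights of the
    rows where cell (k, l) = 1. Rendering such a scene and running the full
    pipeline should reproduce ``matrix`` (the fingerprint round trip).
    """
    cells = np.asarray(matrix, dtype=int)
    if cells.ndim != 2:
        raise SceneError("fingerprint matrix must be 2-D")
    weights = [float(w) for w in cluster_weights]
    if len(weights) != cells.shape[0]:
        raise SceneError(f"{len(weights)} weights for {cells.shape[0]} cluster rows")
    if len(set(weights)) != len(weights):
        raise SceneError("cluster weights must be distinct")
    fragments = tuple(
        tuple(weights[k] for k in range(cells.shape[0]) if cells[k, lane])
        for lane in range(cells.shape[1]))
    return GelScene(fragments=fragments, model=model, **geometry)


def marker_scene(std: MarkerStandard, model: CalibrationModel, **geometry) -> GelScene:
    """Single-lane scene containing a marker standard's fragments."""
    return GelScene(fragments=(std.weights,), model=model, **geometry)


DEFAULT_MODEL = CalibrationModel(alpha=-0.01, beta=math.log(5000.0))


def random_scene(rng: np.random.Generator,
                 n_lanes: int | None = None,
                 bands_per_lane: tuple[int, int] = (2, 10),
                 image_height: int = 500,
                 band_amplitude: float = 230.0,
                 noise_sigma: float = 23.0,
                 model: CalibrationModel = DEFAULT_MODEL,
                 **overrides) -> GelScene:
    """A random multi-lane scene for detection benchmarks.

    Band rows are drawn per lane from a 15-row grid spanning the resolvable
    part of the gel, so bands within a lane never blur together. Bands are
    bright but just below saturation (amplitude 230 over a background of
    10), as in a well-exposed UV photograph; with ``noise_sigma`` 23 the
    band signal-to-noise ratio is 10. Fragment weights follow from the rows
    via the generating model.
    """
    if n_lanes is None:
        n_lanes = int(rng.integers(8, 17))
    grid = np.arange(40, image_height - 40, 15)
    fragments = []
    for _ in range(n_lanes):
        k = int(rng.integers(bands_per_lane[0], bands_per_lane[1] + 1))
        rows = rng.choice(grid, size=min(k, len(grid)), replace=False)
        fragments.append(tuple(float(np.exp(model.alpha * r + model.beta))
                               for r in sorted(rows)))
    return GelScene(fragments=tuple(fragments), model=model,
                    image_height=image_height, band_amplitude=band_amplitude,
                    noise_sigma=noise_sigma,
                    seed=int(rng.integers(2 ** 31)), **overrides)
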