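"""Lane detection from the column-maximum intensity profile.

Each sample migrates down a vertical lane, which shows up as a bright strip.
The detector works on the profile obtained by taking the maximum intensity
of every pixel column: lanes are plateaus of that profile. Seeding happens
at a high threshold (70% of the profile maximum) where noise is unlikely;
the seed runs estimate a typical lane width, and the threshold is then swept
down to 15% of the maximum, accepting runs whose width deviates less than
25% from that typical width. All thresholds are fractions of the profile
maximum, so detection is invariant to overall exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .errors import ConflictError, DetectionError, NotFoundError
from .gel_image import GelImage


@dataclass(frozen=True)
class Profile:
    """A 1-D intensity profile along image columns or rows."""

    values: np.ndarray
    axis: str  # "columns" or "rows"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("profile must be a non-empty 1-D sequence")
        if self.axis not in ("columns", "rows"):
            raise ValueError("axis must be 'columns' or 'rows'")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Lane:
    """A vertical lane strip: half-open column interval [col_start, col_end)."""

    id: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if not 0 <= self.col_start < self.col_end:
            raise ValueError(f"invalid lane interval [{self.col_start},{self.col_end})")

    @property
    def width(self) -> int:
        return self.col_end - self.col_start


@dataclass(frozen=True)
class LaneDetectionParams:
    hi_threshold_frac: float = 0.70
    lo_threshold_frac: float = 0.15
    width_deviation_frac: float = 0.25
    user_lane_width: Optional[int] = None  # overrides the estimated mean width

    def __post_init__(self):
        if not 0 < self.lo_threshold_frac < self.hi_threshold_frac <= 1:
            raise ValueError("need 0 < lo < hi <= 1")
        if not 0 <= self.width_deviation_frac < 1:
            raise ValueError("width deviation fraction must be in [0, 1)")


def column_max_profile(img: GelImage) -> Profile:
    """Maximum intensity of each pixel column; lanes appear as plateaus."""
    return Profile(img.pixels.max(axis=0), axis="columns")


def runs_above(profile: Profile | np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal half-open intervals [a, b) where every value is >= threshold."""
    values = profile.values if isinstance(profile, Profile) else np.asarray(profile, float)
    mask = values >= threshold
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_lanes(profile: Profile, params: LaneDetectionParams = LaneDetectionParams()) -> list[Lane]:
    """Detect lanes on the column-max profile.

    Algorithm: seed runs at hi * max(profile); drop runs thinner than the
    seeds' mean width and re-average the survivors to get the typical width
    m (or take ``user_lane_width`` as m directly); then sweep the threshold
    from hi down to lo in 1% steps of the profile maximum, accepting runs
    whose width lies within m * (1 +/- dev) and which do not overlap a lane
    accepted at a higher (more reliable) threshold.
    """
    values = profile.values
    peak = float(values.max())
    if peak <= 0:
        raise DetectionError("no signal: the column profile is flat at zero")

    if params.user_lane_width is not None:
        m = float(params.user_lane_width)
    else:
        seeds = runs_above(values, params.hi_threshold_frac * peak)
        if not seeds:
            raise DetectionError("no signal above the high threshold")
        widths = np.array([b - a for a, b in seeds], dtype=float)
        m0 = widths.mean()
        survivors = widths[widths >= m0]  # runs thinner than the mean are noise
        m = float(survivors.mean()) if survivors.size else float(widths.max())

    lo_w = m * (1 - params.width_deviation_frac)
    hi_w = m * (1 + params.width_deviation_frac)

    accepted: list[tuple[int, int]] = []
    level = params.hi_threshold_frac
    # fixed 1% grid makes the sweep deterministic
    while level >= params.lo_threshold_frac - 1e-12:
        for a, b in runs_above(values, level * peak):
            if not lo_w <= b - a <= hi_w:
                continue
            if any(a < e and s < b for s, e in accepted):
                continue
            accepted.append((a, b))
        level -= 0.01

    accepted.sort()
    return [Lane(id=i, col_start=a, col_end=b) for i, (a, b) in enumerate(accepted)]


def _reindex(intervals: list[tuple[int, int]]) -> list[Lane]:
    intervals = sorted(intervals)
    return [Lane(id=i, col_start=a, col_end=b) for i, (a, b) in enumerate(intervals)]


def add_lane(lanes: list[Lane], col_start: int, col_end: int) -> list[Lane]:
    """Manually add a lane; the new interval must not overlap existing lanes."""
    if col_start >= col_end:
        raise ValueError(f"empty lane interval [{col_start},{col_end})")
    for ln in lanes:
        if col_start < ln.col_end and ln.col_start < col_end:
            raise ConflictError(
                f"new lane [{col_start},{col_end}) overlaps lane {ln.id} "
                f"[{ln.col_start},{ln.col_end})")
    return _reindex([(ln.col_start, ln.col_end) for ln in lanes] + [(col_start, col_end)])


def remove_lane(lanes: list[Lane], lane_id: int) -> list[Lane]:
    """Manually remove a lane by id; remaining lanes are re-indexed."""
    if not any(ln.id == lane_id for ln in lanes):
        raise NotFoundError(f"no lane with id {lane_id}")
    return _reindex([(ln.col_start, ln.col_end) for ln in lanes if ln.id != lane_id])


def subtract_background(img: GelImage, lanes: list[Lane]) -> GelImage:
    """Remove smooth background from each lane; pixels outside lanes go to 0.

    Per lane the baseline is the row-wise mean intensity across the lane's
    columns, passed through a rolling minimum and then a moving average,
    both of window ceil(height/20). The rolling minimum drops under narrow
    bright bands (so bands survive subtraction) while following the slow
    background; the moving average smooths the staircase the minimum leaves.
    Output is clamped at 0.
    """
    out = np.zeros_like(img.pixels)
    window = max(1, -(-img.height // 20))
    for ln in lanes:
        strip = img.pixels[:, ln.col_start:ln.col_end]
        row_mean = strip.mean(axis=1)
        baseline = minimum_filter1d(row_mean, size=window, mode="nearest")
        baseline = uniform_filter1d(baseline, size=window, mode="nearest")
        out[:, ln.col_start:ln.col_end] = np.maximum(strip - baseline[:, None], 0.0)
    return GelImage(out)
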