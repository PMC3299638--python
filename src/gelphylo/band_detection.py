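"""Band detection within a lane from the smoothed row-sum profile.

A band is a DNA fragment resolved at some depth in its lane. Summing the
lane's pixel columns row by row (on the background-subtracted image) gives
a profile in which every band is a peak. The profile is smoothed with a
moving-average filter to suppress false peaks from noise, and peaks of the
filtered profile above ``threshold_factor * lane_width`` become bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import BoundsError, NotFoundError
from .gel_image import GelImage
from .lane_detection import Lane, Profile


@dataclass(frozen=True)
class Band:
    """A band at ``migration_distance`` pixel rows below the image top.

    ``weight`` is filled in by the molecular-weight calibration step;
    ``peak_intensity`` is the filtered profile value at the peak and is
    reported but never used for matching.
    """

    lane_id: int
    migration_distance: int
    peak_intensity: float = 0.0
    weight: Optional[float] = None


@dataclass(frozen=True)
class BandDetectionParams:
    """Detection knobs.

    ``threshold_factor`` multiplies the lane width to give the intensity
    threshold on the summed profile (default 20). ``filter_width`` is the
    half-width of the moving-average window (window size 2*width + 1);
    ``filter_passes`` is how many times the filter is applied. Larger
    images warrant larger values of both.
    """

    threshold_factor: float = 20.0
    filter_width: int = 2
    filter_passes: int = 1

    def __post_init__(self):
        if self.threshold_factor < 0 or self.filter_width < 0 or self.filter_passes < 0:
            raise ValueError("band detection parameters must be non-negative")


def lane_profile(img: GelImage, lane: Lane) -> Profile:
    """Row-wise sum of the lane's pixel columns (one value per image row)."""
    if lane.col_end > img.width:
        raise BoundsError(f"lane [{lane.col_start},{lane.col_end}) exceeds image width {img.width}")
    return Profile(img.pixels[:, lane.col_start:lane.col_end].sum(axis=1), axis="rows")


def moving_average(x: Profile | np.ndarray, width: int, passes: int = 1):
    """Centered moving average xF[i] = 1/(2*width+1) * sum_{k=i-width}^{i+width} x[k].

    Applied ``passes`` times. Out-of-range samples are edge-replicated, so a
    constant profile maps to itself exactly (including at the boundaries);
    width 0 or passes 0 is the identity.
    """
    if width < 0 or passes < 0:
        raise ValueError("width and passes must be non-negative")
    values = x.values if isinstance(x, Profile) else np.asarray(x, dtype=float)
    out = values.astype(float, copy=True)
    if width > 0:
        for _ in range(passes):
            out = uniform_filter1d(out, size=2 * width + 1, mode="nearest")
    if isinstance(x, Profile):
        return Profile(out, axis=x.axis)
    return out


def _plateau_peaks(f: np.ndarray) -> list[int]:
    """Row indices of strict local maxima; plateaus collapse to their center."""
    n = len(f)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and f[j + 1] == f[i]:
            j += 1
        left = f[i - 1] if i > 0 else -np.inf
        right = f[j + 1] if j + 1 < n else -np.inf
        if f[i] > left and f[i] > right:
            peaks.append((i + j) // 2)
        i = j + 1
    return peaks


def detect_bands(profile: Profile, lane: Lane,
                 params: BandDetectionParams = BandDetectionParams()) -> list[Band]:
    """Detect bands as peaks of the filtered lane profile.

    The profile is smoothed with ``moving_average`` and every local maximum
    of the filtered profile with value >= threshold_factor * lane.width
    becomes a band; plateau maxima collapse to their center row.
    """
    f = moving_average(profile.values, params.filter_width, params.filter_passes)
    threshold = params.threshold_factor * lane.width
    return [Band(lane_id=lane.id, migration_distance=r, peak_intensity=float(f[r]))
            for r in _plateau_peaks(f) if f[r] >= threshold]


def _sorted_bands(bands: list[Band]) -> list[Band]:
    return sorted(bands, key=lambda b: (b.lane_id, b.migration_distance))


def add_band(bands: list[Band], lane_id: int, row: int,
             peak_intensity: float = 0.0) -> list[Band]:
    """Manually add a band at ``row`` in lane ``lane_id``."""
    if row < 0:
        raise BoundsError(f"row {row} is negative")
    new = Band(lane_id=lane_id, migration_distance=row, peak_intensity=peak_intensity)
    return _sorted_bands(list(bands) + [new])


def remove_band(bands: list[Band], lane_id: int, row: int) -> list[Band]:
    """Remove the band nearest ``row`` (within +/-2 rows) in lane ``lane_id``."""
    in_lane = [b for b in bands if b.lane_id == lane_id
               and abs(b.migration_distance - row) <= 2]
    if not in_lane:
        raise NotFoundError(f"no band within 2 rows of row {row} in lane {lane_id}")
    victim = min(in_lane, key=lambda b: abs(b.migration_distance - row))
    remaining = list(bands)
    remaining.remove(victim)
    return _sorted_bands(remaining)
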