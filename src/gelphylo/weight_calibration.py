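"""Molecular-weight calibration against a marker (ladder) lane.

Electrophoretic migration of DNA fragments follows a log-linear law over
the useful range of a gel:

    ln(weight) = alpha * migration_distance + beta,   alpha < 0, beta > 0

alpha is negative because heavier fragments travel less; beta absorbs the
offset from the image top to the wells. Fitting ln(weight) against the
detected migration distances of a marker lane with known fragment sizes
yields (alpha, beta), from which the weight of every other band follows.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .band_detection import Band
from .errors import FormatError, PairingError, SingularFitError

MARKER_EXTENSION = ".marker"


@dataclass(frozen=True)
class MarkerStandard:
    """A named ladder: fragment weights (e.g. in bp) in strictly decreasing order."""

    name: str
    weights: tuple[float, ...]

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if len(w) < 2:
            raise FormatError("a marker standard needs at least 2 weights")
        if any(x <= 0 for x in w):
            raise FormatError("marker weights must be positive")
        if any(earlier <= later for earlier, later in zip(w, w[1:])):
            raise FormatError("marker weights must be strictly decreasing")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted migration model: ln(weight) = alpha * distance + beta."""

    alpha: float
    beta: float


def read_marker(path: str | os.PathLike) -> MarkerStandard:
    """Read a ``.marker`` text file: name, band count, then one weight per line."""
    path = os.fspath(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"marker file '{path}' is truncated")
    name = lines[0]
    try:
        count = int(lines[1])
        weights = [float(x) for x in lines[2:]]
    except ValueError as exc:
        raise FormatError(f"marker file '{path}' is malformed: {exc}") from exc
    if len(weights) != count:
        raise FormatError(
            f"marker file '{path}' declares {count} bands but lists {len(weights)} weights")
    return MarkerStandard(name=name, weights=tuple(weights))


def write_marker(std: MarkerStandard, path: str | os.PathLike) -> None:
    """Write a standard in the ``.marker`` text format (round-trips with read)."""
    with open(os.fspath(path), "w") as fh:
        fh.write(f"{std.name}\n{len(std)}\n")
        for w in std.weights:
            fh.write(f"{w:g}\n")


def fit_migration_model(distances, std: MarkerStandard) -> CalibrationModel:
    """Least-squares fit of ln(weight) on migration distance.

    Pairing is positional: the i-th shallowest marker band is matched to the
    i-th largest weight. A marker whose detected band count differs from the
    standard fails loudly rather than guessing a sub-assignment. Warns (does
    not fail) if the fitted signs violate alpha < 0 or beta <= 0, which can
    happen on noisy user data.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or len(d) != len(std):
        raise PairingError(
            f"{len(d)} marker bands cannot be paired with the "
            f"{len(std)}-weight standard '{std.name}'")
    if np.ptp(d) == 0:
        raise SingularFitError("all marker migration distances are equal")
    alpha, beta = np.polyfit(d, np.log(std.weights), 1)
    if alpha >= 0:
        warnings.warn(f"fitted slope alpha = {alpha:.4g} is not negative; "
                      "check marker lane orientation", stacklevel=2)
    if beta <= 0:
        warnings.warn(f"fitted intercept beta = {beta:.4g} is not positive", stacklevel=2)
    return CalibrationModel(alpha=float(alpha), beta=float(beta))


def predict_weight(model: CalibrationModel, distance: float) -> float:
    """Weight of a fragment at the given migration distance: exp(alpha*d + beta)."""
    return float(np.exp(model.alpha * distance + model.beta))


def assign_weights(bands: list[Band], model: CalibrationModel) -> list[Band]:
    """Fill every band's ``weight`` from the fitted model; other fields untouched."""
    return [replace(b, weight=predict_weight(model, b.migration_distance)) for b in bands]
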