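"""Band matching across lanes, the presence/absence matrix, and Dice similarity.

Bands from different lanes that migrated (almost) the same distance are the
same fragment class. The matcher partitions all bands into clusters under
two hard constraints: no two members share a lane, and no two members are
further apart than a tolerance (default 2% of the image height). Clusters
become rows of a binary presence/absence matrix (columns = lanes), the DNA
fingerprint, from which pairwise Dice similarity and genetic distance are
computed:

    Dice(S_i, S_j) = 100 * 2 * c_ij / (n_i + n_j)   [percent]
    D = 100 * ones - S
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .band_detection import Band
from .errors import MatrixError


@dataclass(frozen=True)
class MatchingParams:
    """``tol_frac``: matching tolerance as a fraction of the image height."""

    tol_frac: float = 0.02

    def __post_init__(self):
        if not 0 < self.tol_frac < 1:
            raise ValueError("tol_frac must be in (0, 1)")


@dataclass(frozen=True)
class BandCluster:
    """One matched band class: at most one member per lane, all within tolerance."""

    id: int
    members: tuple[Band, ...]

    @property
    def mean_distance(self) -> float:
        return float(np.mean([b.migration_distance for b in self.members]))

    @property
    def lanes(self) -> frozenset[int]:
        return frozenset(b.lane_id for b in self.members)


@dataclass(frozen=True)
class BinaryBandMatrix:
    """Presence/absence matrix: rows = clusters (by increasing mean migration
    distance), columns = lanes; cell (k, l) = 1 iff cluster k has a band in lane l."""

    cells: np.ndarray
    mean_distances: tuple[float, ...]  # row labels: mean migration distance per cluster

    def __post_init__(self):
        c = np.asarray(self.cells, dtype=int)
        if c.ndim != 2:
            raise MatrixError("presence matrix must be 2-D")
        if c.size and not np.isin(c, (0, 1)).all():
            raise MatrixError("presence matrix cells must be 0 or 1")
        if c.shape[0] != len(self.mean_distances):
            raise MatrixError("one mean distance per cluster row required")
        object.__setattr__(self, "cells", c)

    @property
    def n_clusters(self) -> int:
        return self.cells.shape[0]

    @property
    def n_lanes(self) -> int:
        return self.cells.shape[1]


def match_bands(bands: list[Band], image_height: int,
                params: MatchingParams = MatchingParams()) -> list[BandCluster]:
    """Greedy single-pass band matching.

    Bands are sorted by (migration_distance, lane_id) and swept in order;
    each band joins the open cluster if its lane is new to the cluster and
    its distance to the cluster's shallowest member is below
    ``tol_frac * image_height``, otherwise the cluster is closed and a new
    one opened. Both constraints are hard; the result is a partition.
    """
    tol = params.tol_frac * image_height
    ordered = sorted(bands, key=lambda b: (b.migration_distance, b.lane_id))
    clusters: list[list[Band]] = []
    for band in ordered:
        if clusters:
            current = clusters[-1]
            fits = (band.lane_id not in {m.lane_id for m in current}
                    and band.migration_distance - current[0].migration_distance < tol)
            if fits:
                current.append(band)
                continue
        clusters.append([band])
    return [BandCluster(id=i, members=tuple(members))
            for i, members in enumerate(clusters)]


def clustering_matrix(clusters: list[BandCluster], n_lanes: int) -> BinaryBandMatrix:
    """Build the presence/absence matrix from clusters, rows sorted by depth."""
    ordered = sorted(clusters, key=lambda c: c.mean_distance)
    cells = np.zeros((len(ordered), n_lanes), dtype=int)
    for k, cluster in enumerate(ordered):
        for band in cluster.members:
            if band.lane_id >= n_lanes:
                raise MatrixError(f"band references lane {band.lane_id} >= n_lanes {n_lanes}")
            cells[k, band.lane_id] = 1
    return BinaryBandMatrix(cells=cells,
                            mean_distances=tuple(c.mean_distance for c in ordered))


def dice_similarity(matrix: BinaryBandMatrix) -> np.ndarray:
    """Pairwise Dice similarity between lane fingerprints, in percent.

    S(i, j) = 100 * 2 * c_ij / (n_i + n_j), with c_ij the number of band
    classes present in both lanes and n_i the band count of lane i.
    """
    cells = matrix.cells
    counts = cells.sum(axis=0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise MatrixError(f"similarity undefined: lane(s) {empty.tolist()} have no bands")
    common = cells.T @ cells
    return 100.0 * 2.0 * common / (counts[:, None] + counts[None, :])


def distance_from_similarity(similarity: np.ndarray) -> np.ndarray:
    """Genetic distance matrix D = 100 * ones - S (percent scale)."""
    return 100.0 - np.asarray(similarity, dtype=float)
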