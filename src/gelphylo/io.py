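"""Text-file interchange: lanes/bands TSV, presence-matrix TSV, Phylip matrices.

Every intermediate of the pipeline is a small plain-text table so that users
can inspect or hand-edit it between stages and feed it back in, which
replaces the interactive adjustments a GUI would offer.
"""

from __future__ import annotations

import csv
import os

import numpy as np

from .band_detection import Band
from .band_matching import BinaryBandMatrix
from .errors import FormatError, MatrixError
from .lane_detection import Lane


def write_lanes_tsv(lanes: list[Lane], path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "col_start", "col_end"])
        for ln in lanes:
            writer.writerow([ln.id, ln.col_start, ln.col_end])


def read_lanes_tsv(path: str | os.PathLike) -> list[Lane]:
    lanes = []
    with open(os.fspath(path), newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        try:
            for row in reader:
                lanes.append(Lane(id=int(row["id"]), col_start=int(row["col_start"]),
                                  col_end=int(row["col_end"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed lanes TSV '{path}': {exc}") from exc
    return sorted(lanes, key=lambda ln: ln.col_start)


def write_bands_tsv(bands: list[Band], path: str | os.PathLike) -> None:
    """Columns: lane_id, migration_distance, peak_intensity[, weight if any set]."""
    with_weights = any(b.weight is not None for b in bands)
    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["lane_id", "migration_distance", "peak_intensity"]
        if with_weights:
            header.append("weight")
        writer.writerow(header)
        for b in bands:
            row = [b.lane_id, b.migration_distance, f"{b.peak_intensity:.6g}"]
            if with_weights:
                row.append("" if b.weight is None else f"{b.weight:.6g}")
            writer.writerow(row)


def read_bands_tsv(path: str | os.PathLike) -> list[Band]:
    bands = []
    with open(os.fspath(path), newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        try:
            for row in reader:
                weight = row.get("weight")
                bands.append(Band(
                    lane_id=int(row["lane_id"]),
                    migration_distance=int(row["migration_distance"]),
                    peak_intensity=float(row.get("peak_intensity") or 0.0),
                    weight=float(weight) if weight else None))
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed bands TSV '{path}': {exc}") from exc
    return sorted(bands, key=lambda b: (b.lane_id, b.migration_distance))


def write_matrix_tsv(matrix: BinaryBandMatrix, path: str | os.PathLike,
                     lane_labels: list[str] | None = None,
                     symbols: str = "10") -> None:
    """Presence/absence matrix as TSV; rows labeled by mean migration distance.

    ``symbols``: "10" writes 1/0, "+-" writes +/-.
    """
    if symbols not in ("10", "+-"):
        raise ValueError("symbols must be '10' or '+-'")
    present, absent = symbols[0], symbols[1]
    labels = lane_labels or [f"lane{k}" for k in range(matrix.n_lanes)]
    if len(labels) != matrix.n_lanes:
        raise MatrixError(f"{len(labels)} labels for {matrix.n_lanes} lanes")
    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mean_distance"] + labels)
        for k in range(matrix.n_clusters):
            cells = [present if v else absent for v in matrix.cells[k]]
            writer.writerow([f"{matrix.mean_distances[k]:.2f}"] + cells)


def read_matrix_tsv(path: str | os.PathLike) -> tuple[BinaryBandMatrix, list[str]]:
    with open(os.fspath(path), newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
            labels = header[1:]
            rows, dists = [], []
            for row in reader:
                dists.append(float(row[0]))
                rows.append([1 if v in ("1", "+") else 0 for v in row[1:]])
        except (StopIteration, IndexError, ValueError) as exc:
            raise FormatError(f"malformed matrix TSV '{path}': {exc}") from exc
    cells = np.array(rows, dtype=int).reshape(len(rows), len(labels))
    return BinaryBandMatrix(cells=cells, mean_distances=tuple(dists)), labels


def write_phylip(D: np.ndarray, labels: list[str], path: str | os.PathLike) -> None:
    """Square Phylip distance matrix: taxon count, then one padded-name row each."""
    D = np.asarray(D, dtype=float)
    if D.shape != (len(labels), len(labels)):
        raise MatrixError(f"matrix shape {D.shape} does not match {len(labels)} labels")
    with open(os.fspath(path), "w") as fh:
        fh.write(f"{len(labels)}\n")
        for name, row in zip(labels, D):
            padded = f"{name[:10]:<10}"
            fh.write(padded + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Read a square Phylip distance matrix (names may contain no whitespace)."""
    with open(os.fspath(path)) as fh:
        tokens_per_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_per_line:
        raise FormatError(f"empty Phylip file '{path}'")
    try:
        n = int(tokens_per_line[0][0])
    except ValueError as exc:
        raise FormatError(f"Phylip file '{path}' must start with the taxon count") from exc
    if len(tokens_per_line) != n + 1:
        raise FormatError(f"Phylip file '{path}' declares {n} taxa but has "
                          f"{len(tokens_per_line) - 1} data rows")
    labels, rows = [], []
    for tokens in tokens_per_line[1:]:
        if len(tokens) != n + 1:
            raise FormatError(f"Phylip row for '{tokens[0]}' has {len(tokens) - 1} "
                              f"values, expected {n}")
        labels.append(tokens[0])
        rows.append([float(v) for v in tokens[1:]])
    return np.array(rows, dtype=float), labels
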