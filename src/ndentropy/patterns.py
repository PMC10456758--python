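"""Synthetic 2-D configurations with known degrees of order.

These generators provide calibration and comparison fixtures: hexagonal
lattices (the H_NDist = 0 reference), jittered lattices, uniform gas and
Gaussian-cluster stand-ins for dispersed versus aggregated steady states, and
letter-masked close packings emulating swarm-robot shape assemblies.  All
generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import entropy_by_neighbor_distance
from .errors import ConfigurationError, GeometryError
from .glyphs import GLYPHS
from .neighbors import PointSet, minimum_image

_ROW_HEIGHT = np.sqrt(3.0) / 2.0  # triangular-lattice row spacing, in units of a


def hexagonal_lattice(nx: int, ny: int, spacing: float = 1.0) -> PointSet:
    """Triangular (hexagonally packed) lattice in a commensurate periodic box.

    ``nx`` columns and ``ny`` rows; all nearest-neighbor distances equal
    ``spacing``.  ``ny`` must be even so the alternating row offset wraps
    periodically.
    """
    if nx < 2 or ny < 2:
        raise ConfigurationError("nx and ny must be >= 2")
    if spacing <= 0:
        raise ConfigurationError("spacing must be positive")
    if ny % 2 != 0:
        raise GeometryError(
            f"ny = {ny} is incommensurate with a periodic triangular lattice; "
            "use an even row count"
        )
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    x = (cols + 0.5 * (rows % 2)) * spacing
    y = rows * (_ROW_HEIGHT * spacing)
    coords = np.column_stack([x.ravel(), y.ravel()])
    box = (nx * spacing, ny * _ROW_HEIGHT * spacing)
    return PointSet(coords=coords, boundary="periodic", box=box)


def jittered_lattice(lattice: PointSet, amplitude: float, seed: int = 0) -> PointSet:
    """Displace every site by independent uniform noise in [-amplitude, amplitude]^2."""
    if amplitude < 0:
        raise ConfigurationError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    coords = lattice.coords + rng.uniform(-amplitude, amplitude, size=lattice.coords.shape)
    return PointSet(coords=coords, boundary=lattice.boundary, box=lattice.box)


def uniform_gas(n: int, box: tuple[float, float] = (1000.0, 1000.0), seed: int = 0) -> PointSet:
    """Uniform-random points in a periodic box: the dispersed (gas) stand-in."""
    if n < 3:
        raise ConfigurationError("n must be >= 3")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n, 2)) * np.asarray(box, dtype=float)
    return PointSet(coords=coords, boundary="periodic", box=box)


def gaussian_clusters(
    k: int,
    n_per_cluster: int,
    sigma: float,
    box: tuple[float, float] = (1000.0, 1000.0),
    seed: int = 0,
) -> PointSet:
    """k isotropic Gaussian blobs: the aggregated (clustered) stand-in.

    Cluster centers are resampled until pairwise minimum-image separations are
    at least 6 sigma, so clusters do not overlap.
    """
    if k < 1 or n_per_cluster < 1:
        raise ConfigurationError("k and n_per_cluster must be >= 1")
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    for _ in range(10_000):
        centers = rng.uniform(0.0, 1.0, size=(k, 2)) * box_arr
        if k == 1:
            break
        ii, jj = np.triu_indices(k, k=1)
        sep = np.linalg.norm(minimum_image(centers[jj] - centers[ii], box), axis=1)
        if np.all(sep >= 6.0 * sigma):
            break
    else:
        raise ConfigurationError(
            "could not place cluster centers at least 6*sigma apart; "
            "reduce k or sigma"
        )
    coords = np.repeat(centers, n_per_cluster, axis=0) + rng.normal(
        0.0, sigma, size=(k * n_per_cluster, 2)
    )
    return PointSet(coords=coords, boundary="periodic", box=box)


def gas_series(
    n_frames: int,
    n: int = 500,
    box: tuple[float, float] = (1000.0, 1000.0),
    seed: int = 0,
) -> list[PointSet]:
    """Frames of a dispersed (gas) steady state.

    A gas of active particles decorrelates between observation frames, so each
    frame is an independent uniform draw.
    """
    return [uniform_gas(n, box, seed=seed + 1 + f) for f in range(n_frames)]


def aggregated_series(
    n_frames: int,
    k: int = 5,
    n_per_cluster: int = 100,
    sigma: float = 10.0,
    box: tuple[float, float] = (1000.0, 1000.0),
    seed: int = 0,
    rattle: float | None = None,
) -> list[PointSet]:
    """Frames of an aggregated (clustered) steady state.

    The cluster structure persists across frames; members are caged and only
    rattle about their positions, by default with amplitude sigma / 10.
    """
    if rattle is None:
        rattle = sigma / 10.0
    base = gaussian_clusters(k, n_per_cluster, sigma, box, seed=seed)
    return [jittered_lattice(base, rattle, seed=seed + 1 + f) for f in range(n_frames)]


@dataclass(frozen=True)
class LetterMask:
    """A binary glyph bitmap used to carve a letter out of a dense packing.

    ``scale`` is the linear size of one bitmap cell in lattice spacings, so
    larger scales retain more packing sites per glyph cell.
    """

    letter: str
    bitmap: np.ndarray  # (rows, cols) bool, top row first
    scale: float = 3.0

    def __post_init__(self) -> None:
        bitmap = np.asarray(self.bitmap, dtype=bool)
        if bitmap.ndim != 2 or not bitmap.any():
            raise ConfigurationError("bitmap must be a non-empty 2-D binary grid")
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")
        object.__setattr__(self, "bitmap", bitmap)


def letter_mask(letter: str, scale: float = 3.0) -> LetterMask:
    """Look up the repo's fixed 5x7 glyph for an uppercase letter."""
    letter = letter.upper()
    if letter not in GLYPHS:
        raise ConfigurationError(f"no glyph defined for {letter!r}")
    bitmap = np.array([[c == "#" for c in row] for row in GLYPHS[letter]])
    return LetterMask(letter=letter, bitmap=bitmap, scale=scale)


def letter_configuration(mask: LetterMask, spacing: float = 1.0) -> PointSet:
    """Hexagonally close-packed sites retained where the glyph bitmap is on.

    The packing covers the glyph's bounding box; a site survives iff the
    bitmap cell containing it is filled.  Open boundary (shapes are finite);
    deterministic.
    """
    if spacing <= 0:
        raise ConfigurationError("spacing must be positive")
    n_rows, n_cols = mask.bitmap.shape
    cell = mask.scale * spacing
    width, height = n_cols * cell, n_rows * cell

    n_lat_rows = int(np.floor(height / (_ROW_HEIGHT * spacing))) + 1
    n_lat_cols = int(np.floor(width / spacing)) + 1
    cols, rows = np.meshgrid(np.arange(n_lat_cols), np.arange(n_lat_rows))
    x = (cols + 0.5 * (rows % 2)) * spacing
    y = rows * (_ROW_HEIGHT * spacing)
    coords = np.column_stack([x.ravel(), y.ravel()])
    inside = (coords[:, 0] < width) & (coords[:, 1] < height)
    coords = coords[inside]

    cell_col = np.floor(coords[:, 0] / cell).astype(int)
    cell_row = (n_rows - 1) - np.floor(coords[:, 1] / cell).astype(int)  # y up, row 0 on top
    keep = mask.bitmap[cell_row, cell_col]
    coords = coords[keep]
    if coords.shape[0] < 3:
        raise GeometryError(
            f"mask for {mask.letter!r} retains {coords.shape[0]} sites (< 3); "
            "increase scale or reduce spacing"
        )
    return PointSet(coords=coords, boundary="open")


def letter_entropies(
    spacing: float = 10.0,
    bin_size: float | None = None,
    scale: float = 3.0,
) -> pd.DataFrame:
    """H_NDist of all 26 letter configurations (open boundary, Voronoi).

    Default bin size is spacing/10, i.e. well below the particle scale.
    """
    if bin_size is None:
        bin_size = spacing / 10.0
    rows = []
    for letter in sorted(GLYPHS):
        points = letter_configuration(letter_mask(letter, scale=scale), spacing=spacing)
        res = entropy_by_neighbor_distance(points, bin_size=bin_size, neighbor_mode="voronoi")
        rows.append(
            {
                "letter": letter,
                "n_sites": points.n,
                "bin_size": res.bin_size,
                "h_ndist": res.h_ndist,
                "h_norm": res.h_norm,
                "occupied_bins": res.occupied_bins,
                "n_samples": res.n_samples,
            }
        )
    return pd.DataFrame(rows)
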