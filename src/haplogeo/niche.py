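"""Climatic-niche comparison on gridded environmental data.

Variable filtering by pairwise correlation, transparent suitability models
(Gaussian envelope and BIOCLIM-style percentile envelope), AUC model
evaluation against random background, Schoener's D and the Hellinger-based I
overlap metrics on normalised suitability surfaces, and the pooled-
pseudoreplicate niche identity test.

Rasters are plain-text ESRI ASCII grids; any externally produced suitability
raster on the same grid (e.g. a MaxEnt output) can be fed straight into the
overlap machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EnvStack",
    "OccurrenceSet",
    "SuitabilityRaster",
    "NicheOverlap",
    "PAPER_RETAINED_VARIABLES",
    "filter_variables",
    "fit_suitability",
    "evaluate_auc",
    "niche_overlap",
    "identity_test",
    "read_ascii_grid",
    "write_ascii_grid",
]

# the retained seven-variable preset for WORLDCLIM bioclim stacks
PAPER_RETAINED_VARIABLES = ("BIO_1", "BIO_2", "BIO_3", "BIO_4", "BIO_12", "BIO_15", "BIO_19")


@dataclass(frozen=True)
class GridSpec:
    """North-west-origin grid: cell (0,0) is the NW corner."""

    x_origin: float  # west edge longitude
    y_origin: float  # north edge latitude
    cell_size: float
    nrows: int
    ncols: int

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        col = int(np.floor((lon - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - lat) / self.cell_size))
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin - (row + 0.5) * self.cell_size
        return lon, lat


@dataclass
class EnvStack:
    """Co-registered named environmental layers with a shared validity mask."""

    layers: dict[str, np.ndarray]
    mask: np.ndarray  # True = valid cell
    grid: GridSpec

    def __post_init__(self) -> None:
        shape = (self.grid.nrows, self.grid.ncols)
        if self.mask.shape != shape:
            raise ValueError("mask shape does not match grid")
        for name, arr in self.layers.items():
            if arr.shape != shape:
                raise ValueError(f"layer {name} shape does not match grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def values_at_cells(self, cells: np.ndarray) -> np.ndarray:
        """n_cells x n_layers matrix of values at (row, col) pairs."""
        rows, cols = cells[:, 0], cells[:, 1]
        return np.column_stack([self.layers[v][rows, cols] for v in self.names])

    def valid_matrix(self) -> np.ndarray:
        """n_valid x n_layers matrix over the mask."""
        return np.column_stack([self.layers[v][self.mask] for v in self.names])

    def select(self, names: list[str]) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names}, self.mask, self.grid)


@dataclass(frozen=True)
class OccurrenceSet:
    """Presence points for one species, snapped to grid cells."""

    species: str
    points: np.ndarray  # n x 2 (lon, lat)
    cells: np.ndarray  # n x 2 (row, col), deduplicated if requested
    deduplicated: bool

    @property
    def n(self) -> int:
        return len(self.cells)

    @classmethod
    def from_points(
        cls, species: str, lonlat: np.ndarray, stack: EnvStack, deduplicate: bool = True
    ) -> "OccurrenceSet":
        lonlat = np.asarray(lonlat, dtype=float)
        cells = []
        kept = []
        seen = set()
        for lon, lat in lonlat:
            r, c = stack.grid.cell_of(lon, lat)
            if not (0 <= r < stack.grid.nrows and 0 <= c < stack.grid.ncols):
                continue
            if not stack.mask[r, c]:
                continue
            if deduplicate and (r, c) in seen:
                continue
            seen.add((r, c))
            cells.append((r, c))
            kept.append((lon, lat))
        return cls(species, np.array(kept), np.array(cells, dtype=int), deduplicate)


@dataclass
class SuitabilityRaster:
    """Per-cell habitat suitability in [0, 1] on an EnvStack grid."""

    values: np.ndarray
    mask: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        v = self.values[self.mask]
        if v.size and (v.min() < 0 or v.max() > 1.0 + 1e-9):
            raise ValueError("suitability outside [0, 1]")

    def normalised(self) -> np.ndarray:
        v = np.where(self.mask, self.values, 0.0)
        total = v.sum()
        if total <= 0:
            raise ValueError("all-zero suitability surface")
        return v / total


@dataclass(frozen=True)
class NicheOverlap:
    D: float
    I: float
    null_D: np.ndarray
    null_I: np.ndarray
    p_D: float
    p_I: float
    n_replicates: int
    seed: int | None


# ---------------------------------------------------------------------------
# ASCII grid IO (plain-text rasters)


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec, nodata: float = -9999.0) -> None:
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
        f"xllcorner {grid.x_origin}\nyllcorner {grid.y_origin - grid.nrows * grid.cell_size}\n"
        f"cellsize {grid.cell_size}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    grid = GridSpec(
        header["xllcorner"], header["yllcorner"] + nrows * cell, cell, nrows, ncols
    )
    nodata = header.get("nodata_value", -9999.0)
    values = values.reshape(nrows, ncols)
    values = np.where(values == nodata, np.nan, values)
    return values, grid, nodata


# ---------------------------------------------------------------------------
# operations


def filter_variables(stack: EnvStack, r_max: float = 0.70) -> tuple[EnvStack, list[tuple[str, str, float]]]:
    """Greedy collinearity filter in layer order.

    A layer is dropped when its |Pearson r| over valid cells with any
    already-retained layer exceeds ``r_max``.  Returns the reduced stack and a
    log of (dropped, retained_partner, r) pairs.
    """
    if len(stack.names) < 2:
        raise ValueError("need >=2 layers")
    X = stack.valid_matrix()
    names = stack.names
    retained: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for i, name in enumerate(names):
        xi = X[:, i]
        if np.std(xi) == 0:
            warnings.warn(f"layer {name} is constant; correlation undefined, retained")
            retained.append(i)
            continue
        clash = None
        for j in retained:
            if np.std(X[:, j]) == 0:
                continue
            r = float(np.corrcoef(xi, X[:, j])[0, 1])
            if abs(r) > r_max:
                clash = (name, names[j], r)
                break
        if clash is None:
            retained.append(i)
        else:
            dropped.append(clash)
    return stack.select([names[i] for i in retained]), dropped


def fit_suitability(
    occ: OccurrenceSet, stack: EnvStack, model: str = "gaussian_envelope"
) -> SuitabilityRaster:
    """Fit a transparent suitability model to presence climate values.

    gaussian_envelope: product of per-variable Gaussian kernels at the
    presence mean/SD, rescaled to max 1 over valid cells.
    bioclim_percentile: per-variable percentile-envelope score
    (1 - 2|F(v) - 0.5|, the classic BIOCLIM score), combined by minimum.
    """
    if occ.n < 10:
        raise ValueError("need >=10 presence cells after deduplication")
    P = stack.values_at_cells(occ.cells)  # presences x variables
    shape = (stack.grid.nrows, stack.grid.ncols)
    out = np.zeros(shape)
    Xv = stack.valid_matrix()
    if model == "gaussian_envelope":
        mean = P.mean(axis=0)
        sd = P.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1e-12)
        z2 = ((Xv - mean) / sd) ** 2
        score = np.exp(-0.5 * z2.sum(axis=1))
        score = score / score.max() if score.max() > 0 else score
    elif model == "bioclim_percentile":
        score = np.ones(Xv.shape[0])
        for v in range(P.shape[1]):
            col = np.sort(P[:, v])
            ranks = np.searchsorted(col, Xv[:, v], side="right") / len(col)
            score = np.minimum(score, 1 - 2 * np.abs(ranks - 0.5))
        score = np.clip(score, 0, 1)
    else:
        raise ValueError(f"unknown model: {model}")
    out[stack.mask] = score
    return SuitabilityRaster(out, stack.mask, stack.grid)


def evaluate_auc(
    occ: OccurrenceSet,
    stack: EnvStack,
    model: str = "gaussian_envelope",
    train_frac: float = 0.8,
    n_background: int = 10_000,
    seed: int | None = None,
) -> float:
    """AUC of a train/test split against random background cells.

    The model is fitted on a random ``train_frac`` share of presences and the
    AUC is the Mann-Whitney probability that a held-out presence outscores a
    random valid background cell (ties count half).
    """
    if n_background <= 0:
        raise ValueError("n_background must be positive")
    rng = np.random.default_rng(seed)
    n = occ.n
    n_train = int(round(train_frac * n))
    if n_train >= n:
        raise ValueError("empty test split; lower train_frac")
    perm = rng.permutation(n)
    train_cells = occ.cells[perm[:n_train]]
    test_cells = occ.cells[perm[n_train:]]
    train = OccurrenceSet(occ.species, occ.points[perm[:n_train]], train_cells, occ.deduplicated)
    sr = fit_suitability(train, stack, model=model)

    valid_cells = np.argwhere(stack.mask)
    bg_idx = rng.integers(len(valid_cells), size=n_background)
    bg_cells = valid_cells[bg_idx]
    pres_scores = sr.values[test_cells[:, 0], test_cells[:, 1]]
    bg_scores = sr.values[bg_cells[:, 0], bg_cells[:, 1]]
    # Mann-Whitney AUC with half-weight ties
    greater = (pres_scores[:, None] > bg_scores[None, :]).sum()
    equal = (pres_scores[:, None] == bg_scores[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pres_scores) * len(bg_scores)))


def niche_overlap(s1: SuitabilityRaster, s2: SuitabilityRaster) -> tuple[float, float]:
    """Schoener's D and Hellinger-based I between two suitability surfaces.

    Surfaces are normalised to probability distributions p, q over valid
    cells; D = 1 - 0.5 sum|p - q|, I = 1 - 0.5 sum(sqrt(p) - sqrt(q))^2.
    Both range from 0 (no overlap) to 1 (identical niches).
    """
    if s1.values.shape != s2.values.shape or not np.array_equal(s1.mask, s2.mask):
        raise ValueError("surfaces must share grid and mask")
    p = s1.normalised()[s1.mask]
    q = s2.normalised()[s2.mask]
    D = 1 - 0.5 * float(np.abs(p - q).sum())
    I = 1 - 0.5 * float(((np.sqrt(p) - np.sqrt(q)) ** 2).sum())
    return D, I


def identity_test(
    occ1: OccurrenceSet,
    occ2: OccurrenceSet,
    stack: EnvStack,
    model: str = "gaussian_envelope",
    n_reps: int = 100,
    seed: int | None = None,
) -> NicheOverlap:
    """Niche identity test by pooled pseudoreplication.

    The observed D and I come from the two fitted surfaces.  The null pools
    both species' presences, randomly repartitions them into the original
    sample sizes, refits both models and recomputes D and I, ``n_reps``
    times.  One-tailed p = (1 + #{null <= observed}) / (n_reps + 1): niche
    difference shows up as observed overlap below the null.

    The pooled points are canonically sorted and the partition always drawn
    as (smaller size, rest), so swapping the two species with the same seed
    yields the identical null distribution.
    """
    if n_reps < 10:
        warnings.warn("fewer than 10 identity-test replicates: p is very coarse")
    s1 = fit_suitability(occ1, stack, model=model)
    s2 = fit_suitability(occ2, stack, model=model)
    D_obs, I_obs = niche_overlap(s1, s2)

    pooled = np.vstack([occ1.cells, occ2.cells])
    order = np.lexsort((pooled[:, 1], pooled[:, 0]))
    pooled = pooled[order]
    n_small = min(occ1.n, occ2.n)
    rng = np.random.default_rng(seed)
    null_D = np.empty(n_reps)
    null_I = np.empty(n_reps)
    for b in range(n_reps):
        perm = rng.permutation(len(pooled))
        a_cells = pooled[perm[:n_small]]
        b_cells = pooled[perm[n_small:]]
        oa = OccurrenceSet("nullA", np.empty((len(a_cells), 2)), a_cells, True)
        ob = OccurrenceSet("nullB", np.empty((len(b_cells), 2)), b_cells, True)
        sa = fit_suitability(oa, stack, model=model)
        sb = fit_suitability(ob, stack, model=model)
        null_D[b], null_I[b] = niche_overlap(sa, sb)
    p_D = float((1 + np.sum(null_D <= D_obs)) / (n_reps + 1))
    p_I = float((1 + np.sum(null_I <= I_obs)) / (n_reps + 1))
    return NicheOverlap(D_obs, I_obs, null_D, null_I, p_D, p_I, n_reps, seed)
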