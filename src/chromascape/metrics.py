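"""Per-color spatial structure metrics for binary masks.

Three metrics characterise how a color occupies a scene:

* **Fractal dimension D** — box-counting slope of ``log N(eps)`` against
  ``log(1/eps)``, where ``N(eps)`` is the number of eps-sized grid boxes
  containing at least one foreground pixel.  D approaches 2 for
  space-filling patterns and 1 for curve-like patterns.
* **Diversity H'** — Shannon–Wiener entropy.  Globally it is computed on
  the six-category area proportions; per color it measures the spatial
  evenness of that color over a coarse block partition of the frame.
* **Concentration C** — Moran's I spatial autocorrelation of the color's
  presence on a coarsened lattice: near +1 when the color forms compact
  clusters, near -1 when it alternates like a checkerboard.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np

from .palette import COLOR_NAMES, ColorMaskSet

__all__ = [
    "DEFAULT_SCALES",
    "BoxCountCurve",
    "FractalFit",
    "PresenceLattice",
    "ColorMetricsRecord",
    "MetricsConfig",
    "box_count",
    "fractal_dimension",
    "global_diversity",
    "per_color_spatial_diversity",
    "coarsen_mask",
    "morans_i",
    "compute_color_metrics",
]

logger = logging.getLogger(__name__)

#: Default box-size ladder: twelve scales in geometric progression
#: (powers of two, 1..2048); sizes exceeding min(H, W) are dropped.
DEFAULT_SCALES: tuple[int, ...] = tuple(2 ** k for k in range(12))


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given input (e.g. an
    empty mask or a constant lattice)."""


class InsufficientScalesError(ValueError):
    """Raised when fewer than three usable box scales remain for the
    log-log regression."""


@dataclasses.dataclass(frozen=True)
class BoxCountCurve:
    """Occupied-box counts N(eps) over a ladder of box sizes eps."""

    points: tuple[tuple[int, int], ...]  # (eps, n_boxes), eps increasing
    mask_size: tuple[int, int]

    def __post_init__(self) -> None:
        eps = [p[0] for p in self.points]
        if any(e < 1 for e in eps):
            raise ValueError("box sizes must be >= 1")
        if any(a >= b for a, b in zip(eps, eps[1:])):
            raise ValueError("box sizes must be strictly increasing")

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclasses.dataclass(frozen=True)
class FractalFit:
    """OLS fit of the box-counting curve; ``dimension`` is the slope."""

    dimension: float
    intercept: float
    r_squared: float
    scales_used: int


@dataclasses.dataclass(frozen=True)
class PresenceLattice:
    """Block-mean presence values x_i in [0, 1] on a coarse grid."""

    values: np.ndarray  # rows x cols, float in [0, 1]
    weights_scheme: str = "rook"
    row_standardized: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size < 4:
            raise ValueError("lattice must be 2-D with at least 4 cells")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("lattice values must lie in [0, 1]")
        if self.weights_scheme not in ("rook", "queen"):
            raise ValueError(f"unknown weights scheme {self.weights_scheme!r}")


@dataclasses.dataclass(frozen=True)
class ColorMetricsRecord:
    """One image x color row: the D / H' / C triplet (NaN = undefined)."""

    image_id: str
    color: str
    dimension: float
    r_squared: float
    h_color: float
    concentration: float
    defined: bool


@dataclasses.dataclass(frozen=True)
class MetricsConfig:
    """Knobs for the per-color metric computation.

    The diversity grid (8x8 by default) and the Moran lattice (100x100
    by default, capped at the mask size) trade spatial resolution against
    stability on photograph-sized masks.
    """

    scales: tuple[int, ...] = DEFAULT_SCALES
    lattice_shape: tuple[int, int] = (100, 100)
    weights_scheme: str = "rook"
    row_standardized: bool = True
    diversity_grid: tuple[int, int] = (8, 8)
    diversity_normalized: bool = True


def box_count(mask: np.ndarray, scales: Sequence[int] = DEFAULT_SCALES,
              ) -> BoxCountCurve:
    """Count occupied boxes of each size over a top-left-anchored grid.

    Partial boxes at the right/bottom edges count like full boxes.  Box
    sizes exceeding ``min(H, W)`` are dropped; an empty mask raises
    :class:`UndefinedMetricError`.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise UndefinedMetricError("box count undefined for an empty mask")
    if any(int(s) < 1 for s in scales):
        raise ValueError("box sizes must be positive integers")

    h, w = mask.shape
    usable = sorted({int(s) for s in scales if int(s) <= min(h, w)})
    points = []
    for eps in usable:
        if eps == 1:
            n = int(mask.sum())
        else:
            ph, pw = -h % eps, -w % eps
            padded = np.pad(mask, ((0, ph), (0, pw)))
            blocks = padded.reshape(padded.shape[0] // eps, eps,
                                    padded.shape[1] // eps, eps)
            n = int(blocks.any(axis=(1, 3)).sum())
        points.append((eps, n))
    return BoxCountCurve(points=tuple(points), mask_size=(h, w))


def fractal_dimension(curve: BoxCountCurve) -> FractalFit:
    """Estimate D as the OLS slope of log N(eps) on log(1/eps).

    Trailing scales stuck at N(eps) = 1 beyond the first are trimmed
    (saturation flattens the slope artificially).  At least three scales
    must remain.
    """
    eps = curve.epsilons
    n = curve.counts

    keep = len(n)
    while keep > 1 and n[keep - 1] == 1 and n[keep - 2] == 1:
        keep -= 1
    eps, n = eps[:keep], n[:keep]

    if len(n) < 3 or np.all(n == n[0]):
        raise InsufficientScalesError(
            f"need >= 3 usable scales with varying counts, have {len(n)}")

    x = np.log(1.0 / eps)
    y = np.log(n)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return FractalFit(dimension=float(slope), intercept=float(intercept),
                      r_squared=r2, scales_used=len(n))


def global_diversity(proportions: Mapping[str, float] | Sequence[float],
                     ) -> float:
    """Shannon–Wiener diversity H' = -sum p_i ln p_i of area proportions.

    ``0 * ln 0`` is taken as 0; proportions must be nonnegative and sum
    to 1.  H' ranges from 0 (one category) to ln(n_categories).
    """
    if isinstance(proportions, Mapping):
        p = np.array(list(proportions.values()), dtype=float)
    else:
        p = np.asarray(proportions, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"proportions must be nonnegative and sum to 1, got sum "
            f"{p.sum():.12g}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _block_slices(n: int, k: int) -> list[slice]:
    # integer splitting: first (n % k) blocks get the extra pixel
    edges = np.linspace(0, n, k + 1).round().astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def per_color_spatial_diversity(mask: np.ndarray,
                                grid: tuple[int, int] = (8, 8),
                                normalized: bool = True) -> float:
    """Spatial evenness of one color over a block partition of the frame.

    The frame is split into ``grid`` blocks; p_b is the share of the
    color's pixels falling in block b, and H = -sum p_b ln p_b.  With
    ``normalized`` the value is divided by ln(number of blocks) so it
    lies in [0, 1]: 0 when the color sits in one block, 1 when evenly
    spread over all blocks.
    """
    mask = np.asarray(mask, dtype=bool)
    total = int(mask.sum())
    if total == 0:
        raise UndefinedMetricError(
            "spatial diversity undefined for an empty mask")
    g_rows, g_cols = grid
    if g_rows * g_cols < 2:
        raise ValueError("grid must have at least 2 blocks")

    row_slices = _block_slices(mask.shape[0], min(g_rows, mask.shape[0]))
    col_slices = _block_slices(mask.shape[1], min(g_cols, mask.shape[1]))
    counts = np.array([[int(mask[rs, cs].sum()) for cs in col_slices]
                       for rs in row_slices], dtype=float)
    p = counts.ravel() / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if normalized:
        h /= math.log(len(row_slices) * len(col_slices))
    return h


def coarsen_mask(mask: np.ndarray, lattice: tuple[int, int] = (100, 100),
                 weights_scheme: str = "rook",
                 row_standardized: bool = True) -> PresenceLattice:
    """Block-mean presence of a binary mask on a coarse lattice.

    Each lattice cell holds the mean of the binary pixel values in its
    block (block edges by integer splitting).  Lattices larger than the
    mask are capped at the mask size.
    """
    mask = np.asarray(mask, dtype=float)
    rows = min(lattice[0], mask.shape[0])
    cols = min(lattice[1], mask.shape[1])
    if rows < 2 or cols < 2:
        raise ValueError("lattice must be at least 2x2")
    row_slices = _block_slices(mask.shape[0], rows)
    col_slices = _block_slices(mask.shape[1], cols)
    values = np.array([[mask[rs, cs].mean() for cs in col_slices]
                       for rs in row_slices])
    return PresenceLattice(values=values, weights_scheme=weights_scheme,
                           row_standardized=row_standardized)


def _neighbor_shifts(scheme: str) -> list[tuple[int, int]]:
    rook = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "rook":
        return rook
    return rook + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def _degree_grid(shape: tuple[int, int], scheme: str) -> np.ndarray:
    deg = np.zeros(shape, dtype=float)
    for dr, dc in _neighbor_shifts(scheme):
        # a neighbor exists wherever the shifted index stays in-grid
        valid = np.ones(shape)
        if dr == -1:
            valid[0, :] = 0
        elif dr == 1:
            valid[-1, :] = 0
        if dc == -1:
            valid[:, 0] = 0
        elif dc == 1:
            valid[:, -1] = 0
        deg += valid
    return deg


def morans_i(lattice: PresenceLattice) -> float:
    """Moran's I spatial autocorrelation of lattice presence values.

    I = (N/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with contiguity weights on the lattice grid (rook by default), row
    standardized so each cell's weights sum to 1.  Constant lattices have
    no spatial variance and raise :class:`UndefinedMetricError`.
    """
    x = np.asarray(lattice.values, dtype=float)
    z = x - x.mean()
    denom = float((z ** 2).sum())
    if denom == 0.0:
        raise UndefinedMetricError(
            "Moran's I undefined for a constant lattice")

    shifts = _neighbor_shifts(lattice.weights_scheme)
    deg = _degree_grid(x.shape, lattice.weights_scheme)

    # sum_j w_ij z_j for every i via padded shifts
    neigh_sum = np.zeros_like(z)
    for dr, dc in shifts:
        shifted = np.zeros_like(z)
        src_r = slice(max(dr, 0), z.shape[0] + min(dr, 0))
        dst_r = slice(max(-dr, 0), z.shape[0] + min(-dr, 0))
        src_c = slice(max(dc, 0), z.shape[1] + min(dc, 0))
        dst_c = slice(max(-dc, 0), z.shape[1] + min(-dc, 0))
        shifted[dst_r, dst_c] = z[src_r, src_c]
        neigh_sum += shifted

    if lattice.row_standardized:
        # w_ij = 1/deg(i); with row standardization W = N
        num = float((z * neigh_sum / deg).sum())
        return num / denom
    w_total = float(deg.sum())
    num = float((z * neigh_sum).sum())
    return (z.size / w_total) * num / denom


def compute_color_metrics(maskset: ColorMaskSet, image_id: str = "",
                          config: MetricsConfig | None = None,
                          ) -> list[ColorMetricsRecord]:
    """The D / H' / C triplet for every color mask of one image.

    Colors with empty masks (or masks too degenerate to fit) yield
    records with NaN metrics and ``defined=False`` plus a logged warning,
    so downstream correlations can use pairwise-complete observations.
    """
    if config is None:
        config = MetricsConfig()
    records = []
    for color in COLOR_NAMES:
        mask = maskset.masks[color]
        try:
            fit = fractal_dimension(box_count(mask, config.scales))
            h = per_color_spatial_diversity(mask, config.diversity_grid,
                                            config.diversity_normalized)
            lat = coarsen_mask(mask, config.lattice_shape,
                               config.weights_scheme,
                               config.row_standardized)
            c = morans_i(lat)
            records.append(ColorMetricsRecord(
                image_id=image_id, color=color, dimension=fit.dimension,
                r_squared=fit.r_squared, h_color=h, concentration=c,
                defined=True))
        except (UndefinedMetricError, InsufficientScalesError) as exc:
            logger.warning("image %s, color %s: %s", image_id, color, exc)
            records.append(ColorMetricsRecord(
                image_id=image_id, color=color, dimension=float("nan"),
                r_squared=float("nan"), h_color=float("nan"),
                concentration=float("nan"), defined=False))
    return records
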