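"""Synthetic inputs with known ground truth for the whole pipeline.

Every generator is deterministic given its spec and seed, and each one's
ground truth is recoverable by the corresponding pipeline stage: fractal
masks carry their analytic similarity dimension, composite landscape
images segment back to the planted masks exactly, rating simulators plant
the pass/fail status, factor structure, or correlation matrix that the
downstream statistics are meant to recover.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from .palette import (COLOR_NAMES, ColorCategoryDef, ColorPalette, RGBImage,
                      default_palette)

__all__ = [
    "ANALYTIC_DIMENSIONS",
    "MaskSpec",
    "SDSimSpec",
    "JointSimSpec",
    "gen_mask",
    "gen_landscape_image",
    "gen_healing_ratings",
    "gen_sd_ratings",
    "gen_joint_dataset",
    "safe_color_value",
]

#: Analytic similarity dimensions of the supported IFS fractals.
ANALYTIC_DIMENSIONS = {
    "sierpinski_carpet": math.log(8) / math.log(3),
    "sierpinski_triangle": math.log(3) / math.log(2),
    "cantor_dust": math.log(4) / math.log(3),
    "vicsek": math.log(5) / math.log(3),
}

_IFS_BASE = {"sierpinski_carpet": 3, "sierpinski_triangle": 2,
             "cantor_dust": 3, "vicsek": 3}

# digit patterns removed at each subdivision level (row digit, col digit)
_IFS_HOLES = {
    "sierpinski_carpet": {(1, 1)},
    "sierpinski_triangle": {(1, 1)},          # upper-left corner variant
    "cantor_dust": {(0, 1), (1, 0), (1, 1), (1, 2), (2, 1)},
    "vicsek": {(0, 0), (0, 2), (2, 0), (2, 2)},
}


@dataclasses.dataclass(frozen=True)
class MaskSpec:
    """Recipe for a deterministic binary test mask.

    kinds: ``ifs_fractal`` (name + depth), ``filled``, ``hline``,
    ``checkerboard`` (cell size), ``disc_cluster`` (n_discs, radius,
    layout single/scattered).
    """

    kind: str
    size: tuple[int, int]
    name: str | None = None
    depth: int = 5
    cell: int = 1
    n_discs: int = 1
    radius: int = 8
    layout: str = "single"
    seed: int = 0

    @property
    def analytic_dimension(self) -> float | None:
        if self.kind == "filled":
            return 2.0
        if self.kind == "hline":
            return 1.0
        if self.kind == "ifs_fractal" and self.name in ANALYTIC_DIMENSIONS:
            return ANALYTIC_DIMENSIONS[self.name]
        return None


def _ifs_mask(name: str, depth: int, size: tuple[int, int]) -> np.ndarray:
    base = _IFS_BASE[name]
    side = base ** depth
    if size != (side, side):
        raise ValueError(
            f"{name} at depth {depth} requires size {side}x{side}, "
            f"got {size}")
    holes = _IFS_HOLES[name]
    rows = np.arange(side)
    keep = np.ones((side, side), dtype=bool)
    for level in range(depth):
        digit = (rows // (base ** level)) % base
        for hr, hc in holes:
            keep &= ~((digit[:, None] == hr) & (digit[None, :] == hc))
    return keep


def gen_mask(spec: MaskSpec) -> np.ndarray:
    """Rasterize a mask spec to a boolean array (deterministic)."""
    h, w = spec.size
    if h < 1 or w < 1:
        raise ValueError("mask size must be positive")
    if spec.kind == "filled":
        return np.ones((h, w), dtype=bool)
    if spec.kind == "hline":
        mask = np.zeros((h, w), dtype=bool)
        mask[h // 2, :] = True
        return mask
    if spec.kind == "checkerboard":
        c = spec.cell
        rows = (np.arange(h) // c) % 2
        cols = (np.arange(w) // c) % 2
        return (rows[:, None] + cols[None, :]) % 2 == 0
    if spec.kind == "ifs_fractal":
        if spec.name not in _IFS_BASE:
            raise ValueError(f"unknown fractal {spec.name!r}")
        return _ifs_mask(spec.name, spec.depth, spec.size)
    if spec.kind == "disc_cluster":
        rng = np.random.default_rng(spec.seed)
        mask = np.zeros((h, w), dtype=bool)
        yy, xx = np.mgrid[0:h, 0:w]
        if spec.layout == "single":
            centers = [(h / 2, w / 2)] * spec.n_discs
        elif spec.layout == "scattered":
            margin = spec.radius + 1
            centers = [(rng.uniform(margin, h - margin),
                        rng.uniform(margin, w - margin))
                       for _ in range(spec.n_discs)]
        else:
            raise ValueError(f"unknown layout {spec.layout!r}")
        for cy, cx in centers:
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.radius ** 2
        return mask
    raise ValueError(f"unknown mask kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# composite landscape images

def _in_box(value: tuple[int, int, int], cat: ColorCategoryDef) -> bool:
    return cat.contains(*value)


def safe_color_value(category: str, palette: ColorPalette,
                     rng: np.random.Generator,
                     ) -> tuple[int, int, int]:
    """A pixel value strictly inside one category's range and outside
    every other category's range (rejection sampling; such values exist
    for all six default categories)."""
    cat = palette[category]
    others = [e for e in palette if e.name != category]
    for _ in range(10_000):
        v = (int(rng.integers(cat.r_lo, cat.r_hi + 1)),
             int(rng.integers(cat.g_lo, cat.g_hi + 1)),
             int(rng.integers(cat.b_lo, cat.b_hi + 1)))
        if not any(_in_box(v, o) for o in others):
            return v
    raise RuntimeError(
        f"could not find an unambiguous pixel value for {category!r}")


def gen_landscape_image(
    composition: Mapping[str, float],
    size: tuple[int, int] = (243, 243),
    layout: str = "blocks",
    seed: int = 0,
    palette: ColorPalette | None = None,
    fractal_color: str | None = None,
    fractal_name: str = "sierpinski_carpet",
    fractal_depth: int = 5,
) -> tuple[RGBImage, dict[str, np.ndarray]]:
    """Paint a synthetic landscape image with planted color masks.

    Pixel values are sampled to match exactly one palette category, so
    segmentation recovers the planted masks under any precedence.
    Layouts: ``blocks`` (contiguous runs in raster order — exact target
    fractions), ``blobs`` (random discs per color on background),
    ``fractal_per_color`` (``fractal_color`` painted as an IFS fractal,
    remaining colors as blocks in the leftover pixels).  Fractions may
    sum to < 1; the remainder stays out-of-range background (18, 18, 18).
    """
    if palette is None:
        palette = default_palette()
    unknown = set(composition) - set(palette.names)
    if unknown:
        raise ValueError(f"unknown color categories: {sorted(unknown)}")
    fracs = {c: float(f) for c, f in composition.items() if f > 0}
    if sum(fracs.values()) > 1.0 + 1e-9:
        raise ValueError("composition fractions must sum to <= 1")

    h, w = size
    n_total = h * w
    rng = np.random.default_rng(seed)
    background = (18, 18, 18)  # below every category's range
    pixels = np.empty((h, w, 3), dtype=np.uint8)
    pixels[:] = background
    planted = {c: np.zeros((h, w), dtype=bool) for c in palette.names}

    def paint(mask: np.ndarray, color: str) -> None:
        value = safe_color_value(color, palette, rng)
        pixels[mask] = value
        planted[color] |= mask

    if layout == "blocks":
        counts = {c: int(round(f * n_total)) for c, f in fracs.items()}
        flat_idx = 0
        for color, cnt in counts.items():
            if flat_idx + cnt > n_total:
                raise ValueError("requested fractions unattainable at "
                                 f"size {size}")
            idx = np.arange(flat_idx, flat_idx + cnt)
            mask = np.zeros(n_total, dtype=bool)
            mask[idx] = True
            paint(mask.reshape(h, w), color)
            flat_idx += cnt
    elif layout == "blobs":
        for color, f in fracs.items():
            target = int(round(f * n_total))
            mask = np.zeros((h, w), dtype=bool)
            yy, xx = np.mgrid[0:h, 0:w]
            free = ~np.any(np.stack(list(planted.values())), axis=0)
            tries = 0
            while mask.sum() < target and tries < 500:
                r = max(3, int(math.sqrt(target / math.pi) / 2))
                cy = rng.uniform(0, h)
                cx = rng.uniform(0, w)
                disc = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2) & free
                mask |= disc
                tries += 1
            paint(mask, color)
    elif layout == "fractal_per_color":
        if fractal_color is None or fractal_color not in fracs:
            raise ValueError("fractal_per_color needs fractal_color in "
                             "the composition")
        base = _IFS_BASE[fractal_name]
        side = base ** fractal_depth
        if side > min(h, w):
            raise ValueError(f"fractal side {side} exceeds image size")
        fmask = np.zeros((h, w), dtype=bool)
        fmask[:side, :side] = gen_mask(MaskSpec(
            kind="ifs_fractal", name=fractal_name, depth=fractal_depth,
            size=(side, side)))
        paint(fmask, fractal_color)
        rest = {c: f for c, f in fracs.items() if c != fractal_color}
        free = ~fmask
        free_idx = np.flatnonzero(free.ravel())
        flat = 0
        for color, f in rest.items():
            cnt = int(round(f * n_total))
            if flat + cnt > free_idx.size:
                raise ValueError("fractions unattainable next to fractal")
            mask = np.zeros(n_total, dtype=bool)
            mask[free_idx[flat:flat + cnt]] = True
            paint(mask.reshape(h, w), color)
            flat += cnt
    else:
        raise ValueError(f"unknown layout {layout!r}")

    return RGBImage(pixels), planted


# ---------------------------------------------------------------------------
# rating simulators

def gen_healing_ratings(
    n_images: int = 150,
    n_raters: int = 23,
    seed: int = 0,
    frac_healing: float = 0.3,
    healing_mean: tuple[float, float] = (5.4, 6.3),
    healing_sd: float = 0.7,
    other_mean: tuple[float, float] = (2.5, 4.6),
    other_sd: float = 1.4,
) -> tuple[dict[str, list[int]], dict[str, bool]]:
    """Simulated 7-point healing ratings with planted consensus status.

    A ``frac_healing`` share of images is planted as high-consensus
    healing views (mean uniform in ``healing_mean``, small rater SD);
    the rest are planted below the selection thresholds (lower mean
    and/or noisy ratings).  Ratings are a discretized, clipped normal.
    Returns (ratings per image, planted pass/fail truth).
    """
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(seed)
    ratings: dict[str, list[int]] = {}
    truth: dict[str, bool] = {}
    n_healing = int(round(frac_healing * n_images))
    for i in range(n_images):
        image_id = f"img{i + 1:03d}"
        healing = i < n_healing
        if healing:
            mu = rng.uniform(*healing_mean)
            sd = healing_sd
        else:
            mu = rng.uniform(*other_mean)
            sd = other_sd
        raw = np.clip(np.round(rng.normal(mu, sd, size=n_raters)), 1, 7)
        ratings[image_id] = [int(v) for v in raw]
        truth[image_id] = healing
    return ratings, truth


@dataclasses.dataclass(frozen=True)
class SDSimSpec:
    """Planted-factor semantic-differential simulation.

    Latent responses follow X = F Lambda' + E per participant-image
    observation (factor scores drawn per image, shared by raters of that
    image), then are discretized onto the 5-point scale by normal-
    quantile cut points.  Defaults mirror a 58-participant, 42-image,
    24-item study design.
    """

    n_participants: int = 58
    n_images: int = 42
    n_items: int = 24
    loadings: np.ndarray | None = None   # items x k; default: 6-factor simple
    noise_sd: float = 0.5
    seed: int = 0

    def resolved_loadings(self) -> np.ndarray:
        if self.loadings is not None:
            L = np.asarray(self.loadings, dtype=float)
            if L.shape[0] != self.n_items:
                raise ValueError("loading matrix rows must equal n_items")
            return L
        # simple structure: items split evenly over 6 factors, loading 0.7
        k = 6
        L = np.zeros((self.n_items, k))
        for i in range(self.n_items):
            L[i, i % k] = 0.7
        return L


def gen_sd_ratings(spec: SDSimSpec,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a participants x items x images Likert array.

    Returns (ratings, planted loading matrix, planted image factor
    scores).  Ratings are integers in 1..5; the latent continuum is cut
    at equiprobable normal quantiles.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.resolved_loadings()
    k = L.shape[1]
    F_img = rng.standard_normal((spec.n_images, k))
    ratings = np.empty((spec.n_participants, spec.n_items, spec.n_images),
                       dtype=np.int64)
    # scale latent to ~unit variance so fixed cuts hit all 5 bins
    latent_sd = np.sqrt((L ** 2).sum(axis=1) + spec.noise_sd ** 2)
    from scipy.stats import norm
    cuts = norm.ppf([0.2, 0.4, 0.6, 0.8])
    for p in range(spec.n_participants):
        noise = rng.standard_normal((spec.n_images, spec.n_items))
        latent = (F_img @ L.T + spec.noise_sd * noise) / latent_sd
        ratings[p] = (np.digitize(latent, cuts) + 1).T
    return ratings, L, F_img


def sd_ratings_to_frame(ratings: np.ndarray,
                        item_labels: Sequence[str] | None = None,
                        ):
    """Flatten a participants x items x images array to long-format rows
    (participant, image, item, score) as a pandas DataFrame."""
    import pandas as pd
    n_p, n_i, n_img = ratings.shape
    if item_labels is None:
        item_labels = [f"item{i + 1}" for i in range(n_i)]
    p_idx, i_idx, img_idx = np.meshgrid(
        np.arange(n_p), np.arange(n_i), np.arange(n_img), indexing="ij")
    return pd.DataFrame({
        "participant": p_idx.ravel() + 1,
        "image": [f"img{j + 1:03d}" for j in img_idx.ravel()],
        "item": [item_labels[i] for i in i_idx.ravel()],
        "score": ratings.ravel(),
    })


@dataclasses.dataclass(frozen=True)
class JointSimSpec:
    """Joint Gaussian draw of 18 color metrics and k factor scores with a
    planted cross-correlation structure."""

    n_images: int = 42
    n_factors: int = 6
    cross_correlation: np.ndarray | None = None  # 18 x k target block
    seed: int = 0

    @property
    def metric_labels(self) -> list[str]:
        return [f"{color}_{m}" for color in COLOR_NAMES
                for m in ("D", "H", "C")]


def gen_joint_dataset(spec: JointSimSpec):
    """Draw (metrics table, factor-score table) with planted correlations.

    The joint covariance is the identity except for the requested
    metric-factor cross-correlation block; it must be positive
    semidefinite.  Empirical correlations converge to the targets as
    ``n_images`` grows.
    """
    import pandas as pd
    n_m = 18
    k = spec.n_factors
    cross = (np.zeros((n_m, k)) if spec.cross_correlation is None
             else np.asarray(spec.cross_correlation, dtype=float))
    if cross.shape != (n_m, k):
        raise ValueError(f"cross correlation must be {n_m}x{k}")
    cov = np.eye(n_m + k)
    cov[:n_m, n_m:] = cross
    cov[n_m:, :n_m] = cross.T
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-10:
        raise ValueError(
            f"target correlation matrix is not PSD (min eig {eigmin:.3g})")

    rng = np.random.default_rng(spec.seed)
    root = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    draws = rng.standard_normal((spec.n_images, n_m + k)) @ root.T
    ids = [f"img{i + 1:03d}" for i in range(spec.n_images)]
    metrics = pd.DataFrame(draws[:, :n_m], index=ids,
                           columns=spec.metric_labels)
    factors = pd.DataFrame(draws[:, n_m:], index=ids,
                           columns=[f"factor{j + 1}" for j in range(k)])
    metrics.index.name = factors.index.name = "image_id"
    return metrics, factors
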