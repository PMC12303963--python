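"""Six-category RGB-range color segmentation of landscape photographs.

A landscape image is decomposed into binary masks for six named color
categories (red, yellow, brown, gray, white, green), each defined by an
inclusive axis-aligned box in 8-bit RGB space.  The default palette carries
the published range table for a traditional Japanese garden; ranges overlap,
so two assignment modes exist:

``non_exclusive``
    a pixel belongs to every category whose box contains it (six independent
    binary masks — the form the per-color spatial metrics consume);
``exclusive``
    each pixel is assigned to at most one category by a fixed precedence
    order, yielding a partition of the classified pixels from which area
    proportions are computed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "COLOR_NAMES",
    "EXCLUSIVE_PRECEDENCE",
    "ColorCategoryDef",
    "ColorPalette",
    "RGBImage",
    "ColorMaskSet",
    "default_palette",
    "load_image",
    "segment_image",
    "composition_proportions",
]

#: Canonical category order (the order of the published range table).
COLOR_NAMES = ("red", "yellow", "brown", "gray", "white", "green")

#: Precedence for exclusive assignment: most specific range volume first.
EXCLUSIVE_PRECEDENCE = ("white", "green", "red", "yellow", "gray", "brown")


class SegmentationError(ValueError):
    """Raised for invalid palettes, images, or degenerate classifications."""


@dataclasses.dataclass(frozen=True)
class ColorCategoryDef:
    """One color category: a name plus inclusive per-channel bounds."""

    name: str
    r_lo: int
    r_hi: int
    g_lo: int
    g_hi: int
    b_lo: int
    b_hi: int

    def __post_init__(self) -> None:
        for lo, hi in ((self.r_lo, self.r_hi), (self.g_lo, self.g_hi),
                       (self.b_lo, self.b_hi)):
            if not (0 <= lo <= hi <= 255):
                raise SegmentationError(
                    f"category {self.name!r}: bounds must satisfy "
                    f"0 <= lo <= hi <= 255, got ({lo}, {hi})")

    @property
    def bounds(self) -> tuple[int, int, int, int, int, int]:
        return (self.r_lo, self.r_hi, self.g_lo, self.g_hi,
                self.b_lo, self.b_hi)

    def contains(self, r: int, g: int, b: int) -> bool:
        return (self.r_lo <= r <= self.r_hi
                and self.g_lo <= g <= self.g_hi
                and self.b_lo <= b <= self.b_hi)


@dataclasses.dataclass(frozen=True)
class ColorPalette:
    """An ordered collection of six color category definitions."""

    entries: tuple[ColorCategoryDef, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise SegmentationError(f"duplicate category names: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def __getitem__(self, name: str) -> ColorCategoryDef:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __getattr__(self, name: str) -> ColorCategoryDef:
        # attribute sugar: palette.red -> the red category
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self[name]
        except KeyError:
            raise AttributeError(name) from None

    def __iter__(self) -> Iterable[ColorCategoryDef]:
        return iter(self.entries)

    def to_dict(self) -> dict[str, list[int]]:
        return {e.name: list(e.bounds) for e in self.entries}

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[int]]) -> "ColorPalette":
        entries = tuple(ColorCategoryDef(name, *map(int, bounds))
                        for name, bounds in d.items())
        return cls(entries)


def default_palette() -> ColorPalette:
    """The six-category garden palette (inclusive 8-bit RGB ranges).

    Categories cover the chromatic elements of a traditional Japanese
    garden: autumn maple reds, gold-leaf yellows, wood/soil browns, stone
    grays, sand/sky whites, and vegetation greens.
    """
    rows = [
        ("red", 131, 208, 8, 120, 2, 82),
        ("yellow", 184, 228, 156, 194, 116, 133),
        ("brown", 83, 173, 79, 187, 54, 194),
        ("gray", 123, 184, 105, 184, 101, 184),
        ("white", 212, 255, 212, 255, 212, 255),
        ("green", 76, 169, 93, 199, 38, 113),
    ]
    return ColorPalette(tuple(ColorCategoryDef(*r) for r in rows))


@dataclasses.dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB raster, row-major with origin at the top-left."""

    pixels: np.ndarray  # H x W x 3 uint8

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise SegmentationError(f"expected HxWx3 array, got {p.shape}")
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise SegmentationError("image must have positive dimensions")
        if p.dtype != np.uint8:
            raise SegmentationError(f"expected uint8 pixels, got {p.dtype}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclasses.dataclass(frozen=True)
class ColorMaskSet:
    """Per-category binary masks for one image.

    In exclusive mode the masks partition the classified pixels and
    ``proportions`` holds the area fraction p_i of each category among
    classified pixels (all zero when nothing is classified, in which case
    ``unclassified_fraction`` is 1).
    """

    masks: dict[str, np.ndarray]
    mode: str
    unclassified_fraction: float
    proportions: dict[str, float]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape


def load_image(path: str | Path) -> RGBImage:
    """Load a PNG/TIFF/JPEG file as an 8-bit RGB image.

    An alpha channel is dropped; grayscale images are promoted by channel
    replication.  Unreadable or truncated files raise ``IOError``.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode not in ("RGB", "RGBA", "L", "LA", "P", "I;16"):
                im = im.convert("RGB")
            if im.mode == "I;16":
                raise SegmentationError(
                    f"{path}: 16-bit images are not supported; "
                    "convert to 8-bit first")
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return RGBImage(arr)


def _category_mask(pixels: np.ndarray, cat: ColorCategoryDef) -> np.ndarray:
    r, g, b = pixels[..., 0], pixels[..., 1], pixels[..., 2]
    return ((r >= cat.r_lo) & (r <= cat.r_hi)
            & (g >= cat.g_lo) & (g <= cat.g_hi)
            & (b >= cat.b_lo) & (b <= cat.b_hi))


def segment_image(
    img: RGBImage,
    palette: ColorPalette | None = None,
    mode: str = "non_exclusive",
    precedence: tuple[str, ...] = EXCLUSIVE_PRECEDENCE,
) -> ColorMaskSet:
    """Classify each pixel into the palette's color categories.

    ``non_exclusive`` mode returns one independent binary mask per category
    (a pixel may appear in several).  ``exclusive`` mode assigns each pixel
    to the first matching category in ``precedence`` so the masks are
    disjoint.  Proportions are always computed from the exclusive
    assignment, so they sum to 1 over classified pixels.
    """
    if palette is None:
        palette = default_palette()
    if mode not in ("non_exclusive", "exclusive"):
        raise SegmentationError(f"unknown mode {mode!r}")
    if set(precedence) != set(palette.names):
        raise SegmentationError(
            "precedence must be a permutation of the palette names")

    raw = {e.name: _category_mask(img.pixels, e) for e in palette}

    # exclusive assignment by precedence (used for proportions in both modes)
    taken = np.zeros(img.pixels.shape[:2], dtype=bool)
    exclusive: dict[str, np.ndarray] = {}
    for name in precedence:
        m = raw[name] & ~taken
        exclusive[name] = m
        taken |= m

    n_classified = int(taken.sum())
    n_total = taken.size
    if n_classified:
        proportions = {name: int(exclusive[name].sum()) / n_classified
                       for name in palette.names}
    else:
        proportions = {name: 0.0 for name in palette.names}

    masks = raw if mode == "non_exclusive" else exclusive
    return ColorMaskSet(
        masks={name: masks[name] for name in palette.names},
        mode=mode,
        unclassified_fraction=1.0 - n_classified / n_total,
        proportions=proportions,
    )


def composition_proportions(maskset: ColorMaskSet) -> dict[str, float]:
    """Area fraction p_i of each category among classified pixels.

    Requires an exclusive-mode mask set (the p_i of the diversity index
    are defined over a partition).  Raises if no pixel is classified.
    """
    if maskset.mode != "exclusive":
        raise SegmentationError(
            "proportions require an exclusive-mode mask set")
    total = sum(int(m.sum()) for m in maskset.masks.values())
    if total == 0:
        raise SegmentationError(
            "no classified pixels: composition proportions are undefined")
    return {name: int(m.sum()) / total for name, m in maskset.masks.items()}
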