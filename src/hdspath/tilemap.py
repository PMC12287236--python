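"""Patch tiling and tissue-label grids.

A whole-slide image is cut into non-overlapping square patches (150 px at
20x by convention).  Each patch carries a grid position and pixel box, and
after classification each grid cell holds one of six tissue categories or
``Blank`` (background removed by the blank-area filter).  Per-patch scalar
overlays (attention, probabilities) live in a :class:`ValueGrid` aligned to
the same grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The six tissue categories assigned by the patch classifier, fixed order.
CATEGORIES: tuple[str, ...] = (
    "Tumor", "Necrosis", "Fibrosis", "Lymphocyte", "NormalLiver", "Other",
)
BLANK = "Blank"
LABEL_VOCAB: tuple[str, ...] = CATEGORIES + (BLANK,)

DEFAULT_PATCH_SIZE = 150
DEFAULT_WHITE_THRESHOLD = 220.0


@dataclass(frozen=True)
class PatchRef:
    """Grid position and pixel box of one patch within a slide."""

    slide_id: str
    row: int
    col: int
    patch_size: int = DEFAULT_PATCH_SIZE

    def __post_init__(self):
        if self.row < 0 or self.col < 0:
            raise ValueError("patch grid indices must be non-negative")

    @property
    def x0(self) -> int:
        return self.col * self.patch_size

    @property
    def y0(self) -> int:
        return self.row * self.patch_size


@dataclass
class TissueMap:
    """2-D grid of per-patch tissue labels for one slide."""

    slide_id: str
    labels: np.ndarray  # (n_rows, n_cols) array of label strings
    patch_size: int = DEFAULT_PATCH_SIZE

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        bad = set(self.labels.ravel()) - set(LABEL_VOCAB)
        if bad:
            raise ValueError(
                f"unknown labels {sorted(bad)}; vocabulary is {list(LABEL_VOCAB)}"
            )

    @property
    def n_rows(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.labels.shape[1]

    def mask(self, category: str) -> np.ndarray:
        return self.labels == category

    @property
    def non_blank(self) -> np.ndarray:
        return self.labels != BLANK

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TissueMap)
            and self.slide_id == other.slide_id
            and self.patch_size == other.patch_size
            and self.labels.shape == other.labels.shape
            and bool(np.all(self.labels == other.labels))
        )


@dataclass
class ValueGrid:
    """Per-patch scalar overlay aligned to a TissueMap; NaN marks missing."""

    slide_id: str
    values: np.ndarray  # (n_rows, n_cols) float array, NaN = missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# tiling and blank filtering
# ---------------------------------------------------------------------------

def load_raster(path) -> np.ndarray:
    """Read a PNG/TIFF image into an HxWx3 (or HxW) uint8 array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def tile_slide(image, slide_id: str = "slide",
               patch_size: int = DEFAULT_PATCH_SIZE):
    """Cut an image into non-overlapping patches, row-major.

    Trailing partial tiles are dropped, so the result holds exactly
    ``floor(H/ps) * floor(W/ps)`` patches.

    Returns a list of ``(PatchRef, pixel_array)`` pairs.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image {h}x{w} is smaller than one {patch_size}x{patch_size} patch"
        )
    out = []
    for row in range(h // patch_size):
        for col in range(w // patch_size):
            ref = PatchRef(slide_id, row, col, patch_size)
            tile = image[ref.y0:ref.y0 + patch_size, ref.x0:ref.x0 + patch_size]
            out.append((ref, tile))
    return out


def blank_fraction(patch: np.ndarray,
                   white_threshold: float = DEFAULT_WHITE_THRESHOLD) -> float:
    """Fraction of pixels brighter than `white_threshold` in mean-RGB luminance."""
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("patch is empty")
    lum = patch.mean(axis=-1) if patch.ndim == 3 else patch
    return float(np.mean(lum > white_threshold))


def filter_blank(patches, threshold: float = 0.75,
                 white_threshold: float = DEFAULT_WHITE_THRESHOLD):
    """Split patches into retained and blank-marked ones.

    A patch is discarded iff its blank fraction strictly exceeds `threshold`
    (the "more than 75% blank" rule).  Returns ``(retained, blank_refs)``
    where retained keeps the ``(PatchRef, pixels)`` pairs.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    retained, blank_refs = [], []
    for ref, pixels in patches:
        if blank_fraction(pixels, white_threshold) > threshold:
            blank_refs.append(ref)
        else:
            retained.append((ref, pixels))
    return retained, blank_refs


# ---------------------------------------------------------------------------
# TSV round-trips
# ---------------------------------------------------------------------------

def write_tissue_map(tmap: TissueMap, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["slide_id", "row", "col", "label"])
        for r in range(tmap.n_rows):
            for c in range(tmap.n_cols):
                w.writerow([tmap.slide_id, r, c, tmap.labels[r, c]])


def read_tissue_map(path, patch_size: int = DEFAULT_PATCH_SIZE) -> TissueMap:
    rows: dict[tuple[int, int], str] = {}
    slide_id = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"slide_id", "row", "col", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"tissue map TSV needs columns {sorted(required)}")
        for rec in reader:
            label = rec["label"]
            if label not in LABEL_VOCAB:
                raise ValueError(
                    f"unknown label {label!r}; vocabulary is {list(LABEL_VOCAB)}"
                )
            key = (int(rec["row"]), int(rec["col"]))
            if key in rows:
                raise ValueError(f"duplicate cell {key} in {path}")
            rows[key] = label
            slide_id = rec["slide_id"]
    if not rows:
        raise ValueError(f"empty tissue map file: {path}")
    n_rows = max(r for r, _ in rows) + 1
    n_cols = max(c for _, c in rows) + 1
    labels = np.full((n_rows, n_cols), BLANK, dtype=object)
    for (r, c), label in rows.items():
        labels[r, c] = label
    return TissueMap(slide_id, labels, patch_size)


def write_value_grid(grid: ValueGrid, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["slide_id", "row", "col", "value"])
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                v = grid.values[r, c]
                w.writerow([grid.slide_id, r, c, "" if np.isnan(v) else repr(float(v))])


def read_value_grid(path) -> ValueGrid:
    cells: dict[tuple[int, int], float] = {}
    slide_id = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            key = (int(rec["row"]), int(rec["col"]))
            cells[key] = float(rec["value"]) if rec["value"] != "" else np.nan
            slide_id = rec["slide_id"]
    if not cells:
        raise ValueError(f"empty value grid file: {path}")
    n_rows = max(r for r, _ in cells) + 1
    n_cols = max(c for _, c in cells) + 1
    values = np.full((n_rows, n_cols), np.nan)
    for (r, c), v in cells.items():
        values[r, c] = v
    return ValueGrid(slide_id, values)


# ---------------------------------------------------------------------------
# aggregation & export
# ---------------------------------------------------------------------------

def grid_aggregate(grid: ValueGrid, block: int = 4) -> ValueGrid:
    """Block-mean a ValueGrid; each output cell averages the non-missing
    values of one block x block window (trailing partial windows included).
    All-missing windows stay missing."""
    if block < 1:
        raise ValueError("block must be >= 1")
    nr = -(-grid.n_rows // block)
    nc = -(-grid.n_cols // block)
    out = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            window = grid.values[i * block:(i + 1) * block,
                                 j * block:(j + 1) * block]
            if np.any(~np.isnan(window)):
                out[i, j] = np.nanmean(window)
    return ValueGrid(grid.slide_id, out)


def heatmap_png(grid: ValueGrid, path, cmap: str = "inferno") -> None:
    """Export a ValueGrid as a PNG heatmap (fixed colormap, NaN transparent)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.ma.masked_invalid(grid.values), cmap=cmap, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
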