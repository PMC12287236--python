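"""Per-slide instance bags: patch embeddings grouped by tissue category.

A bag is the multiple-instance-learning unit — one slide, its patch
embedding vectors, and for each vector the grid cell it came from.  Bags
are grouped by the six tissue categories so category-aware models can pool
within a class before relating classes to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tilemap import CATEGORIES


@dataclass
class SlideBag:
    """Instance bag for one slide.

    instances maps category -> (n_c, d) float array; cells maps category ->
    (n_c, 2) int array of (row, col) grid positions.  Empty categories are
    simply absent from the dicts.
    """

    slide_id: str
    instances: dict[str, np.ndarray] = field(default_factory=dict)
    cells: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for cat, arr in self.instances.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError("instance arrays must be (n, d)")
            self.instances[cat] = arr
            if cat in self.cells:
                cells = np.asarray(self.cells[cat], dtype=int)
                if cells.shape != (arr.shape[0], 2):
                    raise ValueError("cells must align with instances")
                self.cells[cat] = cells

    @property
    def n_instances(self) -> int:
        return sum(a.shape[0] for a in self.instances.values())

    @property
    def dim(self) -> int:
        for a in self.instances.values():
            return a.shape[1]
        raise ValueError(f"bag {self.slide_id} is empty")

    @property
    def categories(self) -> list[str]:
        return [c for c in CATEGORIES if c in self.instances
                and self.instances[c].shape[0] > 0]

    def all_instances(self) -> np.ndarray:
        """All embeddings stacked in fixed category order."""
        parts = [self.instances[c] for c in self.categories]
        if not parts:
            raise ValueError(f"bag {self.slide_id} is empty")
        return np.vstack(parts)


def save_bag(bag: SlideBag, path) -> None:
    """NPZ container: X_<cat> and cells_<cat> arrays plus the slide id.

    Written with fixed zip metadata so identical bags produce identical
    bytes (plain ``np.savez`` stamps the archive with the current time).
    """
    import io
    import zipfile

    arrays = {"slide_id": np.array(bag.slide_id)}
    for cat, arr in bag.instances.items():
        arrays[f"X_{cat}"] = arr
        if cat in bag.cells:
            arrays[f"cells_{cat}"] = bag.cells[cat]
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, arrays[name])
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_bag(path) -> SlideBag:
    with np.load(path, allow_pickle=False) as z:
        slide_id = str(z["slide_id"])
        instances, cells = {}, {}
        for key in z.files:
            if key.startswith("X_"):
                instances[key[2:]] = z[key]
            elif key.startswith("cells_"):
                cells[key[6:]] = z[key]
    return SlideBag(slide_id, instances, cells)
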