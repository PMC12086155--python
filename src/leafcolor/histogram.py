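"""Per-color pixel counts for a segmented image region.

A :class:`ColorHistogram` is the raw product of the image front end: the set
of uniquely observed RGB codes in the vegetation region of one photo together
with the number of pixels showing each code.  All downstream color statistics
(normalized intensity, dark-green proportion, band proportions) are weighted
sums over this table, so it is the only image-derived object the statistical
layers ever see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

RGBTriple = tuple[int, int, int]


def _validate_triple(color: tuple) -> RGBTriple:
    if len(color) != 3:
        raise InputError(f"RGB triple must have 3 channels, got {color!r}")
    r, g, b = (int(c) for c in color)
    for c in (r, g, b):
        if not 0 <= c <= 255:
            raise InputError(f"channel value {c} outside [0, 255] in {color!r}")
    return (r, g, b)


@dataclass(frozen=True)
class ColorHistogram:
    """Mapping from RGB code to pixel count.

    Invariants: every stored count is >= 1 and ``total_pixels`` equals the
    sum of counts.  Construct via :meth:`from_counts`, :meth:`from_pixels`
    or :meth:`read_csv`.
    """

    entries: Mapping[RGBTriple, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[RGBTriple, int] = {}
        for color, count in self.entries.items():
            count = int(count)
            if count < 0:
                raise InputError(f"negative pixel count {count} for {color!r}")
            if count == 0:
                continue
            clean[_validate_triple(color)] = count
        object.__setattr__(self, "entries", clean)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_counts(cls, counts: Mapping[tuple, int]) -> "ColorHistogram":
        return cls(dict(counts))

    @classmethod
    def from_pixels(cls, pixels: np.ndarray) -> "ColorHistogram":
        """Tally an (n, 3) uint8 pixel array into a histogram."""
        pixels = np.asarray(pixels)
        if pixels.ndim != 2 or pixels.shape[1] != 3:
            raise InputError(f"expected (n, 3) pixel array, got shape {pixels.shape}")
        if pixels.shape[0] == 0:
            return cls({})
        codes = (
            pixels[:, 0].astype(np.int64) * 65536
            + pixels[:, 1].astype(np.int64) * 256
            + pixels[:, 2].astype(np.int64)
        )
        uniq, counts = np.unique(codes, return_counts=True)
        entries = {
            (int(c >> 16) & 255, int(c >> 8) & 255, int(c) & 255): int(k)
            for c, k in zip(uniq, counts)
        }
        return cls(entries)

    # -- basic protocol ----------------------------------------------------

    @property
    def total_pixels(self) -> int:
        return sum(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RGBTriple]:
        return iter(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def items(self):
        return self.entries.items()

    def filter(self, predicate) -> "ColorHistogram":
        """Histogram restricted to colors satisfying ``predicate(r, g, b)``."""
        return ColorHistogram(
            {c: n for c, n in self.entries.items() if predicate(*c)}
        )

    # -- array / table views ----------------------------------------------

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (colors, counts) as an (k, 3) uint8 array and a (k,) int array."""
        if not self.entries:
            return np.empty((0, 3), dtype=np.uint8), np.empty(0, dtype=np.int64)
        colors = np.array(sorted(self.entries), dtype=np.uint8)
        counts = np.array([self.entries[tuple(c)] for c in colors.tolist()], dtype=np.int64)
        return colors, counts

    def to_frame(self) -> pd.DataFrame:
        colors, counts = self.to_arrays()
        return pd.DataFrame(
            {
                "r": colors[:, 0].astype(int),
                "g": colors[:, 1].astype(int),
                "b": colors[:, 2].astype(int),
                "count": counts,
            }
        )

    # -- text I/O (mirrors the image program's per-color output) -----------

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ColorHistogram":
        df = pd.read_csv(path)
        missing = {"r", "g", "b", "count"} - set(df.columns)
        if missing:
            raise InputError(f"histogram table {path} lacks columns {sorted(missing)}")
        return cls(
            {
                (int(row.r), int(row.g), int(row.b)): int(row.count)
                for row in df.itertuples()
            }
        )
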