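"""Chromosome naming, chromosome lengths and genome window grids.

All internal coordinates are 0-based half-open. Window grids tile each
chromosome with fixed-size windows (the last window per chromosome may be
shorter) and carry stable global ordinal indices in genome order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: chromosomes removed from the default analysis set: Y (excluded from the
#: hotspot analysis) and the mitochondrial contig.
DEFAULT_EXCLUDED_CHROMS = frozenset({"Y", "MT"})


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the un-prefixed convention.

    Accepts ``"chr17"`` and ``"17"`` alike; ``chrM``/``M`` become ``MT``.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in {"M", "MT"}:
        return "MT"
    return s.upper() if s.isalpha() else s


def _chrom_sort_key(name: str) -> tuple[int, int, str]:
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def sort_chroms(names) -> list[str]:
    """Deterministic genome order: numeric chromosomes ascending, then others."""
    return sorted(names, key=_chrom_sort_key)


def read_chrom_lengths(path, exclude=DEFAULT_EXCLUDED_CHROMS) -> dict[str, int]:
    """Read a two-column (chromosome, length) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    out: dict[str, int] = {}
    for chrom, length in zip(df["chrom"], df["length"]):
        c = normalize_chrom(chrom)
        if c in exclude:
            continue
        length = int(length)
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {c!r}")
        out[c] = length
    return out


def write_chrom_lengths(chrom_lengths: dict[str, int], path) -> None:
    pd.DataFrame(
        {"chrom": list(chrom_lengths), "length": list(chrom_lengths.values())}
    ).to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class GenomicWindows:
    """A disjoint tiling of the genome into fixed-size windows.

    Attributes
    ----------
    size:
        Nominal window size in bp (the aggregation level).
    frame:
        DataFrame with columns ``chrom``, ``start``, ``end`` and the global
        ordinal ``index`` in genome order.
    """

    size: int
    frame: pd.DataFrame
    _offsets: dict[str, tuple[int, int]] = field(repr=False, default_factory=dict)
    _chrom_lengths: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def chroms(self) -> list[str]:
        return list(self._offsets)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self._chrom_lengths)

    @property
    def widths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    def locate(self, chrom: str, pos: int) -> int:
        """Global index of the window containing 0-based position ``pos``."""
        first, count = self._index_range(chrom)
        i = int(pos) // self.size
        if i < 0 or i >= count:
            raise ValueError(f"position {pos} outside chromosome {chrom!r}")
        return first + i

    def overlapping(self, chrom: str, start: int, end: int) -> range:
        """Global indices of all windows overlapping [start, end)."""
        if end <= start:
            raise ValueError("empty interval")
        first, count = self._index_range(chrom)
        length = self._chrom_lengths[chrom]
        lo = max(int(start), 0) // self.size
        hi = (min(int(end), length) - 1) // self.size
        return range(first + lo, first + hi + 1)

    def _index_range(self, chrom: str) -> tuple[int, int]:
        try:
            return self._offsets[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def same_grid(self, other: "GenomicWindows") -> bool:
        return self.size == other.size and self._chrom_lengths == other._chrom_lengths

    def to_bed(self, path) -> None:
        self.frame[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False)


def make_windows(chrom_lengths: dict[str, int], size: int) -> GenomicWindows:
    """Tile every chromosome with disjoint windows of ``size`` bp.

    Per chromosome there are ``ceil(length / size)`` windows covering
    ``[0, length)``; the final window is truncated at the chromosome end.
    Global indices follow genome order (numeric chromosomes first, ascending).
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if not chrom_lengths:
        raise ValueError("no chromosomes given")
    chroms, starts, ends = [], [], []
    offsets: dict[str, tuple[int, int]] = {}
    ordered: dict[str, int] = {}
    for chrom in sort_chroms(chrom_lengths):
        length = int(chrom_lengths[chrom])
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        n = -(-length // size)
        offsets[chrom] = (len(chroms), n)
        ordered[chrom] = length
        s = np.arange(n, dtype=np.int64) * size
        starts.append(s)
        ends.append(np.minimum(s + size, length))
        chroms.extend([chrom] * n)
    frame = pd.DataFrame({
        "chrom": chroms,
        "start": np.concatenate(starts),
        "end": np.concatenate(ends),
    })
    frame["index"] = np.arange(len(frame), dtype=np.int64)
    return GenomicWindows(size=size, frame=frame, _offsets=offsets,
                          _chrom_lengths=ordered)
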