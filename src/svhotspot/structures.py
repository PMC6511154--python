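"""Non-B DNA structure annotation: G-quadruplex motifs and mismatch-tolerant
stem-loops (inverted repeats), plus per-window union coverage.

Two structure families are annotated:

* **G-quadruplexes (G4)** — four runs of >= 3 guanines separated by loops of
  1–7 arbitrary bases, the canonical quadparser-style motif
  ``G{3,}([ACGT]{1,7}G{3,}){3}``, matched greedily left-to-right without
  overlap on the plus strand; the C-run mirror of the pattern is reported on
  the minus strand when both strands are requested.

* **Stem-loops (cruciforms)** — inverted repeats whose two arms of length
  ``s`` flank a loop of length ``l`` and pair with at most ``m`` mismatches
  when one arm is reverse-complemented. Three classes are used:
  short (stem 6–15, <= 1 mismatch), medium (stem 15–30, <= 5 mismatches)
  and long (stem 16–50, <= 3 mismatches), all with loop 0–10. N bases never
  pair. Only locally maximal hits are reported: a hit is suppressed when the
  stem can be extended outward by one base at the same center while staying
  within the class bounds and mismatch budget.

Coverage of a window is the length of the union of annotation intervals
clipped to the window, divided by the window width, so overlapping or
redundant annotations cannot inflate it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicWindows, normalize_chrom


@dataclass(frozen=True)
class StructureClass:
    """Parameters of one structure family."""
    name: str
    stem_min: int = 0       # SL only
    stem_max: int = 0       # SL only
    loop_max: int = 10
    max_mismatches: int = 0  # SL only

    @property
    def is_stem_loop(self) -> bool:
        return self.stem_max > 0


G4 = StructureClass("G4")
SL_SHORT = StructureClass("SL_short", stem_min=6, stem_max=15, loop_max=10,
                          max_mismatches=1)
SL_MEDIUM = StructureClass("SL_medium", stem_min=15, stem_max=30, loop_max=10,
                           max_mismatches=5)
SL_LONG = StructureClass("SL_long", stem_min=16, stem_max=50, loop_max=10,
                         max_mismatches=3)
STRUCTURE_CLASSES = {c.name: c for c in (G4, SL_SHORT, SL_MEDIUM, SL_LONG)}

_ANNOT_COLUMNS = ["chrom", "start", "end", "structure_class", "strand"]

# base encoding; complement of code b is 3-b for ACGT, N (code 4) never pairs
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _annotations(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_ANNOT_COLUMNS)


def g4_regex(min_run: int = 3, loop_min: int = 1, loop_max: int = 7,
             n_tetrads: int = 4, base: str = "G") -> re.Pattern:
    run = f"{base}{{{min_run},}}"
    return re.compile(f"{run}(?:[ACGT]{{{loop_min},{loop_max}}}{run}){{{n_tetrads - 1}}}")


def scan_quadruplexes(sequence: str, chrom: str = "seq", min_run: int = 3,
                      loop_min: int = 1, loop_max: int = 7, n_tetrads: int = 4,
                      both_strands: bool = True) -> pd.DataFrame:
    """Greedy non-overlapping G4 motif matches, coordinates on the forward strand."""
    seq = sequence.upper()
    rows = []
    for m in g4_regex(min_run, loop_min, loop_max, n_tetrads, "G").finditer(seq):
        rows.append((chrom, m.start(), m.end(), "G4", "+"))
    if both_strands:
        for m in g4_regex(min_run, loop_min, loop_max, n_tetrads, "C").finditer(seq):
            rows.append((chrom, m.start(), m.end(), "G4", "-"))
    out = _annotations(rows)
    return out.sort_values(["start", "end"], kind="stable").reset_index(drop=True)


def scan_stem_loops(sequence: str, cls: StructureClass,
                    chrom: str = "seq") -> pd.DataFrame:
    """All locally maximal stem-loop hits of one class in a sequence.

    A hit is a triple (arm start ``i``, stem ``s``, loop ``l``) such that the
    arm ``seq[i:i+s]`` and the reverse complement of ``seq[i+s+l:i+2s+l]``
    disagree at <= ``cls.max_mismatches`` positions. Outward extension of the
    stem keeps the inner end of the left arm fixed, so for each (inner end,
    loop) the valid stems form a prefix of a cumulative mismatch count and at
    most one maximal hit exists; this is what makes the scan O(n * stem_max)
    per loop length rather than exhaustive.
    """
    if not cls.is_stem_loop:
        raise ValueError(f"{cls.name} is not a stem-loop class")
    n = len(sequence)
    rows = []
    if n < 2 * cls.stem_min:
        return _annotations(rows)
    code = _CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    smax = cls.stem_max
    BIG = np.int16(smax + 1)  # poisons any stem containing an unpairable position
    for loop in range(0, cls.loop_max + 1):
        # mm[j, t] = mismatch state of the j-th pair (counted inward-out) of a
        # stem whose left arm ends at t; pair j spans gap loop + 1 + 2j.
        mm = np.full((smax, n), BIG, dtype=np.int16)
        for j in range(smax):
            gap = loop + 1 + 2 * j
            u = n - gap  # valid left-base positions: 0 .. u-1
            if u <= 0:
                break
            pair = np.full(n, BIG, dtype=np.int16)
            # complement iff base codes sum to 3; N (code 4) always mismatches
            pair[:u] = ((code[:u] + code[gap:]) != 3).astype(np.int16)
            # row j indexed by the inner arm end t = i + s - 1 = (left base) + j
            mm[j, j:] = pair[: n - j]
        cum = np.cumsum(mm, axis=0)
        # s*(t): largest stem with cum mismatches <= budget
        sstar = (cum <= cls.max_mismatches).sum(axis=0)
        hit_t = np.flatnonzero(sstar >= cls.stem_min)
        for t in hit_t:
            s = int(sstar[t])
            start = int(t) - s + 1
            end = start + 2 * s + loop
            if start >= 0 and end <= n:
                rows.append((chrom, start, end, cls.name, "."))
    out = _annotations(rows)
    return out.sort_values(["start", "end"], kind="stable").reset_index(drop=True)


def scan_sequence(sequence: str, classes=None, chrom: str = "seq") -> pd.DataFrame:
    """Annotate one sequence with every requested structure class."""
    classes = [STRUCTURE_CLASSES[c] if isinstance(c, str) else c
               for c in (classes or STRUCTURE_CLASSES.values())]
    parts = []
    for cls in classes:
        if cls.is_stem_loop:
            parts.append(scan_stem_loops(sequence, cls, chrom=chrom))
        else:
            parts.append(scan_quadruplexes(sequence, chrom=chrom))
    return pd.concat(parts, ignore_index=True)


def scan_fasta(path, classes=None) -> pd.DataFrame:
    """Annotate every record of a FASTA file (record id -> chromosome name)."""
    from Bio import SeqIO

    parts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts.append(scan_sequence(str(rec.seq), classes,
                                   chrom=normalize_chrom(rec.id)))
    if not parts:
        return _annotations([])
    return pd.concat(parts, ignore_index=True)


def read_structure_bed(path, structure_class: str) -> pd.DataFrame:
    """Read a BED3+ file of precomputed annotations, tagging each with a class."""
    rows, rejected = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom = normalize_chrom(parts[0])
                start, end = int(parts[1]), int(parts[2])
            except (IndexError, ValueError):
                rejected.append(lineno)
                continue
            if start >= end or start < 0:
                rejected.append(lineno)
                continue
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            rows.append((chrom, start, end, structure_class, strand))
    if rejected:
        import logging
        logging.getLogger(__name__).warning(
            "rejected %d malformed BED line(s) at %s: lines %s",
            len(rejected), path, rejected[:10])
    return _annotations(rows)


def write_structure_bed(annotations: pd.DataFrame, path) -> None:
    bed = annotations[["chrom", "start", "end", "structure_class"]].copy()
    bed["score"] = 0
    bed["strand"] = annotations["strand"]
    bed.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True, eq=False)
class CoverageTrack:
    """Fraction of each window covered by one structure class's annotations."""
    structure_class: str
    windows: GenomicWindows
    coverage: np.ndarray

    @property
    def aggregation_level(self) -> int:
        return self.windows.size

    def to_tsv(self, path) -> None:
        out = self.windows.frame[["chrom", "start", "end"]].copy()
        out["coverage"] = self.coverage
        out.to_csv(path, sep="\t", index=False)


def coverage(annotations: pd.DataFrame, windows: GenomicWindows,
             structure_class: str | None = None) -> CoverageTrack:
    """Union coverage of annotation intervals per window.

    The union length of all annotation pieces intersecting a window is
    divided by the window width; splitting or duplicating annotations
    cannot change the result.
    """
    if structure_class is None:
        kinds = annotations["structure_class"].unique() if len(annotations) else []
        structure_class = kinds[0] if len(kinds) == 1 else "mixed"
    covered = np.zeros(windows.n, dtype=np.float64)
    for chrom, grp in annotations.groupby("chrom", sort=False):
        if chrom not in windows.chrom_lengths:
            continue
        length = windows.chrom_lengths[chrom]
        starts = np.clip(grp["start"].to_numpy(np.int64), 0, length)
        ends = np.clip(grp["end"].to_numpy(np.int64), 0, length)
        merged = _merge_arrays(starts, ends)
        first, nwin = windows._index_range(chrom)
        size = windows.size
        for s, e in merged:
            if e <= s:
                continue
            w0, w1 = s // size, (e - 1) // size
            for w in range(w0, w1 + 1):
                lo = max(s, w * size)
                hi = min(e, (w + 1) * size, length)
                covered[first + w] += max(hi - lo, 0)
    widths = windows.widths.astype(np.float64)
    return CoverageTrack(structure_class=structure_class, windows=windows,
                         coverage=covered / widths)


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    order = np.argsort(starts, kind="stable")
    out: list[tuple[int, int]] = []
    for s, e in zip(starts[order], ends[order]):
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((int(s), int(e)))
    return out
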