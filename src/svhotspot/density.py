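"""Breakpoint-density profiles, hotspot labeling and profile comparison.

A density profile assigns each genomic window the number of breakpoint ends
falling in it divided by the total number of ends for that cancer type, so
the profile is (up to ends spanning a window boundary) a probability
distribution over windows: the conditional probability P(A|B_i) of a
breakpoint landing in the window given cancer type B_i. The general cancer
profile mixes the per-cancer profiles with incidence weights P(B_i) via the
law of total probability, P(A) = sum_i P(A|B_i) P(B_i).

Hotspots are the top p% of windows by density (p in {1, 0.5, 0.1, 0.05,
0.01} by default), implemented as a deterministic top-k selection with
k = floor(p/100 * n_windows) and ties broken by genome order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicWindows

log = logging.getLogger(__name__)

#: hotspot labeling percentages used by default (percent of windows)
DEFAULT_LABELING_PERCENTS = (1.0, 0.5, 0.1, 0.05, 0.01)
#: window sizes (aggregation levels) used by default, in bp
DEFAULT_WINDOW_SIZES = (10_000, 20_000, 50_000, 100_000, 500_000, 1_000_000)


@dataclass(frozen=True, eq=False)
class DensityProfile:
    """Per-window breakpoint density for one cancer type (or "general")."""
    cancer_type: str
    windows: GenomicWindows
    densities: np.ndarray

    @property
    def aggregation_level(self) -> int:
        return self.windows.size

    def to_frame(self) -> pd.DataFrame:
        out = self.windows.frame[["chrom", "start", "end"]].copy()
        out["density"] = self.densities
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True, eq=False)
class HotspotLabeling:
    """Binary hotspot indicator per window for one (cancer, level, percent)."""
    cancer_type: str
    windows: GenomicWindows
    labeling_percent: float
    labels: np.ndarray

    @property
    def aggregation_level(self) -> int:
        return self.windows.size

    @property
    def n_positives(self) -> int:
        return int(self.labels.sum())

    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels)

    def to_bed(self, path, densities: np.ndarray | None = None) -> None:
        """Write hotspot windows as BED (name = cancer type, score = 1000*density)."""
        frame = self.windows.frame
        pos = self.positive_indices()
        bed = frame.iloc[pos][["chrom", "start", "end"]].copy()
        bed["name"] = self.cancer_type
        score = np.zeros(len(pos)) if densities is None else \
            np.round(1000.0 * np.asarray(densities)[pos])
        bed["score"] = score.astype(int)
        bed["strand"] = "."
        bed.to_csv(path, sep="\t", header=False, index=False)


def breakpoint_density(ends: pd.DataFrame, windows: GenomicWindows,
                       cancer_type: str | None = None) -> DensityProfile:
    """Count breakpoint ends per window and normalize by the total end count.

    An end is credited to every window its interval overlaps, so an end that
    straddles a window boundary contributes to both windows; the denominator
    is the number of ends, not of window assignments, hence the profile sum
    can marginally exceed 1.
    """
    if len(ends) == 0:
        raise ValueError("density is undefined for an empty set of ends")
    if cancer_type is None:
        kinds = ends["cancer_type"].unique() if "cancer_type" in ends else []
        cancer_type = kinds[0] if len(kinds) == 1 else "all"
    ends = ends.reset_index(drop=True)
    counts = np.zeros(windows.n, dtype=np.int64)
    size = windows.size
    first = np.empty(len(ends), dtype=np.int64)
    last = np.empty(len(ends), dtype=np.int64)
    for chrom, grp in ends.groupby("chrom", sort=False):
        off, nwin = windows._index_range(chrom)
        length = windows.chrom_lengths[chrom]
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        if (s >= length).any() or (e > length).any():
            raise ValueError(f"end interval outside chromosome {chrom!r}")
        first[grp.index] = off + s // size
        last[grp.index] = off + (e - 1) // size
    span = last - first
    np.add.at(counts, first, 1)
    for extra in range(1, int(span.max()) + 1 if len(span) else 1):
        sel = first[span >= extra] + extra
        np.add.at(counts, sel, 1)
    return DensityProfile(cancer_type=cancer_type, windows=windows,
                          densities=counts / float(len(ends)))


def load_incidence_weights(path, known_cancers) -> dict[str, float]:
    """Load cancer-incidence counts and turn them into mixture weights.

    The table is two columns (cancer type, new-case count), no header.
    Cancers in ``known_cancers`` missing from the table get the minimum
    available count; weights are normalized to sum to 1.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["cancer_type", "count"],
                     dtype={"cancer_type": str})
    if df.empty:
        raise ValueError(f"empty incidence table: {path}")
    counts = dict(zip(df["cancer_type"], df["count"].astype(float)))
    if any(v <= 0 for v in counts.values()):
        raise ValueError("incidence counts must be positive")
    floor = min(counts.values())
    for cancer in known_cancers:
        if cancer not in counts:
            log.info("cancer %r missing from incidence table; imputing minimum %g",
                     cancer, floor)
            counts[cancer] = floor
    total = sum(counts[c] for c in known_cancers)
    return {c: counts[c] / total for c in known_cancers}


def general_profile(profiles: list[DensityProfile],
                    weights: dict[str, float]) -> DensityProfile:
    """Incidence-weighted mixture of per-cancer profiles (total probability)."""
    if not profiles:
        raise ValueError("no profiles given")
    base = profiles[0].windows
    mixed = np.zeros(base.n)
    total_w = 0.0
    for p in profiles:
        if not p.windows.same_grid(base):
            raise ValueError("profiles are on different window grids")
        if p.cancer_type not in weights:
            raise ValueError(f"no incidence weight for cancer {p.cancer_type!r}")
        w = weights[p.cancer_type]
        mixed += w * p.densities
        total_w += w
    return DensityProfile(cancer_type="general", windows=base,
                          densities=mixed / total_w)


def profile_correlation(p1: DensityProfile, p2: DensityProfile,
                        per_chromosome: bool = False):
    """Spearman rank correlation of two density profiles over shared windows.

    With ``per_chromosome`` a mapping chromosome -> coefficient is returned;
    chromosomes with fewer than 3 windows are reported as NaN.
    """
    if not p1.windows.same_grid(p2.windows):
        raise ValueError("profiles are on different window grids")
    if not per_chromosome:
        return _spearman(p1.densities, p2.densities)
    chrom = p1.windows.frame["chrom"].to_numpy()
    return {c: _spearman(p1.densities[chrom == c], p2.densities[chrom == c])
            for c in p1.windows.chroms}


def _spearman(x, y) -> float:
    if len(x) < 3:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> NaN, reported as such
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def label_hotspots(profile: DensityProfile,
                   labeling_percent: float) -> HotspotLabeling:
    """Mark the top ``labeling_percent`` % of windows by density as hotspots.

    Exactly ``k = floor(percent/100 * n_windows)`` windows are labeled,
    selected by density descending with ties resolved in genome order;
    ``k = 0`` yields an empty (all-negative) labeling.
    """
    if not (0 < labeling_percent <= 100):
        raise ValueError("labeling_percent must be in (0, 100]")
    n = profile.windows.n
    if n == 0:
        raise ValueError("empty profile")
    k = int(np.floor(labeling_percent / 100.0 * n))
    labels = np.zeros(n, dtype=bool)
    if k > 0:
        order = np.lexsort((np.arange(n), -profile.densities))
        labels[order[:k]] = True
    return HotspotLabeling(cancer_type=profile.cancer_type,
                           windows=profile.windows,
                           labeling_percent=labeling_percent, labels=labels)


def prune_and_dedupe(labelings: list[HotspotLabeling], min_positives: int = 10):
    """Drop under-powered and duplicate hotspot labelings.

    Labelings with fewer than ``min_positives`` hotspot windows cannot
    support model fitting and are removed. Among labelings of the same
    (cancer, aggregation level) whose label vectors are identical —
    neighboring labeling percentages often select the same windows — only
    the one with the largest labeling percent is kept.

    Returns ``(kept, report)`` where report is a list of
    ``(cancer_type, aggregation_level, labeling_percent, reason)`` tuples.
    """
    report: list[tuple[str, int, float, str]] = []
    survivors: list[HotspotLabeling] = []
    for lab in labelings:
        if lab.n_positives < min_positives:
            report.append((lab.cancer_type, lab.aggregation_level,
                           lab.labeling_percent, f"fewer than {min_positives} hotspots"))
        else:
            survivors.append(lab)
    kept: list[HotspotLabeling] = []
    seen: dict[tuple, HotspotLabeling] = {}
    for lab in sorted(survivors, key=lambda l: -l.labeling_percent):
        key = (lab.cancer_type, lab.aggregation_level,
               lab.labels.tobytes())
        if key in seen:
            report.append((lab.cancer_type, lab.aggregation_level,
                           lab.labeling_percent,
                           f"duplicate of {seen[key].labeling_percent}% labeling"))
        else:
            seen[key] = lab
            kept.append(lab)
    order = {id(l): i for i, l in enumerate(labelings)}
    kept.sort(key=lambda l: order[id(l)])
    return kept, report


def jaccard(l1: HotspotLabeling, l2: HotspotLabeling) -> float:
    """Jaccard similarity of two hotspot sets on the same window grid."""
    if not l1.windows.same_grid(l2.windows):
        raise ValueError("labelings are on different window grids")
    union = int(np.logical_or(l1.labels, l2.labels).sum())
    if union == 0:
        log.warning("jaccard of two empty labelings defined as 0")
        return 0.0
    inter = int(np.logical_and(l1.labels, l2.labels).sum())
    return inter / union
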