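"""Genomic region sets (genes, promoters, UTRs, exons, introns) and
overlap statistics between breakpoint hotspots / ends and those regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import HotspotLabeling
from .genome import normalize_chrom

log = logging.getLogger(__name__)

#: the fixed region-category vocabulary
REGION_CATEGORIES = ("gene", "promoter", "downstream", "utr5", "utr3",
                     "coding_exon", "intron")


@dataclass
class RegionSet:
    """Named collections of half-open genomic intervals, one per category."""

    intervals: pd.DataFrame  # columns: chrom, start, end, category
    _merged: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        bad = set(self.intervals["category"]) - set(REGION_CATEGORIES)
        if bad:
            raise ValueError(f"unknown region categories: {sorted(bad)}")
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("region intervals must satisfy start < end")

    @property
    def categories(self) -> list[str]:
        return [c for c in REGION_CATEGORIES
                if c in set(self.intervals["category"])]

    def merged(self, category: str) -> dict[str, np.ndarray]:
        """Merged (disjoint, sorted) intervals per chromosome as an (m, 2) array."""
        if category not in self._merged:
            sub = self.intervals[self.intervals["category"] == category]
            self._merged[category] = {
                chrom: _merge(grp["start"].to_numpy(), grp["end"].to_numpy())
                for chrom, grp in sub.groupby("chrom")}
        return self._merged[category]


def _merge(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    order = np.argsort(starts, kind="stable")
    out = []
    cur_s = cur_e = None
    for s, e in zip(starts[order], ends[order]):
        if cur_s is None or s > cur_e:
            if cur_s is not None:
                out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _any_overlap(query: pd.DataFrame, merged: dict[str, np.ndarray]) -> np.ndarray:
    """Boolean: does each query interval overlap >= 1 bp of the merged set."""
    hit = np.zeros(len(query), dtype=bool)
    q = query.reset_index(drop=True)
    for chrom, grp in q.groupby("chrom", sort=False):
        iv = merged.get(chrom)
        if iv is None or len(iv) == 0:
            continue
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        # candidate merged interval: last one starting before the query end
        j = np.searchsorted(iv[:, 0], e, side="left") - 1
        ok = j >= 0
        ok[ok] = iv[j[ok], 1] > s[ok]
        hit[grp.index] = ok
    return hit


def read_region_bed(path) -> RegionSet:
    """Read a BED file whose 4th (name) column is the region category."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "category"],
                     dtype={0: str, 3: str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return RegionSet(df)


def regions_from_gff3(path, promoter_len: int = 1000,
                      downstream_len: int = 1000) -> RegionSet:
    """Derive the region categories from GFF3 gene models.

    Uses ``gene``, ``CDS``, ``five_prime_UTR`` and ``three_prime_UTR``
    features. Promoters are ``promoter_len`` bp upstream of the gene start
    and downstream regions ``downstream_len`` bp past the gene end, both
    strand-aware (defaults of 1 kb are conventional, not canonical).
    Introns are the gene body minus all exon features of the gene.
    """
    cols = ["chrom", "source", "feature", "start", "end",
            "score", "strand", "frame", "attributes"]
    gff = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols,
                      dtype={"chrom": str})
    gff["chrom"] = gff["chrom"].map(normalize_chrom)
    gff["start0"] = gff["start"].astype(np.int64) - 1  # GFF is 1-based closed
    gff["end0"] = gff["end"].astype(np.int64)
    rows = []

    def add(sub, category, start_col="start0", end_col="end0"):
        for _, r in sub.iterrows():
            rows.append((r["chrom"], r[start_col], r[end_col], category))

    genes = gff[gff["feature"] == "gene"]
    add(genes, "gene")
    for _, g in genes.iterrows():
        if g["strand"] == "-":
            prom = (g["end0"], g["end0"] + promoter_len)
            down = (g["start0"] - downstream_len, g["start0"])
        else:
            prom = (g["start0"] - promoter_len, g["start0"])
            down = (g["end0"], g["end0"] + downstream_len)
        for (s, e), cat in ((prom, "promoter"), (down, "downstream")):
            s = max(int(s), 0)
            if e > s:
                rows.append((g["chrom"], s, int(e), cat))
    add(gff[gff["feature"] == "CDS"], "coding_exon")
    add(gff[gff["feature"] == "five_prime_UTR"], "utr5")
    add(gff[gff["feature"] == "three_prime_UTR"], "utr3")

    exons = gff[gff["feature"] == "exon"]
    for _, g in genes.iterrows():
        sub = exons[(exons["chrom"] == g["chrom"]) &
                    (exons["start0"] >= g["start0"]) &
                    (exons["end0"] <= g["end0"])]
        if sub.empty:
            continue
        merged = _merge(sub["start0"].to_numpy(), sub["end0"].to_numpy())
        prev = g["start0"]
        for s, e in merged:
            if s > prev:
                rows.append((g["chrom"], int(prev), int(s), "intron"))
            prev = max(prev, e)
        if g["end0"] > prev:
            rows.append((g["chrom"], int(prev), int(g["end0"]), "intron"))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "category"]))


def region_overlap_stats(query, regions: RegionSet,
                         per_chromosome: bool = False) -> pd.DataFrame:
    """Percent of hotspot windows (or breakpoint ends) overlapping each category.

    ``query`` is either a :class:`HotspotLabeling` (the hotspot windows are
    the units) or a DataFrame of end intervals with chrom/start/end columns.
    Overlap means >= 1 bp intersection. Returns a DataFrame with columns
    ``category, n, n_overlap, percent`` (plus ``chrom`` when stratified).
    """
    if isinstance(query, HotspotLabeling):
        frame = query.windows.frame.iloc[query.positive_indices()]
        frame = frame[["chrom", "start", "end"]]
        if len(frame) == 0:
            log.warning("empty hotspot labeling: all overlaps reported as 0%%")
    else:
        frame = query[["chrom", "start", "end"]]
    frame = frame.reset_index(drop=True)
    out = []
    for cat in regions.categories:
        hits = _any_overlap(frame, regions.merged(cat))
        if per_chromosome:
            for chrom, grp in frame.groupby("chrom", sort=False):
                h = hits[grp.index]
                out.append((cat, chrom, len(grp), int(h.sum()),
                            100.0 * h.mean() if len(grp) else 0.0))
        else:
            n = len(frame)
            out.append((cat, n, int(hits.sum()),
                        100.0 * hits.mean() if n else 0.0))
    cols = (["category", "chrom", "n", "n_overlap", "percent"] if per_chromosome
            else ["category", "n", "n_overlap", "percent"])
    return pd.DataFrame(out, columns=cols)
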