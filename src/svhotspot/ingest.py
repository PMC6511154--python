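"""Reading ICGC-style structural somatic mutation tables into breakpoint ends.

Each structural-variant record names two breakpoint ends (a donor and an
acceptor chromosome position) together with a "range": the radius in bp
around the stated position that may contain the true breakpoint, i.e. the
positional uncertainty of the call. Missing ranges mean an exact call and
are imputed as 0; calls with a range above a threshold (default 10 bp,
which retains ~95% of ICGC calls) are discarded as too imprecise.

Positions are read as 1-based inclusive (ICGC convention) and converted to
0-based half-open intervals ``[pos - range - 1, pos + range)`` of length
``2*range + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DEFAULT_EXCLUDED_CHROMS, normalize_chrom

log = logging.getLogger(__name__)

#: default ICGC column-name mapping (internal field -> file column)
DEFAULT_DIALECT = {
    "donor_id": "icgc_donor_id",
    "cancer_type": "project_code",
    "chrom_from": "chr_from",
    "pos_from": "chr_from_bkpt",
    "range_from": "chr_from_range",
    "chrom_to": "chr_to",
    "pos_to": "chr_to_bkpt",
    "range_to": "chr_to_range",
    "sv_type": "variant_type",
}

_RECORD_COLUMNS = list(DEFAULT_DIALECT)


@dataclass
class IngestReport:
    """Row accounting for an ingest run."""
    n_rows: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    n_range_excluded: int = 0
    n_chrom_dropped_ends: int = 0
    n_clipped_ends: int = 0


def read_breakpoint_table(path, dialect: dict | None = None,
                          report: IngestReport | None = None) -> pd.DataFrame:
    """Parse a tab-separated structural mutation table.

    Returns a DataFrame of breakpoint records with the internal column names
    (``donor_id, cancer_type, chrom_from, pos_from, range_from, chrom_to,
    pos_to, range_to, sv_type``). Missing range cells are preserved as NaN at
    this stage. Rows whose positions cannot be parsed as positive integers
    are skipped and counted in the report.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty and raw.columns.size == 0:
        raise ValueError(f"empty breakpoint table: {path}")
    missing = [dialect[f] for f in _RECORD_COLUMNS if dialect[f] not in raw.columns]
    if missing:
        raise ValueError(
            f"breakpoint table {path} lacks mandatory column(s): {', '.join(missing)}")
    if raw.empty:
        raise ValueError(f"breakpoint table has a header but no rows: {path}")

    df = pd.DataFrame({f: raw[dialect[f]] for f in _RECORD_COLUMNS})
    for col in ("chrom_from", "chrom_to"):
        df[col] = df[col].map(normalize_chrom)

    pos_from = pd.to_numeric(df["pos_from"], errors="coerce")
    pos_to = pd.to_numeric(df["pos_to"], errors="coerce")
    ok = pos_from.notna() & pos_to.notna() & (pos_from >= 1) & (pos_to >= 1)
    for col in ("range_from", "range_to"):
        vals = df[col].str.strip()
        num = pd.to_numeric(vals.where(vals != "", np.nan), errors="coerce")
        # a non-empty, non-numeric or negative range cell is a malformed row
        ok &= (vals == "") | (num.notna() & (num >= 0))
        df[col] = num
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("skipped %d unparseable row(s) in %s", n_bad, path)
    df = df[ok].reset_index(drop=True)
    df["pos_from"] = pos_from[ok].astype(np.int64).to_numpy()
    df["pos_to"] = pos_to[ok].astype(np.int64).to_numpy()

    if report is not None:
        report.n_rows = len(raw)
        report.n_parsed = len(df)
        report.n_skipped = n_bad
    return df


def impute_missing_ranges(records: pd.DataFrame) -> pd.DataFrame:
    """Replace missing uncertainty ranges with 0 (an exact breakpoint call)."""
    out = records.copy()
    for col in ("range_from", "range_to"):
        out[col] = out[col].fillna(0).astype(np.int64)
    return out


def filter_by_range(records: pd.DataFrame, max_range: int = 10,
                    report: IngestReport | None = None) -> pd.DataFrame:
    """Drop records whose positional uncertainty exceeds ``max_range`` on either end."""
    if max_range < 0:
        raise ValueError("max_range must be non-negative")
    keep = (records["range_from"] <= max_range) & (records["range_to"] <= max_range)
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("range filter (> %d bp) excluded %d of %d records",
                 max_range, n_excluded, len(records))
    if report is not None:
        report.n_range_excluded = n_excluded
    return records[keep].reset_index(drop=True)


def explode_to_ends(records: pd.DataFrame,
                    exclude_chroms=DEFAULT_EXCLUDED_CHROMS,
                    report: IngestReport | None = None) -> pd.DataFrame:
    """Expand each record into its two breakpoint-end intervals.

    Each end becomes a 0-based half-open interval ``[pos - range - 1,
    pos + range)`` on its own chromosome; ends on excluded chromosomes
    (Y and MT by default) are dropped. Intervals that would extend below
    position 0 are clipped to 0 with a warning.
    """
    parts = []
    for side in ("from", "to"):
        part = pd.DataFrame({
            "cancer_type": records["cancer_type"],
            "chrom": records[f"chrom_{side}"],
            "start": records[f"pos_{side}"] - records[f"range_{side}"] - 1,
            "end": records[f"pos_{side}"] + records[f"range_{side}"],
            "donor_id": records["donor_id"],
        })
        parts.append(part)
    ends = pd.concat(parts, ignore_index=True)
    dropped = ends["chrom"].isin(set(exclude_chroms))
    if report is not None:
        report.n_chrom_dropped_ends = int(dropped.sum())
    ends = ends[~dropped].reset_index(drop=True)
    clipped = ends["start"] < 0
    if clipped.any():
        log.warning("clipped %d end interval(s) at position 0", int(clipped.sum()))
        ends.loc[clipped, "start"] = 0
    if report is not None:
        report.n_clipped_ends = int(clipped.sum())
    return ends


def normalized_chrom_counts(ends: pd.DataFrame,
                            chrom_lengths: dict[str, int]) -> dict[str, float]:
    """Breakpoint ends per bp for every chromosome (zero counts reported as 0)."""
    unknown = set(ends["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"ends on unknown chromosome(s): {sorted(unknown)}")
    counts = ends["chrom"].value_counts()
    return {c: float(counts.get(c, 0)) / chrom_lengths[c] for c in chrom_lengths}


def write_ends_bed(ends: pd.DataFrame, path) -> None:
    """Write breakpoint ends as BED6 (name = donor id, score = 0, strand = '.')."""
    bed = ends[["chrom", "start", "end", "donor_id"]].copy()
    bed["score"] = 0
    bed["strand"] = "."
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_ends_bed(path) -> pd.DataFrame:
    """Read a BED6 of breakpoint ends written by :func:`write_ends_bed`."""
    bed = pd.read_csv(path, sep="\t", header=None, dtype={0: str},
                      names=["chrom", "start", "end", "donor_id", "score", "strand"])
    bed["chrom"] = bed["chrom"].map(normalize_chrom)
    return bed[["chrom", "start", "end", "donor_id"]]
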