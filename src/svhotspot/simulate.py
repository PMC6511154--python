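"""Synthetic study-scale inputs: toy genomes with planted motifs, ICGC-style
breakpoint tables with a known window-level log-linear signal, and incidence
weight tables.

The generator exists so that every pipeline stage — ingest, density,
hotspot labeling, structure scanning, coverage, model fitting, evaluation —
runs end to end without downloads, and so that parameter recovery can be
checked against a planted truth. Breakpoint placement follows the same
structure the models assume: the per-window propensity of the *from* end is
log-linear in z-scored structure coverage with chosen coefficients
(plus Gaussian window noise), while the *to* end is uniform genome-wide, so
the from-ends carry all the signal and both-end counting merely dilutes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomicWindows, make_windows, sort_chroms
from .ingest import DEFAULT_DIALECT
from .structures import (CoverageTrack, STRUCTURE_CLASSES, g4_regex, revcomp)

_SV_TYPES = ("deletion", "insertion", "inversion",
             "intrachromosomal", "interchromosomal", "other")

#: default planted effect of each structure class on breakpoint propensity
DEFAULT_EFFECTS = {"SL_short": 1.5, "SL_long": -1.0, "G4": 1.0}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic inputs.

    Defaults describe a desk-scale study: a 600 kb genome in three
    chromosomes, three cancer types with 20 donors of 100 structural
    variants each, breakpoint positional uncertainty mostly <= 10 bp with
    some missing and a few large values, and a moderate planted log-linear
    effect of structure coverage on breakpoint placement.
    """
    chrom_lengths: dict = field(
        default_factory=lambda: {"1": 200_000, "2": 200_000, "3": 200_000})
    window_size: int = 10_000
    n_cancers: int = 3
    samples_per_cancer: int = 20
    breakpoints_per_sample: int = 100
    effect_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    baseline_logit: float = 0.0
    noise_sd: float = 0.3
    #: (share_zero, share_1to10, share_above10, share_missing); must sum to 1
    range_distribution: tuple = (0.35, 0.45, 0.05, 0.15)
    motifs_per_chrom: dict = field(
        default_factory=lambda: {"G4": 10, "SL_short": 10, "SL_medium": 5,
                                 "SL_long": 5})
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.range_distribution) - 1.0) > 1e-9:
            raise ValueError("range_distribution shares must sum to 1")

    @property
    def cancer_types(self) -> list[str]:
        return [f"CANCER{i + 1}" for i in range(self.n_cancers)]


def _plant_sequences(cls_name: str, rng) -> str:
    """A pattern-conforming motif instance for one structure class."""
    if cls_name == "G4":
        loops = rng.choice(list("AT"), size=3)
        return "GGG" + "GGG".join(loops) + "GGG"  # GGG?GGG?GGG?GGG, 15 bp
    cls = STRUCTURE_CLASSES[cls_name]
    stem = (cls.stem_min + cls.stem_max) // 2
    loop = min(5, cls.loop_max)
    while True:
        arm = "".join(rng.choice(list("ACGT"), size=stem))
        if "GGG" not in arm and "CCC" not in arm:
            break
    loop_seq = "".join(rng.choice(list("AT"), size=loop))
    return arm + loop_seq + revcomp(arm)


_G4_PLUS = g4_regex(base="G")
_G4_MINUS = g4_regex(base="C")


def _accidental_g4_spans(seq: str, planted: list[tuple[int, int]]):
    spans = []
    for pat in (_G4_PLUS, _G4_MINUS):
        for m in pat.finditer(seq):
            if (m.start(), m.end()) not in planted:
                spans.append((m.start(), m.end()))
    return spans


def generate_genome(config: SimulationConfig, seed: int | None = None):
    """I.i.d. random chromosomes with planted, recoverable structure motifs.

    Motifs are planted at least 50 bp apart with non-G flanks so that
    greedy quadruplex matching recovers the planted G4 intervals exactly;
    background segments that happen to contain a quadruplex motif (either
    strand) are re-randomized until none remain. Background stem-loop hits
    are *not* suppressed: mismatch-tolerant short inverted repeats occur at
    a few percent of the positions of any random sequence, so a stem-loop-
    free background does not exist; planted stem-loops are instead
    guaranteed to be among the scan hits.

    Returns ``(sequences, truth)`` where sequences maps chromosome ->
    string and truth is a DataFrame (chrom, start, end, structure_class).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sequences: dict[str, str] = {}
    truth_rows = []
    for chrom in sort_chroms(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        motifs = []
        for cls_name, count in config.motifs_per_chrom.items():
            motifs += [(cls_name, _plant_sequences(cls_name, rng))
                       for _ in range(count)]
        rng.shuffle(motifs)
        total_motif = sum(len(s) for _, s in motifs)
        gap = 60  # > 50 bp spacer plus non-G flanks
        need = total_motif + gap * (len(motifs) + 1)
        if need > length:
            raise ValueError(
                f"chromosome {chrom!r} ({length} bp) too short for "
                f"{len(motifs)} motifs (needs {need} bp)")
        # spread motifs over jittered slots, then fill background
        slack = length - total_motif - gap * (len(motifs) + 1)
        jitter = np.sort(rng.integers(0, slack + 1, size=len(motifs))) \
            if len(motifs) else np.array([], dtype=int)
        seq = rng.choice(list("ACGT"), size=length)
        planted_here = []
        cumlen = 0
        for k, ((cls_name, motif), jit) in enumerate(zip(motifs, jitter)):
            # sorted jitter keeps motifs ordered and >= gap apart
            start = (k + 1) * gap + cumlen + int(jit)
            seq[start:start + len(motif)] = list(motif)
            seq[start - 1] = "T"  # non-G/C flanks keep runs from extending
            seq[start + len(motif)] = "T"
            planted_here.append((cls_name, start, start + len(motif)))
            cumlen += len(motif)
        s = "".join(seq)
        g4_intervals = [(a, b) for c, a, b in planted_here if c == "G4"]
        protected = np.zeros(length, dtype=bool)
        for a, b in ((a, b) for _, a, b in planted_here):
            protected[a:b] = True
        for _ in range(50):
            bad = _accidental_g4_spans(s, g4_intervals)
            if not bad:
                break
            arr = np.frombuffer(s.encode("ascii"), dtype="S1").copy()
            for a, b in bad:
                # rewrite only unprotected bases; A/T can form neither G- nor
                # C-runs, so a cleared span cannot regenerate a quadruplex
                sel = np.arange(a, b)[~protected[a:b]]
                arr[sel] = rng.choice([b"A", b"T"], size=len(sel))
            s = arr.tobytes().decode("ascii")
        else:
            raise RuntimeError("could not clear accidental quadruplex motifs")
        sequences[chrom] = s
        truth_rows += [(chrom, a, b, c) for c, a, b in planted_here]
    truth = pd.DataFrame(truth_rows,
                         columns=["chrom", "start", "end", "structure_class"])
    return sequences, truth


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sequences:
            fh.write(f">{chrom}\n")
            s = sequences[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def smooth_coverage(n: int, rng, smoothing: int = 20,
                    scale: float = 0.2) -> np.ndarray:
    """A smooth random coverage-like vector in [0, 1].

    Uniform noise box-filtered over ``smoothing`` windows, scaled to a
    typical structure-coverage magnitude; emulates the spatial
    autocorrelation of real coverage tracks.
    """
    x = rng.uniform(size=n + smoothing)
    kernel = np.ones(smoothing) / smoothing
    sm = np.convolve(x, kernel, mode="valid")[:n]
    return np.clip(sm * 2 * scale, 0.0, 1.0)


def synthetic_coverage_tracks(windows: GenomicWindows, names=("SL_short",
                              "SL_long", "G4"), seed: int = 0,
                              smoothing: int = 20) -> dict[str, CoverageTrack]:
    """Independent smooth random coverage tracks on a window grid."""
    rng = np.random.default_rng(seed)
    return {name: CoverageTrack(structure_class=name, windows=windows,
                                coverage=smooth_coverage(windows.n, rng,
                                                         smoothing))
            for name in names}


def window_propensities(coverage_tracks: dict, effect_coefficients: dict,
                        baseline_logit: float, noise_sd: float,
                        rng) -> np.ndarray:
    """Per-window probability of hosting a from-end, log-linear in coverage."""
    names = list(effect_coefficients)
    first = coverage_tracks[names[0]]
    n = len(getattr(first, "coverage", first))
    logit = np.full(n, float(baseline_logit))
    for name, beta in effect_coefficients.items():
        vals = np.asarray(getattr(coverage_tracks[name], "coverage",
                                  coverage_tracks[name]), dtype=float)
        sd = vals.std()
        if sd == 0:
            raise ValueError(f"coverage track {name!r} is constant")
        logit += beta * (vals - vals.mean()) / sd
    if noise_sd > 0:
        logit += rng.normal(0.0, noise_sd, size=n)
    logit -= logit.max()
    p = np.exp(logit)
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate propensity vector")
    return p / total


def _draw_ranges(rng, n: int, dist) -> list[str]:
    share_zero, share_small, share_big, share_missing = dist
    cats = rng.choice(4, size=n, p=[share_zero, share_small, share_big,
                                    share_missing])
    out = []
    for c in cats:
        if c == 0:
            out.append("0")
        elif c == 1:
            out.append(str(int(rng.integers(1, 11))))
        elif c == 2:
            out.append(str(int(rng.integers(11, 101))))
        else:
            out.append("")
    return out


def generate_breakpoints(config: SimulationConfig, coverage_tracks: dict,
                         windows: GenomicWindows,
                         seed: int | None = None):
    """An ICGC-style breakpoint table whose from-ends follow the planted model.

    Per cancer type a propensity vector over windows is drawn from the
    log-linear model; each donor contributes ``breakpoints_per_sample``
    records whose from-end window follows the propensity (position uniform
    within the window) and whose to-end is uniform genome-wide. Range cells
    follow ``config.range_distribution`` with missing values emitted as
    empty strings.

    Returns ``(table, truth)``: the table uses the default ICGC column
    names; truth maps cancer type -> propensity vector.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frame = windows.frame
    chroms = list(windows.chrom_lengths)
    lengths = np.array([windows.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    rows = []
    truth: dict[str, np.ndarray] = {}
    for ci, cancer in enumerate(config.cancer_types):
        p = window_propensities(coverage_tracks, config.effect_coefficients,
                                config.baseline_logit, config.noise_sd, rng)
        truth[cancer] = p
        for s in range(config.samples_per_cancer):
            donor = f"DO{ci + 1:02d}{s + 1:04d}"
            nbp = config.breakpoints_per_sample
            widx = rng.choice(windows.n, size=nbp, p=p)
            wstart = frame["start"].to_numpy()[widx]
            wend = frame["end"].to_numpy()[widx]
            pos_from = rng.integers(wstart, wend) + 1  # 1-based
            chrom_from = frame["chrom"].to_numpy()[widx]
            cto = rng.choice(len(chroms), size=nbp, p=chrom_p)
            pos_to = np.array([int(rng.integers(1, lengths[j] + 1)) for j in cto])
            r_from = _draw_ranges(rng, nbp, config.range_distribution)
            r_to = _draw_ranges(rng, nbp, config.range_distribution)
            sv = rng.choice(_SV_TYPES, size=nbp)
            for i in range(nbp):
                rows.append((donor, cancer, chrom_from[i], int(pos_from[i]),
                             r_from[i], chroms[cto[i]], int(pos_to[i]),
                             r_to[i], sv[i]))
    d = DEFAULT_DIALECT
    table = pd.DataFrame(rows, columns=[
        d["donor_id"], d["cancer_type"], d["chrom_from"], d["pos_from"],
        d["range_from"], d["chrom_to"], d["pos_to"], d["range_to"],
        d["sv_type"]])
    return table, truth


def generate_incidence_weights(config: SimulationConfig,
                               seed: int | None = None) -> pd.DataFrame:
    """Positive incidence counts with one cancer deliberately omitted.

    The omitted cancer (the last one) exercises the minimum-count
    imputation rule in the weight loader.
    """
    if config.n_cancers < 2:
        raise ValueError("need at least 2 cancer types")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cancers = config.cancer_types[:-1]
    counts = rng.integers(50, 1001, size=len(cancers))
    return pd.DataFrame({"cancer_type": cancers, "count": counts})


def _toy_regions(config: SimulationConfig, rng) -> pd.DataFrame:
    """A few invented gene-like intervals per chromosome, BED+category."""
    rows = []
    for chrom, length in config.chrom_lengths.items():
        for _ in range(5):
            start = int(rng.integers(1000, max(length - 6000, 2000)))
            end = start + int(rng.integers(2000, 5000))
            rows.append((chrom, start, min(end, length), "gene"))
            rows.append((chrom, max(start - 1000, 0), start, "promoter"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])


def end_to_end_fixture(config: SimulationConfig | None = None,
                       out_dir=None, seed: int | None = None) -> dict:
    """Generate a complete desk-scale input set, optionally written to disk.

    Produces the toy genome FASTA, the breakpoint TSV, the incidence-weight
    TSV, a regions BED, a chromosome-length TSV and a ground-truth JSON.
    Deterministic: the same seed regenerates byte-identical files.
    """
    from .structures import scan_sequence, coverage as structure_coverage

    config = config or SimulationConfig()
    root_seed = config.seed if seed is None else seed
    sequences, motif_truth = generate_genome(config, seed=root_seed)
    windows = make_windows(config.chrom_lengths, config.window_size)
    annots = pd.concat([scan_sequence(sequences[c], chrom=c)
                        for c in sequences], ignore_index=True)
    tracks = {
        name: structure_coverage(
            annots[annots["structure_class"] == name], windows,
            structure_class=name)
        for name in STRUCTURE_CLASSES}
    table, propensities = generate_breakpoints(
        config, tracks, windows, seed=root_seed + 1)
    weights = generate_incidence_weights(config, seed=root_seed + 2)
    regions = _toy_regions(config, np.random.default_rng(root_seed + 3))
    truth = {
        "effect_coefficients": config.effect_coefficients,
        "baseline_logit": config.baseline_logit,
        "noise_sd": config.noise_sd,
        "propensities": {c: p.tolist() for c, p in propensities.items()},
        "seed": root_seed,
    }
    result = {"sequences": sequences, "motif_truth": motif_truth,
              "windows": windows, "tracks": tracks, "table": table,
              "weights": weights, "regions": regions, "truth": truth}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(sequences, out / "genome.fa")
        table.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
        weights.to_csv(out / "incidence.tsv", sep="\t", index=False,
                       header=False)
        regions.to_csv(out / "regions.bed", sep="\t", index=False,
                       header=False)
        pd.DataFrame({"chrom": list(config.chrom_lengths),
                      "length": list(config.chrom_lengths.values())}
                     ).to_csv(out / "chrom_lengths.tsv", sep="\t",
                              index=False, header=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return result
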