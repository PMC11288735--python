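"""Simplified CENH3 ChIP enrichment analysis.

Chromosomes are divided into 1-kb windows; the unique-read density of each
window (reads per mappable bp) is compared between the ChIP and input
libraries.  Windows are tested under a Poisson count model — the ChIP count
in a window is modelled as Poisson with mean equal to the input count scaled
by the library-size ratio — then Benjamini-Hochberg adjusted across all
windows with at least one input read.  Windows passing both fold-change > 5
and FDR < 0.001 are merged into CENH3-binding domains (islands), bridging up
to ``gap`` failing windows.  A per-repeat-cluster enrichment statistic
(ChIP/input hit ratio normalised by library sizes) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import GenomeAssembly, GenomicInterval


def window_density(
    reads: pd.DataFrame,
    genome: GenomeAssembly,
    window: int = 1000,
    mappable: dict[tuple[str, int], int] | None = None,
) -> pd.DataFrame:
    """Unique read-start counts and per-mappable-bp density in fixed windows.

    ``reads`` needs columns chrom, start (1-based).  Duplicate positions
    collapse to one ("unique reads").  Windows with zero mappable bp have
    missing density.  Returns every window of every chromosome (columns
    chrom, win_start, count, mappable_bp, density).
    """
    uniq = reads.drop_duplicates(subset=["chrom", "start"])
    counts: dict[tuple[str, int], int] = {}
    for chrom, start in zip(uniq["chrom"], uniq["start"]):
        if chrom not in genome:
            raise KeyError(f"read on unknown chromosome {chrom}")
        if not 1 <= start <= genome.length(chrom):
            raise ValueError(f"read start {start} outside {chrom}")
        w = (int(start) - 1) // window
        counts[(chrom, w)] = counts.get((chrom, w), 0) + 1
    rows = []
    for chrom in genome.names:
        clen = genome.length(chrom)
        for w in range((clen + window - 1) // window):
            win_start = w * window + 1
            width = min(window, clen - w * window)
            mbp = mappable.get((chrom, w), width) if mappable else width
            c = counts.get((chrom, w), 0)
            rows.append(
                {
                    "chrom": chrom,
                    "win_start": win_start,
                    "count": c,
                    "mappable_bp": mbp,
                    "density": c / mbp if mbp > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class IslandCall:
    """A called enrichment domain: merged run of significant windows."""

    interval: GenomicInterval
    mean_fold: float
    min_q: float
    n_windows: int


def call_domains(
    chip: pd.DataFrame,
    input_: pd.DataFrame,
    fold_min: float = 5.0,
    fdr_max: float = 0.001,
    gap: int = 1,
    window: int = 1000,
    chip_lib: int | None = None,
    input_lib: int | None = None,
) -> list[IslandCall]:
    """Call enrichment islands from matched ChIP and input window tracks.

    Only windows with >= 1 input read are testable (the expectation is
    otherwise undefined); p = P(Poisson(lambda) >= chip_count) with
    lambda = input_count * chip_lib/input_lib, BH-adjusted across testable
    windows.  Windows with q < ``fdr_max`` and fold > ``fold_min`` seed
    islands; runs separated by at most ``gap`` failing windows merge.
    """
    chip_lib = int(chip_lib if chip_lib is not None else chip["count"].sum())
    input_lib = int(input_lib if input_lib is not None else input_["count"].sum())
    if input_lib == 0:
        raise ValueError("empty input library")
    if chip_lib == 0:
        raise ValueError("empty ChIP library")
    merged = chip.merge(
        input_, on=["chrom", "win_start"], suffixes=("_chip", "_input"), how="inner"
    )
    ratio = chip_lib / input_lib
    testable = merged["count_input"] >= 1
    lam = merged.loc[testable, "count_input"].to_numpy() * ratio
    c = merged.loc[testable, "count_chip"].to_numpy()
    pvals = stats.poisson.sf(c - 1, lam)
    qvals = stats.false_discovery_control(pvals, method="bh")
    merged["p"] = np.nan
    merged["q"] = np.nan
    merged.loc[testable, "p"] = pvals
    merged.loc[testable, "q"] = qvals
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["fold"] = (merged["count_chip"] / chip_lib) / (
            merged["count_input"] / input_lib
        )
    merged["pass"] = (
        testable & (merged["q"] < fdr_max) & (merged["fold"] > fold_min)
    )

    islands: list[IslandCall] = []
    for chrom, sub in merged.groupby("chrom", sort=False):
        sub = sub.sort_values("win_start").reset_index(drop=True)
        run: list[int] = []
        last_pass = None
        for idx, row in sub.iterrows():
            if row["pass"]:
                if last_pass is not None and (idx - last_pass - 1) > gap:
                    islands.append(_make_island(sub, run, window))
                    run = []
                run.append(idx)
                last_pass = idx
        if run:
            islands.append(_make_island(sub, run, window))
    islands.sort(key=lambda isl: (isl.interval.chrom, isl.interval.start))
    return islands


def _make_island(sub: pd.DataFrame, run: list[int], window: int) -> IslandCall:
    first, last = sub.loc[run[0]], sub.loc[run[-1]]
    interval = GenomicInterval(
        str(first["chrom"]),
        int(first["win_start"]),
        int(last["win_start"]) + window - 1,
    )
    passing = sub.loc[run]
    return IslandCall(
        interval=interval,
        mean_fold=float(passing["fold"].mean()),
        min_q=float(passing["q"].min()),
        n_windows=len(run),
    )


@dataclass
class ClusterEnrichment:
    cluster_id: str
    chip_hits: int
    input_hits: int
    chip_lib: int
    input_lib: int
    fold: float
    genome_proportion: float


def cluster_enrichment(
    chip_hits: dict[str, int],
    input_hits: dict[str, int],
    chip_lib: int,
    input_lib: int,
) -> list[ClusterEnrichment]:
    """Per-cluster centromeric enrichment and genome proportion.

    fold = (chip/chip_lib) / (input/input_lib); genome_proportion =
    input/input_lib (the input library samples the genome uniformly).  A
    pseudocount of 1 is added to both hit counts when either is zero.
    """
    if chip_lib <= 0 or input_lib <= 0:
        raise ValueError("empty library")
    out = []
    for cluster in sorted(set(chip_hits) | set(input_hits)):
        c = chip_hits.get(cluster, 0)
        i = input_hits.get(cluster, 0)
        cc, ii = (c + 1, i + 1) if (c == 0 or i == 0) else (c, i)
        fold = (cc / chip_lib) / (ii / input_lib)
        out.append(
            ClusterEnrichment(
                cluster_id=cluster,
                chip_hits=c,
                input_hits=i,
                chip_lib=chip_lib,
                input_lib=input_lib,
                fold=fold,
                genome_proportion=i / input_lib,
            )
        )
    return out


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    """Interval Jaccard index (0 when on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
    union = a.span + b.span - inter
    return inter / union
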