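"""Centromere-targeting statistics.

Quantifies how element copies distribute relative to CENH3-binding domains:
inside/near/outside assignment, the percentage of copies overlapping
domains, a 100-replicate random-region permutation null, 100-kb binned
abundance tracks normalised to a maximum of 100, and nested-insertion
detection from the sequence immediately downstream of each copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CentelineError
from .seqio import GenomeAssembly, GenomicInterval, revcomp
import edlib


@dataclass
class DomainSet:
    """Non-overlapping CENH3-binding (or planted) intervals."""

    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end >= b.start:
                    raise ValueError(f"overlapping domains on {chrom}")

    @property
    def total_length(self) -> int:
        return sum(iv.span for iv in self.intervals)

    @property
    def lengths(self) -> list[int]:
        return [iv.span for iv in self.intervals]

    def on_chrom(self, chrom: str) -> list[GenomicInterval]:
        return sorted(
            (iv for iv in self.intervals if iv.chrom == chrom), key=lambda x: x.start
        )


def assign_domain_relation(
    element: GenomicInterval,
    domains: DomainSet,
    flank: int = 20_000,
    genome: GenomeAssembly | None = None,
) -> str:
    """'inside' (>= 1 bp overlap), 'near' (within ``flank`` bp), else 'outside'."""
    if genome is not None and element.chrom not in genome:
        raise KeyError(f"unknown chromosome {element.chrom}")
    best = None
    for dom in domains.on_chrom(element.chrom):
        if element.overlaps(dom):
            return "inside"
        d = element.distance_to(dom)
        best = d if best is None else min(best, d)
    if best is not None and best <= flank:
        return "near"
    return "outside"


def percent_in_domains(
    elements: Sequence[GenomicInterval], domains: DomainSet
) -> float:
    """100 x (number of elements overlapping any domain) / (number of elements)."""
    if not elements:
        raise ValueError("no elements")
    inside = sum(
        1 for e in elements if assign_domain_relation(e, domains) == "inside"
    )
    return 100.0 * inside / len(elements)


@dataclass
class NullResult:
    """Random-placement null distribution of the in-domain percentage."""

    replicates: list[float]
    seed: int
    mode: str = "per_domain"

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1))


def _place_random(
    rng: np.random.Generator,
    genome: GenomeAssembly,
    domains: DomainSet,
    mode: str,
    max_tries: int = 1000,
) -> DomainSet:
    placed: list[GenomicInterval] = []
    chrom_names = genome.names
    lengths = np.array([genome.length(c) for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    for dom in domains.intervals:
        span = dom.span
        for _ in range(max_tries):
            if mode == "per_domain":
                chrom = dom.chrom
            elif mode == "any_chrom":
                chrom = chrom_names[rng.choice(len(chrom_names), p=probs)]
            else:
                raise ValueError(f"unknown placement mode {mode!r}")
            clen = genome.length(chrom)
            if clen < span:
                continue
            start = int(rng.integers(1, clen - span + 2))
            cand = GenomicInterval(chrom, start, start + span - 1)
            if not any(cand.overlaps(p) for p in placed if p.chrom == chrom):
                placed.append(cand)
                break
        else:
            raise CentelineError("could not place random region after bounded retries")
    return DomainSet(placed)


def random_placement_null(
    genome: GenomeAssembly,
    domains: DomainSet,
    elements: Sequence[GenomicInterval],
    n_replicates: int = 100,
    seed: int = 0,
    mode: str = "per_domain",
) -> NullResult:
    """Re-place region sets of matched lengths uniformly at random.

    Each replicate draws one random interval per observed domain (preserving
    its length and, in the default ``per_domain`` mode, its chromosome),
    without overlap, and recomputes the in-domain percentage of the fixed
    element set against the random regions.
    """
    if domains.total_length > genome.total_length:
        raise ValueError("domains longer than the genome")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        random_set = _place_random(rng, genome, domains, mode)
        reps.append(percent_in_domains(elements, random_set))
    return NullResult(replicates=reps, seed=seed, mode=mode)


def binned_density(
    elements: Sequence[GenomicInterval],
    genome: GenomeAssembly,
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Per-bin covered fraction, rescaled so the densest bin reads 100.

    Returns columns chrom, bin_start (1-based), covered_bp, fraction,
    normalized.  With no elements, the track is all zero and left
    unnormalised (flagged by the ``normalized`` column being all zero).
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    rows = []
    covered: dict[tuple[str, int], int] = {}
    for e in elements:
        b0 = (e.start - 1) // bin_size
        b1 = (e.end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(e.start, b * bin_size + 1)
            hi = min(e.end, (b + 1) * bin_size)
            covered[(e.chrom, b)] = covered.get((e.chrom, b), 0) + (hi - lo + 1)
    for chrom in genome.names:
        clen = genome.length(chrom)
        for b in range((clen + bin_size - 1) // bin_size):
            width = min(bin_size, clen - b * bin_size)
            cov = covered.get((chrom, b), 0)
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b * bin_size + 1,
                    "covered_bp": cov,
                    "fraction": cov / width,
                }
            )
    df = pd.DataFrame(rows)
    peak = df["fraction"].max()
    df["normalized"] = 0.0 if peak == 0 else 100.0 * df["fraction"] / peak
    return df


def downstream_flank(
    element: GenomicInterval, genome: GenomeAssembly, flank: int = 150
) -> str:
    """Strand-aware downstream (3') flanking sequence, clipped at chromosome ends."""
    clen = genome.length(element.chrom)
    if element.strand == "-":
        lo = max(1, element.start - flank)
        if lo > element.start - 1:
            return ""
        return genome.fetch(GenomicInterval(element.chrom, lo, element.start - 1, "-"))
    hi = min(clen, element.end + flank)
    if element.end + 1 > hi:
        return ""
    return genome.fetch(GenomicInterval(element.chrom, element.end + 1, hi, "+"))


def detect_nested(
    elements: Sequence[GenomicInterval],
    donor_library: dict[str, str],
    genome: GenomeAssembly,
    flank: int = 150,
    min_identity: float = 0.8,
    min_len: int = 50,
) -> list[Optional[str]]:
    """Label each element with the donor family its downstream flank matches.

    The ``flank`` bp downstream of each element (3', strand-aware) is aligned
    against every donor sequence in both orientations; the element is called
    nested into the best-matching donor when the flank aligns at
    ``min_identity`` over at least ``min_len`` bp, else None.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    labels: list[Optional[str]] = []
    for e in elements:
        seq = downstream_flank(e, genome, flank)
        if len(seq) < min_len:
            labels.append(None)
            continue
        best_label, best_dist = None, None
        for name, donor in donor_library.items():
            for probe in (seq, revcomp(seq)):
                res = edlib.align(probe, donor.upper(), mode="HW", task="distance")
                d = res["editDistance"]
                if d < 0:
                    continue
                if (1.0 - d / len(probe)) >= min_identity:
                    if best_dist is None or d < best_dist:
                        best_label, best_dist = name, d
        labels.append(best_label)
    return labels
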