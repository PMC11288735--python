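"""Target-site duplications and junction base composition.

A TSD is the short direct repeat created on both sides of an insertion by
staggered endonuclease nicks: the longest suffix of the left flank that
recurs as a prefix of the right flank.  Junction position-frequency
matrices follow the field's numbering: position 1 is the first base of the
TSD and position 0 the base immediately upstream of it, so the 5' junction
window (10 bp upstream + 10 bp of TSD) covers positions -9..0 and 1..10.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .mining import TsdRecord
from .seqio import GenomeAssembly, GenomicInterval

BASE_ORDER = ("A", "C", "G", "T")


def detect_tsd(
    left_flank: str,
    right_flank: str,
    max_tsd: int = 30,
    min_report: int = 5,
    slack: int = 2,
    inner: int = 0,
    high_confidence_min: int = 10,
    element_id: str = "element",
) -> Optional[TsdRecord]:
    """Longest duplicated word across an insertion boundary, or None.

    The word is sought as a suffix of ``left_flank`` (ending ``d1`` bases
    before its end) that recurs as a prefix of ``right_flank`` (starting
    ``d2`` bases in).  ``inner`` is where the junction is expected to sit
    when the element boundaries are exact (flanks extracted with bases
    reaching into the interval put it at ``inner``, plain junction flanks at
    0); ``slack`` is the tolerated boundary-refinement error.  Candidates
    are ranked by length minus total junction deviation
    ``|d1 - inner| + |d2 - inner|`` — a longer word that merely drags the
    junction sideways (e.g. across a poly(A) tail whose bases happen to
    repeat upstream) cannot beat the true duplication — with ties broken by
    smaller deviation, then lexicographically.  Records shorter than
    ``high_confidence_min`` are reported but flagged low-confidence.
    """
    left = left_flank.upper()
    right = right_flank.upper()
    # (score, -deviation, tsd) maximised; store d1/d2 for flank extraction
    best: tuple[int, int, str, int, int] | None = None
    for d1 in range(inner + slack + 1):
        for d2 in range(inner + slack + 1):
            dev = abs(d1 - inner) + abs(d2 - inner)
            l_end = len(left) - d1
            limit = min(max_tsd, l_end, len(right) - d2)
            for k in range(limit, min_report - 1, -1):
                if left[l_end - k : l_end] == right[d2 : d2 + k]:
                    word = left[l_end - k : l_end]
                    cand = (k - dev, -dev, word, d1, d2)
                    if (
                        best is None
                        or cand[:2] > best[:2]
                        or (cand[:2] == best[:2] and word < best[2])
                    ):
                        best = cand
                    break  # longer k already failed at this offset pair
    if best is None:
        return None
    _score, _negdev, tsd, d1, d2 = best
    k = len(tsd)
    l_end = len(left) - d1 - k
    flank5 = left[max(0, l_end - 10) : l_end]
    r_pos = d2 + k
    flank3 = right[r_pos : r_pos + 10]
    return TsdRecord(
        element_id=element_id,
        tsd_sequence=tsd,
        length=k,
        high_confidence=k >= high_confidence_min,
        flank5=flank5,
        flank3=flank3,
    )


def extract_flanks(
    genome: GenomeAssembly,
    interval: GenomicInterval,
    width: int = 40,
    inner: int = 2,
) -> tuple[str, str]:
    """(left, right) assembly-orientation flanks around an element interval.

    Each flank reaches ``inner`` bp *into* the annotated interval: when a
    refined boundary is off by a base or two, the duplicated word would
    otherwise be clipped on one side and become unrecoverable.  The TSD
    detector's trimming slack must cover ``inner`` plus the worst expected
    boundary error (slack = inner + 2 with the defaults).
    """
    chrom_len = genome.length(interval.chrom)
    lo = max(1, interval.start - width)
    hi = min(chrom_len, interval.end + width)
    l_end = min(chrom_len, interval.start - 1 + inner)
    r_start = max(1, interval.end + 1 - inner)
    left = (
        genome.fetch(GenomicInterval(interval.chrom, lo, l_end)) if l_end >= lo else ""
    )
    right = (
        genome.fetch(GenomicInterval(interval.chrom, r_start, hi)) if hi >= r_start else ""
    )
    return left, right


def _matrix(contexts: list[tuple[int, str]], positions: list[int]) -> pd.DataFrame:
    """Position-frequency matrix from (position, base) observations."""
    counts = {p: {b: 0 for b in BASE_ORDER} for p in positions}
    skipped = {p: 0 for p in positions}
    for p, b in contexts:
        if b in counts[p]:
            counts[p][b] += 1
        else:
            skipped[p] += 1
    rows = []
    for p in positions:
        total = sum(counts[p].values())
        row = {"position": p, "n": total, "skipped": skipped[p]}
        for b in BASE_ORDER:
            row[b] = counts[p][b] / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def junction_matrix(
    records: Sequence[TsdRecord], side: str = "five_prime"
) -> pd.DataFrame:
    """Per-position base frequencies at an insertion junction.

    ``five_prime``: 10 bp upstream of the TSD (positions -9..0, where 0 is
    the base immediately upstream) plus the first 10 TSD bases (1..10).
    ``three_prime``: the last 10 TSD bases (-9..0, where 0 is the last TSD
    base) plus 10 bp downstream (1..10).  Records lacking context at a
    position are skipped per position, with the skip count reported.
    """
    if not records:
        raise ValueError("no TSD records")
    positions = list(range(-9, 11))
    obs: list[tuple[int, str]] = []
    for rec in records:
        tsd = rec.tsd_sequence.upper()
        if side == "five_prime":
            upstream = rec.flank5.upper()
            for p in positions:
                if p <= 0:  # -9..0 map to the last 10 flank bases
                    idx = len(upstream) + p - 1
                    if 0 <= idx < len(upstream):
                        obs.append((p, upstream[idx]))
                elif p <= len(tsd):
                    obs.append((p, tsd[p - 1]))
        elif side == "three_prime":
            downstream = rec.flank3.upper()
            for p in positions:
                if p <= 0:  # -9..0 map to the last 10 TSD bases
                    idx = len(tsd) + p - 1
                    if 0 <= idx < len(tsd):
                        obs.append((p, tsd[idx]))
                elif p - 1 < len(downstream):
                    obs.append((p, downstream[p - 1]))
        else:
            raise ValueError(f"unknown side {side!r}")
    return _matrix(obs, positions)


def crm_junction_matrix(records: Sequence[TsdRecord]) -> pd.DataFrame:
    """Junction matrix for 5-bp-TSD elements: 10 bp flank + TSD + 10 bp flank.

    Positions -10..-1 are the upstream flank, 1..5 the TSD, and 6..15 the
    downstream flank.
    """
    if not records:
        raise ValueError("no TSD records")
    positions = list(range(-10, 0)) + list(range(1, 16))
    obs: list[tuple[int, str]] = []
    for rec in records:
        up, tsd, down = (
            rec.flank5.upper(),
            rec.tsd_sequence.upper(),
            rec.flank3.upper(),
        )
        for p in positions:
            if p < 0:
                idx = len(up) + p
                if 0 <= idx < len(up):
                    obs.append((p, up[idx]))
            elif 1 <= p <= 5:
                if p - 1 < len(tsd):
                    obs.append((p, tsd[p - 1]))
            else:
                idx = p - 6
                if idx < len(down):
                    obs.append((p, down[idx]))
    return _matrix(obs, positions)


def gc_content(sequences: Iterable[str]) -> float:
    """(G+C) / (A+C+G+T) over all sequences; N excluded from both sides."""
    gc = at = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no counted bases")
    return gc / (gc + at)
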