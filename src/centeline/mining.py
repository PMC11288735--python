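"""Element discovery and classification.

Copies of a LINE family are found from an anchor sequence by exact k-mer
seeding, diagonal chaining, and edit-distance boundary refinement — a
self-contained seed-and-extend search standing in for a BLASTN scan with a
stringent E-value cutoff.  Candidate copies are then aligned to a full
reference element and classified:

* ``full_length`` — 5' truncation < 100 bp, internal deletion < 500 bp, and
  the 3' end present (LINE insertions are almost always complete at the 3'
  end because reverse transcription starts there);
* ``truncated``  — 5' end missing beyond the threshold but 3' end present;
* ``fragment``   — 3' end absent; excluded from copy-number counts.

ORF intactness is assessed at the sequence level only: both ORFs must retain
their start codon, terminal stop, reading frame, and be free of premature
stops when projected through the alignment onto the copy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import edlib
from Bio.Seq import Seq

from .errors import CentelineError
from .seqio import (
    GenomeAssembly,
    GenomicInterval,
    PairwiseAlignment,
    edit_align,
    revcomp,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ReferenceElement:
    """A full-length reference element with annotated substructure.

    Sub-intervals are 1-based inclusive positions in element coordinates.
    ORF1 and ORF2 are allowed to overlap.
    """

    sequence: str
    utr5: tuple[int, int]
    orf1: tuple[int, int]
    orf2: tuple[int, int]
    utr3: tuple[int, int]
    polyA: tuple[int, int]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("utr5", "orf1", "orf2", "utr3", "polyA"):
            s, e = getattr(self, name)
            if not (1 <= s <= e <= n):
                raise ValueError(f"{name} interval ({s},{e}) outside [1,{n}]")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TsdRecord:
    """A target-site duplication flanking one element copy."""

    element_id: str
    tsd_sequence: str
    length: int
    high_confidence: bool
    flank5: str = ""
    flank3: str = ""


@dataclass
class ElementAnnotation:
    """One mined (or planted) element copy with its classification."""

    element_id: str
    interval: GenomicInterval
    element_class: str  # full_length | truncated | fragment
    truncation5: int
    internal_deletion: int
    orf_status: str  # intact_both | disrupted
    identity: float = float("nan")
    tsd: Optional[TsdRecord] = None
    nested_into: Optional[str] = None

    def gff_attributes(self) -> dict[str, str]:
        attrs = {
            "ID": self.element_id,
            "element_class": self.element_class,
            "truncation5": str(self.truncation5),
            "internal_deletion": str(self.internal_deletion),
            "orf_status": self.orf_status,
        }
        if self.identity == self.identity:  # not NaN
            attrs["identity"] = f"{self.identity:.4f}"
        if self.tsd is not None:
            attrs["tsd"] = self.tsd.tsd_sequence
        if self.nested_into is not None:
            attrs["nested_into"] = self.nested_into
        return attrs


def copy_number(annotations: Iterable[ElementAnnotation]) -> int:
    """Copies counted = full-length + truncated; fragments are excluded."""
    return sum(1 for a in annotations if a.element_class in ("full_length", "truncated"))


# ---------------------------------------------------------------------------
# Seed-and-extend search
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            idx[kmer].append(i)
    return idx


def _cluster_hits(
    hits: list[tuple[int, int]], k: int, gap_break: int, diag_drift: int
) -> list[tuple[int, int, float]]:
    """Chain (genome_pos, anchor_pos) seed hits into (start0, end0, diagonal).

    Hits are bucketed by quantised alignment diagonal (genome_pos -
    anchor_pos) before chaining by genomic proximity: tandem copies sit on
    well-separated diagonals even when genomically adjacent and stay distinct,
    while stray hits from k-mers repeated inside the anchor fall into their
    own tiny clusters instead of breaking the main chain (they are discarded
    later by the minimum-hit-length filter).
    """
    buckets: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for g, a in hits:
        buckets[(g - a) // diag_drift].append((g, a))
    clusters: list[tuple[int, int, float]] = []
    for bucket_hits in buckets.values():
        bucket_hits.sort()
        cur: list[tuple[int, int]] = []

        def _close() -> None:
            diags = sorted(g - a for g, a in cur)
            clusters.append((cur[0][0], cur[-1][0] + k, float(diags[len(diags) // 2])))

        for g, a in bucket_hits:
            if cur and g - cur[-1][0] > gap_break:
                _close()
                cur = []
            cur.append((g, a))
        if cur:
            _close()
    return clusters


def _merge_clusters(
    clusters: list[tuple[int, int, float]], min_dist: int, diag_drift: int
) -> list[tuple[int, int]]:
    """Merge nearby clusters only when their diagonals agree.

    Pieces of one fragmented copy share a diagonal; adjacent distinct copies
    do not, and must stay separate candidates.
    """
    merged: list[list[float]] = []
    for s, e, d in sorted(clusters):
        if merged and s - merged[-1][1] <= min_dist and abs(d - merged[-1][2]) <= diag_drift:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e, d])
    return [(int(s), int(e)) for s, e, _ in merged]


def _aligned_core(
    aln: PairwiseAlignment, match_score: float = 1.0, penalty: float = -2.0
) -> tuple[int, int, int, int, float]:
    """Best-scoring contiguous core of an alignment, 0-based in each row.

    Column scores (+1 match, -2 mismatch or gap) are maximised over a
    contiguous window (Kadane), which trims the noisy flank-absorption
    columns a global alignment of a padded region necessarily carries at its
    ends.  Returns (q_first, q_last, t_first, t_last, identity) where the
    offsets index the ungapped sequences and identity is over core columns.
    """
    a, b = aln.aligned_a, aln.aligned_b
    n = len(a)
    if n == 0:
        raise CentelineError("empty alignment")
    # prefix coordinates of each row at every column
    q_at = [0] * n
    t_at = [0] * n
    qpos = tpos = 0
    for i in range(n):
        q_at[i], t_at[i] = qpos, tpos
        if a[i] != "-":
            qpos += 1
        if b[i] != "-":
            tpos += 1
    best = (float("-inf"), 0, 0)  # score, start col, end col
    run_score, run_start = 0.0, 0
    for i in range(n):
        is_match = a[i] == b[i] and a[i] not in "-N"
        s = match_score if is_match else penalty
        if run_score <= 0:
            run_score, run_start = s, i
        else:
            run_score += s
        if run_score > best[0]:
            best = (run_score, run_start, i)
    if best[0] <= 0:
        raise CentelineError("alignment has no positive-scoring core")
    _, c0, c1 = best
    # clip to columns where both rows have a letter
    while c0 <= c1 and (a[c0] == "-" or b[c0] == "-"):
        c0 += 1
    while c1 >= c0 and (a[c1] == "-" or b[c1] == "-"):
        c1 -= 1
    if c1 < c0:
        raise CentelineError("alignment has no aligned columns")
    matches = sum(1 for i in range(c0, c1 + 1) if a[i] == b[i] and a[i] not in "-N")
    cols = c1 - c0 + 1
    identity = matches / cols
    # Re-anchor each end at a clean run of consecutive match columns: near the
    # junctions the aligner can phase-shift through a short repeat (absorbing
    # the offset with a gap inside a homopolymer), leaving the first aligned
    # column on a false diagonal.  A 20-column pure-match run is unambiguous.
    run_len = 20

    def _is_match(i: int) -> bool:
        return a[i] == b[i] and a[i] not in "-N"

    run = 0
    for i in range(c0, c1 + 1):
        run = run + 1 if _is_match(i) else 0
        if run == run_len:
            c0 = i - run_len + 1
            break
    run = 0
    for i in range(c1, c0 - 1, -1):
        run = run + 1 if _is_match(i) else 0
        if run == run_len:
            c1 = i + run_len - 1
            break
    return q_at[c0], q_at[c1], t_at[c0], t_at[c1], identity


def _semiglobal(query: str, target: str) -> tuple[PairwiseAlignment, int]:
    """Align the full query to the best infix of the target (free target ends).

    Returns the gapped rows plus the 0-based target offset of the infix.
    Semiglobal alignment is essential for truncated copies: a global
    unit-cost alignment of a short copy against the full-length reference
    prefers a degenerate base-scattering over the biologically correct
    suffix alignment.
    """
    query, target = query.upper(), target.upper()
    res = edlib.align(query, target, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    aln = PairwiseAlignment(
        nice["query_aligned"], nice["target_aligned"], -res["editDistance"]
    )
    return aln, res["locations"][0][0]


def _xdrop_extend(
    qseq: str,
    tseq: str,
    q0: int,
    q1: int,
    t0: int,
    t1: int,
    xdrop: float = 8.0,
    mismatch: float = -2.0,
    min_gain: float = 3.0,
) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of an aligned core toward both ends.

    Recovers boundary bases that the global aligner scattered into the
    flanking junk zone: a full-length copy extends until the reference is
    exhausted, while a truncated copy stops at the junction.  The mismatch
    penalty exceeds the match reward and an extension is only accepted once
    it nets ``min_gain``, so AT-rich flanking sequence (a 50% chance match
    per base) cannot drag the boundary across the junction.
    """
    # leftward
    score, best, bi, bj = 0.0, min_gain - 1.0, q0, t0
    i, j = q0 - 1, t0 - 1
    while i >= 0 and j >= 0:
        score += 1.0 if (qseq[i] == tseq[j] and qseq[i] != "N") else mismatch
        if score > best:
            best, bi, bj = score, i, j
        if score < best - xdrop:
            break
        i -= 1
        j -= 1
    q0, t0 = bi, bj
    # rightward
    score, best, bi, bj = 0.0, min_gain - 1.0, q1, t1
    i, j = q1 + 1, t1 + 1
    while i < len(qseq) and j < len(tseq):
        score += 1.0 if (qseq[i] == tseq[j] and qseq[i] != "N") else mismatch
        if score > best:
            best, bi, bj = score, i, j
        if score < best - xdrop:
            break
        i += 1
        j += 1
    q1, t1 = bi, bj
    # terminal snap: a handful of leftover reference bases that match the
    # query exactly extend the boundary to the reference terminus even when
    # the gain is below min_gain — reaching the terminus is evidence itself
    snap = 5
    if 0 < t0 <= snap and t0 <= q0:
        if qseq[q0 - t0 : q0] == tseq[:t0] and "N" not in tseq[:t0]:
            q0, t0 = q0 - t0, 0
    tail = len(tseq) - 1 - t1
    if 0 < tail <= snap and q1 + tail < len(qseq):
        if qseq[q1 + 1 : q1 + 1 + tail] == tseq[t1 + 1 :] and "N" not in tseq[t1 + 1 :]:
            q1, t1 = q1 + tail, len(tseq) - 1
    return q0, q1, t0, t1


def find_element_copies(
    genome: GenomeAssembly,
    anchor: str,
    min_seed: int = 13,
    min_hit_len: int = 200,
    min_identity: float = 0.8,
    gap_break: int = 400,
    diag_drift: int = 300,
    region_slack: int = 30,
    merge_dist: int = 50,
) -> list[GenomicInterval]:
    """Find copies of ``anchor`` on both strands of a genome.

    Exact ``min_seed``-mers shared with the anchor are chained by genomic
    proximity and diagonal consistency; each chained region is refined by a
    global edit-distance alignment against the anchor, and kept when the
    aligned core reaches ``min_hit_len`` bp at ``min_identity``.
    """
    anchor = anchor.upper()
    k = min_seed
    if len(anchor) < k:
        raise ValueError(f"anchor ({len(anchor)} bp) shorter than seed length {k}")
    indexes = {"+": _kmer_index(anchor, k), "-": _kmer_index(revcomp(anchor), k)}
    out: list[GenomicInterval] = []
    for chrom, seq in genome:
        hits: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
        n = len(seq)
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            for strand in ("+", "-"):
                for a in indexes[strand].get(kmer, ()):
                    hits[strand].append((i, a))
        for strand in ("+", "-"):
            clusters = _cluster_hits(hits[strand], k, gap_break, diag_drift)
            regions = _merge_clusters(clusters, merge_dist, diag_drift)
            regions = [
                (max(0, s - region_slack), min(n, e + region_slack)) for s, e in regions
            ]
            for r0, r1 in regions:
                region = seq[r0:r1]
                oriented = revcomp(region) if strand == "-" else region
                aln, t_off = _semiglobal(oriented, anchor)
                q_first, q_last, t0, t1, ident = _aligned_core(aln)
                t0, t1 = t0 + t_off, t1 + t_off
                q_first, q_last, t0, t1 = _xdrop_extend(
                    oriented, anchor, q_first, q_last, t0, t1
                )
                core_len = q_last - q_first + 1
                if core_len < min_hit_len or ident < min_identity:
                    continue
                if strand == "+":
                    g_start0, g_end0 = r0 + q_first, r0 + q_last
                else:
                    m = r1 - r0
                    g_start0 = r0 + (m - 1 - q_last)
                    g_end0 = r0 + (m - 1 - q_first)
                out.append(GenomicInterval(chrom, g_start0 + 1, g_end0 + 1, strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _walk_alignment(
    aln: PairwiseAlignment, ref_offset: int, ref_len: int
) -> tuple[int, int, int, int]:
    """(truncation5, internal_deletion, ref_tail_missing, aligned columns).

    ``aln`` holds the copy against a reference infix starting at
    ``ref_offset`` (0-based); reference positions outside the infix count
    toward the 5' truncation and missing 3' tail respectively.
    """
    a, b = aln.aligned_a, aln.aligned_b  # a = copy, b = reference infix
    cols = len(a)
    first = last = -1
    for i in range(cols):
        if a[i] != "-" and b[i] != "-":
            if first < 0:
                first = i
            last = i
    if first < 0:
        raise CentelineError("element copy does not align to the reference")
    infix_letters = sum(1 for ch in b if ch != "-")
    trunc5 = ref_offset + sum(1 for i in range(first) if b[i] != "-")
    tail_in = sum(1 for i in range(last + 1, cols) if b[i] != "-")
    tail = tail_in + (ref_len - ref_offset - infix_letters)
    internal_del = sum(
        1 for i in range(first, last + 1) if b[i] != "-" and a[i] == "-"
    )
    return trunc5, internal_del, tail, last - first + 1


def classify_element(
    hit: GenomicInterval,
    genome: GenomeAssembly,
    reference: ReferenceElement,
    element_id: str = "element",
    three_prime_slack: int = 50,
    trunc_max: int = 100,
    internal_del_max: int = 500,
) -> ElementAnnotation:
    """Classify one mined copy against the full-length reference."""
    copy = genome.fetch(hit)
    aln, ref_off = _semiglobal(copy, reference.sequence)
    trunc5, internal_del, tail, _span = _walk_alignment(aln, ref_off, reference.length)
    three_prime_present = tail <= three_prime_slack
    if three_prime_present and trunc5 < trunc_max and internal_del < internal_del_max:
        cls = "full_length"
    elif three_prime_present:
        cls = "truncated"
    else:
        cls = "fragment"
    _q0, _q1, _t0, _t1, ident = _aligned_core(aln)
    orf = assess_orf_intactness(copy, reference, alignment=aln, ref_offset=ref_off)
    return ElementAnnotation(
        element_id=element_id,
        interval=hit,
        element_class=cls,
        truncation5=trunc5,
        internal_deletion=internal_del,
        orf_status=orf,
        identity=ident,
    )


def _project_orf(
    aln: PairwiseAlignment, orf: tuple[int, int], ref_offset: int = 0
) -> str:
    """Copy-side nucleotides projected onto a reference ORF interval.

    Insertion columns (gap in the reference) strictly inside the ORF are
    included, so frameshifting insertions change the projected length.
    """
    a, b = aln.aligned_a, aln.aligned_b
    s, e = orf
    tpos = ref_offset  # 1-based ref position of the current column's ref letter
    out = []
    inside = False
    for i in range(len(a)):
        if b[i] != "-":
            tpos += 1
            inside = s <= tpos <= e
            if inside and a[i] != "-":
                out.append(a[i])
        else:
            if inside and tpos < e and a[i] != "-":
                out.append(a[i])
    return "".join(out)


def assess_orf_intactness(
    element_seq: str,
    reference: ReferenceElement,
    alignment: PairwiseAlignment | None = None,
    ref_offset: int = 0,
) -> str:
    """``intact_both`` iff both projected ORFs translate cleanly.

    Each ORF projection must keep length divisible by 3, start with ATG, end
    with a stop codon, and contain no premature stop.  Anything unalignable
    is ``disrupted``.
    """
    try:
        if alignment is None:
            alignment, ref_offset = _semiglobal(element_seq, reference.sequence)
        aln = alignment
        for orf in (reference.orf1, reference.orf2):
            seq = _project_orf(aln, orf, ref_offset)
            if len(seq) == 0 or len(seq) % 3 != 0:
                return "disrupted"
            if not seq.startswith("ATG"):
                return "disrupted"
            if seq[-3:] not in STOP_CODONS:
                return "disrupted"
            protein = str(Seq(seq[:-3]).translate())
            if "*" in protein:
                return "disrupted"
    except CentelineError:
        return "disrupted"
    return "intact_both"
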