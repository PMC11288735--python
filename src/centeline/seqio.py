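"""Sequence/interval containers, coordinate conventions, and pairwise alignment.

Internal coordinates are 1-based inclusive throughout the package, so the
span of an interval is ``end - start + 1`` (a convention under which the
representative 6,114-bp element on poplar chromosome 11 spans exactly
10,103,867..10,109,980).  BED files are converted to and from 0-based
half-open coordinates at the I/O boundary only.

Two alignment engines are exposed:

* :func:`align_global` — optimal global alignment under an explicit
  match/mismatch/affine-gap scoring scheme (Needleman–Wunsch via
  ``Bio.Align.PairwiseAligner``).  Used where the scoring scheme matters.
* :func:`edit_align` — unit-cost edit-distance alignment via ``edlib``,
  orders of magnitude faster on kilobase-scale element copies.  Used for
  bulk identity computation and boundary refinement.

Identity is always recomputed from the gapped rows by the same column rule
(see :meth:`PairwiseAlignment.identity`), so the two engines agree on
substitution-only divergence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidIntervalError, ParseError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Intervals and assemblies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise InvalidIntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise InvalidIntervalError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if they overlap)."""
        if self.chrom != other.chrom:
            raise ValueError("intervals on different chromosomes")
        if self.overlaps(other):
            return 0
        if self.end < other.start:
            return other.start - self.end - 1
        return self.start - other.end - 1


def span_length(interval: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (= end - start + 1)."""
    return interval.span


class GenomeAssembly:
    """An ordered collection of named chromosome sequences over {A,C,G,T,N}."""

    def __init__(self, chromosomes: Sequence[tuple[str, str]]):
        names = [n for n, _ in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, seq in chromosomes:
            bad = set(seq.upper()) - DNA_ALPHABET
            if bad:
                raise ValueError(f"chromosome {name} contains non-DNA letters {bad}")
        self._chroms: dict[str, str] = {n: s.upper() for n, s in chromosomes}

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._chroms.items())

    def sequence(self, name: str) -> str:
        return self._chroms[name]

    def length(self, name: str) -> int:
        return len(self._chroms[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._chroms.values())

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval; reverse-complemented for '-' strand."""
        if interval.chrom not in self._chroms:
            raise KeyError(f"unknown chromosome {interval.chrom}")
        seq = self._chroms[interval.chrom]
        if interval.end > len(seq):
            raise InvalidIntervalError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {len(seq)}"
            )
        sub = seq[interval.start - 1 : interval.end]
        return revcomp(sub) if interval.strand == "-" else sub


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class PairwiseAlignment:
    """Two gapped rows of equal length plus the alignment score."""

    aligned_a: str
    aligned_b: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped rows differ in length")

    def identity(self, mode: str = "exclude_terminal_gaps") -> float:
        """Fraction of identical columns among counted columns.

        A column counts as identical only when both letters are equal and
        neither is a gap or N.  ``all_columns`` counts every column;
        ``exclude_terminal_gaps`` drops leading/trailing columns where either
        row has a gap overhang.
        """
        a, b = self.aligned_a.upper(), self.aligned_b.upper()
        n = len(a)
        if mode == "all_columns":
            lo, hi = 0, n
        elif mode == "exclude_terminal_gaps":
            lo, hi = 0, n
            while lo < n and (a[lo] == "-" or b[lo] == "-"):
                lo += 1
            while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
                hi -= 1
        else:
            raise ValueError(f"unknown identity mode {mode!r}")
        counted = hi - lo
        if counted == 0:
            raise ValueError("identity undefined: zero counted columns")
        matches = sum(
            1 for i in range(lo, hi) if a[i] == b[i] and a[i] not in "-N"
        )
        return matches / counted


def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    from Bio.Align import substitution_matrices

    letters = "ACGTN"
    mat = substitution_matrices.Array(alphabet=letters, dims=2)
    for x in letters:
        for y in letters:
            # N never matches anything, including N
            mat[x, y] = match if (x == y and x != "N") else mismatch
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_global(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment under an affine-gap scheme.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  The result
    is deterministic: ties between co-optimal alignments are broken by the
    engine's canonical enumeration order.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def pairwise_identity(
    aln: PairwiseAlignment, mode: str = "exclude_terminal_gaps"
) -> float:
    """Identity of an alignment under the declared column-counting mode."""
    return aln.identity(mode)


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, columns, leading gap run, trailing gap run) from an edlib cigar."""
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    matches = sum(n for n, op in ops if op == "=")
    columns = sum(n for n, _ in ops)
    lead = ops[0][0] if ops and ops[0][1] in "ID" else 0
    trail = ops[-1][0] if ops and ops[-1][1] in "ID" else 0
    return matches, columns, lead, trail


def edit_align(query: str, target: str, mode: str = "NW") -> PairwiseAlignment:
    """Unit-cost edit-distance alignment (edlib) returning gapped rows.

    ``mode='NW'`` is global; ``mode='HW'`` aligns the full query to the best
    infix of the target.  Row order is (query, target).
    """
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    res = edlib.align(query.upper(), target.upper(), mode=mode, task="path")
    nice = edlib.getNiceAlignment(res, query.upper(), target.upper())
    return PairwiseAlignment(nice["query_aligned"], nice["target_aligned"], -res["editDistance"])


def edit_identity(a: str, b: str, mode: str = "all_columns") -> float:
    """Fast global identity from the edlib cigar without materialising rows.

    Matching columns / counted columns; with ``exclude_terminal_gaps`` the
    leading and trailing pure-gap runs are dropped from the denominator.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches, columns, lead, trail = _cigar_stats(res["cigar"])
    if mode == "exclude_terminal_gaps":
        columns -= lead + trail
    if columns == 0:
        raise ValueError("identity undefined: zero counted columns")
    return matches / columns


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly` (order preserved)."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((rec.id, str(rec.seq)))
    except ValueError as exc:
        raise ParseError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return GenomeAssembly(records)


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name->sequence mapping (no alphabet check)."""
    out: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise ParseError(f"malformed FASTA in {path}: {exc}") from exc
    if not out:
        raise ParseError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) records as 60-column wrapped FASTA."""
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def interval_to_bed(interval: GenomicInterval) -> tuple[str, int, int]:
    """Convert a 1-based inclusive interval to BED 0-based half-open."""
    return interval.chrom, interval.start - 1, interval.end


def bed_to_interval(
    chrom: str, start0: int, end0: int, strand: str = "."
) -> GenomicInterval:
    """Convert BED 0-based half-open coordinates to internal 1-based inclusive."""
    return GenomicInterval(chrom, start0 + 1, end0, strand)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into internal intervals."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{i}: BED line has <3 fields")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer BED coordinate") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            out.append(bed_to_interval(parts[0], start0, end0, strand))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
) -> None:
    """Write intervals as BED6 (name column optional, score fixed at 0)."""
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            chrom, s0, e0 = interval_to_bed(iv)
            name = names[i] if names else f"region{i + 1}"
            fh.write(f"{chrom}\t{s0}\t{e0}\t{name}\t0\t{iv.strand if iv.strand != '.' else '.'}\n")


def write_gff3(
    features: Iterable[tuple[GenomicInterval, str, dict[str, str]]],
    path: str | Path,
    source: str = "centeline",
) -> None:
    """Write (interval, feature_type, attributes) triples as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype, attrs in features:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != '.' else '.'}\t.\t{attr_str}\n"
            )


def read_gff3(path: str | Path) -> list[tuple[GenomicInterval, str, dict[str, str]]]:
    """Read GFF3 rows back into (interval, feature_type, attributes) triples."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{i}: GFF3 line has {len(parts)} fields")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            attr_d = {}
            for item in attrs.split(";"):
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attr_d[k] = v
            out.append(
                (
                    GenomicInterval(chrom, int(start), int(end), strand if strand in "+-" else "."),
                    ftype,
                    attr_d,
                )
            )
    return out
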