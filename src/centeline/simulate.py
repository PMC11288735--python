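"""Synthetic genomes with planted LINE insertions of known age.

The simulator emulates the study system at a configurable (by default
desk-sized) scale: a multi-chromosome background genome at 33.8% GC, one
CENH3-like domain per chromosome, a library of LTR-retrotransposon donor
copies, and a master LINE element amplified at known times.  Each planted
copy is

* mutated by a Poisson(2 * mu * age * L) substitution process — the factor 2
  models divergence accumulating on both the source and the copy lineage, so
  highest-pairwise-identity dating with age = (1 - identity) / (2 * mu)
  recovers the planted age;
* optionally 5'-truncated (LINE reverse transcription frequently aborts
  before reaching the 5' end);
* inserted at a site whose 5' junction matches a sampled endonuclease nick
  motif (AAGA/AATA by default) when one is available nearby, flanked by an
  exact target-site duplication of 10-30 bp (mean 15);
* optionally nested into a previously planted donor LTR interval.

Insertions are planted oldest-first and never inside previously planted
copies of the same family, so every truth-table interval extracts verbatim
from the emitted assembly.  All randomness flows through one
``numpy.random.Generator``; a fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mining import STOP_CODONS, ReferenceElement
from .seqio import GenomeAssembly, GenomicInterval, revcomp
from .targeting import DomainSet

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the study conditions at 1/20 scale.

    ``mu`` is substitutions per bp per year; ``gc_background`` matches the
    poplar genome-wide 33.8% GC; ``domain_length_range`` is the reported
    427-1,267 kb CENH3 domain size range scaled down by 20; TSD lengths are
    10 + Binomial(20, 0.25), i.e. integers on [10, 30] with mean 15.
    """

    n_chromosomes: int = 3
    chrom_length: int = 150_000
    gc_background: float = 0.338
    mu: float = 1.3e-8
    n_insertions: int = 60
    age_distribution: tuple[str, dict] = ("exponential", {"mean": 5.0e5})
    tsd_min: int = 10
    tsd_binomial_n: int = 20
    tsd_binomial_p: float = 0.25
    p_truncation: float = 0.6
    truncation_min: int = 100
    nick_motifs: dict[str, float] = field(
        default_factory=lambda: {"AAGA": 1.0, "AATA": 1.0}
    )
    motif_window: int = 60
    domain_length_range: tuple[int, int] = (21_350, 63_350)
    p_target_in_domain: float = 0.84
    p_nested: float = 0.65
    n_donors: int = 8
    donor_length: int = 5_000
    polyA_length: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.gc_background,
            self.p_truncation,
            self.p_target_in_domain,
            self.p_nested,
            self.tsd_binomial_p,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0,1]")
        if self.mu <= 0:
            raise ConfigError("mu must be positive")
        if self.chrom_length <= 0 or self.n_chromosomes <= 0:
            raise ConfigError("genome dimensions must be positive")
        if self.domain_length_range[1] >= self.chrom_length:
            raise ConfigError("domain longer than chromosome")
        if self.domain_length_range[0] > self.domain_length_range[1]:
            raise ConfigError("empty domain length range")


@dataclass
class TruthRecord:
    """Ground truth for one planted insertion."""

    insertion_id: str
    interval: GenomicInterval
    strand: str
    age_years: float
    tsd: str
    truncation5: int
    nested_into: Optional[str]
    intact_orfs: bool
    n_substitutions: int
    motif_matched: bool
    sequence: str  # copy in element orientation, incl. poly(A) tail


@dataclass
class DonorRecord:
    donor_id: str
    interval: GenomicInterval


@dataclass
class Simulation:
    """Bundle of everything one simulator run produced."""

    genome: GenomeAssembly
    domains: DomainSet
    master: ReferenceElement
    truth: list[TruthRecord]
    donors: list[DonorRecord]
    donor_library: dict[str, str]
    config: SimConfig


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense codons (no stop codons)."""
    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]
    idx = rng.choice(len(sense), size=n)
    return "".join(sense[i] for i in idx)


def make_master_element(
    rng: np.random.Generator | int = 0,
    utr5_len: int = 635,
    orf1_len: int = 1617,
    orf2_len: int = 3765,
    utr3_len: int = 85,
    polyA_len: int = 12,
    gc: float = 0.338,
) -> ReferenceElement:
    """Build a synthetic full-length master element with intact ORFs.

    The default layout (635 + 1617 + 3765 + 85 + 12) totals 6,114 bp, the
    length of the representative full-length element.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    for L in (orf1_len, orf2_len):
        if L % 3 != 0 or L < 9:
            raise ConfigError("ORF lengths must be multiples of 3 and >= 9")
    utr5 = _random_seq(rng, utr5_len, gc)
    orf1 = "ATG" + _random_codons(rng, orf1_len // 3 - 2) + "TAA"
    orf2 = "ATG" + _random_codons(rng, orf2_len // 3 - 2) + "TAA"
    utr3 = _random_seq(rng, utr3_len, gc)
    seq = utr5 + orf1 + orf2 + utr3 + "A" * polyA_len
    o1 = (utr5_len + 1, utr5_len + orf1_len)
    o2 = (o1[1] + 1, o1[1] + orf2_len)
    u3 = (o2[1] + 1, o2[1] + utr3_len)
    pa = (u3[1] + 1, u3[1] + polyA_len)
    return ReferenceElement(
        sequence=seq, utr5=(1, utr5_len), orf1=o1, orf2=o2, utr3=u3, polyA=pa
    )


def simulate_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeAssembly, DomainSet]:
    """Background assembly plus one non-overlapping domain per chromosome."""
    rng = rng or np.random.default_rng(cfg.seed)
    chroms = []
    domains = []
    for i in range(cfg.n_chromosomes):
        name = f"chr{i + 1}"
        seq = _random_seq(rng, cfg.chrom_length, cfg.gc_background)
        chroms.append((name, seq))
        dlen = int(rng.integers(cfg.domain_length_range[0], cfg.domain_length_range[1] + 1))
        start = int(rng.integers(1, cfg.chrom_length - dlen + 2))
        domains.append(GenomicInterval(name, start, start + dlen - 1))
    return GenomeAssembly(chroms), DomainSet(domains)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _sample_age(rng: np.random.Generator, dist: tuple[str, dict]) -> float:
    name, params = dist
    if name == "exponential":
        return float(rng.exponential(params["mean"]))
    if name == "uniform":
        return float(rng.uniform(params["low"], params["high"]))
    if name == "fixed":
        return float(params["age"])
    raise ConfigError(f"unknown age distribution {name!r}")


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    if n_sub == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for p in pos:
        old = arr[p].decode()
        choices = [b for b in "ACGT" if b != old]
        arr[p] = choices[rng.integers(3)].encode()
    return arr.tobytes().decode()


def _orfs_intact(copy: str, master: ReferenceElement, truncation: int) -> bool:
    """ORF check on a substitution-only mutated, possibly truncated copy."""
    for s, e in (master.orf1, master.orf2):
        if truncation >= s:
            return False
        sub = copy[s - 1 : e]
        if not sub.startswith("ATG") or sub[-3:] not in STOP_CODONS:
            return False
        for i in range(0, len(sub) - 3, 3):
            if sub[i : i + 3] in STOP_CODONS:
                return False
    return True


class _Planter:
    """Mutable per-chromosome sequences plus coordinate bookkeeping."""

    def __init__(self, genome: GenomeAssembly, domains: DomainSet):
        self.seqs: dict[str, str] = {name: seq for name, seq in genome}
        self.domains: dict[str, list[int]] = {}  # chrom -> [start, end] 1-based
        for iv in domains.intervals:
            self.domains[iv.chrom] = [iv.start, iv.end]
        self.features: list[dict] = []  # planted copies and donors

    def in_domain(self, chrom: str, pos0: int) -> bool:
        dom = self.domains.get(chrom)
        return dom is not None and dom[0] - 1 <= pos0 < dom[1]

    def blocked(self, chrom: str, lo0: int, hi0: int, margin: int = 2) -> bool:
        """True when 0-based [lo0, hi0) comes too close to a planted copy."""
        for f in self.features:
            if f["chrom"] != chrom or f["kind"] == "donor":
                continue
            if lo0 < f["end"] + margin and f["start"] - 1 - margin < hi0:
                return True
        return False

    def insert(self, chrom: str, p0: int, tsd_len: int, insert_seq: str) -> tuple[int, int, str]:
        """Insert at 0-based point p0 duplicating the next ``tsd_len`` bases.

        Returns the 1-based inclusive interval of the inserted copy and the
        TSD sequence.  All previously planted features and the domain are
        shifted/grown consistently.
        """
        s = self.seqs[chrom]
        tsd = s[p0 : p0 + tsd_len]
        delta = len(insert_seq) + tsd_len
        self.seqs[chrom] = s[: p0 + tsd_len] + insert_seq + s[p0:]
        for f in self.features:
            if f["chrom"] != chrom:
                continue
            if f["start"] - 1 >= p0:
                f["start"] += delta
                f["end"] += delta
            elif f["end"] > p0:  # insertion point inside the feature: it grows
                f["end"] += delta
        dom = self.domains.get(chrom)
        if dom is not None:
            if dom[0] - 1 >= p0:
                dom[0] += delta
                dom[1] += delta
            elif dom[1] > p0:
                dom[1] += delta
        start1 = p0 + tsd_len + 1
        end1 = p0 + tsd_len + len(insert_seq)
        return start1, end1, tsd


def _find_motif_site(
    seq: str, p0: int, motif: str, window: int, lo0: int, hi0: int
) -> Optional[int]:
    """Nearest q in [p0-window, p0+window] with seq[q-2:q+2] == motif.

    The motif spans junction positions (-1, 0, 1, 2): its first two bases are
    the last two bases upstream of the TSD and its last two are the first two
    TSD bases.  q is the 0-based TSD start; the search respects [lo0, hi0).
    """
    for off in range(window + 1):
        for q in (p0 + off, p0 - off) if off else (p0,):
            if q - 2 < lo0 or q + 2 > hi0:
                continue
            if seq[q - 2 : q + 2] == motif:
                return q
    return None


def plant_insertions(
    genome: GenomeAssembly,
    domains: DomainSet,
    master: ReferenceElement,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> Simulation:
    """Plant donor LTR copies then LINE insertions; return the full bundle."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    planter = _Planter(genome, domains)

    # donor LTR-element copies (exact copies of one random donor master)
    donor_master = _random_seq(rng, cfg.donor_length, cfg.gc_background)
    donor_library = {"CRM_donor": donor_master}
    for d in range(cfg.n_donors):
        chrom, p0 = _sample_site(rng, planter, cfg, want_domain=rng.random() < cfg.p_target_in_domain)
        planter.insert(chrom, p0, 5, donor_master)
        s = p0 + 5 + 1
        planter.features.append(
            {
                "kind": "donor",
                "id": f"donor{d + 1}",
                "chrom": chrom,
                "start": s,
                "end": s + cfg.donor_length - 1,
            }
        )

    # sample all insertion parameters up front, plant oldest first
    ages = sorted(
        (_sample_age(rng, cfg.age_distribution) for _ in range(cfg.n_insertions)),
        reverse=True,
    )
    motifs = list(cfg.nick_motifs)
    weights = np.array([cfg.nick_motifs[m] for m in motifs], dtype=float)
    weights /= weights.sum()

    truth: list[TruthRecord] = []
    full_len = master.length
    for i, age in enumerate(ages):
        n_sub = int(rng.poisson(2.0 * cfg.mu * age * full_len))
        copy = _mutate(rng, master.sequence, n_sub)
        truncation = 0
        if rng.random() < cfg.p_truncation:
            trunc_max = full_len - 600
            truncation = int(rng.integers(cfg.truncation_min, trunc_max + 1))
        intact = _orfs_intact(copy, master, truncation)
        copy = copy[truncation:]
        strand = "+" if rng.random() < 0.5 else "-"
        tsd_len = cfg.tsd_min + int(rng.binomial(cfg.tsd_binomial_n, cfg.tsd_binomial_p))

        nested_into: Optional[str] = None
        donors = [f for f in planter.features if f["kind"] == "donor"]
        if donors and rng.random() < cfg.p_nested:
            donor = donors[int(rng.integers(len(donors)))]
            nested_into = donor["id"]
            chrom = donor["chrom"]
            lo0, hi0 = donor["start"] + 10 - 1, donor["end"] - tsd_len - 10
            p0 = _retry_unblocked(rng, planter, chrom, lo0, hi0, tsd_len)
        else:
            want_domain = rng.random() < cfg.p_target_in_domain
            chrom, p0 = _sample_site(rng, planter, cfg, want_domain, tsd_len=tsd_len)

        # prefer a nick-motif site near the sampled position
        motif = motifs[int(rng.choice(len(motifs), p=weights))]
        seq = planter.seqs[chrom]
        if nested_into is not None:
            donor = next(f for f in planter.features if f["id"] == nested_into)
            lo0, hi0 = donor["start"] - 1, donor["end"]
        elif planter.in_domain(chrom, p0):
            lo0, hi0 = planter.domains[chrom][0] - 1, planter.domains[chrom][1]
        else:
            lo0, hi0 = 0, len(seq)
        q0 = _find_motif_site(seq, p0, motif, cfg.motif_window, lo0, hi0)
        motif_matched = q0 is not None
        if (
            q0 is None
            or q0 + tsd_len > len(seq)
            or planter.blocked(chrom, q0, q0 + tsd_len)
        ):
            q0, motif_matched = p0, motif_matched and q0 == p0

        insert_seq = copy if strand == "+" else revcomp(copy)
        start1, end1, tsd = planter.insert(chrom, q0, tsd_len, insert_seq)
        rec = TruthRecord(
            insertion_id=f"ins{i + 1:03d}",
            interval=GenomicInterval(chrom, start1, end1, strand),
            strand=strand,
            age_years=age,
            tsd=tsd,
            truncation5=truncation,
            nested_into=nested_into,
            intact_orfs=intact,
            n_substitutions=n_sub,
            motif_matched=motif_matched,
        sequence=copy,
        )
        planter.features.append(
            {"kind": "line", "id": rec.insertion_id, "chrom": chrom, "start": start1, "end": end1}
        )
        truth.append(rec)

    # re-read final coordinates from the bookkeeping (they shift as later
    # insertions land upstream), then freeze everything
    by_id = {f["id"]: f for f in planter.features}
    for rec in truth:
        f = by_id[rec.insertion_id]
        rec.interval = GenomicInterval(f["chrom"], f["start"], f["end"], rec.strand)
    donors_out = [
        DonorRecord(f["id"], GenomicInterval(f["chrom"], f["start"], f["end"]))
        for f in planter.features
        if f["kind"] == "donor"
    ]
    new_genome = GenomeAssembly(list(planter.seqs.items()))
    new_domains = DomainSet(
        [GenomicInterval(c, se[0], se[1]) for c, se in planter.domains.items()]
    )
    return Simulation(
        genome=new_genome,
        domains=new_domains,
        master=master,
        truth=truth,
        donors=donors_out,
        donor_library=donor_library,
        config=cfg,
    )


def _retry_unblocked(
    rng: np.random.Generator,
    planter: _Planter,
    chrom: str,
    lo0: int,
    hi0: int,
    tsd_len: int,
    max_tries: int = 200,
) -> int:
    if hi0 <= lo0:
        raise ConfigError("empty placement window")
    for _ in range(max_tries):
        p0 = int(rng.integers(lo0, hi0))
        if not planter.blocked(chrom, p0, p0 + tsd_len):
            return p0
    raise ConfigError("no unblocked insertion site after bounded retries")


def _sample_site(
    rng: np.random.Generator,
    planter: _Planter,
    cfg: SimConfig,
    want_domain: bool,
    tsd_len: int = 5,
    max_tries: int = 500,
) -> tuple[str, int]:
    """Sample (chrom, 0-based insertion point) inside or outside domains."""
    chroms = list(planter.seqs)
    if want_domain:
        weights = np.array(
            [planter.domains[c][1] - planter.domains[c][0] + 1 for c in chroms],
            dtype=float,
        )
    else:
        weights = np.array(
            [
                len(planter.seqs[c]) - (planter.domains[c][1] - planter.domains[c][0] + 1)
                for c in chroms
            ],
            dtype=float,
        )
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        dom = planter.domains[chrom]
        if want_domain:
            p0 = int(rng.integers(dom[0] - 1 + 10, dom[1] - tsd_len - 10))
        else:
            p0 = int(rng.integers(100, len(planter.seqs[chrom]) - tsd_len - 100))
            if planter.in_domain(chrom, p0):
                continue
        if not planter.blocked(chrom, p0, p0 + tsd_len):
            return chrom, p0
    raise ConfigError("no insertion site found after bounded retries")


def simulate(cfg: SimConfig) -> Simulation:
    """Convenience wrapper: background genome + domains + planted insertions."""
    rng = np.random.default_rng(cfg.seed)
    genome, domains = simulate_genome(cfg, rng)
    master = make_master_element(rng, gc=cfg.gc_background, polyA_len=cfg.polyA_length)
    return plant_insertions(genome, domains, master, cfg, rng)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: GenomeAssembly,
    domains: DomainSet,
    enrichment_fold: float = 30.0,
    n_chip: int = 100_000,
    n_input: int = 100_000,
    read_len: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ChIP and input read-start tables (chrom, start, strand).

    Input starts are uniform over the genome; ChIP starts follow a mixture
    with ``enrichment_fold`` times higher per-bp rate inside domains.
    """
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    if n_chip <= 0 or n_input <= 0:
        raise ValueError("read counts must be positive")
    rng = np.random.default_rng(seed)
    chroms = genome.names
    clens = np.array([genome.length(c) for c in chroms], dtype=float)
    G = clens.sum()
    D = float(domains.total_length)

    def _uniform(n: int) -> pd.DataFrame:
        ci = rng.choice(len(chroms), size=n, p=clens / G)
        rows = {
            "chrom": [chroms[i] for i in ci],
            "start": [int(rng.integers(1, clens[i] - read_len + 2)) for i in ci],
            "strand": ["+" if b else "-" for b in rng.random(n) < 0.5],
        }
        return pd.DataFrame(rows)

    def _in_domains(n: int) -> pd.DataFrame:
        ivs = domains.intervals
        lens = np.array([iv.span for iv in ivs], dtype=float)
        di = rng.choice(len(ivs), size=n, p=lens / lens.sum())
        rows = {
            "chrom": [ivs[i].chrom for i in di],
            "start": [int(rng.integers(ivs[i].start, ivs[i].end + 1)) for i in di],
            "strand": ["+" if b else "-" for b in rng.random(n) < 0.5],
        }
        return pd.DataFrame(rows)

    input_df = _uniform(n_input)
    f = enrichment_fold
    p_dom = f * D / (f * D + (G - D))
    n_dom = int(rng.binomial(n_chip, p_dom))
    chip_df = pd.concat(
        [_in_domains(n_dom), _background(rng, genome, domains, n_chip - n_dom, read_len)],
        ignore_index=True,
    )
    chip_df = chip_df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    return chip_df, input_df


def _background(
    rng: np.random.Generator,
    genome: GenomeAssembly,
    domains: DomainSet,
    n: int,
    read_len: int,
) -> pd.DataFrame:
    """n uniform read starts outside the domains (rejection sampling)."""
    chroms = genome.names
    clens = np.array([genome.length(c) for c in chroms], dtype=float)
    rows = {"chrom": [], "start": [], "strand": []}
    dom_by_chrom = {c: domains.on_chrom(c) for c in chroms}
    while len(rows["chrom"]) < n:
        ci = int(rng.choice(len(chroms), p=clens / clens.sum()))
        chrom = chroms[ci]
        pos = int(rng.integers(1, clens[ci] - read_len + 2))
        if any(iv.start <= pos <= iv.end for iv in dom_by_chrom[chrom]):
            continue
        rows["chrom"].append(chrom)
        rows["start"].append(pos)
        rows["strand"].append("+" if rng.random() < 0.5 else "-")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth-table serialisation
# ---------------------------------------------------------------------------

def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for r in truth:
        rows.append(
            {
                "insertion_id": r.insertion_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "strand": r.strand,
                "age_years": r.age_years,
                "tsd": r.tsd,
                "truncation5": r.truncation5,
                "nested_into": r.nested_into or "",
                "intact_orfs": r.intact_orfs,
                "n_substitutions": r.n_substitutions,
                "motif_matched": r.motif_matched,
            }
        )
    return pd.DataFrame(rows)
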