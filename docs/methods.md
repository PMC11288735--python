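# Methods

This note documents the models, conventions, and numerical choices behind
`centeline`, in the order the pipeline runs them.

## Coordinates and alignment primitives

All internal coordinates are 1-based and inclusive; an interval's span is
`end − start + 1` (so the representative element at 10,103,867–10,109,980
spans exactly 6,114 bp). BED I/O converts to 0-based half-open at the file
boundary only.

Two alignment engines coexist. `align_global` is an affine-gap
Needleman–Wunsch (match +1, mismatch −1, gap open −2, gap extend −1; a gap
of length *k* costs −2 − (*k* − 1)); ties between co-optimal alignments are
broken by the engine's deterministic canonical order. `edit_align` /
`edit_identity` use unit-cost edit distance (edlib), orders of magnitude
faster on kilobase copies, and are used for bulk identity and boundary
work. Identity is always recomputed from the gapped rows by one column
rule: a column counts as identical only if both letters are equal and
neither is a gap or N (N never matches anything, including N). The default
denominator excludes terminal gap overhangs; `all_columns` is available.
On substitution-only divergence the two engines agree exactly; where the
unit-cost engine ties a substitution against an indel pair, per-pair
identity can wobble by ~1 column in a few hundred.

## The synthetic genome

The simulator emulates the study system at a configurable scale; defaults
are the study conditions scaled down 20-fold so a run fits on a desk:

| parameter | default | meaning |
|---|---|---|
| `n_chromosomes`, `chrom_length` | 3 × 150 kb | background assembly |
| `gc_background` | 0.338 | genome-wide GC of the host |
| `domain_length_range` | 21,350–63,350 bp | CENH3 domain sizes (the reported 427–1,267 kb ÷ 20) |
| `mu` | 1.3 × 10⁻⁸ /bp/yr | substitution rate used for planting and dating |
| `n_insertions` | 60 | planted LINE copies |
| `age_distribution` | exponential, mean 5 × 10⁵ yr | matches a recently amplified family (~86% of copies younger than 1 My) |
| TSD length | 10 + Binomial(20, 0.25) | integers on [10, 30], mean 15 |
| `p_truncation` | 0.6 | 5′ truncation probability; length uniform on [100, L − 600] |
| `nick_motifs` | AAGA, AATA equally weighted | 5′ nick preference at junction positions (−1, 0, 1, 2) |
| `p_target_in_domain` | 0.84 | probability an insertion lands inside a domain |
| `p_nested` | 0.65 | probability of inserting into a planted donor LTR copy |
| `polyA_length` | 12 | tail appended to every copy |

The master element is 635 bp 5′UTR + 1,617 bp ORF1 + 3,765 bp ORF2 + 85 bp
3′UTR + 12 bp poly(A) = 6,114 bp, with ORFs built from stop-free sense
codons between an ATG and a TAA. The two ORFs are laid out back-to-back
rather than overlapping; an overlapping layout would need stop-free codons
in two frames simultaneously and buys nothing for testing.

Each copy is mutated by Poisson(2 μ T L) substitutions at uniform sites —
the factor 2 models divergence accumulating on both the source and the copy
lineage, which is what makes `(1 − identity)/(2μ)` recover the planted age.
Insertions are planted oldest first. The insertion machinery duplicates the
`k` bases at the chosen point (the TSD), prefers a site whose junction
matches a sampled nick motif within ±60 bp (falling back to the sampled
uniform site, with the fallback recorded), and never inserts inside a
previously planted copy of its own family, so every truth interval
extracts verbatim from the final assembly. Nesting is induced by steering
the site into a previously planted donor LTR interval with probability
`p_nested`; self-nesting is deliberately not modelled. Coordinates of all
earlier features (and the domains) are shifted or grown through every
insertion.

ChIP/input read tables are mixtures: input starts uniform; ChIP starts with
an `enrichment_fold`-times higher per-bp rate inside domains. All
randomness flows through one `numpy` generator; a fixed seed reproduces
byte-identical output.

What the simulator does **not** emulate: indels and rearrangements inside
copies, rate heterogeneity, satellite arrays, mappability structure,
sequencing error, solo LTRs. Passing recovery tests therefore demonstrates
the pipeline's correctness under substitution-only divergence with clean
boundaries, not robustness to assembly artefacts in real data.

## Mining and classification

Copies are found by exact k-mer seeding (default k = 13, both strands),
bucketing hits by alignment diagonal (genome − anchor position, bucket
width 300 bp) and chaining within a bucket across genomic gaps ≤ 400 bp.
Diagonal bucketing keeps genomically adjacent tandem copies apart (their
diagonals differ by an element length) while stray hits from k-mers
repeated inside the anchor form tiny clusters that the minimum-hit-length
filter removes. Nearby clusters merge only if their diagonals agree.

Each candidate region (±30 bp slack) is aligned to the anchor semiglobally
(full query against the best reference infix, edlib HW). Semiglobal
alignment is essential: a unit-cost *global* alignment of a short truncated
copy against the full reference prefers a degenerate scatter of single-base
matches over the correct suffix alignment. The aligned core is then the
best-scoring contiguous column window (+1 match / −2 otherwise, Kadane),
re-anchored at the first and last run of 20 consecutive match columns
(defeating phase shifts through short repeats at the junctions), and
extended outward by an ungapped X-drop (match +1, mismatch −2, X = 8,
extensions accepted only once they net +3, except that up to 5 leftover
reference bases matching exactly snap the boundary to the reference
terminus). Hits shorter than 200 bp or under 80% core identity are
discarded — the self-contained analogue of a BLASTN E-value cutoff.

Classification aligns the extracted copy to the full reference the same
way: `truncation5` is the count of reference positions before the first
aligned column (plus the infix offset), `internal_deletion` the reference
positions aligned to copy gaps inside the aligned span, and the 3′ end is
"present" if at most 50 bp of reference remain beyond the last aligned
column. Full-length requires truncation < 100 bp, internal deletion
< 500 bp, and the 3′ end; 5′-truncated copies with a 3′ end are
`truncated`; everything else is a `fragment` and is excluded from copy
number. ORF intactness projects each reference ORF through the alignment
onto the copy and requires length ≡ 0 (mod 3), an ATG start, a terminal
stop, and no premature stop.

On mutation-free simulations all boundaries are exact except at truncated
5′ junctions, where the parse is intrinsically ambiguous by 1–2 bp whenever
the flanking base coincides with the reference base at the cut; tests and
the acceptance script treat that ambiguity as such rather than as error.

## TSDs and junction matrices

Flank extraction reaches 2 bp into the annotated interval on each side
(`inner = 2`), so a boundary off by a base or two cannot clip the
duplication irrecoverably. Candidate duplicated words (suffix of the left
flank recurring as a prefix of the right flank) are ranked by
`length − |d1 − inner| − |d2 − inner|` where d1/d2 are the junction
offsets; ties prefer the smaller deviation, then the lexicographically
smaller word. The deviation penalty is what stops a longest-match rule from
systematically dragging the junction across the poly(A) tail or the planted
nick motif (both of which create genuine longer duplications one or two
bases off the true junction). Words ≥ 10 bp are high confidence; ≥ 5 bp are
reported but flagged.

The 5′ junction matrix covers positions −9…0 (10 bp upstream; 0 is the base
immediately upstream of the TSD) and 1…10 (first 10 TSD bases); the 3′
matrix mirrors it (0 = last TSD base, 1…10 downstream); the 5-bp-TSD
variant for chromovirus-clade (CRM) elements uses −10…−1 / 1…5 / 6…15.
Row frequencies are over records with context at that position, with skip
counts reported. GC content is (G+C)/(A+C+G+T), N excluded from both sides.

## Dating

`highest_pairwise_identity` computes the all-vs-all identity matrix
(edit-distance engine, terminal gaps excluded) once and takes each
element's best partner. Ages use `T = (1 − p)/(2μ)`; the divisor 2μ is
fixed by requiring that 84% identity correspond to 6.2 My and 96% to 1.5 My
at μ = 1.3 × 10⁻⁸. LTR dating shares the same kernel and flags estimates
below 80% LTR identity as beyond the method's reliable range (at that
divergence homology itself is in doubt). Recovery at the default scale:
median relative error 6–12% for planted ages ≥ 10⁵ yr (n ≈ 60–80); the
floor is set by Poisson substitution noise (relative SD ≈ (2μTL)^−½) plus
the age of each element's youngest relative.

## Targeting statistics

"Inside" means ≥ 1 bp overlap with a domain; "near" means within 20 kb;
the three relations partition every element. The permutation null re-places
one random interval per observed domain, preserving its length and (by
default) its chromosome, rejecting overlaps, 100 replicates; an
`any_chrom` mode re-assigns chromosomes length-weighted. With domains a
small fraction of the genome the null mean equals the domain genome
fraction; when regions span a large share of a chromosome, edge effects
make mid-chromosome positions more coverable than ends, so the null is the
honest reference precisely where naive fraction arithmetic fails. Binned
abundance tracks use 100-kb bins of covered bp, rescaled so the densest bin
reads 100. Nesting detection aligns the 150 bp downstream (3′,
strand-aware) of each element against the donor library in both
orientations and labels the element with the best donor at ≥ 80% identity
over ≥ 50 bp; its two documented blind spots are a second element
immediately downstream and insertions within 150 bp of a donor's edge.

## ChIP domain calling

Windows are 1 kb, counts are unique read-start positions, density is per
mappable bp (fully mappable unless a track is supplied). Only windows with
≥ 1 input read are testable; for those, the ChIP count is tested against
Poisson(λ = input count × chip-library/input-library), Benjamini–Hochberg
adjusted; windows with fold > 5 and q < 0.001 merge into islands across at
most one failing window. The caller is deliberately simple — the stated
fold/FDR thresholds on a Poisson background — not a reimplementation of a
clustering island statistic. Fold-1 simulations yield zero islands across
20 seeded replicates; a planted 50-kb domain at 30-fold enrichment and
20 k + 20 k reads is recovered with Jaccard ≥ 0.98. Read depth for that
check is chosen to keep per-window unique-position counts in the linear
regime: at much higher depth the unique-read rule saturates dense windows
and compresses observed fold. Per-cluster enrichment is
(chip/chip-lib)/(input/input-lib) with a pseudocount of 1 on both counts
when either is zero; the input share of a cluster estimates its genome
proportion.

## Fiber-FISH quantitation

Lengths in μm convert at 3.21 kb/μm; summaries use the sample (n − 1)
standard deviation; the genome total is mean-kb × chromosome count. Means
are reported to 1 decimal and single-signal conversions as integers,
matching how such measurements are conventionally printed.

## Phylogeny

p-distance is mismatches over compared columns with pairwise gap deletion
(complete deletion available). Neighbor-joining is implemented directly
because its branch-length handling is part of the contract: a negative
branch length is clamped to zero with the deficit moved to the sister
branch, preserving the pair's path length; the final three nodes join at an
unrooted trifurcation. Bootstrap resamples columns with replacement,
recomputes the tree, and scores each internal bipartition of the original
tree by the percentage of replicates containing it; branches below the
cutoff (default 50%) collapse into polytomies. A replicate that leaves some
pair with no comparable columns is dropped (conservative: it counts as not
supporting). NJ output is cross-checked in the test suite against
dendropy's independent implementation and recovers the generating topology
for additive matrices up to 8 taxa.

## Pipeline and reproducibility

`run_pipeline` executes simulate → mine → tsd → date → target → nest → chip
and writes stable filenames plus a JSON report; the effective configuration
is echoed into the run directory, unknown keys are rejected, and a stage
failure aborts with a stage-named error (exit code 3 from the CLI; 2 for
configuration errors). All stage seeds derive from the single run seed by
fixed offsets, so disabling one stage leaves the others' draws unchanged.
Problem sizes throughout (150–500 kb chromosomes, 60–100 insertions,
20 k-read libraries, 100-replicate nulls) are chosen so a full run and the
entire validation suite execute in well under a minute each while keeping
every statistical check's power high.

## Known limitations

Truncated-junction boundaries are ambiguous by 1–2 bp at the sequence level
(see above). The miner assumes copies diverge by substitutions; large
internal insertions split a copy into two hits on different diagonals
(observed once per ~60 copies at default settings, where the two hits
still cover the copy). Dating saturates near the ~80%-identity detection
limit and inherits any misspecification of μ linearly. The domain caller
ignores spatial clustering information a dedicated island caller would
use, and the placement null is not GC- or gap-aware.
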