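"""Call CENH3-binding domains from simulated ChIP/input read tables.

Reads are binned into 1-kb windows; each window's unique-read count is
tested against a Poisson expectation scaled from the input library, and
windows passing fold > 5 and FDR < 0.001 merge into domains (islands).
"""

import centeline as C
from centeline import chipseq

cfg = C.SimConfig(n_chromosomes=1, chrom_length=500_000,
                  domain_length_range=(50_000, 50_000), seed=41)
genome, domains = C.simulate_genome(cfg)
chip, inp = C.simulate_reads(genome, domains, enrichment_fold=30.0,
                             n_chip=20_000, n_input=20_000, seed=42)

chip_track = chipseq.window_density(chip, genome)
input_track = chipseq.window_density(inp, genome)
islands = chipseq.call_domains(chip_track, input_track)

true = domains.intervals[0]
print(f"true domain:   {true.chrom}:{true.start:,}-{true.end:,}")
for isl in islands:
    j = chipseq.jaccard(isl.interval, true)
    print(f"called island: {isl.interval.chrom}:{isl.interval.start:,}-"
          f"{isl.interval.end:,}  fold {isl.mean_fold:.1f}  "
          f"min q {isl.min_q:.2e}  Jaccard {j:.3f}")

# per-cluster enrichment, the statistic used to spot centromeric repeats
res = chipseq.cluster_enrichment({"repeat_A": 290}, {"repeat_A": 10},
                                 chip_lib=10_000, input_lib=10_000)
r = res[0]
print(f"\nrepeat cluster enrichment: {r.fold:.0f}x, "
      f"genome proportion {100*r.genome_proportion:.2f}%")
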