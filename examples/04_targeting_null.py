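"""Quantify centromere targeting against a random-placement null.

The observed percentage of element copies overlapping CENH3-like domains is
compared with the mean over 100 re-placements of equally sized random
regions — the null gives what untargeted insertion would look like.
"""

import centeline as C
from centeline import targeting

sim = C.simulate(C.SimConfig(n_insertions=30, chrom_length=500_000,
                             domain_length_range=(10_000, 20_000),
                             p_target_in_domain=0.84, p_nested=0.0, seed=23))
elements = [r.interval for r in sim.truth]

pct = targeting.percent_in_domains(elements, sim.domains)
null = targeting.random_placement_null(sim.genome, sim.domains, elements,
                                       n_replicates=100, seed=24)
frac = 100 * sim.domains.total_length / sim.genome.total_length

print(f"elements in domains: {pct:.1f}% (planted probability 84%)")
print(f"random-region null:  {null.mean:.1f}% +/- {null.sd:.1f} "
      f"over {null.n_replicates} replicates")
print(f"domain genome fraction: {frac:.1f}% — the null mean tracks it")
print(f"enrichment over chance: {pct/null.mean:.1f}x")

relations = [targeting.assign_domain_relation(e, sim.domains) for e in elements]
near = relations.count("near")
print(f"{near} additional copies sit within 20 kb of a domain ('near')")
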