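"""Convert fiber-FISH signal lengths from micrometres to kilobases.

Stretched-DNA hybridisation signals are measured in um and converted at
3.21 kb/um; extrapolating the mean signal across all 19 chromosomes
estimates the genome's total centromeric DNA.
"""

import math

from centeline.cytometry import fiber_summary, genome_total_estimate, um_to_kb

# twelve synthetic measurements with mean 215.1 um and sample SD 63 um
d = 63.0 * math.sqrt(11 / 12)
signals = [215.1 - s * d for s in (1,) * 6] + [215.1 + d] * 6

s = fiber_summary(signals)
print(f"{s.n} signals: {s.mean_um:.1f} +/- {s.sd_um:.1f} um")
print(f"           = {s.mean_kb:.1f} +/- {s.sd_kb:.1f} kb at 3.21 kb/um")

total = genome_total_estimate(s.mean_kb, n_chromosomes=19)
print(f"x19 chromosomes -> {total:.2f} Mb of centromeric DNA")

for um in (273.6, 25.2):
    print(f"single signal {um} um -> ~{um_to_kb(um):.0f} kb")
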