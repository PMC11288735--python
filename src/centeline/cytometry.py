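"""Fiber-FISH quantitation.

Signal lengths measured in micrometres on stretched DNA fibers convert to
kilobases with a calibration rate (default 3.21 kb/um).  Summaries use the
sample (n-1) standard deviation; the genome-wide centromere total
extrapolates the mean signal to all chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

DEFAULT_KB_PER_UM = 3.21


@dataclass
class CytometryConfig:
    kb_per_um: float = DEFAULT_KB_PER_UM
    n_chromosomes: int = 19

    def __post_init__(self) -> None:
        if self.kb_per_um <= 0:
            raise ValueError("conversion rate must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("chromosome count must be positive")


def um_to_kb(length_um: float, rate: float = DEFAULT_KB_PER_UM) -> float:
    """Convert a fiber length in micrometres to kilobases."""
    if length_um < 0:
        raise ValueError("length must be non-negative")
    return length_um * rate


@dataclass
class FiberSignalSet:
    lengths_um: list[float]
    mean_um: float
    sd_um: float
    mean_kb: float
    sd_kb: float

    @property
    def n(self) -> int:
        return len(self.lengths_um)


def fiber_summary(
    lengths_um: Sequence[float], cfg: CytometryConfig | None = None
) -> FiberSignalSet:
    """Mean and sample SD of fiber signal lengths, in um and kb."""
    cfg = cfg or CytometryConfig()
    if len(lengths_um) < 2:
        raise ValueError("need at least 2 measurements for a sample SD")
    m = mean(lengths_um)
    s = stdev(lengths_um)
    return FiberSignalSet(
        lengths_um=list(lengths_um),
        mean_um=m,
        sd_um=s,
        mean_kb=um_to_kb(m, cfg.kb_per_um),
        sd_kb=s * cfg.kb_per_um,
    )


def genome_total_estimate(mean_kb: float, n_chromosomes: int) -> float:
    """Total centromeric DNA in Mb assuming one measured signal per centromere."""
    if mean_kb <= 0 or n_chromosomes <= 0:
        raise ValueError("inputs must be positive")
    return mean_kb * n_chromosomes / 1000.0
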