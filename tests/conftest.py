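"""Shared fixtures: one moderately sized simulation reused across modules."""

from __future__ import annotations

import pytest

import centeline as C


@pytest.fixture(scope="session")
def default_sim() -> C.Simulation:
    """The standard study-condition simulation (3 chromosomes, 60 insertions)."""
    return C.simulate(C.SimConfig(seed=3))


@pytest.fixture(scope="session")
def mined(default_sim):
    """Mined hits plus classifications on the standard simulation."""
    hits = C.find_element_copies(default_sim.genome, default_sim.master.sequence)
    annotations = [
        C.classify_element(
            h, default_sim.genome, default_sim.master, element_id=f"copy{i + 1:03d}"
        )
        for i, h in enumerate(hits)
    ]
    return hits, annotations


@pytest.fixture(scope="session")
def mutation_free_sim() -> C.Simulation:
    """All insertions at age zero: planted copies are exact master copies."""
    return C.simulate(C.SimConfig(seed=7, age_distribution=("fixed", {"age": 0.0})))


@pytest.fixture(scope="session")
def master():
    return C.make_master_element(0)
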