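import numpy as np
import pandas as pd
import pytest

from bgakit import (
    Locus,
    Population,
    ReferencePanel,
    SimConfig,
    apply_frequency_floor,
    simulate_panel,
)


@pytest.fixture
def toy_panel() -> ReferencePanel:
    """2 populations x 3 loci with hand-set frequencies (already strictly in (0,1))."""
    loci = [
        Locus("rs1", "A", "G"),
        Locus("rs2", "C", "T"),
        Locus("rs3", "A", "C"),
    ]
    pops = [
        Population("Norwegians", "Europe", 100),
        Population("Han", "East Asia", 80),
    ]
    freq = pd.DataFrame(
        [[0.8, 0.5, 0.3], [0.2, 0.6, 0.9]],
        index=["Norwegians", "Han"],
        columns=["rs1", "rs2", "rs3"],
    )
    return ReferencePanel(loci=loci, populations=pops, freq=freq)


@pytest.fixture(scope="session")
def sim_panel():
    """Default 56-locus, 3-population panel at FST 0.15 (seed 0), plus ancestral freqs."""
    panel, p0 = simulate_panel(SimConfig(seed=0))
    return panel, p0


@pytest.fixture(scope="session")
def sim_panel_floored(sim_panel):
    panel, _ = sim_panel
    return apply_frequency_floor(panel)
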