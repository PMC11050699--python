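"""Synthetic cohorts emulating an aiSNP sequencing study.

The study conditions this generator reproduces:

* **Population structure** — designated-allele frequencies drift from a
  shared ancestral frequency under the Balding-Nichols model: with
  divergence F (an FST), each population's frequency is
  ``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)``, so ``E[p] = p0`` and
  ``Var[p] = F p0 (1-p0)``.
* **Individuals** — unadmixed genotypes are Hardy-Weinberg draws from a
  population's frequencies; first-generation admixed individuals draw one
  allele at each parent population's frequency (1:1 admixture).
* **Sequencing depth** — per-locus total read depth follows a
  negative-binomial law whose mean scales linearly with input DNA
  (``depth_mean_at_1ng x efficiency x input_pg/1000``), with per-locus
  amplification efficiencies including a few deliberately poor loci (the
  real multiplex has markers whose median depth stays under ~100 reads).
  Heterozygote reads split ``Binomial(depth, 1/2)``; homozygotes receive a
  low rate (0.5% by default, below the 1.5% analytical threshold in
  expectation) of noise reads on the non-carried allele so the calling
  thresholds are exercised.  Depth 0 removes the locus.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel import Locus, Population, ReferencePanel
from .qc import AlleleDepthProfile, GenotypeProfile

__all__ = [
    "SimConfig",
    "simulate_panel",
    "simulate_individuals",
    "simulate_read_depths",
    "default_locus_efficiencies",
]

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class SimConfig:
    """All simulation parameters.

    ``fst`` may be a single divergence applied to every population or one
    value per population.  ``locus_efficiency`` defaults to 1.0 everywhere
    except ``n_low_efficiency`` designated poor loci at
    ``low_efficiency`` x mean depth.
    """

    n_loci: int = 56
    n_populations: int = 3
    fst: float | Sequence[float] = 0.15
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    cohort_size: int = 100
    depth_mean_at_1ng: float = 1000.0
    dispersion: float = 5.0
    noise_rate: float = 0.005
    input_dna_pg: float = 1000.0
    n_low_efficiency: int = 3
    low_efficiency: float = 0.1
    locus_efficiency: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_populations < 1 or self.cohort_size < 1:
            raise ValueError("counts must be >= 1")
        fsts = self.fst_per_population
        if any(not (0 <= f < 1) for f in fsts):
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        if self.locus_efficiency is not None:
            if len(self.locus_efficiency) != self.n_loci:
                raise ValueError("locus_efficiency must have one value per locus")
            if any(e < 0 for e in self.locus_efficiency):
                raise ValueError("efficiencies must be >= 0")

    @property
    def fst_per_population(self) -> tuple[float, ...]:
        if isinstance(self.fst, (int, float)):
            return (float(self.fst),) * self.n_populations
        fsts = tuple(float(f) for f in self.fst)
        if len(fsts) != self.n_populations:
            raise ValueError("fst sequence must have one value per population")
        return fsts


def default_locus_efficiencies(cfg: SimConfig) -> np.ndarray:
    """Per-locus amplification efficiencies: 1.0, with the first
    ``n_low_efficiency`` loci set to ``low_efficiency``."""
    if cfg.locus_efficiency is not None:
        return np.asarray(cfg.locus_efficiency, dtype=float)
    eff = np.ones(cfg.n_loci)
    eff[: min(cfg.n_low_efficiency, cfg.n_loci)] = cfg.low_efficiency
    return eff


def simulate_panel(
    cfg: SimConfig, seed: Optional[int] = None
) -> tuple[ReferencePanel, np.ndarray]:
    """Simulate a reference panel under Balding-Nichols drift.

    Ancestral frequencies are uniform on ``ancestral_freq_range``; each
    population's frequency at each locus is a Beta draw with mean p0 and
    variance F p0 (1-p0).  F = 0 copies p0 exactly (no sampling).  Returns
    the panel (populations POP1..POPn, metapopulations META1..METAn) and
    the ancestral frequency vector.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=cfg.n_loci)
    fsts = cfg.fst_per_population
    freqs = np.empty((cfg.n_populations, cfg.n_loci))
    for k, F in enumerate(fsts):
        if F == 0.0:
            freqs[k] = p0
        else:
            a = p0 * (1 - F) / F
            b = (1 - p0) * (1 - F) / F
            freqs[k] = rng.beta(a, b)
    loci = [
        Locus(id=f"rs{1000 + i}", allele_a=_ALLELE_PAIRS[i % 4][0],
              allele_b=_ALLELE_PAIRS[i % 4][1])
        for i in range(cfg.n_loci)
    ]
    pops = [
        Population(name=f"POP{k + 1}", metapopulation=f"META{k + 1}",
                   sample_size=cfg.cohort_size)
        for k in range(cfg.n_populations)
    ]
    freq = pd.DataFrame(freqs, index=[p.name for p in pops],
                        columns=[l.id for l in loci])
    return ReferencePanel(loci=loci, populations=pops, freq=freq), p0


def simulate_individuals(
    panel: ReferencePanel,
    population: str,
    n: int,
    seed: int = 0,
    admixed_pair: Optional[tuple[str, str]] = None,
    sample_prefix: Optional[str] = None,
) -> list[GenotypeProfile]:
    """Draw HWE genotype profiles from a population's true frequencies.

    With ``admixed_pair=(popA, popB)`` each individual is first-generation
    admixed: one allele Bernoulli(p_A), the other Bernoulli(p_B) per locus
    (``population`` is then used only for labelling).  Frequencies must be
    strictly inside (0, 1).
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    loci = panel.loci
    lids = [l.id for l in loci]
    if admixed_pair is not None:
        pa = panel.frequencies(admixed_pair[0])[lids].to_numpy(dtype=float)
        pb = panel.frequencies(admixed_pair[1])[lids].to_numpy(dtype=float)
        truth = f"{admixed_pair[0]}x{admixed_pair[1]}"
    else:
        pa = pb = panel.frequencies(population)[lids].to_numpy(dtype=float)
        truth = panel.metapopulation_of(population)
    for p in (pa, pb):
        if np.any(np.isnan(p)) or np.any((p <= 0) | (p >= 1)):
            raise ValueError("simulation needs frequencies strictly inside (0, 1)")
    prefix = sample_prefix or (truth if admixed_pair else population)
    a1 = rng.random((n, len(loci))) < pa
    a2 = rng.random((n, len(loci))) < pb
    profiles = []
    for i in range(n):
        calls = {}
        for j, loc in enumerate(loci):
            pair = tuple(sorted(
                (loc.allele_a if a1[i, j] else loc.allele_b,
                 loc.allele_a if a2[i, j] else loc.allele_b)
            ))
            calls[loc.id] = pair
        profiles.append(
            GenotypeProfile(
                sample_id=f"{prefix}_{i:04d}",
                calls=calls,
                flags={lid: frozenset() for lid in lids},
                n_panel_loci=len(loci),
                truth_population=truth,
            )
        )
    return profiles


def simulate_read_depths(
    genotypes: GenotypeProfile,
    panel: ReferencePanel,
    cfg: SimConfig,
    seed: int = 0,
    input_dna_pg: Optional[float] = None,
) -> AlleleDepthProfile:
    """Simulate per-allele read counts for a known genotype profile.

    Total depth per locus is negative-binomial with mean
    ``depth_mean_at_1ng x efficiency x input_pg / 1000`` and dispersion
    ``cfg.dispersion`` (variance ``m + m^2/dispersion``); heterozygote
    reads split Binomial(depth, 1/2); homozygotes get
    Binomial(depth, noise_rate) reads on the non-carried allele.  Loci at
    depth 0 are absent from the output.
    """
    input_pg = cfg.input_dna_pg if input_dna_pg is None else input_dna_pg
    if input_pg <= 0:
        raise ValueError("input_dna_pg must be positive")
    rng = np.random.default_rng(seed)
    eff = default_locus_efficiencies(cfg)
    by_id = {l.id: (l, eff[i]) for i, l in enumerate(panel.loci)}
    depths: dict[str, dict[str, int]] = {}
    for lid, g in genotypes.calls.items():
        if g is None or lid not in by_id:
            continue
        loc, e = by_id[lid]
        mean = cfg.depth_mean_at_1ng * e * input_pg / 1000.0
        if mean <= 0:
            continue
        k = cfg.dispersion
        total = int(rng.negative_binomial(k, k / (k + mean)))
        if total == 0:
            continue
        a, b = loc.allele_a, loc.allele_b
        if g[0] != g[1]:
            r_a = int(rng.binomial(total, 0.5))
            counts = {a: r_a, b: total - r_a}
        else:
            carried = g[0]
            other = b if carried == a else a
            noise = int(rng.binomial(total, cfg.noise_rate))
            counts = {carried: total - noise, other: noise}
        depths[lid] = {al: r for al, r in counts.items() if r > 0}
    return AlleleDepthProfile(
        sample_id=genotypes.sample_id, depths=depths, input_dna_pg=float(input_pg)
    )
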