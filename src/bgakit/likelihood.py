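"""Likelihood-ranking ancestry prediction.

Each reference population is scored with the profile's log10 likelihood
under Hardy-Weinberg proportions: independent loci contribute
``log10 p^2`` (homozygous designated allele), ``log10 2p(1-p)``
(heterozygous) or ``log10 (1-p)^2`` (homozygous other allele), where ``p``
is the population's designated-allele frequency.  Populations are ranked by
likelihood; populations within one order of magnitude (1.0 on the log10
scale by default) of the best are not considered significantly different
and form the candidate set.  If every candidate belongs to one
metapopulation the sample is predicted to that metapopulation; candidates
from different metapopulations make the prediction inconclusive.  This
predictor always ranks — it has no "rejected" outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision import Decision, INCONCLUSIVE, PREDICTED
from .panel import ReferencePanel
from .qc import GenotypeProfile

__all__ = [
    "LikelihoodResult",
    "profile_log10_likelihood",
    "predict_by_likelihood",
]

_LN10 = math.log(10.0)


@dataclass
class LikelihoodResult:
    """Ranked per-population log10 likelihoods and the resulting decision."""

    sample_id: str
    loglik10: pd.Series              # per population, descending
    ranking: list[str]
    candidate_set: list[str]
    n_loci_used: int
    decision: Decision

    def to_frame(self, panel: ReferencePanel | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "log10_likelihood": self.loglik10,
                "rank": range(1, len(self.loglik10) + 1),
                "in_candidate_set": [p in self.candidate_set for p in self.loglik10.index],
            }
        ).rename_axis("population")
        if panel is not None:
            df.insert(0, "metapopulation", [panel.metapopulation_of(p) for p in df.index])
        return df


def _genotype_log_prob(genotype: tuple[str, str], p: float, alleles: tuple[str, str]) -> float:
    """Natural-log HWE probability of a called genotype given frequency p of allele_a."""
    a, b = alleles
    g = tuple(sorted(genotype))
    if g == tuple(sorted((a, a))):
        return 2.0 * math.log(p)
    if g == tuple(sorted((b, b))):
        return 2.0 * math.log1p(-p)
    if g == tuple(sorted((a, b))):
        return math.log(2.0) + math.log(p) + math.log1p(-p)
    raise ValueError(f"genotype {genotype} not composed of panel alleles {alleles}")


def profile_log10_likelihood(
    genotypes: GenotypeProfile,
    panel: ReferencePanel,
    population: str,
    loci: list[str] | None = None,
) -> tuple[float, int]:
    """Log10 likelihood of a genotype profile under one population's frequencies.

    Missing/no-call loci and loci untyped in the population are skipped.
    Returns ``(log10 likelihood, number of loci used)``.  The panel must be
    floored (no frequency of exactly 0 or 1).  Accumulation is in natural
    log, converted to log10 at the interface.
    """
    use = loci if loci is not None else genotypes.called_loci
    freqs = panel.frequencies(population)
    total = 0.0
    n_used = 0
    for lid in use:
        g = genotypes.calls.get(lid)
        if g is None or lid not in freqs.index:
            continue
        p = freqs[lid]
        if pd.isna(p):
            continue
        if p <= 0.0 or p >= 1.0:
            raise ValueError(
                f"population {population!r}, locus {lid}: frequency {p} — "
                "apply a frequency floor before computing likelihoods"
            )
        total += _genotype_log_prob(g, float(p), panel.locus(lid).alleles)
        n_used += 1
    if n_used == 0:
        raise ValueError(
            f"no usable loci for sample {genotypes.sample_id!r} in population {population!r}"
        )
    return total / _LN10, n_used


def predict_by_likelihood(
    genotypes: GenotypeProfile,
    panel: ReferencePanel,
    window_log10: float = 1.0,
) -> LikelihoodResult:
    """Rank populations by likelihood and apply the order-of-magnitude rule.

    All populations are scored on the common locus set (the sample's called
    loci typed in every scored population) so likelihoods are comparable.
    The candidate set holds every population within ``window_log10`` of the
    top; the decision is ``predicted(metapopulation)`` iff all candidates
    share one metapopulation, otherwise ``inconclusive``.  Ties in ranking
    are broken by population name.
    """
    if not panel.populations:
        raise ValueError("empty reference panel")
    called = genotypes.called_loci
    common = [
        lid
        for lid in called
        if lid in panel.freq.columns and panel.freq[lid].notna().all()
    ]
    scores = {}
    for pop in panel.population_names:
        ll, _n = profile_log10_likelihood(genotypes, panel, pop, loci=common)
        scores[pop] = ll
    ser = pd.Series(scores, name="log10_likelihood")
    ser = ser.sort_index().sort_values(ascending=False, kind="stable")
    top = ser.iloc[0]
    candidates = list(ser.index[(top - ser) <= window_log10])
    metas = {panel.metapopulation_of(p) for p in candidates}
    if len(metas) == 1:
        decision = Decision(PREDICTED, label=next(iter(metas)), candidates=tuple(candidates))
    else:
        decision = Decision(INCONCLUSIVE, candidates=tuple(candidates))
    return LikelihoodResult(
        sample_id=genotypes.sample_id,
        loglik10=ser,
        ranking=list(ser.index),
        candidate_set=candidates,
        n_loci_used=len(common),
        decision=decision,
    )
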