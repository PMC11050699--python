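"""Z-score outlier test for population assignment.

Rather than only ranking populations, this predictor asks whether a profile
plausibly originates from *any* reference population.  Under a hypothesized
population with designated-allele frequencies ``p``, the log-likelihood of
a random member's profile has an exact per-locus expectation and variance:

    mu_locus  = sum_g q_g ln q_g
    var_locus = sum_g q_g (ln q_g)^2 - mu_locus^2

with genotype probabilities ``q_g in {p^2, 2p(1-p), (1-p)^2}``; totals add
over independent loci.  The standardized deviation

    z = (mu - l_obs) / sqrt(var)

is approximately standard normal (CLT over ~56 loci), so a one-sided test
accepts the population when ``z <= 1.64`` (95% level).  Larger z means the
observed profile is less likely than a typical member's: a worse fit.

A sample is *rejected* when no population is accepted.  When several are,
the most likely accepted population must beat each other accepted one by a
likelihood ratio whose 95% confidence interval excludes zero, else the
prediction is *inconclusive*.  Population hypotheses are the pooled
metapopulation frequencies by default.  A first-generation admixture
hypothesis (one allele drawn from each parental population) is also
testable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decision import Decision, INCONCLUSIVE, PREDICTED, REJECTED
from .panel import ReferencePanel, apply_frequency_floor
from .qc import GenotypeProfile

__all__ = [
    "ZTestConfig",
    "ZScoreResult",
    "loglik_moments",
    "z_score",
    "z_scores_from_codes",
    "genotype_codes",
    "predict_by_zscore",
    "admixture_hypothesis",
]


@dataclass(frozen=True)
class ZTestConfig:
    """Critical value and confidence level for the z-score test.

    ``z_crit`` defaults to 1.64, the one-sided 95% standard-normal quantile
    rounded to two decimals (the exact quantile is available as
    ``ZTestConfig.exact_z_crit()``).
    """

    z_crit: float = 1.64
    ci_level: float = 0.95
    admixture_enabled: bool = False

    def __post_init__(self) -> None:
        if self.z_crit <= 0:
            raise ValueError("z_crit must be positive")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")

    @staticmethod
    def exact_z_crit(level: float = 0.95) -> float:
        return float(stats.norm.ppf(level))


@dataclass
class ZScoreResult:
    """Per-population z-scores, LR comparisons among accepted populations, decision."""

    sample_id: str
    z: pd.Series                       # per population hypothesis
    accepted_set: list[str]
    lr_comparisons: pd.DataFrame       # top vs other: log10 LR with 95% CI
    decision: Decision
    admixed_accepted: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z": self.z, "accepted": [p in self.accepted_set for p in self.z.index]}
        ).rename_axis("population")


# ---------------------------------------------------------------------------
# Moments and z-scores
# ---------------------------------------------------------------------------

def _hwe_log_probs(p: np.ndarray) -> np.ndarray:
    """ln q_g per locus for genotype codes g = 2, 1, 0 copies of allele_a.

    Returns an array of shape (3, L): rows are ln p^2, ln 2p(1-p), ln (1-p)^2.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("frequencies must lie strictly in (0, 1); floor the panel first")
    return np.stack([2 * np.log(p), np.log(2 * p * (1 - p)), 2 * np.log1p(-p)])


def _moments_from_log_probs(lnq: np.ndarray) -> tuple[float, float]:
    q = np.exp(lnq)
    mu_locus = (q * lnq).sum(axis=0)
    var_locus = (q * lnq**2).sum(axis=0) - mu_locus**2
    return float(mu_locus.sum()), float(var_locus.sum())


def loglik_moments(p: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Exact mean and variance of the natural-log HWE profile likelihood.

    ``p`` is the designated-allele frequency at each locus (strictly inside
    (0, 1)).  Per-locus moments are computed over the three genotype
    outcomes and summed over loci (independence).
    """
    return _moments_from_log_probs(_hwe_log_probs(np.asarray(p, dtype=float)))


def genotype_codes(
    genotypes: GenotypeProfile, panel: ReferencePanel, loci: Sequence[str]
) -> np.ndarray:
    """Copies of the designated allele (2/1/0) per locus; NaN where missing."""
    codes = np.full(len(loci), np.nan)
    for i, lid in enumerate(loci):
        g = genotypes.calls.get(lid)
        if g is None:
            continue
        a = panel.locus(lid).allele_a
        b = panel.locus(lid).allele_b
        for allele in g:
            if allele not in (a, b):
                raise ValueError(
                    f"locus {lid}: genotype allele {allele!r} not in panel pair ({a}, {b})"
                )
        codes[i] = sum(1 for allele in g if allele == a)
    return codes


def z_scores_from_codes(codes: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorized z-scores for genotype-code matrices.

    ``codes`` has shape (n_samples, L) with entries 2/1/0 (copies of the
    designated allele); ``p`` the frequencies at those L loci.  All loci
    must be typed (no NaN).
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=float))
    if np.isnan(codes).any():
        raise ValueError("codes must not contain missing values")
    lnq = _hwe_log_probs(p)  # (3, L)
    mu, var = _moments_from_log_probs(lnq)
    if var <= 0:
        raise ValueError("zero log-likelihood variance: no polymorphic loci")
    row = (2 - codes).astype(int)  # genotype code 2 -> row 0 (hom a), 1 -> het, 0 -> hom b
    lobs = lnq[row, np.arange(codes.shape[1])].sum(axis=1)
    return (mu - lobs) / math.sqrt(var)


def z_score(
    genotypes: GenotypeProfile,
    panel: ReferencePanel,
    population: str,
    loci: Optional[Sequence[str]] = None,
) -> float:
    """Z-score of one profile against one population hypothesis.

    Uses the sample's called loci that are typed in the population; the
    observed log-likelihood and the moments use the same locus set, so z is
    invariant to the logarithm base and to locus order.
    """
    use = list(loci) if loci is not None else genotypes.called_loci
    freqs = panel.frequencies(population)
    use = [lid for lid in use if lid in freqs.index and not pd.isna(freqs[lid])
           and genotypes.calls.get(lid) is not None]
    if not use:
        raise ValueError(f"no usable loci for population {population!r}")
    p = freqs[use].to_numpy(dtype=float)
    codes = genotype_codes(genotypes, panel, use)
    return float(z_scores_from_codes(codes[None, :], p)[0])


# ---------------------------------------------------------------------------
# LR comparison between accepted populations
# ---------------------------------------------------------------------------

_LN10 = math.log(10.0)


def _lr_with_ci(
    codes: np.ndarray,
    p_top: np.ndarray,
    p_other: np.ndarray,
    ci_level: float,
) -> tuple[float, float, float]:
    """log10 LR (top vs other) for one profile with a CI under the top model.

    The per-locus log-probability difference ``d_g = ln q_top,g - ln q_other,g``
    has exact moments under the top population's genotype distribution; the
    CI is ``D_obs +/- z_{(1+ci)/2} * sd(D)``.  Returns (log10 LR, lo, hi).
    """
    lnq_top = _hwe_log_probs(p_top)
    lnq_oth = _hwe_log_probs(p_other)
    d = lnq_top - lnq_oth                      # (3, L)
    q_top = np.exp(lnq_top)
    ed = (q_top * d).sum(axis=0)
    vd = (q_top * d**2).sum(axis=0) - ed**2
    sd = math.sqrt(float(vd.sum()))
    row = (2 - codes).astype(int)
    d_obs = float(d[row, np.arange(len(codes))].sum())
    zq = float(stats.norm.ppf(0.5 + ci_level / 2))
    return d_obs / _LN10, (d_obs - zq * sd) / _LN10, (d_obs + zq * sd) / _LN10


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_by_zscore(
    genotypes: GenotypeProfile,
    panel: ReferencePanel,
    cfg: ZTestConfig = ZTestConfig(),
    pool_metapopulations: bool = True,
) -> ZScoreResult:
    """Accept/reject population hypotheses and resolve among accepted ones.

    By default each metapopulation's pooled (sample-size-weighted, floored)
    frequencies form one hypothesis.  ``accepted_set = {pop : z <= z_crit}``;
    no acceptance is a *rejected* sample; a single acceptance is the
    prediction; among several, the highest-likelihood accepted population
    must beat each other accepted one with an LR confidence interval that
    excludes zero in its favour, else *inconclusive*.
    """
    if not panel.populations:
        raise ValueError("empty reference panel")
    hyp_panel = panel.pool_metapopulations() if pool_metapopulations else panel
    if not hyp_panel.floor_applied:
        hyp_panel = apply_frequency_floor(hyp_panel)

    called = genotypes.called_loci
    common = [
        lid
        for lid in called
        if lid in hyp_panel.freq.columns and hyp_panel.freq[lid].notna().all()
    ]
    if not common:
        raise ValueError("no loci shared between the profile and every hypothesis")
    codes = genotype_codes(genotypes, hyp_panel, common)

    zs = {}
    lobs = {}
    for pop in hyp_panel.population_names:
        p = hyp_panel.frequencies(pop)[common].to_numpy(dtype=float)
        zs[pop] = float(z_scores_from_codes(codes[None, :], p)[0])
        lnq = _hwe_log_probs(p)
        lobs[pop] = float(lnq[(2 - codes).astype(int), np.arange(len(common))].sum())
    z_ser = pd.Series(zs, name="z").sort_values(kind="stable")
    accepted = sorted([p for p, z in zs.items() if z <= cfg.z_crit])

    lr_rows = []
    if not accepted:
        decision = Decision(REJECTED)
    elif len(accepted) == 1:
        decision = Decision(PREDICTED, label=accepted[0], candidates=(accepted[0],))
    else:
        top = max(accepted, key=lambda p: (lobs[p], p))
        p_top = hyp_panel.frequencies(top)[common].to_numpy(dtype=float)
        all_excluded = True
        for other in accepted:
            if other == top:
                continue
            p_oth = hyp_panel.frequencies(other)[common].to_numpy(dtype=float)
            lr, lo, hi = _lr_with_ci(codes, p_top, p_oth, cfg.ci_level)
            lr_rows.append(
                {"top": top, "other": other, "log10_lr": lr, "ci_lower": lo, "ci_upper": hi}
            )
            if lo <= 0:
                all_excluded = False
        if all_excluded:
            decision = Decision(PREDICTED, label=top, candidates=tuple(accepted))
        else:
            decision = Decision(INCONCLUSIVE, candidates=tuple(accepted))

    admixed_accepted: list[tuple[str, str]] = []
    if cfg.admixture_enabled:
        pops = hyp_panel.population_names
        for i, pa in enumerate(pops):
            for pb in pops[i + 1:]:
                z_ad = admixture_hypothesis(
                    genotypes, hyp_panel, pa, pb, loci=common
                )
                if z_ad <= cfg.z_crit:
                    admixed_accepted.append((pa, pb))

    lr_df = pd.DataFrame(
        lr_rows, columns=["top", "other", "log10_lr", "ci_lower", "ci_upper"]
    )
    return ZScoreResult(
        sample_id=genotypes.sample_id,
        z=z_ser,
        accepted_set=accepted,
        lr_comparisons=lr_df,
        decision=decision,
        admixed_accepted=admixed_accepted,
    )


# ---------------------------------------------------------------------------
# First-generation admixture hypothesis
# ---------------------------------------------------------------------------

def _admixed_log_probs(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """ln genotype probabilities when one allele comes from each parent population."""
    for p in (pa, pb):
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("frequencies must lie strictly in (0, 1); floor first")
    hom_a = pa * pb
    het = pa * (1 - pb) + pb * (1 - pa)
    hom_b = (1 - pa) * (1 - pb)
    return np.log(np.stack([hom_a, het, hom_b]))


def admixture_hypothesis(
    genotypes: GenotypeProfile,
    panel: ReferencePanel,
    pop_a: str,
    pop_b: str,
    loci: Optional[Sequence[str]] = None,
) -> float:
    """Z-score under a first-generation (1:1) admixture hypothesis.

    A first-generation admixed individual draws one allele at pop_a's
    frequency and one at pop_b's, so P(hom designated) = p_A p_B,
    P(het) = p_A(1-p_B) + p_B(1-p_A), P(hom other) = (1-p_A)(1-p_B).
    With ``pop_a == pop_b`` this reduces to the single-population HWE test
    (a warning is emitted).
    """
    if pop_a == pop_b:
        warnings.warn(
            f"admixture hypothesis with pop_a == pop_b ({pop_a!r}) is the "
            "single-population test",
            stacklevel=2,
        )
    use = list(loci) if loci is not None else genotypes.called_loci
    fa = panel.frequencies(pop_a)
    fb = panel.frequencies(pop_b)
    use = [
        lid for lid in use
        if genotypes.calls.get(lid) is not None
        and lid in fa.index and not pd.isna(fa[lid]) and not pd.isna(fb[lid])
    ]
    if not use:
        raise ValueError("no usable loci for the admixture hypothesis")
    pa = fa[use].to_numpy(dtype=float)
    pb = fb[use].to_numpy(dtype=float)
    lnq = _admixed_log_probs(pa, pb)
    mu, var = _moments_from_log_probs(lnq)
    if var <= 0:
        raise ValueError("zero variance under the admixture hypothesis")
    codes = genotype_codes(genotypes, panel, use)
    lobs = float(lnq[(2 - codes).astype(int), np.arange(len(use))].sum())
    return (mu - lobs) / math.sqrt(var)
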