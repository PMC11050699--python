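"""Reference population allele-frequency panels.

A :class:`ReferencePanel` holds, for a set of biallelic ancestry-informative
SNPs, the frequency ``p`` of one *designated* allele (``allele_a``) in each
reference population, together with the population sample sizes ``N`` and a
metapopulation (continental) grouping.  It is the shared substrate of the
three ancestry predictors: per-population genotype likelihoods, z-score
outlier tests and PCA all read their frequencies from it.

Frequencies of exactly 0 or 1 make log-likelihoods undefined, so panels are
*floored* before likelihood work: every ``p`` is clamped into
``[f_min, 1 - f_min]``, by default with the pseudo-count rule
``f_min = 1/(2N + 2)`` per population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Locus",
    "Population",
    "ReferencePanel",
    "HweResult",
    "load_frequency_table",
    "write_frequency_table",
    "hwe_chi_square",
    "hwe_table",
    "apply_frequency_floor",
]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP identified by rsID with a designated allele pair.

    ``allele_a`` is the designated allele whose frequency the panel stores;
    the other allele's frequency is ``1 - p``.
    """

    id: str
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"locus {self.id}: alleles must differ")
        for a in (self.allele_a, self.allele_b):
            if a not in _NUCLEOTIDES:
                raise ValueError(f"locus {self.id}: invalid allele {a!r}")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)


@dataclass(frozen=True)
class Population:
    """A reference population with its metapopulation label and size N."""

    name: str
    metapopulation: str
    sample_size: int

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError(f"population {self.name}: sample_size must be >= 1")


@dataclass
class HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions at one locus."""

    locus_id: str
    chi2: float
    p_value: float
    observed: tuple[int, int, int]
    monomorphic: bool = False


@dataclass
class ReferencePanel:
    """Loci, populations and the population x locus designated-allele frequency matrix.

    ``freq`` is indexed by population name (rows) and locus id (columns);
    missing (population, locus) cells are NaN and are skipped, not treated
    as zero, in every downstream computation.
    """

    loci: list[Locus]
    populations: list[Population]
    freq: pd.DataFrame
    floor_applied: bool = False

    def __post_init__(self) -> None:
        locus_ids = [l.id for l in self.loci]
        pop_names = [p.name for p in self.populations]
        if len(set(locus_ids)) != len(locus_ids):
            raise ValueError("duplicate locus ids in panel")
        if len(set(pop_names)) != len(pop_names):
            raise ValueError("duplicate population names in panel")
        if list(self.freq.columns) != locus_ids or list(self.freq.index) != pop_names:
            raise ValueError("freq matrix dimensions/labels do not match loci x populations")
        vals = self.freq.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("frequencies must lie in [0, 1]")
        self._locus_by_id = {l.id: l for l in self.loci}
        self._pop_by_name = {p.name: p for p in self.populations}

    # -- convenience lookups -------------------------------------------------

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def locus(self, locus_id: str) -> Locus:
        return self._locus_by_id[locus_id]

    def population(self, name: str) -> Population:
        return self._pop_by_name[name]

    def metapopulation_of(self, pop_name: str) -> str:
        return self.population(pop_name).metapopulation

    def frequencies(self, pop_name: str) -> pd.Series:
        """Designated-allele frequency per locus for one population (NaN = missing)."""
        return self.freq.loc[pop_name]

    # -- metapopulation pooling ---------------------------------------------

    def pool_metapopulations(self) -> "ReferencePanel":
        """Collapse populations into one pooled pseudo-population per metapopulation.

        Pooled frequency at a locus is the sample-size-weighted mean of the
        member populations typed at that locus; the pooled sample size is the
        sum of member sizes.  Flooring is NOT applied here.
        """
        groups: dict[str, list[Population]] = {}
        for p in self.populations:
            groups.setdefault(p.metapopulation, []).append(p)
        rows = {}
        pooled_pops = []
        for meta in sorted(groups):
            members = groups[meta]
            w = np.array([p.sample_size for p in members], dtype=float)
            f = self.freq.loc[[p.name for p in members]].to_numpy(dtype=float)
            mask = ~np.isnan(f)
            wsum = (mask * w[:, None]).sum(axis=0)
            with np.errstate(invalid="ignore"):
                pooled = np.nansum(f * w[:, None], axis=0) / np.where(wsum > 0, wsum, np.nan)
            rows[meta] = pooled
            pooled_pops.append(
                Population(name=meta, metapopulation=meta, sample_size=int(w.sum()))
            )
        freq = pd.DataFrame.from_dict(rows, orient="index", columns=self.locus_ids)
        freq = freq.loc[[p.name for p in pooled_pops]]
        return ReferencePanel(loci=list(self.loci), populations=pooled_pops, freq=freq)


# ---------------------------------------------------------------------------
# Frequency-table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "locus",
    "allele_a",
    "allele_b",
    "population",
    "metapopulation",
    "sample_size",
    "frequency",
]


def load_frequency_table(source, sep: str | None = None) -> ReferencePanel:
    """Load a reference panel from a long-format CSV/TSV frequency table.

    One row per (population, locus); required columns are
    ``locus, allele_a, allele_b, population, metapopulation, sample_size,
    frequency``.  Missing (population, locus) combinations are recorded as
    missing.  Duplicated (population, locus) rows, frequencies outside
    [0, 1] and inconsistent allele pairs for the same rsID are hard errors.
    """
    if sep is None:
        sep = "\t" if str(source).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(source, sep=sep, dtype={"locus": str, "population": str})
    missing_cols = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"frequency table missing columns: {missing_cols}")

    dup = df.duplicated(subset=["population", "locus"], keep=False)
    if dup.any():
        bad = df.loc[dup, ["population", "locus"]].iloc[0]
        raise ValueError(
            f"duplicate row for population {bad['population']!r}, locus {bad['locus']!r}"
        )
    bad_freq = df[(df["frequency"] < 0) | (df["frequency"] > 1)]
    if not bad_freq.empty:
        r = bad_freq.iloc[0]
        raise ValueError(
            f"frequency {r['frequency']} outside [0, 1] at population "
            f"{r['population']!r}, locus {r['locus']!r}"
        )

    loci: list[Locus] = []
    seen_alleles: dict[str, tuple[str, str]] = {}
    for _, r in df.iterrows():
        pair = (str(r["allele_a"]).upper(), str(r["allele_b"]).upper())
        lid = r["locus"]
        if lid in seen_alleles:
            if seen_alleles[lid] != pair:
                raise ValueError(
                    f"allele mismatch for locus {lid!r}: "
                    f"{seen_alleles[lid]} vs {pair}"
                )
        else:
            seen_alleles[lid] = pair
            loci.append(Locus(id=lid, allele_a=pair[0], allele_b=pair[1]))

    pops: list[Population] = []
    seen_pops: set[str] = set()
    for _, r in df.drop_duplicates(subset="population").iterrows():
        name = r["population"]
        if name in seen_pops:  # pragma: no cover - drop_duplicates guards this
            continue
        seen_pops.add(name)
        pops.append(
            Population(
                name=name,
                metapopulation=str(r["metapopulation"]),
                sample_size=int(r["sample_size"]),
            )
        )

    freq = df.pivot(index="population", columns="locus", values="frequency")
    freq = freq.reindex(index=[p.name for p in pops], columns=[l.id for l in loci])
    return ReferencePanel(loci=loci, populations=pops, freq=freq)


def write_frequency_table(panel: ReferencePanel, path: str | Path, sep: str | None = None) -> None:
    """Write a panel back to the long-format dialect read by :func:`load_frequency_table`."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    rows = []
    by_id = {l.id: l for l in panel.loci}
    for pop in panel.populations:
        for lid in panel.locus_ids:
            p = panel.freq.at[pop.name, lid]
            if pd.isna(p):
                continue
            loc = by_id[lid]
            rows.append(
                {
                    "locus": lid,
                    "allele_a": loc.allele_a,
                    "allele_b": loc.allele_b,
                    "population": pop.name,
                    "metapopulation": pop.metapopulation,
                    "sample_size": pop.sample_size,
                    "frequency": repr(float(p)),
                }
            )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg testing
# ---------------------------------------------------------------------------

def hwe_chi_square(
    observed: tuple[int, int, int] | Sequence[int], locus_id: str = ""
) -> HweResult:
    """Pearson chi-square test of HWE from genotype counts (AA, AB, BB).

    The allele frequency is estimated as ``p = (2 AA + AB) / (2 n)`` and the
    statistic compares observed counts with the expected HWE counts
    ``(p^2 n, 2 p (1-p) n, (1-p)^2 n)`` on 1 degree of freedom, with no
    continuity correction.  A monomorphic locus (p in {0, 1}) is returned
    with chi2 = 0, p_value = 1 and ``monomorphic=True``.
    """
    aa, ab, bb = (int(x) for x in observed)
    if min(aa, ab, bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = aa + ab + bb
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * aa + ab) / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(locus_id, 0.0, 1.0, (aa, ab, bb), monomorphic=True)
    expected = np.array([p * p * n, 2 * p * (1 - p) * n, (1 - p) ** 2 * n])
    obs = np.array([aa, ab, bb], dtype=float)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(locus_id, chi2, p_value, (aa, ab, bb))


def hwe_table(counts: Mapping[str, tuple[int, int, int]]) -> pd.DataFrame:
    """HWE test per locus with raw and Bonferroni-adjusted p-values."""
    results = [hwe_chi_square(c, locus_id=lid) for lid, c in counts.items()]
    m = len(results)
    return pd.DataFrame(
        {
            "locus": [r.locus_id for r in results],
            "chi2": [r.chi2 for r in results],
            "p_value": [r.p_value for r in results],
            "p_bonferroni": [min(1.0, r.p_value * m) for r in results],
            "monomorphic": [r.monomorphic for r in results],
        }
    ).set_index("locus")


# ---------------------------------------------------------------------------
# Frequency flooring
# ---------------------------------------------------------------------------

def apply_frequency_floor(
    panel: ReferencePanel, f_min: float | None = None
) -> ReferencePanel:
    """Clamp every frequency into ``[f_min, 1 - f_min]`` so likelihoods are finite.

    With ``f_min=None`` (default) the floor is the per-population pseudo-count
    value ``1/(2N + 2)`` where ``N`` is the population's sample size; a
    constant ``f_min`` applies uniformly.  Clamping is idempotent and never
    reorders populations by frequency at a locus except for ties created at
    the bounds.
    """
    if f_min is not None and not (0 < f_min < 0.5):
        raise ValueError("f_min must lie in (0, 0.5)")
    freq = panel.freq.copy()
    for pop in panel.populations:
        fl = f_min if f_min is not None else 1.0 / (2 * pop.sample_size + 2)
        freq.loc[pop.name] = freq.loc[pop.name].clip(lower=fl, upper=1 - fl)
    return replace(panel, freq=freq, floor_applied=True)
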