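"""Genotype calling and QC from per-allele read counts.

Massively parallel sequencing of a SNP multiplex reports, per sample and
locus, the number of reads supporting each allele.  Calling follows a
two-tier threshold scheme: an allele is *detected* only if it clears the
analytical threshold (a minimum read count AND a minimum fraction of the
locus's total reads); a detected allele below the stricter interpretation
threshold yields a low-confidence call.  Two detected alleles make a
heterozygote, one a homozygote, none a missing locus.

Diagnostics follow the field's standard vocabulary: heterozygote balance
(Hb, minor-allele read fraction at a het call), drop-out (a truly present
allele or whole locus missed), false homozygotes (hets reported homozygous
because one allele fell below the analytical threshold), and profile
completeness (fraction of panel loci with an interpretable call).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "AlleleDepthProfile",
    "GenotypeProfile",
    "QCReport",
    "call_genotypes",
    "heterozygote_balance",
    "ordered_het_balance",
    "qc_summary",
]

# per-locus QC flags
LOW_CONFIDENCE = "low_confidence"
IMBALANCED = "imbalanced"
DROPOUT_SUSPECTED = "dropout_suspected"
NO_CALL = "no_call"


@dataclass(frozen=True)
class Thresholds:
    """Detection and interpretation thresholds for allele calling.

    Defaults are the ForenSeq-style analytical threshold of 1.5% of the
    locus total (minimum 10 reads) and interpretation threshold of 4.5%
    (minimum 30 reads); heterozygotes with balance below ``min_het_balance``
    are flagged, and homozygotes at total depth below
    ``dropout_depth`` are flagged as possible drop-outs.
    """

    analytical_fraction: float = 0.015
    analytical_min_reads: int = 10
    interpretation_fraction: float = 0.045
    interpretation_min_reads: int = 30
    min_het_balance: float = 0.1
    dropout_depth: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.analytical_fraction <= self.interpretation_fraction < 1):
            raise ValueError("need 0 < analytical_fraction <= interpretation_fraction < 1")
        if not (0 < self.analytical_min_reads <= self.interpretation_min_reads):
            raise ValueError("need 0 < analytical_min_reads <= interpretation_min_reads")


@dataclass
class AlleleDepthProfile:
    """One sample's per-locus allele -> read-count map.

    ``depths`` maps locus id to a dict of allele letter -> non-negative read
    count.  ``input_dna_pg`` (picograms) is optional metadata used to group
    sensitivity summaries.
    """

    sample_id: str
    depths: dict[str, dict[str, int]]
    input_dna_pg: Optional[float] = None

    def __post_init__(self) -> None:
        for lid, alleles in self.depths.items():
            for a, r in alleles.items():
                if r < 0:
                    raise ValueError(
                        f"sample {self.sample_id}, locus {lid}: negative read count"
                    )
        if self.input_dna_pg is not None and self.input_dna_pg <= 0:
            raise ValueError("input_dna_pg must be positive")

    def total_depth(self, locus_id: str) -> int:
        return sum(self.depths.get(locus_id, {}).values())


@dataclass
class GenotypeProfile:
    """Called biallelic genotypes with per-locus QC flags.

    ``calls`` maps locus id to a sorted allele pair, or ``None`` for a
    missing locus.  ``completeness`` is the fraction of panel loci with an
    interpretable (non-missing) call.
    """

    sample_id: str
    calls: dict[str, Optional[tuple[str, str]]]
    flags: dict[str, frozenset[str]] = field(default_factory=dict)
    n_panel_loci: Optional[int] = None
    truth_population: Optional[str] = None
    input_dna_pg: Optional[float] = None

    @property
    def completeness(self) -> float:
        denom = self.n_panel_loci if self.n_panel_loci else len(self.calls)
        if denom == 0:
            return 0.0
        return sum(1 for g in self.calls.values() if g is not None) / denom

    @property
    def called_loci(self) -> list[str]:
        return [lid for lid, g in self.calls.items() if g is not None]

    def is_het(self, locus_id: str) -> bool:
        g = self.calls.get(locus_id)
        return g is not None and g[0] != g[1]


@dataclass
class QCReport:
    """Cohort QC tables: depth/balance distributions, drop-outs, success rates."""

    depth_summary: pd.DataFrame       # per locus: min, median, max total depth
    balance_summary: pd.DataFrame     # per locus: n_het, min, median, max ordered Hb
    completeness: pd.Series           # per sample
    dropout_counts: pd.Series         # per locus: number of missing calls
    success_rate: pd.DataFrame        # per group: called, expected, percent


def heterozygote_balance(reads_allele1: int, reads_allele2: int) -> float:
    """Minor-allele heterozygote balance: min(r1, r2) / (r1 + r2), in (0, 0.5].

    This is the order-free convention used for flagging; both counts must be
    positive (a heterozygote has two detected alleles by definition).
    """
    if reads_allele1 <= 0 or reads_allele2 <= 0:
        raise ValueError("heterozygote balance requires two positive read counts")
    return min(reads_allele1, reads_allele2) / (reads_allele1 + reads_allele2)


def ordered_het_balance(reads_allele1: int, reads_allele2: int) -> float:
    """Allele-order-dependent balance: reads of allele1 / total, in (0, 1).

    Allele1 is taken alphabetically; this convention reproduces the spread
    of reported balances both below and above 0.5 and is the one summarised
    in distribution plots.  Flagging uses :func:`heterozygote_balance`.
    """
    total = reads_allele1 + reads_allele2
    if total <= 0 or min(reads_allele1, reads_allele2) <= 0:
        raise ValueError("ordered balance requires two positive read counts")
    return reads_allele1 / total


def call_genotypes(
    profile: AlleleDepthProfile,
    thresholds: Thresholds = Thresholds(),
    panel_loci: Optional[Sequence[str]] = None,
) -> GenotypeProfile:
    """Call biallelic genotypes from per-allele read counts.

    An allele is detected iff ``reads >= analytical_min_reads`` and
    ``reads / total >= analytical_fraction``.  Two detected alleles form a
    heterozygote, one a homozygote; zero detected alleles (or an absent
    locus) is a missing call flagged ``no_call``.  Detected alleles below
    the interpretation threshold flag the locus ``low_confidence``;
    homozygotes whose other allele showed sub-threshold reads, or whose
    total depth is below ``thresholds.dropout_depth``, are flagged
    ``dropout_suspected``; heterozygotes with balance below
    ``min_het_balance`` are flagged ``imbalanced``.  More than two detected
    alleles at a locus is an error (the panel is biallelic).
    """
    t = thresholds
    calls: dict[str, Optional[tuple[str, str]]] = {}
    flags: dict[str, frozenset[str]] = {}
    loci = list(panel_loci) if panel_loci is not None else list(profile.depths)
    for lid in loci:
        alleles = profile.depths.get(lid, {})
        total = sum(alleles.values())
        detected = {
            a: r
            for a, r in alleles.items()
            if r >= t.analytical_min_reads and total > 0 and r / total >= t.analytical_fraction
        }
        locus_flags: set[str] = set()
        if len(detected) > 2:
            raise ValueError(
                f"sample {profile.sample_id}, locus {lid}: >2 alleles detected "
                f"({sorted(detected)}) in a biallelic panel"
            )
        if not detected:
            calls[lid] = None
            flags[lid] = frozenset({NO_CALL})
            continue
        if any(
            r < t.interpretation_min_reads or r / total < t.interpretation_fraction
            for r in detected.values()
        ):
            locus_flags.add(LOW_CONFIDENCE)
        if len(detected) == 2:
            (a1, r1), (a2, r2) = sorted(detected.items())
            calls[lid] = (a1, a2)
            if heterozygote_balance(r1, r2) < t.min_het_balance:
                locus_flags.add(IMBALANCED)
        else:
            (a1, r1) = next(iter(detected.items()))
            calls[lid] = (a1, a1)
            undetected = {a: r for a, r in alleles.items() if a != a1 and r > 0}
            if any(1 <= r < t.analytical_min_reads for r in undetected.values()):
                locus_flags.add(DROPOUT_SUSPECTED)
            elif total < t.dropout_depth:
                locus_flags.add(DROPOUT_SUSPECTED)
        flags[lid] = frozenset(locus_flags)
    return GenotypeProfile(
        sample_id=profile.sample_id,
        calls=calls,
        flags=flags,
        n_panel_loci=len(loci),
        input_dna_pg=profile.input_dna_pg,
    )


def qc_summary(
    profiles: Sequence[AlleleDepthProfile],
    genotypes: Sequence[GenotypeProfile],
    group_by: Optional[str] = None,
) -> QCReport:
    """Summarise depth, balance, completeness, drop-out and success rates.

    ``group_by="input_dna_pg"`` groups the success-rate table by DNA input,
    which on a dilution series yields the sensitivity curve (success rate
    non-increasing as input decreases).  Success rate per group is
    ``called genotypes / expected genotypes x 100`` where expected counts
    every panel locus of every profile in the group.
    """
    if not profiles:
        raise ValueError("qc_summary requires at least one profile")
    if len(profiles) != len(genotypes):
        raise ValueError("profiles and genotypes must align one-to-one")

    depth_rows: dict[str, list[int]] = {}
    balance_rows: dict[str, list[float]] = {}
    dropout: dict[str, int] = {}
    for adp, gp in zip(profiles, genotypes):
        for lid, g in gp.calls.items():
            total = adp.total_depth(lid)
            if total > 0:
                depth_rows.setdefault(lid, []).append(total)
            if g is None:
                dropout[lid] = dropout.get(lid, 0) + 1
            elif g[0] != g[1]:
                r1 = adp.depths[lid].get(g[0], 0)
                r2 = adp.depths[lid].get(g[1], 0)
                if min(r1, r2) > 0:
                    balance_rows.setdefault(lid, []).append(ordered_het_balance(r1, r2))

    depth_summary = pd.DataFrame(
        {
            lid: {
                "min": int(np.min(v)),
                "median": float(np.median(v)),
                "max": int(np.max(v)),
            }
            for lid, v in depth_rows.items()
        }
    ).T.rename_axis("locus")
    balance_summary = pd.DataFrame(
        {
            lid: {
                "n_het": len(v),
                "min": float(np.min(v)),
                "median": float(np.median(v)),
                "max": float(np.max(v)),
            }
            for lid, v in balance_rows.items()
        }
    ).T.rename_axis("locus") if balance_rows else pd.DataFrame(
        columns=["n_het", "min", "median", "max"]
    ).rename_axis("locus")

    completeness = pd.Series(
        {gp.sample_id: gp.completeness for gp in genotypes}, name="completeness"
    )
    all_loci = sorted({lid for gp in genotypes for lid in gp.calls})
    dropout_counts = pd.Series(
        {lid: dropout.get(lid, 0) for lid in all_loci}, name="dropouts", dtype=int
    )

    def _group_key(gp: GenotypeProfile):
        if group_by is None:
            return "all"
        return getattr(gp, group_by)

    grp: dict[object, list[GenotypeProfile]] = {}
    for gp in genotypes:
        grp.setdefault(_group_key(gp), []).append(gp)
    rows = []
    for key in sorted(grp, key=lambda k: (k is None, k)):
        members = grp[key]
        expected = sum(gp.n_panel_loci or len(gp.calls) for gp in members)
        called = sum(len(gp.called_loci) for gp in members)
        rows.append(
            {
                "group": key,
                "called": called,
                "expected": expected,
                "success_rate_pct": 100.0 * called / expected if expected else np.nan,
            }
        )
    success = pd.DataFrame(rows).set_index("group")

    return QCReport(
        depth_summary=depth_summary,
        balance_summary=balance_summary,
        completeness=completeness,
        dropout_counts=dropout_counts,
        success_rate=success,
    )
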