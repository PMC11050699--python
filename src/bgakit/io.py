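"""Readers and writers for the package's text formats.

Three genotype input formats are supported, all keyed by rsID:

* **read-count TSV** — columns ``sample_id, locus, allele, reads`` and an
  optional ``input_dna_pg``; one row per observed allele.  The raw input
  to genotype calling.
* **genotype TSV** — columns ``sample_id, locus, allele1, allele2``; a
  missing locus is an empty allele pair (``.``).  Already-called profiles.
* **VCF** — biallelic records whose ID matches a panel rsID; ``./.``
  genotypes become missing loci.  Read via cyvcf2.

All dialects are UTF-8 with mandatory headers; writers emit exactly what
the readers accept (round-trip safe).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .panel import ReferencePanel
from .qc import AlleleDepthProfile, GenotypeProfile, QCReport

__all__ = [
    "read_depth_tsv",
    "write_depth_tsv",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_vcf_profiles",
    "read_genotype_input",
    "write_qc_report",
]

_DEPTH_COLUMNS = ["sample_id", "locus", "allele", "reads"]


def read_depth_tsv(path: str | Path) -> list[AlleleDepthProfile]:
    """Read per-allele read counts (one row per sample x locus x allele)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus": str, "allele": str})
    missing = [c for c in _DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["reads"] < 0).any():
        line = int(df.index[df["reads"] < 0][0]) + 2  # +2: header + 1-based
        raise ValueError(f"{path}: negative read count at line {line}")
    profiles = []
    for sid, g in df.groupby("sample_id", sort=True):
        depths: dict[str, dict[str, int]] = {}
        for _, r in g.iterrows():
            depths.setdefault(r["locus"], {})[r["allele"]] = int(r["reads"])
        input_pg = None
        if "input_dna_pg" in g.columns and g["input_dna_pg"].notna().any():
            input_pg = float(g["input_dna_pg"].dropna().iloc[0])
        profiles.append(AlleleDepthProfile(sample_id=str(sid), depths=depths,
                                           input_dna_pg=input_pg))
    return profiles


def write_depth_tsv(profiles: Sequence[AlleleDepthProfile], path: str | Path) -> None:
    rows = []
    for pr in profiles:
        for lid in sorted(pr.depths):
            for allele in sorted(pr.depths[lid]):
                rows.append(
                    {
                        "sample_id": pr.sample_id,
                        "locus": lid,
                        "allele": allele,
                        "reads": pr.depths[lid][allele],
                        "input_dna_pg": pr.input_dna_pg,
                    }
                )
    pd.DataFrame(rows, columns=_DEPTH_COLUMNS + ["input_dna_pg"]).to_csv(
        path, sep="\t", index=False
    )


def read_genotype_tsv(path: str | Path) -> list[GenotypeProfile]:
    """Read called genotypes; '.' in both allele columns marks a missing locus."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["sample_id", "locus", "allele1", "allele2"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for sid, g in df.groupby("sample_id", sort=True):
        calls: dict[str, Optional[tuple[str, str]]] = {}
        truth = None
        for _, r in g.iterrows():
            if r["allele1"] in (".", "") or r["allele2"] in (".", ""):
                calls[r["locus"]] = None
            else:
                calls[r["locus"]] = tuple(sorted((r["allele1"], r["allele2"])))
            if "truth_population" in g.columns and r.get("truth_population"):
                truth = r["truth_population"]
        out.append(
            GenotypeProfile(
                sample_id=str(sid), calls=calls, n_panel_loci=len(calls),
                truth_population=truth,
            )
        )
    return out


def write_genotype_tsv(profiles: Sequence[GenotypeProfile], path: str | Path) -> None:
    rows = []
    for pr in profiles:
        for lid in sorted(pr.calls):
            g = pr.calls[lid]
            rows.append(
                {
                    "sample_id": pr.sample_id,
                    "locus": lid,
                    "allele1": g[0] if g else ".",
                    "allele2": g[1] if g else ".",
                    "truth_population": pr.truth_population or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf_profiles(path: str | Path, panel: ReferencePanel) -> list[GenotypeProfile]:
    """Read profiles from a VCF: biallelic records matched to the panel by rsID.

    ``./.`` genotypes become missing loci; records whose ID is not a panel
    locus are warned about and dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    panel_ids = set(pn.id for pn in panel.loci)
    calls: dict[str, dict[str, Optional[tuple[str, str]]]] = {s: {} for s in samples}
    for rec in vcf:
        rsid = rec.ID
        if rsid not in panel_ids:
            warnings.warn(f"VCF record {rsid!r} not in panel; dropped", stacklevel=2)
            continue
        if len(rec.ALT) != 1:
            raise ValueError(f"VCF record {rsid!r} is not biallelic")
        alleles = [rec.REF] + list(rec.ALT)
        for s, gt in zip(samples, rec.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                calls[s][rsid] = None
            else:
                calls[s][rsid] = tuple(sorted((alleles[a1], alleles[a2])))
    n = len(panel.loci)
    out = []
    for s in samples:
        sample_calls = {lid: calls[s].get(lid) for lid in panel.locus_ids
                        if lid in calls[s]}
        out.append(GenotypeProfile(sample_id=s, calls=sample_calls,
                                   n_panel_loci=len(sample_calls) or n))
    return out


def read_genotype_input(
    path: str | Path,
    fmt: str,
    panel: Optional[ReferencePanel] = None,
):
    """Dispatch to the reader for ``fmt`` in {'depth-tsv', 'genotype-tsv', 'vcf'}."""
    if fmt == "depth-tsv":
        return read_depth_tsv(path)
    if fmt == "genotype-tsv":
        return read_genotype_tsv(path)
    if fmt == "vcf":
        if panel is None:
            raise ValueError("reading VCF requires a reference panel for rsID mapping")
        return read_vcf_profiles(path, panel)
    raise ValueError(f"unknown genotype input format {fmt!r}")


def write_qc_report(report: QCReport, out_dir: str | Path) -> None:
    """Serialise a QC report as CSV tables plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.depth_summary.to_csv(out / "depth_summary.csv")
    report.balance_summary.to_csv(out / "balance_summary.csv")
    report.completeness.to_csv(out / "completeness.csv")
    report.dropout_counts.to_csv(out / "dropout_counts.csv")
    report.success_rate.to_csv(out / "success_rate.csv")
    summary = {
        "n_samples": int(len(report.completeness)),
        "mean_completeness": float(report.completeness.mean()),
        "total_dropouts": int(report.dropout_counts.sum()),
        "success_rate": {
            str(k): float(v) for k, v in report.success_rate["success_rate_pct"].items()
        },
    }
    (out / "qc_summary.json").write_text(json.dumps(summary, indent=2))
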