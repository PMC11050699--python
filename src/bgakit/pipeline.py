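"""End-to-end pipeline: QC -> three predictors -> consensus tables.

``run_pipeline`` wires the modules together the way a casework analysis
would: call genotypes from read counts (or take called profiles directly),
enforce the complete-profile requirement, run the likelihood ranking, the
z-score outlier test and the PCA assignment for every sample, classify
outcomes against truth labels when present, and write per-sample JSON
decisions plus cohort CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .decision import Decision
from .likelihood import predict_by_likelihood
from .panel import ReferencePanel, apply_frequency_floor
from .pca import PcaModel, fit_reference_pca, project_and_assign
from .qc import AlleleDepthProfile, GenotypeProfile, Thresholds, call_genotypes, qc_summary
from .report import OutcomeRecord, agreement_matrix, cohort_accuracy
from .simulate import simulate_individuals
from .zscore import ZTestConfig, genotype_codes, predict_by_zscore
from .io import write_qc_report

log = logging.getLogger("bgakit")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "build_pca_model_from_panel"]

# distinct exit-code families for the CLI
EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_STAGE_ERROR = 4


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``min_completeness`` enforces the complete-profile requirement:
    profiles below it are excluded from prediction (the default 1.0 means
    only complete profiles are analysed; relax it explicitly to predict on
    partial profiles, which is logged as a warning because drop-outs can
    mislead predictions).
    """

    out_dir: Optional[Path] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    ztest: ZTestConfig = field(default_factory=ZTestConfig)
    likelihood_window: float = 1.0
    pca_quantile: float = 0.95
    pca_cohort_size: int = 100
    min_completeness: float = 1.0
    seed: int = 0


@dataclass
class PipelineResult:
    genotypes: list[GenotypeProfile]
    excluded: list[str]
    records: list[OutcomeRecord]
    accuracy: Optional[pd.DataFrame]
    agreement: pd.DataFrame
    qc_report: object = None


def build_pca_model_from_panel(
    panel: ReferencePanel,
    cohort_size: int = 100,
    seed: int = 0,
    admixed_labels: Sequence[str] = (),
) -> PcaModel:
    """Fit the reference PCA on synthetic HWE cohorts drawn from panel frequencies.

    Stands in for real reference individuals when only allele frequencies
    are available: each population contributes ``cohort_size`` simulated
    individuals labelled by its metapopulation.
    """
    codes_rows = []
    labels = []
    for i, pop in enumerate(panel.populations):
        profs = simulate_individuals(panel, pop.name, cohort_size, seed=seed + i)
        for pr in profs:
            codes_rows.append(genotype_codes(pr, panel, panel.locus_ids))
            labels.append(pop.metapopulation)
    X = np.vstack(codes_rows)
    return fit_reference_pca(X, labels, loci=panel.locus_ids,
                             admixed_labels=admixed_labels)


def run_pipeline(
    panel: ReferencePanel,
    profiles: Sequence[AlleleDepthProfile] | Sequence[GenotypeProfile],
    cfg: RunConfig = RunConfig(),
    truth: Optional[dict[str, str]] = None,
    pca_model: Optional[PcaModel] = None,
) -> PipelineResult:
    """Run QC, all three predictors and the consensus tabulation.

    ``profiles`` may be raw read-count profiles (genotypes are then called
    under ``cfg.thresholds``) or already-called genotype profiles.  Truth
    metapopulation labels come from ``truth`` (sample_id -> label) or the
    profiles' ``truth_population`` attribute; without truth, outcome
    classification is skipped and only decisions are reported.
    """
    floored = panel if panel.floor_applied else apply_frequency_floor(panel)

    qc_report = None
    if profiles and isinstance(profiles[0], AlleleDepthProfile):
        genotypes = [
            call_genotypes(p, cfg.thresholds, panel_loci=panel.locus_ids)
            for p in profiles
        ]
        qc_report = qc_summary(list(profiles), genotypes, group_by="input_dna_pg")
    else:
        genotypes = list(profiles)  # type: ignore[arg-type]

    kept, excluded = [], []
    for g in genotypes:
        if g.completeness + 1e-12 >= cfg.min_completeness:
            kept.append(g)
        else:
            excluded.append(g.sample_id)
    if excluded:
        log.warning("excluded %d incomplete profiles: %s", len(excluded), excluded)

    if pca_model is None:
        pca_model = build_pca_model_from_panel(
            floored, cohort_size=cfg.pca_cohort_size, seed=cfg.seed
        )

    records = []
    for g in kept:
        lik = predict_by_likelihood(g, floored, window_log10=cfg.likelihood_window)
        zres = predict_by_zscore(g, floored, cfg.ztest)
        pres = project_and_assign(pca_model, g, panel=floored,
                                  chi2_quantile=cfg.pca_quantile)
        t = (truth or {}).get(g.sample_id, g.truth_population)
        rec = OutcomeRecord(
            sample_id=g.sample_id,
            truth=t,
            decisions={"likelihood": lik.decision, "zscore": zres.decision,
                       "pca": pres.decision},
        )
        if t is not None:
            rec.classify()
        records.append(rec)

    labelled = [r for r in records if r.truth is not None]
    accuracy = cohort_accuracy(labelled) if labelled else None
    agreement = agreement_matrix(records) if records else pd.DataFrame()

    if cfg.out_dir is not None:
        _write_bundle(cfg, records, accuracy, agreement, qc_report, excluded)

    return PipelineResult(
        genotypes=kept, excluded=excluded, records=records,
        accuracy=accuracy, agreement=agreement, qc_report=qc_report,
    )


def _decision_json(d: Decision) -> dict:
    return {"status": d.status, "label": d.label, "candidates": list(d.candidates)}


def _write_bundle(cfg, records, accuracy, agreement, qc_report, excluded) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    decisions = {
        r.sample_id: {
            "truth": r.truth,
            "decisions": {t: _decision_json(d) for t, d in r.decisions.items()},
            "outcomes": r.outcomes,
        }
        for r in records
    }
    (out / "decisions.json").write_text(json.dumps(decisions, indent=2))
    if accuracy is not None:
        accuracy.to_csv(out / "accuracy.csv")
    agreement.to_csv(out / "agreement.csv")
    if qc_report is not None:
        write_qc_report(qc_report, out / "qc")
    cfg_echo = {
        "version": __version__,
        "seed": cfg.seed,
        "excluded_samples": excluded,
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "ztest": dataclasses.asdict(cfg.ztest),
        "likelihood_window": cfg.likelihood_window,
        "pca_quantile": cfg.pca_quantile,
        "min_completeness": cfg.min_completeness,
    }
    (out / "run_config.json").write_text(json.dumps(cfg_echo, indent=2, default=str))
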