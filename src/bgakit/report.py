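"""Consensus reporting across the three ancestry predictors.

Each predictor's decision for a sample is classified against the truth
label (when known) into the field's outcome vocabulary: *correct*
(predicted the truth's metapopulation), *incorrect* (predicted another),
*inconclusive*, or *rejected* (z-score tool only).  Cohort tables count
outcomes per tool and truth group and report both the unconditional
accuracy ``correct / group size`` and the conditional accuracy excluding
rejected samples, ``correct / (group size - rejected)`` — the latter is
never smaller when any sample is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .decision import Decision, INCONCLUSIVE, PREDICTED, REJECTED

__all__ = [
    "OutcomeRecord",
    "classify_outcome",
    "cohort_accuracy",
    "agreement_matrix",
    "CORRECT",
    "INCORRECT",
]

CORRECT = "correct"
INCORRECT = "incorrect"
OUTCOMES = (CORRECT, INCORRECT, INCONCLUSIVE, REJECTED)


@dataclass
class OutcomeRecord:
    """Per-sample decisions of each tool with their classified outcomes."""

    sample_id: str
    truth: Optional[str]
    decisions: dict[str, Decision]                 # tool name -> decision
    outcomes: dict[str, str] = field(default_factory=dict)

    def classify(self) -> "OutcomeRecord":
        self.outcomes = {
            tool: classify_outcome(d, self.truth) for tool, d in self.decisions.items()
        }
        return self


def classify_outcome(decision: Decision, truth: Optional[str]) -> str:
    """Classify one decision against a truth metapopulation label."""
    if decision.status == INCONCLUSIVE:
        return INCONCLUSIVE
    if decision.status == REJECTED:
        return REJECTED
    if truth is None:
        raise ValueError("truth label required to classify a predicted decision")
    return CORRECT if decision.label == truth else INCORRECT


def cohort_accuracy(
    records: Sequence[OutcomeRecord],
    groups: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Tabulate outcome counts and accuracy per tool and truth group.

    ``groups`` optionally maps sample_id to a grouping label; by default
    samples group by their truth label.  Each row carries the four outcome
    counts (summing to the group size), percentage columns, exact fraction
    strings, and the conditional accuracy excluding rejected samples.
    Percentages are rounded to one decimal.
    """
    if not records:
        raise ValueError("cohort_accuracy requires at least one record")
    rows = []
    tools = sorted({t for r in records for t in r.decisions})
    for tool in tools:
        by_group: dict[str, list[OutcomeRecord]] = {}
        for r in records:
            if tool not in r.decisions:
                continue
            key = groups.get(r.sample_id) if groups else r.truth
            if key is None:
                key = "(unlabelled)"
            by_group.setdefault(key, []).append(r)
        for key in sorted(by_group):
            members = by_group[key]
            if not members:  # pragma: no cover - defensive
                warnings.warn(f"empty group {key!r} omitted", stacklevel=2)
                continue
            outs = [
                r.outcomes.get(tool) or classify_outcome(r.decisions[tool], r.truth)
                for r in members
            ]
            n = len(outs)
            counts = {o: outs.count(o) for o in OUTCOMES}
            n_nonrej = n - counts[REJECTED]
            cond = counts[CORRECT] / n_nonrej if n_nonrej else float("nan")
            rows.append(
                {
                    "tool": tool,
                    "group": key,
                    "n": n,
                    **{f"n_{o}": counts[o] for o in OUTCOMES},
                    **{f"pct_{o}": round(100.0 * counts[o] / n, 1) for o in OUTCOMES},
                    "accuracy_fraction": f"{counts[CORRECT]}/{n}",
                    "conditional_fraction": f"{counts[CORRECT]}/{n_nonrej}",
                    "pct_correct_conditional": round(100.0 * cond, 1)
                    if n_nonrej
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows).set_index(["tool", "group"])


def agreement_matrix(records: Sequence[OutcomeRecord]) -> pd.DataFrame:
    """Symmetric tool x tool matrix counting samples where decisions agree.

    Two tools agree on a sample when their decisions share status and label
    (truth is not needed, so unlabelled cohorts tabulate too).
    """
    tools = sorted({t for r in records for t in r.decisions})
    mat = pd.DataFrame(0, index=tools, columns=tools, dtype=int)
    for r in records:
        keys = {t: (d.status, d.label) for t, d in r.decisions.items()}
        for a in keys:
            for b in keys:
                if keys[a] == keys[b]:
                    mat.loc[a, b] += 1
    return mat
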