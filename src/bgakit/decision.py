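"""Uniform decision record shared by the three ancestry predictors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PREDICTED = "predicted"
INCONCLUSIVE = "inconclusive"
REJECTED = "rejected"


@dataclass(frozen=True)
class Decision:
    """Outcome of one predictor for one sample.

    ``status`` is ``predicted`` (with ``label`` the assigned metapopulation
    or cluster), ``inconclusive``, or ``rejected`` (z-score tool only: no
    reference population was plausible).  ``candidates`` lists the
    populations that remained in contention, where the tool defines such a
    set.
    """

    status: str
    label: Optional[str] = None
    candidates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in (PREDICTED, INCONCLUSIVE, REJECTED):
            raise ValueError(f"unknown decision status {self.status!r}")
        if self.status == PREDICTED and self.label is None:
            raise ValueError("a predicted decision needs a label")
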