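"""Function-classification decision flow and prediction-vs-assay evaluation.

A query compound passes through four gates in order: docking acceptance,
MD stability, profile correlation against the active-state agonist
signature (strictly greater than the R threshold), and binding energy
(strictly more negative than the energy threshold).  Only a compound
passing all four is called an agonist; otherwise it is a non-agonist,
optionally flagged as an antagonist candidate when its correlation with
the inactive-state antagonist signature clears the same R threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "CompoundEvidence",
    "FunctionCall",
    "AssayOutcome",
    "EvaluationSummary",
    "classify",
    "evaluate",
    "combine_selectivity",
    "R_THRESHOLD",
    "DE_THRESHOLD",
]

R_THRESHOLD = 0.84
DE_THRESHOLD = -10.0  # kcal/mol

AGONIST = "AGONIST"
NON_AGONIST = "NON_AGONIST"
ANTAGONIST = "ANTAGONIST"
INACTIVE = "INACTIVE"
ANTAGONIST_CANDIDATE = "ANTAGONIST_CANDIDATE"
UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class CompoundEvidence:
    """Per-compound inputs to the decision flow.

    Docking and MD stability enter as precomputed booleans; docking and
    simulation themselves are upstream of this package.
    """

    compound_id: str
    docking_pass: bool
    md_stable: bool
    r_active: float
    de: float
    receptor: str = "CB2"
    r_inactive: float | None = None

    def __post_init__(self) -> None:
        if self.r_active is None or not math.isfinite(self.r_active):
            raise ValueError(f"{self.compound_id}: r_active is required and finite")
        if not -1.0 <= self.r_active <= 1.0:
            raise ValueError(f"{self.compound_id}: r_active outside [-1, 1]")
        if self.r_inactive is not None and not -1.0 <= self.r_inactive <= 1.0:
            raise ValueError(f"{self.compound_id}: r_inactive outside [-1, 1]")
        if not math.isfinite(self.de):
            raise ValueError(f"{self.compound_id}: de must be finite")


@dataclass(frozen=True)
class FunctionCall:
    compound_id: str
    predicted: str  # AGONIST | NON_AGONIST
    non_agonist_subclass: str | None  # ANTAGONIST_CANDIDATE | UNDETERMINED | None
    rationale: tuple[str, ...]


@dataclass(frozen=True)
class AssayOutcome:
    compound_id: str
    truth: str  # AGONIST | ANTAGONIST | INACTIVE
    receptor: str = "CB2"
    ec50_um: float | None = None
    ic50_um: float | None = None

    def __post_init__(self) -> None:
        if self.truth not in (AGONIST, ANTAGONIST, INACTIVE):
            raise ValueError(f"unknown assay truth {self.truth!r}")
        if self.truth == AGONIST and self.ic50_um is not None:
            raise ValueError(f"{self.compound_id}: agonist outcome carries IC50")
        if self.truth == ANTAGONIST and self.ec50_um is not None:
            raise ValueError(f"{self.compound_id}: antagonist outcome carries EC50")
        if self.truth == INACTIVE and (
            self.ec50_um is not None or self.ic50_um is not None
        ):
            raise ValueError(f"{self.compound_id}: inactive outcome carries potency")


@dataclass(frozen=True)
class EvaluationSummary:
    n_total: int
    n_pred_agonist: int
    n_pred_non_agonist: int
    n_correct_agonist: int
    n_correct_antagonist: int
    n_correct_inactive: int
    overall_accuracy_pct: int
    agonist_success_pct: int


def classify(
    evidence: CompoundEvidence,
    r_threshold: float = R_THRESHOLD,
    de_threshold: float = DE_THRESHOLD,
) -> FunctionCall:
    """Apply the four-gate decision flow to one compound."""
    gates = [
        ("docking", evidence.docking_pass),
        ("md_stable", evidence.md_stable),
        ("r_active", evidence.r_active > r_threshold),
        ("binding_energy", evidence.de < de_threshold),
    ]
    rationale = tuple(
        f"{name}: {'pass' if passed else 'fail'}" for name, passed in gates
    )
    if all(passed for _, passed in gates):
        return FunctionCall(
            compound_id=evidence.compound_id,
            predicted=AGONIST,
            non_agonist_subclass=None,
            rationale=rationale,
        )
    subclass = UNDETERMINED
    if evidence.r_inactive is not None and evidence.r_inactive > r_threshold:
        subclass = ANTAGONIST_CANDIDATE
    return FunctionCall(
        compound_id=evidence.compound_id,
        predicted=NON_AGONIST,
        non_agonist_subclass=subclass,
        rationale=rationale,
    )


def _is_correct(predicted: str, truth: str) -> bool:
    if predicted == AGONIST:
        return truth == AGONIST
    return truth in (ANTAGONIST, INACTIVE)


def evaluate(
    calls: Sequence[FunctionCall], outcomes: Sequence[AssayOutcome]
) -> EvaluationSummary:
    """Tally predictions against assay outcomes.

    A prediction is correct when agonist matches agonist, or when a
    non-agonist call meets an antagonist or inactive outcome.
    """
    call_ids = {c.compound_id for c in calls}
    outcome_ids = {o.compound_id for o in outcomes}
    if call_ids != outcome_ids:
        unmatched = sorted(call_ids.symmetric_difference(outcome_ids))
        raise ValueError(f"unmatched compound ids: {unmatched}")
    if len(call_ids) != len(calls) or len(outcome_ids) != len(outcomes):
        raise ValueError("duplicate compound ids")

    truth_by_id = {o.compound_id: o.truth for o in outcomes}
    n_pred_agonist = sum(1 for c in calls if c.predicted == AGONIST)
    n_pred_non = len(calls) - n_pred_agonist
    n_correct_ag = sum(
        1
        for c in calls
        if c.predicted == AGONIST and truth_by_id[c.compound_id] == AGONIST
    )
    n_correct_ant = sum(
        1
        for c in calls
        if c.predicted == NON_AGONIST and truth_by_id[c.compound_id] == ANTAGONIST
    )
    n_correct_ina = sum(
        1
        for c in calls
        if c.predicted == NON_AGONIST and truth_by_id[c.compound_id] == INACTIVE
    )
    n_total = len(calls)
    n_correct = n_correct_ag + n_correct_ant + n_correct_ina
    # nearest-integer percent, halves up
    overall = int(100.0 * n_correct / n_total + 0.5) if n_total else 0
    success = (
        int(100.0 * n_correct_ag / n_pred_agonist + 0.5) if n_pred_agonist else 0
    )
    return EvaluationSummary(
        n_total=n_total,
        n_pred_agonist=n_pred_agonist,
        n_pred_non_agonist=n_pred_non,
        n_correct_agonist=n_correct_ag,
        n_correct_antagonist=n_correct_ant,
        n_correct_inactive=n_correct_ina,
        overall_accuracy_pct=overall,
        agonist_success_pct=success,
    )


def combine_selectivity(cb2_call: FunctionCall, cb1_call: FunctionCall) -> str:
    """Combine per-receptor calls into a selectivity verdict."""
    if cb2_call.predicted == AGONIST and cb1_call.predicted == NON_AGONIST:
        return "CB2_SELECTIVE_AGONIST"
    if cb2_call.predicted == AGONIST and cb1_call.predicted == AGONIST:
        return "NONSELECTIVE_AGONIST"
    return "OTHER"
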