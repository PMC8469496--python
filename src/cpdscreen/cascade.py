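"""The screening cascade: composite score, reactive exclusion, subtype flags.

The cascade mirrors routine triage of a full blood count.  Stage 1 computes
the composite neoplastic score
``(SD-V-NE x MN-UMALS-LY x SD-AL2-MO) / MN-C-NE`` and compares it against
its cutoff (106.44 in the published registry); samples at or below the
cutoff stop as non-neoplastic.  Stage 2 applies the reactive discriminant
(MN-AL2-NE at 147.5) to rule out infection-driven reactive samples.
Samples still flagged neoplastic are then screened by the subtype rules
(AML, APL, ALL, CLL), which are advisory and independent — a sample can
raise several flags, or none.

Every comparison is appended to an audit trail, so a flag raised on a
sample can be traced back to the exact parameter values and cutoffs that
produced it.

:class:`CascadeClassifier` wraps the cascade as a scikit-learn estimator
operating on a DataFrame with CPD-parameter columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import NEOPLASTIC, NON_NEOPLASTIC, Cohort, CPDRecord
from .parameters import CPDParameter, is_parameter_name, parse_parameter
from .rules import (
    COMPOSITE_NEOPLASTIC_RULE,
    REACTIVE_RULE,
    DiscriminantRule,
    MissingParameterError,
    RulesRegistry,
)


@dataclass(frozen=True)
class AuditEntry:
    """One rule evaluation: inputs, score, comparison, and outcome."""

    rule: str
    inputs: tuple[tuple[str, float], ...]
    score: float
    comparison: str
    outcome: str

    def as_dict(self) -> dict:
        return {
            "rule": self.rule,
            "inputs": dict(self.inputs),
            "score": self.score,
            "comparison": self.comparison,
            "outcome": self.outcome,
        }


@dataclass
class CascadeResult:
    """Outcome of the full cascade for one sample."""

    sample_id: str
    composite_score: float
    stage1_label: str
    stage2_label: str | None = None
    subtype_flags: dict[str, bool | None] = field(default_factory=dict)
    rule_flags: dict[str, bool | None] = field(default_factory=dict)
    audit_trail: list[AuditEntry] = field(default_factory=list)

    @property
    def final_label(self) -> str:
        if self.stage1_label == NON_NEOPLASTIC:
            return NON_NEOPLASTIC
        return self.stage2_label or self.stage1_label


def _comparison_text(rule: DiscriminantRule) -> str:
    op = ">" if rule.orientation == "high_is_positive" else "<"
    return f"score {op} {rule.cutoff:g} -> {rule.positive_label}"


def apply_rule(record: CPDRecord, rule: DiscriminantRule) -> tuple[str, AuditEntry]:
    """Score a record under a rule and return (label, audit entry).

    A score strictly beyond the cutoff in the positive direction yields the
    positive label; equality always yields the negative label.
    """
    score = rule.score(record)
    label = rule.decide(score)
    entry = AuditEntry(
        rule=rule.name,
        inputs=tuple((str(p), record.values[p]) for p in rule.parameters),
        score=score,
        comparison=_comparison_text(rule),
        outcome=label,
    )
    return label, entry


def composite_score(
    record: CPDRecord, rule: DiscriminantRule = COMPOSITE_NEOPLASTIC_RULE
) -> float:
    """Composite neoplastic score: (SD-V-NE x MN-UMALS-LY x SD-AL2-MO) / MN-C-NE.

    Requires all four parameters present (no imputation) and MN-C-NE > 0.
    """
    return rule.score(record)


def reactive_discriminant(
    record: CPDRecord, rule: DiscriminantRule = REACTIVE_RULE
) -> tuple[str, AuditEntry]:
    """Classify neoplastic vs reactive on MN-AL2-NE.

    The rule must carry an explicit orientation (the shipped default,
    low_is_positive for the neoplastic label, is provisional and
    configurable); an unset orientation raises an error rather than
    guessing.
    """
    return apply_rule(record, rule)


def subtype_flags(
    record: CPDRecord,
    rules: dict[str, tuple[DiscriminantRule, ...]],
) -> tuple[dict[str, bool | None], dict[str, bool | None], list[AuditEntry]]:
    """Evaluate the leukaemia-subtype rules on a record.

    Returns (per-subtype summary, per-rule flags, audit entries).  A
    subtype is flagged if any of its rules is positive.  Rules whose input
    parameter is absent evaluate to None ("not evaluated"), never False;
    a subtype with no evaluable rule is None.
    """
    summary: dict[str, bool | None] = {}
    per_rule: dict[str, bool | None] = {}
    trail: list[AuditEntry] = []
    for subtype, subtype_rules in rules.items():
        evaluated: list[bool] = []
        for rule in subtype_rules:
            try:
                label, entry = apply_rule(record, rule)
            except MissingParameterError:
                per_rule[rule.name] = None
                continue
            flag = label == rule.positive_label
            per_rule[rule.name] = flag
            evaluated.append(flag)
            trail.append(entry)
        summary[subtype] = any(evaluated) if evaluated else None
    return summary, per_rule, trail


def cascade_classify(
    record: CPDRecord, registry: RulesRegistry | None = None
) -> CascadeResult:
    """Run the full decision cascade on one record.

    Stage 1 (composite score vs cutoff) decides neoplastic vs
    non-neoplastic; non-neoplastic samples short-circuit.  Stage 2 applies
    the reactive discriminant; reactive samples stop there.  Remaining
    samples get the advisory subtype flags.  Errors are re-raised with the
    failing stage named.
    """
    registry = registry or RulesRegistry()
    try:
        label1, entry1 = apply_rule(record, registry.composite)
    except ValueError as exc:
        raise type(exc)(f"stage 1 (composite screen): {exc}") from exc
    result = CascadeResult(
        sample_id=record.sample_id,
        composite_score=entry1.score,
        stage1_label=label1,
        audit_trail=[entry1],
    )
    if label1 != registry.composite.positive_label:
        return result
    try:
        label2, entry2 = reactive_discriminant(record, registry.reactive)
    except ValueError as exc:
        raise type(exc)(f"stage 2 (reactive exclusion): {exc}") from exc
    result.stage2_label = label2
    result.audit_trail.append(entry2)
    if label2 != registry.reactive.positive_label:
        return result
    summary, per_rule, trail = subtype_flags(record, registry.subtypes)
    result.subtype_flags = summary
    result.rule_flags = per_rule
    result.audit_trail.extend(trail)
    return result


def _row_to_record(sample_id: str, row: pd.Series, params: dict[str, CPDParameter]) -> CPDRecord:
    values = {
        p: float(row[col]) for col, p in params.items() if pd.notna(row[col])
    }
    return CPDRecord(sample_id=sample_id, values=values)


class CascadeClassifier(ClassifierMixin, BaseEstimator):
    """Rule-cascade screen for neoplastic blood samples, sklearn style.

    Applies a fixed registry of published discriminant rules; ``fit`` only
    validates that the required parameter columns are present (the rules
    are calibrated separately, see :class:`cpdscreen.calibration.DiscriminantCalibrator`).

    Parameters
    ----------
    registry : RulesRegistry or None
        Rule set to apply; None uses the published defaults.

    Attributes
    ----------
    classes_ : ndarray
        ``["neoplastic", "non-neoplastic"]`` stage-1 labels.
    feature_names_in_ : ndarray of str
        Parameter columns required by the stage-1 composite rule.
    """

    def __init__(self, registry: RulesRegistry | None = None):
        self.registry = registry

    def _registry(self) -> RulesRegistry:
        return self.registry if self.registry is not None else RulesRegistry()

    def fit(self, X: pd.DataFrame, y=None) -> "CascadeClassifier":
        X = self._validate_frame(X)
        reg = self._registry()
        self.classes_ = np.array(
            sorted([reg.composite.positive_label, reg.composite.negative_label])
        )
        self.feature_names_in_ = np.array(
            [str(p) for p in reg.composite.parameters]
        )
        self.n_features_in_ = len(self.feature_names_in_)
        return self

    def _validate_frame(self, X) -> pd.DataFrame:
        if isinstance(X, Cohort):
            X = X.to_frame().set_index("sample_id")
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "CascadeClassifier expects a DataFrame with CPD-parameter "
                "columns (or a Cohort)"
            )
        reg = self._registry()
        missing = [
            str(p)
            for p in reg.composite.parameters
            if str(p) not in X.columns
        ]
        if missing:
            raise ValueError(f"missing required parameter columns: {missing}")
        return X

    def _param_columns(self, X: pd.DataFrame) -> dict[str, CPDParameter]:
        return {
            col: parse_parameter(col)
            for col in X.columns
            if is_parameter_name(col)
        }

    def classify(self, X) -> list[CascadeResult]:
        """Run the full cascade per row, returning rich results."""
        check_is_fitted(self)
        X = self._validate_frame(X)
        params = self._param_columns(X)
        reg = self._registry()
        return [
            cascade_classify(_row_to_record(str(idx), row, params), reg)
            for idx, row in X.iterrows()
        ]

    def decision_function(self, X) -> np.ndarray:
        """Composite neoplastic score per row."""
        check_is_fitted(self)
        X = self._validate_frame(X)
        params = self._param_columns(X)
        reg = self._registry()
        return np.array(
            [
                reg.composite.score(_row_to_record(str(i), row, params))
                for i, row in X.iterrows()
            ]
        )

    def predict(self, X) -> np.ndarray:
        """Stage-1 screening label (neoplastic / non-neoplastic) per row."""
        reg = self._registry()
        scores = self.decision_function(X)
        return np.where(
            scores > reg.composite.cutoff,
            reg.composite.positive_label,
            reg.composite.negative_label,
        )

    def results_frame(self, X) -> pd.DataFrame:
        """Tabular cascade output: scores, stage labels, subtype flags."""
        rows = []
        for res in self.classify(X):
            row = {
                "sample_id": res.sample_id,
                "composite_score": res.composite_score,
                "stage1_label": res.stage1_label,
                "stage2_label": res.stage2_label,
                "final_label": res.final_label,
            }
            for subtype in self._registry().subtypes:
                row[f"flag_{subtype}"] = res.subtype_flags.get(subtype)
            rows.append(row)
        return pd.DataFrame(rows)
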