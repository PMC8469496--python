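"""Re-derive CPD discriminants from a labelled cohort.

The calibration pipeline mirrors the statistical procedure used to derive
the published rules: per-parameter hypothesis tests gate candidates at
p < 0.05, candidates go to ROC analysis, parameters are kept above an AUC
floor (0.9 for the neoplastic screen, 0.7 for subtype discriminants), and
cutoffs are placed on the empirical ROC while maintaining sensitivity and
specificity.

Two-group contrasts use a two-tailed t-test (Welch form by default).
Multi-group screens branch on Levene's homogeneity-of-variance test:
homogeneous variances go to one-way ANOVA with Tukey HSD post hoc tests,
heterogeneous variances to a Welch ANOVA with Games-Howell post hoc tests.
Kolmogorov-Smirnov normality (Lilliefors-corrected) is recorded per group
but does not gate the pipeline.

The empirical AUC equals the Mann-Whitney probability that a random
positive scores beyond a random negative (ties count one half); its 95% CI
is computed by DeLong's method (Hanley-McNeil available).  Cutoffs default
to Youden's J with deterministic tie-breaking, placed at the midpoint
between the adjacent distinct observed values bracketing the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .cohort import NEOPLASTIC, NON_NEOPLASTIC, Cohort
from .parameters import CPDParameter
from .rules import (
    HIGH_IS_POSITIVE,
    LOW_IS_POSITIVE,
    DiscriminantRule,
    RulesRegistry,
)

P_SELECT = 0.05


class DegenerateDataError(ValueError):
    """A sample or group is too small or has zero variance."""


class InfeasibleCutoffError(ValueError):
    """No threshold satisfies the constrained sensitivity/specificity floor."""


# --------------------------------------------------------------------------
# Hypothesis tests
# --------------------------------------------------------------------------

def ks_normality(values: Sequence[float]) -> float:
    """Lilliefors-corrected Kolmogorov-Smirnov normality p-value.

    Tests against a normal distribution with mean and SD estimated from
    the data (the correction SPSS applies in its K-S normality test).
    Requires n >= 4 and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise DegenerateDataError(f"normality test needs n >= 4, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("normality test undefined for a constant sample")
    _, p = lilliefors(x, dist="norm")
    return float(p)


@dataclass
class ParameterScreenResult:
    """Outcome of the candidate screen for one parameter."""

    parameter: CPDParameter | None
    test_used: str
    p_value: float
    normality_p: dict[str, float | None] = field(default_factory=dict)
    selected: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.selected = self.p_value < P_SELECT


def group_difference_test(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = False,
    parameter: CPDParameter | None = None,
    group_names: tuple[str, str] = ("a", "b"),
) -> ParameterScreenResult:
    """Two-tailed two-sample t-test (Welch by default).

    Records Lilliefors normality per group when n permits.  Raises if both
    groups are degenerate (no variance to test against).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise DegenerateDataError("each group needs n >= 2")
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        if xa[0] == xb[0]:
            # identical constants: no evidence of difference
            p = 1.0
        else:
            raise DegenerateDataError("both groups have zero variance")
    else:
        _, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        p = float(p)
    normality: dict[str, float | None] = {}
    for name, x in zip(group_names, (xa, xb)):
        try:
            normality[name] = ks_normality(x)
        except DegenerateDataError:
            normality[name] = None
    return ParameterScreenResult(
        parameter=parameter,
        test_used="welch_t" if not equal_var else "student_t",
        p_value=min(max(p, 0.0), 1.0),
        normality_p=normality,
    )


@dataclass
class MultiGroupScreenResult:
    """Omnibus + post hoc outcome for a >= 3-group comparison."""

    parameter: CPDParameter | None
    levene_p: float
    homogeneous: bool
    test_used: str  # "anova_tukey" or "welch_anova_games_howell"
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]
    welch_p: float
    normality_p: dict[str, float | None]
    selected: bool

    @property
    def p_value(self) -> float:
        return self.omnibus_p


def multi_group_screen(
    groups: Mapping[str, Sequence[float]],
    parameter: CPDParameter | None = None,
    levene_alpha: float = 0.05,
) -> MultiGroupScreenResult:
    """Screen a parameter across >= 3 groups with variance-aware branching.

    Levene's test (mean-centred) decides the branch: homogeneous variances
    use one-way ANOVA with Tukey HSD pairwise comparisons; heterogeneous
    variances use a Welch ANOVA with Games-Howell pairwise comparisons.
    The omnibus p-value gates selection at p < 0.05; the Welch omnibus p is
    always recorded alongside for confirmation.
    """
    import pingouin as pg

    if len(groups) < 3:
        raise ValueError("multi_group_screen needs >= 3 groups")
    arrays: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        if x.size < 2:
            raise DegenerateDataError(f"group {name!r} needs n >= 2")
        if np.ptp(x) == 0:
            raise DegenerateDataError(f"group {name!r} has zero variance")
        arrays[name] = x

    names = list(arrays)
    _, levene_p = stats.levene(*arrays.values(), center="mean")
    homogeneous = levene_p >= levene_alpha

    long = pd.DataFrame(
        {
            "value": np.concatenate(list(arrays.values())),
            "group": np.repeat(names, [len(arrays[n]) for n in names]),
        }
    )
    welch_table = pg.welch_anova(data=long, dv="value", between="group")
    pcol = "p_unc" if "p_unc" in welch_table.columns else "p-unc"
    welch_p = float(welch_table[pcol].iloc[0])

    pairwise: dict[tuple[str, str], float] = {}
    if homogeneous:
        _, omnibus_p = stats.f_oneway(*arrays.values())
        tukey = pairwise_tukeyhsd(long["value"], long["group"])
        summary = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        for _, row in summary.iterrows():
            pairwise[(str(row["group1"]), str(row["group2"]))] = float(row["p-adj"])
        test_used = "anova_tukey"
        omnibus_p = float(omnibus_p)
    else:
        omnibus_p = welch_p
        gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        for _, row in gh.iterrows():
            pairwise[(str(row["A"]), str(row["B"]))] = float(row["pval"])
        test_used = "welch_anova_games_howell"

    normality = {}
    for name, x in arrays.items():
        try:
            normality[name] = ks_normality(x)
        except DegenerateDataError:
            normality[name] = None

    return MultiGroupScreenResult(
        parameter=parameter,
        levene_p=float(levene_p),
        homogeneous=homogeneous,
        test_used=test_used,
        omnibus_p=min(max(omnibus_p, 0.0), 1.0),
        pairwise_p=pairwise,
        welch_p=welch_p,
        normality_p=normality,
        selected=omnibus_p < P_SELECT,
    )


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Empirical ROC of one score against a binary outcome.

    ``thresholds`` are candidate cutoffs at midpoints between adjacent
    distinct observed values; ``sensitivity``/``specificity`` are evaluated
    there under ``orientation`` (chosen so AUC >= 0.5 and recorded
    explicitly, never inferred later).  ``auc`` is the Mann-Whitney
    estimate (ties half-weighted); ``auc_ci`` is a 95% interval.
    """

    parameter: CPDParameter | None
    orientation: str
    auc: float
    auc_ci: tuple[float, float]
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_positive: int
    n_negative: int
    chosen_cutoff: float | None = None
    sens_at_cutoff: float | None = None
    spec_at_cutoff: float | None = None


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float, level: float) -> tuple[float, float]:
    """DeLong 95% CI for the AUC, midrank form (handles ties)."""
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - stats.rankdata(neg)) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def _hanley_mcneil_ci(m: int, n: int, auc: float, level: float) -> tuple[float, float]:
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc(
    values: Sequence[float],
    labels: Sequence,
    positive_label=1,
    parameter: CPDParameter | None = None,
    ci_method: str = "delong",
    level: float = 0.95,
) -> ROCResult:
    """Empirical ROC analysis of a score against binary class labels.

    The AUC equals the probability a random positive scores beyond a random
    negative (ties one half); the orientation is flipped (and recorded) if
    the raw AUC falls below 0.5, so the reported AUC is always >= 0.5.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray([lbl == positive_label for lbl in labels], dtype=bool)
    if x.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    if y.all() or (~y).all():
        raise ValueError("ROC needs both classes present")

    auc_raw = float(roc_auc_score(y, x))
    orientation = HIGH_IS_POSITIVE
    auc = auc_raw
    if auc_raw < 0.5:
        orientation = LOW_IS_POSITIVE
        auc = 1.0 - auc_raw

    pos, neg = x[y], x[~y]
    if orientation == LOW_IS_POSITIVE:
        # DeLong variance is orientation-symmetric under negation
        pos_o, neg_o = -pos, -neg
    else:
        pos_o, neg_o = pos, neg
    if ci_method == "delong":
        ci = _delong_ci(pos_o, neg_o, auc, level)
    elif ci_method == "hanley":
        ci = _hanley_mcneil_ci(len(pos), len(neg), auc, level)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    distinct = np.unique(x)
    if distinct.size < 2:
        raise DegenerateDataError("all observed values identical; no ROC thresholds")
    thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    if orientation == HIGH_IS_POSITIVE:
        sens = np.array([(pos > t).mean() for t in thresholds])
        spec = np.array([(neg <= t).mean() for t in thresholds])
    else:
        sens = np.array([(pos < t).mean() for t in thresholds])
        spec = np.array([(neg >= t).mean() for t in thresholds])

    return ROCResult(
        parameter=parameter,
        orientation=orientation,
        auc=auc,
        auc_ci=ci,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        n_positive=len(pos),
        n_negative=len(neg),
    )


def select_cutoff(
    roc_result: ROCResult,
    policy: str = "youden",
    min_sens: float = 0.80,
    min_spec: float = 0.80,
) -> ROCResult:
    """Choose a cutoff on an empirical ROC.

    ``youden`` maximises J = sensitivity + specificity - 1; ties are broken
    by minimising |sensitivity - specificity|, then by the lower threshold.
    ``constrained`` applies the same optimisation restricted to thresholds
    with sensitivity and specificity both at or above their floors (0.80
    by default) and raises :class:`InfeasibleCutoffError` if none qualify.
    The returned copy carries the chosen cutoff (a midpoint between
    adjacent observed values) and its sensitivity/specificity.
    """
    sens, spec, thr = roc_result.sensitivity, roc_result.specificity, roc_result.thresholds
    candidates = np.arange(len(thr))
    if policy == "constrained":
        ok = (sens >= min_sens) & (spec >= min_spec)
        if not ok.any():
            raise InfeasibleCutoffError(
                f"no threshold reaches sensitivity >= {min_sens} and "
                f"specificity >= {min_spec}"
            )
        candidates = candidates[ok]
    elif policy != "youden":
        raise ValueError(f"unknown cutoff policy {policy!r}")

    j = sens[candidates] + spec[candidates] - 1.0
    best_j = j.max()
    tied = candidates[np.isclose(j, best_j)]
    balance = np.abs(sens[tied] - spec[tied])
    tied = tied[np.isclose(balance, balance.min())]
    idx = tied[np.argmin(thr[tied])]
    return replace(
        roc_result,
        chosen_cutoff=float(thr[idx]),
        sens_at_cutoff=float(sens[idx]),
        spec_at_cutoff=float(spec[idx]),
    )


# --------------------------------------------------------------------------
# Cohort-level screening and composite building
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """Binary contrast over cohort groups or coarse classes.

    ``positive`` and ``negative`` are sets of labels matched
    case-insensitively against each record's fine group and its coarse
    class, so ``Contrast({"neoplastic"}, {"non-neoplastic"})`` and
    ``Contrast({"aml"}, {"apl", "all", "cll", "lymphoma"})`` both work.
    Records matching neither side are excluded.
    """

    positive: frozenset[str]
    negative: frozenset[str]
    name: str = "contrast"

    def __init__(self, positive, negative, name="contrast"):
        object.__setattr__(self, "positive", frozenset(s.lower() for s in positive))
        object.__setattr__(self, "negative", frozenset(s.lower() for s in negative))
        object.__setattr__(self, "name", name)

    def side(self, group: str | None, coarse: str | None) -> bool | None:
        """True = positive, False = negative, None = excluded."""
        for label in (group, coarse):
            if label is None:
                continue
            if label.lower() in self.positive:
                return True
            if label.lower() in self.negative:
                return False
        return None


NEOPLASTIC_CONTRAST = Contrast({NEOPLASTIC}, {NON_NEOPLASTIC}, "neoplastic-screen")
REACTIVE_CONTRAST = Contrast(
    {"aml", "apl", "apml", "all", "lymphoma", "cll", "cml", "mds"},
    {"reactive"},
    "reactive-exclusion",
)


def _contrast_values(
    cohort: Cohort, parameter: CPDParameter, contrast: Contrast
) -> tuple[np.ndarray, np.ndarray]:
    pos, neg = [], []
    for rec in cohort:
        side = contrast.side(rec.group, cohort.coarse_class(rec))
        if side is None or parameter not in rec.values:
            continue
        (pos if side else neg).append(rec.values[parameter])
    return np.asarray(pos), np.asarray(neg)


def screen_parameters(
    cohort: Cohort,
    contrast: Contrast,
    auc_min: float = 0.9,
    p_max: float = P_SELECT,
    equal_var: bool = False,
    ci_method: str = "delong",
    correction: str | None = None,
) -> list[ROCResult]:
    """Screen every cohort parameter for discriminating power.

    Per parameter: two-tailed t-test between contrast classes (gate at
    ``p_max``), then ROC; parameters whose AUC exceeds ``auc_min`` are
    returned ranked by AUC descending.  ``correction="fdr_bh"`` applies
    Benjamini-Hochberg across the candidate p-values before gating (off by
    default, matching the original derivation).
    """
    params = cohort.parameters()
    tested: list[tuple[CPDParameter, float, np.ndarray, np.ndarray]] = []
    for param in params:
        pos, neg = _contrast_values(cohort, param, contrast)
        if pos.size == 0 or neg.size == 0:
            raise ValueError(
                f"contrast {contrast.name!r}: a class has no values for {param}"
            )
        try:
            res = group_difference_test(neg, pos, equal_var=equal_var, parameter=param)
        except DegenerateDataError:
            continue
        tested.append((param, res.p_value, pos, neg))

    pvals = [t[1] for t in tested]
    if correction == "fdr_bh" and pvals:
        pvals = list(multipletests(pvals, method="fdr_bh")[1])

    results: list[ROCResult] = []
    for (param, _, pos, neg), p in zip(tested, pvals):
        if p >= p_max:
            continue
        values = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
        r = roc(values, labels, positive_label=1, parameter=param, ci_method=ci_method)
        if r.auc > auc_min:
            results.append(r)
    results.sort(key=lambda r: r.auc, reverse=True)
    return results


def build_composite(
    cohort: Cohort,
    contrast: Contrast,
    selected: Sequence[ROCResult],
    positive_label: str = NEOPLASTIC,
    negative_label: str = NON_NEOPLASTIC,
    cutoff_policy: str = "youden",
    name: str = "composite",
) -> tuple[DiscriminantRule, ROCResult]:
    """Combine selected parameters into a product/quotient composite rule.

    Positively oriented parameters multiply into the numerator and
    negatively oriented ones into the denominator; the cutoff is then
    re-derived by ROC + cutoff selection on the composite scores over the
    contrast, reported to 2 decimals.
    """
    if not selected:
        raise ValueError("no parameters selected for the composite")
    numerator, denominator = [], []
    for r in selected:
        if r.parameter is None or r.orientation is None:
            raise ValueError("composite needs parameters with known orientation")
        (numerator if r.orientation == HIGH_IS_POSITIVE else denominator).append(
            r.parameter
        )
    draft = DiscriminantRule(
        name=name,
        numerator=tuple(numerator),
        denominator=tuple(denominator),
        cutoff=0.0,
        orientation=HIGH_IS_POSITIVE,
        positive_label=positive_label,
        negative_label=negative_label,
    )
    scores, labels = [], []
    for rec in cohort:
        side = contrast.side(rec.group, cohort.coarse_class(rec))
        if side is None or not rec.is_scoreable(draft.parameters):
            continue
        scores.append(draft.score(rec))
        labels.append(1 if side else 0)
    composite_roc = select_cutoff(
        roc(scores, labels, positive_label=1), policy=cutoff_policy
    )
    rule = replace(
        draft,
        cutoff=round(composite_roc.chosen_cutoff, 2),
        orientation=composite_roc.orientation,
    )
    return rule, composite_roc


class DiscriminantCalibrator(BaseEstimator):
    """Learn a CPD discriminant rule set from a labelled cohort.

    scikit-learn-style estimator: ``fit`` takes a DataFrame of CPD
    parameter columns and a binary label vector, screens parameters
    (t-test gate, ROC, AUC floor), builds the product/quotient composite,
    and derives its cutoff; ``predict`` applies the fitted composite rule.

    Parameters
    ----------
    auc_min : float
        AUC floor for keeping a parameter (0.9 for the neoplastic screen).
    p_max : float
        Candidate gate on the two-tailed t-test p-value.
    cutoff_policy : {"youden", "constrained"}
        Cutoff-selection policy on the composite ROC.
    equal_var : bool
        Use the Student (pooled-variance) t form instead of Welch.
    ci_method : {"delong", "hanley"}
        AUC confidence-interval method.
    correction : None or "fdr_bh"
        Optional multiplicity correction across parameters.
    positive_label, negative_label : str
        Labels emitted by the fitted rule.

    Attributes
    ----------
    screen_results_ : list of ROCResult
        Parameters passing the screen, ranked by AUC descending.
    rule_ : DiscriminantRule
        Fitted composite rule (cutoff re-derived on the training data).
    roc_ : ROCResult
        Composite-score ROC with the chosen cutoff.
    """

    def __init__(
        self,
        auc_min: float = 0.9,
        p_max: float = P_SELECT,
        cutoff_policy: str = "youden",
        equal_var: bool = False,
        ci_method: str = "delong",
        correction: str | None = None,
        positive_label: str = NEOPLASTIC,
        negative_label: str = NON_NEOPLASTIC,
    ):
        self.auc_min = auc_min
        self.p_max = p_max
        self.cutoff_policy = cutoff_policy
        self.equal_var = equal_var
        self.ci_method = ci_method
        self.correction = correction
        self.positive_label = positive_label
        self.negative_label = negative_label

    def _to_cohort(self, X: pd.DataFrame, y) -> Cohort:
        from .cohort import CPDRecord
        from .parameters import is_parameter_name, parse_parameter

        params = {c: parse_parameter(c) for c in X.columns if is_parameter_name(c)}
        if not params:
            raise ValueError("X has no CPD-parameter columns")
        y = np.asarray(y)
        records = []
        for i, (idx, row) in enumerate(X.iterrows()):
            values = {
                p: float(row[c]) for c, p in params.items() if pd.notna(row[c])
            }
            group = "pos" if bool(y[i]) else "neg"
            records.append(CPDRecord(f"{idx}", values, group))
        return Cohort(records, {"pos": "pos", "neg": "neg"})

    def fit(self, X: pd.DataFrame, y) -> "DiscriminantCalibrator":
        cohort = self._to_cohort(X, y)
        contrast = Contrast({"pos"}, {"neg"})
        return self._fit_cohort(cohort, contrast)

    def fit_cohort(self, cohort: Cohort, contrast: Contrast = NEOPLASTIC_CONTRAST):
        """Fit directly from a :class:`Cohort` and a group contrast."""
        return self._fit_cohort(cohort, contrast)

    def _fit_cohort(self, cohort: Cohort, contrast: Contrast):
        self.screen_results_ = screen_parameters(
            cohort,
            contrast,
            auc_min=self.auc_min,
            p_max=self.p_max,
            equal_var=self.equal_var,
            ci_method=self.ci_method,
            correction=self.correction,
        )
        if not self.screen_results_:
            raise InfeasibleCutoffError(
                f"no parameter passed the screen (AUC > {self.auc_min})"
            )
        self.rule_, self.roc_ = build_composite(
            cohort,
            contrast,
            self.screen_results_,
            positive_label=self.positive_label,
            negative_label=self.negative_label,
            cutoff_policy=self.cutoff_policy,
        )
        self.n_features_in_ = len(cohort.parameters())
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self)
        cols = [str(p) for p in self.rule_.numerator]
        dens = [str(p) for p in self.rule_.denominator]
        num = np.prod([X[c].to_numpy(float) for c in cols], axis=0)
        if dens:
            den = np.prod([X[c].to_numpy(float) for c in dens], axis=0)
            if np.any(den == 0):
                raise ValueError("zero denominator value; composite score undefined")
            return num / den
        return num

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.decision_function(X)
        if self.rule_.orientation == HIGH_IS_POSITIVE:
            positive = scores > self.rule_.cutoff
        else:
            positive = scores < self.rule_.cutoff
        return np.where(positive, self.positive_label, self.negative_label)

    def to_registry(self, base: RulesRegistry | None = None) -> RulesRegistry:
        """Registry with the fitted composite in place of the shipped one."""
        check_is_fitted(self)
        base = base or RulesRegistry()
        return RulesRegistry(
            composite=self.rule_,
            reactive=base.reactive,
            subtypes=base.subtypes,
            singles=tuple(
                DiscriminantRule(
                    name=str(r.parameter),
                    numerator=(r.parameter,),
                    cutoff=round(select_cutoff(r).chosen_cutoff, 2),
                    orientation=r.orientation,
                    positive_label=self.positive_label,
                    negative_label=self.negative_label,
                )
                for r in self.screen_results_
            ),
        )
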