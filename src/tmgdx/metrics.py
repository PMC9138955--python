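"""Diagnostic-accuracy toolkit: ROC, PRC, association and power.

All threshold-based quantities use the criterion form ``score > c ⇒
positive``; candidate thresholds are the observed scores plus −∞, which
sweeps the full empirical ROC from (sens 1, spec 0) to (sens 0, spec 1).

AUC standard errors come in two flavours:

* Hanley–McNeil: closed form from A and the class sizes, with
  Q1 = A/(2−A) and Q2 = 2A²/(1+A);
* DeLong: nonparametric, from per-subject placement values; it is the
  default because it conditions on the observed score configuration.

Confidence intervals for AUC, the Youden cut-off and J come from a
stratified (within-class) percentile bootstrap.  The association between a
dichotomised score and the true class is measured by Cramér's V with a
Monte-Carlo permutation p-value.  Power for the two-sided two-sample
t-test uses the noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "PRCResult",
    "AssociationTestResult",
    "DeLongResult",
    "roc_points",
    "auc",
    "auc_se_hanley_mcneil",
    "auc_var_delong",
    "youden_optimal",
    "evaluate_roc",
    "bootstrap_ci",
    "compare_independent_rocs",
    "pr_curve",
    "cramers_v_mc",
    "two_sample_t_power",
    "group_tests",
]


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_points(scores, labels) -> np.ndarray:
    """Empirical ROC operating points for the criterion ``score > c``.

    Returns a structured sweep as an ``(m, 3)`` array of rows
    ``(threshold, sensitivity, specificity)`` sorted by threshold, with
    c = −∞ first (all positive) and c = max(score) last (all negative).
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    thresholds = np.concatenate([[-np.inf], np.unique(scores)])
    # score > c counts via searchsorted on the sorted class scores
    sens = (pos.size - np.searchsorted(pos, thresholds, side="right")) / pos.size
    spec = np.searchsorted(neg, thresholds, side="right") / neg.size
    return np.column_stack([thresholds, sens, spec])


def auc(scores, labels) -> float:
    """Area under the empirical ROC (trapezoidal; ties get half credit).

    Numerically equal to the Mann–Whitney probability
    P(score⁺ > score⁻) + ½ P(score⁺ = score⁻), computed here in rank form.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_se_hanley_mcneil(a: float, n_pos: int, n_neg: int) -> float:
    """Closed-form AUC standard error (Q1 = A/(2−A), Q2 = 2A²/(1+A))."""
    if not (0.0 <= a <= 1.0):
        raise ValueError("auc must be in [0, 1]")
    if min(n_pos, n_neg) < 2:
        raise ValueError("class sizes must be >= 2")
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class DeLongResult:
    """DeLong AUC variance with the per-subject placement components."""

    auc: float
    variance: float
    placements_pos: np.ndarray  # V10: one value per positive subject
    placements_neg: np.ndarray  # V01: one value per negative subject

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def auc_var_delong(scores, labels) -> DeLongResult:
    """Nonparametric (DeLong) variance of the empirical AUC.

    Placement of positive i: fraction of negatives scoring below it (ties
    half); placement of negative j: fraction of positives scoring above it.
    The variance is S₁₀/n⁺ + S₀₁/n⁻ with S the sample variances of the
    placements.
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = scores[labels]
    neg = scores[~labels]
    if min(pos.size, neg.size) < 2:
        raise ValueError("need >= 2 subjects per class")
    neg_sorted = np.sort(neg)
    v10 = (
        np.searchsorted(neg_sorted, pos, side="left")
        + 0.5 * (np.searchsorted(neg_sorted, pos, side="right")
                 - np.searchsorted(neg_sorted, pos, side="left"))
    ) / neg.size
    pos_sorted = np.sort(pos)
    v01 = (
        (pos.size - np.searchsorted(pos_sorted, neg, side="right"))
        + 0.5 * (np.searchsorted(pos_sorted, neg, side="right")
                 - np.searchsorted(pos_sorted, neg, side="left"))
    ) / pos.size
    a = float(v10.mean())
    var = float(np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)
    return DeLongResult(auc=a, variance=var, placements_pos=v10, placements_neg=v01)


def youden_optimal(curve: np.ndarray) -> tuple[float, float, float, float]:
    """Maximise Youden's J = sens + spec − 1 over the ROC sweep.

    ``curve`` is the array from :func:`roc_points`.  Ties (within 1e-12, to
    absorb float rounding of sens + spec) are broken toward the smallest
    threshold — the most sensitive operating point.
    Returns ``(cutoff, J, sens, spec)``.
    """
    curve = np.asarray(curve, dtype=float)
    j = curve[:, 1] + curve[:, 2] - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # rows sorted by c
    return (
        float(curve[best, 0]),
        float(j[best]),
        float(curve[best, 1]),
        float(curve[best, 2]),
    )


def _stat_from_scores(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float, float]:
    """(auc, youden cutoff, J) from class score vectors — single sort pass."""
    pos_s = np.sort(pos)
    neg_s = np.sort(neg)
    thresholds = np.unique(np.concatenate([pos_s, neg_s]))
    sens = (pos_s.size - np.searchsorted(pos_s, thresholds, side="right")) / pos_s.size
    spec = np.searchsorted(neg_s, thresholds, side="right") / neg_s.size
    ranks = stats.rankdata(np.concatenate([pos_s, neg_s]))
    u = ranks[: pos_s.size].sum() - pos_s.size * (pos_s.size + 1) / 2.0
    a = u / (pos_s.size * neg_s.size)
    j = sens + spec - 1.0
    # the all-positive point (c = -inf) has J = 0; only relevant if all J <= 0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    if j[best] <= 0.0:
        return float(a), float(-np.inf), 0.0
    return float(a), float(thresholds[best]), float(j[best])


def bootstrap_ci(
    scores,
    labels,
    statistic: Literal["auc", "cutoff", "youden_j"] = "auc",
    B: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for AUC, the Youden cut-off or J.

    Resampling is with replacement within each class, so every resample
    retains both classes.  Percentile interval at level ``1 − alpha``.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    scores, labels = _check_scores_labels(scores, labels)
    pos = scores[labels]
    neg = scores[~labels]
    rng = np.random.default_rng(seed)
    idx = {"auc": 0, "cutoff": 1, "youden_j": 2}[statistic]
    vals = np.empty(B)
    for b in range(B):
        p = pos[rng.integers(0, pos.size, pos.size)]
        n = neg[rng.integers(0, neg.size, neg.size)]
        vals[b] = _stat_from_scores(p, n)[idx]
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def compare_independent_rocs(
    auc1: float, se1: float, auc2: float, se2: float
) -> tuple[float, float, float, float]:
    """Normal-theory comparison of two AUCs from independent samples.

    Returns ``(difference, se_diff, z, p_two_sided)`` with
    z = (AUC₁ − AUC₂)/√(SE₁² + SE₂²).
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    diff = auc1 - auc2
    se = float(np.sqrt(se1**2 + se2**2))
    z = diff / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(diff), se, float(z), p


# ---------------------------------------------------------------------------
# Precision–recall
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    """Full ROC evaluation of one classifier.

    ``thresholds`` use the criterion ``score > c``; ``se_method`` tags how
    ``se_auc`` was computed (``delong`` or ``hanley_mcneil``).  CI fields
    are percentile-bootstrap intervals and are ``None`` when the bootstrap
    was not requested.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    se_auc: float
    se_method: str
    p_value: float
    youden_j: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    auc_ci95: tuple[float, float] | None = None
    youden_ci95: tuple[float, float] | None = None
    cutoff_ci95: tuple[float, float] | None = None
    bootstrap_B: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc, "se_auc": self.se_auc, "se_method": self.se_method,
            "p_value": self.p_value, "youden_j": self.youden_j,
            "cutoff": self.cutoff, "sens_at_cutoff": self.sens_at_cutoff,
            "spec_at_cutoff": self.spec_at_cutoff,
        }
        for name in ("auc_ci95", "youden_ci95", "cutoff_ci95"):
            v = getattr(self, name)
            d[name] = list(v) if v is not None else None
        d["bootstrap_B"] = self.bootstrap_B
        d["seed"] = self.seed
        return d


@dataclass(frozen=True)
class PRCResult:
    """Precision–recall evaluation: AUPRC (average precision), F1max and
    the operating point (association criterion, PPV, TPR) attaining F1max."""

    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    auprc: float
    f1max: float
    association_criterion: float
    ppv: float
    tpr: float

    def to_dict(self) -> dict:
        return {
            "auprc": self.auprc, "f1max": self.f1max,
            "association_criterion": self.association_criterion,
            "ppv": self.ppv, "tpr": self.tpr,
        }


def evaluate_roc(
    scores,
    labels,
    se_method: Literal["delong", "hanley_mcneil"] = "delong",
    bootstrap_B: int = 0,
    seed: int | None = None,
) -> ROCResult:
    """Assemble the full ROC block: curve, AUC ± SE, p vs 0.5, Youden point,
    and (when ``bootstrap_B`` > 0) stratified-bootstrap 95 % CIs."""
    scores, labels = _check_scores_labels(scores, labels)
    curve = roc_points(scores, labels)
    a = auc(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if se_method == "delong":
        se = auc_var_delong(scores, labels).se
    elif se_method == "hanley_mcneil":
        se = auc_se_hanley_mcneil(a, n_pos, n_neg)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    # two-sided test of AUC = 0.5 (null of no discrimination)
    if se > 0:
        p_value = float(2.0 * stats.norm.sf(abs(a - 0.5) / se))
    else:
        p_value = 0.0 if a != 0.5 else 1.0
    cutoff, j, sens_c, spec_c = youden_optimal(curve)
    kw: dict = {}
    if bootstrap_B > 0:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
        kw = {
            "auc_ci95": bootstrap_ci(scores, labels, "auc", bootstrap_B, seeds[0]),
            "youden_ci95": bootstrap_ci(scores, labels, "youden_j", bootstrap_B, seeds[1]),
            "cutoff_ci95": bootstrap_ci(scores, labels, "cutoff", bootstrap_B, seeds[2]),
            "bootstrap_B": bootstrap_B,
            "seed": seed,
        }
    return ROCResult(
        thresholds=curve[:, 0], sens=curve[:, 1], spec=curve[:, 2],
        auc=a, se_auc=se, se_method=se_method, p_value=p_value,
        youden_j=j, cutoff=cutoff, sens_at_cutoff=sens_c, spec_at_cutoff=spec_c,
        **kw,
    )


def pr_curve(scores, labels, interpolation: Literal["step", "trapezoid"] = "step") -> PRCResult:
    """Precision–recall analysis over ``score > c`` thresholds.

    AUPRC uses the step-function (average-precision) rule Σ ΔR·P by
    default; ``interpolation='trapezoid'`` averages adjacent precisions
    instead.  The F1-maximising threshold is reported as the association
    criterion with its PPV (precision) and TPR (recall); F1 ties break
    toward the smallest threshold.
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    # thresholds in decreasing order: recall grows monotonically along the sweep
    thresholds = np.unique(scores)[::-1]
    tp = pos.size - np.searchsorted(pos, thresholds, side="right")
    fp = neg.size - np.searchsorted(neg, thresholds, side="right")
    pred_pos = tp + fp
    recall = tp / pos.size
    with np.errstate(invalid="ignore"):
        precision = np.where(pred_pos > 0, tp / np.where(pred_pos > 0, pred_pos, 1), 1.0)
    # append the all-positive end (c = -inf): recall 1, precision = prevalence
    thresholds = np.concatenate([thresholds, [-np.inf]])
    recall = np.concatenate([recall, [1.0]])
    precision = np.concatenate([precision, [pos.size / scores.size]])
    dr = np.diff(np.concatenate([[0.0], recall]))
    if interpolation == "step":
        auprc = float(np.sum(dr * precision))
    elif interpolation == "trapezoid":
        prev_p = np.concatenate([[precision[0]], precision[:-1]])
        auprc = float(np.sum(dr * (precision + prev_p) / 2.0))
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(
            (precision + recall) > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    valid = recall > 0  # need at least one predicted & true positive
    f1 = np.where(valid, f1, 0.0)
    f1max = float(f1.max())
    # smallest threshold attaining the max (thresholds are in decreasing order)
    best = int(np.flatnonzero(np.isclose(f1, f1max, rtol=0, atol=1e-12))[-1])
    return PRCResult(
        thresholds=thresholds, recall=recall, precision=precision,
        auprc=auprc, f1max=f1max,
        association_criterion=float(thresholds[best]),
        ppv=float(precision[best]), tpr=float(recall[best]),
    )


# ---------------------------------------------------------------------------
# Association and power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationTestResult:
    """Cramér's V for a 2×2 table with asymptotic and Monte-Carlo p-values."""

    cramers_v: float
    chi2: float
    p_asymptotic: float
    p_monte_carlo: float
    n_resamples: int
    seed: int | None
    table: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "cramers_v": self.cramers_v, "chi2": self.chi2,
            "p_asymptotic": self.p_asymptotic, "p_monte_carlo": self.p_monte_carlo,
            "n_resamples": self.n_resamples, "seed": self.seed,
            "table": self.table.tolist() if self.table is not None else None,
        }


def cramers_v_mc(
    predicted,
    truth,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> AssociationTestResult:
    """Cramér's V of a 2×2 classification table with a permutation p-value.

    ``predicted`` and ``truth`` are binary vectors; the chi-square statistic
    carries no continuity correction and V = √(χ²/n).  The Monte-Carlo
    p-value permutes the predictions against the fixed truth labels and
    applies the (r + 1)/(B + 1) correction.
    """
    predicted = np.asarray(predicted).ravel().astype(int)
    truth = np.asarray(truth).ravel().astype(int)
    if predicted.size != truth.size or predicted.size < 4:
        raise ValueError("need matched vectors with n >= 4")
    if n_resamples < 1000:
        raise ValueError("n_resamples must be >= 1000")
    n = predicted.size
    m1 = int(predicted.sum())
    n1 = int(truth.sum())
    if m1 in (0, n) or n1 in (0, n):
        raise ValueError("Cramér's V undefined: a table margin is zero")
    a = int(np.sum((predicted == 1) & (truth == 1)))
    denom = m1 * (n - m1) * n1 * (n - n1)

    def cross(a_val):
        # ad - bc for table [[a, m1-a], [n1-a, n-m1-n1+a]]
        return a_val * (n - m1 - n1 + a_val) - (m1 - a_val) * (n1 - a_val)

    obs_cross2 = cross(a) ** 2
    chi2 = float(n * obs_cross2 / denom)
    v = float(np.sqrt(chi2 / n))
    p_asym = float(stats.chi2.sf(chi2, df=1))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(predicted, (n_resamples, 1)), axis=1)
    a_perm = perms[:, truth == 1].sum(axis=1)
    cross2_perm = cross(a_perm.astype(np.int64)) ** 2
    exceed = int(np.sum(cross2_perm >= obs_cross2))
    p_mc = (exceed + 1) / (n_resamples + 1)
    table = np.array([[a, m1 - a], [n1 - a, n - m1 - n1 + a]])
    return AssociationTestResult(
        cramers_v=v, chi2=chi2, p_asymptotic=p_asym, p_monte_carlo=float(p_mc),
        n_resamples=n_resamples, seed=seed, table=table,
    )


def two_sample_t_power(d: float, n_per_group: int, alpha_two_sided: float = 0.05) -> float:
    """Power of the two-sided independent-samples t-test at effect size d.

    Noncentral-t computation: df = 2n − 2, noncentrality δ = d·√(n/2);
    power = P(|T'| > t_crit).  At d = 0 this returns α exactly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not (0 < alpha_two_sided < 1):
        raise ValueError("alpha must be in (0, 1)")
    if d < 0:
        raise ValueError("d must be >= 0")
    df = 2 * n_per_group - 2
    delta = d * np.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1 - alpha_two_sided / 2.0, df)
    power = stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)
    return float(power)


# ---------------------------------------------------------------------------
# Cohort-level hypothesis tests
# ---------------------------------------------------------------------------

def group_tests(cohort, equal_var: bool = False) -> "pd.DataFrame":
    """Descriptive hypothesis tests on a bilateral cohort.

    Runs, per parameter: the paired t-test of injured vs contralateral leg
    (injured group) and of left vs right leg (non-injured group); the
    independent t-test of female vs male values (Welch by default, pooled
    with ``equal_var=True``); and a Lilliefors-corrected
    Kolmogorov–Smirnov normality test per cell.  Returns a tidy frame with
    columns ``test, parameter, stratum, statistic, p, n``; cells with
    n < 2 are skipped with a warning.
    """
    import pandas as pd
    import warnings as _warnings
    from statsmodels.stats.diagnostic import lilliefors

    from .cohort import PARAM_NAMES, cohort_to_frame

    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    inj = frame[frame["group"] == "injured"]
    non = frame[frame["group"] == "non_injured"]
    rows = []

    def leg_cols(sub, param, oriented):
        if oriented:  # injured leg first
            left_is_inj = sub["injured_side"] == "L"
            a = np.where(left_is_inj, sub[f"{param}_l"], sub[f"{param}_r"])
            b = np.where(left_is_inj, sub[f"{param}_r"], sub[f"{param}_l"])
            return a.astype(float), b.astype(float)
        return sub[f"{param}_l"].to_numpy(float), sub[f"{param}_r"].to_numpy(float)

    def paired_t(a, b):
        if np.allclose(a - b, 0.0):  # degenerate: identical columns
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)

    for param in PARAM_NAMES:
        if len(inj) >= 2:
            a, b = leg_cols(inj, param, oriented=True)
            t, p = paired_t(a, b)
            rows.append({"test": "paired_t_injured_vs_contralateral", "parameter": param,
                         "stratum": "injured", "statistic": float(t), "p": float(p),
                         "n": len(inj)})
        else:
            _warnings.warn("paired test skipped: injured group too small", stacklevel=2)
        if len(non) >= 2:
            a, b = leg_cols(non, param, oriented=False)
            t, p = paired_t(a, b)
            rows.append({"test": "paired_t_left_vs_right", "parameter": param,
                         "stratum": "non_injured", "statistic": float(t), "p": float(p),
                         "n": len(non)})
        else:
            _warnings.warn("paired test skipped: non-injured group too small", stacklevel=2)
        for grp_label, sub in (("injured", inj), ("non_injured", non)):
            f = sub[sub["sex"] == "F"]
            m = sub[sub["sex"] == "M"]
            if len(f) >= 2 and len(m) >= 2:
                fv = np.concatenate(leg_cols(f, param, grp_label == "injured")[:1])
                mv = np.concatenate(leg_cols(m, param, grp_label == "injured")[:1])
                t, p = stats.ttest_ind(fv, mv, equal_var=equal_var)
                rows.append({"test": "independent_t_F_vs_M", "parameter": param,
                             "stratum": grp_label, "statistic": float(t),
                             "p": float(p), "n": len(f) + len(m)})
            else:
                _warnings.warn(f"sex comparison skipped in {grp_label}: cell too small",
                               stacklevel=2)
            # normality per cell (pooled legs)
            vals = np.concatenate([sub[f"{param}_l"].to_numpy(float),
                                   sub[f"{param}_r"].to_numpy(float)])
            if vals.size >= 4:
                ks, p = lilliefors(vals, dist="norm")
                rows.append({"test": "lilliefors_normality", "parameter": param,
                             "stratum": grp_label, "statistic": float(ks),
                             "p": float(p), "n": vals.size})
    return pd.DataFrame(rows)
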