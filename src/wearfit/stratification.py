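"""Cohort-level stratification against the 6-minute-walk outcome.

The clinical question: can a wearable-derived feature split patients into
adequate (6MWD >= 350 m, "fit") versus reduced (< 350 m, "unfit") exercise
tolerance?  The module provides

* Pearson correlation of each feature with 6MWD,
* ROC analysis with an optimal cutpoint (maximal Youden J = TPR - FPR,
  thresholds at midpoints between adjacent distinct scores),
* a Wilcoxon rank-sum comparison of 6MWD between the predicted groups
  (exact enumeration for small samples, normal approximation with tie
  correction otherwise), with the 2x2 predicted-vs-observed contingency
  table, and
* conditional outcome probabilities such as
  P(6MWD < 350 m | mean daily steps < 10,000).

Patients with a missing feature (e.g. on-clip HROS) are excluded pairwise
per analysis, with the excluded count reported.  The "fit" class is the
positive class throughout; features where lower values indicate fitness
(HROS, RHR) are negated before ROC construction and the reported
threshold is mapped back to the original scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

OUTCOME_THRESHOLD_M = 350.0
MAX_EXACT_ARRANGEMENTS = 1_000_000

HIGHER_IS_FIT = "higher_is_fit"
LOWER_IS_FIT = "lower_is_fit"


@dataclass
class CorrelationResult:
    feature_name: str
    r: float
    p_value: float
    n: int
    n_excluded: int = 0


@dataclass
class RocResult:
    feature_name: str
    orientation: str
    auc: float
    threshold: float  # on the original feature scale; nan if degenerate
    tpr: float
    fpr: float
    curve: list[tuple[float, float]]  # (fpr, tpr), (0,0) .. (1,1)
    n_excluded: int = 0

    def predict_fit(self, values: np.ndarray) -> np.ndarray:
        """Classify values as fit using the chosen threshold."""
        v = np.asarray(values, dtype=float)
        if self.orientation == HIGHER_IS_FIT:
            return v >= self.threshold
        return v <= self.threshold


@dataclass
class GroupComparison:
    feature_name: str
    threshold: float
    n_fit: int  # predicted fit
    n_unfit: int
    rank_sum_statistic: float  # rank sum of the predicted-fit group
    p_value: float
    # contingency[pred][obs]: rows predicted fit/unfit, cols observed >=350 / <350
    contingency: list[list[int]]


@dataclass
class CohortAnalysis:
    """Everything the comparative analysis produces for one cohort."""

    n_patients: int
    correlations: list[CorrelationResult] = field(default_factory=list)
    roc: dict[str, RocResult] = field(default_factory=dict)
    group_comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    conditional_probs: dict[str, float | None] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            "Wearable features vs 6-minute-walk distance",
            f"patients analyzed: {self.n_patients}",
            "",
            "Correlation analysis (Pearson r vs 6MWD)",
        ]
        for c in self.correlations:
            lines.append(
                f"  {c.feature_name:<18s} r={c.r:+.3f}  p={c.p_value:.4f}  "
                f"n={c.n}" + (f"  excluded={c.n_excluded}" if c.n_excluded else "")
            )
        lines.append("")
        lines.append("ROC threshold analysis (fit = 6MWD >= 350 m)")
        for name, r in self.roc.items():
            lines.append(
                f"  {name:<18s} AUC={r.auc:.3f}  threshold={r.threshold:.4g} "
                f"({r.orientation})  TPR={r.tpr:.2f}  FPR={r.fpr:.2f}"
                + (f"  excluded={r.n_excluded}" if r.n_excluded else "")
            )
        lines.append("")
        lines.append("Group comparison at chosen thresholds (Wilcoxon rank-sum)")
        for name, g in self.group_comparisons.items():
            lines.append(
                f"  {name:<18s} predicted fit={g.n_fit} unfit={g.n_unfit}  "
                f"W={g.rank_sum_statistic:.1f}  p={g.p_value:.4f}"
            )
            (a, b), (c, d) = g.contingency
            lines.append(f"    contingency [pred fit | pred unfit] x [6MWD>=350 | <350]:")
            lines.append(f"      {a:3d} {b:3d}")
            lines.append(f"      {c:3d} {d:3d}")
        lines.append("")
        lines.append("Conditional probabilities")
        for name, p in self.conditional_probs.items():
            val = "undefined (empty condition)" if p is None else f"{p:.3f}"
            lines.append(f"  {name}: {val}")
        lines.append("")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def pearson(x, y, feature_name: str = "") -> CorrelationResult:
    """Pearson r with a two-sided p-value (t transform, n-2 df).

    Pairs with a missing (NaN/None) feature value are dropped and counted.
    """
    x = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("%s: %d pair(s) excluded for missing values", feature_name, n_excluded)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        feature_name=feature_name,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
        n_excluded=n_excluded,
    )


def binarize_outcome(six_mwd, cut: float = OUTCOME_THRESHOLD_M) -> np.ndarray:
    """True = fit (6MWD >= cut, boundary included), False = unfit."""
    d = np.asarray(six_mwd, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("six_mwd must be finite")
    return d >= cut


# ---------------------------------------------------------------------------
# ROC / optimal cutpoint
# ---------------------------------------------------------------------------


def _roc_points(scores: np.ndarray, fit: np.ndarray, thresholds: np.ndarray):
    """TPR/FPR for 'predict fit iff score >= t' at each threshold."""
    n_fit = int(fit.sum())
    n_unfit = len(fit) - n_fit
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tpr[i] = (pred & fit).sum() / n_fit
        fpr[i] = (pred & ~fit).sum() / n_unfit
    return tpr, fpr


def roc_threshold(values, fit_labels, orientation: str, feature_name: str = "") -> RocResult:
    """ROC curve and Youden-optimal cutpoint for one feature.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus -inf/+inf sentinels, so the cutpoint never coincides
    with an observed value.  The chosen threshold maximizes
    J = TPR - FPR; ties are broken by smaller FPR, then by classifying
    fewer patients as fit.  Missing feature values are excluded pairwise.
    """
    if orientation not in (HIGHER_IS_FIT, LOWER_IS_FIT):
        raise ValueError(f"unknown orientation {orientation!r}")
    v = np.asarray([np.nan if x is None else x for x in values], dtype=float)
    fit = np.asarray(fit_labels, dtype=bool)
    ok = np.isfinite(v)
    n_excluded = int((~ok).sum())
    v, fit = v[ok], fit[ok]
    if fit.all() or (~fit).all():
        raise ValueError("ROC requires both classes non-empty")
    scores = v if orientation == HIGHER_IS_FIT else -v

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    tpr, fpr = _roc_points(scores, fit, thresholds)

    # curve from (0,0) (t=+inf) to (1,1) (t=-inf)
    order = np.lexsort((tpr, fpr))
    curve = list(dict.fromkeys(zip(fpr[order], tpr[order])))
    cx = np.array([p[0] for p in curve])
    cy = np.array([p[1] for p in curve])
    auc = float(np.trapezoid(cy, cx))

    degenerate = len(distinct) < 2
    if degenerate:
        logger.warning("%s: constant scores, no meaningful threshold", feature_name)
        return RocResult(
            feature_name=feature_name,
            orientation=orientation,
            auc=auc,
            threshold=float("nan"),
            tpr=1.0,
            fpr=1.0,
            curve=curve,
            n_excluded=n_excluded,
        )

    j = tpr - fpr
    n_pred_fit = np.array([(scores >= t).sum() for t in thresholds])
    # lexicographic: max J, then min FPR, then min predicted-fit count
    best = min(
        range(len(thresholds)),
        key=lambda i: (-j[i], fpr[i], n_pred_fit[i]),
    )
    t = thresholds[best]
    threshold = float(t if orientation == HIGHER_IS_FIT else -t)
    return RocResult(
        feature_name=feature_name,
        orientation=orientation,
        auc=auc,
        threshold=threshold,
        tpr=float(tpr[best]),
        fpr=float(fpr[best]),
        curve=curve,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Rank-sum comparison
# ---------------------------------------------------------------------------


def exact_rank_sum_p(group1, group2) -> tuple[float, float]:
    """Two-sided exact rank-sum p by full enumeration (handles ties).

    Returns (W, p) where W is the midrank sum of group1 and p the
    permutation probability of |W' - E[W]| >= |W - E[W]|.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    pooled = np.concatenate([g1, g2])
    ranks = stats.rankdata(pooled)
    n1, n = len(g1), len(pooled)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    d_obs = abs(w_obs - mu) - 1e-9
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= d_obs:
            count += 1
    return w_obs, count / total


def rank_sum_compare(
    fit_six_mwd,
    unfit_six_mwd,
    observed_fit_counts: tuple[int, int, int, int] | None = None,
    feature_name: str = "",
    threshold: float = float("nan"),
) -> GroupComparison:
    """Wilcoxon rank-sum comparison of 6MWD between predicted groups.

    Exact permutation enumeration is used when C(n1+n2, n1) < 10^6,
    otherwise the normal approximation with tie correction.
    ``observed_fit_counts`` is (pred-fit & obs-fit, pred-fit & obs-unfit,
    pred-unfit & obs-fit, pred-unfit & obs-unfit) for the contingency table.
    """
    g1 = np.asarray(fit_six_mwd, dtype=float)
    g2 = np.asarray(unfit_six_mwd, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(g1), len(g2)
    if math.comb(n1 + n2, n1) < MAX_EXACT_ARRANGEMENTS:
        w, p = exact_rank_sum_p(g1, g2)
    else:
        ranks = stats.rankdata(np.concatenate([g1, g2]))
        w = float(ranks[:n1].sum())
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    if observed_fit_counts is None:
        contingency = [[n1, 0], [n2, 0]]
    else:
        a, b, c, d = observed_fit_counts
        contingency = [[a, b], [c, d]]
    return GroupComparison(
        feature_name=feature_name,
        threshold=threshold,
        n_fit=n1,
        n_unfit=n2,
        rank_sum_statistic=w,
        p_value=min(1.0, float(p)),
        contingency=contingency,
    )


# ---------------------------------------------------------------------------
# Conditional probability
# ---------------------------------------------------------------------------


def conditional_probability(condition, outcome) -> float | None:
    """P(outcome | condition) by counting; None if nobody meets the condition."""
    cond = np.asarray(condition, dtype=bool)
    out = np.asarray(outcome, dtype=bool)
    if cond.shape != out.shape:
        raise ValueError("condition and outcome must have equal length")
    n_cond = int(cond.sum())
    if n_cond == 0:
        logger.warning("conditional probability undefined: empty condition set")
        return None
    return float((cond & out).sum() / n_cond)


# ---------------------------------------------------------------------------
# Full cohort analysis
# ---------------------------------------------------------------------------

#: feature name -> (FeatureVector attribute, ROC orientation)
ANALYSIS_FEATURES = {
    "netf": ("netf", HIGHER_IS_FIT),
    "mean_rhr": ("mean_rhr", LOWER_IS_FIT),
    "hros_q01": ("hros_q01", LOWER_IS_FIT),
    "mean_daily_steps": ("mean_daily_steps", HIGHER_IS_FIT),
}

ROC_FEATURES = ("netf", "hros_q01")


def analyze_cohort(
    features,
    patients,
    outcome_cut: float = OUTCOME_THRESHOLD_M,
    step_threshold: float = 10_000,
) -> CohortAnalysis:
    """Run the full comparative analysis for a cohort.

    ``features`` are FeatureVector rows aligned with ``patients`` (matched
    by patient_id).  Produces 6MWD correlations for the four headline
    features, ROC cutpoints and rank-sum group comparisons for the two
    composed indices (NET-F, HROS 1% quantile), and the below-10k-steps
    conditional outcome probabilities.
    """
    by_id = {f.patient_id: f for f in features}
    pts = [p for p in patients if p.patient_id in by_id]
    six_mwd = np.array([p.six_mwd for p in pts], dtype=float)
    fit = binarize_outcome(six_mwd, outcome_cut)
    analysis = CohortAnalysis(n_patients=len(pts))

    feat_values: dict[str, np.ndarray] = {}
    for name, (attr, _) in ANALYSIS_FEATURES.items():
        vals = [getattr(by_id[p.patient_id], attr) for p in pts]
        feat_values[name] = np.asarray(
            [np.nan if v is None else v for v in vals], dtype=float
        )
        analysis.correlations.append(pearson(feat_values[name], six_mwd, name))

    for name in ROC_FEATURES:
        orientation = ANALYSIS_FEATURES[name][1]
        roc = roc_threshold(feat_values[name], fit, orientation, name)
        analysis.roc[name] = roc
        v = feat_values[name]
        ok = np.isfinite(v)
        pred = roc.predict_fit(v[ok])
        obs = fit[ok]
        counts = (
            int((pred & obs).sum()),
            int((pred & ~obs).sum()),
            int((~pred & obs).sum()),
            int((~pred & ~obs).sum()),
        )
        analysis.group_comparisons[name] = rank_sum_compare(
            six_mwd[ok][pred],
            six_mwd[ok][~pred],
            observed_fit_counts=counts,
            feature_name=name,
            threshold=roc.threshold,
        )

    mean_steps = feat_values["mean_daily_steps"]
    max_steps = np.array(
        [by_id[p.patient_id].max_daily_steps for p in pts], dtype=float
    )
    analysis.conditional_probs["P(6MWD<350 | mean steps < 10k)"] = (
        conditional_probability(mean_steps < step_threshold, ~fit)
    )
    analysis.conditional_probs["P(6MWD<350 | max steps < 10k)"] = (
        conditional_probability(max_steps < step_threshold, ~fit)
    )
    return analysis
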