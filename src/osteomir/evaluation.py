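"""ROC analysis, DeLong paired AUC comparison, normality testing, and 10-fold CV.

The positive class is always osteoporosis.  Score orientation is explicit:
model outputs track BMD, so a *low* score marks a positive; the raw marker is
negatively correlated with BMD, so *high* expression marks a positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import CohortTable, fit_minmax
from .dann import M_RANGE_DEFAULT, train_dann
from .rbf import RBFConfig


class UndefinedROCError(ValueError):
    pass


@dataclass
class ROCResult:
    """Empirical ROC over all distinct thresholds, plus summary operating points."""

    thresholds: np.ndarray      # on the oriented score scale
    se: np.ndarray
    sp: np.ndarray
    auc: float
    orientation: str            # "low" or "high": which scores are positive-like
    positive_label: str = "osteoporosis"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "se": self.se, "sp": self.sp}
        )


def roc(scores, labels, orientation: str = "low") -> ROCResult:
    """Empirical ROC; AUC by the trapezoidal rule (= tie-corrected concordance).

    ``orientation="low"`` means lower scores indicate the positive class
    (BMD-like model outputs); ``"high"`` is the usual direction (marker
    expression).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if orientation not in ("low", "high"):
        raise ValueError(f"orientation must be 'low' or 'high', got {orientation!r}")
    if labels.min() == labels.max():
        raise UndefinedROCError("both classes must be present")
    oriented = -scores if orientation == "low" else scores
    fpr, tpr, thr = _sk_roc_curve(labels, oriented, drop_intermediate=False)
    order = np.argsort(thr[1:])  # ascending thresholds, skip the +inf sentinel
    thresholds = thr[1:][order]
    se = tpr[1:][order]
    sp = 1.0 - fpr[1:][order]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, se=se, sp=sp, auc=auc,
                     orientation=orientation)


def auc_concordance(scores, labels, orientation: str = "high") -> float:
    """Concordance-probability AUC (ties counted 1/2) by direct pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if orientation == "low":
        scores = -scores
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedROCError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def optimal_cutoff(result: ROCResult) -> tuple[float, float, float]:
    """(threshold, SE, SP) maximizing Youden J = SE + SP - 1; ties prefer higher SP.

    The threshold is reported on the original score scale, inclusive: the
    positive call at the returned point is ``score <= threshold`` for low
    orientation (``>=`` for high).
    """
    j = result.se + result.sp - 1.0
    tied = np.flatnonzero(j >= j.max() - 1e-9)
    best = tied[np.argmax(result.sp[tied])]
    thr = result.thresholds[best]
    if result.orientation == "low":
        thr = -thr
    return float(thr), float(result.se[best]), float(result.sp[best])


def se_at_fixed_sp(result: ROCResult, sp_min: float = 0.9) -> float:
    """Highest sensitivity among operating points with SP >= sp_min (step rule)."""
    ok = result.sp >= sp_min
    if not ok.any():
        return 0.0
    return float(result.se[ok].max())


def accuracy_at_threshold(scores, labels, threshold: float,
                          orientation: str = "low") -> float:
    """Fraction of correct binary calls at a fixed cut-off."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    call = scores < threshold if orientation == "low" else scores > threshold
    return float((call.astype(int) == labels).mean())


# ---------------------------------------------------------------------------
# DeLong paired comparison of correlated AUCs
# ---------------------------------------------------------------------------

@dataclass
class DeLongComparison:
    auc1: float
    auc2: float
    var_diff: float
    z: float
    p: float


def _placements(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10[i] = P(score_i > neg) over negatives; V01[j] over positives
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    return cmp_mat.mean(axis=1), 1.0 - cmp_mat.mean(axis=0), cmp_mat.mean()


def delong_test(scores1, scores2, labels,
                orientation1: str = "high", orientation2: str = "high"
                ) -> DeLongComparison:
    """DeLong comparison of two correlated AUCs measured on the same subjects.

    Uses the structural-component (placement value) covariance estimate and a
    two-sided normal reference for the AUC difference.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise UndefinedROCError("both classes must be present")
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if len(s1) != len(s2) or len(s1) != len(labels):
        raise ValueError("scores must be paired on identical subjects")
    if orientation1 == "low":
        s1 = -s1
    if orientation2 == "low":
        s2 = -s2
    v10_1, v01_1, auc1 = _placements(s1, labels)
    v10_2, v01_2, auc2 = _placements(s2, labels)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2])) if m > 1 else np.zeros((2, 2))
    # placements V01 estimate 1 - AUC; flip so both components are on the AUC scale
    s01 = np.cov(np.vstack([1 - v01_1, 1 - v01_2])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc1 - auc2
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return DeLongComparison(float(auc1), float(auc2), var_diff, float(z),
                            min(1.0, p))


# ---------------------------------------------------------------------------
# D'Agostino-Pearson omnibus normality
# ---------------------------------------------------------------------------

@dataclass
class NormalityReport:
    skewness: float
    kurtosis: float             # excess kurtosis
    z_skew: float
    z_kurt: float
    k2: float
    p: float
    passes: bool                # at alpha = 0.01


def dagostino_pearson(values, alpha: float = 0.01) -> NormalityReport:
    """Omnibus K^2 = Z_skew^2 + Z_kurt^2 against chi-square with 2 df."""
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise ValueError(f"need n >= 20, got {len(values)}")
    z_s, _ = stats.skewtest(values)
    z_k, _ = stats.kurtosistest(values)
    k2, p = stats.normaltest(values)
    return NormalityReport(
        skewness=float(stats.skew(values)),
        kurtosis=float(stats.kurtosis(values)),
        z_skew=float(z_s), z_kurt=float(z_k),
        k2=float(k2), p=float(p), passes=bool(p > alpha),
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    anova_f: float
    anova_p: float
    pairwise: dict[tuple[str, str], float]   # two-sided t-test p-values


def group_compare(values, groups) -> GroupComparison:
    """One-way ANOVA across bone-status groups plus pairwise Student t-tests."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    samples = {g: values[groups == g] for g in names}
    for g, s in samples.items():
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    f, p = stats.f_oneway(*samples.values())
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            _, tp = stats.ttest_ind(samples[a], samples[b])
            pairwise[(a, b)] = float(tp)
    return GroupComparison(float(f), float(p), pairwise)


# ---------------------------------------------------------------------------
# 10-fold cross-validation of the whole DANN system
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    scores: np.ndarray          # pooled out-of-fold DANN scores, cohort order
    rho: float                  # Spearman(score, BMD) on pooled scores
    roc: ROCResult
    fold_assignment: np.ndarray
    fold_reference_ids: list[set] = field(default_factory=list)
    selected_m: list[int] = field(default_factory=list)


def kfold_cv(
    cohort: CohortTable,
    features,
    k: int = 10,
    seed: int = 0,
    m_range=M_RANGE_DEFAULT,
    rbf_config: RBFConfig | None = None,
) -> CVResult:
    """Out-of-fold DANN scores: train the full cascade on k-1 folds, score the rest.

    Everything — min-max normalization, ANN I, the (m, d_index) search, ANN II,
    and the derivative-feature reference — is refitted inside each training
    fold, so no held-out participant ever influences the model that scores her.
    """
    features = tuple(features)
    n = len(cohort)
    if n < 2 * k:
        raise ValueError(f"need n >= {2 * k} for {k}-fold CV")
    rng = np.random.default_rng(seed)
    fold = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    fold = fold[rng.permutation(n)]
    scores = np.full(n, np.nan)
    ref_ids, selected_m = [], []
    for f in range(k):
        hold = fold == f
        train_df = cohort.df[~hold].reset_index(drop=True)
        train_cohort = CohortTable(train_df, registry=cohort.registry,
                                   provenance=cohort.provenance)
        model, _ = train_dann(train_cohort, features, seed=seed + 31 * f,
                              m_range=m_range, rbf_config=rbf_config)
        hold_df = cohort.df[hold].reset_index(drop=True)
        hold_cohort = CohortTable(hold_df, registry=cohort.registry,
                                  provenance=cohort.provenance)
        scores[hold] = model.score_external(hold_cohort)
        ref_ids.append(set(map(str, model.ref_ids)))
        selected_m.append(model.m)
    rho, _ = stats.spearmanr(scores, cohort.bmd)
    roc_res = roc(scores, cohort.risk_labels(), orientation="low")
    return CVResult(scores=scores, rho=float(rho), roc=roc_res,
                    fold_assignment=fold, fold_reference_ids=ref_ids,
                    selected_m=selected_m)
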