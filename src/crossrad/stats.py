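"""ROC, confusion-matrix and reader-study statistics.

Everything a diagnostic-accuracy report needs: AUROC as the
Mann-Whitney statistic, the Youden-index operating point, confusion
metrics (sensitivity, specificity, PPV, NPV, F1) with exact binomial
confidence intervals, the DeLong test for paired AUROC differences,
McNemar's test for paired sensitivities/specificities, and the
five-point-scale machinery of a two-session human-reader study.

Conventions: a case is predicted positive when its score >= threshold;
confidence level defaults to 95%; all tests are two-sided at 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ReaderRecord",
    "auroc",
    "roc_points",
    "youden_cutoff",
    "confusion_at_threshold",
    "metrics_from_confusion",
    "f1_from_rates",
    "clopper_pearson_ci",
    "logit_ci",
    "delong_test",
    "DelongResult",
    "mcnemar_test",
    "dichotomize_scores",
    "reader_study_table",
]


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) with ties counting 1/2.

    Identical to the trapezoidal area under the empirical ROC curve.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    ranks = sps.rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores, labels) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) over all distinct scores + +inf."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    thresholds = np.concatenate([np.unique(s), [np.inf]])
    n_pos = y.sum()
    n_neg = y.size - n_pos
    rows = []
    for t in thresholds:
        pred = s >= t
        rows.append({
            "threshold": t,
            "sensitivity": float((pred & (y == 1)).sum() / n_pos),
            "specificity": float((~pred & (y == 0)).sum() / n_neg),
        })
    return pd.DataFrame(rows)


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the distinct observed scores (predict positive at
    score >= threshold).  Ties in J are broken toward higher sensitivity,
    i.e. the lower threshold.
    """
    pts = roc_points(scores, labels)
    finite = pts[np.isfinite(pts.threshold)]
    j = finite.sensitivity + finite.specificity - 1.0
    best = None
    for t, jj, sens in zip(finite.threshold, j, finite.sensitivity):
        if best is None or jj > best[1] + 1e-12 or (
            abs(jj - best[1]) <= 1e-12 and sens > best[2] + 1e-12
        ):
            best = (float(t), float(jj), float(sens))
    return best[0], best[1]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    y = _check_binary(labels)
    pred = np.asarray(scores, dtype=np.float64) >= threshold
    return ConfusionCounts(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
        tn=int((~pred & (y == 0)).sum()),
    )


def f1_from_rates(sensitivity: float, ppv: float) -> float:
    """F1 as the harmonic mean of sensitivity (recall) and PPV (precision)."""
    if sensitivity < 0 or ppv < 0 or (sensitivity + ppv) == 0:
        raise ValueError("need non-negative rates with a positive sum")
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (beta-quantile) confidence interval for k successes of n."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if n < 1:
        raise ValueError("n must be at least 1")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


def logit_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Standard-logit (Wald on the log-odds) interval; an alternative for
    predictive values whose source-software CI method may not be exact."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("require 0 <= k <= n, n >= 1")
    if k == 0 or k == n:
        return clopper_pearson_ci(k, n, level)
    p = k / n
    z = sps.norm.ppf(0.5 + level / 2.0)
    l = math.log(p / (1 - p))
    se = math.sqrt(1.0 / k + 1.0 / (n - k))
    lo, hi = l - z * se, l + z * se
    return 1.0 / (1.0 + math.exp(-lo)), 1.0 / (1.0 + math.exp(-hi))


@dataclass
class MetricSet:
    """Point estimates with 95% CIs; undefined ratios carry a reason, never 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    ppv_ci: tuple[float, float] | None = None
    npv_ci: tuple[float, float] | None = None
    auroc: float | None = None
    auroc_ci: tuple[float, float] | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            val = getattr(self, name)
            ci = getattr(self, f"{name}_ci")
            if val is not None and ci is not None:
                if not (ci[0] - 1e-12 <= val <= ci[1] + 1e-12):
                    raise ValueError(f"{name} point estimate outside its CI")


def metrics_from_confusion(
    c: ConfusionCounts, level: float = 0.95, predictive_ci: str = "clopper_pearson"
) -> MetricSet:
    """Sens/spec/PPV/NPV/F1 with exact binomial CIs.

    ``predictive_ci`` selects "clopper_pearson" (default) or "logit"
    intervals for PPV/NPV; sensitivity and specificity always use the
    exact interval.
    """
    if c.total == 0:
        raise ValueError("confusion matrix is empty")
    ci_fn = {"clopper_pearson": clopper_pearson_ci, "logit": logit_ci}[predictive_ci]
    undefined: dict[str, str] = {}

    def ratio(k, n, name, fn):
        if n == 0:
            undefined[name] = f"denominator {n} (no qualifying cases)"
            return None, None
        return k / n, fn(k, n, level)

    sens, sens_ci = ratio(c.tp, c.tp + c.fn, "sensitivity", clopper_pearson_ci)
    spec, spec_ci = ratio(c.tn, c.tn + c.fp, "specificity", clopper_pearson_ci)
    ppv, ppv_ci = ratio(c.tp, c.tp + c.fp, "ppv", ci_fn)
    npv, npv_ci = ratio(c.tn, c.tn + c.fn, "npv", ci_fn)
    if sens is None or ppv is None or (sens + ppv) == 0:
        f1 = None
        undefined.setdefault("f1", "sensitivity or PPV undefined or both zero")
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return MetricSet(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f1=f1,
        sensitivity_ci=sens_ci, specificity_ci=spec_ci, ppv_ci=ppv_ci, npv_ci=npv_ci,
        undefined=undefined,
    )


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    diff: float
    ci: tuple[float, float]
    p: float


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: V10 per positive, V01 per negative."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(np.float64)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_test(scores_a, scores_b, labels, level: float = 0.95) -> DelongResult:
    """Compare two correlated AUROCs measured on the same cases.

    Variance of the paired difference from the empirical covariance of the
    per-case placement values; two-sided normal test.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != y.shape or b.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    v10_a, v01_a = _placements(a, y)
    v10_b, v01_b = _placements(b, y)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    m = v10_a.size  # positives
    n = v01_a.size  # negatives
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
        return DelongResult(auc_a, auc_b, diff, (diff, diff), p)
    se = math.sqrt(var)
    z = diff / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    zq = sps.norm.ppf(0.5 + level / 2.0)
    return DelongResult(auc_a, auc_b, diff, (diff - zq * se, diff + zq * se), p)


def mcnemar_test(b: int, c: int) -> float:
    """Two-sided McNemar p from the discordant-pair counts b and c.

    Exact binomial (p = min(1, 2 P[X <= min(b,c)]), X ~ Bin(b+c, 1/2)) when
    b + c < 25; continuity-corrected chi-square otherwise; p = 1 when there
    are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if n < 25:
        return float(min(1.0, 2.0 * sps.binom.cdf(min(b, c), n, 0.5)))
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    return float(sps.chi2.sf(chi2, df=1))


def dichotomize_scores(scores) -> np.ndarray:
    """Five-point confidence scores -> binary: 1-3 normal, 4-5 fracture."""
    s = np.asarray(scores, dtype=int)
    if s.size and (s.min() < 1 or s.max() > 5):
        raise ValueError("scores must lie in 1..5")
    return (s >= 4).astype(int)


@dataclass(frozen=True)
class ReaderRecord:
    """Per-case five-point confidence of one reader in both sessions."""

    case_id: str
    truth: int
    session1_score: int
    session2_score: int
    reader_id: str

    def __post_init__(self):
        for s in (self.session1_score, self.session2_score):
            if not (1 <= s <= 5):
                raise ValueError("session scores must lie in 1..5")
        if self.truth not in (0, 1):
            raise ValueError("truth must be binary")


def _session_metrics(truth: np.ndarray, scores: np.ndarray, predictive_ci: str) -> MetricSet:
    binary = dichotomize_scores(scores)
    c = ConfusionCounts(
        tp=int(((binary == 1) & (truth == 1)).sum()),
        fp=int(((binary == 1) & (truth == 0)).sum()),
        fn=int(((binary == 0) & (truth == 1)).sum()),
        tn=int(((binary == 0) & (truth == 0)).sum()),
    )
    ms = metrics_from_confusion(c, predictive_ci=predictive_ci)
    ms.auroc = auroc(scores.astype(float), truth)
    return ms


def reader_study_table(records: list[ReaderRecord], predictive_ci: str = "clopper_pearson") -> pd.DataFrame:
    """Per-reader, per-session diagnostic performance with paired tests.

    For each reader: AUROC from the five-point scores (with a DeLong
    session-1 vs session-2 p), dichotomized sensitivity/specificity/PPV/NPV
    with 95% CIs, and McNemar p-values for the paired change in
    sensitivity (discordances among truth-positive cases) and specificity
    (among truth-negative cases).  One row per (reader, metric).
    """
    if not records:
        raise ValueError("no reader records supplied")
    df = pd.DataFrame([r.__dict__ for r in records])
    rows = []
    for reader_id, grp in df.groupby("reader_id", sort=True):
        truth = grp.truth.to_numpy(dtype=int)
        s1 = grp.session1_score.to_numpy(dtype=int)
        s2 = grp.session2_score.to_numpy(dtype=int)
        m1 = _session_metrics(truth, s1, predictive_ci)
        m2 = _session_metrics(truth, s2, predictive_ci)
        p_auc = delong_test(s1.astype(float), s2.astype(float), truth).p
        b1, b2 = dichotomize_scores(s1), dichotomize_scores(s2)
        pos = truth == 1
        neg = ~pos
        p_sens = mcnemar_test(
            int(((b1 == 1) & (b2 == 0) & pos).sum()),
            int(((b1 == 0) & (b2 == 1) & pos).sum()),
        )
        p_spec = mcnemar_test(
            int(((b1 == 0) & (b2 == 1) & neg).sum()),
            int(((b1 == 1) & (b2 == 0) & neg).sum()),
        )
        metric_rows = [
            ("auroc", m1.auroc, None, m2.auroc, None, p_auc),
            ("sensitivity", m1.sensitivity, m1.sensitivity_ci,
             m2.sensitivity, m2.sensitivity_ci, p_sens),
            ("specificity", m1.specificity, m1.specificity_ci,
             m2.specificity, m2.specificity_ci, p_spec),
            ("ppv", m1.ppv, m1.ppv_ci, m2.ppv, m2.ppv_ci, None),
            ("npv", m1.npv, m1.npv_ci, m2.npv, m2.npv_ci, None),
        ]
        for name, v1, ci1, v2, ci2, p in metric_rows:
            rows.append({
                "reader_id": reader_id,
                "metric": name,
                "session1": v1,
                "session1_ci_low": ci1[0] if ci1 else None,
                "session1_ci_high": ci1[1] if ci1 else None,
                "session2": v2,
                "session2_ci_low": ci2[0] if ci2 else None,
                "session2_ci_high": ci2[1] if ci2 else None,
                "p_value": p,
            })
    return pd.DataFrame(rows)
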