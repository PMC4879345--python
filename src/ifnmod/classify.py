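"""Healthy-reference threshold calibration, IFN-high classification and
group comparisons.

The per-subset threshold for "elevated IFN-1 module expression" is the
99th centile of the interferon score in healthy volunteers, computed
after removing outliers — samples whose two-sided normal p value
(z-score against the healthy mean/SD) survives a Holm adjustment below
0.001.  A sample anywhere in the cohort is IFN-high when its score
strictly exceeds that threshold.  Between-diagnosis differences use the
Kruskal-Wallis omnibus test and pairwise two-sided Wilcoxon rank-sum
tests (normal approximation with continuity correction) with Holm
adjustment over the pairwise family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import SampleAnnotation

logger = logging.getLogger(__name__)

STAR_CUTPOINTS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Stars at the 0.05 / 0.005 / 0.0005 cutpoints ('' when n.s.)."""
    for cut, stars in STAR_CUTPOINTS:
        if p < cut:
            return stars
    return ""


# ---------------------------------------------------------------------------
# outlier removal and threshold calibration
# ---------------------------------------------------------------------------


@dataclass
class OutlierReport:
    """Healthy samples retained/removed by the adjusted-normal-p rule."""

    retained: pd.Series
    removed: pd.Series
    p_raw: pd.Series
    p_adjusted: pd.Series
    alpha: float
    method: str


def remove_outliers(scores: pd.Series, alpha: float = 0.001,
                    method: str = "holm") -> OutlierReport:
    """Single-pass removal of extreme healthy-volunteer scores.

    z-scores are taken against the healthy mean/SD (n-1); two-sided
    normal p values are adjusted across the healthy set (Holm by
    default, Bonferroni as an option) and samples with adjusted
    p < ``alpha`` are removed.  No re-iteration.  Zero SD removes
    nothing (warning).
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 5:
        raise ValueError("outlier removal requires at least 5 healthy scores")
    if method not in ("holm", "bonferroni"):
        raise ValueError("adjustment method must be 'holm' or 'bonferroni'")
    sd = scores.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        logger.warning("remove_outliers: zero variance among healthy scores; "
                       "nothing removed")
        ones = pd.Series(1.0, index=scores.index)
        return OutlierReport(retained=scores, removed=scores.iloc[:0],
                             p_raw=ones, p_adjusted=ones, alpha=alpha, method=method)
    z = (scores - scores.mean()) / sd
    p_raw = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=scores.index)
    adjusted = multipletests(p_raw.to_numpy(), method=method)[1]
    p_adj = pd.Series(adjusted, index=scores.index)
    removed_mask = p_adj < alpha
    if removed_mask.any():
        logger.info("remove_outliers: removed %d of %d healthy samples: %s",
                    int(removed_mask.sum()), len(scores),
                    list(scores.index[removed_mask]))
    return OutlierReport(retained=scores[~removed_mask], removed=scores[removed_mask],
                         p_raw=p_raw, p_adjusted=p_adj, alpha=alpha, method=method)


@dataclass
class ThresholdReport:
    """Healthy-reference percentile threshold for one leucocyte subset."""

    subset: str
    threshold: float
    percentile: float
    n_healthy: int
    n_retained: int
    removed: tuple[str, ...]
    removed_p_adjusted: dict[str, float]
    alpha: float

    def to_dict(self) -> dict:
        return {"subset": self.subset, "threshold": self.threshold,
                "percentile": self.percentile, "n_healthy": self.n_healthy,
                "n_retained": self.n_retained, "removed": list(self.removed),
                "removed_p_adjusted": dict(self.removed_p_adjusted),
                "alpha": self.alpha}


def calibrate_threshold(retained: pd.Series | Sequence[float],
                        percentile: float = 99.0) -> float:
    """Linear-interpolation percentile of the retained healthy scores."""
    values = np.asarray(pd.Series(retained, dtype=float))
    if values.size == 0:
        raise ValueError("cannot calibrate a threshold from an empty score set")
    if values.size < 5:
        logger.warning("calibrate_threshold: only %d retained scores", values.size)
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(values, percentile, method="linear"))


def calibrate_subset_threshold(healthy_scores: pd.Series, subset: str,
                               percentile: float = 99.0, alpha: float = 0.001,
                               method: str = "holm") -> ThresholdReport:
    """Outlier removal followed by percentile calibration, with provenance."""
    report = remove_outliers(healthy_scores, alpha=alpha, method=method)
    threshold = calibrate_threshold(report.retained, percentile=percentile)
    return ThresholdReport(
        subset=subset, threshold=threshold, percentile=percentile,
        n_healthy=len(healthy_scores), n_retained=len(report.retained),
        removed=tuple(report.removed.index),
        removed_p_adjusted={s: float(report.p_adjusted.loc[s])
                            for s in report.removed.index},
        alpha=alpha)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationResult:
    """Per-sample IFN-high flags and per-diagnosis proportions."""

    flags: pd.Series
    threshold: float
    proportions: pd.DataFrame  # index diagnosis; columns n_high, n, proportion

    def to_dict(self) -> dict:
        return {"threshold": self.threshold,
                "flags": {s: bool(v) for s, v in self.flags.items()},
                "proportions": self.proportions.reset_index().to_dict(orient="records")}


def classify(scores: pd.Series, annot: SampleAnnotation,
             threshold: float) -> ClassificationResult:
    """Flag samples with score strictly above the threshold.

    Every scored sample must carry a diagnosis annotation; proportions
    are flagged/total per diagnosis.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = pd.Series(scores).astype(float)
    diag = annot.column("diagnosis", scores.index)
    flags = scores > threshold
    rows = []
    for d, group in diag.groupby(diag, sort=True):
        samples = group.index
        n_high = int(flags.loc[samples].sum())
        rows.append({"diagnosis": d, "n_high": n_high, "n": len(samples),
                     "proportion": n_high / len(samples)})
    return ClassificationResult(flags=flags, threshold=float(threshold),
                                proportions=pd.DataFrame(rows).set_index("diagnosis"))


class IfnHighClassifier(BaseEstimator):
    """Scikit-learn style healthy-reference threshold classifier.

    ``fit`` takes the interferon scores of the healthy reference group
    (1-d array or single-column 2-d), removes outliers by the
    adjusted-normal-p rule and stores the percentile threshold;
    ``predict`` flags scores strictly above it.

    Parameters
    ----------
    percentile : float
        Reference centile of retained healthy scores (default 99).
    outlier_alpha : float
        Adjusted-p cutoff for outlier removal (default 0.001).
    adjust : str
        "holm" (default) or "bonferroni".
    """

    def __init__(self, percentile: float = 99.0, outlier_alpha: float = 0.001,
                 adjust: str = "holm"):
        self.percentile = percentile
        self.outlier_alpha = outlier_alpha
        self.adjust = adjust

    @staticmethod
    def _scores(X) -> pd.Series:
        if isinstance(X, pd.Series):
            return X.astype(float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise ValueError("expected a single score column")
            arr = arr[:, 0]
        return pd.Series(arr)

    def fit(self, X, y=None) -> "IfnHighClassifier":
        scores = self._scores(X)
        self.outlier_report_ = remove_outliers(scores, alpha=self.outlier_alpha,
                                               method=self.adjust)
        self.threshold_ = calibrate_threshold(self.outlier_report_.retained,
                                              percentile=self.percentile)
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("IfnHighClassifier is not fitted")
        return self._scores(X).to_numpy() - self.threshold_

    def predict(self, X) -> np.ndarray:
        """Boolean IFN-high flags (score strictly above the threshold)."""
        return self.decision_function(X) > 0


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------


@dataclass
class GroupTestReport:
    """Kruskal-Wallis omnibus plus Holm-adjusted pairwise Wilcoxon tests."""

    kruskal_statistic: float
    kruskal_p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_holm, stars
    groups: tuple[str, ...]
    excluded: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"kruskal_statistic": self.kruskal_statistic,
                "kruskal_p": self.kruskal_p,
                "groups": list(self.groups), "excluded": list(self.excluded),
                "pairwise": self.pairwise.to_dict(orient="records")}


def group_tests(scores: pd.Series, annot: SampleAnnotation,
                group_column: str = "diagnosis") -> GroupTestReport:
    """Nonparametric score comparison across diagnosis groups.

    Kruskal-Wallis with midrank ties and tie correction over groups with
    >= 2 samples (smaller groups are excluded with a warning); all
    pairwise two-sided Wilcoxon rank-sum tests via the normal
    approximation with continuity correction, Holm-adjusted as one
    family.  Stars follow the 0.05/0.005/0.0005 cutpoints on adjusted p.
    """
    scores = pd.Series(scores).astype(float)
    groups_all = annot.column(group_column, scores.index)
    by_group = {g: scores.loc[idx].to_numpy()
                for g, idx in groups_all.groupby(groups_all, sort=True).groups.items()}
    excluded = tuple(g for g, v in by_group.items() if len(v) < 2)
    for g in excluded:
        logger.warning("group_tests: group %r has <2 samples; excluded", g)
    by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(by_group) < 2:
        raise ValueError("group_tests needs at least 2 groups with >= 2 samples")
    names = tuple(by_group)
    h, p = stats.kruskal(*by_group.values())

    rows = []
    for a, b in combinations(names, 2):
        res = stats.mannwhitneyu(by_group[a], by_group[b], alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        rows.append({"group_a": a, "group_b": b,
                     "statistic": float(res.statistic), "p_raw": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = multipletests(pairwise["p_raw"].to_numpy(), method="holm")[1]
    pairwise["stars"] = [significance_stars(p) for p in pairwise["p_holm"]]
    return GroupTestReport(kruskal_statistic=float(h), kruskal_p=float(p),
                           pairwise=pairwise, groups=names, excluded=excluded)
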