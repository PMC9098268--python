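"""Statistical feature screening and Relief-F ranking.

The screening stage mirrors a conventional two-step radiomics workflow:
each feature is checked for normality (Lilliefors-corrected one-sample
Kolmogorov-Smirnov test) and compared between classes with the classical
equal-variance two-sample t-test; features with two-sided P < alpha
(default 0.05, no multiplicity correction) pass the gate.  Relief-F then
scores the significant features and the top ``top_n`` (default 10) are
ranked, ties broken by registry order.

Relief-F here is the two-class form: for every instance R, find the k
nearest hits and k nearest misses under Manhattan distance on
range-normalized features and update

    W[f] += ( sum_miss |R_f - M_f| - sum_hit |R_f - H_f| ) / (range_f * m * k)

over all m instances.  Scores therefore lie in [-1, 1]; a constant feature
scores exactly 0 and scores are invariant to affine rescaling of any
feature column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .registry import FEATURE_GROUP, FEATURE_INDEX

__all__ = [
    "ScreeningResult",
    "ks_normality",
    "two_sample_t",
    "screen",
    "relieff_scores",
    "rank_best",
]

#: Metadata columns of a feature table; everything else is a feature.
META_COLUMNS = ("subject_id", "phase", "class")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _split_classes(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = feature_columns(table)
    labels = table["class"].to_numpy()
    x = table[names].to_numpy(dtype=np.float64)
    if not set(np.unique(labels)) <= {0, 1} or len(np.unique(labels)) < 2:
        raise ValueError("feature table must contain both classes, labelled 0/1")
    return x, labels.astype(int), names


def ks_normality(values) -> float:
    """Lilliefors-style one-sample KS p-value against a normal with the
    sample's mean and SD.  A zero-variance sample is degenerate (certainly
    non-normal) and returns p = 0 by convention."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 3:
        raise ValueError("normality test needs at least 3 observations")
    if v.std() == 0.0:
        return 0.0
    _, p = lilliefors(v, dist="norm")
    return float(p)


def two_sample_t(a, b) -> tuple[float, float]:
    """Classical equal-variance independent two-sample t-test (two-sided).

    Degenerate zero-pooled-variance samples follow the conventions
    t = 0, p = 1 for equal means and p = 0 (perfect separation) otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass(frozen=True)
class ScreeningResult:
    """Per-feature normality p-value, t-test p-value and significance flag."""

    table: pd.DataFrame  # columns: feature, ks_p, t_stat, t_p, significant
    alpha: float

    @property
    def significant(self) -> list[str]:
        return self.table.loc[self.table["significant"], "feature"].tolist()


def screen(table: pd.DataFrame, alpha: float = 0.05) -> ScreeningResult:
    """Gate each feature by the two-sample t-test at two-sided ``alpha``
    (raw p-values, no multiplicity correction); normality p-values are
    reported alongside."""
    x, labels, names = _split_classes(table)
    pos = x[labels == 1]
    neg = x[labels == 0]
    rows = []
    for j, name in enumerate(names):
        t, p = two_sample_t(pos[:, j], neg[:, j])
        rows.append(
            {
                "feature": name,
                "ks_p": ks_normality(x[:, j]),
                "t_stat": t,
                "t_p": p,
                "significant": bool(p < alpha),
            }
        )
    return ScreeningResult(table=pd.DataFrame(rows), alpha=alpha)


def relieff_scores(
    table: pd.DataFrame,
    k_neighbors: int = 5,
    feature_names: list[str] | None = None,
) -> pd.Series:
    """Two-class Relief-F weights for every feature (all instances used).

    Neighbours are found by Manhattan distance on range-normalized features;
    distance ties are broken by lowest sample index, so the result is
    deterministic and independent of sample order.
    """
    x, labels, names = _split_classes(table)
    if feature_names is not None:
        idx = [names.index(f) for f in feature_names]
        x = x[:, idx]
        names = list(feature_names)
    m, nf = x.shape
    for cls in (0, 1):
        if (labels == cls).sum() < k_neighbors + 1:
            raise ValueError(
                f"class {cls} has fewer than k_neighbors + 1 = "
                f"{k_neighbors + 1} samples; reduce k_neighbors"
            )
    lo = x.min(axis=0)
    rng_w = x.max(axis=0) - lo
    scale = np.where(rng_w > 0, rng_w, 1.0)
    xn = (x - lo) / scale
    xn[:, rng_w == 0] = 0.0  # constant features contribute nothing

    # pairwise Manhattan distances (m is small: cohort-scale data)
    diffs = np.abs(xn[:, None, :] - xn[None, :, :])
    dist = diffs.sum(axis=2)
    w = np.zeros(nf)
    order_key = np.arange(m)
    for r in range(m):
        same = labels == labels[r]
        for is_hit in (True, False):
            pool = np.flatnonzero(same if is_hit else ~same)
            if is_hit:
                pool = pool[pool != r]
            # stable sort on (distance, index) -> lowest-index tie-breaking
            sel = pool[np.lexsort((order_key[pool], dist[r, pool]))][:k_neighbors]
            contrib = diffs[r, sel, :].sum(axis=0)
            w += contrib if not is_hit else -contrib
    w /= m * k_neighbors
    return pd.Series(w, index=names, name="relieff_score")


def rank_best(
    scores: pd.Series,
    screening: ScreeningResult | None = None,
    top_n: int = 10,
) -> pd.DataFrame:
    """Rank the top ``top_n`` screened-significant features by descending
    Relief-F score (ties by registry order).

    Returns a table with columns ``Group, Rank, Feature, Score``.  When
    fewer than ``top_n`` features are significant, all of them are returned
    and a warning flags the shortfall.
    """
    if screening is not None:
        keep = [f for f in scores.index if f in set(screening.significant)]
        scores = scores.loc[keep]
    order = sorted(
        scores.index,
        key=lambda f: (-scores[f], FEATURE_INDEX.get(f, len(FEATURE_INDEX))),
    )
    if len(order) < top_n:
        warnings.warn(
            f"only {len(order)} significant features available "
            f"(requested top {top_n})",
            RuntimeWarning,
            stacklevel=2,
        )
    chosen = order[:top_n]
    return pd.DataFrame(
        {
            "Group": [FEATURE_GROUP.get(f, "unknown") for f in chosen],
            "Rank": np.arange(1, len(chosen) + 1),
            "Feature": chosen,
            "Score": [float(scores[f]) for f in chosen],
        }
    )
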