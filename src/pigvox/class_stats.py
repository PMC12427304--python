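"""Per-class distribution statistics and class comparisons.

Feature vectors are aggregated per sound class into quartile summaries
(the boxplot representation: quartiles, Tukey whiskers clipped to the
data range, quartile-based skewness label), radar-chart axis limits are
derived from a reference class, interquartile ranges of two classes are
compared by their overlap fraction, and the observation-count arithmetic
(percentages per category and subcategory) is reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pigvox.features import FEATURE_NAMES, FeatureVector

SKEW_POSITIVE = "positive"
SKEW_NEGATIVE = "negative"
SKEW_NONE = "none"

#: Display scalings mirroring the conventional table layout:
#: sum_ai is printed in units of 10^-1, var in units of 10^-6.
DISPLAY_SCALE = {"sum_ai": 10.0, "var": 1e6}


@dataclass(frozen=True)
class FeatureStats:
    """Boxplot-style summary of one feature within one class."""

    mean: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    skew: str

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class DistributionSummary:
    """Per-class summary: sample count and per-feature statistics."""

    n: int
    stats: dict[str, FeatureStats]

    def __getitem__(self, feature: str) -> FeatureStats:
        return self.stats[feature]


@dataclass(frozen=True)
class RadarAxisSpec:
    """Axis limits per feature for the radar-chart representation."""

    axes: dict[str, tuple[float, float]]
    scale_factor: float


def skew_label(
    q1: float, median: float, q3: float, threshold: float = 0.33
) -> str:
    """Quartile (Bowley) skewness label.

    B = (q3 + q1 - 2 median) / (q3 - q1); positive if B > threshold,
    negative if B < -threshold, else none.  Zero IQR yields none.
    """
    if not q1 <= median <= q3:
        raise ValueError("need q1 <= median <= q3")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    iqr = q3 - q1
    if iqr == 0:
        return SKEW_NONE
    b = (q3 + q1 - 2.0 * median) / iqr
    if b > threshold:
        return SKEW_POSITIVE
    if b < -threshold:
        return SKEW_NEGATIVE
    return SKEW_NONE


def summarize_values(
    values: Sequence[float], skew_threshold: float = 0.33
) -> FeatureStats:
    """Summary of one feature's data: quartiles by linear interpolation,
    Tukey whiskers clipped to the data range, skewness label.

    whisker_low is the smallest datum >= q1 - 1.5 IQR and whisker_high
    the largest datum <= q3 + 1.5 IQR.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    low_fence, high_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= low_fence) & (x <= high_fence)]
    skew = skew_label(q1, med, q3, skew_threshold) if x.size >= 3 else SKEW_NONE
    return FeatureStats(
        mean=float(x.mean()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        skew=skew,
    )


def summarize(
    class_features: Sequence[FeatureVector] | pd.DataFrame,
    skew_threshold: float = 0.33,
    class_name: str = "",
) -> DistributionSummary:
    """Aggregate feature vectors of one class into a DistributionSummary."""
    if isinstance(class_features, pd.DataFrame):
        df = class_features
        cols = {"sum_ai": "sum_ai", "a_bar": "a_bar_db", "var": "var",
                "q1": "q1_hz", "q2": "q2_hz", "q3": "q3_hz"}
        data = {f: df[c].to_numpy(float) for f, c in cols.items() if c in df}
        n = len(df)
    else:
        vecs = list(class_features)
        n = len(vecs)
        if n == 0:
            raise ValueError(f"empty class: {class_name or '<unnamed>'}")
        data = {
            "sum_ai": [v.sum_ai for v in vecs],
            "a_bar": [v.a_bar for v in vecs],
            "var": [v.var for v in vecs],
            "q1": [v.q1 for v in vecs],
            "q2": [v.q2 for v in vecs],
            "q3": [v.q3 for v in vecs],
        }
    if n == 0:
        raise ValueError(f"empty class: {class_name or '<unnamed>'}")
    stats = {f: summarize_values(vals, skew_threshold) for f, vals in data.items()}
    return DistributionSummary(n=n, stats=stats)


def summary_from_quartiles(
    n: int,
    quartiles: Mapping[str, Mapping[str, float]],
    skew_threshold: float = 0.33,
) -> DistributionSummary:
    """Build a summary from printed per-feature quartile tables.

    *quartiles* maps feature -> {mean, q1, med, q3}.  Whiskers are not
    derivable from quartiles alone and are set to the quartiles
    themselves.
    """
    stats = {}
    for f, q in quartiles.items():
        stats[f] = FeatureStats(
            mean=float(q.get("mean", np.nan)),
            q1=float(q["q1"]),
            median=float(q["med"]),
            q3=float(q["q3"]),
            whisker_low=float(q["q1"]),
            whisker_high=float(q["q3"]),
            skew=skew_label(q["q1"], q["med"], q["q3"], skew_threshold),
        )
    return DistributionSummary(n=n, stats=stats)


OVERLAP_NONE = "none"
OVERLAP_SLIGHT = "slight"
OVERLAP_STRONG = "strong"
OVERLAP_DEGENERATE = "degenerate"


def iqr_overlap(
    a: DistributionSummary | FeatureStats,
    b: DistributionSummary | FeatureStats,
    feature: str | None = None,
    slight_threshold: float = 0.25,
) -> tuple[float, str]:
    """Overlap of two classes' interquartile ranges for one feature.

    fraction = |[a.q1, a.q3] ∩ [b.q1, b.q3]| / min(IQR_a, IQR_b);
    0 -> none, (0, slight_threshold] -> slight, above -> strong.
    Symmetric in its arguments.
    """
    sa = a[feature] if isinstance(a, DistributionSummary) else a
    sb = b[feature] if isinstance(b, DistributionSummary) else b
    if sa.iqr == 0 or sb.iqr == 0:
        return 0.0, OVERLAP_DEGENERATE
    inter = min(sa.q3, sb.q3) - max(sa.q1, sb.q1)
    frac = max(0.0, inter) / min(sa.iqr, sb.iqr)
    if frac == 0.0:
        return 0.0, OVERLAP_NONE
    return frac, (OVERLAP_SLIGHT if frac <= slight_threshold else OVERLAP_STRONG)


def radar_axes(
    reference: DistributionSummary, scale_factor: float = 2.0
) -> RadarAxisSpec:
    """Radar-chart axis limits from a reference class.

    Per feature: axis_min = 0.5 q1_ref, axis_max = scale_factor x q3_ref
    (scale factors 2, 3 and 5.5 are the conventional choices).
    """
    axes = {}
    for f, st in reference.stats.items():
        if st.q1 <= 0 or st.q3 <= 0:
            raise ValueError(
                f"reference quartiles for {f} must be positive "
                f"(q1={st.q1}, q3={st.q3})"
            )
        axes[f] = (0.5 * st.q1, scale_factor * st.q3)
    return RadarAxisSpec(axes=axes, scale_factor=scale_factor)


def category_shares(
    counts: Mapping[str, int | float],
    decimals: int | None = 1,
) -> dict[str, float]:
    """Percentage share of each category within the total of *counts*.

    share = 100 * count / sum(counts), rounded to *decimals* places
    (``decimals=0`` yields whole-percent figures as floats;
    ``decimals=None`` disables rounding).  Shares over one denominator
    sum to 100 up to rounding slack.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be nonnegative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("zero denominator: no counts to share")
    shares = {k: 100.0 * c / total for k, c in counts.items()}
    if decimals is not None:
        shares = {k: round(v, decimals) for k, v in shares.items()}
    return shares


def share_of(count: float, denominator: float, decimals: int | None = 1) -> float:
    """Single percentage 100*count/denominator with the same rounding."""
    if denominator <= 0:
        raise ValueError("zero denominator")
    v = 100.0 * count / denominator
    return v if decimals is None else round(v, decimals)


def compare_classes(
    summaries: Mapping[str, DistributionSummary],
    features: Iterable[str] = FEATURE_NAMES,
    slight_threshold: float = 0.25,
) -> pd.DataFrame:
    """Pairwise class comparison report.

    For every feature and ordered class pair (a, b) with a < b in the
    mapping order: which median is higher (or 'equal'), the IQR-overlap
    fraction and label, and the IQR ratio a/b.
    """
    names = list(summaries)
    if len(names) < 2:
        raise ValueError("need at least two class summaries to compare")
    rows = []
    for f in features:
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                sa, sb = summaries[a][f], summaries[b][f]
                if sa.median > sb.median:
                    higher = a
                elif sb.median > sa.median:
                    higher = b
                else:
                    higher = "equal"
                frac, label = iqr_overlap(sa, sb, slight_threshold=slight_threshold)
                ratio = sa.iqr / sb.iqr if sb.iqr > 0 else np.inf
                rows.append(
                    {
                        "feature": f,
                        "class_a": a,
                        "class_b": b,
                        "median_a": sa.median,
                        "median_b": sb.median,
                        "higher_median": higher,
                        "overlap_fraction": frac,
                        "overlap_label": label,
                        "iqr_ratio_a_over_b": ratio,
                    }
                )
    return pd.DataFrame(rows)


def summaries_to_table(
    summaries: Mapping[str, DistributionSummary],
    display_scale: Mapping[str, float] = DISPLAY_SCALE,
) -> pd.DataFrame:
    """Summary table: rows = feature x statistic, columns = classes.

    sum_ai and var cells are shown x10 and x10^6 respectively, matching
    the conventional printed layout.
    """
    feature_rows = ["mean", "q1", "med", "q3"]
    index = pd.MultiIndex.from_tuples(
        [("n", "")] + [(f, s) for f in FEATURE_NAMES for s in feature_rows]
    )
    table = pd.DataFrame(index=index, columns=list(summaries), dtype=float)
    for cls, summ in summaries.items():
        table.loc[("n", ""), cls] = summ.n
        for f in FEATURE_NAMES:
            scale = display_scale.get(f, 1.0)
            st = summ[f]
            table.loc[(f, "mean"), cls] = st.mean * scale
            table.loc[(f, "q1"), cls] = st.q1 * scale
            table.loc[(f, "med"), cls] = st.median * scale
            table.loc[(f, "q3"), cls] = st.q3 * scale
    return table
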