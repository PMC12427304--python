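"""Reference tables from the expert-annotated barn study of fattening pigs.

These are the published observation counts and per-class feature
quartiles that the statistics layer is validated against.  The quartile
table ships as package data (``data/reference_class_quartiles.csv``) in
its printed display scale (sum_ai cells x10, var cells x10^6); loaders
below return it either as printed or converted to natural units.

The printed tables contain a few internal inconsistencies (subcategory
counts that do not sum to their stated totals); they are carried
verbatim here, not reconciled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from pigvox.class_stats import DISPLAY_SCALE, DistributionSummary, summary_from_quartiles

#: Behaviour counts over all 1705 directly observed behaviour-vocalization
#: combinations (six observation days, four pens).
OBSERVED_BEHAVIOR_COUNTS: dict[str, int] = {
    "grunting": 1018,
    "aversive_physical_contact": 240,
    "conflict_over_resources": 169,
    "alert": 93,
    "oral_manipulation": 73,
    "fight": 68,
    "playing_behavior": 44,
}

#: Acoustic subsample analysed with the feature framework.
SUBSAMPLE_TOTAL: int = 1167
SUBSAMPLE_VALENCE_COUNTS: dict[str, int] = {
    "positive_neutral": 380,
    "negative": 296,
    "alert": 51,
    "other": 427,
}

#: Subcategory counts within the negative class (denominator 296).
NEGATIVE_SUBCOUNTS: dict[str, int] = {
    "conflict_over_resources": 74,
    "fight": 54,
    "oral_manipulation": 45,
    "aversive_physical_contact": 123,
}

#: Subcategory counts within the "others" class.  Note these sum to 440,
#: not to the stated class total below; published percentages use the
#: stated total as denominator, and so do the checks here.
OTHERS_SUBCOUNTS: dict[str, int] = {
    "coughing": 81,
    "sneezing": 319,
    "ear_shaking": 27,
    "snoring": 13,
}
OTHERS_TOTAL: int = 427


def load_reference_quartiles(natural_units: bool = True) -> pd.DataFrame:
    """The per-class quartile table (rows feature x stat, columns classes).

    With ``natural_units=True`` the display scalings are undone so that
    sum_ai is in normalised amplitude per second and var in normalised
    amplitude squared.
    """
    path = resources.files("pigvox.data").joinpath("reference_class_quartiles.csv")
    with path.open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index(["feature", "stat"])
    if natural_units:
        for feature, factor in DISPLAY_SCALE.items():
            if feature in df.index.get_level_values(0):
                df.loc[feature] = (df.loc[feature] / factor).to_numpy()
    return df


def reference_summaries(
    classes: list[str] | None = None, skew_threshold: float = 0.33
) -> dict[str, DistributionSummary]:
    """DistributionSummary per class, built from the printed quartiles."""
    df = load_reference_quartiles(natural_units=True)
    ns = df.loc[("n", "n")]
    all_classes = [c for c in df.columns]
    classes = classes or all_classes
    out: dict[str, DistributionSummary] = {}
    features = [f for f in df.index.get_level_values(0).unique() if f != "n"]
    for cls in classes:
        quartiles = {
            f: {s: df.loc[(f, s), cls] for s in ("mean", "q1", "med", "q3")}
            for f in features
        }
        out[cls] = summary_from_quartiles(
            int(ns[cls]), quartiles, skew_threshold=skew_threshold
        )
    return out
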