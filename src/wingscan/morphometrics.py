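"""Wing-morphotype classification and the forewing-length linear model.

Morph classification is a one-dimensional two-cluster split of the
forewing:body length ratio.  Wing dimorphism is declared only when the two
ratio clusters are separated by a strict gap and each cluster holds a
non-trivial share of the sample — a singleton "cluster" is an outlier
measurement, not a morph.

The wing model is a Gaussian identity-link linear model of forewing length
on body length, sex, sampling altitude and the morph classification, with
per-term two-sided t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans

MACRO = "macropterous"
MICRO = "micropterous"
UNASSIGNED = "unassigned"


@dataclass
class MorphClassification:
    labels: pd.Series  # per-record class label
    dimorphic: bool
    class_stats: pd.DataFrame  # per-class ratio mean / sd / count
    threshold: float


def classify_morphs(
    records: pd.DataFrame,
    min_cluster_frac: float = 0.1,
    seed: int = 0,
) -> MorphClassification:
    """Split records into macropterous / micropterous by wing:body ratio.

    Two-means clustering of the ratios (25 restarts, fixed seed); the
    higher-ratio cluster is labeled macropterous and the threshold is the
    midpoint of the cluster means.  The dimorphism flag requires a strict
    positive gap between the clusters' ratio ranges and at least
    ``min_cluster_frac`` of the records in each cluster.  Scale-invariant:
    rescaling all lengths leaves ratios, labels and the flag unchanged.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    body = records["body_mm"].to_numpy(dtype=float)
    wing = records["forewing_mm"].to_numpy(dtype=float)
    if (body <= 0).any():
        raise ValueError("body length must be positive")
    ratio = wing / body

    if np.ptp(ratio) == 0.0:
        labels = pd.Series(UNASSIGNED, index=records.index, name="class_label")
        stats_df = pd.DataFrame(
            {"ratio_mean": [ratio[0]], "ratio_sd": [0.0], "n": [len(ratio)]},
            index=[UNASSIGNED],
        )
        return MorphClassification(labels, False, stats_df, float(ratio[0]))

    km = KMeans(n_clusters=2, n_init=25, random_state=seed).fit(ratio[:, None])
    means = km.cluster_centers_.ravel()
    upper = int(np.argmax(means))
    is_macro = km.labels_ == upper
    labels = pd.Series(
        np.where(is_macro, MACRO, MICRO), index=records.index, name="class_label"
    )

    gap = ratio[is_macro].min() - ratio[~is_macro].max()
    frac = min(is_macro.mean(), 1.0 - is_macro.mean())
    dimorphic = bool(gap > 0.0 and frac >= min_cluster_frac)

    stats_df = pd.DataFrame(
        {
            "ratio_mean": [ratio[is_macro].mean(), ratio[~is_macro].mean()],
            "ratio_sd": [ratio[is_macro].std(ddof=1) if is_macro.sum() > 1 else 0.0,
                         ratio[~is_macro].std(ddof=1) if (~is_macro).sum() > 1 else 0.0],
            "n": [int(is_macro.sum()), int((~is_macro).sum())],
        },
        index=[MACRO, MICRO],
    )
    threshold = float(means.mean())
    return MorphClassification(labels, dimorphic, stats_df, threshold)


def wing_model(
    records: pd.DataFrame,
    class_column: str = "class_label",
) -> pd.DataFrame:
    """OLS of forewing length on body length, sex, altitude and morph class.

    Sex and class enter as binary indicators (male = 1, micropterous = 1);
    altitude is continuous meters.  A regressor constant across the sample
    is dropped with a warning.  Returns a per-term coefficient table with
    estimate, standard error, t and two-sided p.
    """
    y = records["forewing_mm"].to_numpy(dtype=float)
    terms: dict[str, np.ndarray] = {
        "body_mm": records["body_mm"].to_numpy(dtype=float),
        "sex_male": (records["sex"].astype(str).str.upper() == "M").to_numpy(float),
        "altitude_m": records["altitude_m"].to_numpy(dtype=float),
        "class_micropterous": (
            records[class_column].astype(str) == MICRO
        ).to_numpy(float),
    }
    kept = {}
    for name, col in terms.items():
        if np.ptp(col) == 0.0:
            warnings.warn(f"dropping constant regressor {name!r}", stacklevel=2)
            continue
        kept[name] = col
    if len(records) <= len(kept) + 1:
        raise ValueError("more model terms than informative observations")
    x = sm.add_constant(pd.DataFrame(kept, index=records.index))
    fit = sm.OLS(y, x).fit()
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "std_error": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )
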