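"""Differential-feature screening and recovery assessment.

Candidate metabolites are screened between the control and model groups by
the joint rule VIP > 1.5 (from the OPLS-DA model) and Welch two-sided
t-test p < 0.05 on raw intensities, both strict.  Each marker carries its
fold change (model mean / control mean), the direction of change in the
model group, and per-treated-group recovery flags from treated-vs-model
t-tests.  A z-scored marker matrix with hierarchical clustering orders is
provided for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .features import FeatureTable

__all__ = [
    "MarkerRecord",
    "screen_markers",
    "fold_change_trend",
    "recovery_assessment",
    "heatmap_matrix",
    "bh_adjust",
]


@dataclass
class MarkerRecord:
    feature_id: str
    vip: float
    p_value: float
    p_adjusted: float
    fold_change: float
    trend: str  # "up" | "down" in the model group relative to control
    recovery_flags: dict = field(default_factory=dict)
    annotation: list = field(default_factory=list)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, never used to select)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sided t-test on log intensities.

    LC-MS intensities are approximately log-normal, so the test runs on the
    natural-log scale where it is well calibrated at small n; if either
    group contains non-positive values (e.g. zero-imputed entries) the raw
    scale is used instead.
    """
    if (a > 0).all() and (b > 0).all():
        a, b = np.log(a), np.log(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def fold_change_trend(
    t: FeatureTable, feature_id: str, control: str = "control", model: str = "model"
) -> tuple[float, str]:
    """Fold change (model mean / control mean) and direction in the model group.

    A fold change of exactly 1 is labelled ``down`` — an arbitrary but fixed
    tie rule so output is deterministic.
    """
    i = t.feature_ids.index(feature_id)
    mc = t.group_matrix(control)[i].mean()
    mm = t.group_matrix(model)[i].mean()
    if mc <= 0:
        raise ValueError(f"control mean non-positive for {feature_id!r}")
    fc = mm / mc
    return fc, ("up" if fc > 1 else "down")


def screen_markers(
    t: FeatureTable,
    vips: np.ndarray,
    vip_min: float = 1.5,
    alpha: float = 0.05,
    control: str = "control",
    model: str = "model",
) -> list[MarkerRecord]:
    """Select features with VIP strictly > ``vip_min`` and Welch p strictly < ``alpha``.

    ``vips`` must align with ``t.feature_ids``.  Returned records are sorted
    by VIP descending.  No multiple-testing correction enters the selection;
    BH-adjusted p-values ride along for transparency.
    """
    vips = np.asarray(vips, float)
    if len(vips) != t.n_features:
        raise ValueError("VIP vector does not align with the feature table")
    xc = t.group_matrix(control)
    xm = t.group_matrix(model)
    if xc.shape[1] < 2 or xm.shape[1] < 2:
        raise ValueError("both control and model groups need >= 2 samples")
    pvals = np.array([_welch_p(xc[i], xm[i]) for i in range(t.n_features)])
    padj = bh_adjust(pvals)
    records = []
    for i in range(t.n_features):
        if vips[i] > vip_min and pvals[i] < alpha:
            fc, trend = fold_change_trend(t, t.feature_ids[i], control, model)
            records.append(
                MarkerRecord(
                    feature_id=t.feature_ids[i],
                    vip=float(vips[i]),
                    p_value=float(pvals[i]),
                    p_adjusted=float(padj[i]),
                    fold_change=fc,
                    trend=trend,
                )
            )
    records.sort(key=lambda r: (-r.vip, r.feature_id))
    return records


def recovery_assessment(
    t: FeatureTable,
    markers: list[MarkerRecord],
    treated_groups: tuple[str, ...] = ("kansui", "vkansui"),
    model: str = "model",
) -> list[MarkerRecord]:
    """Flag treated-vs-model differences per marker: ns / p05 / p01.

    A significant treated-vs-model difference on a marker that separated
    model from control is read as (partial) normalisation by the treatment.
    Flags are written into each record's ``recovery_flags`` in place and the
    list is returned for chaining.
    """
    xm = t.group_matrix(model)
    for rec in markers:
        i = t.feature_ids.index(rec.feature_id)
        for g in treated_groups:
            xt = t.group_matrix(g)
            if xt.shape[1] < 2:
                rec.recovery_flags[g] = "ns"
                continue
            p = _welch_p(xt[i], xm[i])
            rec.recovery_flags[g] = "p01" if p < 0.01 else ("p05" if p < 0.05 else "ns")
    return markers


def heatmap_matrix(t: FeatureTable, markers: list[MarkerRecord]):
    """Z-scored marker x sample matrix with dendrogram leaf orders.

    Rows (markers) are z-scored across non-QC samples; both axes are
    clustered with average linkage on Euclidean distance and the leaf order
    is made deterministic by scipy's ordered dendrogram.  Zero-variance
    markers z-score to 0 and are flagged.

    Returns ``(z, row_order, col_order, marker_ids, sample_ids, flags)``.
    """
    if len(markers) < 2:
        raise ValueError("need at least 2 markers to cluster")
    mask = ~t.is_qc
    ids = [m.feature_id for m in markers]
    idx = [t.feature_ids.index(i) for i in ids]
    x = t.intensities[np.ix_(idx, np.flatnonzero(mask))]
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flags = (sd[:, 0] == 0)
    z = np.where(sd > 0, (x - mean) / np.where(sd == 0, 1, sd), 0.0)
    row_link = hierarchy.linkage(pdist(z), method="average")
    row_order = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(row_link, pdist(z)))
    col_d = pdist(z.T)
    col_link = hierarchy.linkage(col_d, method="average")
    col_order = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(col_link, col_d))
    sample_ids = [s for s, m in zip(t.sample_ids, mask) if m]
    return z, row_order, col_order, ids, sample_ids, flags
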