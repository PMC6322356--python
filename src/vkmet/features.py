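"""Aligned LC-MS feature tables and the preprocessing the chemometrics assumes.

A feature table is the usual metabolomics container: one row per aligned
feature (with m/z and retention time) and one column per sample, plus sample
metadata carrying group labels and QC flags.  Preprocessing covers missing
value imputation, a QC-based relative-standard-deviation filter, and Pareto
scaling (mean-centering followed by division by the square root of the
standard deviation), the scaling conventionally applied before PCA/OPLS-DA
of intensity data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "ScaledMatrix",
    "FormatError",
    "read_feature_table",
    "write_feature_table",
    "impute_missing",
    "qc_rsd_filter",
    "pareto_scale",
]


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix with m/z, RT and sample metadata.

    Attributes
    ----------
    feature_ids : list of str
    mz, rt : arrays (Th, minutes), one entry per feature
    intensities : (n_features, n_samples) float array; NaN marks missing
    sample_ids : list of str
    groups : list of str, per sample (e.g. control/model/kansui/vkansui)
    is_qc : boolean array, per sample
    """

    feature_ids: list[str]
    mz: np.ndarray
    rt: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    groups: list[str]
    is_qc: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.is_qc = np.asarray(self.is_qc, dtype=bool)
        nf, ns = self.intensities.shape
        if len(self.feature_ids) != nf or len(self.mz) != nf or len(self.rt) != nf:
            raise FormatError("feature annotation length does not match matrix rows")
        if len(self.sample_ids) != ns or len(self.groups) != ns or len(self.is_qc) != ns:
            raise FormatError("sample annotation length does not match matrix columns")
        if len(set(self.feature_ids)) != nf:
            raise FormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != ns:
            raise FormatError("duplicate sample ids")
        if np.any(self.mz <= 0):
            raise FormatError("m/z values must be positive")
        if np.any(self.rt < 0):
            raise FormatError("retention times must be non-negative")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise FormatError("negative intensities")

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def sample_mask(self, group: str, include_qc: bool = False) -> np.ndarray:
        m = np.array([g == group for g in self.groups])
        if not include_qc:
            m &= ~self.is_qc
        return m

    def group_matrix(self, group: str) -> np.ndarray:
        """Intensity sub-matrix (features x samples) of one non-QC group."""
        return self.intensities[:, self.sample_mask(group)]

    def subset_features(self, keep: np.ndarray) -> "FeatureTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return FeatureTable(
            [self.feature_ids[i] for i in idx],
            self.mz[idx],
            self.rt[idx],
            self.intensities[idx, :],
            list(self.sample_ids),
            list(self.groups),
            self.is_qc.copy(),
        )

    def copy(self) -> "FeatureTable":
        return self.subset_features(np.arange(self.n_features))


@dataclass
class ScaledMatrix:
    """Samples x features matrix after column scaling.

    ``values`` is oriented samples-by-features (the orientation multivariate
    models consume).  For Pareto scaling each column is centered and divided
    by the square root of its sample standard deviation, so the column
    variance of ``values`` equals the original feature SD.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    scaling: str
    constant_features: list[str] = field(default_factory=list)


def read_feature_table(path, metadata_path) -> FeatureTable:
    """Read a feature CSV (``feature_id,mz,rt,<sample...>``) + metadata TSV.

    The metadata TSV has columns ``sample_id  group  is_qc``; its sample set
    must match the table's columns exactly.
    """
    df = pd.read_csv(path, dtype={0: str})
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise FormatError(f"feature table missing column {col!r}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group", "is_qc"):
        if col not in meta.columns:
            raise FormatError(f"metadata missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("feature_id", "mz", "rt")]
    meta_ids = list(meta["sample_id"])
    missing = set(sample_cols) - set(meta_ids)
    if missing:
        raise FormatError(f"samples absent from metadata: {sorted(missing)}")
    extra = set(meta_ids) - set(sample_cols)
    if extra:
        raise FormatError(f"metadata samples absent from table: {sorted(extra)}")
    meta = meta.set_index("sample_id").loc[sample_cols]
    inten = df[sample_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    raw = df[sample_cols]
    bad = inten != inten
    originally_blank = raw.isna().to_numpy()
    if np.any(bad & ~originally_blank):
        i, j = np.argwhere(bad & ~originally_blank)[0]
        raise FormatError(
            f"non-numeric intensity at feature {df['feature_id'].iat[i]!r}, "
            f"sample {sample_cols[j]!r}"
        )
    is_qc = meta["is_qc"].astype(str).str.lower().isin(["1", "true", "yes"]).to_numpy()
    return FeatureTable(
        list(df["feature_id"].astype(str)),
        df["mz"].to_numpy(float),
        df["rt"].to_numpy(float),
        inten,
        sample_cols,
        list(meta["group"].astype(str)),
        is_qc,
    )


def write_feature_table(t: FeatureTable, path, metadata_path) -> None:
    df = pd.DataFrame({"feature_id": t.feature_ids, "mz": t.mz, "rt": t.rt})
    for j, sid in enumerate(t.sample_ids):
        df[sid] = t.intensities[:, j]
    df.to_csv(path, index=False)
    meta = pd.DataFrame(
        {"sample_id": t.sample_ids, "group": t.groups, "is_qc": t.is_qc.astype(int)}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def impute_missing(t: FeatureTable, rule: str = "half_min") -> FeatureTable:
    """Fill missing intensities.

    half_min
        replace missing entries of a feature by half its observed minimum;
        a feature missing everywhere is dropped (with a warning).
    zero
        replace by 0.
    drop_feature
        remove any feature with at least one missing entry.
    """
    if rule not in ("half_min", "zero", "drop_feature"):
        raise ValueError(f"unknown imputation rule {rule!r}")
    x = t.intensities.copy()
    missing = np.isnan(x)
    if rule == "drop_feature":
        return t.subset_features(~missing.any(axis=1))
    if rule == "zero":
        x[missing] = 0.0
        out = t.copy()
        out.intensities = x
        return out
    all_missing = missing.all(axis=1)
    if all_missing.any():
        dropped = [t.feature_ids[i] for i in np.flatnonzero(all_missing)]
        warnings.warn(f"dropping entirely-missing features: {dropped}")
    for i in np.flatnonzero(missing.any(axis=1) & ~all_missing):
        row = x[i]
        row[np.isnan(row)] = np.nanmin(row) / 2.0
    out = t.subset_features(~all_missing)
    out.intensities = x[~all_missing]
    return out


def qc_rsd_filter(t: FeatureTable, max_rsd_pct: float = 30.0) -> FeatureTable:
    """Drop features whose relative SD across QC injections exceeds the cap.

    RSD = sample SD / mean (ddof=1), in percent.  With fewer than two QC
    samples the filter is a no-op (warned), matching practice when no QC
    series was acquired.
    """
    qc = t.intensities[:, t.is_qc]
    if qc.shape[1] < 2:
        warnings.warn("fewer than 2 QC samples; RSD filter skipped")
        return t.copy()
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, sd / mean * 100.0, np.inf)
    keep = rsd <= max_rsd_pct
    return t.subset_features(keep)


def pareto_scale(t: FeatureTable, include_qc: bool = False) -> ScaledMatrix:
    """Pareto-scale: center each feature, divide by sqrt(sample SD).

    QC samples are excluded by default so they do not shift biological group
    means.  Constant features scale to all-zero columns and are flagged
    rather than raising, which keeps tiny hand-made fixtures usable.
    """
    mask = ~t.is_qc if not include_qc else np.ones(t.n_samples, bool)
    x = t.intensities[:, mask].T  # samples x features
    if x.shape[0] < 2:
        raise ValueError("Pareto scaling needs at least 2 samples")
    if np.isnan(x).any():
        raise ValueError("missing values present; impute first")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    centered = x - means
    constant = sds == 0
    scale = np.where(constant, 1.0, np.sqrt(np.where(constant, 1.0, sds)))
    values = centered / scale
    values[:, constant] = 0.0
    return ScaledMatrix(
        values=values,
        feature_ids=list(t.feature_ids),
        sample_ids=[s for s, m in zip(t.sample_ids, mask) if m],
        feature_means=means,
        feature_sds=sds,
        scaling="pareto",
        constant_features=[t.feature_ids[i] for i in np.flatnonzero(constant)],
    )
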