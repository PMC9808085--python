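"""Detection-limit filtering, variance stabilization and left-censored imputation.

The preprocessing chain mirrors common practice for targeted metabolomics /
DIA proteomics quantitation tables:

1. :func:`filter_low_abundance` — drop analytes that are reliably quantified
   (above 10x LOD or above the LLOQ) in too few samples.
2. :func:`glog_transform` — median-ratio per-sample scaling followed by a
   generalized log2, yielding approximately homoskedastic values.
3. :func:`impute_min_det` — deterministic left-censored imputation: missing
   cells take a low quantile of the observed values of their sample (MinDet).
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix


@dataclasses.dataclass
class DetectionLimits:
    """Per-feature LOD / LLOQ table (concentration units; either may be NaN)."""

    table: pd.DataFrame  # index feature_id, columns lod, lloq

    def __post_init__(self) -> None:
        for col in ("lod", "lloq"):
            if col not in self.table.columns:
                raise ValueError(f"limits table must have a {col!r} column")
            vals = self.table[col].to_numpy(dtype=float)
            if (vals < 0).any():
                raise ValueError(f"{col} values must be >= 0")
        self.table.index = self.table.index.astype(str)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DetectionLimits":
        df = pd.read_csv(path, sep="\t", comment="#")
        if "feature_id" not in df.columns:
            raise ValueError("limits TSV must have a feature_id column")
        return cls(df.set_index("feature_id")[["lod", "lloq"]].astype(float))

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", na_rep="NA")


def filter_low_abundance(matrix: OmicsMatrix,
                         limits: DetectionLimits | None = None,
                         min_frac: float = 0.66
                         ) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Remove low-abundance features.

    A cell qualifies when its value exceeds 10x the feature's LOD or is at or
    above its LLOQ (features without any limit qualify wherever they are
    non-missing).  A feature is retained iff its qualifying fraction is
    strictly greater than `min_frac`.

    Returns the filtered matrix and a report of the removed features with
    their qualifying fractions.
    """
    if matrix.stage != "raw":
        raise ValueError("filtering operates on raw matrices")
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")

    vals = matrix.values()
    observed = ~np.isnan(vals)
    if limits is None:
        qualifies = observed
    else:
        lod = limits.table["lod"].reindex(matrix.features).to_numpy(dtype=float)
        lloq = limits.table["lloq"].reindex(matrix.features).to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            above_lod = vals > 10.0 * lod[:, None]
            above_lloq = vals >= lloq[:, None]
        qualifies = above_lod | above_lloq
        no_limit = np.isnan(lod) & np.isnan(lloq)
        qualifies[no_limit, :] = observed[no_limit, :]
    frac = qualifies.mean(axis=1)
    keep = frac > min_frac
    report = pd.DataFrame({"feature_id": matrix.features[~keep],
                           "qualifying_fraction": frac[~keep]})
    return OmicsMatrix(matrix.data.loc[keep], "raw"), report


def glog2(x, c: float):
    """Generalized log2: log2((x + sqrt(x^2 + c^2)) / 2); equals log2(x) at c=0."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def glog_transform(matrix: OmicsMatrix,
                   c_quantile: float = 0.05) -> OmicsMatrix:
    """Variance-stabilizing transform: median-ratio scaling + generalized log2.

    Per-sample scale factors are medians of ratios to a geometric-mean
    reference profile (computed over features complete in all samples, falling
    back to observed values when no feature is complete).  The glog offset `c`
    is the `c_quantile` quantile of the scaled non-missing values, one value
    for the whole dataset.  Missing stays missing; the transform is monotone
    within each sample.
    """
    if matrix.stage != "raw":
        raise ValueError("glog_transform operates on raw matrices")
    vals = matrix.values()
    if np.nanmin(vals) < 0:
        raise ValueError("negative values encountered")
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} all-missing feature(s) kept as missing")

    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), np.nan)
    complete = ~np.isnan(logv).any(axis=1)
    if complete.any():
        ref = np.exp(logv[complete].mean(axis=1))
        ratios = vals[complete] / ref[:, None]
    else:
        ref = np.exp(np.nanmean(logv, axis=1))
        ratios = vals / ref[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN sample columns
        s = np.nanmedian(ratios, axis=0)
    if np.isnan(s).any() or (s <= 0).any():
        raise ValueError("could not estimate positive scale factors for all samples")

    scaled = vals / s[None, :]
    c = float(np.nanquantile(scaled, c_quantile))
    out = glog2(scaled, c)
    out[np.isnan(vals)] = np.nan
    return matrix.advance(pd.DataFrame(out, index=matrix.features,
                                       columns=matrix.samples), "transformed")


def impute_min_det(matrix: OmicsMatrix, q: float = 0.01) -> OmicsMatrix:
    """Deterministic left-censored imputation (MinDet).

    Each missing cell of sample j is replaced by the `q`-quantile (linear
    interpolation between order statistics) of the observed values of sample
    j.  A sample with no observed values is an error.
    """
    if matrix.stage != "transformed":
        raise ValueError("impute_min_det operates on transformed matrices")
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    vals = matrix.values().copy()
    for j, sid in enumerate(matrix.samples):
        col = vals[:, j]
        miss = np.isnan(col)
        if miss.all():
            raise ValueError(f"sample {sid!r} has no observed values; cannot impute")
        if miss.any():
            col[miss] = np.quantile(col[~miss], q)
    return matrix.advance(pd.DataFrame(vals, index=matrix.features,
                                       columns=matrix.samples), "imputed")


def average_duplicates(matrix: OmicsMatrix,
                       sample_map: dict[str, str]) -> OmicsMatrix:
    """Average duplicate injections per sample.

    `sample_map` maps each matrix column to the sample it belongs to; columns
    mapping to the same sample are averaged (mean over observed values) and
    the result is one column per sample, in first-appearance order.
    """
    missing = [c for c in matrix.samples if c not in sample_map]
    if missing:
        raise ValueError(f"columns without a sample assignment: {missing}")
    groups = pd.Series({c: sample_map[c] for c in matrix.samples})
    averaged = matrix.data.T.groupby(groups, sort=False).mean().T
    return OmicsMatrix(averaged, matrix.stage)
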