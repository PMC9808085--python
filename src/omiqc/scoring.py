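"""Signature enrichment scoring with a permutation-based empirical null.

For a sample profile x (per-feature z-scores across the cohort) and a weighted
signature S, the raw activity is the weighted mean

    score = sum_{i in S} w_i x_i / sum_{i in S} |w_i|

over the signature members present in the measured feature universe.  An
empirical null is built per sample by permuting that sample's values across
the whole universe (weights stay attached to the signature's features) and
recomputing the score; the normalized enrichment score (NES) is the raw score
expressed in null standard deviations:

    NES = (score - null_mean) / null_sd.

An NES of 0 means average degradation / contamination relative to the cohort;
the score is relative by construction and cannot quantify absolute sample
quality, hence the recommendation to include reference samples of known
quality (see :func:`delta_vs_reference`).
"""
from __future__ import annotations

import dataclasses
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .signatures import Signature


@dataclasses.dataclass
class ScoreTable:
    """Per (sample, signature) raw scores, null summaries and NES."""

    table: pd.DataFrame  # sample_id, signature, raw_score, null_mean, null_sd, nes, n_overlap

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path, sep="\t", na_values=["NA"]))

    def wide_nes(self) -> pd.DataFrame:
        return self.table.pivot(index="sample_id", columns="signature",
                                values="nes")


def scale_per_feature(matrix: OmicsMatrix) -> OmicsMatrix:
    """Z-score each feature across samples (mean 0, sample SD 1, ddof=1).

    Constant features become all zeros with a warning.  Requires at least two
    samples and an imputed (missing-free) matrix.
    """
    if matrix.stage != "imputed":
        raise ValueError("scaling expects an imputed matrix")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to scale across the cohort")
    vals = matrix.values()
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) scaled to zeros")
    sd[constant, :] = 1.0
    out = (vals - mean) / sd
    out[constant, :] = 0.0
    return matrix.advance(pd.DataFrame(out, index=matrix.features,
                                       columns=matrix.samples), "scaled")


def wmean_score(profile: pd.Series, signature: Signature,
                min_overlap: int = 3) -> float:
    """Weighted-mean activity of `signature` on one sample profile.

    Unmeasured signature features are dropped (reported via a warning); the
    overlap must reach `min_overlap` and carry some non-zero weight.
    """
    present = [f for f in signature.entries if f in profile.index]
    missing = [f for f in signature.entries if f not in profile.index]
    if missing:
        warnings.warn(f"signature {signature.name!r}: "
                      f"{len(missing)} unmeasured feature(s): {missing}")
    if len(present) < min_overlap:
        raise ValueError(
            f"signature {signature.name!r} overlaps the measured features in "
            f"{len(present)} < min_overlap={min_overlap} features")
    w = np.array([signature.entries[f] for f in present], dtype=float)
    denom = np.abs(w).sum()
    if denom == 0:
        raise ValueError(f"signature {signature.name!r}: all overlapping weights are zero")
    x = profile.loc[present].to_numpy(dtype=float)
    return float((w @ x) / denom)


def _sample_rng(seed: int | None, sample_id: str) -> np.random.Generator:
    # keyed by sample id so scores are invariant to column order
    key = zlib.crc32(str(sample_id).encode())
    return np.random.default_rng(np.random.SeedSequence((0 if seed is None else seed, key)))


def nes_scores(matrix: OmicsMatrix, signatures: list[Signature],
               n_perm: int = 1000, seed: int | None = None,
               min_overlap: int = 3) -> ScoreTable:
    """Normalized enrichment scores for every sample x signature.

    The null permutes each sample's values across the full measured feature
    universe (`n_perm` draws, shared across signatures within a sample) and
    recomputes the weighted-mean score.  NES = (raw - null_mean) / null_sd;
    when the null is degenerate (sd 0) the NES is missing and a warning is
    emitted.  Deterministic given `seed`, independent of sample column order.
    """
    if matrix.stage != "scaled":
        raise ValueError("nes_scores expects a scaled matrix")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    feats = matrix.features
    pos_of = {f: k for k, f in enumerate(feats)}
    sig_info = []
    for sig in signatures:
        present = [f for f in sig.entries if f in pos_of]
        missing = [f for f in sig.entries if f not in pos_of]
        if missing:
            warnings.warn(f"signature {sig.name!r}: {len(missing)} "
                          f"unmeasured feature(s) dropped")
        if len(present) < min_overlap:
            raise ValueError(
                f"signature {sig.name!r} overlaps the measured universe in "
                f"{len(present)} < min_overlap={min_overlap} features")
        w = np.array([sig.entries[f] for f in present], dtype=float)
        denom = np.abs(w).sum()
        if denom == 0:
            raise ValueError(f"signature {sig.name!r}: all overlapping weights are zero")
        idx = np.array([pos_of[f] for f in present], dtype=int)
        sig_info.append((sig.name, idx, w, denom))

    vals = matrix.values()
    n_feat = vals.shape[0]
    rows = []
    degenerate: list[tuple[str, str]] = []
    for j, sid in enumerate(matrix.samples):
        x = vals[:, j]
        rng = _sample_rng(seed, sid)
        perm_idx = np.argsort(rng.random((n_perm, n_feat)), axis=1)
        xp = x[perm_idx]                      # n_perm x n_feat
        for name, idx, w, denom in sig_info:
            raw = float((w @ x[idx]) / denom)
            null = xp[:, idx] @ w / denom
            nm = float(null.mean())
            nsd = float(null.std(ddof=1))
            if nsd > 0:
                nes = (raw - nm) / nsd
            else:
                nes = np.nan
                degenerate.append((sid, name))
            rows.append((sid, name, raw, nm, nsd, nes, len(idx)))
    if degenerate:
        warnings.warn(f"degenerate permutation null (sd=0); NES missing for: "
                      f"{degenerate}")
    return ScoreTable(pd.DataFrame(rows, columns=[
        "sample_id", "signature", "raw_score", "null_mean", "null_sd", "nes",
        "n_overlap"]))


def group_average(score_table: ScoreTable, metadata: pd.DataFrame,
                  keys: tuple[str, ...] = ("matrix", "temperature", "time_h")
                  ) -> pd.DataFrame:
    """Mean NES per signature per condition group (plus group sizes)."""
    missing = [k for k in keys if k not in metadata.columns]
    if missing:
        raise ValueError(f"grouping keys not in metadata: {missing}")
    merged = score_table.table.merge(metadata[list(keys)], left_on="sample_id",
                                     right_index=True, how="left")
    if merged[list(keys)].isna().any().any():
        orphans = merged.loc[merged[list(keys)].isna().any(axis=1),
                             "sample_id"].unique().tolist()
        raise ValueError(f"samples missing from metadata: {orphans}")
    grouped = (merged.groupby(["signature", *keys], observed=True)["nes"]
               .agg(mean_nes="mean", n="size").reset_index())
    return grouped


def delta_vs_reference(score_table: ScoreTable,
                       reference_samples: list[str]) -> pd.DataFrame:
    """NES relative to the mean NES of designated reference samples.

    Implements the advice to anchor the relative score on at least one sample
    of known quality: returns the score table with a `delta_nes` column (NES
    minus the per-signature reference mean).
    """
    table = score_table.table
    refs = set(reference_samples)
    missing = refs - set(table["sample_id"])
    if missing:
        raise ValueError(f"reference samples not scored: {sorted(missing)}")
    ref_mean = (table[table["sample_id"].isin(refs)]
                .groupby("signature")["nes"].mean())
    out = table.copy()
    out["delta_nes"] = out["nes"] - out["signature"].map(ref_mean)
    return out
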