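"""Weighted feature signatures for sample quality and contamination scoring.

Two kinds of signatures are handled here:

* **Derived quality signatures** — the top-k features (by p-value) of a
  differential contrast between long-sat and fresh samples under a handling
  condition (e.g. plasma kept at room temperature for 8 h vs 0 h), weighted by
  the moderated t-value of that contrast.  Positive weight means the feature
  increases in the degraded condition.
* **Contamination signatures** — marker panels for erythrocyte lysis
  (hemolysis), platelet carry-over and coagulation.  These are data, not
  algorithm: the bundled panels are representative marker sets from the plasma
  proteome quality-control literature and can be replaced wholesale through
  :func:`load_signatures`.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

SOURCES = ("derived_quality", "contamination")


@dataclasses.dataclass
class Signature:
    """Named weighted feature set.

    entries maps feature id -> signed weight; positive weight means the
    feature increases under the degraded / contaminated condition.
    """

    name: str
    entries: dict[str, float]
    source: str = "derived_quality"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown signature source {self.source!r}")
        if not self.entries:
            raise ValueError(f"signature {self.name!r} has no entries")
        weights = np.array(list(self.entries.values()), dtype=float)
        if not np.isfinite(weights).all():
            raise ValueError(f"signature {self.name!r} has non-finite weights")
        if (weights == 0).all():
            raise ValueError(f"signature {self.name!r} has all-zero weights")
        self.entries = {str(k): float(v) for k, v in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Signature):
            return NotImplemented
        return (
            self.name == other.name
            and self.source == other.source
            and self.provenance == other.provenance
            and self.entries.keys() == other.entries.keys()
            and all(math.isclose(self.entries[k], other.entries[k]) for k in self.entries)
        )


def derive_quality_signature(result, condition_label: str, k: int = 20,
                             factor: str | None = None) -> Signature:
    """Build a quality signature from a differential-contrast result.

    Selects the `k` features with the smallest raw p-value (ties broken by
    larger |t|, then lexicographic feature id) and uses the moderated t-value
    as the signed weight.

    Parameters
    ----------
    result
        A :class:`~omiqc.stability.StabilityResult` holding the late-vs-fresh
        contrast (one factor, typically ``time8_vs_0``).
    condition_label
        Human-readable handling condition, e.g. ``"plasma_RT_8h"``; recorded
        as provenance.
    factor
        Which factor of `result` to rank on; may be omitted when the result
        contains a single factor.
    """
    table = result.table
    if factor is None:
        factors = table["factor"].unique()
        if len(factors) != 1:
            raise ValueError(
                f"result has factors {sorted(factors)}; pass `factor` explicitly")
        factor = factors[0]
    sub = table[table["factor"] == factor]
    if sub.empty:
        raise ValueError(f"factor {factor!r} not present in result")
    sub = sub[np.isfinite(sub["p"].to_numpy(dtype=float))]
    if sub.empty:
        raise ValueError("no finite p-values to rank")
    sub = sub.assign(_abs_t=sub["statistic"].abs())
    sub = sub.sort_values(["p", "_abs_t", "feature_id"],
                          ascending=[True, False, True], kind="mergesort")
    if len(sub) < k:
        warnings.warn(
            f"only {len(sub)} features with finite p-values; signature smaller than k={k}")
    top = sub.head(k)
    entries = dict(zip(top["feature_id"], top["statistic"].astype(float)))
    return Signature(name=condition_label, entries=entries,
                     source="derived_quality",
                     provenance=f"top-{k} by p-value, factor={factor}")


# -- TSV round trip ---------------------------------------------------------

def write_signatures(signatures: list[Signature], path: str | Path) -> None:
    """Write signatures as TSV with columns signature, feature_id, weight (+provenance)."""
    rows = []
    for sig in signatures:
        for feat, w in sig.entries.items():
            rows.append((sig.name, feat, w, sig.source, sig.provenance))
    pd.DataFrame(rows, columns=["signature", "feature_id", "weight",
                                "source", "provenance"]).to_csv(
        path, sep="\t", index=False)


def load_signatures(path: str | Path) -> list[Signature]:
    """Load signatures from TSV (header: signature, feature_id, weight)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"signature", "feature_id", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"signature file must have columns {sorted(required)}")
    weights = pd.to_numeric(df["weight"], errors="coerce")
    if weights.isna().any():
        bad = df.loc[weights.isna(), ["signature", "feature_id"]].values.tolist()
        raise ValueError(f"non-numeric weights for rows: {bad}")
    df["weight"] = weights
    if df.duplicated(subset=["signature", "feature_id"]).any():
        dups = df[df.duplicated(subset=["signature", "feature_id"], keep=False)]
        raise ValueError(
            "duplicate (signature, feature) rows: "
            f"{dups[['signature', 'feature_id']].values.tolist()}")
    out = []
    for name, grp in df.groupby("signature", sort=False):
        source = grp["source"].iloc[0] if "source" in grp else "derived_quality"
        prov = grp["provenance"].iloc[0] if "provenance" in grp else ""
        if pd.isna(prov):
            prov = ""
        out.append(Signature(name=str(name),
                             entries=dict(zip(grp["feature_id"], grp["weight"])),
                             source=str(source), provenance=str(prov)))
    return out


# -- bundled contamination panels -------------------------------------------
#
# Representative blood-cell contamination markers.  Erythrocyte and platelet
# panels carry unit weights (+1, no continuous weighting available);
# the coagulation panel is signed: platelet-release proteins rise in serum
# (PPBP, THBS1, PF4) while factor XIII and fibrinogen chains are consumed by
# the clot (F13A1, F13B, FGA, FGB, FGG).  All three panels are replaceable via
# load_signatures.

_ERYTHROCYTE = ["CAT", "CA1", "CA2", "BLVRB", "PRDX1", "PRDX2", "ALDOA",
                "HBA1", "HBB", "HBD", "SLC4A1", "SPTA1"]
_PLATELET = ["PF4", "PPBP", "THBS1", "FLNA", "TLN1", "MYH9", "ITGA2B",
             "ITGB3", "TUBB1", "VCL"]
_COAGULATION = {"PPBP": 1.0, "THBS1": 1.0, "PF4": 1.0,
                "F13A1": -1.0, "F13B": -1.0, "FGA": -1.0, "FGB": -1.0,
                "FGG": -1.0}


def bundled_contamination_signatures() -> list[Signature]:
    """Return the bundled erythrocyte, platelet and coagulation signatures."""
    return [
        Signature("erythrocyte", {g: 1.0 for g in _ERYTHROCYTE},
                  source="contamination", provenance="bundled marker panel"),
        Signature("platelet", {g: 1.0 for g in _PLATELET},
                  source="contamination", provenance="bundled marker panel"),
        Signature("coagulation", dict(_COAGULATION),
                  source="contamination", provenance="bundled marker panel"),
    ]


def contamination_marker_ids() -> list[str]:
    """All feature ids appearing in the bundled contamination panels."""
    ids: list[str] = []
    for sig in bundled_contamination_signatures():
        for g in sig.entries:
            if g not in ids:
                ids.append(g)
    return ids
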