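"""Data containers shared across the pipeline.

Quantitation matrices are features x samples pandas DataFrames wrapped with a
processing-stage tag.  Sample metadata is a plain DataFrame indexed by sample
id carrying the pre-analytical design factors (individual, matrix type,
sitting time, temperature, centrifugation force).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Processing stages in pipeline order; transitions may only move rightwards.
STAGES = ("raw", "transformed", "imputed", "scaled")

#: Required metadata columns besides the sample-id index.
METADATA_COLUMNS = ("individual", "matrix", "time_h", "temperature", "centrifugation_g")

MATRIX_TYPES = ("plasma", "serum")


@dataclasses.dataclass
class OmicsMatrix:
    """Features x samples quantitation matrix with a processing-stage tag.

    Parameters
    ----------
    data
        DataFrame with feature ids as index, sample ids as columns and NaN as
        the explicit missing-value marker.
    stage
        One of :data:`STAGES`.  Raw matrices must be non-negative
        (concentrations / intensities).
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        if self.stage == "raw" and self.data.size:
            vals = self.data.to_numpy(dtype=float)
            if (vals < 0).any():
                raise ValueError("raw matrices must not contain negative values")

    # -- basic accessors ---------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def advance(self, data: pd.DataFrame, stage: str) -> "OmicsMatrix":
        """Return a new matrix at `stage`, enforcing forward-only transitions."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage may not move backwards ({self.stage} -> {stage})")
        return OmicsMatrix(data=data, stage=stage)

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write a TSV with a `# stage:` comment line and `feature_id` column."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# stage: {self.stage}\n")
            out = self.data.copy()
            out.index.name = "feature_id"
            out.to_csv(fh, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str | None = None) -> "OmicsMatrix":
        path = Path(path)
        file_stage = "raw"
        with path.open() as fh:
            first = fh.readline()
        if first.startswith("#"):
            if "stage:" in first:
                file_stage = first.split("stage:", 1)[1].strip()
        df = pd.read_csv(path, sep="\t", comment="#", index_col="feature_id",
                         na_values=["NA"])
        return cls(data=df, stage=stage or file_stage)


# -- sample metadata -------------------------------------------------------

def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample-metadata table.

    Accepts either a `sample_id` column or sample ids in the index; returns a
    copy indexed by sample id with the canonical columns.
    """
    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    md.index = md.index.astype(str)
    if md.index.has_duplicates:
        dups = md.index[md.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    bad = set(md["matrix"]) - set(MATRIX_TYPES)
    if bad:
        raise ValueError(f"unknown matrix types {sorted(bad)}; expected {MATRIX_TYPES}")
    md["time_h"] = md["time_h"].astype(float)
    md["individual"] = md["individual"].astype(str)
    md["temperature"] = md["temperature"].astype(str)
    return md


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t", comment="#"))


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = validate_metadata(metadata)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
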