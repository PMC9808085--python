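"""End-to-end pipeline orchestration, configuration and input validation.

The full run executes simulate -> preprocess -> stability -> signature ->
score on both omics layers and writes plain-TSV artifacts plus a provenance
record (package version, seed, resolved configuration) sufficient to
reproduce the run exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import OmicsMatrix, read_metadata, write_metadata
from .preprocess import DetectionLimits, filter_low_abundance, glog_transform, \
    impute_min_det
from .scoring import group_average, nes_scores, scale_per_feature
from .signatures import bundled_contamination_signatures, \
    derive_quality_signature, write_signatures
from .simulate import SimulationParams, generate_cohort
from .stability import PLASMA_LIMMA, PLASMA_MIXED, SERUM_LIMMA, SERUM_MIXED, \
    build_design, fit_linear_ebayes, fit_mixed_stability, fit_timepoint_contrast

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)}

DEFAULT_CONFIG: dict = {
    "simulate": {},             # overrides for SimulationParams fields
    "preprocess": {"min_frac": 0.66, "q": 0.01, "use_limits": True},
    "stability": {"mode": "ebayes"},          # ebayes | mixed | none
    "signature": {"k": 20},
    "score": {"n_perm": 1000, "min_overlap": 3,
              "group_by": ["matrix", "temperature", "time_h"]},
}

#: handling conditions from which quality signatures are derived
SIGNATURE_CONDITIONS = (("plasma", "4C"), ("plasma", "RT"), ("serum", "RT"))


def resolve_config(config: dict | None) -> dict:
    """Merge a partial config over the defaults, rejecting unknown keys."""
    resolved = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if config is None:
        return resolved
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for section, value in config.items():
        if not isinstance(value, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        allowed = _SIM_FIELDS if section == "simulate" else set(DEFAULT_CONFIG[section])
        bad = set(value) - allowed
        if bad:
            raise ValueError(f"unknown keys in config section {section!r}: {sorted(bad)}")
        resolved[section].update(value)
    return resolved


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    return resolve_config(raw)


def _preprocess_layer(raw: OmicsMatrix, limits: DetectionLimits | None,
                      cfg: dict) -> tuple[OmicsMatrix, pd.DataFrame]:
    filtered, report = filter_low_abundance(raw, limits, min_frac=cfg["min_frac"])
    transformed = glog_transform(filtered)
    imputed = impute_min_det(transformed, q=cfg["q"])
    return imputed, report


def run_pipeline(config: dict | None = None, seed: int = 0,
                 out_dir: str | Path = ".") -> dict[str, Path]:
    """Execute the five-stage pipeline on a simulated cohort.

    Returns a mapping from artifact name to path.  Identical config + seed
    give byte-identical artifacts.
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        paths[name] = path

    # -- simulate -----------------------------------------------------------
    params = SimulationParams(**{**cfg["simulate"], "seed": seed})
    metab_raw, prot_raw, metadata, truth = generate_cohort(params)
    save("metabolome_raw.tsv", metab_raw.to_tsv)
    save("proteome_raw.tsv", prot_raw.to_tsv)
    save("samples.tsv", lambda p: write_metadata(metadata, p))
    save("truth.json", truth.to_json)

    # -- preprocess ---------------------------------------------------------
    layers: dict[str, OmicsMatrix] = {}
    for layer, raw, truth_layer in (("metabolome", metab_raw, "metabolites"),
                                    ("proteome", prot_raw, "proteins")):
        limits = None
        if cfg["preprocess"]["use_limits"] and params.lod_quantile > 0:
            limits = DetectionLimits(truth.detection_limits(truth_layer))
        imputed, report = _preprocess_layer(raw, limits, cfg["preprocess"])
        layers[layer] = imputed
        save(f"{layer}_imputed.tsv", imputed.to_tsv)
        save(f"{layer}_filter_report.tsv",
             lambda p, r=report: r.to_csv(p, sep="\t", index=False))

    # -- stability ----------------------------------------------------------
    mode = cfg["stability"]["mode"]
    if mode not in ("ebayes", "mixed", "none"):
        raise ValueError(f"unknown stability mode {mode!r}")
    if mode != "none":
        for layer, imputed in layers.items():
            for spec_eb, spec_mx in ((PLASMA_LIMMA, PLASMA_MIXED),
                                     (SERUM_LIMMA, SERUM_MIXED)):
                if mode == "ebayes":
                    res = fit_linear_ebayes(imputed, build_design(metadata, spec_eb))
                    mtype = spec_eb.matrix_type
                else:
                    res = fit_mixed_stability(imputed, metadata, spec_mx)
                    mtype = spec_mx.matrix_type
                save(f"stability_{layer}_{mtype}.tsv", res.to_tsv)

    # -- signatures ---------------------------------------------------------
    k = cfg["signature"]["k"]
    signatures_by_layer: dict[str, list] = {}
    for layer, imputed in layers.items():
        sigs = []
        for mtype, temp in SIGNATURE_CONDITIONS:
            contrast = fit_timepoint_contrast(imputed, metadata, mtype,
                                              temperature=temp)
            label = f"{layer}_{mtype}_{temp}_8h"
            sigs.append(derive_quality_signature(contrast, label, k=k))
        if layer == "proteome":
            sigs.extend(bundled_contamination_signatures())
        signatures_by_layer[layer] = sigs
        save(f"signatures_{layer}.tsv", lambda p, s=sigs: write_signatures(s, p))

    # -- scoring ------------------------------------------------------------
    score_cfg = cfg["score"]
    for i, (layer, imputed) in enumerate(layers.items()):
        scaled = scale_per_feature(imputed)
        scores = nes_scores(scaled, signatures_by_layer[layer],
                            n_perm=score_cfg["n_perm"],
                            seed=seed + 1000 + i,
                            min_overlap=score_cfg["min_overlap"])
        save(f"scores_{layer}.tsv", scores.to_tsv)
        grouped = group_average(scores, metadata,
                                keys=tuple(score_cfg["group_by"]))
        save(f"group_nes_{layer}.tsv",
             lambda p, g=grouped: g.to_csv(p, sep="\t", index=False))

    # -- provenance ---------------------------------------------------------
    prov = {
        "package": "omiqc",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "artifacts": sorted(paths),
    }
    save("provenance.json", lambda p: Path(p).write_text(
        json.dumps(prov, indent=1, sort_keys=True, default=str)))
    return paths


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

EXPECTED_TIMES = {0.0, 2.0, 4.0, 8.0}


def validate_inputs(matrix_path: str | Path,
                    metadata_path: str | Path) -> dict:
    """Cross-check a quantitation matrix against its sample metadata.

    Returns a machine-readable report ``{"issues": [{kind, severity,
    message}, ...]}``; an empty issue list means the pair is consistent.
    """
    issues: list[dict] = []

    def add(kind: str, severity: str, message: str) -> None:
        issues.append({"kind": kind, "severity": severity, "message": message})

    df = pd.read_csv(matrix_path, sep="\t", comment="#")
    if "feature_id" not in df.columns:
        add("schema", "error", "matrix has no feature_id column")
        return {"issues": issues}
    feats = df["feature_id"]
    if feats.duplicated().any():
        dups = feats[feats.duplicated()].unique().tolist()
        add("duplicate_feature", "error", f"duplicated feature ids: {dups}")
    value_cols = [c for c in df.columns if c != "feature_id"]
    for col in value_cols:
        coerced = pd.to_numeric(df[col].replace("NA", np.nan), errors="coerce")
        raw_na = df[col].isna() | (df[col].astype(str) == "NA")
        bad = coerced.isna() & ~raw_na
        if bad.any():
            add("non_numeric_cell", "error",
                f"sample {col!r} has non-numeric values at features "
                f"{feats[bad].tolist()}")

    try:
        md = read_metadata(metadata_path)
    except Exception as exc:  # surfaced as a schema issue, not a crash
        add("metadata_schema", "error", str(exc))
        return {"issues": issues}

    matrix_samples = set(value_cols)
    meta_samples = set(md.index)
    for sid in sorted(matrix_samples - meta_samples):
        add("missing_sample_metadata", "error",
            f"sample {sid!r} is in the matrix but not in the metadata")
    for sid in sorted(meta_samples - matrix_samples):
        add("unmeasured_sample", "warning",
            f"sample {sid!r} is in the metadata but not in the matrix")

    times = set(md["time_h"])
    if not times.issubset(EXPECTED_TIMES):
        add("unusual_time_grid", "warning",
            f"time points {sorted(times - EXPECTED_TIMES)} outside the "
            f"reference grid {sorted(EXPECTED_TIMES)}")
    serum_cold = md[(md["matrix"] == "serum") & (md["temperature"] != "RT")]
    if len(serum_cold):
        add("serum_temperature", "warning",
            f"serum samples at non-RT temperature (design violation): "
            f"{serum_cold.index.tolist()}")
    return {"issues": issues}
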