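"""Feature-wise stability statistics for pre-analytical factors.

Two complementary analyses are provided:

* :func:`fit_linear_ebayes` — per-feature ordinary least squares with
  empirical-Bayes moderation of the residual variances toward a global prior
  (the moderated t / F machinery familiar from microarray-style differential
  analysis).  Used for the individual-effect test and for the late-vs-fresh
  contrasts that feed signature derivation.
* :func:`fit_mixed_stability` — per-feature linear mixed models with a random
  intercept per individual (REML), falling back to a fixed-effects ANOVA when
  the random-effect variance collapses to the boundary (singular fit).  Used
  for the time/temperature stability assessment.

Both report per-factor statistics with Benjamini-Hochberg adjusted p-values,
computed separately per factor.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

#: t-distribution df above this are treated as effectively infinite
_DF_CAP = 1e6

FIXED_TERMS = ("individual", "time", "temperature", "time:temperature")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """Model terms for one matrix type.

    Time enters as numeric hours; temperature and individual are categorical
    with reference levels 4C and the lowest individual id.  Serum designs may
    not contain temperature terms (single level by design).
    """

    matrix_type: str
    fixed: tuple[str, ...]
    random: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.matrix_type not in ("plasma", "serum"):
            raise ValueError(f"unknown matrix type {self.matrix_type!r}")
        unknown = (set(self.fixed) | set(self.random)) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        both = set(self.fixed) & set(self.random)
        if both:
            raise ValueError(f"terms cannot be both fixed and random: {sorted(both)}")
        if self.random and set(self.random) != {"individual"}:
            raise ValueError("only 'individual' may be a random term")
        if self.matrix_type == "serum" and any(
                "temperature" in t for t in self.fixed + self.random):
            raise ValueError("serum designs have a single temperature level; "
                             "temperature terms are not allowed")


#: reference designs matching the published analysis
PLASMA_LIMMA = DesignSpec("plasma", ("individual", "time", "temperature",
                                     "time:temperature"))
SERUM_LIMMA = DesignSpec("serum", ("individual", "time"))
PLASMA_MIXED = DesignSpec("plasma", ("time", "temperature", "time:temperature"),
                          ("individual",))
SERUM_MIXED = DesignSpec("serum", ("time",), ("individual",))


@dataclasses.dataclass
class Design:
    """Full-rank design matrix plus the mapping factor -> design columns."""

    X: pd.DataFrame
    factor_map: dict[str, list[str]]
    spec: DesignSpec


def build_design(metadata: pd.DataFrame, spec: DesignSpec) -> Design:
    """Encode the fixed terms of `spec` over the samples of its matrix type."""
    md = metadata[metadata["matrix"] == spec.matrix_type]
    if md.empty:
        raise ValueError(f"no {spec.matrix_type} samples in metadata")
    X = pd.DataFrame(index=md.index)
    X["intercept"] = 1.0
    factor_map: dict[str, list[str]] = {}

    if "individual" in spec.fixed:
        levels = sorted(md["individual"].unique())
        if len(levels) < 2:
            raise ValueError("factor 'individual' has a single level")
        cols = []
        for lev in levels[1:]:
            col = f"individual[{lev}]"
            X[col] = (md["individual"] == lev).astype(float)
            cols.append(col)
        factor_map["individual"] = cols

    if "time" in spec.fixed:
        X["time_h"] = md["time_h"].to_numpy(dtype=float)
        factor_map["time"] = ["time_h"]

    temp_dummies: dict[str, np.ndarray] = {}
    if "temperature" in spec.fixed or "time:temperature" in spec.fixed:
        levels = sorted(md["temperature"].unique())
        if len(levels) < 2:
            raise ValueError("factor 'temperature' has a single level")
        ref = "4C" if "4C" in levels else levels[0]
        for lev in levels:
            if lev != ref:
                temp_dummies[lev] = (md["temperature"] == lev).to_numpy(dtype=float)

    if "temperature" in spec.fixed:
        cols = []
        for lev, dummy in temp_dummies.items():
            col = f"temperature[{lev}]"
            X[col] = dummy
            cols.append(col)
        factor_map["temperature"] = cols

    if "time:temperature" in spec.fixed:
        t = md["time_h"].to_numpy(dtype=float)
        cols = []
        for lev, dummy in temp_dummies.items():
            col = f"time_h:temperature[{lev}]"
            X[col] = t * dummy
            cols.append(col)
        factor_map["time:temperature"] = cols

    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return Design(X=X, factor_map=factor_map, spec=spec)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Missing entries are excluded from m and reinserted as missing.  The
    adjusted value for the i-th order statistic is min_{j>=i} p_(j) * m / j,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        scaled = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        restored = np.empty(m)
        restored[order] = np.minimum(adj, 1.0)
        out[mask] = restored
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def fit_f_dist_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed residual variances.

    Given s2_g ~ s0^2 F(df, d0), estimates (d0, s0^2) from the mean and excess
    variance of log s2 via digamma/trigamma equations.  When the log-variances
    show no excess spread the prior df is infinite and s0^2 is the mean
    variance (variances fully shared).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return 0.0, 0.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


def moderate_variances(s2: np.ndarray, df: float,
                       prior_df: float | None = None
                       ) -> tuple[np.ndarray, float, float]:
    """Shrink per-feature variances toward the global prior.

    Returns (posterior variances, d0, s0^2); `prior_df` overrides the
    estimated d0 (0 disables moderation).
    """
    s2 = np.asarray(s2, dtype=float)
    if prior_df is None:
        d0, s02 = fit_f_dist_prior(s2, df)
    else:
        d0 = float(prior_df)
        s02 = fit_f_dist_prior(s2, df)[1] if d0 > 0 else 0.0
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StabilityResult:
    """Per-feature per-factor statistics.

    `table` columns: feature_id, factor, estimate (coefficient for 1-df
    factors, NaN for multi-df F tests), statistic, df, p, p_adj, fit_flag.
    """

    table: pd.DataFrame
    prior_df: float | None = None
    prior_var: float | None = None
    method: str = "ebayes"

    def factors(self) -> list[str]:
        return list(self.table["factor"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, method: str = "ebayes") -> "StabilityResult":
        return cls(table=pd.read_csv(path, sep="\t", na_values=["NA"]),
                   method=method)


def count_significant(result: StabilityResult, factor: str,
                      alpha: float = 0.05) -> int:
    """Number of features with adjusted p < alpha for `factor`."""
    table = result.table
    if factor not in set(table["factor"]):
        raise ValueError(f"factor {factor!r} not in result "
                         f"(has {sorted(set(table['factor']))})")
    sub = table[table["factor"] == factor]
    return int((sub["p_adj"] < alpha).sum())


# ---------------------------------------------------------------------------
# moderated linear models
# ---------------------------------------------------------------------------

def _check_matrix_for_fit(matrix, samples) -> np.ndarray:
    if matrix.stage == "raw":
        raise ValueError("model fitting expects transformed/imputed values")
    missing = [s for s in samples if s not in matrix.samples]
    if missing:
        raise ValueError(f"samples in design but not in matrix: {missing}")
    Y = matrix.data[list(samples)].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("matrix contains missing values; impute first")
    return Y


def fit_linear_ebayes(matrix, design: Design,
                      prior_df: float | None = None) -> StabilityResult:
    """Per-feature OLS with empirical-Bayes moderated statistics.

    Fits every feature against the shared design, shrinks residual variances
    toward a moment-matched global prior and reports moderated t (1-df
    factors) or moderated F (multi-df factors) with p-values on d0 + d_g
    degrees of freedom, BH-adjusted per factor.

    `prior_df` fixes the prior degrees of freedom (0 recovers ordinary
    per-feature OLS t/F statistics); None estimates it from the data.
    """
    X = design.X
    Y = _check_matrix_for_fit(matrix, X.index)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    Xv = X.to_numpy(dtype=float)
    XtX = Xv.T @ Xv
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (Xv.T @ Y.T)                      # p x G
    resid = Y.T - Xv @ coef                            # n x G
    d = n - p
    s2 = (resid ** 2).sum(axis=0) / d
    degenerate = Y.var(axis=1) <= 0

    ok = ~degenerate
    post = np.full_like(s2, np.nan)
    post[ok], d0, s02 = moderate_variances(s2[ok], d, prior_df=prior_df)
    df_total = min(d0 + d, _DF_CAP)

    col_index = {c: k for k, c in enumerate(X.columns)}
    rows = []
    for factor, cols in design.factor_map.items():
        idx = [col_index[c] for c in cols]
        k = len(idx)
        if k == 1:
            beta = coef[idx[0]]
            se = np.sqrt(post * XtX_inv[idx[0], idx[0]])
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = beta / se
            pvals = 2.0 * stats.t.sf(np.abs(stat), df_total)
            est = beta
        else:
            Vff = XtX_inv[np.ix_(idx, idx)]
            Bf = coef[idx]                              # k x G
            q = np.einsum("kg,kg->g", Bf, np.linalg.solve(Vff, Bf))
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = q / (k * post)
            pvals = stats.f.sf(stat, k, df_total)
            est = np.full(Y.shape[0], np.nan)
        stat = np.where(degenerate, np.nan, stat)
        pvals = np.where(degenerate, np.nan, pvals)
        rows.append(pd.DataFrame({
            "feature_id": matrix.features,
            "factor": factor,
            "estimate": np.where(degenerate, np.nan, est),
            "statistic": stat,
            "df": df_total,
            "p": pvals,
            "p_adj": benjamini_hochberg(pvals),
            "fit_flag": np.where(degenerate, "degenerate", "ebayes"),
        }))
    table = pd.concat(rows, ignore_index=True)
    return StabilityResult(table=table, prior_df=d0, prior_var=s02,
                           method="ebayes")


def fit_timepoint_contrast(matrix, metadata: pd.DataFrame, matrix_type: str,
                           temperature: str | None = None,
                           t_high: float = 8.0, t_low: float = 0.0,
                           prior_df: float | None = None) -> StabilityResult:
    """Moderated t contrast of the late time point against baseline.

    Restricts to samples of `matrix_type` (and `temperature`, if given) at the
    two time points, adjusts for individual, and tests the late-vs-fresh shift
    per feature.  This is the contrast from which handling-condition quality
    signatures are derived.
    """
    md = metadata[metadata["matrix"] == matrix_type]
    if temperature is not None:
        md = md[md["temperature"] == temperature]
    md = md[md["time_h"].isin([t_low, t_high])]
    if md.empty:
        raise ValueError("no samples match the requested contrast")
    if md["time_h"].nunique() < 2:
        raise ValueError(f"need samples at both t={t_low} and t={t_high}")
    X = pd.DataFrame(index=md.index)
    X["intercept"] = 1.0
    cols = []
    for lev in sorted(md["individual"].unique())[1:]:
        col = f"individual[{lev}]"
        X[col] = (md["individual"] == lev).astype(float)
        cols.append(col)
    contrast = f"time{t_high:g}_vs_{t_low:g}"
    X["late"] = (md["time_h"] == t_high).astype(float)
    design = Design(X=X, factor_map={contrast: ["late"]},
                    spec=DesignSpec(matrix_type, ("time",)))
    return fit_linear_ebayes(matrix, design, prior_df=prior_df)


# ---------------------------------------------------------------------------
# mixed models with singular-fit fallback
# ---------------------------------------------------------------------------

def _ols_factor_stats(y: np.ndarray, Xv: np.ndarray, XtX_inv: np.ndarray,
                      factor_idx: dict[str, list[int]]) -> dict[str, tuple]:
    n, p = Xv.shape
    beta = XtX_inv @ (Xv.T @ y)
    resid = y - Xv @ beta
    dfres = n - p
    s2 = float(resid @ resid) / dfres
    out = {}
    for factor, idx in factor_idx.items():
        k = len(idx)
        if s2 <= 0:
            out[factor] = (np.nan, np.nan, dfres, np.nan)
            continue
        if k == 1:
            se = np.sqrt(s2 * XtX_inv[idx[0], idx[0]])
            t = beta[idx[0]] / se
            out[factor] = (beta[idx[0]], t, dfres,
                           2.0 * stats.t.sf(abs(t), dfres))
        else:
            Vff = XtX_inv[np.ix_(idx, idx)]
            bf = beta[idx]
            F = float(bf @ np.linalg.solve(Vff, bf)) / (k * s2)
            out[factor] = (np.nan, F, dfres, float(stats.f.sf(F, k, dfres)))
    return out


def fit_mixed_stability(matrix, metadata: pd.DataFrame, spec: DesignSpec,
                        singular_tol: float = 1e-8) -> StabilityResult:
    """Per-feature random-intercept mixed models with ANOVA fallback.

    Each feature is fit by REML with the fixed terms of `spec` and a random
    intercept per individual.  A fit is deemed singular when the estimated
    random-effect variance falls below `singular_tol` times the residual
    variance or the optimizer fails; such features are refit as fixed-effects
    ANOVA (same terms minus the random effect) and flagged `anova_fallback`.
    Wald t / F statistics use residual degrees of freedom n - p; p-values are
    BH-adjusted per factor, excluding degenerate features from m.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if not spec.random:
        raise ValueError("spec must declare at least one random term")
    fixed_spec = DesignSpec(spec.matrix_type,
                            tuple(t for t in spec.fixed if t != "individual"))
    design = build_design(metadata, fixed_spec)
    X = design.X
    md = metadata.loc[X.index]
    counts = md["individual"].value_counts()
    if (counts < 2).any():
        raise ValueError("each individual needs at least 2 samples")
    Y = _check_matrix_for_fit(matrix, X.index)
    Xv = X.to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    groups = md["individual"].to_numpy()
    n, p = Xv.shape
    col_index = {c: k for k, c in enumerate(X.columns)}
    factor_idx = {f: [col_index[c] for c in cols]
                  for f, cols in design.factor_map.items()}
    dfres_mixed = n - p

    records: list[tuple] = []
    for g, fid in enumerate(matrix.features):
        y = Y[g]
        if np.ptp(y) == 0:
            for factor in factor_idx:
                records.append((fid, factor, np.nan, np.nan, np.nan, np.nan,
                                "degenerate"))
            continue
        singular = False
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = MixedLM(y, Xv, groups=groups).fit(reml=True)
                re_var = float(np.asarray(res.cov_re)[0, 0])
                if (not res.converged) or not np.isfinite(re_var) \
                        or re_var < singular_tol * res.scale:
                    singular = True
            except Exception:
                singular = True
        if singular:
            st = _ols_factor_stats(y, Xv, XtX_inv, factor_idx)
            for factor, (est, stat, dfr, pv) in st.items():
                records.append((fid, factor, est, stat, dfr, pv,
                                "anova_fallback"))
        else:
            fe = np.asarray(res.fe_params, dtype=float)
            cov = np.asarray(res.cov_params())[:p, :p]
            for factor, idx in factor_idx.items():
                k = len(idx)
                if k == 1:
                    se = np.sqrt(cov[idx[0], idx[0]])
                    t = fe[idx[0]] / se
                    records.append((fid, factor, fe[idx[0]], t, dfres_mixed,
                                    2.0 * stats.t.sf(abs(t), dfres_mixed),
                                    "mixed"))
                else:
                    bf = fe[idx]
                    Vff = cov[np.ix_(idx, idx)]
                    F = float(bf @ np.linalg.solve(Vff, bf)) / k
                    records.append((fid, factor, np.nan, F, dfres_mixed,
                                    float(stats.f.sf(F, k, dfres_mixed)),
                                    "mixed"))
    table = pd.DataFrame(records, columns=["feature_id", "factor", "estimate",
                                           "statistic", "df", "p", "fit_flag"])
    table["p_adj"] = np.nan
    for factor in factor_idx:
        sel = table["factor"] == factor
        table.loc[sel, "p_adj"] = benjamini_hochberg(table.loc[sel, "p"])
    table = table[["feature_id", "factor", "estimate", "statistic", "df",
                   "p", "p_adj", "fit_flag"]]
    return StabilityResult(table=table, method="mixed")
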