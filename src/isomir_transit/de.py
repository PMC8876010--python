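"""Normalization and negative-binomial Wald differential expression.

Implements the DESeq-style chain: median-of-ratios size factors, a
log-based variance-stabilizing transform, per-feature NB dispersion
(method of moments shrunk toward a fitted mean-dispersion trend), NB
log-link GLMs with technical batch and centered age as covariates, Wald
tests on group contrasts against a standard-normal reference,
Benjamini-Hochberg adjustment, DE calling at P_FDR < 0.01 and |log2FC| >
0.5, and the three-way set logic comparing both colon conditions (AP,
CRC) against healthy controls.

GLM fitting goes through statsmodels (``sm.GLM`` with the
NegativeBinomial family at fixed per-feature alpha and a log
size-factor offset); the contrast machinery, normalization and
dispersion estimation are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

LN2 = np.log(2.0)


# ---- normalization --------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over features i (with positive counts in every sample)
    of count_ij / geometric-mean_i.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "consider a pseudo-reference (e.g. add a pseudocount) before estimating size factors"
        )
    log_geo = np.log(arr[positive]).mean(axis=1)
    ratios = np.log(arr[positive]) - log_geo[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def vst(counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0) -> pd.DataFrame:
    """Variance-flattening transform: log2(count / s_j + pseudocount)."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    normed = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    return pd.DataFrame(np.log2(normed + pseudocount), index=counts.index, columns=counts.columns)


def estimate_dispersion(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """Per-feature NB dispersion alpha (var = mu + alpha mu^2).

    Method-of-moments on normalized counts, shrunk 50/50 toward the
    trend alpha(mu) = a1/mu + a0 fitted by least squares across
    features; floored at 1e-8.
    """
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation requires at least 2 samples")
    normed = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    mu = normed.mean(axis=1)
    var = normed.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (var - mu) / mu**2, 0.0)
    raw = np.maximum(raw, 0.0)

    ok = mu > 0
    if ok.sum() >= 2:
        X = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a1, a0 = coef
        trend = np.zeros_like(mu)
        trend[ok] = np.maximum(a1 / mu[ok] + a0, 0.0)
    else:
        trend = raw
    alpha = np.maximum(0.5 * raw + 0.5 * trend, 1e-8)
    return pd.Series(alpha, index=counts.index, name="dispersion")


# ---- NB GLM Wald test -----------------------------------------------------

@dataclass
class DEResult:
    feature_id: str
    baseMean: float
    log2FC: float
    se: float  # log2 scale
    wald_z: float
    p: float
    p_adj: float = np.nan
    contrast: tuple[str, str] = ("", "")


def _design_matrix(
    metadata: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Intercept + group dummies (first sorted level as reference) + covariates.

    Returns (X, column names, map group level -> coefficient column or -1
    for the reference level).
    """
    levels = sorted(metadata["group"].unique())
    cols = [np.ones(len(metadata))]
    names = ["intercept"]
    group_col: dict[str, int] = {levels[0]: -1}
    for lev in levels[1:]:
        group_col[lev] = len(names)
        cols.append((metadata["group"] == lev).to_numpy(float))
        names.append(f"group_{lev}")
    for cov in covariates:
        if cov not in metadata.columns:
            continue
        vals = metadata[cov]
        if vals.dtype.kind in "OUSb" or cov == "batch":
            for lev in sorted(pd.unique(vals))[1:]:
                cols.append((vals == lev).to_numpy(float))
                names.append(f"{cov}_{lev}")
        else:
            centered = vals.to_numpy(float) - vals.to_numpy(float).mean()
            cols.append(centered)
            names.append(f"{cov}_centered")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    return X, names, group_col


def nb_wald_test(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: tuple[str, ...] = ("batch", "age"),
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB GLM Wald test for ``contrast`` = (case, reference).

    Fits log-link NB GLMs with log size-factor offsets and fixed
    per-feature dispersion on all samples; the Wald statistic tests the
    difference of the two group coefficients.  Returns a DataFrame with
    baseMean, log2FC, se (log2 scale), wald_z, p and BH-adjusted p_adj.
    Features whose fit fails get p = NaN and are excluded from the
    adjustment.
    """
    case, ref = contrast
    present = set(metadata["group"])
    if case not in present or ref not in present:
        raise ValueError(f"contrast groups {contrast} not present in metadata")
    metadata = metadata.loc[counts.columns]
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, factors)
    X, names, group_col = _design_matrix(metadata, covariates)
    offset = np.log(factors.reindex(counts.columns).to_numpy(float))

    cvec = np.zeros(X.shape[1])
    if group_col[case] >= 0:
        cvec[group_col[case]] = 1.0
    if group_col[ref] >= 0:
        cvec[group_col[ref]] = -1.0

    base_mean = (counts.to_numpy(float) / np.exp(offset)[None, :]).mean(axis=1)
    rows = []
    for i, fid in enumerate(counts.index):
        y = counts.iloc[i].to_numpy(float)
        alpha = max(float(dispersions.iloc[i]), 1e-8)
        lfc = se2 = z = p = np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
                )
                fit = model.fit(maxiter=100, tol=1e-8)
            beta = fit.params
            cov = fit.cov_params()
            est = float(cvec @ beta)
            var = float(cvec @ cov @ cvec)
            if np.isfinite(est) and np.isfinite(var) and var >= 0:
                se_ln = np.sqrt(var)
                lfc = est / LN2
                se2 = se_ln / LN2
                if se_ln > 0:
                    z = est / se_ln
                    p = 2.0 * stats.norm.sf(abs(z))
                else:
                    z = 0.0
                    p = 1.0
        except Exception:
            pass
        rows.append((fid, base_mean[i], lfc, se2, z, p))
    out = pd.DataFrame(
        rows, columns=["feature_id", "baseMean", "log2FC", "se", "wald_z", "p"]
    ).set_index("feature_id")
    out["p_adj"] = bh_adjust(out["p"])
    out["contrast"] = f"{case}_vs_{ref}"
    return out


def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs excluded from m."""
    arr = np.asarray(p, dtype=float)
    if np.any(((arr < 0) | (arr > 1)) & ~np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(arr, np.nan)
    mask = ~np.isnan(arr)
    m = int(mask.sum())
    if m:
        vals = arr[mask]
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        adj[mask] = out
    if isinstance(p, pd.Series):
        return pd.Series(adj, index=p.index, name="p_adj")
    return adj


# ---- DE calling and three-way set logic -----------------------------------

def call_de(results: pd.DataFrame, alpha: float = 0.01, lfc: float = 0.5) -> tuple[set, set]:
    """(up, down) feature sets at p_adj < alpha and |log2FC| > lfc (strict)."""
    sig = results["p_adj"] < alpha
    up = set(results.index[sig & (results["log2FC"] > lfc)])
    down = set(results.index[sig & (results["log2FC"] < -lfc)])
    return up, down


@dataclass
class ThreeWaySummary:
    """Set regions of the three-way comparison of AP and CRC against HC."""

    shared_up: set = field(default_factory=set)
    shared_down: set = field(default_factory=set)
    unique_up: dict[str, set] = field(default_factory=dict)
    unique_down: dict[str, set] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {"shared_up": len(self.shared_up), "shared_down": len(self.shared_down)}
        for g, s in self.unique_up.items():
            out[f"unique_up_{g}"] = len(s)
        for g, s in self.unique_down.items():
            out[f"unique_down_{g}"] = len(s)
        return out


def three_way_summary(
    de_sets: dict[tuple[str, str], tuple[set, set]]
) -> ThreeWaySummary:
    """Set algebra over the (CRC vs HC), (AP vs HC), (CRC vs AP) contrasts.

    ``de_sets`` maps each contrast to its (up, down) sets.  Shared
    regions are intersections of the two against-HC contrasts; unique
    regions are their set differences.
    """
    required = [("CRC", "HC"), ("AP", "HC"), ("CRC", "AP")]
    for key in required:
        if key not in de_sets:
            raise ValueError(f"missing contrast {key}")
    up_crc, down_crc = de_sets[("CRC", "HC")]
    up_ap, down_ap = de_sets[("AP", "HC")]
    return ThreeWaySummary(
        shared_up=up_crc & up_ap,
        shared_down=down_crc & down_ap,
        unique_up={"CRC": up_crc - up_ap, "AP": up_ap - up_crc},
        unique_down={"CRC": down_crc - down_ap, "AP": down_ap - down_crc},
    )
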