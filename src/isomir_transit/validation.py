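"""RT-qPCR ΔCt statistics and cohort contingency tests.

ΔCt = mean(target wells) - mean over normalizers of mean(normalizer
wells), duplicates averaged before subtraction; lower ΔCt means higher
expression, so expression is reported as -ΔCt.  Group comparisons use
the two-sided Mann-Whitney U test (exact enumeration when both groups
have at most 8 samples, else the tie-corrected normal approximation)
with BH adjustment across targets; a target is called at adjusted p <
0.05 and |log2FC| > 1.  Cohort tables are tested with Pearson's
chi-squared (no continuity correction) and quantitative variables with
the tie-corrected Kruskal-Wallis test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust


@dataclass
class DeltaCtRecord:
    sample_id: str
    target_id: str
    delta_ct: float

    @property
    def expression_proxy(self) -> float:
        return -self.delta_ct


def delta_ct(
    ct_table: pd.DataFrame,
    target_id: str,
    normalizer_ids: tuple[str, ...],
) -> pd.DataFrame:
    """Per-sample ΔCt for ``target_id`` against the mean of the normalizers.

    ``ct_table`` is tidy: sample_id, assay_id, well, ct.  Wells of each
    assay are averaged first; with several normalizers their per-sample
    means are arithmetically averaged.  Samples missing the target or
    any normalizer assay are skipped with a warning.
    """
    means = ct_table.groupby(["sample_id", "assay_id"])["ct"].mean().unstack()
    needed = [target_id, *normalizer_ids]
    missing_cols = [a for a in needed if a not in means.columns]
    if missing_cols:
        raise KeyError(f"assays absent from Ct table: {missing_cols}")
    rows = []
    for sample_id, row in means.iterrows():
        if row[needed].isna().any():
            warnings.warn(f"sample {sample_id}: missing assay, record skipped")
            continue
        norm = float(np.mean([row[a] for a in normalizer_ids]))
        dct = float(row[target_id]) - norm
        rows.append((sample_id, target_id, dct, -dct))
    return pd.DataFrame(
        rows, columns=["sample_id", "target_id", "delta_ct", "expression_proxy"]
    ).set_index("sample_id")


def mwu_group_test(
    records: pd.DataFrame,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
    exact_max_n: int = 8,
) -> dict:
    """Two-sided Mann-Whitney U on ΔCt for the contrast ``group_a vs group_b``.

    log2FC = mean ΔCt(B) - mean ΔCt(A): ΔCt is inverse to expression, so
    a positive value means higher expression in group A (the case).
    Exact enumeration when both n <= ``exact_max_n`` and no ties span the
    groups, otherwise the tie-corrected normal approximation.
    """
    groups = metadata.loc[records.index, "group"]
    a = records.loc[groups == group_a, "delta_ct"].to_numpy(float)
    b = records.loc[groups == group_b, "delta_ct"].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    log2fc = float(b.mean() - a.mean())
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "log2FC": log2fc,
        "method": method,
        "n_a": len(a),
        "n_b": len(b),
    }


def mwu_panel(
    ct_table: pd.DataFrame,
    metadata: pd.DataFrame,
    targets: list[str],
    normalizer_ids: tuple[str, ...],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """ΔCt tests for several targets, BH-adjusted across targets.

    A target is called differentially expressed iff adjusted p < alpha
    and |log2FC| > lfc (both strict).
    """
    rows = []
    for target in targets:
        rec = delta_ct(ct_table, target, normalizer_ids)
        res = mwu_group_test(rec, metadata, group_a, group_b)
        rows.append((target, res["U"], res["p"], res["log2FC"]))
    out = pd.DataFrame(rows, columns=["target_id", "U", "p", "log2FC"]).set_index("target_id")
    out["p_adj"] = bh_adjust(out["p"])
    out["called"] = (out["p_adj"] < alpha) & (out["log2FC"].abs() > lfc)
    return out


# ---- contingency / cohort tests -------------------------------------------

def pearson_chi_squared(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared without continuity correction: (chi2, df, p).

    Rows/columns with zero margins are dropped with a warning.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("contingency table total must be positive")
    row_ok = arr.sum(axis=1) > 0
    col_ok = arr.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        arr = arr[row_ok][:, col_ok]
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("table degenerate after dropping zero margins")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis: (H, df, p) with chi-squared reference."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    per_group = [values[groups == g] for g in levels]
    if np.all(values == values[0]):
        return 0.0, len(levels) - 1, 1.0
    H, p = stats.kruskal(*per_group)
    return float(H), len(levels) - 1, float(p)


def cohort_report(fixture: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Chi-squared tests over the printed cohort tables.

    One row per categorical table: (variable, statistic, df, p).
    """
    rows = []
    for name, table in fixture.items():
        chi2, df, p = pearson_chi_squared(table)
        rows.append((name, chi2, df, p))
    return pd.DataFrame(rows, columns=["variable", "chi2", "df", "p"]).set_index("variable")
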