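"""Global structure and transition statistics across HC -> AP -> CRC.

Classical (Torgerson) MDS on Euclidean distances between VST expression
profiles, per-feature Spearman correlation with the ordinal disease
stage (HC=0, AP=1, CRC=2) with the published |rho| tiers, and
tie-corrected Kruskal-Wallis tests on positional isomiR modification
abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .de import bh_adjust

STAGE_ENCODING = {"HC": 0, "AP": 1, "CRC": 2}

TIER_HIGH = 0.7
TIER_MODERATE = 0.5


def encode_stages(groups: pd.Series) -> pd.Series:
    """Map group labels onto the ordinal stage scale HC=0, AP=1, CRC=2."""
    unknown = set(groups.unique()) - set(STAGE_ENCODING)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return groups.map(STAGE_ENCODING)


def mds(matrix: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Classical MDS of samples (columns) on Euclidean distances.

    Double-centers the squared distance matrix, eigendecomposes, and
    returns coordinates ordered by eigenvalue.  Per axis the sign is
    fixed so the largest-magnitude coordinate is positive.
    """
    n = matrix.shape[1]
    if n < n_dims + 1:
        raise ValueError(f"need at least {n_dims + 1} samples for {n_dims} dimensions")
    d2 = squareform(pdist(matrix.to_numpy(float).T, metric="sqeuclidean"))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    # numerically-zero eigenvalues carry arbitrary eigenvectors; zero them out
    eigval[eigval < 1e-12 * max(eigval.max(), 1.0)] = 0.0
    order = np.argsort(eigval)[::-1][:n_dims]
    coords = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords, index=matrix.columns, columns=[f"MDS{j + 1}" for j in range(n_dims)]
    )


def spearman_screen(matrix: pd.DataFrame, stages: pd.Series) -> pd.DataFrame:
    """Per-feature Spearman correlation with the ordinal stage.

    Tiers follow the published intervals: high when |rho| > 0.7,
    moderate when 0.5 < |rho| <= 0.7, none otherwise (the boundary 0.7
    itself is moderate).  Constant features get rho = NaN, tier none.
    """
    stages = stages.reindex(matrix.columns)
    if stages.nunique() < 2:
        raise ValueError("need at least two distinct stages")
    svals = stages.to_numpy(float)
    rows = []
    for fid, values in matrix.iterrows():
        x = values.to_numpy(float)
        if np.all(x == x[0]):
            rows.append((fid, np.nan, "none", "none"))
            continue
        rho = stats.spearmanr(x, svals).statistic
        if np.isnan(rho):
            tier, direction = "none", "none"
        elif abs(rho) > TIER_HIGH:
            tier, direction = "high", "increasing" if rho > 0 else "decreasing"
        elif abs(rho) > TIER_MODERATE:
            tier, direction = "moderate", "increasing" if rho > 0 else "decreasing"
        else:
            tier, direction = "none", "increasing" if rho > 0 else "decreasing"
        rows.append((fid, rho, tier, direction))
    return pd.DataFrame(rows, columns=["feature_id", "rho", "tier", "direction"]).set_index(
        "feature_id"
    )


def kruskal_positional(profiles: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Kruskal-Wallis test per (modification type, signed position).

    ``profiles`` is the tidy frame from ``modification_profiles``;
    samples missing an entry for a (type, position) combination
    contribute abundance 0.  Reports tie-corrected H, the chi-squared
    p (df = groups - 1), BH-adjusted p across all positional tests, and
    per-group medians to expose monotone trends.
    """
    group_levels = sorted(groups.unique(), key=lambda g: STAGE_ENCODING.get(g, 99))
    if len(group_levels) < 2:
        raise ValueError("need at least two groups")
    samples = groups.index
    wide = profiles.pivot_table(
        index=["mod_type", "position"], columns="sample", values="abundance", fill_value=0.0
    ).reindex(columns=samples, fill_value=0.0)
    rows = []
    for (mod, pos), values in wide.iterrows():
        per_group = [values[groups == g].to_numpy(float) for g in group_levels]
        if any(len(v) < 2 for v in per_group):
            raise ValueError("each group needs at least 2 samples")
        pooled = np.concatenate(per_group)
        if np.all(pooled == pooled[0]):
            H, p = 0.0, 1.0
        else:
            H, p = stats.kruskal(*per_group)
        medians = [float(np.median(v)) for v in per_group]
        rows.append((mod, pos, H, p, *medians))
    out = pd.DataFrame(
        rows,
        columns=["mod_type", "position", "H", "p"] + [f"median_{g}" for g in group_levels],
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
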