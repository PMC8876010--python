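"""Seed-site scanning and pathway overrepresentation.

The canonical 8-mer target site is perfect Watson-Crick complementarity
to miRNA positions 2-8 (the seed) followed by an adenosine opposite
position 1; in 3'UTR coordinates the site reads (5'->3') as the reverse
complement of the seed plus a literal 'A'.  Overrepresentation of a
target set in pathway gene sets uses the one-sided Fisher's exact
(hypergeometric upper-tail) test with BH adjustment and the enrichment
score E = (k/n)/(K/N); a pathway is significant at adjusted p < 0.05
and E > 1 (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .de import bh_adjust
from .reference import revcomp


@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    site_type: str
    mature_id: str


def seed_of(mature: str) -> str:
    """The 7-nt seed: miRNA positions 2-8 (1-based)."""
    if len(mature) < 8:
        raise ValueError("mature sequence must be at least 8 nt")
    return mature[1:8]


def site_motif(mature: str) -> str:
    """The 8-mer site motif on the 3'UTR: revcomp(seed) + 'A'."""
    return revcomp(seed_of(mature)) + "A"


def find_8mer_sites(
    utr: str, mature: str, utr_id: str = "", mature_id: str = ""
) -> list[SeedSite]:
    """All (possibly overlapping) 8-mer sites, 1-based inclusive coordinates."""
    motif = site_motif(mature)
    sites = []
    start = utr.find(motif)
    while start != -1:
        sites.append(SeedSite(utr_id, start + 1, start + 8, "8mer", mature_id))
        start = utr.find(motif, start + 1)
    return sites


def scan_utrs(utrs: dict[str, str], mature: str, mature_id: str = "") -> pd.DataFrame:
    rows = []
    for utr_id, seq in utrs.items():
        for s in find_8mer_sites(seq, mature, utr_id, mature_id):
            rows.append((s.utr_id, s.start, s.end, s.site_type, s.mature_id))
    return pd.DataFrame(rows, columns=["utr_id", "start", "end", "site_type", "mature_id"])


def fisher_ora(
    target_set: set[str],
    pathway_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pathway overrepresentation of ``target_set`` within ``universe``.

    Per pathway: k = targets in pathway, K = pathway size, n = target-set
    size, N = universe size; p = P(X >= k) under Hypergeometric(N, K, n);
    E = (k/n)/(K/N); BH across pathways; significant iff p_adj < alpha
    and E > 1.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not target_set <= universe:
        raise ValueError("target set must be a subset of the universe")
    N = len(universe)
    n = len(target_set)
    rows = []
    for pid, genes in pathway_sets.items():
        if not genes <= universe:
            raise ValueError(f"pathway {pid} not a subset of the universe")
        K = len(genes)
        k = len(target_set & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        E = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        rows.append((pid, k, K, n, N, E, p))
    out = pd.DataFrame(
        rows, columns=["pathway_id", "k", "K", "n", "N", "E", "p"]
    ).set_index("pathway_id")
    out["p_adj"] = bh_adjust(out["p"])
    out["significant"] = (out["p_adj"] < alpha) & (out["E"] > 1.0)
    return out
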