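"""End-to-end driver: simulated reads -> isomiR counts -> DE -> screening.

Chains the individual stages exactly as a real study run would: FASTQ
preprocessing (adapter/quality/length), isomiR profiling, miRNA-level
NB Wald differential expression for the three contrasts with batch and
centered-age covariates, the three-way set summary, and the ordinal
Spearman screen on VST values.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import de, preprocess, profiler, transition
from .reference import HairpinReference
from .simulate import SimulationDesign, generate_reference, simulate_counts, simulate_isomir_reads

CONTRASTS = [("CRC", "HC"), ("AP", "HC"), ("CRC", "AP")]


@dataclass
class PipelineResult:
    reference: HairpinReference
    true_counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    profiling: profiler.ProfilingResult
    de_tables: dict[tuple[str, str], pd.DataFrame]
    de_sets: dict[tuple[str, str], tuple[set, set]]
    three_way: de.ThreeWaySummary
    vst_matrix: pd.DataFrame
    screen: pd.DataFrame


def preprocess_samples(
    reads_by_sample: dict[str, list[tuple[str, str, str]]],
    adapter: str,
    min_len: int = 18,
    q_threshold: int = 20,
) -> dict[str, list[str]]:
    """Adapter/quality/length preprocessing; returns kept sequences per sample."""
    out: dict[str, list[str]] = {}
    for sample, reads in reads_by_sample.items():
        records = (preprocess.ReadRecord(rid, seq, qual) for rid, seq, qual in reads)
        kept, _ = preprocess.preprocess_reads(records, adapter, min_len, q_threshold)
        out[sample] = [r.sequence for r in kept]
    return out


def analyze_counts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("batch", "age"),
    alpha: float = 0.01,
    lfc: float = 0.5,
) -> tuple[dict, dict, de.ThreeWaySummary, pd.DataFrame, pd.DataFrame]:
    """DE for all three contrasts, three-way summary, VST and Spearman screen."""
    factors = de.size_factors(counts)
    dispersions = de.estimate_dispersion(counts, factors)
    de_tables = {
        contrast: de.nb_wald_test(counts, metadata, contrast, covariates, factors, dispersions)
        for contrast in CONTRASTS
    }
    de_sets = {c: de.call_de(t, alpha=alpha, lfc=lfc) for c, t in de_tables.items()}
    summary = de.three_way_summary(de_sets)
    vst_matrix = de.vst(counts, factors)
    stages = transition.encode_stages(metadata.loc[counts.columns, "group"])
    screen = transition.spearman_screen(vst_matrix, stages)
    return de_tables, de_sets, summary, vst_matrix, screen


def run_pipeline(design: SimulationDesign) -> PipelineResult:
    """Simulate a full cohort and push it through every analysis stage."""
    reference = generate_reference(design.n_hairpins, design.seed)
    true_counts, metadata, truth = simulate_counts(design, reference)
    raw_reads, _ = simulate_isomir_reads(true_counts, reference, design)
    clean = preprocess_samples(raw_reads, design.adapter)
    profiling = profiler.profile_reads(clean, reference)
    counts = profiling.mirna_counts.reindex(columns=metadata.index).fillna(0).astype(int)
    de_tables, de_sets, summary, vst_matrix, screen = analyze_counts(counts, metadata)
    return PipelineResult(
        reference=reference,
        true_counts=true_counts,
        metadata=metadata,
        truth=truth,
        profiling=profiling,
        de_tables=de_tables,
        de_sets=de_sets,
        three_way=summary,
        vst_matrix=vst_matrix,
        screen=screen,
    )
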