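"""Synthetic study generator for the healthy -> adenoma -> carcinoma design.

Emulates a three-group (HC, AP, CRC) small RNA-seq cohort: random
hairpin references with unique mature annotations, stage-monotone
negative-binomial count truth with batch and age covariates, per-read
isomiR structure (5'/3' end variation, non-templated A/T tails, a fixed
"real" substitution per miRNA, uniform sequencing error, a 3' adapter),
and duplicate-well qPCR Ct tables.  All randomness flows from a single
integer seed; identical designs produce byte-identical outputs.

Stages are encoded ordinally HC=0, AP=1, CRC=2 and a planted miRNA's
expected log2 expression moves by ``lfc_per_step`` per stage, which is
the signal every downstream recovery test chases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiler import IsomiRCall
from .reference import HairpinReference, MatureAnnotation

GROUPS = ("HC", "AP", "CRC")
STAGE = {"HC": 0, "AP": 1, "CRC": 2}
BASES = "ACGT"

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_ISOMIR_PROFILE = {
    "canonical": 0.55,
    "trim5": 0.08,
    "trim3": 0.15,
    "ext3": 0.07,
    "add3": 0.10,
    "substitution": 0.05,
}


@dataclass
class SimulationDesign:
    """Parameters of one synthetic cohort.

    ``isomir_profile`` gives the per-read probabilities of emitting a
    canonical read, a 5' trim (+1/+2), a 3' trim (-1/-2), a templated 3'
    extension (+1/+2), a non-templated 3' A/T tail (1-3 nt), or the
    miRNA's fixed internal substitution.  ``nb_dispersion`` is the NB
    alpha (var = mu + alpha*mu^2); 0 gives Poisson counts.
    """

    n_hairpins: int = 50
    n_samples_per_group: int = 30
    frac_monotone: float = 0.1
    lfc_per_step: float = 1.0
    nb_dispersion: float = 0.1
    batch_levels: int = 2
    batch_sd: float = 0.3
    age_slope: float = 0.01
    isomir_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_PROFILE)
    )
    seq_error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    baseline_log2_range: tuple[float, float] = (4.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hairpins < 1:
            raise ValueError("n_hairpins must be >= 1")
        if not 0 <= self.frac_monotone <= 1:
            raise ValueError("frac_monotone must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        probs = list(self.isomir_profile.values())
        if any(not 0 <= p <= 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ValueError("isomir_profile probabilities must lie in [0,1] and sum to 1")
        unknown = set(self.isomir_profile) - set(DEFAULT_ISOMIR_PROFILE)
        if unknown:
            raise ValueError(f"unknown isomiR classes: {sorted(unknown)}")


# ---- reference ------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def generate_reference(n_hairpins: int, seed: int, max_retries: int = 1000) -> HairpinReference:
    """Random hairpins (60-90 nt) each carrying one mature (20-24 nt).

    Matures keep >= 5 nt of precursor flanking both ends, are pairwise
    distinct, occur exactly once in their own hairpin and never inside
    any other hairpin, so canonical reads map uniquely.
    """
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    rng = np.random.default_rng(seed)
    hairpins: dict[str, str] = {}
    matures: list[MatureAnnotation] = []
    mature_seqs: list[str] = []
    attempts = 0
    while len(hairpins) < n_hairpins:
        attempts += 1
        if attempts > max_retries * n_hairpins:
            raise RuntimeError("reference rejection sampling exceeded retry budget")
        length = int(rng.integers(60, 91))
        mlen = int(rng.integers(20, 25))
        seq = _random_seq(rng, length)
        start = int(rng.integers(5, length - mlen - 4))
        mature = seq[start:start + mlen]
        if seq.count(mature) != 1:
            continue
        if any(mature in hp for hp in hairpins.values()):
            continue
        if any(m in seq for m in mature_seqs):
            continue
        if mature in mature_seqs:
            continue
        i = len(hairpins) + 1
        hid = f"syn-mir-{i}"
        hairpins[hid] = seq
        matures.append(MatureAnnotation(hid, f"syn-miR-{i}", start, start + mlen))
        mature_seqs.append(mature)
    return HairpinReference(hairpins=hairpins, matures=matures)


# ---- counts ---------------------------------------------------------------

def simulate_counts(
    design: SimulationDesign, reference: HairpinReference | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(counts, metadata, truth) for the three-group design.

    Counts are NB with log2 mean = baseline + direction*lfc_per_step*stage
    (planted features only) + batch effect + age_slope*(age - mean age).
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    if reference is None:
        reference = generate_reference(design.n_hairpins, design.seed)
    features = reference.mature_ids
    n_feat = len(features)

    n = design.n_samples_per_group
    sample_ids, groups = [], []
    for g in GROUPS:
        for i in range(n):
            sample_ids.append(f"{g}_{i + 1:02d}")
            groups.append(g)
    stage = np.array([STAGE[g] for g in groups], dtype=float)
    ages = rng.integers(45, 81, size=len(sample_ids)).astype(float)
    batches = rng.integers(0, design.batch_levels, size=len(sample_ids))
    batch_eff = rng.normal(0.0, design.batch_sd, size=design.batch_levels)
    batch_eff -= batch_eff.mean()

    n_mono = int(round(design.frac_monotone * n_feat))
    mono_idx = rng.choice(n_feat, size=n_mono, replace=False)
    is_monotone = np.zeros(n_feat, dtype=bool)
    is_monotone[mono_idx] = True
    direction = np.where(rng.random(n_feat) < 0.5, 1, -1)
    direction[~is_monotone] = 1
    lo, hi = design.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=n_feat)

    log2_mu = (
        baseline[:, None]
        + (is_monotone * direction * design.lfc_per_step)[:, None] * stage[None, :]
        + batch_eff[batches][None, :]
        + design.age_slope * (ages - ages.mean())[None, :]
    )
    mu = np.power(2.0, log2_mu)
    if design.nb_dispersion > 0:
        shape = 1.0 / design.nb_dispersion
        lam = rng.gamma(shape, mu * design.nb_dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=features, columns=sample_ids)
    counts_df.index.name = "feature_id"
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "age": ages.astype(int), "batch": batches}
    ).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "feature_id": features,
            "is_monotone": is_monotone,
            "direction": direction,
            "true_lfc_per_step": np.where(is_monotone, direction * design.lfc_per_step, 0.0),
        }
    ).set_index("feature_id")
    return counts_df, metadata, truth


# ---- reads ----------------------------------------------------------------

def _planted_substitution(rng: np.random.Generator, mature: str) -> tuple[int, str, str]:
    """Fixed internal substitution site for one miRNA (0-based read index)."""
    pos = int(rng.integers(3, len(mature) - 3))
    ref = mature[pos]
    alt = rng.choice([b for b in BASES if b != ref])
    return pos, ref, str(alt)


def _nontemplated_tail(rng: np.random.Generator, continuation: str, length: int) -> str:
    """A/T tail whose every base differs from the templated continuation."""
    tail = []
    for i in range(length):
        templ = continuation[i] if i < len(continuation) else None
        options = [b for b in "AT" if b != templ]
        tail.append(str(rng.choice(options)))
    return "".join(tail)


def simulate_isomir_reads(
    counts: pd.DataFrame,
    reference: HairpinReference,
    design: SimulationDesign,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Emit per-sample FASTQ reads realizing ``counts`` with isomiR structure.

    Returns (reads_by_sample, truth) where reads are (id, sequence,
    quality) tuples and truth records every read's planted IsomiRCall
    fields.  When ``out_dir`` is given, one ``<sample>.fastq`` per sample
    is also written.
    """
    if set(counts.index) != set(reference.mature_ids):
        raise ValueError("count-matrix features do not match mature annotations")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    profile_keys = list(DEFAULT_ISOMIR_PROFILE)
    probs = np.array([design.isomir_profile.get(k, 0.0) for k in profile_keys])

    sub_site = {
        ann.mature_id: _planted_substitution(rng, reference.mature_sequence(ann.mature_id))
        for ann in reference.matures
    }

    reads_by_sample: dict[str, list[tuple[str, str, str]]] = {}
    truth_rows = []
    L = design.read_length
    hi_q = "I"  # Q40
    lo_q = "#"  # Q2

    for sample in counts.columns:
        reads: list[tuple[str, str, str]] = []
        ctr = itertools.count(1)
        for ann in reference.matures:
            mid = ann.mature_id
            n_reads = int(counts.at[mid, sample])
            if n_reads == 0:
                continue
            hp = reference.hairpins[ann.hairpin_id]
            mstart, mend = ann.start, ann.end
            type_counts = rng.multinomial(n_reads, probs)
            for cls, n_cls in zip(profile_keys, type_counts):
                for _ in range(int(n_cls)):
                    off5 = off3 = 0
                    tail = ""
                    subs: tuple = ()
                    if cls == "trim5":
                        off5 = int(rng.integers(1, 3))
                    elif cls == "trim3":
                        off3 = -int(rng.integers(1, 3))
                    elif cls == "ext3":
                        off3 = int(rng.integers(1, 3))
                    elif cls == "add3":
                        tail = _nontemplated_tail(rng, hp[mend:], int(rng.integers(1, 4)))
                    elif cls == "substitution":
                        pos0, ref, alt = sub_site[mid]
                        subs = ((pos0 + 1, ref, alt),)
                    insert = hp[mstart + off5:mend + off3]
                    if subs:
                        pos0 = subs[0][0] - 1
                        insert = insert[:pos0] + subs[0][2] + insert[pos0 + 1:]
                    insert = insert + tail
                    # uniform sequencing errors on the insert
                    if design.seq_error_rate > 0:
                        n_err = rng.binomial(len(insert), design.seq_error_rate)
                        if n_err:
                            chars = list(insert)
                            for p in rng.choice(len(chars), size=n_err, replace=False):
                                chars[p] = str(rng.choice([b for b in BASES if b != chars[p]]))
                            insert = "".join(chars)
                    seq = (insert + design.adapter)[:L].ljust(L, "A")
                    qual = hi_q * L
                    if rng.random() < 0.10:  # occasional low-quality 3' tail
                        n_low = int(rng.integers(1, 5))
                        qual = qual[:L - n_low] + lo_q * n_low
                    rid = f"{sample}:{next(ctr)}:{mid}"
                    reads.append((rid, seq, qual))
                    truth_rows.append(
                        (sample, rid, mid, off5, off3, tail,
                         ";".join(f"{p}{r}>{a}" for p, r, a in subs))
                    )
        reads_by_sample[sample] = reads
        if out_dir is not None:
            path = Path(out_dir) / f"{sample}.fastq"
            with open(path, "w") as fh:
                for rid, seq, qual in reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "read_id", "mature_id", "offset5", "offset3", "tail", "substitutions"],
    )
    return reads_by_sample, truth


def truth_to_calls(truth: pd.DataFrame) -> dict[str, list[IsomiRCall]]:
    """Collapse the per-read truth table into per-sample IsomiRCall lists."""
    out: dict[str, list[IsomiRCall]] = {}
    grouped = truth.groupby(
        ["sample", "mature_id", "offset5", "offset3", "tail", "substitutions"], sort=False
    ).size()
    for (sample, mid, o5, o3, tail, subs_str), n in grouped.items():
        subs = []
        if subs_str:
            for token in subs_str.split(";"):
                subs.append((int(token[:-3]), token[-3], token[-1]))
        call = IsomiRCall(mid, int(o5), int(o3), str(tail), tuple(subs), count=int(n))
        out.setdefault(sample, []).append(call)
    return out


# ---- qPCR -----------------------------------------------------------------

def simulate_qpcr(
    metadata: pd.DataFrame,
    planted_shifts: dict[str, dict[str, float]],
    seed: int,
    normalizers: tuple[str, ...] = ("hsa-miR-16-5p", "hsa-miR-191-5p"),
    noise_sd: float = 0.25,
    n_wells: int = 2,
    base_ct: float = 20.0,
    sample_sd: float = 1.0,
) -> pd.DataFrame:
    """Duplicate-well Ct table with planted per-group expression shifts.

    ``planted_shifts[target][group]`` is the expression shift in Ct units
    (positive shift = higher expression = lower Ct).  Normalizer Ct is
    constant in expectation across groups; a per-sample RNA-input offset
    moves all assays of a sample together and cancels in the ΔCt.
    """
    if metadata["group"].nunique() < 2:
        raise ValueError("metadata must contain at least two groups")
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, meta in metadata.iterrows():
        offset = rng.normal(0.0, sample_sd)
        for norm in normalizers:
            for w in range(1, n_wells + 1):
                rows.append((sample_id, norm, w, base_ct + offset + rng.normal(0, noise_sd)))
        for target, shifts in planted_shifts.items():
            shift = shifts.get(str(meta["group"]), 0.0)
            for w in range(1, n_wells + 1):
                ct = base_ct + offset + 5.0 - shift + rng.normal(0, noise_sd)
                rows.append((sample_id, target, w, ct))
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "well", "ct"])


# ---- printed cohort tables ------------------------------------------------

def cohort_fixture() -> dict[str, pd.DataFrame]:
    """The published cohort contingency tables (profiling n=72, validation n=120).

    Columns are the AP/CRC/HC groups (or the two cohorts for the CRC
    stage table); rows are category levels.  These printed counts serve
    as oracle inputs for the chi-squared cohort tests.
    """
    cols = ["AP", "CRC", "HC"]

    def tab(rows: dict[str, list[int]]) -> pd.DataFrame:
        return pd.DataFrame(rows, index=cols).T

    fixture = {
        "profiling_sex": tab({"Male": [8, 10, 12], "Female": [12, 10, 20]}),
        "validation_sex": tab({"Male": [20, 23, 20], "Female": [20, 17, 20]}),
        "profiling_smoking": tab({"Yes": [8, 2, 4], "No": [10, 11, 23], "Unknown": [2, 7, 5]}),
        "validation_smoking": tab({"Yes": [1, 3, 5], "No": [27, 12, 26], "Unknown": [12, 25, 9]}),
        "crc_stage": pd.DataFrame(
            {
                "0": [8, 18], "I": [1, 2], "II": [4, 4], "III": [4, 14], "IV": [3, 2],
            },
            index=["profiling", "validation"],
        ).T,
        "adenoma_type": pd.DataFrame(
            {
                "Tubular adenoma": [13, 11],
                "Adenoma": [5, 28],
                "Tubulovillous adenoma": [2, 0],
                "Papiloadenoma": [0, 1],
            },
            index=["profiling", "validation"],
        ).T,
    }
    return fixture
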