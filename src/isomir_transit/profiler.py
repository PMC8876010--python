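"""isomiR profiling: read placement on hairpins and modification calling.

A preprocessed read is placed on the precursor set by exact k-mer
seeding followed by ungapped mismatch counting.  Relative to the
annotated mature miRNA the placement is then decomposed into

* a 5' end offset (positive = 5' trimming, which shifts the seed),
* a 3' end offset of the *templated* read end (positive = templated
  extension copied from the precursor, negative = trimming),
* a non-templated 3' tail — the maximal 3' suffix that disagrees with
  the precursor continuation (greedy from the 3' end, at most 3 nt), and
* internal substitutions, recorded at signed positions relative to the
  mature 5' end (position 1 = first mature base, -1 = one base 5' of it;
  there is no position 0).

Substitutions are then filtered: a substitution supported by less than
``min_fraction`` (default 0.25) of the reads assigned to its miRNA is
treated as sequencing error and those reads are merged into the
matching substitution-free isomiR; substitution-bearing reads whose
best placement is not unique are discarded.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd

from .reference import HairpinReference, MatureAnnotation

Substitution = tuple[int, str, str]  # (signed mature-relative position, ref, alt)


@dataclass(frozen=True)
class Placement:
    hairpin_id: str
    start: int  # 0-based offset of the read on the hairpin
    n_substitutions: int
    tail_length: int
    unique: bool = False


@dataclass(frozen=True)
class IsomiRCall:
    """A read's (or a group of identical reads') relation to a mature miRNA."""

    mature_id: str
    offset5: int
    offset3: int
    tail: str
    substitutions: tuple[Substitution, ...]
    count: int = 1
    unique: bool = True

    @property
    def is_canonical(self) -> bool:
        return (
            self.offset5 == 0
            and self.offset3 == 0
            and not self.tail
            and not self.substitutions
        )

    def key(self) -> tuple:
        return (self.mature_id, self.offset5, self.offset3, self.tail, self.substitutions)

    def label(self) -> str:
        subs = ",".join(f"{p}{r}>{a}" for p, r, a in self.substitutions) or "-"
        return f"{self.mature_id}|5p{self.offset5:+d}|3p{self.offset3:+d}|tail={self.tail or '-'}|sub={subs}"


# ---- alignment ------------------------------------------------------------

class KmerIndex:
    """Exact k-mer index over the hairpin set."""

    def __init__(self, hairpins: dict[str, str], k: int = 12):
        ids = list(hairpins)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate hairpin ids")
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for hid, seq in hairpins.items():
            for off in range(len(seq) - k + 1):
                self.index[seq[off:off + k]].append((hid, off))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def build_index(hairpins: dict[str, str], k: int = 12) -> KmerIndex:
    return KmerIndex(hairpins, k=k)


def _tail_and_subs(read: str, hairpin: str, start: int, max_tail: int) -> tuple[int, int]:
    """(tail_length, n_substitutions) for an ungapped placement.

    Bases overhanging the hairpin 3' end mismatch by definition.  The
    greedy tail is the run of trailing mismatches, capped at
    ``max_tail``; every other mismatch counts as a substitution.
    """
    n = len(read)
    mismatch = [
        (start + i >= len(hairpin)) or (read[i] != hairpin[start + i])
        for i in range(n)
    ]
    run = 0
    for i in range(n - 1, -1, -1):
        if mismatch[i]:
            run += 1
        else:
            break
    tail_len = min(run, max_tail)
    n_subs = sum(mismatch) - tail_len
    return tail_len, n_subs


def align_read(
    read: str,
    index: KmerIndex,
    hairpins: dict[str, str],
    max_subs: int = 2,
    max_tail: int = 3,
) -> list[Placement]:
    """All placements of ``read`` with <= max_subs substitutions.

    Candidate diagonals come from exact k-mer seeds at every read
    offset; each candidate is verified over the full read length with
    the non-templated tail (trailing mismatch run, <= max_tail nt)
    excluded from the substitution count.  When substitutions are so
    spaced that no seed-length window is clean, an exhaustive scan of
    all hairpin offsets backs the seeds up, so every placement within
    the substitution budget is returned regardless of k.  ``unique``
    marks placements when exactly one attains the minimal substitution
    count.
    """
    k = index.k
    if len(read) < k:
        return []
    candidates: set[tuple[str, int]] = set()
    for off in range(len(read) - k + 1):
        for hid, hoff in index.lookup(read[off:off + k]):
            start = hoff - off
            if start >= 0:
                candidates.add((hid, start))
    if not candidates:
        # no clean seed window: fall back to all diagonals
        for hid, hp in hairpins.items():
            for start in range(len(hp) - len(read) + max_tail + 1):
                candidates.add((hid, start))
    placements: list[Placement] = []
    for hid, start in candidates:
        hp = hairpins[hid]
        if start + len(read) > len(hp) + max_tail:
            continue
        tail_len, n_subs = _tail_and_subs(read, hp, start, max_tail)
        if n_subs <= max_subs:
            placements.append(Placement(hid, start, n_subs, tail_len))
    if not placements:
        return []
    best = min(p.n_substitutions for p in placements)
    n_best = sum(1 for p in placements if p.n_substitutions == best)
    unique = n_best == 1
    placements = [
        replace(p, unique=unique and p.n_substitutions == best) for p in placements
    ]
    placements.sort(key=lambda p: (p.n_substitutions, p.hairpin_id, p.start))
    return placements


# ---- classification -------------------------------------------------------

def _signed_position(hairpin_pos: int, mature_start: int) -> int:
    """1-based signed position relative to the mature 5' end (no zero)."""
    delta = hairpin_pos - mature_start
    return delta + 1 if delta >= 0 else delta


def classify_isomir(
    read: str,
    placement: Placement,
    reference: HairpinReference,
    max_tail: int = 3,
    min_overlap_fraction: float = 0.5,
) -> IsomiRCall | None:
    """Decompose a placed read into end offsets, tail and substitutions.

    Returns None (unassigned) when the placement does not overlap any
    mature annotation by at least ``min_overlap_fraction`` of the mature
    length.
    """
    hp = reference.hairpins[placement.hairpin_id]
    read_start = placement.start
    read_end = placement.start + len(read)

    best_ann: MatureAnnotation | None = None
    best_overlap = -1
    for ann in reference.matures_on(placement.hairpin_id):
        overlap = min(read_end, ann.end) - max(read_start, ann.start)
        if overlap > best_overlap:
            best_overlap = overlap
            best_ann = ann
    if best_ann is None or best_overlap < min_overlap_fraction * (best_ann.end - best_ann.start):
        return None

    tail_len, _ = _tail_and_subs(read, hp, read_start, max_tail)
    templated_end = read_end - tail_len
    tail = read[len(read) - tail_len:] if tail_len else ""

    subs: list[Substitution] = []
    for i in range(len(read) - tail_len):
        hp_pos = read_start + i
        if read[i] != hp[hp_pos]:
            subs.append((_signed_position(hp_pos, best_ann.start), hp[hp_pos], read[i]))

    return IsomiRCall(
        mature_id=best_ann.mature_id,
        offset5=read_start - best_ann.start,
        offset3=templated_end - best_ann.end,
        tail=tail,
        substitutions=tuple(subs),
        count=1,
        unique=placement.unique,
    )


# ---- substitution filters -------------------------------------------------

def _merge(calls: list[IsomiRCall]) -> list[IsomiRCall]:
    agg: dict[tuple, int] = Counter()
    uniq: dict[tuple, bool] = {}
    for c in calls:
        agg[c.key()] += c.count
        uniq[c.key()] = uniq.get(c.key(), True) and c.unique
    return [
        IsomiRCall(key[0], key[1], key[2], key[3], key[4], count=n, unique=uniq[key])
        for key, n in agg.items()
    ]


def apply_substitution_filters(
    calls: list[IsomiRCall], min_fraction: float = 0.25
) -> list[IsomiRCall]:
    """Filter substitutions per miRNA by supporting-read fraction.

    For each distinct (position, ref, alt) substitution of a miRNA the
    supporting fraction is (reads carrying it) / (reads assigned to the
    miRNA).  Substitutions below ``min_fraction`` are deemed sequencing
    error: they are dropped from their calls and the reads merge into
    the isomiR with identical end offsets and tail.  Substitution-bearing
    calls from non-unique placements are discarded first.
    """
    kept = [c for c in calls if not (c.substitutions and not c.unique)]

    by_mirna: dict[str, list[IsomiRCall]] = defaultdict(list)
    for c in kept:
        by_mirna[c.mature_id].append(c)

    out: list[IsomiRCall] = []
    for mirna_calls in by_mirna.values():
        total = sum(c.count for c in mirna_calls)
        support: Counter = Counter()
        for c in mirna_calls:
            for sub in c.substitutions:
                support[sub] += c.count
        failing = {sub for sub, n in support.items() if total == 0 or n / total < min_fraction}
        cleaned = [
            replace(c, substitutions=tuple(s for s in c.substitutions if s not in failing))
            for c in mirna_calls
        ]
        out.extend(_merge(cleaned))
    return out


# ---- aggregation ----------------------------------------------------------

def aggregate_counts(
    calls_by_sample: dict[str, list[IsomiRCall]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(miRNA counts, isomiR counts) as features x samples DataFrames."""
    samples = list(calls_by_sample)
    isomir_rows: dict[str, dict[str, int]] = defaultdict(dict)
    mirna_rows: dict[str, dict[str, int]] = defaultdict(dict)
    for sample, calls in calls_by_sample.items():
        for c in calls:
            label = c.label()
            isomir_rows[label][sample] = isomir_rows[label].get(sample, 0) + c.count
            mirna_rows[c.mature_id][sample] = mirna_rows[c.mature_id].get(sample, 0) + c.count
    mirna = pd.DataFrame(mirna_rows).T.reindex(columns=samples).fillna(0).astype(int)
    isomir = pd.DataFrame(isomir_rows).T.reindex(columns=samples).fillna(0).astype(int)
    mirna.index.name = "feature_id"
    isomir.index.name = "feature_id"
    return mirna.sort_index(), isomir.sort_index()


MOD_5P_SHIFT = "5p_shift"
MOD_3P_TRIM = "3p_trim"
MOD_3P_TEMPLATED_EXT = "3p_templated_ext"
MOD_3P_ADDITION = "3p_addition"
MOD_SUBSTITUTION = "substitution"


def modification_profiles(calls_by_sample: dict[str, list[IsomiRCall]]) -> pd.DataFrame:
    """Per-sample relative abundance of each modification at each position.

    Tidy frame (sample, mod_type, position, abundance) where abundance is
    reads carrying the modification at that signed position divided by
    all miRNA-assigned reads of the sample.  Positions: 5' shift uses the
    5' offset; 3' trim / templated extension use the 3' offset;
    non-templated addition uses the index within the tail (1 = first
    added base); substitutions use their mature-relative position.
    """
    rows = []
    for sample, calls in calls_by_sample.items():
        total = sum(c.count for c in calls)
        counts: Counter = Counter()
        for c in calls:
            if c.offset5 != 0:
                counts[(MOD_5P_SHIFT, c.offset5)] += c.count
            if c.offset3 < 0:
                counts[(MOD_3P_TRIM, c.offset3)] += c.count
            elif c.offset3 > 0:
                counts[(MOD_3P_TEMPLATED_EXT, c.offset3)] += c.count
            for i in range(1, len(c.tail) + 1):
                counts[(MOD_3P_ADDITION, i)] += c.count
            for pos, _, _ in c.substitutions:
                counts[(MOD_SUBSTITUTION, pos)] += c.count
        for (mod, pos), n in counts.items():
            rows.append((sample, mod, pos, n / total if total else 0.0))
    df = pd.DataFrame(rows, columns=["sample", "mod_type", "position", "abundance"])
    return df.sort_values(["sample", "mod_type", "position"]).reset_index(drop=True)


# ---- high-level driver ----------------------------------------------------

@dataclass
class ProfilingResult:
    mirna_counts: pd.DataFrame
    isomir_counts: pd.DataFrame
    profiles: pd.DataFrame
    calls_by_sample: dict[str, list[IsomiRCall]]
    n_assigned: dict[str, int] = field(default_factory=dict)
    n_unassigned: dict[str, int] = field(default_factory=dict)


def profile_reads(
    reads_by_sample: dict[str, list[str]],
    reference: HairpinReference,
    max_subs: int = 2,
    max_tail: int = 3,
    min_sub_fraction: float = 0.25,
    k: int = 8,
) -> ProfilingResult:
    """Run placement, classification and filtering for every sample.

    ``reads_by_sample`` maps sample ids to preprocessed read sequences.
    Identical sequences are collapsed before alignment, so cost scales
    with distinct isomiR sequences, not read depth.  The seed length k
    defaults to 8 here (shorter than the index default) so that a
    single internal substitution in a minimum-length read still leaves
    a clean seed window on one side.
    """
    index = build_index(reference.hairpins, k=k)
    calls_by_sample: dict[str, list[IsomiRCall]] = {}
    n_assigned: dict[str, int] = {}
    n_unassigned: dict[str, int] = {}
    cache: dict[str, IsomiRCall | None] = {}
    for sample, reads in reads_by_sample.items():
        counter = Counter(reads)
        calls: list[IsomiRCall] = []
        assigned = 0
        unassigned = 0
        for seq, n in counter.items():
            if seq not in cache:
                placements = align_read(seq, index, reference.hairpins, max_subs, max_tail)
                call = None
                if placements:
                    best = [p for p in placements if p.n_substitutions == placements[0].n_substitutions]
                    call = classify_isomir(seq, best[0], reference, max_tail)
                    if call is not None and len(best) > 1:
                        # multi-mapper: keep only if every best placement hits
                        # the same mature, else unassigned (conservative)
                        others = [
                            classify_isomir(seq, p, reference, max_tail) for p in best[1:]
                        ]
                        if any(o is None or o.mature_id != call.mature_id for o in others):
                            call = None
                cache[seq] = call
            call = cache[seq]
            if call is None:
                unassigned += n
            else:
                calls.append(replace(call, count=n))
                assigned += n
        calls_by_sample[sample] = apply_substitution_filters(calls, min_sub_fraction)
        n_assigned[sample] = assigned
        n_unassigned[sample] = unassigned
    mirna, isomir = aggregate_counts(calls_by_sample)
    profiles = modification_profiles(calls_by_sample)
    return ProfilingResult(mirna, isomir, profiles, calls_by_sample, n_assigned, n_unassigned)
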