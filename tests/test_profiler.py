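"""isomiR placement, classification, substitution filters and aggregation."""

import numpy as np
import pytest

from isomir_transit import (
    HairpinReference,
    IsomiRCall,
    MatureAnnotation,
    aggregate_counts,
    align_read,
    apply_substitution_filters,
    build_index,
    classify_isomir,
    modification_profiles,
    profile_reads,
)


class TestBuildIndex:
    def test_window_count_identity(self):
        hp = {"h": "ACGTACGTACGTACGT"}  # length 16
        idx = build_index(hp, k=12)
        assert sum(len(v) for v in idx.index.values()) == 16 - 12 + 1

    def test_query_returns_true_origin(self, small_reference):
        idx = build_index(small_reference.hairpins, k=12)
        hid = next(iter(small_reference.hairpins))
        window = small_reference.hairpins[hid][3:15]
        assert (hid, 3) in idx.lookup(window)

    def test_absent_query_empty(self, small_reference):
        idx = build_index(small_reference.hairpins, k=12)
        assert idx.lookup("N" * 12) == []

    def test_duplicate_fasta_ids_rejected(self, tmp_path):
        fasta = tmp_path / "dup.fa"
        fasta.write_text(">a\nACGTACGTACGTACGT\n>a\nTGCATGCATGCATGCA\n")
        mature = tmp_path / "mature.tsv"
        mature.write_text("hairpin_id\tmature_id\tstart\tend\n")
        with pytest.raises(ValueError):
            HairpinReference.read(fasta, mature)


class TestAlignRead:
    def test_canonical_read_unique_zero_subs(self, small_reference):
        idx = build_index(small_reference.hairpins, k=8)
        ann = small_reference.matures[0]
        read = small_reference.mature_sequence(ann.mature_id)
        placements = align_read(read, idx, small_reference.hairpins)
        assert len(placements) == 1
        p = placements[0]
        assert p.unique and p.n_substitutions == 0
        assert (p.hairpin_id, p.start) == (ann.hairpin_id, ann.start)

    def test_shared_repeat_gives_two_nonunique_placements(self):
        core = "ACGTTGCAGGTCAATCGGATCA"  # 22-nt repeat planted in two hairpins
        hp = {
            "h1": "GGGGGCC" + core + "TTAACCGGTTAACCG",
            "h2": "AATTCCG" + core + "CCGGAATTCCGGAAT",
        }
        idx = build_index(hp, k=8)
        placements = align_read(core, idx, hp)
        # brute-force scan oracle over all hairpin windows
        expected = {
            (hid, s)
            for hid, seq in hp.items()
            for s in range(len(seq) - len(core) + 1)
            if sum(a != b for a, b in zip(core, seq[s:s + len(core)])) <= 2
        }
        assert {(p.hairpin_id, p.start) for p in placements} == expected
        assert len(placements) == 2
        assert not any(p.unique for p in placements)

    def test_three_substitutions_rejected_at_max_two(self, small_reference):
        idx = build_index(small_reference.hairpins, k=8)
        ann = small_reference.matures[0]
        read = list(small_reference.mature_sequence(ann.mature_id))
        for pos in (3, 8, 13):  # internal, non-adjacent so none are tail
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        placements = align_read("".join(read), idx, small_reference.hairpins, max_subs=2)
        assert placements == []


class TestClassifyIsomir:
    def place(self, ref, read, k=8):
        idx = build_index(ref.hairpins, k=k)
        placements = align_read(read, idx, ref.hairpins)
        assert placements, "read did not align"
        return placements[0]

    def test_canonical(self, toy_hairpin):
        ref, mature = toy_hairpin
        call = classify_isomir(mature, self.place(ref, mature), ref)
        assert (call.offset5, call.offset3, call.tail, call.substitutions) == (0, 0, "", ())
        assert call.is_canonical

    def test_five_prime_trim_is_positive_offset(self, toy_hairpin):
        ref, mature = toy_hairpin
        call = classify_isomir(mature[1:], self.place(ref, mature[1:]), ref)
        assert call.offset5 == 1 and call.offset3 == 0

    def test_templated_vs_nontemplated_extension(self, toy_hairpin):
        ref, mature = toy_hairpin  # hairpin continues TTTTT after the mature
        tailed = mature + "AA"
        call = classify_isomir(tailed, self.place(ref, tailed), ref)
        assert call.tail == "AA" and call.offset3 == 0

        templated = mature + "TT"
        call = classify_isomir(templated, self.place(ref, templated), ref)
        assert call.tail == "" and call.offset3 == 2

    def test_substitution_recorded_with_mature_position(self, toy_hairpin):
        ref, mature = toy_hairpin
        read = mature[:4] + ("C" if mature[4] != "C" else "G") + mature[5:]
        call = classify_isomir(read, self.place(ref, read), ref)
        assert len(call.substitutions) == 1
        pos, r, a = call.substitutions[0]
        assert pos == 5 and r == mature[4] and a == read[4]


class TestSubstitutionFilters:
    def make_calls(self, n_with_sub, n_without, sub=(5, "C", "T"), unique=True):
        calls = []
        if n_without:
            calls.append(IsomiRCall("m1", 0, 0, "", (), count=n_without))
        if n_with_sub:
            calls.append(IsomiRCall("m1", 0, 0, "", (sub,), count=n_with_sub, unique=unique))
        return calls

    def test_30pct_substitution_retained(self):
        out = apply_substitution_filters(self.make_calls(30, 70))
        with_sub = [c for c in out if c.substitutions]
        assert len(with_sub) == 1 and with_sub[0].count == 30

    def test_10pct_substitution_merged_and_conserved(self):
        out = apply_substitution_filters(self.make_calls(10, 90))
        assert all(not c.substitutions for c in out)
        assert sum(c.count for c in out) == 100
        assert len(out) == 1 and out[0].count == 100

    def test_nonunique_substitution_calls_discarded(self):
        calls = self.make_calls(30, 70, unique=False)
        out = apply_substitution_filters(calls)
        assert sum(c.count for c in out) == 70
        assert all(not c.substitutions for c in out)

    def test_threshold_boundary_is_inclusive(self):
        out = apply_substitution_filters(self.make_calls(25, 75))
        assert any(c.substitutions for c in out)  # exactly 0.25 kept

    def test_total_count_conserved_without_nonunique(self):
        calls = [
            IsomiRCall("m1", 0, 0, "", ((5, "C", "T"),), count=10),
            IsomiRCall("m1", 1, 0, "", ((5, "C", "T"), (9, "G", "A")), count=5),
            IsomiRCall("m1", 0, -1, "A", (), count=85),
        ]
        out = apply_substitution_filters(calls)
        assert sum(c.count for c in out) == 100


class TestAggregation:
    def test_mirna_column_sums_match_assigned_reads(self):
        calls = {
            "s1": [IsomiRCall("m1", 0, 0, "", (), count=10),
                   IsomiRCall("m1", 1, 0, "", (), count=5),
                   IsomiRCall("m2", 0, 0, "", (), count=7)],
            "s2": [],
        }
        mirna, isomir = aggregate_counts(calls)
        assert mirna["s1"].sum() == 22
        assert (mirna["s2"] == 0).all()
        assert isomir["s1"].sum() == 22
        assert mirna.loc["m1", "s1"] == 15

    def test_planted_mixture_recovered_with_multinomial_tolerance(self):
        from isomir_transit import SimulationDesign, generate_reference, simulate_counts
        from isomir_transit.simulate import simulate_isomir_reads
        from isomir_transit.pipeline import preprocess_samples

        profile = {"canonical": 0.5, "trim5": 0.1, "trim3": 0.2, "ext3": 0.1,
                   "add3": 0.1, "substitution": 0.0}
        design = SimulationDesign(
            n_hairpins=1, n_samples_per_group=1, isomir_profile=profile,
            seq_error_rate=0.0, baseline_log2_range=(8.0, 8.0), seed=21,
        )
        ref = generate_reference(1, design.seed)
        counts, _, _ = simulate_counts(design, ref)
        counts.iloc[0, :] = 2000
        reads, _ = simulate_isomir_reads(counts, ref, design)
        clean = preprocess_samples(reads, design.adapter)
        sample = counts.columns[0]
        result = profile_reads({sample: clean[sample]}, ref)
        calls = result.calls_by_sample[sample]
        n = 2000

        def frac(pred):
            return sum(c.count for c in calls if pred(c)) / sum(c.count for c in calls)

        checks = {
            "canonical": (lambda c: c.is_canonical, 0.5),
            "trim5": (lambda c: c.offset5 > 0 and c.offset3 == 0 and not c.tail, 0.1),
            "ext3": (lambda c: c.offset3 > 0 and c.offset5 == 0, 0.1),
            "add3": (lambda c: bool(c.tail) and c.offset5 == 0 and c.offset3 == 0, 0.1),
        }
        # some trim5/trim3 reads fall under the 18-nt length filter, so only
        # categories unaffected by filtering are compared against 3 sd
        for name, (pred, p) in checks.items():
            sd = np.sqrt(p * (1 - p) / n)
            observed = frac(pred)
            assert abs(observed - p) < max(3 * sd, 0.02), name


class TestModificationProfiles:
    def test_all_canonical_gives_no_modifications(self):
        calls = {"s1": [IsomiRCall("m1", 0, 0, "", (), count=50)]}
        prof = modification_profiles(calls)
        assert prof.empty

    def test_single_base_tail_quarter_abundance(self):
        calls = {"s1": [IsomiRCall("m1", 0, 0, "", (), count=75),
                        IsomiRCall("m1", 0, 0, "A", (), count=25)]}
        prof = modification_profiles(calls)
        row = prof[(prof.mod_type == "3p_addition") & (prof.position == 1)]
        assert np.isclose(row["abundance"].iloc[0], 0.25)

    def test_scale_invariance(self):
        base = [IsomiRCall("m1", 0, 0, "", (), count=30),
                IsomiRCall("m1", 2, 0, "", (), count=10),
                IsomiRCall("m1", 0, 0, "AT", (), count=10)]
        doubled = [IsomiRCall(c.mature_id, c.offset5, c.offset3, c.tail,
                              c.substitutions, count=2 * c.count) for c in base]
        p1 = modification_profiles({"s": base})
        p2 = modification_profiles({"s": doubled})
        assert np.allclose(p1["abundance"], p2["abundance"])


class TestRoundTrip:
    def test_zero_error_recovers_every_planted_call(self):
        """classify o simulate is the identity on planted isomiR calls."""
        from isomir_transit import SimulationDesign, generate_reference, simulate_counts
        from isomir_transit.simulate import simulate_isomir_reads, truth_to_calls
        from isomir_transit.pipeline import preprocess_samples
        from isomir_transit.profiler import align_read, build_index, classify_isomir
        from isomir_transit.preprocess import ReadRecord, preprocess_reads

        design = SimulationDesign(
            n_hairpins=15, n_samples_per_group=2, seq_error_rate=0.0, seed=13
        )
        ref = generate_reference(15, design.seed)
        counts, _, _ = simulate_counts(design, ref)
        reads, truth = simulate_isomir_reads(counts, ref, design)
        truth = truth.set_index(["sample", "read_id"])
        idx = build_index(ref.hairpins, k=8)
        n_checked = 0
        for sample, sample_reads in reads.items():
            records = [ReadRecord(rid, s, q) for rid, s, q in sample_reads]
            kept, _ = preprocess_reads(records, design.adapter)
            for rec in kept:
                placements = align_read(rec.sequence, idx, ref.hairpins)
                assert placements
                call = classify_isomir(rec.sequence, placements[0], ref)
                row = truth.loc[(sample, rec.id)]
                assert call.mature_id == row["mature_id"]
                assert call.offset5 == row["offset5"]
                assert call.offset3 == row["offset3"]
                assert call.tail == row["tail"]
                expected_subs = row["substitutions"]
                got_subs = ";".join(f"{p}{r}>{a}" for p, r, a in call.substitutions)
                assert got_subs == expected_subs
                n_checked += 1
        assert n_checked > 500


def test_read_conservation_through_profiling(small_reference):
    """assigned + unassigned equals the preprocessed read count exactly."""
    from isomir_transit import SimulationDesign, simulate_counts
    from isomir_transit.simulate import simulate_isomir_reads
    from isomir_transit.pipeline import preprocess_samples

    design = SimulationDesign(n_hairpins=20, n_samples_per_group=2, seed=17)
    counts, _, _ = simulate_counts(design, small_reference)
    reads, _ = simulate_isomir_reads(counts, small_reference, design)
    clean = preprocess_samples(reads, design.adapter)
    result = profile_reads(clean, small_reference)
    for sample, seqs in clean.items():
        assert result.n_assigned[sample] + result.n_unassigned[sample] == len(seqs)
        assert result.mirna_counts[sample].sum() == result.n_assigned[sample]
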