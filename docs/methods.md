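# Methods

`isomir_transit` re-implements, as a reusable and tested pipeline, an
isomiR-resolved small RNA-seq analysis of the colorectal
healthy-mucosa → adenomatous-polyp → carcinoma (HC → AP → CRC)
transition, together with a synthetic-data generator that emulates the
three-group study design so that every stage is testable without any
external download.

## The synthetic cohort

The generator is the package's definition of the study conditions, not
a tuning knob.

**Reference.** Random precursor ("hairpin") sequences of 60–90 nt over
the DNA alphabet (A/C/G/T; published RNA sequences are transliterated,
U → T, per FASTQ convention), each carrying one annotated mature miRNA
of 20–24 nt with ≥ 5 nt of precursor flanking both ends. Rejection
sampling enforces that mature sequences are pairwise distinct, occur
exactly once in their own hairpin and never inside any other hairpin,
so canonical reads map uniquely by construction. Sampling aborts with a
reproducibility error after a bounded number of retries.

**Counts.** For feature *i* in sample *j* of stage *s* (HC = 0, AP = 1,
CRC = 2, treated ordinally),

    log2 mu_ij = baseline_i + d_i * beta * s_j * [i planted]
                 + batch_j + gamma * (age_j - mean age)

with counts drawn NB(mu, alpha) via the gamma–Poisson mixture
(variance mu + alpha mu²; alpha = 0 gives Poisson). Defaults: baseline
log2 mean uniform on [4, 8] (mean count ≈ 90, a realistic mid-depth
miRNA); fraction of planted stage-monotone features 0.1 with random
sign d_i; effect beta = 1 log2 unit per ordinal step; dispersion
alpha = 0.1 (typical for bulk tissue miRNA counts); two technical
batches with mean-zero Gaussian log2 effects of sd 0.3; ages uniform on
45–80 years with a small positive age slope (0.01 log2/yr). Ages are
uniform rather than matched to any reported mean ± sd because only
summary moments are published and the distribution is immaterial to the
covariate-adjustment logic being tested.

**Reads.** Each count becomes one single-end read. A read is drawn from
the isomiR class profile — canonical 0.55, 5' trim 0.08, 3' trim 0.15,
templated 3' extension 0.07, non-templated 3' addition 0.10,
substitution 0.05 — values chosen once as a realistic tissue isomiR
mixture (canonical plus 3'-end variation dominating, substitutions
rare). End shifts are ±1–2 nt; non-templated tails are 1–3 nt over
{A, T} (adenylation/uridylation being the dominant biological
additions), with every tail base forced to differ from the templated
continuation so the tail is well defined; each miRNA carries one fixed
internal substitution site (position and alternative base drawn once),
emulating a genuine sequence variant as opposed to sequencing error.
Uniform per-base sequencing errors (default 10⁻³; the real error
profile of the instrument is unknown, so uniformity is assumed) are
then applied, the 3' adapter (Illumina TruSeq small-RNA,
`TGGAATTCTCGGGTGCCAAGG`, configurable) appended, and the read clipped
or padded to 50 nt. Qualities are Q40 throughout except an occasional
(10 %) low-quality 3' run of 1–4 bases, which by construction falls in
the adapter/pad region — quality trimming is thereby exercised without
ever invading the biological insert.

**qPCR.** Duplicate wells per assay per sample; a per-sample RNA-input
offset moves all assays of a sample together (and cancels in ΔCt);
normalizer Ct is constant in expectation across groups; a planted
expression shift of *x* Ct lowers the target Ct by *x* in the shifted
group; Gaussian well noise (sd 0.25 Ct) on every well.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: multi-mapping between paralogous
precursor families, 5p/3p arm competition, ligation and GC biases of
library preparation, indel sequencing errors, adapter dimers,
non-miRNA small-RNA background, plasma/exosome biology, and any
correlation structure between features. Recovery rates measured here
are therefore upper bounds on what the same pipeline achieves on real
libraries.

## Preprocessing

Adapter removal, quality trimming and length filtering, in that order.
Adapter matching is ungapped semi-global: every start offset is scored
over min(adapter length, remaining read) bases, a candidate is valid
when its mismatch count is ≤ floor(rate × matched length) (default
rate 0.1, minimum overlap 3 nt), and the candidate with the most
matching bases wins (ties: fewer mismatches, then leftmost). Everything
from the match onward is removed. Indel-tolerant matching is out of
scope; on 1 × 50 chemistry with a 21-nt adapter this loses essentially
nothing. Quality trimming uses the standard partial-sum rule: remove
the suffix maximizing the running sum of (Q20 − q) from the 3' end.
Reads shorter than 18 nt are then discarded. The full pass is
idempotent and every output read is a prefix of its input.

## isomiR profiling

Reads are placed on the precursor set by exact k-mer seeding plus
ungapped verification. The index default is k = 12; the high-level
driver seeds with k = 8 because a single internal substitution in an
18–24-nt read can interrupt every 12-mer window (pigeonhole), while an
8-mer window always survives one substitution at these lengths. When
even 8-mer seeding finds nothing (two awkwardly spaced substitutions),
an exhaustive scan over all diagonals guarantees that every placement
within the budget (≤ 2 substitutions) is still found. Distinct read
sequences are collapsed before alignment, so cost scales with isomiR
diversity, not depth.

A placement is decomposed relative to the overlapping mature annotation
(≥ 50 % of the mature length required): the maximal run of trailing
mismatches, capped at 3 nt, is the non-templated tail — calling the
tail greedily *before* substitutions prevents a terminal mismatch from
being counted twice; the 5' offset is positive for 5' trimming (the
reading that makes "seed shifting" a positive shift); the 3' offset of
the templated end is positive for templated extension; remaining
mismatches are substitutions at signed mature-relative positions
(1 = first mature base, −1 = one base 5' of it, no position 0).

Substitution filtering follows the published rule: a substitution
supported by < 25 % of a miRNA's reads is deemed sequencing error. The
threshold is read as ≥ 0.25 (a strict-equality reading would be
degenerate), and filtered reads are *merged* into the isomiR with
identical end offsets and tail rather than discarded — merging
conserves miRNA-level totals, which downstream normalization relies
on; whether the original analysis merged or discarded is unstated.
Substitution-bearing reads whose best placement is not unique are
discarded entirely. Multi-mapping reads are counted only when every
best placement falls in the same mature annotation; otherwise they are
left unassigned (conservative).

Positional modification profiles report, per sample, the fraction of
assigned reads carrying each modification type at each signed position
(tail positions indexed from 1 at the first added base; 5' shifts by
their offset). A read with a 2-nt tail contributes to tail positions 1
and 2.

## Normalization and differential expression

Size factors are median-of-ratios over features positive in every
sample; factors are defined only up to the geometric-mean
renormalization, so all contracts are stated on factor ratios. The
variance-stabilizing transform is log2(count/s + 1): every downstream
consumer (Euclidean MDS, rank-based screening) needs only a monotone
variance-flattening transform, so the closed-form NB VST is not
required; on NB data with alpha = 0.05 the transform's per-feature sd
varies by less than 2× across the mean range.

Per-feature NB dispersion is method-of-moments on normalized counts,
alpha = max(0, (s² − m)/m²), shrunk 50/50 toward a mean–dispersion
trend a₁/mu + a₀ fitted by least squares across features, floored at
10⁻⁸. This is deliberately simpler than a full empirical-Bayes
treatment; the 50/50 shrinkage stabilizes small-sample estimates enough
that the Wald test holds its nominal level (measured type-I error
0.052 at n = 30/group over 2000 null features).

Each feature is fitted with a log-link NB GLM (statsmodels, fixed
alpha, log size-factor offset) on all samples, with design intercept +
group indicators + technical-batch indicators + centered age. The Wald
statistic tests the difference of the two contrast-group coefficients
against a standard normal (matching the reference implementation's
default, not a t reference); log2FC = coefficient/ln 2. No fold-change
shrinkage and no independent filtering are applied — calls use the raw
Wald log2FC against the published thresholds. Features that fail to
converge get p = NA and are excluded from the Benjamini–Hochberg
step-up adjustment. DE calls require adjusted p < 0.01 **and**
|log2FC| > 0.5, both strict. Fold-change estimates were cross-checked
against an independent NB GLM implementation (pydeseq2) and agree to
< 0.02 mean absolute log2FC difference on a two-group design.

The three-way summary intersects the two against-HC contrasts:
shared-up/down regions (deregulated in both AP and CRC vs HC, same
direction) and per-condition unique regions.

## Transition statistics

MDS is classical (Torgerson): double-center the squared Euclidean
distance matrix of VST profiles, eigendecompose, order axes by
eigenvalue; numerically-zero eigenvalues are clamped to zero (their
eigenvectors are arbitrary) and each axis's sign is fixed by making its
largest-magnitude coordinate positive. Classical rather than non-metric
scaling because the distances are genuinely Euclidean on transformed
counts.

The ordinal screen computes per-feature Spearman rho between VST
expression (the published analysis correlates transformed counts) and
stage 0/1/2 with average-rank ties. Tiers follow the published
intervals: high |rho| > 0.7, moderate 0.5 < |rho| ≤ 0.7 — the boundary
point 0.7 itself is assigned to moderate by strict reading of the
high-tier inequality. Constant features get rho = NA.

Positional modification abundances are compared across groups with the
tie-corrected Kruskal–Wallis test (chi-squared reference, df =
groups − 1; all-identical values give p = 1 by convention), BH-adjusted
across (type, position) cells, with per-group medians reported to
expose monotone trends. The chi-squared reference is adequate from
about 10 samples per group; below that the rank statistic's
discreteness is visible.

## qPCR validation statistics

ΔCt = mean(target wells) − mean over normalizers of mean(normalizer
wells); duplicates are averaged before subtraction, and with two
normalizers their per-sample means are arithmetically averaged. Lower
ΔCt means higher expression, so for a case-vs-control contrast
log2FC = mean ΔCt(control) − mean ΔCt(case): positive log2FC = higher
expression in the case group, matching the "inverted ΔCt" display
convention. Group comparison is the two-sided Mann–Whitney U — exact
enumeration when both groups have ≤ 8 samples and no cross-group ties,
else the tie-corrected normal approximation (the two agree to
|Δp| < 0.02 at n = 8/8) — BH-adjusted across targets, called at
adjusted p < 0.05 and |log2FC| > 1 (both strict). Assays of different
chemistry are analyzed separately, never pooled.

Cohort tables are tested with Pearson's chi-squared without continuity
correction (zero-margin rows/columns dropped with a warning);
quantitative variables with Kruskal–Wallis. The published cohort tables
ship as a programmatic fixture. Two published cells (adenoma "Type"
p = 0.004, validation smoking p = 0.00001) cannot be reconciled with
any obvious partition of the printed counts; they are reported but not
asserted. The exact profiling-sex p is 0.66270, printed truncated as
0.662, so agreement there is to one unit in the last printed digit.
Age comparisons are supported for synthetic data only — raw ages behind
the published mean ± sd are unavailable.

## Target scanning and overrepresentation

The 8-mer site is literal: reverse complement of miRNA positions 2–8
followed by 'A' in the 3'UTR (the 'A' opposite position 1 is matched
literally regardless of the miRNA's first nucleotide, the standard
convention). Only 8-mer sites are scanned — weaker 7-mer classes,
context scoring, conservation weighting and live database retrieval are
out of scope; the scanner runs over user-supplied UTR FASTA.
Overlapping occurrences are all reported with 1-based inclusive
coordinates. Overrepresentation uses the hypergeometric upper tail
P(X ≥ k), enrichment E = (k/n)/(K/N), BH across pathways, significant
at adjusted p < 0.05 and E > 1 (both strict; a pathway equal to the
universe has E = 1 exactly and is never significant).

## Problem sizes and determinism

The simulation scales used throughout tests and the acceptance script —
300 miRNAs, 30 samples/group for end-to-end recovery; 2000 features for
the null type-I measurement; 40/group for qPCR recovery — are the
package's chosen working sizes: large enough that Monte-Carlo noise is
well inside every asserted tolerance, small enough to run interactively.
All randomness flows from integer seeds through `numpy.random.Generator`;
identical design + seed reproduces byte-identical FASTQ/TSV outputs.

## Known limitations

Ungapped alignment only (no indel isomiRs); no novel-miRNA discovery;
no A-to-I editing inference beyond raw substitution records; the exact
published DE counts (208/157/51/146/191…) and the identities
hsa-miR-1246/hsa-miR-215-5p are properties of the deposited cohort
(GSE160432) and are not reproducible from synthetic data — the package
instead demonstrates planted-signal recovery under the same design; the
log-based VST is not the closed-form NB VST (a flag-gated addition if
ever needed); Cook's-distance outlier handling and shrinkage estimators
are deliberately absent.
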