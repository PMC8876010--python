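# isomir-transit

Analysis of miRNA and isomiR expression along the colorectal
adenoma–carcinoma transition: healthy mucosa (HC) → adenomatous polyp
(AP) → colorectal carcinoma (CRC). The package is aimed at small
RNA-seq practitioners who want the complete chain — read
preprocessing, isomiR classification, negative-binomial differential
expression with covariates, ordinal stage screening, qPCR ΔCt
validation statistics, and seed-site target scanning — as plain,
tested Python, together with a synthetic-cohort generator that makes
every stage verifiable against planted ground truth.

## What it computes

**isomiR classification.** Each read is placed on a hairpin precursor
(ungapped, ≤ 2 substitutions) and decomposed relative to the annotated
mature miRNA into a 5' end offset (positive = 5' trimming, which
shifts the seed), a templated 3' end offset, a non-templated 3' tail
(greedy trailing-mismatch run, ≤ 3 nt), and internal substitutions. A
substitution is kept as real only when ≥ 25 % of the miRNA's reads
carry it and its reads map uniquely; otherwise those reads merge into
the matching substitution-free isomiR.

**Differential expression.** Median-of-ratios size factors s_j, then a
per-feature NB log-link GLM

    log mu_ij = x_j' beta_i + log s_j ,   Var = mu + alpha_i mu^2

with technical batch and centered age as covariates and a
method-of-moments dispersion shrunk toward a fitted mean–dispersion
trend. The Wald statistic z = beta_hat / SE(beta_hat) on a group
contrast is referred to N(0, 1); Benjamini–Hochberg adjustment across
features; a miRNA is differentially expressed at P_FDR < 0.01 and
|log2FC| > 0.5. A three-way summary intersects the AP-vs-HC and
CRC-vs-HC calls into shared and condition-unique regions.

**Transition screening.** Classical (Torgerson) MDS on Euclidean
distances of variance-stabilized counts, and per-miRNA Spearman
correlation of expression with the ordinal stage (HC = 0, AP = 1,
CRC = 2): |rho| > 0.7 is the high tier, 0.5 < |rho| ≤ 0.7 moderate.
Positional isomiR-modification abundances are compared across groups
with tie-corrected Kruskal–Wallis tests.

**Validation statistics.** ΔCt = Ct(target) − mean Ct(normalizers),
duplicates averaged first; two-sided Mann–Whitney U (exact for small
groups) with BH adjustment, called at adjusted p < 0.05 and
|log2FC| > 1; Pearson chi-squared cohort tests.

**Target scanning.** 8-mer seed sites — reverse complement of miRNA
positions 2–8 followed by 'A' — located in user-supplied 3'UTRs, and
Fisher's-exact (hypergeometric) pathway overrepresentation with
enrichment score E = (k/n)/(K/N), significant at P_FDR < 0.05 and
E > 1.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

Simulate a 45-sample cohort (15 per group, 100 miRNAs, 20 % of them
planted with a +/-1 log2-per-stage monotone effect), push the reads
through the full pipeline, and summarize:

```python
import numpy as np
import isomir_transit as it
from isomir_transit.pipeline import run_pipeline

design = it.SimulationDesign(
    n_hairpins=100, n_samples_per_group=15,
    frac_monotone=0.2, lfc_per_step=1.0, seed=7,
)
res = run_pipeline(design)

up, down = res.de_sets[("CRC", "HC")]
print(f"CRC vs HC: {len(up)} up, {len(down)} down "
      f"(P_FDR < 0.01, |log2FC| > 0.5)")
print(f"three-way shared with AP: {len(res.three_way.shared_up)} up, "
      f"{len(res.three_way.shared_down)} down")
high = res.screen[res.screen.tier == "high"]
print(f"stage-correlated (|rho| > 0.7): {len(high)} miRNAs")
planted = res.truth.index[res.truth.is_monotone]
shared = res.three_way.shared_up | res.three_way.shared_down
print(f"planted monotone miRNAs recovered in the shared region: "
      f"{np.mean([f in shared for f in planted]):.0%}")
```

Output:

```
CRC vs HC: 10 up, 10 down (P_FDR < 0.01, |log2FC| > 0.5)
three-way shared with AP: 8 up, 7 down
stage-correlated (|rho| > 0.7): 20 miRNAs
planted monotone miRNAs recovered in the shared region: 75%
```

All 20 planted miRNAs reach the high Spearman tier and 20 of them pass
the CRC-vs-HC thresholds; 15 of the 20 are already significant in *both*
colon conditions at this modest sample size, i.e. the shared region of
the three-way comparison collects the stage-monotone features, which is
exactly the behavior the screen is designed to expose. (At 30 samples
per group the shared-region recovery exceeds 90 %.)

The same stages are scriptable from the shell:

```sh
isomir-transit simulate --config design.json --out sim/
isomir-transit preprocess --fastq sim/fastq/HC_01.fastq --adapter TGGAATTCTCGGGTGCCAAGG --out trimmed/HC_01.fastq
isomir-transit profile --ref sim/hairpins.fa --mature sim/mature.tsv --fastq-dir trimmed/ --out profiled/
isomir-transit de --counts profiled/mirna_counts.tsv --meta sim/metadata.tsv --contrast CRC,HC --out de.tsv
isomir-transit targets --mirna AAUGGAUUUUUGGAGCAGG --utrs utrs.fa --out sites.tsv
```

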