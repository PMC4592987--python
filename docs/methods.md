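# Methods

## Data model

All stability statistics operate on log₁₀-FPKM values. Raw FPKM input is
log-transformed on load; zero FPKM maps to a configurable floor (default
−4), placed below the expression cutoff (−2) so non-detected genes always
fail the filter. Sample metadata carries (time in hours, replicate index,
course id); every (course, time, replicate) triple must be unique. A matrix
is either `absolute` or `relative_to_t0`; the latter is produced by
subtracting each gene's (replicate-mean) value at the earliest time point
of each course — on the log scale, subtraction and FPKM division are the
same operation, which is why only one normalization is implemented.
Induction-style series that only support relative quantification are
handled on this scale, and the statistics that need absolute levels
(expression cutoff, SD/RSD candidacy, expression quintiles) refuse to run
on it; the pipeline then reports the top-n PIRS genes overall instead of
per-quintile picks.

## ENCAS screening

1. **Expression**: mean log₁₀ FPKM across all samples must exceed −2
   (strict inequality; the summary statistic is the dataset-level mean —
   the simplest choice, documented and tested at the boundary).
2. **Rhythmicity**: genes called rhythmic at BH q < 0.05 are rejected
   (see below). Skipped for un-replicated datasets.
3. **ANOVA**: one-way fixed-effects F-test with time point as the factor;
   genes with P < 0.05 are rejected. Deliberately **not** adjusted for
   multiple testing: the filter's job is to screen out variable genes, and
   an FDR adjustment would only let more of them through. Skipped when no
   time point has replicates (within-group variance undefined); a
   zero-variance gene gets P = 1.

A consequence worth knowing: the ANOVA falsely rejects a truly flat gene
with probability exactly α, so on a synthetic panel with planted flat
genes roughly 5% of the planted set is lost per screen. The workflow
therefore offers `screen="pooled"` — one screen on the concatenated
courses (courses acting as extra replicates), applied to all datasets —
alongside the default per-dataset screen. Multi-course selection uses the
single pooled screen; it avoids compounding the per-screen loss three
times, and matches a workflow where one screening dataset defines the
candidate pool that other datasets only score.

## The rhythm test

Per gene, Kendall's S is computed against cosine references at the
configured period(s) (default 22 h) with phases on the sampling-interval
grid; replicates share the reference value, so reference ties define
groups. For tie-free observations the null law of S against a tied
reference is the Jonckheere–Terpstra null, computed **exactly** at any
series length as the convolution of Mann–Whitney count distributions over
sequentially added groups. Observations with ties (rare for continuous
expression) fall back to a seeded Monte-Carlo permutation null.

Phase-shifted cosines are strongly correlated (adjacent 2 h phases at a
22 h period correlate at ≈0.84), so a Bonferroni correction of the
within-gene min-p over ~11 references is markedly conservative: measured
empirical type-I at α = 0.05 on 1000 null genes is ≈0.02. The default
family-wise correction is therefore the permutation null of the min-p
statistic itself: since the joint law of the per-reference S under
permutation depends only on the reference family, one seeded simulation
(default 10,000 permutations) per sampling design calibrates every gene.
Measured type-I with this correction is ≈0.044 — consistent with the
nominal level — and power on cyclers with amplitude twice the noise SD
(12 time points × 2 replicates) is ≈1.0. `correction="bonferroni"`
restores the conservative variant. Across genes, q-values are
Benjamini–Hochberg (statsmodels); rhythmic means q strictly below α.
Precomputed rhythmicity calls (TSV of gene_id, q_value) can replace the
built-in test entirely.

## PIRS and the alternative rankings

OLS of log expression on time over all replicate points; the 95%
prediction interval (the interval for a new observation; a
confidence-interval variant for the mean sits behind a flag) is evaluated
at each **distinct** time point, not at each replicate. The score sums
|U − m| + |L − m| over time points against the gene's overall mean m;
the alternative reading Σ|U − L| is available behind `formula="width"` —
the two differ exactly when a gene trends (the width variant is blind to
slope, the default is not), which is why the default follows the
mean-deviation form. PIRS is invariant to adding a constant to a gene
(tested exactly) and strictly increasing in residual noise.

The independent SD/RSD route flags genes whose log-value SD is ≤0.5% of
the absolute mean log expression, with cross-course consensus (candidate
in the averaged course and in ≥1 individual course). Rankings are compared
by the Jaccard coefficient of top-k sets. Expression quintiles are five
equal-frequency bins of mean expression; the report takes the
`per_quintile` lowest-PIRS genes per bin, ties broken by gene id.

## Consensus across datasets

Per-dataset PIRS vectors (genes scored in every dataset; others excluded
with a log entry) are min–max normalized per dataset (z-score variant
behind a flag), summed with equal weights, and the candidate list is the
intersection of the top-n (default 10) summed scores with the pareto front
under weak dominance (≤ everywhere, < somewhere). The front is invariant
under any strictly monotone per-dataset transform, so the normalization
cannot change it — it only affects the summed ranking.

## Primer catalog

GFF3 + FASTA are parsed into per-transcript models (gffutils/biopython;
1-based inclusive coordinates converted to 0-based half-open; minus-strand
exons reordered and the spliced sequence reverse-complemented). Region
rules: mono-exonic genes search [len−500, len−100) of the spliced
sequence (genes shorter than the window use the whole sequence minus the
3′ margin and are flagged; genes whose usable window cannot hold a minimal
product fail with `gene_too_short`); intron-containing genes must amplify
across the **last** exon–exon junction, with at least 18 bp of exon on
each side (`exon_too_short` otherwise). The amplicon is constrained to
100–250 bp on the spliced transcript.

The built-in engine scores every candidate oligo (lengths 18–27) by
penalty = |Tm − 60| + |len − 20| + |GC − 0.5|, with Tm from unified
nearest-neighbor thermodynamics (SantaLucia 1998 ΔH/ΔS, 50 mM Na⁺
entropic salt correction, 50 nM strand concentration) — verified against
an independent nearest-neighbor implementation to within 0.5 °C. Hard
windows: Tm 55–65 °C, GC 25–75%, homopolymers ≤5, no self-complementary
run ≥8 (hairpin/self-dimer proxy), pair Tm difference ≤3 °C. Pairs are
enumerated vectorized, deduplicated on (left_start, right_start), and
ranked 1..5 by ascending pair penalty (left + right + 0.5·|ΔTm|). The
search is fully deterministic; re-running a catalog is byte-identical.
All knobs live in `EngineParams` and are echoed into the catalog metadata.
An engine interface keeps the search pluggable; the optional external
Primer3 binding maps the same parameters onto the Primer3 global settings.

## Ct analysis

"Unreadable" (no amplification) is an explicit flag, never a sentinel
cycle number. Per gene: mean Ct over all readable values; SD only when ≥3
readable values exist; detected means **any** pair with Ct strictly below
30 (threshold configurable). The replicate-outlier rule operates on
linear-scale relative levels (helper: 2^(−ΔCt)): among three biological
replicates, drop the single value that differs from **both** others by
more than three-fold; any other pattern keeps all three. The
penalty-vs-detection comparison averages the engine pair penalties of
tested pairs within the detected and undetected gene groups.

## Synthetic generators

`simulate_expression` emulates a replicated circadian design — default
0–44 h every 2 h, 2 replicates, 3 courses, 22 h period — with four gene
classes: flat (σ = 0.05), cosine cyclers (amplitude 0.5, σ = 0.1),
linear trenders (0.02 log₁₀/h, σ = 0.1) and low-expressed genes (mean −3,
below the cutoff), at proportions 0.3/0.4/0.2/0.1 and baselines uniform
over 0–3 log₁₀ FPKM (the span typical of expressed genes). Noise is
Gaussian on the log scale — the scale on which the ANOVA and regression
operate. The planted recovery benchmark (`planted_reference_spec`) gives
ten flat genes tiny per-course noise SDs (0.004–0.06) in opposed orders
across courses so each is pareto-nondominated by construction.
`simulate_genome` plants genes of all three exon classes on both strands
with 40–60% GC and no homopolymer >6, which keeps ordinary design
feasible; `simulate_ct` makes Ct fall by log₂10 ≈ 3.32 cycles per decade
of expression with dropout probability rising in pair penalty and in Ct
above a soft ceiling. All generators are bit-reproducible under a fixed
seed and emit ground-truth sidecars.

What the generators do **not** emulate: library-size and length biases in
FPKM, heteroskedastic count noise at low expression, non-sinusoidal or
damping waveforms, batch effects between courses, primer-template
mispriming and amplification-efficiency differences. Passing tests
demonstrate correctness of the statistics and bookkeeping under the
model's assumptions, not robustness to those real-data features.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale inputs chosen to exercise
every code path while keeping the suite fast: 100–200-gene expression
panels, 1000-gene null panels for calibration, 8–50-gene genomes. The
recovery-by-consensus quantity is intrinsically stochastic: a truly flat
gene survives the ANOVA screen with probability 1 − α, so exact recovery
of all ten planted genes occurs in roughly half of seeds even with the
pooled screen; the acceptance script reports the realized counts.
Degenerate inputs are defined, not crashed on: zero-variance genes (ANOVA
P = 1, PIRS 0), zero PIRS spread (normalized to 0 with a warning),
zero-mean genes (RSD undefined, recorded reason), empty engine results
(failure reason, not an exception). Ties break by gene id everywhere a
ranking is emitted, which together with seeded RNG makes every command's
output byte-reproducible.
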