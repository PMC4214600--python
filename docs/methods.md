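# Methods

`shfgrn` re-implements, as a tested library, the integration analysis used to
nominate Hedgehog-dependent, GLI-bound target genes in the posterior second
heart field (pSHF) and the GLI + T-box co-regulated enhancer logic that follows
from it. The pipeline has five computational stages — differential-expression
signature construction, peak-to-gene annotation, set intersection with
Fisher-exact enrichment, consensus-motif co-occurrence scanning, and a seeded
synthetic-data generator that gives every stage a ground-truth test surface.

## Differential-expression signature

Input is a probes × samples matrix of raw array intensities for pooled
case (mutant) and control (wild-type) RNA samples, default design 4 vs 3.

**Probe filtering.** Three criteria, applied in order: (1) the probe passes
its QC flag on every array; (2) its cross-sample spread is in the top half of
all probes' spread — measured as the inter-quartile range of log2(x+1), so the
criterion reflects relative spread rather than brightness (the usual
convention for expression IQR filters; a raw-intensity IQR would silently
discard dim but genuinely differential probes); (3) the probe maps to an
annotated gene. The spread threshold is stored with the dataset and reused on
re-application, which makes the filter idempotent. Removed probes are
attributed to the first criterion they fail, so per-criterion counts sum to
the total removed.

**Normalization.** Each array is affinely calibrated so its median and IQR
match the across-array medians of those statistics, then transformed with the
generalized log `glog2(x) = log2(x + sqrt(x^2 + c^2)) − 1`, with `c` the 5th
percentile of the calibrated intensities. The transform is monotone per array,
tolerates background-subtracted values near zero, and approaches plain log2
for bright features, so large-intensity differences read as log2 ratios. This
is a deliberate simplification of full variance-stabilizing normalization: it
removes affine array effects and compresses low-intensity variance without the
maximum-likelihood per-array fit.

**Moderated statistic.** Per probe, `d = (mean_case − mean_ctrl)/(s + s0)`
with `s` the pooled two-sample standard error and `s0` the exchangeability
("fudge") factor chosen from the quantiles of `s` to minimize the coefficient
of variation of the median |d| across windows of `s` — the standard SAM
recipe. With `s0 = 0`, `d` is exactly the classical pooled two-sample t
statistic (tested against `scipy.stats.ttest_ind`).

**Permutation null.** Group labels are permuted over distinct case/control
assignments. With 4 vs 3 samples there are only C(7,4) = 35 distinct splits,
fewer than the default 100 permutations, so the null is enumerated exactly;
larger designs sample assignments without replacement. Two quantities come
out of the null:

- `perm_p`: the pooled permutation p — the fraction of all permuted |d*|
  values (all probes × all assignments) at or above the observed |d|.
- `q`: a SAM-style permutation FDR. At each observed |d| threshold, the
  false-call estimate is the **median** over label assignments of the number
  of permuted |d*| beyond the threshold, scaled by a null-proportion estimate
  π0 (fraction of observed d inside the central 50% of the permuted d
  distribution), divided by the observed call count; q is the minimum FDR over
  all thresholds at least as strict. The median is essential with few distinct
  permutations: the single truth-aligned assignment reproduces the observed
  statistics and floors any *pooled* tail estimate at ~1/35, which would make
  Q ≤ 0.005 unattainable for every gene regardless of effect size. The median
  over 35 assignments is immune to that one aligned split. A Storey estimator
  over p-values (`storey_qvalues`, BH fallback when π0 is unstable) is kept as
  a utility but is not the signature Q-value for exactly this reason.

**Gene collapsing.** Statistics are computed per probe; a gene inherits the
probe with the largest |d| (probes map ~1.3-to-1 onto genes, mirroring the
array's probe/gene ratio). Fold change is the linear case/control ratio of
raw group means, not back-transformed normalized values.

**Selection.** The signature keeps genes with q ≤ 0.005 and linear fold
change ≥ 2 or ≤ 0.5, recording direction. The stringent candidate filter
additionally requires a two-sided exact rank-sum p < 0.15, a permutation-t
FDR < 0.1 (same null machinery applied to the unmoderated t), and |FC| > 3,
sorted by |log2FC|. Tightening any threshold can only shrink the selection
(q is monotone-enforced in |d|).

**Clustering and gene sets.** Sample clustering is average-linkage
agglomerative clustering on Euclidean distances between sample columns
restricted to a gene list, cut at two groups. Gene-set over-representation is
the one-sided hypergeometric tail with BH adjustment across sets.

## Peak-to-gene annotation

Peaks are BED-style 0-based half-open intervals. A peak's distance anchor is
its midpoint (the summit when provided). Annotation follows the
window-plus-nearest rule for distal regulatory elements: link the peak to
every TSS within 100 kbp (default) on its chromosome; when none is that
close, link to the nearest TSS on the same chromosome, with all equidistant
genes linked in gene-id order. Link distances are reported signed, positive
downstream of the TSS in gene orientation; the window test itself is
unsigned. Location classification uses promoter > intragenic-proxy >
intergenic precedence, with the gene body proxied by 30 kbp downstream of the
TSS (full gene models are out of scope). Annotation is validated against an
exhaustive all-pairs oracle, and is translation-invariant by construction.

## Enrichment engine

All enrichment questions reduce to a 2×2 table over an explicit universe
(never inferred silently; the published analysis used ≈22,000 mouse genes).
The odds ratio is the unconditional cross-product `a·d/(b·c)` — this is what
reproduces the printed 1.4 from the printed 112/3296/560/22,000 counts — with
∞/0/NaN markers for empty cells and an optional Haldane correction. The
p-value is the exact Fisher p: two-sided (sum of table probabilities at or
below the observed table's) for phenotype tables, one-sided
over-representation for enrichment tests; sidedness is recorded in every
result. The implementation is checked against an independent fixed-margin
enumeration built from binomial coefficients.

The synergy index for reporter fold inductions is descriptive
super-additivity: `excess = fold_ab − (fold_a + fold_b − 1)`; it is not a
hypothesis test.

## Motif scanning and co-occurrence

Motifs are IUPAC consensus strings matched by per-position set membership
with a mismatch budget; an `N` in the sequence never matches. Built-ins: the
ChIP-derived GLI 12-mer `CGTGGGTGGTCC` (default budget 2 — the published
Foxf1a GLI site itself differs from the consensus at two positions on the
minus strand) and the canonical T-box 8-mer `AGGTGTGG` (exact). Minus-strand
hits are reported in plus-strand coordinates. Heterotypic sites are paired by
edge-to-edge gap under half-open coordinates (overlap → 0); the default
pairing window is 50 bp, since the published site pair itself sits 32 bp
apart edge-to-edge and the "within ~30 bp" phrasing has no stated convention.
Known-motif enrichment tabulates per-sequence presence/absence against a
supplied background or a per-sequence Altschul–Erickson dinucleotide shuffle,
and feeds the Fisher engine. Scanning and pairing are validated against naive
sliding-window and all-pairs oracles and satisfy strand symmetry (scanning a
reverse complement mirrors the site list).

## Synthetic data

The generator emulates the *shape* of the study's deposited data, not its
content: a TSS-annotated genome, pooled case/control arrays, TF-binding peak
sets, and enhancer sequences.

- **Genome** — chromosomes of equal length with uniformly placed TSSs at a
  minimum spacing (default 5 kbp), random strands, and independent Bernoulli
  family labels. Pipeline default: 2 × 100 Mbp with 2,000 genes, i.e. mouse
  gene density (~1 gene/100 kbp) at one-tenth genome size.
- **Expression** — log-normal intensities: log2 intensity = probe baseline
  N(8, 1.5) + planted log2FC (case columns) + per-array scale jitter N(0,
  0.1) + noise N(0, 0.25). The jitter gives the normalization stage a real
  effect to remove. Planted |log2FC| is uniform in [2, 3] (default 50 down,
  25 up), matching the signature's fold-change threshold regime. Probes map
  1.3-to-1 onto genes; 5% of probes are unannotated; QC-fail flags are
  injected at 0.2% per feature-array (a realistic outlier-flag rate — the
  all-arrays-pass rule amplifies anything larger into substantial probe
  loss).
- **Peaks** — a requested fraction (pipeline default 2/3 of 150) placed with
  midpoints within 50 kbp of planted down-regulated genes' TSSs, cycling
  through the target list so every target receives a peak; the rest uniform.
- **Sequences** — i.i.d. uniform ACGT backgrounds (a GC knob exists but is
  off) with an exact GLI-consensus + 30 bp + T-box cassette planted on a
  random strand at a random offset, coordinates recorded in the truth.

What this does **not** model: background-dominated dim probes, probe-specific
affinity, correlated biological variation between pools, fragment-level ChIP
coverage, sequence conservation, and real genomic base composition. Passing
recovery tests therefore demonstrate that the code implements the intended
statistics and rules, not that the thresholds would behave identically on
real arrays.

## Numerical choices and degenerate inputs

- Flat probes (zero pooled SE and zero difference) get d = 0; a zero SE with
  a non-zero difference maps to a large finite value of the right sign.
- All-equal datasets give d = 0 and q = 1 everywhere; empty signatures are
  legal throughout (enrichment of an empty set is a valid 2×2 table).
- Ties in nearest-TSS fallback link all equidistant genes, ordered by gene
  id; ordering of scanner/pairing output is fully specified (start, strand;
  seq, gap) so runs are reproducible byte-for-byte.
- Every stochastic routine takes an explicit seed; the pipeline derives
  per-stage seeds from the master seed with a fixed affine map mod 2^31 and
  stamps the config hash into the report, making reruns byte-identical.

## Problem sizes

The shipped defaults (2,000-gene genome, 150 peaks, 100 enhancer sequences,
35 enumerated permutations; 300-gene genomes for replicated null studies)
were chosen so that a full pipeline run takes ~1 s and the replicated
validity studies run in seconds while leaving planted/chance structure
clearly separable. All sizes are plain config values and scale up directly.

## Known limitations

- The glog calibration is a simplification of full VSN (no ML per-array
  variance fit); with strongly nonlinear array effects the affine step is
  incomplete.
- The permutation FDR is granular at small designs (35 splits), so q-values
  below ~1e-3 reflect the monotone envelope rather than resolved tail mass.
- `intragenic-proxy` classification uses a fixed downstream window, not real
  gene bodies.
- Consensus scanning is set-membership, not a weight matrix; information
  content differences between site positions are ignored.
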