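# shfgrn

Gene-regulatory-network integration for the second heart field (SHF): a
tested re-implementation of the analysis pattern that identifies
Hedgehog-dependent, GLI-bound target genes from paired transcriptional
profiling and transcription-factor ChIP data, and nominates enhancers
carrying adjacent GLI and T-box binding sites.

It is written for computational biologists who want the individual stages —
differential-expression signature construction, peak-to-gene annotation,
Fisher-exact enrichment, consensus-motif co-occurrence — as composable,
seeded, unit-tested functions rather than a one-off analysis script, with a
synthetic-data generator that plants known structure so every stage can be
scored against ground truth.

## The method

1. **Signature.** Pooled mutant vs wild-type array intensities (default 4 vs
   3) are QC/spread/annotation filtered, calibrated per array, and
   glog-transformed. Per gene, a moderated statistic

   d = (x̄_case − x̄_ctrl) / (s + s₀)

   is referenced to a permutation null over distinct group-label assignments
   (enumerated exactly when there are fewer than the requested permutations —
   C(7,4) = 35 for the default design). The signature keeps genes with
   permutation FDR q ≤ 0.005 and linear fold change ≥ 2 (or ≤ ½).

2. **Annotation.** Binding peaks are linked to every TSS within 100 kbp on
   the same chromosome, or to the nearest TSS when none is that close —
   the standard rule for assigning distal regulatory elements to genes.

3. **Integration.** The signature is intersected with the bound-gene set and
   every enrichment question is answered by a 2×2 Fisher-exact engine over an
   explicit gene universe, reporting the cross-product odds ratio
   OR = a·d/(b·c) and the exact p, with recorded sidedness. A descriptive
   super-additivity index summarizes reporter-assay synergy.

4. **Motifs.** Sequences are scanned for IUPAC consensus sites with a
   mismatch budget — built-ins `GLI` (CGTGGGTGGTCC, ≤2 mismatches) and `TBX`
   (AGGTGTGG, exact) — and heterotypic sites are paired by edge-to-edge gap
   (default window 50 bp), the operation that flags candidate co-regulated
   enhancers.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the full synthetic pipeline (2,000-gene genome, 75 planted
differentially expressed genes, 150 peaks of which 100 sit near planted
down-regulated genes, enhancer sequences carrying a planted GLI+TBX pair):

```python
from shfgrn.pipeline import run_all
report = run_all({"seed": 7})
```

Selected report fields from this exact call:

```
expression:  signature_size 73   s0 0.458   n_permutations 35
annotate:    391 links, 253 bound genes (388 window / 3 nearest)
integrate:   50 target genes via 99 peaks
             cotarget recall 0.98, precision 0.98
             signature-vs-bound enrichment: a=50 b=23 c=203 d=1724 (N=2000)
             OR = 18.5, one-sided Fisher p = 6.2e-30
motifs:      105 GLI sites, 100 TBX sites, 102 pairs; planted-pair recall 1.0
```

Reading: of the 75 planted DE genes, 73 were recovered in the signature; the
50 planted peak-linked down-regulated genes intersect the signature almost
perfectly (recall/precision 0.98), and the signature is massively enriched
among peak-annotated genes — the synthetic analogue of the bound-vs-dependent
enrichment the method is designed to detect. All 100 planted GLI+TBX site
pairs are recovered at their recorded coordinates.

The same stages are available from the shell:

```bash
shfgrn run --config cfg.yaml --out out/
shfgrn annotate --peaks peaks.bed --genes genes.tsv --window 100000 --out links.tsv
shfgrn motifs pairs --fasta seqs.fa --motif-a GLI --motif-b TBX --max-gap 50 --out pairs.tsv
```

Desk-scale calls on published summary counts:

```python
import shfgrn as s
s.enrichment_fet_counts(112, 3296, 560, 22_000).odds_ratio   # 1.433... -> 1.4
s.fet_2x2(3, 0, 0, 4, sidedness="two").p_value               # 0.02857  -> 0.03
s.synergy_index(91.9, 3.9, 171.6)                            # excess 76.8, super-additive
```

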