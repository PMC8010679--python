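# retroatlas

Tools for three recurring analyses in plant genome and transcriptome
projects, built around the common buckwheat (*Fagopyrum esculentum*) use
case of explaining genome-size divergence through transposable-element
activity and building an organ/stage expression atlas:

1. **LTR retroelement insertion dating.** The two long terminal repeats
   (LTRs) of a retroelement are identical when it inserts and then diverge
   neutrally. For each full-length element (one carrying GAG, RT, RH, AP
   and INT protein domains) the package aligns the 5′ and 3′ LTRs, counts
   transition (p) and transversion (q) frequencies, computes the Kimura
   two-parameter distance

   K = −½ · ln[(1 − 2p − q) · √(1 − 2q)]

   and dates the insertion as T = K / (2r) with r = 1.3 × 10⁻⁸
   substitutions·site⁻¹·year⁻¹ by default. Elements younger than 0.5 My are
   "recent"; two genomes' recent/old counts are contrasted with an exact
   two-sided Fisher test, and per-family copy numbers and cumulative age
   curves summarise the dynamics.

2. **Transcriptome-atlas statistics.** Gene-level read-count tables
   (2 biological replicates per sample) are normalised with the DESeq
   median-of-ratios size factors; genes are called expressed at a
   normalised count ≥ 5 in *both* replicates; expression breadth is the
   Shannon entropy H = −Σ pₛ log₂ pₛ of the replicate-averaged profile;
   stability is SD/mean for reference-gene selection; samples are clustered
   on the distance 1 − r² (Pearson) with UPGMA.

3. **Evidence-ranked gene-model selection.** Pooled candidates from several
   predictors are scored (bonus per RNA-seq-supported intron/exon, homology
   bonus weighted Arabidopsis > SwissProt > nr and scaled by hit
   significance, large negative repeat/TE penalties) and a non-overlapping
   annotation is assembled greedily, best score first.

Each stage has a synthetic-data generator with recorded ground truth
(LTR pairs diverged under a two-parameter substitution process with known
ages, negative-binomial count matrices with planted broad / specific /
stable / silent genes and unequal library sizes, candidate pools with
designated dominant-evidence winners), so every estimator can be validated
by round-trip recovery without any external downloads.

## Worked example

Simulate two small genomes that differ in recent retroelement activity and
contrast them:

```bash
retroatlas simulate-ltrs --n-elements 40 --ltr-length 120 \
    --recent-fraction 0.6 --seed 1 --out /tmp/a
retroatlas simulate-ltrs --n-elements 40 --ltr-length 120 \
    --recent-fraction 0.1 --seed 2 --out /tmp/b
retroatlas compare-genomes --a-gff /tmp/a.gff3 --a-fasta /tmp/a.fasta \
    --b-gff /tmp/b.gff3 --b-fasta /tmp/b.fasta --out /tmp/cmp
```

prints

```
Fisher exact p = 0.000254
```

and `/tmp/cmp.contingency.tsv` holds the 2×2 table behind it — 21/40
elements dated younger than 0.5 My in genome A against 5/40 in genome B
(recent fractions 0.53 vs 0.13, near the planted 0.6 / 0.1; the drift is
estimation noise on 120 bp LTRs):

```
genome  recent  old  recent_fraction  fisher_p
A       21      19   0.525            0.000254108052640539
B       5      35    0.125            0.000254108052640539
```

The atlas stage runs the same way from a count table
(`retroatlas atlas-stats --counts counts.tsv --out prefix`), and
`retroatlas rank-models --gff candidates.gff3 --out prefix` scores and
selects gene models. Every command is a thin wrapper over the importable
modules `retroatlas.ltr_dating`, `retroatlas.expression_atlas`,
`retroatlas.annotation_ranker` and `retroatlas.synthetic_data`.

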