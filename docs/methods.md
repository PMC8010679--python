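# Methods

## LTR insertion dating

**Model.** A long-terminal-repeat (LTR) retroelement inserts with two
identical LTRs; afterwards each copy accumulates substitutions
independently and neutrally at a constant per-year rate r. The pairwise
divergence of the two LTRs therefore grows at 2r per site per year, and the
insertion age is T = K / (2r), where K is the substitution distance between
the LTRs. K is the Kimura two-parameter (K2P) distance

    K = -1/2 · ln[(1 - 2p - q) · sqrt(1 - 2q)]

with p and q the transition and transversion frequencies over compared
alignment columns. Assumptions: no gene conversion between LTRs, no
selection on LTR sequence, a clock-like rate shared by all elements, and
substitution saturation below the K2P validity boundary (1 − 2p − q > 0 and
1 − 2q > 0). Pairs beyond that boundary are flagged "saturated", carry an
undefined age, and are counted in an undatable tally rather than dropped
silently.

**Parameters.** r defaults to 1.3 × 10⁻⁸ substitutions·site⁻¹·year⁻¹, the
standard plant LTR-dating rate; the recency cutoff defaults to 5 × 10⁵
years, with the boundary age itself classified *old* (strict T < cutoff; an
exact-threshold guard keeps float round-off from flipping the
classification). Only full-length elements — domain evidence for all of
GAG, RT, RH, AP, INT — are dated, since truncated elements may be
recombination products whose LTR divergence no longer reflects the
insertion.

**Alignment.** 5′ and 3′ LTRs are aligned end-to-end (global, affine gaps;
defaults match +2, mismatch −1, gap open −5, gap extend −1, configurable)
with Biopython's pairwise aligner; among co-optimal alignments the
aligner's deterministic first traceback is used. Columns are typed as
match / transition / transversion / gap / ambiguous (N); gap and ambiguous
columns are pairwise-deleted before p and q are estimated. A brute-force
enumeration oracle over all alignments of short sequences checks the
optimal score in the test suite.

**Fisher exact test.** The two-genome recent/old contrast uses an exact
two-sided Fisher test implemented by enumerating the full hypergeometric
support at fixed margins and summing the probabilities of tables whose
point probability is at most that of the observed table, within relative
tolerance 1 × 10⁻⁷ (the minimum-likelihood convention of R's
`fisher.test`). Tests verify exhaustive agreement with an independent
exact-integer enumeration for every table with N ≤ 30 and with
`scipy.stats.fisher_exact` on random tables. Degenerate margins (an empty
row or column) admit only one table and return p = 1.

**Repeatome renormalisation.** Read-clustering summaries may contain
organelle-derived clusters; these are removed and each remaining cluster's
genome fraction is recomputed against the reduced read total before
aggregation by annotation label.

## Synthetic LTR libraries

The generator draws one ancestral LTR per element (uniform base
composition; GC bias out of scope) and mutates the two copies independently
under the exact closed-form K2P site probabilities at branch length
d = r · age — no per-generation iteration, so the simulated process is
precisely the model the estimator inverts, and ages are recovered by
round-trip. The transition/transversion *rate* ratio kappa defaults to 2.0,
a typical plant nuclear value; it is a free simulation parameter, not an
estimated quantity. Indels are not simulated by default (the distance uses
substitutions only); an optional injector adds indels at a stated per-site
rate to exercise gap handling. Age samplers include uniform ranges and a
two-class sampler that plants a known fraction of ages below the recency
cutoff. Elements are embedded in a single contig with random spacers and
internal regions, annotated with 1-based inclusive GFF3
(`LTR_retrotransposon` with two `long_terminal_repeat` children; `ID`,
`Family`, `Complete`, `Domains` attributes). All randomness flows from one
integer seed per call; re-runs are byte-identical.

Problem sizes used in validation: 200 pairs × 1,000 bp per true age for age
recovery (0.1–5 My); 1,000 elements per genome × 300 bp LTRs for the
recency-contrast power sweep (50 replicate simulations); 2,000 elements for
recent-fraction recovery. These sizes give binomial/standard-error margins
comfortably inside the 5% recovery and p < 10⁻⁶ power checks while keeping
a full run to a few minutes on one core.

## Count-matrix simulation and atlas statistics

The generator emulates an organ/stage atlas: 46 samples × 2 replicates by
default, negative-binomial counts (gamma–Poisson, dispersion 0.05) around
class-determined means scaled by per-column library size factors (log-normal,
sd 0.3, geometric mean 1). Planted classes: *broad* (base mean 100, per-sample
log-normal jitter sd 0.4), *specific* (mean 400 in one sample, zero
elsewhere), *stable* (constant mean 200), *silent* (all zero), at fractions
0.6 / 0.2 / 0.1 / 0.1. The broad-gene jitter of 0.4 keeps the typical gene
close to non-differential — the regime the median-of-ratios estimator
assumes — so planted size factors are recoverable to a few percent; real
atlases show larger fold changes, heavier-tailed dispersion and correlated
samples, so passing recovery tests here demonstrates estimator correctness
under model assumptions, not robustness to everything field data can do.

**Size factors** follow the DESeq median-of-ratios definition: per-gene
reference = geometric mean across columns over genes positive everywhere;
column factor = median ratio to the reference. If no gene is positive in
every column the estimator refuses (no pseudo-reference fallback) rather
than silently switching method. Note the estimator's conservation laws:
scaling *all* counts by c cancels (factors invariant, normalised values
scale by c — every downstream ratio-based statistic is unchanged), while
scaling one library by c multiplies its factor relative to any other
column by exactly c.

**Expressed calls** use normalised count ≥ 5 in both replicates of a sample
(inclusive threshold). **Breadth** is Shannon entropy (log base 2,
0·log 0 = 0) of the replicate-averaged profile renormalised over samples;
all-zero genes are NA, not 0. **Stability** is SD/mean on
replicate-averaged sample values with population SD (divisor n) by default;
both the ddof and the replicate-averaging are configurable, since the
descriptive convention varies between groups. Zero-mean genes are excluded
and flagged. **Sample distance** is 1 − r² on replicate-averaged profiles;
zero-variance samples are an error (correlation undefined). **Clustering**
is agglomerative with UPGMA by default (heights then ultrametric), emitted
as newick via scikit-bio. Differential-expression testing is deliberately
out of scope; the conventional fold-change ≥ 2 / FDR < 0.05 configuration
is recorded only for provenance.

## Gene-model scoring and selection

Score = b·(supported introns + supported exons) + Σ tier-weight ×
significance over homology hits + repeat penalty + TE penalty. Published
descriptions of such schemes fix only the signs and the tier ordering
(Arabidopsis > SwissProt > nr); the magnitudes here (b = 1, tiers 10/5/2,
penalties −100) are configuration with those constraints enforced at
construction. Hit significance is any non-negative score; a helper maps
blastp e-values to min(1, −log₁₀ e / 20). Selection is greedy best-first:
ties broken by longer span then lexicographic id (input-order invariant);
overlap means ≥ 1 shared base on the same contig *and strand* —
opposite-strand overlap is allowed, a choice that favours keeping nested
antisense genes. The rejection log names the blocking accepted model, so
every exclusion is auditable. The candidate simulator's default evidence
rates are the dominant-evidence regime (winner: all bonuses; decoys: all
penalties), under which a correct implementation must recover every
planted winner; softer rates are configurable for robustness exploration.

## Numerical and degenerate-input choices

- K2P saturation is flagged, never clamped; NaN ages propagate to an
  explicit undatable count.
- Exact-threshold insertion ages (T = cutoff) are old; a relative
  tolerance of 10⁻¹² absorbs float round-off in T = K/(2r).
- Fisher point-probability comparison uses relative slack 10⁻⁷, matching
  the convention of the reference implementations it is tested against.
- Entropy and stability are undefined (NA / excluded) for all-zero genes
  rather than coerced to 0.
- The distance matrix is symmetrised against float noise (≤ 10⁻¹⁰) before
  linkage; genuinely asymmetric input is an error.

## Known limitations

- No solo-LTR or nested/fragmented element modelling; the genome simulator
  lays elements out linearly without TE nesting.
- The aligner dates well-conserved LTR pairs; at divergences approaching
  saturation the global alignment itself becomes unreliable before the
  distance does.
- The count simulator does not model batch effects, sample correlation
  structure, or gene length bias.
- Family labels are consumed as input; classification is out of scope.
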