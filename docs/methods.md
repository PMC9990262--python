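# Methods

This note documents the statistical models and numerical conventions behind
`rkit`, the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Coordinates and interval semantics

All coordinates inside the package are 0-based half-open (BED convention);
conversion happens only at parse/serialize boundaries (e.g. wiggle export is
1-based as its format requires). Two regions *overlap* when they share at
least one base pair; abutting half-open intervals ([0,10) and [10,20)) do not
overlap but are fused by `merge`, since they cover a contiguous base-pair
set. Chromosomes sort lexicographically (`chr10 < chr2`) for determinism; a
natural-order key is provided but never applied implicitly, and chromosome
names are matched by exact string equality (a `chr` prefixing helper is
opt-in). Strand is ignored by the set algebra except where an explicit
`strand_aware` flag exists (extension, profile aggregation).

The algebra is implemented as sorted sweeps and binary searches over
per-chromosome endpoint arrays. At the region counts this package targets
(10^4–10^5 intervals) this is entirely adequate; no interval-tree structure
is used. Every operation is validated against an independent per-basepair
boolean-bitmap implementation on randomized instances in the test suite.

Midpoint-centered extension collapses a region to a zero-width anchor at
`floor((start+end)/2)` and produces `[mid-left, mid+right)`, so a symmetric
window has width exactly `left+right`. This keeps profile-matrix windows at
width `2*window` and makes bin counts independent of the source region's
parity.

## Signal model

`coverage` replaces each read by `[5'end, 5'end+extension)` on its strand
(extension 0 keeps the read's own interval) and counts a read in every bin
window it overlaps by ≥ 1 bp. Bin windows are `[start + i*step,
start + i*step + bin)`; a region narrower than one bin gets a single bin.
Counting is done with two `searchsorted` calls per region on the sorted
extended start/end arrays (`#(starts < window_end) − #(ends ≤ window_start)`),
which is exact for interval/window overlap.

The preprocessing utilities are the simplest standard constructions for
their tasks, and are documented as this package's own choices:

* **Fragment-size estimation** — Pearson cross-correlation between the
  plus-strand and minus-strand 5′-end profiles on 10 bp bins, maximized over
  shifts 0…400 bp; ties break toward the smallest shift. The 10 bp bin
  matches typical ChIP fragment-length resolution; estimates are multiples
  of the bin size.
* **Smoothing** — centered moving average with an odd window; edge bins use
  truncated windows, so interior mass is preserved but edge mass is not.
* **Library normalization** — counts-per-million: values scaled by
  `target/total_reads`, target 10^6.
* **Input-DNA correction** — `max(0, treat − control · treat_total/control_total)`
  per bin; the floor at zero keeps tracks non-negative for downstream Poisson
  reasoning.
* **GC correction** — bins are stratified into GC-fraction deciles (quantile
  strata over the track's own bins, N bases excluded from the GC
  denominator, all-N bins left alone) and each stratum is rescaled by
  `global_mean/stratum_mean`; empty or zero-mean strata are left unscaled.

The demo peak caller is deliberately minimal: genome-wide non-overlapping
bins, one global Poisson rate λ = mean bin count, a bin is significant when
`P(X ≥ k; λ) < α` (default α = 10⁻⁵), adjacent significant bins merge, and a
peak is scored `−log10(min p)`. One global λ means locally elevated
background (e.g. copy-number gain) will produce false peaks; that is the
accepted price of a tutorial-scope caller.

## Region-association tests

All four tests consume plain BED-style region sets. Empirical p-values use
the add-one rule `p = (1 + #{null ≥ observed}) / (1 + n_perm)`, so the
smallest achievable p is `1/(n_perm+1)` and identical seeds reproduce
identical p-values bit for bit.

* **Projection test.** With `q` = fraction of the genome covered by the
  merged reference, `n` = number of query regions and `k` = number of query
  regions overlapping the reference (original, unmerged regions — the count
  must match the `n` denominator), the p-value is the exact upper binomial
  tail `P(X ≥ k)`, `X ~ Bin(n, q)`. A reference covering the whole genome
  gives `q = 1, k = n, p = 1`.
* **Intersection test.** Observed statistic: number of a-regions overlapping
  b. Null: pool all regions of a and b, repartition uniformly at random into
  pseudo-sets of the original sizes, recount. This *relabelling* null keeps
  every interval where it is and destroys only set membership. Note the
  statistic is asymmetric (count on the first argument); the test has most
  power when the first argument is the set whose members are expected to lie
  inside the second.
* **Combinatorial test.** Contingency table `C[i][j]` = number of regions of
  query j overlapping reference i (a region overlapping several references
  counts toward each); Pearson χ² of homogeneity without continuity
  correction, dof = (R−1)(Q−1). All-zero rows/columns are dropped with a
  warning; fewer than two nonzero rows or columns is an error.
* **Jaccard test.** `J = bp(a ∩ b) / bp(a ∪ b)`, symmetric by construction.
  Null: b is relocated uniformly on the genome (same region count, lengths
  resampled from b's lengths) `n_perm` times — a *positional* null.

The two permutation tests deliberately use different nulls (relabelling vs
relocation): relabelling preserves the pooled positional structure and asks
whether membership matters; relocation asks whether position matters.

**Calibration and its limits.** Both permutation tests are exactly valid by
exchangeability, but their p-values are discrete: when the statistic is
heavily tied (very sparse region sets where observed overlap counts are
0–2), rejection rates at nominal α fall well below α. The calibration
experiments in the test suite therefore use sets dense enough for the
statistic to take many values (50 regions of 500 bp on a 100 kb chromosome),
where the type-I error at α = 0.05 is within 3 Monte-Carlo SE of nominal
over 200 datasets × 199 permutations. Users testing very sparse sets should
expect conservative p-values, not anti-conservative ones.

## Aggregation matrices

`profile_matrix` anchors every region at its midpoint, extends ±`window`,
and stacks per-region binned coverage; with `strand_aware`, rows of
minus-strand regions are reversed so 5′→3′ reads left to right. Bin offsets
are reported relative to the region center (center = 0), so matrices from
different window sizes align. Heatmap rows are ordered by total signal
descending; the lineplot shows the column mean with a ±1 SE band; the
boxplot shows per-region read counts per library, optionally CPM-normalized.

## Motif model

A motif's PWM is the log2-odds matrix

    pwm[b][j] = log2( (counts[b][j] + pc·bg[b]) / (col_total[j] + pc) / bg[b] )

with pseudocount `pc = 1.0` distributed by the background frequencies and a
uniform default background — both user-overridable. Scores are in bits; a
window scores the sum of its per-position entries, and the minus strand is
scored with the reverse-complemented matrix so coordinates stay on the
forward strand.

**Exact threshold calibration.** The background score distribution of a
random sequence of motif length is computed exactly: each column's four
scores are discretized to a 0.01-bit grid by *flooring*, and the per-column
4-outcome distributions are convolved. The threshold for a target false
positive rate is the smallest grid score whose upper tail mass is ≤ the
target (default 10⁻⁴; sensible range 10⁻⁵–10⁻³). When even the maximum
score has tail mass above the target (short or low-information motifs), the
returned threshold is one grid step past the maximum — no random sequence
can pass — and the result is flagged unreachable. Because the score support
can have gaps, the returned threshold may sit far below the maximum score
while excluding exactly the same sequences; the defining property is
`tail(t) ≤ fpr < tail(t − step)` whenever the threshold is reachable.

**Lattice match decisions.** Scanning makes the match decision on the same
discretized grid the threshold was calibrated on (window grid-score ≥
threshold), while reporting the exact bit score (always ≥ the grid score).
This makes the probability that a random background window matches equal the
calibrated tail mass *exactly*. Comparing exact scores against the
grid-calibrated threshold instead would re-admit score tiers the calibration
excluded — per-column flooring shifts window sums by up to L·0.01 bits — and
inflate the realized FPR above the target. Windows containing N are never
matched.

**Enrichment.** All three modes reduce to a per-motif 2×2 table — target
regions with/without ≥ 1 hit vs background regions with/without — tested
one-sided in the enrichment direction with Fisher's exact test
(hypergeometric upper tail) and corrected across the motif set by
Benjamini–Hochberg. Hits are counted per region (binary), not summed.
The three background constructions:

1. *Input vs background*: user-provided background, or `max(|target|, 1000)`
   random regions with lengths resampled from the target (seeded);
2. *Gene-associated vs rest*: regions are associated to genes via promoter
   window (default 1 kb upstream of the TSS, strand-aware), gene body, or
   distal proximity (default 50 kb); nearest gene wins, ties to the smallest
   gene id; target = regions associated with the genes of interest;
3. *Promoters of listed genes vs promoters of all other genes*.

Rows are sorted by adjusted p, then raw p, then motif id; output is a TSV
plus an HTML table with identical content.

## Synthetic data

The fixture generators emulate exactly the features the statistics consume:

* genomes are i.i.d. bases at a target GC (default 0.5), with planted motif
  consensus sequences overwritten at chosen loci (reverse-complemented for
  minus-strand plants);
* reads are Poisson-thinned uniform fragment starts (default 0.01 fragments
  per bp) with per-peak rate multipliers, fixed fragment length (200 bp) and
  a fixed 50 bp read taken from the fragment's 5′ end on a random strand;
* paired region sets place a controlled expected fraction of one set's
  regions overlapping the other (jittered copies vs rejection-sampled
  placements).

They do **not** emulate mappability variation, GC-dependent amplification,
PCR duplicates, chromatin-structure covariance between nearby sites, or
sequencing error. Tests passing on these fixtures therefore demonstrate the
correctness of the computations and the calibration of the statistics under
their stated assumptions — not robustness to real-data artifacts.

Problem sizes used by the validation suite (chosen to exercise each property
at meaningful scale): 500 randomized interval-algebra instances on ≤ 5 kb
genomes; 4^L enumeration oracles for motifs up to length 8; 200 datasets ×
199 permutations for type-I calibration; 100 planted 500 bp peaks at 10×
enrichment on a 2 Mb genome; 200 planted consensus sites on a 201 kb genome.

## Known limitations

* Single-end read semantics; properly-paired mates are not fragment-merged.
* The combinatorial test implements the plain R×Q homogeneity table; no
  per-reference background reweighting.
* The demo peak caller's single global λ ignores local background variation.
* `random_regions` rejects and redraws against `forbid` (1000 attempts per
  region), which biases placement slightly toward uncluttered chromosomes
  when the forbidden set is large.
* Fisher enrichment treats regions as independent; overlapping target
  regions double-count hits.
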