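# Methods

`promotif` infers candidate cis-regulatory motifs shared by a list of
co-responding genes — the setting it was built for is nitrogen-responsive
genes in a crop genome, but nothing in the code is crop-specific.  This
note records the models, the statistics, the tunable parameters and the
design choices, and what the synthetic benchmarks do and do not show.

## Pipeline overview

1. **DE consensus** — per-condition differential-expression tables
   (CuffDiff-style, one per cultivar x time point) are intersected into a
   single list of consistently over-expressed and one of consistently
   under-expressed genes.  A gene qualifies only if it is flagged
   significant, has q ≤ α (default α = 0.05) and the same fold-change
   sign in *every* grid cell.  Genes responding in all cultivars at
   exactly one time point are tallied separately and excluded.
2. **Upstream extraction** — the 1000 bp immediately 5′ of each gene's
   TSS, read on the gene's strand (minus-strand genes reverse
   complemented); the TSS base itself is never included.
3. **Background model** — word-frequency tables of orders 1..K (default
   K = 4) over *all* genes' upstream regions, single strand, windows
   containing N excluded.  Words longer than K get probabilities from the
   order-(K−1) Markov factorization
   p(w) = f(w₁..w_K) · ∏ᵢ f(wᵢ..wᵢ₊K₋₁)/f(wᵢ..wᵢ₊K₋₂).
4. **Subsample-ensemble discovery** — engines run on many small random
   promoter subsets (defaults 5000 subsets of 10, drawn independently,
   without replacement within a subset), separately for the over- and
   under-expressed lists.
5. **Redundancy clustering** — pooled motifs clustered by PAM k-medoids
   under the inter-motif distance; each cluster represented by its
   position-wise average PWM.
6. **Mapping and annotation** — cluster averages scanned against the
   regions on both strands, instances laid out TSS-relative, and matched
   against a flat-file IUPAC consensus database.

## Discovery engines and their statistics

All engines enumerate plain-base words of widths 6–8 (the minimum motif
width is fixed at 6 bp), search both strands, and collapse a word with its
reverse complement into one canonical entry (the lexicographically smaller
of the pair; a palindrome's two orientations at one offset count once).

For a canonical word w in a subset of n regions of length L, the statistic
is the number of regions containing at least one match (`seq_hits`).
Under the background, one window matches with probability
p_w = p(w) + p(rc(w)) (p(w) alone for palindromes), a region contains ≥ 1
match with probability p₁ = 1 − (1 − p_w)^(L−|w|+1) (window-independence
approximation), and the p-value is the binomial upper tail
P(X ≥ seq_hits | n, p₁).  The approximation is validated against Monte
Carlo simulation in the test suite (50 000 simulated subsets, agreement
within 3 standard errors).

Three significance gates mirror the three roles classic tools play:

- `seed_qvalue` — Benjamini–Hochberg step-up over all candidates of one
  subset run; motifs with q ≤ 0.05 are significant.  PWMs are built from
  the word's actual matching instances (oriented to the canonical word)
  with pseudocount 0.1.
- `ranked_topk` — the five best candidates by p-value, ranks as scores;
  ties broken by width (point-mass information content) descending, then
  lexicographic word.
- `em_refine` — seeds from the top 20 candidates whose e-value-like score
  (seed p-value × number of candidates tested, a Bonferroni-style
  expected count) is ≤ 0.001; each seed PWM is refined by EM under a
  one-occurrence-per-sequence model (posterior over positions and strands
  proportional to the PWM/background likelihood ratio), capped at 20
  iterations or mean log-likelihood-ratio change < 1e−4.

Multiple-testing correction is applied within each subset run; the
ensemble relies on clustering, not on cross-subset correction, to absorb
the repeated testing of the same word across subsets.

## Why subsets help, and when they do not

A motif carried by 30 % of a 60-gene list gives ~18/60 sequence hits —
diluted, but a 10-promoter subset occasionally contains 6+ carriers, and
with 300 subsets such enriched draws are near-certain (P(Bin(10, 0.3) ≥ 6)
≈ 0.047, so ≈ 14 enriched subsets in 300).  Note that for the count-based
binomial gate used here a single pooled run is *also* very sensitive
(18/60 hits is an extreme binomial tail); the subsetting strategy is
essential specifically for tools whose objective assumes the motif is
present in most input sequences, which is the regime the ensemble driver
emulates and the regime in which it is used.

## Motif algebra

- PWM columns are probability distributions over (A, C, G, T); consensus
  rendering is three-tier: uppercase base when max p ≥ 0.7, lowercase
  two-base IUPAC code when the top two sum to ≥ 0.8, else `.` (thresholds
  chosen to reproduce the uppercase / lowercase-pair / dot notation used
  for degenerate plant motifs, e.g. `A.ATrGAC`; both configurable).
- The inter-motif distance is the minimum over all ungapped offsets with
  ≥ 4 overlapping columns and both orientations of the mean per-column
  Euclidean distance between column distributions.  It is symmetric,
  non-negative, zero for a motif and its reverse complement, and is
  checked against exhaustive enumeration.  A Pearson-based variant is
  provided for sensitivity analyses.  The underlying alignment search
  breaks distance ties toward longer overlaps, then the forward
  orientation — without this a trivial 4-column perfect overlap could
  displace a full-width perfect alignment during cluster averaging.
- k-medoids is PAM alternation (assign to nearest medoid; update medoid
  to the member minimizing within-cluster cost) with 10 random restarts;
  `k="auto"` sweeps k = 2..min(20, n−1) and keeps the best mean
  silhouette (ties → smallest k; all-zero distance matrices collapse to
  one cluster).  Medoids are pinned to their own clusters so zero-distance
  ties cannot orphan them.
- Cluster averages align every member to the medoid at its best
  offset/orientation, average columns over the members covering each
  position, drop positions covered by < 50 % of members (longest
  contiguous covered run kept), renormalize, and re-derive the consensus.

## Scanning and annotation

Scanning scores every window and strand by log₂ odds against the order-0
background and reports positions reaching ≥ 85 % (configurable) of the
motif's maximum achievable score; windows containing N are skipped.
Offsets are TSS-relative and negative (TSS at the right end, offset 0),
matching the instance-map layout; file exports use region-relative
BED-like coordinates.

Database matching is consensus-based: query and database IUPAC strings are
compared over all ungapped offsets with ≥ 4 overlapping positions and both
orientations; a position matches when the two codes' base sets intersect
(`.` matches anything); entries are ranked by mismatch count, ties by
database id.  `consensus_alignment_distance` extends this to a Hamming
distance between consensi of unequal widths by adding overhang positions
to the mismatch count (for equal widths at full overlap it is plain
Hamming distance).

## Synthetic data: what it emulates and what it does not

The generator produces (i) promoters sampled from the background model as
an order-(K−1) Markov chain; (ii) motif instances planted by overwriting
the background at non-overlapping uniform offsets (sequence length
unchanged, so mapping coordinates stay comparable), words drawn
column-wise from the motif, reverse-strand instances written as reverse
complements (strand probability 0.5 by default); (iii) DE grids in which
designated genes are significant with the designated sign in every cell,
timepoint-specific genes only in their cell's timepoint, and all other
genes get small symmetric log2FC noise (sd 0.2) and q uniform above α;
(iv) motif databases holding one single-substitution variant of each true
motif plus random decoys.  All generators are seed-deterministic and
return ground truth.

What passing the synthetic benchmarks does **not** show: real promoters
are not stationary Markov text (repeats, CpG-like composition gradients,
TATA-region structure), real motifs are degenerate rather than planted
words, real DE calls have correlated errors across conditions, and the
real analysis depends on a specific genome, annotation and RNA-seq data.
The study-scale headline counts (a 39-gene consensus, nine motif
clusters, specific instance totals) are therefore not reproducible at
desk scale, and the benchmarks instead check properties: recovery of
planted truth, calibration on null data, and equality with independent
oracles.

## Benchmark problem sizes

The planted-recovery benchmark uses 60 promoters of 1000 bp, an 8-bp
motif at 30 % prevalence, 300 subsets of 10 with the `seed_qvalue`
engine, 10 seeded replicates; null calibration uses 500 background-only
subsets of 10.  These sizes were chosen as the smallest at which the
ensemble's behaviour is unambiguous (enriched subsets near-certain, null
rate estimable to ~1 %).

## Degenerate inputs and numerical choices

- Upstream regions truncated by contig edges are kept when ≥ 50 bp,
  otherwise dropped with a warning; zero-length regions (TSS at the edge)
  are omitted.  Overlapping gene models are extracted independently.
- Genes absent from one DE table are treated as non-significant there
  (union-of-genes universe).
- A word with zero background probability but observed hits gets p = 0
  with a warning.
- Column sums are enforced to 1 ± 1e−9 at Motif construction; EM clips
  probabilities at 1e−12 before logs; scan log-odds floor background
  frequencies at 1e−9.
- All randomness flows from a single seed per entry point via
  `numpy.random.default_rng`; derived seeds are drawn below 2³¹.

## Known limitations

- Word enumeration is exhaustive over widths 6–8; wider motifs are found
  only via EM refinement seeded from their cores.
- No gapped/spaced motif model, no dinucleotide PWM, no repeat masking,
  no transcript-level TSS inference.
- The binomial statistic treats windows as independent; for highly
  self-overlapping words (poly-A runs) p₁ is slightly conservative.
- Database matching reports mismatch counts, not match significance.
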