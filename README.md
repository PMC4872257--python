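# promotif

Subsample-ensemble de novo discovery of shared promoter motifs in
co-responding gene lists, with differential-expression consensus
screening, k-medoids redundancy clustering, TSS-anchored motif mapping
and consensus-database annotation.

## The problem

Given a genome, its gene annotation, and per-condition differential-
expression tables for a grid of genotypes x time points (the motivating
study: potato cultivars under nitrogen supplementation), find the genes
that respond consistently in *every* condition, and ask whether their
1000 bp upstream flanking regions share cis-regulatory motifs.

Motif discovery tools that assume a motif occurs in most input sequences
miss motifs carried by a fraction of a gene list.  The ensemble strategy
implemented here runs discovery over thousands of small random promoter
subsets (default 5000 subsets of 10): a subset occasionally concentrates
the carriers enough for the motif to clear its significance gate.  The
price is massive redundancy — the same motif resurfaces across subsets —
which is resolved by clustering the pooled motifs with PAM k-medoids
under an offset/orientation-searching PWM distance and representing each
cluster by its position-wise average PWM.

## The statistic at the core

For a candidate word $w$ found in a subset of $n$ promoters of length
$L$, with background word probability $p_w$ (both strands, order-$(K{-}1)$
Markov model over all genes' upstream regions), the per-promoter match
probability is

$$p_1 = 1 - (1 - p_w)^{L - |w| + 1},$$

and the significance of observing the word in $s$ of the $n$ promoters is
the binomial upper tail $P(X \ge s \mid n, p_1)$.  Three engines gate
these scores the way the classic tools do: Benjamini–Hochberg q ≤ 0.05,
top-5 by rank, and EM-refined PWMs at an e-value-like score ≤ 0.001.
Minimum motif width is 6 bp; both strands are always searched.

## Worked example

Sixty synthetic 1 kb promoters from a uniform background, the 8-bp motif
`ACGTCAGT` planted in 30 % of them, 300 subsets of 10:

```python
from promotif import (EngineConfig, MotifDiscoveryModel, DatabaseMotif,
                      match_database, pwm_from_instances)
from promotif.synthetic import (PlantedMotifSpec, motif_from_consensus,
                                plant_motifs, sample_background_sequences,
                                uniform_background)

bg = uniform_background()
regions = sample_background_sequences(bg, 60, 1000, seed=11)
planted, truth = plant_motifs(regions, PlantedMotifSpec(
    motif_from_consensus("ACGTCAGT"), prevalence=0.3, seed=12))

model = MotifDiscoveryModel(planted, background=bg,
                            n_subsets=300, subset_size=10)
results = model.fit(seed=13)
print(results.summary().to_string(index=False))
```

```
 cluster  n_members medoid_consensus average_consensus  width  within_cost     engines
       0         22         AACGTCAG          ACGTCAGT      8     0.857381 seed_qvalue
       1          6         CTTAAGTC          AAkTC...      8     1.384953 seed_qvalue
       2          3         ACAGATAT          ACAGwTAT      8     0.275188 seed_qvalue
       3          3         GAGACGAC          CGA.yrsT      8     0.654729 seed_qvalue
       4          2         CGCTCGCC      GTGGCGCyCGCC     12     0.336931 seed_qvalue
```

The largest cluster (22 of 36 pooled motifs) averages to exactly the
planted consensus; the remaining small clusters are subset-level noise.
Lowercase letters are two-base IUPAC codes (`k` = G/T, `w` = A/T) and `.`
marks uninformative columns.  Matching a discovered motif against a
consensus database reports the closest entries by IUPAC-compatible
mismatches — e.g. a discovered `TACCAC` against the S1F binding site
`TACCAT`:

```python
query = pwm_from_instances(["TACCAC"], pseudocount=0)
hit, = match_database(query, [DatabaseMotif("S1F", "TACCAT")], top_n=1)
print(hit.database_id, hit.mismatches)   # -> S1F 1
```

The same stages run from the shell (`promotif extract-upstream`,
`background`, `simulate`, `de-consensus`, `discover`, `map`, `annotate`,
`run-all --config pipeline.yaml`); `run-all` executes DE consensus →
upstream extraction → background → ensemble discovery (separately for
over- and under-expressed lists) → clustering → mapping → annotation and
writes FASTA/MEME/BED/TSV/JSON artifacts plus a manifest.

## Layout

- `promotif.genome_io` — FASTA/GFF3 loading, upstream extraction,
  background word model
- `promotif.synthetic` — ground-truth generators for every input
- `promotif.de_consensus` — DE-table loading, cross-condition consensus,
  housekeeping normalization, Spearman validation
- `promotif.motifs` — PWM algebra: construction, IUPAC consensus,
  reverse complement, information content, inter-motif distance
- `promotif.discovery` — word enumeration, background significance, BH
  correction, the three engines
- `promotif.ensemble` — subset driver, k-medoids clustering, cluster
  averages, and the `MotifDiscoveryModel`/`MotifDiscoveryResults` pair
- `promotif.map_annotate` — both-strand scanning, tallies, database
  matching, TSS-anchored layout export
- `promotif.pipeline` / `promotif.cli` — configuration and the
  end-to-end driver

See `docs/methods.md` for the model details, parameter defaults and
limitations.
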