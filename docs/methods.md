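# Methods

This note documents the models behind each analysis, the defaults that
matter, what the synthetic-data generators do and do not emulate, and the
design choices made where the design was genuinely open.

## Collector's curves

The score of a feature (orthogroup or canonical k-mer) is the number of
haplotypes containing it, `s ∈ [0, H]`. Under uniform sampling of `h`
haplotypes without replacement, the number of a score-`s` feature's
carriers in the sample is hypergeometric, so the expected count of
features seen at least `n` times is

```
C_n(h) = Σ_{s=1..H} P(s) · Pr[X ≥ n],   X ~ Hypergeom(H, s, h).
```

The pan curve is `C_1`; the core curve sets `n = h` (present in every
sampled haplotype), giving `Σ P(s)·C(s,h)/C(H,h)`. Two conventions were
fixed deliberately:

* the survival function is `Pr[X ≥ n]` (so that `C_1` reproduces the pan
  curve's complementary-product form and `C_h(h)` the core form);
* features with score 0 are retained in the histogram but excluded from
  all curve sums — they are unobservable under subsampling.

Probabilities come from scipy's hypergeometric survival function
(log-gamma arithmetic, no raw factorials); the weighted sums use
extended-precision accumulation (`math.fsum`). `subsample_oracle` is an
intentionally independent check: it literally draws `reps` random
h-subsets and counts, and the suite requires agreement within three
standard errors up to `H = 8`, `X = 50` at 20,000 replicates.

### Occupancy classes

Breakpoints at 1%, 5% and 95% of `H`, rounded half away from zero, make
contiguous inclusive bands: unique `[1, b_u]`, cloud `[b_u+1, b_c−1]`,
shell `[b_c, b_n−1]`, nearly-core `[b_n, H−1]`, core `{H}`. Rounding half
away from zero is the unique simple convention that produces the published
bands at `H = 193` (unique 1–2, cloud 3–9, shell 10–182, nearly-core
183–192). At small `H` bands are clamped to `1..H−1` and may be empty
(e.g. `H = 10` has no unique band because 1% of 10 rounds to 0); the bands
always partition `1..H−1`, which is property-tested.

## Canonical k-mers

`k = 31` by default; `k` must be odd so no k-mer equals its own reverse
complement, and `k ≤ 31` so a k-mer packs into a 64-bit integer (2 bits
per base). The canonical form is the lexicographic minimum of a k-mer and
its reverse complement; windows containing non-ACGT symbols are skipped.
Genome k-mer sets are exact (no sketching) and stored as sorted integer
arrays, which keeps Jaccard, histogram and anchoring queries vectorized.

UPGMA clustering of `1 − Jaccard` is hand-written rather than delegated so
that ties in the minimal inter-cluster distance break deterministically on
the lexicographically smallest pair of cluster labels; scipy's average
linkage is the independent oracle in the tests.

### Anchoring and crossovers

Anchoring scores each query window by the fraction of its valid canonical
k-mers present in a reference index. Defaults: window and step 10 kb
(non-overlapping), chosen coarse enough to smooth TE-driven spurious
sharing yet fine enough to localize crossovers to one window; windows with
under 50% valid k-mers are uninformative. Crossover calling labels each
window with the better-conserved parent when the conservation gap exceeds
`margin = 0.2`, keeps maximal same-label runs of at least `min_run = 3`
informative windows, and places a call at the midpoint between consecutive
kept runs of different labels. These resolution parameters are this
package's own defaults — the anchoring resolution used to declare a
haplotype switch is not prescribed by the method itself — and all are
configurable. Donor-haplotype identification compares genome-wide mean
conservation of the two offspring haplotypes in the donor parent's index
and returns an explicit "ambiguous" when the gap is below 0.02.

## TE landscape

**Insertion age.** The two LTRs of an element are identical on insertion,
so `T = (1 − identity)/(2µ)` with the Arabidopsis-derived substitution
rate `µ = 6.1e−9`/site/year by default.

**Solo-LTR cascade.** Candidates are homology-method LTR records not
assigned to an intact element. Filters, in order, each recorded in a
per-candidate audit trail: length ≥ 100 bp; identity ≥ 0.8; alignment
score ≥ 300; none of the four genomically adjacent LTR-RT annotations (two
per side, same chromosome) sharing the candidate's family identifier; gap
≥ 5 kb to the nearest other candidate, intact LTR, or internal record; and
length within the 95th percentile of structural LTR lengths. Open choices
resolved here: "four adjacent annotations" means nearest-two-per-side in
genomic order (boundary records use what neighbors exist); the percentile
is stratified per superfamily from structural LTR lengths (and skipped
with a warning when no structural LTRs exist); the neighbor comparison
uses the family `Name` by default with the element id as a configurable
alternative. Ratios are solo calls over intact elements per superfamily ×
chromosome (or named region); a group with zero intact elements reports a
missing ratio, never infinity.

**Flanking enrichment.** With `a` = focal TE type in focal-feature flanks,
`b` = focal type in all-feature flanks, `c` = all TEs in focal flanks,
`d` = all TEs in all flanks (flank 1 kb each side, feature body excluded,
a TE counted once per flank interval it intersects): `ES = (a/b)/(c/d)`
and the p value is the single-table Fisher point probability
`(a+b)!(c+d)!(a+c)!(b+d)!/(a!b!c!d!N!)`, computed in log space — a point
probability by design, not a tail sum; a conventional two-sided tail is
available behind an explicit flag. Benjamini–Hochberg correction runs
across the batch; significance requires q < 0.05 and ES ≥ 2.

## SV breakpoints

The unit statistic for the bootstrap is the per-SV total TE count of the
focal family in the two 500-bp-per-side breakpoint flanks; this is the
most direct reading of "TE content" at breakpoints. Each of the 1,000
replicates re-places the SV set uniformly at random with lengths and
chromosomes preserved (shuffled intervals may overlap each other and real
features; no exclusion constraints are imposed), compares observed vs
replicate vectors with Welch's two-sided t-test, and the replicate t and p
values are averaged before Benjamini–Hochberg correction across family ×
subtype at α = 0.05. Replicates with zero variance on both sides are
skipped and tallied. Tests run per SV subtype by default; pooling is a
flag. Association of a family with an SV requires presence in **both**
breakpoints' flanks.

Inversion-breakpoint classification considers inversions ≥ 10 kb, takes
8-kb windows centred on each breakpoint, and aligns each window to itself
(excluding the trivial identity alignment) and to the opposite breakpoint
window. The built-in detector chains exact 31-bp seed matches along
diagonals into maximal gap-free matches scored by length — adequate for
synthetic data; externally computed hit tables are preferred for real
genomes. The top alignment per breakpoint decides: any opposing-orientation
alignment → inverted repeat; otherwise same orientation → segmental
duplication; none → unclassified.

## Sequence statistics

Column entropy uses base-2 logarithms (the stated maxima, 4.32 bits for 20
amino acids and 2.0 for 4 nucleotides, force bits) over gap-free symbol
frequencies; gaps are excluded because counting them as a state would
exceed those maxima. Alignments with fewer than five rows are rejected.
CpG o/e is `(N_CG/L)/((N_C/L)(N_G/L))` with a step-1 dinucleotide scan,
case-insensitive, Ns excluded from `L`; o/e is missing (not zero) when C
or G is absent. Island calling slides 200-bp windows at step 50 (both
configurable; unstated by the defining criteria, chosen to satisfy the
"> 200 bp" rule at modest resolution), merges overlapping passing windows,
re-checks each merged region as a whole, and drops regions intersecting a
supplied methylation mask. `F_IS = (H_S − H_O)/H_S` with `H_S = 2p(1−p)`
computed from allele *frequencies* over non-missing calls (the frequency
reading keeps the ratio dimensionless); monomorphic sites are missing, and
multi-site summaries are plain means over polymorphic sites.

## Synthase cassettes

Synthase hits shorter than 500 bp and LTR08 hits below bitscore 1,250 are
dropped (strict inequalities: boundary values are kept). Hits with fewer
than 10 mismatches and zero gap openings are Full, typed by their query
reference; the rest are Partial, re-typed CBDAS when within 60 kb —
measured edge-to-edge between subject intervals — of a retained LTR08 hit,
regardless of the partial hit's own query (the rule is applied as stated;
provenance is recorded on every label). Hits sharing a subject start
collapse with precedence Full > LTR08-proximal Partial > highest bitscore.
Cassette signatures are the ordered (type, completeness, strand) tuples of
regions with at least four hits. Manual post-hoc label corrections are out
of scope; an override table can be applied downstream. Labels describe
alignment hits, not coding competence — no ORF screening is performed.

## Synthetic data

Generators draw everything from one seeded stream per bundle, with
per-component sub-streams derived from `(seed, component)` so outputs are
byte-identical under a fixed seed and stable when unrelated parameters
change. Defaults define the study conditions used throughout the tests:

* presence matrices: scores drawn i.i.d. from the requested distribution,
  carriers uniform — no phylogenetic correlation between orthogroups;
* TE genomes (200 kb): intact elements as element + two LTR + internal
  structural records (LTRs 0.8–1.2 kb, internals 3–5 kb), solos as lone
  homology LTRs whose length/identity/score straddle the cascade
  thresholds so each is pre-classified pass or fail; features are spaced
  ≥ 6 kb with distinct families between neighbors except for deliberately
  planted same-family adjacent pairs and < 5 kb pairs, so the truth table
  is determined by construction, not by re-running the caller;
* trios: parents at 2% divergence from a common ancestor (substitutions
  only — no indels or structural variation), child segments alternating at
  breakpoints with a minimum spacing (uniform conditional on the spacing),
  fresh mutations at 1e−4;
* genotypes: per-site heterozygosity `2p(1−p)(1−F)`, sites independent
  (no linkage);
* SV datasets: two 2-Mb chromosomes, 20 SVs per subtype of 2–20 kb, three
  TE families at 60 background copies/Mb each, with the focal family
  planted inside both breakpoint flanks for the associated fraction of the
  chosen subtype;
* CpG sequences: AT-rich background (GC 35%, below the 50% island
  threshold) with dinucleotide-built islands (CG pair probability 0.15,
  GC 65%).

Because the generators are structurally simple, passing tests demonstrate
correctness of the statistics and callers under their stated models — not
robustness to annotation noise, nested/fragmented TEs, alignment error or
population structure in real data.

## Problem sizes

The validation suite runs at desk scale: curve/oracle agreement up to
`H = 8`, `X = 50` at 20,000 subsampling replicates; 100 trios of 400-kb
parents with 2–6 crossovers; 20 TE genomes of 200 kb; 2,000 sites × 100
samples for F_IS; SV bootstrap calibration over 20 seeds (200 replicates)
plus a 1,000-replicate power run. These sizes were chosen so the whole
suite validates every claim in minutes while leaving the algorithms
identical to what full-genome inputs would use.
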