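# Methods

## Model and assumptions

The core inference is deliberately non-probabilistic: a chain of
presence/absence rules mirroring how the underlying field study was
analyzed. Its assumptions, stated plainly:

- **Presence is count ≥ 1** after filtering, everywhere. No abundance
  thresholds enter any biomarker, matching or scavenging decision.
- **Decay biomarkers are window-exclusive.** An ASV is a biomarker only
  if its *day-pooled* occupancy (present at ≥ 1 replicate site on a
  day) is confined to the fresh window {D0_LAB, D0_FIELD, D1} or the
  decayed window {D2, D4, D7, D11}. The two day-0 labels are distinct
  categorical controls that both sit in the fresh window. Pooling
  across sites assumes site effects on composition are negligible
  relative to day effects.
- **Sequence identity stands in for taxonomic identity.** A gut ASV and
  a biomarker ASV at ≥ 97% global-alignment identity are treated as the
  same signal carrier. This does not claim they are the same strain.
- **The resident-flora filter is a hard veto.** One occurrence of a
  matched ASV in one confirmed non-consumer disqualifies it. This is
  conservative for calling scavengers (fewer informative ASVs) and
  assumes non-consumer status from the diet assay is reliable.
- **Diet assays are the arbiter of consumption.** Scavenging calls are
  only issued for diet-confirmed consumers; non-consumers are reported
  `unresolved`, never "did not scavenge". The ≥ 2-ASV rule for
  ambiguous rats is exploratory and labeled as such in every output.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| identity threshold | 97.0 | % identical columns | standard 16S similarity operating point; inclusive (≥) |
| Sanger quality cutoff | 50 | % | minimum for a usable trace |
| BLAST-hit e-value | < 1e-50 | — | confident-hit cutoff (strict <) |
| query coverage | > 95 | % | confident-hit cutoff (strict >) |
| negative replication | 2 per primer pair | tests | a not-consumed call requires four negative tests |
| low-depth cutoff | 2,000 | reads | the study design implies a cutoff between ~1,000 and ~4,800 reads; 2,000 is the package default and is configurable |
| ambiguous-rat rule | ≥ 2 | informative ASVs | exploratory suggested-carrion threshold |
| IndVal prevalence prefilter | 0.15 | fraction of samples | limits multiplicity |
| indicator rule | stat > 0.7 and p < .05 | — | conventional indicator-species cutoff |
| permutations | 999 | — | Monte-Carlo default; exact enumeration below 10,000 arrangements |

All are configurable at the function or CLI level.

## Numerical and algorithmic choices

- **Alignment.** Global Needleman–Wunsch (biopython `PairwiseAligner`)
  with match +1, mismatch −1, gap open −2, gap extend −0.5. Under this
  scoring a substitution-only variant of equal length aligns without
  gaps, so identity arithmetic on such pairs is exact (e.g. 12
  substitutions in 425 nt → 413/425 = 97.18%). Identity uses the full
  alignment length, gap columns included — the stricter, reproducible
  denominator. `N` never counts as identical. Top-hit ties break by
  identity, then identical-column count, then lexicographic id.
  Semi-global (free end gaps) alignment is available for length-variant
  inputs.
- **Contaminant rule.** Any ASV present in any negative-control sample
  is removed from all samples — the strictest defensible reading of
  "contaminants were removed".
- **Faith's PD / unweighted UniFrac** are computed from a shared
  edge-incidence structure over the rooted tree (PD: total length of
  edges with ≥ 1 observed descendant; UniFrac: unshared / observed
  branch length). Unrooted input trees are midpoint-rooted.
- **PERMANOVA** uses the among/within partition of squared distances
  (pseudo-F). When the number of distinct label arrangements is ≤
  10,000 the p-value is exact: the fraction of arrangements (observed
  included) whose F reaches the observed value — note the mirror
  assignment of a two-group design always ties the observed F, so the
  minimum exact p for n=3+3 is 2/20. Otherwise Monte-Carlo with
  p = (count + 1)/(n_perm + 1), seeded.
- **PERMDISP** embeds the distance matrix by principal coordinates,
  keeps negative-eigenvalue axes with sign-corrected squared
  contributions (Anderson 2006), computes each sample's distance to its
  group centroid, and permutes those distances across samples for the
  F-statistic null. In exactly symmetric configurations the observed F
  is a 0/0 ratio of rounding noise; the p-value remains well behaved.
- **IndVal** is the group-size-equalized presence-absence form
  ("IndVal.g"): B_g = within-group prevalence, A_g = B_g/(B₁+B₂),
  stat = max_g √(A_g·B_g). This variant is pinned by an exact check:
  prevalences 7/11 vs 2/20 give stat 0.74 to two decimals. p-values
  come from group-label permutation; q-values from an in-package BH
  step-up (cross-checked against statsmodels).
- **Total sum scaling** precedes Bray–Curtis only; Jaccard and UniFrac
  use presence/absence.
- **Degenerate inputs** fail loudly: zero-depth rows are directed to
  the depth filter, empty-vs-empty sample pairs are rejected by the
  beta-diversity metrics, a not-consumed diet call with fewer than four
  negative tests is an error, and an informative-set build with zero
  unambiguous rats is an error.

## What the synthetic generator does and does not emulate

`simulate` reproduces the *structure* the analysis depends on: the
7-day × 10-site decomposition layout with lab controls; taxa with
window-confined occupancy (plus spanning/sporadic noise classes);
negative-binomial counts with a lognormal per-sample depth factor
(~16× depth spread); a 51-rat cohort (28 fecal / 23 stomach, 20
consumers / 11 non-consumers / 20 ambiguous, 9 scavengers among
consumers) whose scavengers carry substitution-only mutants (≤ 3% of
sites) of decayed biomarker sequences; confounder lookalikes planted in
confirmed non-consumers; and per-primer evidence records consistent
with each rat's true status. Where the emulated study fixes a value
(cohort composition, day layout, divergence budget) the default is that
value; remaining defaults (detection probability 0.9, NB dispersion 2,
resident pool 300 with Dirichlet 0.5 weights, mean per-taxon counts)
were chosen once as field-realistic and are not fitted to anything.

It does **not** emulate: indels or realistic molecular evolution (the
mutation model is substitution-only so identity arithmetic is exact and
auditable), chimeras or PCR error, taxonomy, phylogenetic signal
between related sequences (trees are random), or covariance between
gut-community structure and diet. Consequently, passing recovery tests
demonstrates the pipeline's logic is correct under its own assumptions
— not that those assumptions hold in any real system (e.g. real
resident flora could include a taxon genuinely < 3% diverged from a
decay biomarker yet absent from all sampled non-consumers; the filter
cannot detect that).

## Problem sizes used by the test suite

The suite exercises the pipeline at reduced scale — cohorts of 20–30
rats over resident pools of 40–60 ASVs and decomposition runs of ~11
taxa — which keeps the full suite under half a minute while leaving
every rule at full fidelity; generator structure is identical at every
scale. Exact-enumeration oracles run at n ≤ 7 samples; null-calibration
checks use 200–300 replicate datasets.

## Known limitations

- The informative filter's hard veto makes informative-ASV counts
  sensitive to single false-negative diet calls.
- IndVal analysis supports exactly two groups (the use case here);
  multi-group designs are rejected rather than silently mishandled.
- Permutations are unconstrained; a blocked design (e.g. by forest
  fragment) would require restricted permutation, which is not
  implemented.
- Percent identity from optimal alignment can differ slightly from
  heuristic local aligners' reporting conventions on length-variant
  pairs; the package's convention (full alignment length denominator)
  is the stricter one.
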