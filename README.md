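# scavtrace

Did a consumer eat its prey fresh, or scavenge it as carrion? Molecular
diet analysis can tell *that* a diet item was eaten, but not *in what
state*. `scavtrace` implements a forensic-microbiology answer for the
model system of invasive black rats (*Rattus rattus*) and birds in
Hawaiian forest fragments: bacteria that colonize decaying tissue can
survive digestion, so decay-specific bacterial taxa found in a
consumer's gut are evidence that the diet item was carrion.

The package is aimed at molecular ecologists working with 16S amplicon
(ASV) tables, per-sample diet-assay evidence, and phylogenies. It
provides the full analysis as a library plus a thin `scavtrace` CLI.

## The method

1. **Biomarker discovery.** A tissue-decomposition time series (day 0 in
   the lab; days 0, 1, 2, 4, 7, 11 in the field at replicate sites) is
   singleton-filtered, cleaned against negative controls and pooled by
   day. An ASV whose day-occupancy lies entirely in the *fresh* window
   {day 0 lab, day 0 field, day 1} is a fresh-tissue biomarker; one
   confined to the *decayed* window {days 2, 4, 7, 11} is a
   decayed-tissue biomarker; window-spanning ASVs are neither.
2. **Diet calls.** Each consumer sample is assayed with two independent
   bird-specific mitochondrial primer pairs (COI, Cytb). A sample is
   *consumed bird* if any assay yields a Sanger sequence of >50% quality
   whose confident database hits (e-value < 1e-50, coverage > 95%) agree
   on one expected bird species (with a genus fallback for expected
   species lacking reference sequences); *not consumed* if all four
   tests (two replicates per pair) show no amplification; *ambiguous*
   otherwise.
3. **Matching and the informative filter.** Gut ASVs are matched to
   biomarker sequences by optimal global alignment; a top hit at ≥ 97%
   identity (identical columns / alignment length) is a match. A matched
   ASV is *informative* only if it occurs in at least one confirmed
   consumer and in no confirmed non-consumer — otherwise it is resident
   gut flora.
4. **Scavenging calls.** A confirmed consumer carrying ≥ 1 informative
   decayed-tissue ASV is flagged `carrion_likely`; one carrying none is
   `predation_or_unknown`. As an exploratory rule, an ambiguous rat
   carrying ≥ 2 informative ASVs is flagged `suggested_carrion`.

Supporting statistics (implemented from first principles, with
permutation nulls): ASV richness, Faith's PD, Jaccard / Bray–Curtis /
unweighted UniFrac distances, PERMANOVA, PERMDISP, group-equalized
presence-absence indicator values (IndVal.g, stat = √(A·B)) with
Benjamini–Hochberg FDR, and total-sum scaling.

A synthetic-data module generates decomposition series, rat cohorts with
planted carrion ASVs (≤ 3% diverged from biomarker sequences) and
confounder lookalikes, and diet evidence — with ground-truth labels, so
the whole pipeline is testable by parameter recovery.

## Worked example

A simulated end-to-end run on a small, noise-free cohort:

```python
from scavtrace import RunConfig, DecompositionConfig, CohortConfig, run_pipeline

cfg = RunConfig(
    seed=42,
    decomposition=DecompositionConfig(seed=101, n_fresh_only=3, n_decayed_only=10,
                                      n_spanning=0, n_sporadic=0, detection_prob=1.0),
    cohort=CohortConfig(seed=202, n_rats=24, n_feces=12, frac_consumed=10/24,
                        frac_not_consumed=6/24, frac_scavenger=0.5,
                        n_resident_pool=60, resident_richness=20, n_confounders=3),
)
result = run_pipeline(cfg)
print(result.report.to_dict())
```

prints

```
{'n_rats': 24, 'n_consumed': 10, 'n_not_consumed': 6, 'n_ambiguous': 8,
 'n_carrion': 5, 'carrion_by_type': {'rat_feces': 2, 'rat_stomach': 3},
 'n_suggested_carrion': 0,
 'species_consumed': ['Lophura leucomelanos', 'Meleagris gallopavo',
                      'Myadestes obscurus', 'Zosterops japonicus'],
 'species_with_carrion': [...same four...],
 'pct_consumed': 42, 'pct_carrion': 21}
```

Of 24 simulated rats, 10 were confirmed bird consumers by the diet
assays and 5 of those carried informative decay-biomarker ASVs in their
gut — exactly the 5 rats the generator made scavengers. The 3 planted
confounder ASVs (decay lookalikes living in non-consumers) were all
rejected by the informative filter.

The packaged study tables can be re-derived in one command; every line
must read `[ok]`:

```sh
$ scavtrace reproduce-tables
indval_prevotella                          0.74  [ok]
n_carrion_rats                                9  [ok]
n_consumed                                   20  [ok]
...
```

Other subcommands: `simulate`, `discover`, `match`, `diet-call`,
`classify`, `stats`, `pipeline` — see `scavtrace --help`.

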