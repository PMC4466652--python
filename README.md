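# cansplice

Identification and characterization of cancer-specific alternative-splicing
(AS) events from PSI matrices across multiple cancer types.

## The problem

Alternative splicing is regulated tissue-specifically, so comparing tumors
of one tissue against normals of the same tissue mixes cancer biology with
tissue identity.  A way through is to screen several cancer types
independently and keep only the events dysregulated in *all* of them.
`cansplice` implements that workflow for anyone with per-cancer PSI
(Percent Spliced In) matrices — events × samples, values in [0, 1],
missing entries allowed — over the four major AS modes: skipped exon (SE),
retained intron (RI), alternative 3′/5′ splice sites (A3SS/A5SS).

Per cancer type, an event is **significant** when

1. it is detected (non-missing PSI) in ≥ 10 tumor and ≥ 10 normal samples,
2. tumor and normal PSI distributions differ (Welch t-test, p < 0.05), and
3. |ΔPSI| = |mean PSI(tumor) − mean PSI(normal)| > 0.1.

The **core set** is the intersection of significant sets across all cancer
types.  The package then quantifies everything one would want to know about
that set:

* a 1000-replicate permutation null for the intersection size (matched-size
  random draws from each cancer's detectable events; rank p with
  pseudo-count),
* direction consistency of ΔPSI across cancers,
* hypergeometric overlap with a frequently-mutated-gene list,
* exon reading-frame phase (length mod 3) with a Fisher exact test,
* conservation meta-profiles around core exons,
* 5-mer Z-score motif enrichment in exon-proximal windows, with
  single-linkage clustering of enriched words into candidate motifs,
* PSI-variability (SD) comparison against mean-PSI-matched control events,
* PCA of core-event PSI vectors as a tumor/normal and subtype classifier,
* a median-split Kaplan–Meier / log-rank survival screen, and
* a genome-wide Spearman screen linking core-event PSI to gene expression
  (|ρ| ≥ 0.4, p ≤ 0.005, candidate regulators correlated with > 30 events).

Because real multi-cancer cohorts are controlled-access, the package ships
a first-class synthetic-cohort generator (`cansplice.synthetic_cohort`)
that plants known differential events, regulators, survival couplings,
motifs and conservation structure, so every stage is testable end to end
against ground truth.

## Worked example

```python
from cansplice import (SyntheticConfig, generate_cohort, screen_events,
                       intersect_significant, direction_consistency)

bundle = generate_cohort(SyntheticConfig(seed=1))   # 3 cancers, 40T/40N each
results = {c: screen_events(bundle.psi[c], bundle.meta)
           for c in sorted(bundle.psi)}
for c, res in results.items():
    print(c, int(res["significant"].sum()), "significant events")

venn, core = intersect_significant(results)
rep = direction_consistency(core, results)
planted = set(bundle.truth.planted_shared)
print(f"core set: {len(core)} events "
      f"({len(set(core) & planted)} of {len(planted)} planted recovered)")
print(f"direction-consistent: {rep.fraction_consistent:.1%}")
```

prints

```
CAN1 199 significant events
CAN2 200 significant events
CAN3 200 significant events
core set: 149 events (149 of 150 planted recovered)
direction-consistent: 84.6%
```

Each cancer's screen finds its ~150 planted-shared plus ~50
cancer-specific events; the three-way intersection strips the
cancer-specific ones, recovering 149/150 planted shared events with no
contamination.  The 84.6% direction consistency matches the generator's
85% consistent-direction setting.

The same stages are available as a CLI
(`cansplice simulate | screen | intersect | seqfeat | variability | pca |
survival | correlate | run`); `cansplice run --config run.yaml` executes
the whole pipeline with content-hash stage caching and writes TSV/JSON
outputs plus a run summary.

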