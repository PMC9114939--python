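# codaclan

Analysis pipeline for sperm whale (*Physeter macrocephalus*) cultural
population structure and movement scale, built around three questions a
vessel-based photo-identification and acoustic survey can answer:

1. **Which coda types do the whales produce?** Codas — short stereotyped
   click trains — are classified into types from their absolute inter-click
   intervals (ICIs), per click-count family, with a mixture of multivariate
   Gaussian components plus a broad uniform contamination component, the
   number of components chosen by BIC.
2. **Which vocal clans are present?** Daily coda *usage repertoires* (the
   distribution of type proportions a group produces on one day) are
   clustered by average linkage on Bhattacharyya similarity, and clans are
   delineated by *identity codas*: types used consistently by one set of
   repertoires and rarely by others.
3. **At what spatial scale do the clans live?** Vessel-track displacement
   over 1/3/6-h windows, and root-mean-squared (RMS) displacement of
   photo-identified individuals over day-to-year time lags, estimated by an
   effort-corrected maximum likelihood with leave-one-individual-out
   jackknife standard errors, plus kernel-density encounter maps and
   same-island re-sighting fractions.

The package is aimed at cetacean researchers who have coda tables, a fluke
photo-identification catalogue and GPS tracks (the fixed CSV schemas are
documented in the module docstrings), and at methods work: a synthetic-data
generator (`codaclan.synthetic_data`) produces clan-structured codas,
island-resident movement and effort-biased resighting histories with full
ground truth, so every stage can be validated against a known answer.

## The statistical core

**Coda typing.** Within a click-count family, the ICI vector
x ∈ R^(c−1) follows a mixture

&nbsp;&nbsp;f(x) = Σ_j π_j N(x; μ_j, Σ_j) + π_0 U(box),

with diagonal Σ_j by default and U a fixed uniform density over the padded
ICI bounding box (the contamination component). Codas whose maximum
posterior falls on the contamination component stay "unclassified". k is
selected by BIC over k = 1..k_max.

**Clan delineation.** Type *t* is an *identity coda* of clan *c* when at
least `prevalence_min` of c's repertoires use it at proportion ≥ `u_min`,
its mean proportion outside c is ≤ `out_max`, and no other clan meets the
same thresholds for *t*. The accepted partition is the dendrogram cut with
the most clusters such that every cluster owns at least one identity coda;
the partition is re-derived from identity-type usage alone as a stability
check, and a threshold sweep reports robustness as agreement with the modal
partition.

**Movement scale.** For re-sighting pairs (individual at x, later at y, lag
τ in a bin), the per-axis displacement sd s maximises

&nbsp;&nbsp;Σ_pairs log [ E(cell(y)) φ₂(y − x; s²I) / Σ_z E(z) φ₂(z − x; s²I) ],

where E is the gridded identification-effort field — the denominator is
what corrects for whales being seen only where the survey looked. RMS
displacement is s√2; errors come from jackknifing individuals.

## Worked example

```python
from codaclan import gen_codas, classify_codas, build_repertoires, delineate_clans

bundle = gen_codas(seed=42)                       # 3-clan synthetic study
typing = classify_codas(bundle.codas, seed=42)    # mixture fit per click count
reps, report = build_repertoires(bundle.codas, typing.assignment)
result = delineate_clans(reps)
```

prints, via the obvious summaries:

```
17490 codas -> 144 repertoires (6 days below 25 codas)
3 vocal clans; 10 identity coda types
  clan_1:        4R  inside 0.07  outside 0.00
  clan_1:       1+3  inside 0.10  outside 0.00
  clan_1:       2+3  inside 0.06  outside 0.00
  clan_1:     1+1+3  inside 0.55  outside 0.00
  clan_2:   2+1+1+1  inside 0.26  outside 0.00
  clan_2:        5R  inside 0.35  outside 0.00
  clan_2:        6R  inside 0.12  outside 0.00
  clan_3:       10R  inside 0.20  outside 0.00
  clan_3:       11R  inside 0.12  outside 0.00
  clan_3:        9R  inside 0.25  outside 0.00
identity-weighted re-clustering agreement (ARI): 1.00
```

Reading this: of 150 simulated (group, day) cells, 144 had the required 25
codas and became usage repertoires; the delineation recovered the three
planted clans exactly, each marked by its planted identity types (e.g. the
"1+1+3" type — two single clicks then a triplet — makes up 55% of clan_1's
output and 0% elsewhere), and clustering on identity-type usage alone gives
the identical partition.

The same pipeline is available from a shell (`codaclan simulate`,
`codaclan type-codas`, `codaclan clans`, `codaclan rms`, ...).

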