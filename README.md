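# metaboregion

Regional metabolome analysis for tissue-profiling studies: given a
metabolite concentration matrix (metabolites × samples) annotated with
metabolite categories and sample groups — typically brain regions such
as olfactory bulb (OB), frontal cortex (FCX), hippocampus (HC), and
cerebellum (CBL) — the package answers two questions:

1. **Which metabolites differ between regions?**  A per-metabolite
   one-way ANOVA screen with Benjamini–Hochberg FDR control, pairwise
   Welch *t*-tests with log2 fold changes, and region-signature
   counting (metabolites characteristically high or low in one region
   versus all others), plus PCA of the standardized profile.
2. **How are metabolites organized into co-varying modules?**  A
   weighted correlation network: from the pairwise correlation matrix
   *S*, a soft-threshold adjacency *a*<sub>ij</sub> = |*s*<sub>ij</sub>|<sup>β</sup>
   (default β = 11, chosen against the scale-free topology criterion
   *p*(*k*) ~ *k*<sup>−γ</sup>), the topological overlap

   ω<sub>ij</sub> = (*l*<sub>ij</sub> + *a*<sub>ij</sub>) / (min(*k*<sub>i</sub>, *k*<sub>j</sub>) + 1 − *a*<sub>ij</sub>),  *l*<sub>ij</sub> = Σ<sub>u</sub> *a*<sub>iu</sub>*a*<sub>uj</sub>,  *k*<sub>i</sub> = Σ<sub>u≠i</sub> *a*<sub>iu</sub>,

   the dissimilarity *d*<sub>ij</sub> = 1 − ω<sub>ij</sub>, complete-linkage
   hierarchical clustering, and a dynamic branch cut.  Modules must be
   connected subtrees with **more than 10** members; clustering repeats
   on the unassigned remainder until no new module appears.  Each
   module is summarized by its **eigen-metabolite** (first principal
   component of the standardized member submatrix) and its **hub**
   (the member with the highest absolute correlation to the
   eigen-metabolite, the kME membership score).

Because such studies rarely deposit raw data, the package ships a
synthetic-data generator that emulates the study design — 215
metabolites over 8 chemical categories, 4 regions × 6 replicates, 70
region-affected metabolites, and 5 planted co-varying modules (sizes
12, 12, 12, 12, 13) on a lognormal background — with full ground truth
for recovery scoring (adjusted Rand index).

## Worked example

```python
import metaboregion as mr

profile, truth = mr.generate_dataset(mr.SyntheticConfig(seed=0))
assignment = mr.detect_modules(profile)
for m in assignment.modules:
    p = mr.eigen_region_anova(m.eigen, profile.groups)
    print(f"{m.name:9s} size={m.size:2d} hub={m.hub} kME={m.hub_score:.3f} "
          f"eigen ANOVA p={p:.3g}")
print("recovery ARI vs planted truth:",
      round(mr.recovery_score(assignment, truth), 3))
print("significant metabolites (q<0.01):",
      len(mr.significant_metabolites(profile, q_threshold=0.01)))
```

prints

```
turquoise size=13 hub=met_011 kME=0.969 eigen ANOVA p=0.9
blue      size=13 hub=met_061 kME=0.937 eigen ANOVA p=0.62
brown     size=12 hub=met_013 kME=0.954 eigen ANOVA p=0.814
yellow    size=12 hub=met_031 kME=0.967 eigen ANOVA p=0.227
green     size=11 hub=met_037 kME=0.905 eigen ANOVA p=0.601
recovery ARI vs planted truth: 0.98
significant metabolites (q<0.01): 4
```

The detector finds exactly the five planted modules (61 metabolites
planted, 62 assigned, adjusted Rand index 0.98 restricted to planted
members); hub kME scores sit in the 0.90–0.97 range typical of tight
modules.  At the default planted effect size (1 noise-SD contrast) the
q < 0.01 ANOVA screen is deliberately underpowered — raise
`effect_size` to 2 and it recovers essentially all 70 affected
metabolites (see `scripts/acceptance.py`).

The same stages are available from the shell:

```sh
metaboregion simulate --seed 0 --out-prefix out/sim
metaboregion run --profile out/sim_profile.tsv \
    --annotations out/sim_samples.tsv --out-dir out/run
```

`run` writes every stage table as TSV plus a deterministic
`summary.json`; `univariate`, `pca`, and `network` run the stages
individually and compose to the same outputs.

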