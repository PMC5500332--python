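# pneumotyper

Analysis toolkit for **low-biomass lung microbiome** studies, built around the
murine lung / upper-respiratory-tract (URT) 16S amplicon design: in-silico
reagent decontamination of paired-end amplicon contigs, genus-level community
statistics, iterative classification of lung samples into three
**pneumotypes**, and alpha/beta diversity — together with a synthetic-data
generator that reproduces the statistical structure such a study assumes, so
every stage can be exercised and validated at desk scale.

It is aimed at microbiome researchers and methodologists who need a tested,
reproducible implementation of these steps rather than an ad-hoc script
collection.

## The problem and the methods

Healthy lungs are a low-biomass site: bacterial DNA intrinsic to extraction
and amplification reagents can dominate the signal. The pipeline addresses
this and the downstream questions with the following pieces:

* **Read joining.** Paired reads are merged over their largest
  suffix/prefix overlap of at least 6 bp (≥ 90% identity inside the window;
  forward read wins mismatches).
* **In-silico decontamination.** A sample contig is removed when it matches
  any reagent/NTC control contig at ≥ 99% identity over ≥ 250 bp (ungapped
  sliding alignment, both orientations, shared-31-mer prefilter). Working at
  the sequence level rather than the OTU level avoids discarding genuine
  low-abundance organisms together with contaminant OTUs.
* **Representative microbiomes and correlation.** For a group *G* with
  counts *c₍s,g₎*, the representative profile is
  `r_g = mean_{s∈G} log2(c_{s,g} + 1)`; each sample is summarized by its
  Pearson correlation with a representative.
* **Percent overlap.** For groups *A, B* with pooled samples *P = A ∪ B*,

  ```
  overlap(A,B) = 100 · Σ_{g ∈ D(A)∩D(B)} T_P(g) · f_P(g) / N_P
  ```

  where `T_P(g)` is the pooled count of genus *g*, `f_P(g)` the fraction of
  pooled samples containing it, `N_P` the pooled total and `D(·)` the sets of
  detected genera.
* **Pneumotype classification.** Lung samples with fewer than 50 retained
  reads are `background`; the rest are seeded by correlation to the URT
  representative and refined by iterative reassignment to the better-correlated
  of the current `aspirate`/`unique` representatives (a two-group Pearson
  analogue of k-means).
* **Diversity.** Chao1 (`S_obs + F1²/2F2`, bias-corrected at `F2 = 0`) on
  reads rarefied to depth 340, inverse Simpson `1/Σp²`, Bray-Curtis
  dissimilarity and one-factor PERMANOVA with permutation p-values.
* **Synthetic communities.** Genus profiles (URT, two lung pneumotypes,
  reagent contaminants, bedding/chow/water) are sampled through a
  Dirichlet-multinomial with log-normal depths; error-bearing read pairs are
  generated from per-genus reference amplicons with Poisson contaminant
  spiking and dedicated reagent/NTC control samples.

## Worked example

```python
from pneumotyper import classify, paper_default, recovery_rate, simulate_scenario

sim = simulate_scenario(paper_default(), seed=1)   # 18 animals, 74 samples
result = classify(sim.counts, sim.metadata)
print({k: int(v) for k, v in result.group_sizes.items()})
print(f"{recovery_rate(result.labels, sim.truth):.1%}")
```

prints

```
{'background': 12, 'aspirate': 3, 'unique': 21}
100.0%
```

i.e. the classifier recovers the generating 33/58/9% pneumotype mix of the 36
lung samples exactly on this draw. The scripts in `examples/` walk through
each capability (`01` simulation + classification, `02` read-level
decontamination, `03` overlap/correlation tables, `04` diversity); from
`examples/04_diversity.py`:

```
group    inverse_simpson   chao1@340
urt               1.68        6.06  (n=18)
aspirate          1.49        7.09  (n=3)
unique            7.40       19.49  (n=21)

PERMANOVA (group factor): F=36.9 R2=0.65 p=0.001
```

showing the unique pneumotype as the most diverse group and a significant
group separation on Bray-Curtis distances.

A thin CLI mirrors the stages (`pneumotyper simulate | join | filter |
classify | diversity | run-all`); `pneumotyper run-all --scenario desk
--seed 1 --outdir out/` writes the full TSV report bundle (counts, filter
report, labels, representative profiles, correlation/overlap tables,
abundance report, diversity and PERMANOVA summaries) plus a checksummed run
manifest. Deposited FASTQ data can be processed with `pneumotyper real`,
which stops after decontamination unless a per-contig genus annotation is
supplied (external taxonomy assignment is out of scope).

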