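# Methods

This note documents the models implemented in `pneumotyper`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing a
run.

## Study design being modeled

The package targets a murine lung microbiome design: 18 co-housed animals
sampled at the posterior oropharynx (URT) and at two lung lobes (UL/LL,
pooled as one "lung" site because the two lobes are compositionally
indistinguishable), with 8 reagent controls, 3 no-template water controls
(NTC) and 3 samples each of cage bedding, rodent chow and drinking water.
The URT carries orders of magnitude more bacterial 16S material than the
lung, and lung samples fall into three pneumotypes: `background` (fewer than
50 retained reads, indistinguishable from water controls), `aspirate`
(URT-like) and `unique` (diverse, resembling chow/bedding material), in
roughly a 33/58/9% mix.

## Synthetic community generator

**Count model.** For a group with profile **π** (a genus → relative
abundance map summing to 1), dispersion *α* and log-normal depth law, each
sample draws depth `D ~ round(LogNormal(μ, σ))`, proportions
`p ~ Dirichlet(α·π)` over the profile's support, and counts
`c ~ Multinomial(D, p)`. The Dirichlet-multinomial gives the
overdispersion real amplicon counts show; *α* = 500 for the URT (a highly
reproducible community) and *α* = 20 for the unique pneumotype (strong
mouse-to-mouse variability) bracket the observed behavior, with 100 used
for groups in between.

**Depth defaults** (median reads/sample): URT 50 000, aspirate 3 000,
unique 300, background 15, environmental sources 10 000, reagent controls
800, NTC 30. Published sources do not state per-group depths; the only
anchor is the >1000-fold URT/lung 16S asymmetry and the <50-read background
floor, and the defaults are calibrated to that structure only. A
`desk_scenario()` variant scales the deep groups down (URT 2 000, aspirate
1 200, environment 2 000) so read-level runs finish in seconds; all
analysis-level conclusions in the test suite are depth-structure properties,
not absolute-depth properties.

**Profiles.** The three tissue profiles are the published >1% genus tables
for URT, lung-aspirate and lung-unique, renormalized. The contaminant
profile carries the published *Pseudomonas* (53%) / *Escherichia* (15%)
signature padded with well-known kit/water contaminants (*Ralstonia*,
*Bradyrhizobium*, *Delftia*, *Herbaspirillum*). The environmental profiles
are **synthetic**: constructed so bedding and chow share mass with the
unique pneumotype, bedding additionally shares *Streptococcus* with the
URT, and drinking water is disjoint from all tissue groups. Background lung
samples draw from the contaminant profile, which makes them vanish almost
entirely under decontamination — exactly the behavior the background rule
expects.

**Reads.** Each genus has a random 254-nt reference amplicon (pairwise
identity between references < 90%, so 97% genus assignment is unambiguous).
A count of *c* yields *c* read pairs: forward = first 150 nt of the
reference, reverse = reverse complement of the last 150 nt, each base
substituted independently with probability 0.002 (roughly a Q27 uniform
error model; no indels, no chimeras, no quality-score structure). Specimen
samples additionally receive `Poisson(30)` contaminant read pairs;
reagent/NTC control samples contain contaminant-derived reads only.

**Determinism.** Every draw is keyed by
`(seed, fixed stream id, CRC32(sample name))`, so outputs are pure
functions of (configuration, seed) and adding samples never perturbs
earlier ones. Read identifiers embed the originating sample and genus
purely as a test oracle; a `scramble_labels` flag erases the genus token,
and an integration test verifies the analysis output is unchanged.

**What passing tests do not show.** The generator has no chimeras, no
indels, no primer/amplification bias, no length variation and exact
per-genus reference sequences, so decontamination and genus assignment
operate in their cleanest regime. Results on real data additionally depend
on chimera filtering and external taxonomy, both out of scope here.

## Decontamination

A sample contig is removed when it aligns to any reagent/NTC control contig
with ≥ 99% identity over ≥ 250 alignment columns. Identity is matching
columns / alignment columns of an **ungapped** sliding alignment, evaluated
in both orientations. Gapped alignment is deliberately omitted: simulated
and V4 amplicon contigs are fixed-length, and for real indel-bearing data
this is a documented limitation (an indel shifts the frame and deflates
identity). At 254 bp the rule resolves exactly: 2 mismatches (252/254 ≈
99.2%) are removed, 3 mismatches (251/254 ≈ 98.8%) are retained.

Candidates are prefiltered by requiring at least one shared 31-mer: a
≥ 250 bp match at ≥ 99% identity has at most 3 mismatches, which cannot
break all 31-mers, so the prefilter never misses a true match. NTC contigs
are indexed alongside reagent contigs (they are processed identically);
this is configurable off. Genus assignment is direct reference matching at
> 97% identity (strict), ties broken by lexicographically first genus name;
sub-threshold contigs land in a reserved `unassigned` column excluded from
all statistics.

## Community statistics

* Counts are normalized to proportions summing to 100% per sample; all-zero
  rows are preserved and flagged.
* log2 transform uses pseudocount 1 (zeros stay at 0, monotone); the
  pseudocount is a package choice, as the transform is undefined at zero.
* Correlations are Pearson on log2 counts over the full genus set
  (Spearman behind a flag). For intra-group figures the member is **not**
  excluded from its own group's representative; a leave-one-out variant is
  provided separately.
* Percent overlap uses the pooled formulation described in the README. The
  verbally "literal" variant — dividing the per-genus *average* rather than
  total count by the pooled total — scales like 1/n_samples and is kept
  behind `literal=True` for comparison; the pooled form is the one whose
  intra-group value reaches 100 exactly when every detected genus occurs in
  every sample, which is the only analytically checkable anchor. Between
  groups the sum is restricted to genera detected in both, so disjoint
  communities score 0. Output headers record which variant produced a
  table.
* The abundance report lists a genus when its group-mean relative abundance
  exceeds 1% in any group; cells for genera undetected in a group are
  rendered `-`.

Because the shipped profiles contain only the >1% genera (the published
tables truncate the rare tail), simulated intra-group overlaps and
correlations sit higher than the corresponding full-resolution field values;
the test suite therefore asserts the *directional* structure (intra-URT >
URT-vs-unique; unique most diverse) rather than absolute levels.

## Pneumotype classification

`background` is decided purely by the sample's own post-decontamination
total (strictly < 50). The "does not differ from water controls"
qualification is reported as a non-gating QC (Bray-Curtis distance to the
NTC proportion centroid) because no compositional test or threshold is
specified for it, and inventing one would gate samples on an unstated
criterion.

Non-background samples are seeded `aspirate` when their Pearson correlation
to the URT representative is ≥ 0.6 (boundary inclusive), else `unique`,
then refined: recompute both representatives from current members, reassign
every sample to the better-correlated one (exact ties → `unique`,
conservative against inflating the URT-like group), repeat until labels are
stable or 20 iterations. If either group empties, iteration stops and
current labels are kept. The scheme is one defensible formalization of
"iterative comparisons between samples"; the separation of aspirate from
unique was not operationally specified in the source material. On the
default scenario it converges in 1–3 iterations and recovers the generating
labels at ≥ 95% across seeds (the residual errors are genuine boundary
events — background-truth samples that drew ≥ 50 reads).

## Diversity

Chao1 uses the classic estimator `S_obs + F1²/(2·F2)` and switches to the
bias-corrected `S_obs + F1(F1−1)/(2(F2+1))` only at `F2 = 0`, where the
classic form is undefined; output headers record the variant. Rarefaction
draws without replacement (multivariate hypergeometric), 50 replicates at
depth 340 by default; samples shallower than the target depth are skipped
with a logged warning rather than failing the run, since group curves are
still needed when some lung samples are shallow. Reported SDs use the n−1
denominator. Inverse Simpson is `1/Σp²`. Bray-Curtis is `Σ|x−y|/Σ(x+y)`.

PERMANOVA is the one-factor pseudo-F from the among/within partition of
squared distances, with `p = (1 + #{F* ≥ F}) / (1 + B)` so p is never 0 and
its floor at B = 999 is 0.001. It is implemented in-package (rather than
delegated) so permutations are seed-deterministic; the test suite
cross-checks the statistic against scikit-bio and calibrates the type-I
error to its nominal level. A two-factor design (site + animal) is reduced
to two one-factor runs reporting both R² values; full multi-factor
partitioning is out of scope. Groups with fewer than two members are
excluded from the factor.

## Pipeline and problem sizes

`run_pipeline` composes simulate → join → filter → tabulate → classify →
stats → diversity, writes TSV everywhere, stamps every table header with
the seed, a config hash and the statistic-variant flags, and emits a
manifest with SHA-256 checksums; reruns with the same seed are
byte-identical. Stage failures raise errors named for the stage, keeping
completed outputs.

The test suite and the acceptance script run the full default scenario at
count level (all 74 samples, URT depth 50 000) and the read-level stages on
the desk-depth scenario (~70 000 read pairs), which keeps the whole suite
around a minute on one CPU while exercising every code path at full sample
count.

## Known limitations

* Ungapped identity only — real indel-bearing contigs need a gapped
  aligner upstream.
* No chimera filtering or OTU clustering; genus assignment is exact
  reference matching (desk mode) or an externally supplied annotation
  (real-data mode).
* The uniform substitution error model understates real MiSeq error
  structure (quality-dependent, position-dependent).
* Environmental profiles are invented surrogates; their absolute overlap
  values are illustrative, only their sharing structure is designed.
* The overlap statistic's published algebra is under-specified; both
  interpretations are implemented and the choice is recorded in output
  headers.
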