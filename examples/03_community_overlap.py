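"""Representative microbiomes, correlation coefficients and percent overlap.

The representative microbiome of a group is the per-genus mean of
log2-transformed counts over its members; each sample is then correlated
(Pearson) against it.  Percent overlap weights each shared genus's pooled
read mass by the fraction of pooled samples containing it.
"""

from pneumotyper import classify, paper_default, simulate_scenario
from pneumotyper.stats import (
    group_correlation,
    log2_transform,
    overlap_matrix,
    representative_profile,
)

sim = simulate_scenario(paper_default(), seed=1)
result = classify(sim.counts, sim.metadata)
meta = sim.metadata

groups = {"urt": meta.index[meta["site"] == "URT"].tolist()}
for label in ("aspirate", "unique"):
    groups[label] = result.labels.index[result.labels == label].tolist()

log2 = log2_transform(sim.counts)
print("mean correlation of each group (rows) with each representative (cols):")
for a, members in groups.items():
    row = {
        b: round(group_correlation(log2, members, representative_profile(log2, mb, b))[0], 2)
        for b, mb in groups.items()
    }
    print(f"  {a:9s} {row}")

print("\npercent overlap between groups (diagonal = intra-group):")
print(overlap_matrix(sim.counts, groups).round(1).to_string())

env = {src: meta.index[meta["site"] == src].tolist() for src in ("bedding", "chow", "water")}
print("\npercent overlap of environmental sources with tissue groups:")
print(overlap_matrix(sim.counts, env, groups).round(1).to_string())
# High bedding/chow overlap with the unique pneumotype (and none for water)
# reflects inhaled food/bedding material as its likely source.
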