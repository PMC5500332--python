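"""Group-level community statistics for genus count matrices.

Implements the study's bespoke machinery: per-sample proportion
normalization, log2 transformation (pseudocount 1, so zeros stay zero), the
"representative" microbiome of a group (per-genus mean of log2-transformed
counts), sample-versus-representative correlation coefficients, the percent
overlap statistic, and threshold-filtered group abundance reports.

The overlap between groups A and B pools their samples (P = A ∪ B) and sums,
over the genera detected in both groups, each genus's total pooled count
weighted by the fraction of pooled samples containing it, divided by the
total pooled count:

    overlap = 100 × Σ_{g ∈ D(A) ∩ D(B)} T_P(g) · f_P(g) / N_P

Intra-group overlap is the A = B case, where the restriction spans all
detected genera, so a community whose every detected genus occurs in every
sample scores exactly 100.  A literal variant that divides the per-genus
*average* (rather than total) count by the pooled total is retained behind
``literal=True`` for comparison; it scales like 1/n_samples and is not the
formulation whose intra-group values sit on the published scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def _check_members(counts: pd.DataFrame, members: Sequence[str], what: str) -> list[str]:
    members = list(members)
    if not members:
        raise ValueError(f"{what} must contain at least one sample")
    missing = [m for m in members if m not in counts.index]
    if missing:
        raise KeyError(f"{what} not in matrix: {missing}")
    return members


def to_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize each row to percentages summing to 100.

    All-zero rows stay all-zero and are flagged in
    ``result.attrs["zero_samples"]``.
    """
    totals = counts.sum(axis=1)
    zero = totals == 0
    props = counts.div(totals.where(~zero, 1.0), axis=0) * 100.0
    props.attrs["zero_samples"] = list(counts.index[zero])
    return props


def log2_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(count + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    out = np.log2(counts.astype(float) + pseudocount)
    out.attrs["pseudocount"] = pseudocount
    return out


@dataclass(frozen=True)
class RepresentativeProfile:
    """Per-group mean of log2-transformed genus counts."""

    group: str
    values: pd.Series  # genus -> mean log2 abundance, over the full genus set
    n_samples: int


def representative_profile(
    log2_matrix: pd.DataFrame, members: Sequence[str], group: str = ""
) -> RepresentativeProfile:
    """Average the log2 rows of a group's members over the full genus set."""
    members = _check_members(log2_matrix, members, "group members")
    values = log2_matrix.loc[members].mean(axis=0)
    values.name = group or "representative"
    return RepresentativeProfile(group=values.name, values=values, n_samples=len(members))


def correlation_to_profile(
    sample_row: pd.Series,
    profile: RepresentativeProfile | pd.Series,
    method: str = "pearson",
) -> float:
    """Correlation of one sample's log2 row with a representative profile.

    Pearson by default (Spearman via ``method="spearman"``), computed across
    the full genus set; raises on constant vectors, where the coefficient is
    undefined.
    """
    ref = profile.values if isinstance(profile, RepresentativeProfile) else profile
    if set(sample_row.index) != set(ref.index):
        raise ValueError("sample and profile must share the same genus set")
    if len(sample_row) < 3:
        raise ValueError("need at least 3 genera for a correlation")
    x = sample_row.to_numpy(dtype=float)
    y = ref.reindex(sample_row.index).to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def group_correlation(
    log2_matrix: pd.DataFrame,
    members: Sequence[str],
    profile: RepresentativeProfile | pd.Series,
    method: str = "pearson",
) -> tuple[float, pd.Series]:
    """Mean (and per-sample) correlation of a group against a profile.

    For intra-group figures pass the profile computed from *all* members:
    each member is compared against it without leave-one-out (use
    ``leave_one_out_correlation`` for the excluded variant).
    """
    members = _check_members(log2_matrix, members, "group members")
    per_sample = pd.Series(
        {m: correlation_to_profile(log2_matrix.loc[m], profile, method) for m in members},
        name="correlation",
    )
    return float(per_sample.mean()), per_sample


def leave_one_out_correlation(
    log2_matrix: pd.DataFrame, members: Sequence[str], method: str = "pearson"
) -> tuple[float, pd.Series]:
    """Intra-group correlation with each member excluded from its profile."""
    members = _check_members(log2_matrix, members, "group members")
    if len(members) < 2:
        raise ValueError("leave-one-out needs at least 2 members")
    vals = {}
    for m in members:
        rest = [x for x in members if x != m]
        prof = representative_profile(log2_matrix, rest)
        vals[m] = correlation_to_profile(log2_matrix.loc[m], prof, method)
    per_sample = pd.Series(vals, name="correlation")
    return float(per_sample.mean()), per_sample


def overlap(
    counts: pd.DataFrame,
    members_a: Sequence[str],
    members_b: Sequence[str] | None = None,
    literal: bool = False,
) -> float:
    """Percent overlap between two groups (see module docstring).

    ``members_b=None`` (or identical member sets) gives intra-group overlap.
    Genera detected in only one of the two groups contribute nothing, so
    communities with disjoint support score 0.
    """
    members_a = _check_members(counts, members_a, "group A")
    if members_b is None:
        members_b = members_a
    members_b = _check_members(counts, members_b, "group B")
    sub_a = counts.loc[members_a]
    sub_b = counts.loc[members_b]
    pooled_ids = list(dict.fromkeys(members_a + members_b))
    pooled = counts.loc[pooled_ids]
    n_total = float(pooled.to_numpy().sum())
    if n_total == 0:
        raise ValueError("pooled groups contain no counts")
    detected_a = sub_a.columns[(sub_a > 0).any(axis=0)]
    detected_b = sub_b.columns[(sub_b > 0).any(axis=0)]
    shared = detected_a.intersection(detected_b)
    if len(shared) == 0:
        return 0.0
    totals = pooled[shared].sum(axis=0).to_numpy(dtype=float)
    fractions = (pooled[shared] > 0).mean(axis=0).to_numpy(dtype=float)
    if literal:
        totals = totals / len(pooled_ids)
    return float(100.0 * (totals * fractions).sum() / n_total)


def overlap_matrix(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    groups_b: Mapping[str, Sequence[str]] | None = None,
    literal: bool = False,
) -> pd.DataFrame:
    """Group × group percent-overlap table (diagonal = intra-group)."""
    cols = groups_b if groups_b is not None else groups
    out = pd.DataFrame(index=list(groups), columns=list(cols), dtype=float)
    for a, mem_a in groups.items():
        for b, mem_b in cols.items():
            out.loc[a, b] = overlap(counts, mem_a, mem_b, literal=literal)
    out.index.name = "group"
    return out


def abundance_report(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Mean relative abundance (%) per group for prominent genera.

    A genus is listed when its group-mean abundance exceeds ``threshold``
    percent in *any* group; cells for genera undetected in a group are NaN
    (rendered as "-" on export).
    """
    for name, members in groups.items():
        _check_members(counts, members, f"group {name!r}")
    props = to_proportions(counts)
    means = pd.DataFrame(
        {name: props.loc[list(members)].mean(axis=0) for name, members in groups.items()}
    )
    keep = means.index[(means > threshold).any(axis=1)]
    report = means.loc[sorted(keep)]
    detected = pd.DataFrame(
        {
            name: (counts.loc[list(members)] > 0).any(axis=0)
            for name, members in groups.items()
        }
    ).loc[report.index]
    report = report.where(detected)
    report.index.name = "genus"
    report.attrs["threshold"] = threshold
    return report


def write_table(
    frame: pd.DataFrame,
    path,
    header_lines: Iterable[str] = (),
    index_label: str | None = None,
    na_rep: str = "-",
    float_format: str = "%.4f",
) -> None:
    """TSV export with leading ``#`` header comment lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(
            fh, sep="\t", index_label=index_label, na_rep=na_rep, float_format=float_format
        )


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    counts.index.name = "sample_id"
    return counts
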