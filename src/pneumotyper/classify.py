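"""Pneumotype classification of lung samples.

Every lung sample (upper and lower lobes pooled as one "lung" site) receives
exactly one of three labels:

* ``background`` — fewer than 50 retained reads after decontamination; such
  samples carry no signal distinguishable from water controls.  A Bray-Curtis
  similarity to the NTC centroid is reported per background sample as QC but
  never gates the decision, because no compositional test is defined for it.
* ``aspirate`` — community mirroring the upper respiratory tract.
* ``unique`` — diverse community resembling chow/bedding material.

Non-background samples are seeded by their Pearson correlation to the URT
representative profile and then refined by hard reassignment to whichever of
the two current representative profiles (aspirate / unique) they correlate
with best — a two-group Pearson analogue of k-means, iterated to a fixed
point (convergence is forced by an iteration cap; empirically a handful of
passes suffice).  Ties go to ``unique``, which avoids inflating the URT-like
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import bray_curtis
from .stats import (
    RepresentativeProfile,
    correlation_to_profile,
    log2_transform,
    representative_profile,
    to_proportions,
)

BACKGROUND = "background"
ASPIRATE = "aspirate"
UNIQUE = "unique"
LABELS = (BACKGROUND, ASPIRATE, UNIQUE)


@dataclass(frozen=True)
class ClassifierConfig:
    background_count_threshold: int = 50
    initial_corr_threshold: float = 0.6
    max_iterations: int = 20
    tie_policy: str = UNIQUE
    correlation_method: str = "pearson"

    def __post_init__(self) -> None:
        if self.background_count_threshold < 0:
            raise ValueError("background_count_threshold must be >= 0")
        if not 0 < self.initial_corr_threshold < 1:
            raise ValueError("initial_corr_threshold must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tie_policy not in (ASPIRATE, UNIQUE):
            raise ValueError("tie_policy must be 'aspirate' or 'unique'")


@dataclass
class ClassificationResult:
    labels: pd.Series  # lung sample -> label
    iterations: int
    converged: bool
    correlations: pd.DataFrame  # per-sample corr_urt / corr_aspirate / corr_unique
    trace: list[dict[str, str]] = field(default_factory=list)
    ntc_similarity: pd.Series | None = None  # background-sample QC

    @property
    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(LABELS, fill_value=0)

    def to_frame(self, totals: pd.Series | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"label": self.labels})
        if totals is not None:
            out["total_reads"] = totals.reindex(out.index)
        out = out.join(self.correlations, how="left")
        if self.ntc_similarity is not None:
            out["ntc_bray_curtis"] = self.ntc_similarity.reindex(out.index)
        out.index.name = "sample_id"
        return out


def classify_background(
    counts_row: pd.Series, cfg: ClassifierConfig | None = None
) -> bool:
    """True iff the sample's total retained count is strictly below threshold."""
    cfg = cfg or ClassifierConfig()
    return int(counts_row.sum()) < cfg.background_count_threshold


def _safe_corr(row: pd.Series, profile, method: str) -> float:
    try:
        return correlation_to_profile(row, profile, method)
    except ValueError:
        return float("nan")


def initial_assignment(
    log2_lung: pd.DataFrame,
    urt_profile: RepresentativeProfile,
    cfg: ClassifierConfig | None = None,
) -> pd.Series:
    """Provisional aspirate/unique labels from correlation to the URT profile."""
    cfg = cfg or ClassifierConfig()
    if log2_lung.empty:
        raise ValueError("no non-background lung samples to assign")
    labels = {}
    for sid, row in log2_lung.iterrows():
        corr = _safe_corr(row, urt_profile, cfg.correlation_method)
        labels[sid] = ASPIRATE if corr >= cfg.initial_corr_threshold else UNIQUE
    return pd.Series(labels, name="label")


def iterate_assignments(
    log2_lung: pd.DataFrame,
    provisional: pd.Series,
    cfg: ClassifierConfig | None = None,
) -> tuple[pd.Series, int, bool, pd.DataFrame, list[dict[str, str]]]:
    """Refine labels by reassignment to the best-correlated representative.

    Repeats until labels stop changing or ``max_iterations`` is hit; stops
    early (keeping current labels) if either group empties.  Returns
    ``(labels, iterations, converged, correlations, trace)``.
    """
    cfg = cfg or ClassifierConfig()
    labels = provisional.copy()
    corr = pd.DataFrame(
        index=labels.index, columns=["corr_aspirate", "corr_unique"], dtype=float
    )
    trace: list[dict[str, str]] = [labels.to_dict()]
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        members = {lab: labels.index[labels == lab].tolist() for lab in (ASPIRATE, UNIQUE)}
        if not members[ASPIRATE] or not members[UNIQUE]:
            converged = True
            break
        profiles = {
            lab: representative_profile(log2_lung, mem, lab)
            for lab, mem in members.items()
        }
        new_labels = {}
        for sid, row in log2_lung.iterrows():
            ca = _safe_corr(row, profiles[ASPIRATE], cfg.correlation_method)
            cu = _safe_corr(row, profiles[UNIQUE], cfg.correlation_method)
            corr.loc[sid, "corr_aspirate"] = ca
            corr.loc[sid, "corr_unique"] = cu
            if np.isnan(ca) and np.isnan(cu):
                new_labels[sid] = labels[sid]
            elif np.isnan(cu) or ca > cu:
                new_labels[sid] = ASPIRATE
            elif np.isnan(ca) or cu > ca:
                new_labels[sid] = UNIQUE
            else:
                new_labels[sid] = cfg.tie_policy
        new = pd.Series(new_labels, name="label").reindex(labels.index)
        trace.append(new.to_dict())
        if new.equals(labels):
            converged = True
            labels = new
            break
        labels = new
    return labels, iterations, converged, corr, trace


def classify(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    cfg: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Full pneumotype assignment for every lung sample.

    ``counts`` is the post-decontamination genus count matrix (without the
    unassigned column); ``metadata`` must distinguish lung (UL/LL), URT and
    NTC samples.  URT, control and environmental samples never receive a
    pneumotype label.
    """
    cfg = cfg or ClassifierConfig()
    meta = metadata.loc[metadata.index.intersection(counts.index)]
    lung_ids = meta.index[meta["site"].isin(("UL", "LL"))].tolist()
    if not lung_ids:
        raise ValueError("no lung (UL/LL) samples in metadata")
    urt_ids = meta.index[meta["site"] == "URT"].tolist()
    if not urt_ids:
        raise ValueError("no URT samples available for the initial assignment")

    totals = counts.loc[lung_ids].sum(axis=1)
    background = [sid for sid in lung_ids if classify_background(counts.loc[sid], cfg)]
    nonbg = [sid for sid in lung_ids if sid not in background]

    log2_all = log2_transform(counts)
    urt_prof = representative_profile(log2_all, urt_ids, "urt")

    corr = pd.DataFrame(
        index=lung_ids,
        columns=["corr_urt", "corr_aspirate", "corr_unique"],
        dtype=float,
    )
    for sid in lung_ids:
        corr.loc[sid, "corr_urt"] = _safe_corr(
            log2_all.loc[sid], urt_prof, cfg.correlation_method
        )

    labels = pd.Series(BACKGROUND, index=lung_ids, name="label")
    iterations, converged, trace = 0, True, []
    if nonbg:
        provisional = initial_assignment(log2_all.loc[nonbg], urt_prof, cfg)
        refined, iterations, converged, it_corr, trace = iterate_assignments(
            log2_all.loc[nonbg], provisional, cfg
        )
        labels.loc[refined.index] = refined
        corr.loc[it_corr.index, ["corr_aspirate", "corr_unique"]] = it_corr

    ntc_ids = meta.index[meta["site"].str.upper() == "NTC"].tolist()
    ntc_sim = None
    if ntc_ids and background:
        props = to_proportions(counts)
        ntc_centroid = props.loc[ntc_ids].mean(axis=0)
        sims = {}
        for sid in background:
            row = props.loc[sid]
            if row.sum() == 0 or ntc_centroid.sum() == 0:
                sims[sid] = float("nan")
            else:
                sims[sid] = bray_curtis(row.to_numpy(), ntc_centroid.to_numpy())
        ntc_sim = pd.Series(sims, name="ntc_bray_curtis")

    result = ClassificationResult(
        labels=labels,
        iterations=iterations,
        converged=converged,
        correlations=corr,
        trace=trace,
        ntc_similarity=ntc_sim,
    )
    result.totals = totals  # type: ignore[attr-defined]
    return result


def recovery_rate(labels: pd.Series, truth: pd.Series) -> float:
    """Fraction of lung samples whose label matches the generating truth."""
    common = labels.index.intersection(truth.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between labels and truth")
    return float((labels.loc[common] == truth.loc[common]).mean())


def write_labels(
    result: ClassificationResult,
    path: str | Path,
    totals: pd.Series | None = None,
    header_lines: Sequence[str] = (),
) -> Path:
    path = Path(path)
    frame = result.to_frame(totals if totals is not None else getattr(result, "totals", None))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            f"# iterations={result.iterations} converged={result.converged}\n"
        )
        frame.to_csv(fh, sep="\t", float_format="%.4f", na_rep="NA")
    return path
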