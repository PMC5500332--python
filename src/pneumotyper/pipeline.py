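"""End-to-end orchestration: simulate → join → filter → tabulate → classify →
statistics → diversity, as one reproducible run.

Desk (synthetic) runs draw a scenario, optionally at read level with
contaminant spiking and in-silico decontamination against the simulated
reagent/NTC controls, then produce the full report bundle: count matrices,
filter report, pneumotype labels, representative profiles, correlation
table, group/environment overlap matrices, abundance report and diversity
summaries — all as TSV with a header comment carrying the seed, a config
hash and the statistic-variant flags.

Real-data runs (FASTQ + metadata) stop after the decontamination stage unless
a per-contig genus annotation table is supplied, since external taxonomy
assignment is outside this package's scope.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ASPIRATE, BACKGROUND, UNIQUE, ClassifierConfig, classify
from .diversity import (
    distance_matrix,
    inverse_simpson,
    permanova,
    rarefied_chao1,
)
from .reads import (
    FilterConfig,
    build_contaminant_index,
    drop_unassigned,
    filter_contigs,
    join_samples,
    tabulate_counts,
)
from .stats import (
    abundance_report,
    group_correlation,
    log2_transform,
    overlap_matrix,
    representative_profile,
    to_proportions,
    write_table,
)
from .synth import (
    Scenario,
    paper_default,
    simulate_scenario,
    write_metadata,
)

logger = logging.getLogger("pneumotyper")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    scenario: Scenario | None = None
    read_level: bool = True
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    classifier_cfg: ClassifierConfig = field(default_factory=ClassifierConfig)
    rarefaction_depth: int = 340
    rarefaction_reps: int = 50
    n_permutations: int = 999
    overlap_literal: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.scenario is None:
            self.scenario = paper_default()

    def config_hash(self) -> str:
        blob = repr(
            (
                self.seed,
                self.scenario,
                self.read_level,
                self.filter_cfg,
                self.classifier_cfg,
                self.rarefaction_depth,
                self.rarefaction_reps,
                self.n_permutations,
                self.overlap_literal,
            )
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [
            f"pneumotyper {__version__}",
            f"seed={self.seed} config_hash={self.config_hash()}",
            "variants: overlap="
            + ("literal" if self.overlap_literal else "pooled")
            + " chao1=classic,bias_corrected_at_F2=0 correlation="
            + self.classifier_cfg.correlation_method,
        ]


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    version: str
    files: dict[str, str]  # relative path -> sha256
    started: float
    finished: float

    def to_json(self, path: Path) -> Path:
        payload = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "files": self.files,
            "started": self.started,
            "finished": self.finished,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [logging.StreamHandler(sys.stderr)]
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute a full synthetic-scenario run and write the report bundle."""
    started = time.time()
    outdir = config.outdir
    _setup_logging(outdir)
    header = config.header_lines()
    written: list[Path] = []

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("simulate")
        sim = simulate_scenario(
            config.scenario, config.seed, with_reads=config.read_level
        )
        written.append(write_metadata(sim.metadata, outdir / "metadata.tsv"))
        write_table(sim.counts, outdir / "counts_true.tsv", header, "sample_id", float_format="%d")
        written.append(outdir / "counts_true.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    if config.read_level:
        try:
            _stage("join")
            contigs, unjoined = join_samples(sim.reads, config.filter_cfg)
            ctl_contigs, _ = join_samples(sim.control_reads, config.filter_cfg)
            logger.info("unjoined pairs: %d", sum(unjoined.values()))
        except Exception as exc:  # noqa: BLE001
            raise StageError("join", exc) from exc
        try:
            _stage("filter")
            all_controls = [c for lst in ctl_contigs.values() for c in lst]
            index = build_contaminant_index(
                all_controls,
                k=config.filter_cfg.k,
                include_revcomp=config.filter_cfg.check_reverse_complement,
            )
            retained, report = filter_contigs(contigs, index, config.filter_cfg)
            written.append(report.to_tsv(outdir / "filter_report.tsv", header))
        except Exception as exc:  # noqa: BLE001
            raise StageError("filter", exc) from exc
        try:
            _stage("tabulate")
            counts_obs = tabulate_counts(
                retained, sim.refs, config.filter_cfg, sim.counts.columns
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("tabulate", exc) from exc
    else:
        counts_obs = sim.counts.copy()
    write_table(counts_obs, outdir / "counts_observed.tsv", header, "sample_id", float_format="%d")
    written.append(outdir / "counts_observed.tsv")

    counts = drop_unassigned(counts_obs)
    meta = sim.metadata

    try:
        _stage("classify")
        result = classify(counts, meta, config.classifier_cfg)
        from .classify import write_labels

        written.append(
            write_labels(result, outdir / "labels.tsv", header_lines=header)
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    try:
        _stage("stats")
        groups = {
            "urt": meta.index[meta["site"] == "URT"].tolist(),
            ASPIRATE: result.labels.index[result.labels == ASPIRATE].tolist(),
            UNIQUE: result.labels.index[result.labels == UNIQUE].tolist(),
        }
        groups = {k: v for k, v in groups.items() if v}
        log2 = log2_transform(counts)
        profiles = {
            name: representative_profile(log2, members, name)
            for name, members in groups.items()
        }
        prof_frame = pd.DataFrame({n: p.values for n, p in profiles.items()})
        prof_frame.index.name = "genus"
        write_table(prof_frame, outdir / "representative_profiles.tsv", header, "genus")
        written.append(outdir / "representative_profiles.tsv")

        corr = pd.DataFrame(index=list(groups), columns=list(groups), dtype=float)
        for a, members in groups.items():
            for b, prof in profiles.items():
                corr.loc[a, b], _ = group_correlation(
                    log2, members, prof, config.classifier_cfg.correlation_method
                )
        corr.index.name = "group"
        write_table(corr, outdir / "correlation_table.tsv", header, "group")
        written.append(outdir / "correlation_table.tsv")

        write_table(
            overlap_matrix(counts, groups, literal=config.overlap_literal),
            outdir / "overlap_groups.tsv",
            header,
            "group",
        )
        written.append(outdir / "overlap_groups.tsv")

        env_groups = {
            src: meta.index[meta["site"] == src].tolist()
            for src in ("bedding", "chow", "water")
        }
        env_groups = {
            k: [s for s in v if counts.loc[s].sum() > 0] for k, v in env_groups.items()
        }
        env_groups = {k: v for k, v in env_groups.items() if v}
        if env_groups:
            write_table(
                overlap_matrix(
                    counts, env_groups, groups, literal=config.overlap_literal
                ),
                outdir / "overlap_environment.tsv",
                header,
                "environmental_source",
            )
            written.append(outdir / "overlap_environment.tsv")

        write_table(
            abundance_report(counts, groups),
            outdir / "abundance_report.tsv",
            header,
            "genus",
            float_format="%.2f",
        )
        written.append(outdir / "abundance_report.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("stats", exc) from exc

    try:
        _stage("diversity")
        tissue_ids = [s for members in groups.values() for s in members]
        alpha_rows = []
        for i, sid in enumerate(tissue_ids):
            row = counts.loc[sid]
            total = int(row.sum())
            inv = inverse_simpson(row) if total > 0 else float("nan")
            ch = rarefied_chao1(
                row,
                config.rarefaction_depth,
                config.rarefaction_reps,
                seed=config.seed * 100003 + i,
            )
            if np.isnan(ch):
                logger.info(
                    "rarefaction skipped for %s (total %d < depth %d)",
                    sid,
                    total,
                    config.rarefaction_depth,
                )
            alpha_rows.append((sid, total, inv, ch))
        alpha = pd.DataFrame(
            alpha_rows,
            columns=["sample_id", "total_reads", "inverse_simpson", "chao1_rarefied"],
        ).set_index("sample_id")
        alpha["group"] = pd.Series(
            {s: g for g, members in groups.items() for s in members}
        )
        write_table(alpha, outdir / "diversity_alpha.tsv", header, "sample_id")
        written.append(outdir / "diversity_alpha.tsv")

        props = to_proportions(counts.loc[tissue_ids])
        dist = distance_matrix(props)
        write_table(dist, outdir / "bray_curtis.tsv", header, "sample_id")
        written.append(outdir / "bray_curtis.tsv")

        site_labels = alpha["group"]
        perm_rows = []
        big_enough = site_labels.value_counts()
        usable = site_labels.index[
            site_labels.isin(big_enough.index[big_enough >= 2])
        ]
        if usable.size >= 4 and site_labels.loc[usable].nunique() >= 2:
            res = permanova(
                dist.loc[usable, usable],
                site_labels.loc[usable],
                config.n_permutations,
                seed=config.seed + 1,
            )
            perm_rows.append(
                ("group", res.f_statistic, res.p_value, res.r_squared, res.n_permutations)
            )
        else:
            logger.info("group-factor PERMANOVA skipped: groups too small")
        animals = meta.loc[tissue_ids, "animal_id"]
        animal_counts = animals.value_counts()
        keep = animals.index[animals.isin(animal_counts.index[animal_counts >= 2]) & (animals != "")]
        if keep.size >= 4 and animals.loc[keep].nunique() >= 2:
            sub = dist.loc[keep, keep]
            try:
                res_a = permanova(
                    sub, animals.loc[keep], config.n_permutations, seed=config.seed + 2
                )
                perm_rows.append(
                    ("animal", res_a.f_statistic, res_a.p_value, res_a.r_squared, res_a.n_permutations)
                )
            except ValueError as exc:
                logger.info("animal-factor PERMANOVA skipped: %s", exc)
        perm = pd.DataFrame(
            perm_rows, columns=["factor", "pseudo_F", "p_value", "r_squared", "n_permutations"]
        ).set_index("factor")
        write_table(perm, outdir / "permanova.tsv", header, "factor")
        written.append(outdir / "permanova.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("diversity", exc) from exc

    written.append(outdir / "metadata.tsv")
    manifest = RunManifest(
        seed=config.seed,
        config_hash=config.config_hash(),
        version=__version__,
        files={str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))},
        started=started,
        finished=time.time(),
    )
    manifest.to_json(outdir / "run_manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# input validation (real-data mode)
# ---------------------------------------------------------------------------

ALLOWED_SITES = {"URT", "UL", "LL", "NTC", "reagent", "bedding", "chow", "water"}
ALLOWED_ROLES = {"specimen", "control", "environmental"}


def validate_inputs(fastq_dir: str | Path, metadata: pd.DataFrame) -> list[str]:
    """Check FASTQ pairing and metadata completeness; returns error messages."""
    fastq_dir = Path(fastq_dir)
    errors: list[str] = []
    seen = set()
    for lineno, (_, row) in enumerate(metadata.iterrows(), start=2):
        sid = row["sample_id"]
        if sid in seen:
            errors.append(f"metadata line {lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        if row["site"] not in ALLOWED_SITES:
            errors.append(
                f"metadata line {lineno}: unknown site {row['site']!r}; "
                f"allowed: {sorted(ALLOWED_SITES)}"
            )
        if row["role"] not in ALLOWED_ROLES:
            errors.append(
                f"metadata line {lineno}: unknown role {row['role']!r}; "
                f"allowed: {sorted(ALLOWED_ROLES)}"
            )
        r1 = fastq_dir / f"{sid}_R1.fastq"
        r2 = fastq_dir / f"{sid}_R2.fastq"
        if r1.exists() != r2.exists():
            missing = "R2" if r1.exists() else "R1"
            errors.append(f"sample {sid!r}: missing {missing} mate file")
        elif not r1.exists():
            errors.append(f"sample {sid!r}: no FASTQ files in {fastq_dir}")
    for path in sorted(fastq_dir.glob("*_R1.fastq")):
        sid = path.name[: -len("_R1.fastq")]
        if sid not in seen:
            errors.append(f"FASTQ sample {sid!r} has no metadata row")
    return errors


def run_real_data(
    fastq_dir: str | Path,
    metadata: pd.DataFrame,
    outdir: str | Path,
    filter_cfg: FilterConfig | None = None,
    annotation: pd.Series | None = None,
) -> dict[str, Path]:
    """Join, decontaminate and (optionally) tabulate deposited FASTQ data.

    Control samples (role ``control``) seed the contaminant index.  Without a
    per-contig genus ``annotation`` (contig id → genus), the run stops after
    writing retained contigs and the filter report.
    """
    from .reads import pairs_to_batch, read_fastq_pairs, write_contigs_fasta

    fastq_dir = Path(fastq_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    filter_cfg = filter_cfg or FilterConfig()
    errors = validate_inputs(fastq_dir, metadata)
    if errors:
        raise ValueError("invalid inputs:\n" + "\n".join(errors))
    batches = {}
    for sid in metadata["sample_id"]:
        pairs = read_fastq_pairs(
            fastq_dir / f"{sid}_R1.fastq", fastq_dir / f"{sid}_R2.fastq", sid
        )
        batches[sid] = pairs_to_batch(pairs, sid)
    contigs, _ = join_samples(batches, filter_cfg)
    control_ids = metadata.loc[metadata["role"] == "control", "sample_id"]
    control_contigs = [c for sid in control_ids for c in contigs.get(sid, [])]
    specimen_contigs = {
        sid: contigs[sid]
        for sid in metadata.loc[metadata["role"] != "control", "sample_id"]
    }
    index = build_contaminant_index(
        control_contigs, filter_cfg.k, filter_cfg.check_reverse_complement
    )
    retained, report = filter_contigs(specimen_contigs, index, filter_cfg)
    out = {}
    out["filter_report"] = report.to_tsv(outdir / "filter_report.tsv")
    all_retained = [c for lst in retained.values() for c in lst]
    out["retained_fasta"] = write_contigs_fasta(
        all_retained, outdir / "retained_contigs.fasta"
    )
    if annotation is not None:
        rows = {}
        for sid, lst in retained.items():
            tally: dict[str, int] = {}
            for c in lst:
                genus = annotation.get(c.id, "unassigned")
                tally[genus] = tally.get(genus, 0) + 1
            rows[sid] = tally
        counts = pd.DataFrame(rows).T.fillna(0).astype(int)
        counts.index.name = "sample_id"
        write_table(counts, outdir / "counts_observed.tsv", (), "sample_id", float_format="%d")
        out["counts"] = outdir / "counts_observed.tsv"
    return out
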