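"""Synthetic community generator for the low-biomass lung microbiome scenario.

Emulates the statistical structure the downstream analysis assumes:

* a deep, highly conserved upper-respiratory-tract (URT) community;
* lung samples split over three pneumotypes — ``background`` (fewer than ~50
  reads, indistinguishable from water controls), ``aspirate`` (URT-like) and
  ``unique`` (diverse, chow/bedding-like);
* reagent and no-template (NTC) controls containing only reagent-contaminant
  sequences (*Pseudomonas*/*Escherichia*-dominated);
* environmental sources (cage bedding, rodent chow, drinking water).

Counts are drawn from a Dirichlet-multinomial around each group profile with a
log-normal sequencing-depth law; reads are error-bearing paired-end copies of
per-genus reference amplicons.  Every draw is a pure function of
``(configuration, seed)``: the global seed is expanded into per-operation,
per-sample substreams keyed by fixed stream numbers and CRC32 of the sample
name, so adding samples never perturbs earlier ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from . import profiles as _shipped
from ._seq import BASES, decode, encode, revcomp

# fixed substream identifiers (see module docstring)
_STREAM_REFS = 1
_STREAM_COUNTS = 2
_STREAM_READS = 3
_STREAM_SPIKE = 4
_STREAM_SCENARIO = 5


def _substream(seed: int, stream: int, *names: str) -> np.random.Generator:
    key = [int(seed), stream] + [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(key)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenusProfile:
    """A named genus → relative-abundance map, normalized to sum to one."""

    name: str
    abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.abundances.values()), dtype=float)
        if len(self.abundances) == 0:
            raise ValueError("profile must contain at least one genus")
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise ValueError("abundances must be finite and non-negative")
        total = vals.sum()
        if total <= 0:
            raise ValueError("profile abundances must not all be zero")
        norm = {g: v / total for g, v in self.abundances.items()}
        object.__setattr__(self, "abundances", norm)

    @classmethod
    def from_percent(cls, name: str, percent: Mapping[str, float]) -> "GenusProfile":
        return cls(name=name, abundances=dict(percent))

    @property
    def genera(self) -> list[str]:
        return list(self.abundances)

    def as_series(self, genus_universe: Iterable[str] | None = None) -> pd.Series:
        s = pd.Series(self.abundances, dtype=float, name=self.name)
        if genus_universe is not None:
            s = s.reindex(list(genus_universe), fill_value=0.0)
        return s


@dataclass(frozen=True)
class GroupSpec:
    """Sampling law for one group: profile + depth law + overdispersion.

    ``depth_log_mean``/``depth_log_sd`` parametrize a log-normal read-depth
    distribution on the natural-log scale; ``dispersion`` scales the Dirichlet
    concentration (higher pulls samples toward the profile).
    """

    name: str
    profile: GenusProfile
    n_samples: int
    depth_log_mean: float
    depth_log_sd: float = 0.4
    dispersion: float = 100.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not np.isfinite(self.depth_log_sd) or self.depth_log_sd < 0:
            raise ValueError("depth_log_sd must be finite and >= 0")
        if np.isnan(self.depth_log_mean) or self.depth_log_mean == np.inf:
            raise ValueError("depth_log_mean must be finite or -inf")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")

    @classmethod
    def with_median_depth(
        cls,
        name: str,
        profile: GenusProfile,
        n_samples: int,
        depth_median: float,
        depth_log_sd: float = 0.4,
        dispersion: float = 100.0,
    ) -> "GroupSpec":
        mean = np.log(depth_median) if depth_median > 0 else -np.inf
        return cls(name, profile, n_samples, mean, depth_log_sd, dispersion)

    @property
    def depth_median(self) -> float:
        return float(np.exp(self.depth_log_mean))


@dataclass(frozen=True)
class ReferenceSequenceSet:
    """Genus → reference amplicon sequence (all the same length).

    Pairwise identity between any two references must stay below 0.9 so a
    97%-identity genus assignment can never be ambiguous.
    """

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference set must not be empty")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("all reference sequences must have the same length")
        for g, s in self.sequences.items():
            if set(s) - set("ACGT"):
                raise ValueError(f"reference for {g} contains non-ACGT characters")
        object.__setattr__(self, "sequences", dict(self.sequences))

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def genera(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, genus: str) -> str:
        return self.sequences[genus]

    def __contains__(self, genus: str) -> bool:
        return genus in self.sequences

    def encoded(self) -> dict[str, np.ndarray]:
        return {g: encode(s) for g, s in self.sequences.items()}


@dataclass(frozen=True)
class ContaminantSpec:
    """Reagent-contamination model.

    ``load`` is the expected (Poisson) number of contaminant read pairs added
    to each specimen sample.  The control arm mirrors the study design: a set
    of reagent controls plus no-template (NTC) water controls whose reads are
    drawn exclusively from the contaminant profile.
    """

    profile: GenusProfile
    load: float = 30.0
    n_reagent: int = 8
    n_ntc: int = 3
    reagent_depth: float = 800.0
    ntc_depth: float = 30.0

    def __post_init__(self) -> None:
        if self.load < 0:
            raise ValueError("contaminant load must be >= 0")
        if self.reagent_depth < 0 or self.ntc_depth < 0:
            raise ValueError("control depths must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Read-level simulation parameters."""

    seed: int
    groups: tuple[GroupSpec, ...] = ()
    contaminant: ContaminantSpec | None = None
    read_length: int = 150
    reference_length: int = 254
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if 2 * self.read_length - self.reference_length < 6:
            raise ValueError(
                "reads must overlap by at least 6 bases: need "
                "2*read_length - reference_length >= 6"
            )
        if not (0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must be in [0, 0.25)")


# ---------------------------------------------------------------------------
# read batches
# ---------------------------------------------------------------------------


@dataclass
class ReadBatch:
    """A vectorized collection of read pairs from one sample.

    ``fwd``/``rev`` are (n, read_length) uint8 arrays.  Read ids carry the
    originating sample and true genus purely as a test oracle; inference code
    must never parse them.
    """

    sample_id: str
    ids: list[str]
    fwd: np.ndarray
    rev: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        for i, rid in enumerate(self.ids):
            yield rid, decode(self.fwd[i]), decode(self.rev[i])

    @classmethod
    def empty(cls, sample_id: str, read_length: int) -> "ReadBatch":
        z = np.zeros((0, read_length), dtype=np.uint8)
        return cls(sample_id, [], z, z.copy())

    @classmethod
    def concat(cls, batches: list["ReadBatch"]) -> "ReadBatch":
        if not batches:
            raise ValueError("cannot concatenate zero batches")
        sid = batches[0].sample_id
        return cls(
            sid,
            [rid for b in batches for rid in b.ids],
            np.concatenate([b.fwd for b in batches]),
            np.concatenate([b.rev for b in batches]),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    return float((a == b).mean())


def make_reference_sequences(
    genera: list[str], length: int = 254, seed: int = 0
) -> ReferenceSequenceSet:
    """Generate one random reference amplicon per genus.

    Rejects and regenerates any candidate whose ungapped identity to an
    already-accepted reference is >= 0.9, so that genus assignment at a 97%
    threshold is unambiguous.  Deterministic for a fixed seed.
    """
    if not genera:
        raise ValueError("genus list must not be empty")
    if len(set(genera)) != len(genera):
        raise ValueError("genus names must be unique")
    if length < 250:
        raise ValueError(
            "reference length must be >= 250 (the decontamination rule "
            "requires matches of at least 250 bp)"
        )
    rng = _substream(seed, _STREAM_REFS)
    accepted: dict[str, np.ndarray] = {}
    for genus in genera:
        for _attempt in range(1000):
            cand = rng.integers(0, 4, size=length).astype(np.uint8)
            if all(_pairwise_identity(cand, prev) < 0.90 for prev in accepted.values()):
                accepted[genus] = cand
                break
        else:  # pragma: no cover - astronomically unlikely for random 250-mers
            raise RuntimeError(f"could not place a distinct reference for {genus}")
    return ReferenceSequenceSet({g: decode(a) for g, a in accepted.items()})


def simulate_counts(
    spec: GroupSpec,
    seed: int,
    genus_universe: Iterable[str] | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw a samples × genera count matrix for one group.

    Per sample: depth ~ round(LogNormal(depth_log_mean, depth_log_sd));
    genus proportions ~ Dirichlet(dispersion × profile) over the profile's
    support; counts ~ Multinomial(depth, proportions).
    """
    if sample_ids is None:
        sample_ids = [f"{spec.name}_s{i + 1:02d}" for i in range(spec.n_samples)]
    if len(sample_ids) != spec.n_samples:
        raise ValueError("sample_ids length must equal n_samples")
    support = spec.profile.genera
    alpha = spec.dispersion * np.asarray(
        [spec.profile.abundances[g] for g in support], dtype=float
    )
    rows = np.zeros((spec.n_samples, len(support)), dtype=np.int64)
    for i, sid in enumerate(sample_ids):
        rng = _substream(seed, _STREAM_COUNTS, spec.name, sid)
        if np.isneginf(spec.depth_log_mean):
            continue
        depth = int(round(rng.lognormal(spec.depth_log_mean, spec.depth_log_sd)))
        if depth <= 0:
            continue
        p = rng.dirichlet(alpha)
        rows[i] = rng.multinomial(depth, p)
    mat = pd.DataFrame(rows, index=sample_ids, columns=support)
    if genus_universe is not None:
        mat = mat.reindex(columns=list(genus_universe), fill_value=0)
    return mat


def _reads_for_genus_counts(
    rng: np.random.Generator,
    sample_id: str,
    genus_counts: Mapping[str, int],
    encoded_refs: Mapping[str, np.ndarray],
    read_length: int,
    error_rate: float,
    id_prefix: str = "",
    scramble_labels: bool = False,
) -> ReadBatch:
    """Build the error-bearing read pairs for one sample's genus counts."""
    total = int(sum(genus_counts.values()))
    if total == 0:
        return ReadBatch.empty(sample_id, read_length)
    fwd = np.empty((total, read_length), dtype=np.uint8)
    rev = np.empty((total, read_length), dtype=np.uint8)
    ids: list[str] = []
    pos = 0
    for genus, c in genus_counts.items():
        if c == 0:
            continue
        ref = encoded_refs[genus]
        fwd[pos : pos + c] = ref[:read_length]
        rev[pos : pos + c] = revcomp(ref[-read_length:])
        label = "x" if scramble_labels else genus
        ids.extend(f"{id_prefix}{sample_id}|{label}|{pos + j}" for j in range(c))
        pos += c
    if error_rate > 0:
        for arr in (fwd, rev):
            mask = rng.random(arr.shape) < error_rate
            shift = rng.integers(1, 4, size=arr.shape, dtype=np.uint8)
            arr[mask] = (arr[mask] + shift[mask]) % 4
    return ReadBatch(sample_id, ids, fwd, rev)


def counts_to_read_pairs(
    counts: pd.DataFrame,
    refs: ReferenceSequenceSet,
    cfg: SimulationConfig,
    scramble_labels: bool = False,
) -> dict[str, ReadBatch]:
    """Turn a count matrix into per-sample paired-read collections.

    For a genus count ``c`` in a sample, emits exactly ``c`` read pairs:
    forward read = first ``read_length`` bases of the genus reference,
    reverse read = reverse complement of the last ``read_length`` bases, each
    base independently substituted with probability ``error_rate``.
    """
    present = counts.columns[(counts.to_numpy() > 0).any(axis=0)]
    missing = [g for g in present if g not in refs]
    if missing:
        raise KeyError(f"no reference sequence for genera: {missing}")
    enc = {g: refs_enc for g, refs_enc in refs.encoded().items() if g in counts.columns}
    out: dict[str, ReadBatch] = {}
    for sid, row in counts.iterrows():
        rng = _substream(cfg.seed, _STREAM_READS, str(sid))
        genus_counts = {g: int(v) for g, v in row.items() if v > 0}
        out[str(sid)] = _reads_for_genus_counts(
            rng,
            str(sid),
            genus_counts,
            enc,
            cfg.read_length,
            cfg.error_rate,
            scramble_labels=scramble_labels,
        )
    return out


def spike_contaminants(
    samples: dict[str, ReadBatch],
    spec: ContaminantSpec,
    refs: ReferenceSequenceSet,
    cfg: SimulationConfig,
    seed: int | None = None,
    emit_controls: bool = True,
    scramble_labels: bool = False,
) -> tuple[dict[str, ReadBatch], dict[str, ReadBatch]]:
    """Add Poisson(load) contaminant read pairs to every specimen sample.

    Also emits reagent-control and NTC read collections containing only
    contaminant-derived reads (unless ``emit_controls`` is False).  Returns
    ``(augmented_samples, control_samples)``.
    """
    if seed is None:
        seed = cfg.seed
    missing = [g for g in spec.profile.genera if g not in refs]
    if missing:
        raise KeyError(f"no reference sequence for contaminant genera: {missing}")
    enc = refs.encoded()
    genera = spec.profile.genera
    p = np.asarray([spec.profile.abundances[g] for g in genera])

    def _contaminant_batch(
        rng: np.random.Generator, sid: str, n: int, prefix: str
    ) -> ReadBatch:
        per_genus = rng.multinomial(n, p) if n > 0 else np.zeros(len(p), dtype=int)
        return _reads_for_genus_counts(
            rng,
            sid,
            dict(zip(genera, per_genus.tolist())),
            enc,
            cfg.read_length,
            cfg.error_rate,
            id_prefix=prefix,
            scramble_labels=scramble_labels,
        )

    augmented: dict[str, ReadBatch] = {}
    for sid, batch in samples.items():
        rng = _substream(seed, _STREAM_SPIKE, sid)
        n = int(rng.poisson(spec.load))
        spiked = _contaminant_batch(rng, sid, n, prefix="spk:")
        augmented[sid] = ReadBatch.concat([batch, spiked]) if len(spiked) else batch

    controls: dict[str, ReadBatch] = {}
    if emit_controls:
        for kind, count, depth in (
            ("reagent", spec.n_reagent, spec.reagent_depth),
            ("ntc", spec.n_ntc, spec.ntc_depth),
        ):
            for i in range(count):
                sid = f"{kind}{i + 1:02d}"
                rng = _substream(seed, _STREAM_SPIKE, sid)
                n = int(rng.poisson(depth))
                controls[sid] = _contaminant_batch(rng, sid, n, prefix="")
    return augmented, controls


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

LUNG_SITES = ("UL", "LL")
SITES = ("URT", "UL", "LL", "NTC", "reagent", "bedding", "chow", "water")


def default_profiles() -> dict[str, GenusProfile]:
    p = GenusProfile.from_percent
    return {
        "urt": p("urt", _shipped.URT_PERCENT),
        "lung_aspirate": p("lung_aspirate", _shipped.LUNG_ASPIRATE_PERCENT),
        "lung_unique": p("lung_unique", _shipped.LUNG_UNIQUE_PERCENT),
        "contaminant": p("contaminant", _shipped.CONTAMINANT_PERCENT),
        "bedding": p("bedding", _shipped.BEDDING_PERCENT),
        "chow": p("chow", _shipped.CHOW_PERCENT),
        "water": p("water", _shipped.WATER_PERCENT),
    }


@dataclass(frozen=True)
class Scenario:
    """Full study design: who is sampled, at what depth, from which profile."""

    name: str
    n_animals: int
    pneumotype_counts: Mapping[str, int]  # background/unique/aspirate over lung slots
    group_specs: Mapping[str, GroupSpec]  # urt, lung_*, bedding, chow, water
    contaminant: ContaminantSpec
    n_environment: int = 3
    read_length: int = 150
    reference_length: int = 254
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        n_lung = self.n_animals * len(LUNG_SITES)
        if sum(self.pneumotype_counts.values()) != n_lung:
            raise ValueError(
                f"pneumotype counts must sum to {n_lung} lung samples"
            )

    def genus_universe(self) -> list[str]:
        names: set[str] = set(self.contaminant.profile.genera)
        for gs in self.group_specs.values():
            names.update(gs.profile.genera)
        return sorted(names)

    def sim_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            seed=seed,
            groups=tuple(self.group_specs.values()),
            contaminant=self.contaminant,
            read_length=self.read_length,
            reference_length=self.reference_length,
            error_rate=self.error_rate,
        )


def paper_default(
    n_animals: int = 18,
    urt_depth: float = 50_000.0,
    aspirate_depth: float = 3_000.0,
    unique_depth: float = 300.0,
    background_depth: float = 15.0,
    environment_depth: float = 10_000.0,
    contaminant_load: float = 30.0,
    error_rate: float = 0.002,
    name: str = "paper_default",
) -> Scenario:
    """The shipped default scenario.

    18 animals, URT + two lung sites each; lung slots split 12/21/3 over the
    background/unique/aspirate pneumotypes (the 33/58/9% mix); 8 reagent + 3
    NTC controls; 3 samples per environmental source.  Depth medians follow
    the study's qualitative structure: the URT carries orders of magnitude
    more bacterial 16S material than the lung, background lung samples sit
    below the 50-read floor, and NTCs are shallow.
    """
    prof = default_profiles()
    n_lung = n_animals * len(LUNG_SITES)
    n_bg = round(n_lung / 3)
    n_asp = max(1, round(0.09 * n_lung))
    n_unique = n_lung - n_bg - n_asp
    mk = GroupSpec.with_median_depth
    group_specs = {
        "urt": mk("urt", prof["urt"], n_animals, urt_depth, 0.3, dispersion=500),
        "lung_background": mk(
            "lung_background", prof["contaminant"], n_bg, background_depth, 0.5, 50
        ),
        "lung_unique": mk(
            "lung_unique", prof["lung_unique"], n_unique, unique_depth, 0.5, 20
        ),
        "lung_aspirate": mk(
            "lung_aspirate", prof["lung_aspirate"], n_asp, aspirate_depth, 0.5, 100
        ),
        "bedding": mk("bedding", prof["bedding"], 3, environment_depth, 0.3, 100),
        "chow": mk("chow", prof["chow"], 3, environment_depth, 0.3, 100),
        "water": mk("water", prof["water"], 3, environment_depth, 0.3, 100),
    }
    contaminant = ContaminantSpec(profile=prof["contaminant"], load=contaminant_load)
    return Scenario(
        name=name,
        n_animals=n_animals,
        pneumotype_counts={"background": n_bg, "unique": n_unique, "aspirate": n_asp},
        group_specs=group_specs,
        contaminant=contaminant,
        error_rate=error_rate,
    )


def desk_scenario(**overrides) -> Scenario:
    """`paper_default` with depths scaled down for fast read-level runs."""
    kw = dict(
        urt_depth=2_000.0,
        aspirate_depth=1_200.0,
        environment_depth=2_000.0,
        name="paper_default_desk",
    )
    kw.update(overrides)
    return paper_default(**kw)


@dataclass
class SimulationResult:
    """Everything one scenario draw produces."""

    scenario: Scenario
    seed: int
    counts: pd.DataFrame  # all samples × genus universe (ground truth)
    metadata: pd.DataFrame  # sample_id, site, animal_id, role (+ pneumotype truth)
    truth: pd.Series  # lung sample_id -> generating pneumotype
    refs: ReferenceSequenceSet
    reads: dict[str, ReadBatch] | None = None  # specimen + environmental
    control_reads: dict[str, ReadBatch] | None = None  # reagent + NTC


def simulate_scenario(
    scenario: Scenario,
    seed: int,
    with_reads: bool = False,
    scramble_labels: bool = False,
) -> SimulationResult:
    """Draw a full study from a scenario.

    The returned ``counts`` matrix is the pre-contamination ground truth for
    specimen/environmental samples; control rows are draws from the
    contaminant profile.  With ``with_reads=True``, error-bearing read pairs
    are generated for every specimen/environmental sample (plus Poisson
    contaminant spiking) and pure-contaminant control read collections are
    emitted.
    """
    rng = _substream(seed, _STREAM_SCENARIO)
    universe = scenario.genus_universe()
    gs = scenario.group_specs

    # sample bookkeeping -----------------------------------------------------
    meta_rows: list[dict[str, str]] = []
    urt_ids = [f"a{i + 1:02d}_URT" for i in range(scenario.n_animals)]
    for sid in urt_ids:
        meta_rows.append(
            {"sample_id": sid, "site": "URT", "animal_id": sid.split("_")[0], "role": "specimen"}
        )
    lung_ids = [
        f"a{i + 1:02d}_{site}"
        for i in range(scenario.n_animals)
        for site in LUNG_SITES
    ]
    labels = [
        lab
        for lab, n in scenario.pneumotype_counts.items()
        for _ in range(n)
    ]
    perm = rng.permutation(len(lung_ids))
    truth = pd.Series(
        {lung_ids[j]: labels[k] for k, j in enumerate(perm)}, name="pneumotype"
    ).loc[lung_ids]
    for sid in lung_ids:
        meta_rows.append(
            {"sample_id": sid, "site": sid.split("_")[1], "animal_id": sid.split("_")[0], "role": "specimen"}
        )
    env_ids = {
        src: [f"{src}{i + 1:02d}" for i in range(scenario.n_environment)]
        for src in ("bedding", "chow", "water")
    }
    for src, ids in env_ids.items():
        for sid in ids:
            meta_rows.append(
                {"sample_id": sid, "site": src, "animal_id": "", "role": "environmental"}
            )
    ctl = scenario.contaminant
    control_ids = {
        "reagent": [f"reagent{i + 1:02d}" for i in range(ctl.n_reagent)],
        "NTC": [f"ntc{i + 1:02d}" for i in range(ctl.n_ntc)],
    }
    for site, ids in control_ids.items():
        for sid in ids:
            meta_rows.append(
                {"sample_id": sid, "site": site, "animal_id": "", "role": "control"}
            )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)

    # counts -----------------------------------------------------------------
    blocks = [
        simulate_counts(gs["urt"], seed, universe, urt_ids)
    ]
    for label in ("background", "unique", "aspirate"):
        ids = truth.index[truth == label].tolist()
        spec = replace(gs[f"lung_{label}"], n_samples=len(ids))
        blocks.append(simulate_counts(spec, seed, universe, ids))
    for src in ("bedding", "chow", "water"):
        spec = replace(gs[src], n_samples=len(env_ids[src]))
        blocks.append(simulate_counts(spec, seed, universe, env_ids[src]))
    for kind, ids, depth in (
        ("reagent", control_ids["reagent"], ctl.reagent_depth),
        ("ntc", control_ids["NTC"], ctl.ntc_depth),
    ):
        spec = GroupSpec.with_median_depth(
            kind, ctl.profile, len(ids), depth, 0.4, dispersion=100
        )
        blocks.append(simulate_counts(spec, seed, universe, ids))
    counts = pd.concat(blocks).loc[metadata.index]
    counts.index.name = "sample_id"

    reads = control_reads = None
    if with_reads:
        cfg = scenario.sim_config(seed)
        refs = make_reference_sequences(universe, scenario.reference_length, seed)
        specimen_env = metadata.index[metadata["role"] != "control"]
        reads = counts_to_read_pairs(
            counts.loc[specimen_env], refs, cfg, scramble_labels=scramble_labels
        )
        reads, control_reads = spike_contaminants(
            reads, ctl, refs, cfg, scramble_labels=scramble_labels
        )
    else:
        refs = make_reference_sequences(universe, scenario.reference_length, seed)

    meta_out = metadata.copy()
    meta_out["pneumotype_truth"] = truth.reindex(meta_out.index).fillna("")
    return SimulationResult(
        scenario=scenario,
        seed=seed,
        counts=counts,
        metadata=meta_out,
        truth=truth,
        refs=refs,
        reads=reads,
        control_reads=control_reads,
    )


# ---------------------------------------------------------------------------
# external interfaces
# ---------------------------------------------------------------------------

_QUAL = chr(30 + 33)  # constant placeholder Q30


def write_fastq_pairs(batches: Mapping[str, ReadBatch], outdir: str | Path) -> list[Path]:
    """Write one ``<sample>_R1.fastq`` / ``<sample>_R2.fastq`` pair per sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sid, batch in batches.items():
        for mate, arr in (("R1", batch.fwd), ("R2", batch.rev)):
            path = outdir / f"{sid}_{mate}.fastq"
            with open(path, "w") as fh:
                for i, rid in enumerate(batch.ids):
                    seq = decode(arr[i])
                    fh.write(f"@{rid}/{mate[-1]}\n{seq}\n+\n{_QUAL * len(seq)}\n")
            written.append(path)
    return written


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["sample_id", "site", "animal_id", "role"]
    extra = [c for c in metadata.columns if c not in cols]
    metadata[cols + extra].to_csv(path, sep="\t", index=False)
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"sample_id", "site", "role"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    return meta.set_index("sample_id", drop=False)


# recognized keys for flat key-value scenario files
_SCENARIO_KEYS = {
    "n_animals": int,
    "urt_depth": float,
    "aspirate_depth": float,
    "unique_depth": float,
    "background_depth": float,
    "environment_depth": float,
    "contaminant_load": float,
    "error_rate": float,
    "name": str,
}


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a flat ``key = value`` text file.

    Unset keys fall back to the `paper_default` values; the special line
    ``base = desk`` starts from the depth-scaled desk scenario instead.
    """
    kw: dict[str, object] = {}
    base = "paper_default"
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key == "base":
            base = value
            continue
        if key not in _SCENARIO_KEYS:
            raise ValueError(
                f"{path}:{lineno}: unknown key {key!r}; "
                f"allowed: {sorted(_SCENARIO_KEYS) + ['base']}"
            )
        kw[key] = _SCENARIO_KEYS[key](value)
    if base == "desk":
        return desk_scenario(**kw)
    if base != "paper_default":
        raise ValueError(f"unknown base scenario {base!r}")
    return paper_default(**kw)
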