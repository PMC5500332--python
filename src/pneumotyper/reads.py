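"""Paired-read joining, in-silico reagent decontamination and genus tabulation.

The decontamination rule is the one this pipeline exists for: a sample contig
is discarded when it aligns to any reagent/NTC control contig at >= 99%
identity over at least 250 bp.  Identity here is matching columns divided by
alignment columns of an ungapped sliding alignment (both orientations by
default); gapped alignment is deliberately omitted because the simulated and
V4-amplicon contigs are fixed-length — a documented limitation for real,
indel-bearing data.

Candidate control contigs are found through a shared-k-mer prefilter (k=31):
a >= 250 bp match at >= 99% identity has at most 3 mismatches, which cannot
break every 31-mer, so the prefilter can never miss a true match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import decode, encode, revcomp
from .synth import ReadBatch, ReferenceSequenceSet

UNASSIGNED = "unassigned"


@dataclass(slots=True)
class ReadPair:
    id: str
    forward: str
    reverse: str
    sample_id: str


@dataclass(slots=True)
class Contig:
    id: str
    sequence: str
    sample_id: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for joining, decontamination and genus assignment."""

    identity_threshold: float = 0.99
    min_match_length: int = 250
    min_join_overlap: int = 6
    assign_identity_threshold: float = 0.97
    check_reverse_complement: bool = True
    join_identity: float = 0.90
    k: int = 31

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "assign_identity_threshold", "join_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_match_length < 1 or self.min_join_overlap < 1 or self.k < 1:
            raise ValueError("lengths must be >= 1")


# ---------------------------------------------------------------------------
# read joining
# ---------------------------------------------------------------------------


def _choose_overlap(
    fwd: np.ndarray, rev_rc: np.ndarray, cfg: FilterConfig
) -> int | None:
    """Largest overlap length whose within-window identity passes, else None."""
    max_l = min(len(fwd), len(rev_rc))
    for L in range(max_l, cfg.min_join_overlap - 1, -1):
        mism = int(np.count_nonzero(fwd[-L:] != rev_rc[:L]))
        if (L - mism) / L >= cfg.join_identity:
            return L
    return None


def join_pair(pair: ReadPair, cfg: FilterConfig | None = None) -> Contig | None:
    """Merge a read pair over its suffix/prefix overlap.

    Finds the largest suffix of the forward read matching (at
    ``join_identity`` within the window) a prefix of the reverse complement
    of the reverse read, of length >= ``min_join_overlap``.  Mismatches in
    the overlap are resolved in favor of the forward read.  Returns ``None``
    when no qualifying overlap exists.
    """
    cfg = cfg or FilterConfig()
    if not pair.forward or not pair.reverse:
        raise ValueError("reads must be non-empty")
    fwd = encode(pair.forward)
    rev_rc = revcomp(encode(pair.reverse))
    L = _choose_overlap(fwd, rev_rc, cfg)
    if L is None:
        return None
    seq = pair.forward + decode(rev_rc[L:])
    return Contig(id=pair.id, sequence=seq, sample_id=pair.sample_id)


def join_batch(
    batch: ReadBatch, cfg: FilterConfig | None = None
) -> tuple[list[Contig], int]:
    """Vectorized `join_pair` over a uniform-length read batch.

    Returns ``(contigs, n_unjoined)``; scan order (largest overlap first)
    matches the scalar routine exactly.
    """
    cfg = cfg or FilterConfig()
    n = len(batch)
    if n == 0:
        return [], 0
    fwd = batch.fwd
    rrc = revcomp(batch.rev)
    max_l = min(fwd.shape[1], rrc.shape[1])
    chosen = np.zeros(n, dtype=np.int64)
    unresolved = np.arange(n)
    for L in range(max_l, cfg.min_join_overlap - 1, -1):
        if unresolved.size == 0:
            break
        mism = np.count_nonzero(
            fwd[unresolved, fwd.shape[1] - L :] != rrc[unresolved, :L], axis=1
        )
        ok = (L - mism) / L >= cfg.join_identity
        chosen[unresolved[ok]] = L
        unresolved = unresolved[~ok]
    contigs: list[Contig] = []
    for L in np.unique(chosen):
        if L == 0:
            continue
        rows = np.nonzero(chosen == L)[0]
        merged = np.concatenate([fwd[rows], rrc[rows, L:]], axis=1)
        for j, row in enumerate(rows):
            contigs.append(
                Contig(batch.ids[row], decode(merged[j]), batch.sample_id)
            )
    # restore input order
    order = {rid: i for i, rid in enumerate(batch.ids)}
    contigs.sort(key=lambda c: order[c.id])
    return contigs, int(np.count_nonzero(chosen == 0))


def join_samples(
    batches: Mapping[str, ReadBatch], cfg: FilterConfig | None = None
) -> tuple[dict[str, list[Contig]], dict[str, int]]:
    """Join every sample's batch; returns contigs and unjoined tallies."""
    contigs: dict[str, list[Contig]] = {}
    unjoined: dict[str, int] = {}
    for sid, batch in batches.items():
        contigs[sid], unjoined[sid] = join_batch(batch, cfg)
    return contigs, unjoined


# ---------------------------------------------------------------------------
# ungapped sliding identity
# ---------------------------------------------------------------------------


def sliding_identity(
    a: np.ndarray, b: np.ndarray, min_len: int
) -> tuple[float, int]:
    """Best (identity, alignment length) over all ungapped offsets.

    Only alignments with at least ``min_len`` overlapping columns are
    considered; returns ``(0.0, 0)`` when none exists.  Identity is matching
    columns / alignment columns; ties on identity prefer the longer
    alignment.
    """
    na, nb = len(a), len(b)
    best_ident, best_len = 0.0, 0
    for off in range(-(nb - min_len), na - min_len + 1):
        a0 = max(0, off)
        b0 = max(0, -off)
        L = min(na - a0, nb - b0)
        if L < min_len:
            continue
        matches = int(np.count_nonzero(a[a0 : a0 + L] == b[b0 : b0 + L]))
        ident = matches / L
        if ident > best_ident or (ident == best_ident and L > best_len):
            best_ident, best_len = ident, L
    return best_ident, best_len


# ---------------------------------------------------------------------------
# contaminant index and matching
# ---------------------------------------------------------------------------


@dataclass
class ContaminantIndex:
    """Deduplicated control contigs plus a k-mer lookup for candidates."""

    k: int
    sequences: list[str] = field(default_factory=list)
    ids: list[str] = field(default_factory=list)
    kmers: dict[str, list[int]] = field(default_factory=dict)
    encoded: list[np.ndarray] = field(default_factory=list)
    encoded_rc: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequences)

    def candidates(self, sequence: str) -> set[int]:
        found: set[int] = set()
        for i in range(len(sequence) - self.k + 1):
            hit = self.kmers.get(sequence[i : i + self.k])
            if hit:
                found.update(hit)
        return found


def build_contaminant_index(
    control_contigs: Iterable[Contig],
    k: int = 31,
    include_revcomp: bool = True,
) -> ContaminantIndex:
    """Index reagent/NTC control contigs (and their reverse complements)."""
    index = ContaminantIndex(k=k)
    seen: dict[str, int] = {}
    for contig in control_contigs:
        if len(contig.sequence) < k:
            raise ValueError(
                f"k={k} exceeds control contig length {len(contig.sequence)} "
                f"({contig.id})"
            )
        if contig.sequence in seen:
            continue
        idx = len(index.sequences)
        seen[contig.sequence] = idx
        index.sequences.append(contig.sequence)
        index.ids.append(contig.id)
        enc = encode(contig.sequence)
        index.encoded.append(enc)
        index.encoded_rc.append(revcomp(enc))
        variants = [contig.sequence]
        if include_revcomp:
            variants.append(decode(revcomp(enc)))
        for seq in variants:
            for i in range(len(seq) - k + 1):
                index.kmers.setdefault(seq[i : i + k], []).append(idx)
    return index


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    reference_id: str | None
    alignment_length: int
    identity: float


def match_contaminant(
    contig: Contig, index: ContaminantIndex, cfg: FilterConfig | None = None
) -> MatchResult:
    """Test one contig against the contaminant index.

    Matched iff some indexed contig aligns (ungapped, either orientation when
    configured) with >= ``min_match_length`` columns at >=
    ``identity_threshold`` identity.  Candidates are prefiltered by shared
    k-mers and then verified by alignment.
    """
    cfg = cfg or FilterConfig()
    if len(index) == 0 or len(contig.sequence) < index.k:
        return MatchResult(False, None, 0, 0.0)
    enc = encode(contig.sequence)
    best = MatchResult(False, None, 0, 0.0)
    for idx in sorted(index.candidates(contig.sequence)):
        targets = [index.encoded[idx]]
        if cfg.check_reverse_complement:
            targets.append(index.encoded_rc[idx])
        for target in targets:
            ident, length = sliding_identity(enc, target, cfg.min_match_length)
            if length == 0:
                continue
            if (ident, length) > (best.identity, best.alignment_length):
                best = MatchResult(
                    ident >= cfg.identity_threshold,
                    index.ids[idx],
                    length,
                    ident,
                )
    return best


@dataclass
class FilterReport:
    """Decontamination accounting: per-sample tallies and removal fraction."""

    per_sample: pd.DataFrame  # columns: input, removed, retained
    per_reference: dict[str, int]

    @property
    def overall_removed_fraction(self) -> float:
        total = int(self.per_sample["input"].sum())
        return float(self.per_sample["removed"].sum() / total) if total else 0.0

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# overall_removed_fraction\t{self.overall_removed_fraction:.6f}\n")
            self.per_sample.to_csv(fh, sep="\t", index_label="sample_id")
        return path


def filter_contigs(
    sample_contigs: Mapping[str, list[Contig]],
    index: ContaminantIndex,
    cfg: FilterConfig | None = None,
) -> tuple[dict[str, list[Contig]], FilterReport]:
    """Remove contigs that match the contaminant index; keep input order."""
    cfg = cfg or FilterConfig()
    cache: dict[str, MatchResult] = {}
    retained: dict[str, list[Contig]] = {}
    rows = []
    per_reference: dict[str, int] = {}
    for sid, contigs in sample_contigs.items():
        keep: list[Contig] = []
        removed = 0
        for contig in contigs:
            result = cache.get(contig.sequence)
            if result is None:
                result = match_contaminant(contig, index, cfg)
                cache[contig.sequence] = result
            if result.matched:
                removed += 1
                per_reference[result.reference_id] = (
                    per_reference.get(result.reference_id, 0) + 1
                )
            else:
                keep.append(contig)
        retained[sid] = keep
        rows.append((sid, len(contigs), removed, len(keep)))
    per_sample = pd.DataFrame(
        rows, columns=["sample_id", "input", "removed", "retained"]
    ).set_index("sample_id")
    return retained, FilterReport(per_sample=per_sample, per_reference=per_reference)


# ---------------------------------------------------------------------------
# genus assignment and tabulation
# ---------------------------------------------------------------------------


def _best_genus(
    enc: np.ndarray, encoded_refs: dict[str, np.ndarray], threshold: float
) -> str:
    best_ident = -1.0
    best_genus = UNASSIGNED
    for genus in sorted(encoded_refs):
        ref = encoded_refs[genus]
        if len(ref) == len(enc):
            ident = float(np.count_nonzero(enc == ref)) / len(ref)
        else:
            ident, length = sliding_identity(enc, ref, min(len(ref), len(enc)))
            if length == 0:
                continue
        if ident > best_ident:  # ties keep the lexicographically first genus
            best_ident, best_genus = ident, genus
    return best_genus if best_ident > threshold else UNASSIGNED


def assign_genus(
    contig: Contig, refs: ReferenceSequenceSet, cfg: FilterConfig | None = None
) -> str:
    """Reference genus with the highest ungapped identity, if > threshold.

    Ties at the best identity go to the lexicographically first genus;
    contigs below the threshold are ``"unassigned"``.
    """
    cfg = cfg or FilterConfig()
    return _best_genus(
        encode(contig.sequence), refs.encoded(), cfg.assign_identity_threshold
    )


def assign_genera(
    contigs: list[Contig], refs: ReferenceSequenceSet, cfg: FilterConfig | None = None
) -> list[str]:
    """Batch genus assignment with a per-sequence cache and vectorized core."""
    cfg = cfg or FilterConfig()
    enc_refs = refs.encoded()
    genera_sorted = sorted(enc_refs)
    ref_mat = np.stack([enc_refs[g] for g in genera_sorted])
    ref_len = ref_mat.shape[1]
    cache: dict[str, str] = {}
    out: list[str] = []
    uniform: list[str] = [
        c.sequence
        for c in contigs
        if len(c.sequence) == ref_len and c.sequence not in cache
    ]
    uniform = list(dict.fromkeys(uniform))
    if uniform:
        mat = np.stack([encode(s) for s in uniform])
        # chunk to bound memory: n_unique x n_refs x ref_len bytes
        chunk = max(1, int(4e7) // max(1, ref_mat.size))
        for start in range(0, len(uniform), chunk):
            block = mat[start : start + chunk]
            matches = (block[:, None, :] == ref_mat[None, :, :]).sum(axis=2)
            ident = matches / ref_len
            best = ident.argmax(axis=1)
            best_ident = ident[np.arange(len(block)), best]
            for j in range(len(block)):
                seq = uniform[start + j]
                if best_ident[j] > cfg.assign_identity_threshold:
                    cache[seq] = genera_sorted[best[j]]
                else:
                    cache[seq] = UNASSIGNED
    for c in contigs:
        genus = cache.get(c.sequence)
        if genus is None:
            genus = _best_genus(encode(c.sequence), enc_refs, cfg.assign_identity_threshold)
            cache[c.sequence] = genus
        out.append(genus)
    return out


def tabulate_counts(
    retained: Mapping[str, list[Contig]],
    refs: ReferenceSequenceSet,
    cfg: FilterConfig | None = None,
    genus_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Samples × genera count matrix from retained contigs.

    Contigs below the assignment threshold land in a reserved ``unassigned``
    column which downstream statistics exclude.  All-zero samples keep their
    rows.
    """
    cfg = cfg or FilterConfig()
    columns = list(genus_universe) if genus_universe is not None else sorted(refs.genera)
    if UNASSIGNED not in columns:
        columns = columns + [UNASSIGNED]
    mat = pd.DataFrame(0, index=list(retained), columns=columns, dtype=np.int64)
    for sid, contigs in retained.items():
        for genus in assign_genera(contigs, refs, cfg):
            if genus not in mat.columns:  # genus outside requested universe
                mat[genus] = 0
            mat.loc[sid, genus] += 1
    mat.index.name = "sample_id"
    return mat


def drop_unassigned(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove the reserved unassigned column before statistics."""
    return counts.drop(columns=[UNASSIGNED], errors="ignore")


# ---------------------------------------------------------------------------
# FASTQ / FASTA interfaces
# ---------------------------------------------------------------------------


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path, sample_id: str
) -> list[ReadPair]:
    fwd = list(SeqIO.parse(str(r1_path), "fastq"))
    rev = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(fwd) != len(rev):
        raise ValueError(
            f"unequal mate counts for {sample_id}: {len(fwd)} vs {len(rev)}"
        )
    pairs = []
    for f, r in zip(fwd, rev):
        rid = f.id.rsplit("/", 1)[0]
        pairs.append(ReadPair(rid, str(f.seq), str(r.seq), sample_id))
    return pairs


def pairs_to_batch(pairs: list[ReadPair], sample_id: str) -> ReadBatch:
    """Pack uniform-length read pairs into a vectorized batch."""
    if not pairs:
        return ReadBatch.empty(sample_id, 0)
    fwd = np.stack([encode(p.forward) for p in pairs])
    rev = np.stack([encode(p.reverse) for p in pairs])
    return ReadBatch(sample_id, [p.id for p in pairs], fwd, rev)


def write_contigs_fasta(contigs: Iterable[Contig], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id} sample={c.sample_id}\n{c.sequence}\n")
    return path


def read_contigs_fasta(path: str | Path, sample_id: str | None = None) -> list[Contig]:
    contigs = []
    for record in SeqIO.parse(str(path), "fasta"):
        sid = sample_id
        if sid is None:
            sid = next(
                (p.split("=", 1)[1] for p in record.description.split() if p.startswith("sample=")),
                "",
            )
        contigs.append(Contig(record.id, str(record.seq).upper(), sid))
    return contigs
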