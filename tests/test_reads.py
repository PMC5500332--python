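"""Read joining, decontamination matching and genus tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pneumotyper._seq import revcomp_str
from pneumotyper.reads import (
    Contig,
    ContaminantIndex,
    FilterConfig,
    ReadPair,
    assign_genus,
    assign_genera,
    build_contaminant_index,
    drop_unassigned,
    filter_contigs,
    join_batch,
    join_pair,
    match_contaminant,
    pairs_to_batch,
    read_fastq_pairs,
    tabulate_counts,
)
from pneumotyper.synth import (
    ReferenceSequenceSet,
    SimulationConfig,
    counts_to_read_pairs,
    make_reference_sequences,
    write_fastq_pairs,
)
from _oracles import match_contaminant_bruteforce


def _pair(fwd: str, rc_rev: str, rid="r1", sid="s1") -> ReadPair:
    return ReadPair(rid, fwd, revcomp_str(rc_rev), sid)


def _mutate(seq: str, positions, base_map={"A": "C", "C": "G", "G": "T", "T": "A"}):
    out = list(seq)
    for p in positions:
        out[p] = base_map[out[p]]
    return "".join(out)


class TestJoinPair:
    def test_exact_six_base_overlap(self):
        contig = join_pair(_pair("ACGTACGTAA", "ACGTAAGGGG"))
        assert contig is not None
        assert contig.sequence == "ACGTACGTAAGGGG"
        assert contig.length == 14

    def test_five_base_overlap_is_unjoined(self):
        # shared block "CGTAA" is only 5 bases, below the 6 bp minimum
        assert join_pair(_pair("ATTTTTCGTAA", "CGTAAGGGGG")) is None

    def test_roundtrip_from_reference(self, small_refs):
        ref = small_refs["g_beta"]
        pair = _pair(ref[:150], ref[-150:])
        contig = join_pair(pair)
        assert contig.sequence == ref

    def test_forward_read_wins_overlap_mismatches(self):
        fwd = "ACGTACGTAA"
        rc_rev = _mutate("ACGTAAGGGG", [5]) + ""  # one mismatch inside 10-col window
        # overlap window of 6 has 1 mismatch -> 5/6 < 0.9, so joining relies on
        # a perfect smaller overlap not existing; use a clean 10-base overlap
        fwd2 = "AACCGGTTACGTACGTAC"
        rc2 = _mutate("ACGTACGTAC", [2]) + "GGGGTTTT"
        contig = join_pair(_pair(fwd2, rc2))
        assert contig is not None
        # the overlap columns come from the forward read
        assert contig.sequence.startswith(fwd2)

    def test_empty_read_raises(self):
        with pytest.raises(ValueError):
            join_pair(ReadPair("r", "", "ACGT", "s"))

    def test_batch_agrees_with_scalar(self, small_refs):
        cfg = SimulationConfig(seed=42, error_rate=0.02)
        counts = pd.DataFrame({"g_alpha": [40], "g_gamma": [40]}, index=["s"])
        batch = counts_to_read_pairs(counts, small_refs, cfg)["s"]
        contigs, n_unjoined = join_batch(batch)
        scalar = {}
        for rid, fwd, rev in batch:
            c = join_pair(ReadPair(rid, fwd, rev, "s"))
            if c is not None:
                scalar[rid] = c.sequence
        assert {c.id: c.sequence for c in contigs} == scalar
        assert n_unjoined == len(batch) - len(scalar)


class TestContaminantIndex:
    def test_kmer_position_count(self):
        contig = Contig("c1", "ACGT" * 63 + "AC", "ctl")  # 254 nt
        index = build_contaminant_index([contig], k=31, include_revcomp=False)
        assert sum(len(v) for v in index.kmers.values()) == 254 - 31 + 1

    def test_deduplicates_identical_controls(self):
        seq = "ACGT" * 70
        contigs = [Contig(f"c{i}", seq, "ctl") for i in range(4)]
        assert len(build_contaminant_index(contigs, k=31)) == 1

    def test_k_larger_than_contig_errors(self):
        with pytest.raises(ValueError):
            build_contaminant_index([Contig("c", "ACGT", "ctl")], k=31)

    def test_empty_index_removes_nothing(self, small_refs):
        contigs = {"s": [Contig("a", small_refs["g_alpha"], "s")]}
        retained, report = filter_contigs(contigs, ContaminantIndex(k=31))
        assert len(retained["s"]) == 1
        assert report.overall_removed_fraction == 0.0


@pytest.fixture(scope="module")
def index(small_refs):
    ctl = [Contig("ctl1", small_refs["g_alpha"], "reagent01")]
    return build_contaminant_index(ctl, k=31)


class TestMatchContaminant:
    def test_identical_contig_matches_fully(self, small_refs, index):
        result = match_contaminant(Contig("q", small_refs["g_alpha"], "s"), index)
        assert result.matched
        assert result.identity == 1.0
        assert result.alignment_length == 254

    def test_two_mismatches_at_254bp_still_match(self, small_refs, index):
        seq = _mutate(small_refs["g_alpha"], [10, 100])
        result = match_contaminant(Contig("q", seq, "s"), index)
        assert result.matched
        assert result.identity == pytest.approx(252 / 254)

    def test_three_mismatches_at_254bp_do_not_match(self, small_refs, index):
        seq = _mutate(small_refs["g_alpha"], [10, 100, 200])
        result = match_contaminant(Contig("q", seq, "s"), index)
        assert not result.matched
        assert result.identity == pytest.approx(251 / 254)

    def test_reverse_complement_matches(self, small_refs, index):
        result = match_contaminant(
            Contig("q", revcomp_str(small_refs["g_alpha"]), "s"), index
        )
        assert result.matched

    def test_perfect_200bp_block_is_below_length_floor(self, small_refs, index):
        other = make_reference_sequences(["decoy"], 254, seed=99)["decoy"]
        chimera = small_refs["g_alpha"][:200] + other[200:]
        result = match_contaminant(Contig("q", chimera, "s"), index)
        assert not result.matched

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        controls = ["".join(rng.choice(bases, 254)) for _ in range(5)]
        index = build_contaminant_index(
            [Contig(f"c{i}", s, "ctl") for i, s in enumerate(controls)], k=31
        )
        cfg = FilterConfig()
        for trial in range(50):
            src = controls[rng.integers(0, len(controls))]
            n_mut = int(rng.integers(0, 6))
            seq = _mutate(src, rng.choice(254, size=n_mut, replace=False))
            if rng.random() < 0.3:
                seq = revcomp_str(seq)
            if rng.random() < 0.2:
                seq = "".join(rng.choice(bases, 254))
            got = match_contaminant(Contig("q", seq, "s"), index, cfg).matched
            want = match_contaminant_bruteforce(seq, controls)
            assert got == want


class TestFilterContigs:
    def test_spiked_copies_are_exactly_removed(self, small_refs):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        specimen = [
            Contig(f"s{i}", "".join(rng.choice(bases, 254)), "sampleA")
            for i in range(100)
        ]
        control_seq = small_refs["g_alpha"]
        spiked = [Contig(f"spk{i}", control_seq, "sampleA") for i in range(40)]
        index = build_contaminant_index([Contig("ctl", control_seq, "reagent01")])
        retained, report = filter_contigs({"sampleA": specimen + spiked}, index)
        assert report.per_sample.loc["sampleA", "removed"] == 40
        assert [c.id for c in retained["sampleA"]] == [c.id for c in specimen]

    def test_all_identical_to_control_removed(self, small_refs):
        seq = small_refs["g_beta"]
        contigs = {"s": [Contig(f"c{i}", seq, "s") for i in range(10)]}
        index = build_contaminant_index([Contig("ctl", seq, "reagent01")])
        retained, report = filter_contigs(contigs, index)
        assert retained["s"] == []
        assert report.overall_removed_fraction == 1.0

    def test_report_is_deterministic(self, small_refs, tmp_path):
        contigs = {"s": [Contig("c", small_refs["g_alpha"], "s")]}
        index = build_contaminant_index([Contig("ctl", small_refs["g_beta"], "r")])
        paths = []
        for i in range(2):
            _, report = filter_contigs(contigs, index)
            paths.append(report.to_tsv(tmp_path / f"rep{i}.tsv"))
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestAssignGenus:
    def test_error_free_contig_assigned_to_its_genus(self, small_refs):
        for genus in small_refs.genera:
            contig = Contig("c", small_refs[genus], "s")
            assert assign_genus(contig, small_refs) == genus

    def test_95_percent_identity_is_unassigned(self, small_refs):
        seq = _mutate(small_refs["g_alpha"], range(0, 254, 20))  # 13 mismatches
        assert assign_genus(Contig("c", seq, "s"), small_refs) == "unassigned"

    def test_tie_goes_to_lexicographically_first(self):
        base = make_reference_sequences(["seed"], 254, seed=1)["seed"]
        ref_b = _mutate(base, [10])
        ref_a = _mutate(base, [200])
        refs = ReferenceSequenceSet({"zeta": ref_b, "alpha": ref_a})
        # contig equidistant (1 mismatch) from both references
        assert assign_genus(Contig("c", base, "s"), refs) == "alpha"

    def test_batch_matches_scalar(self, small_refs):
        rng = np.random.default_rng(8)
        contigs = []
        for i in range(30):
            genus = small_refs.genera[rng.integers(0, 3)]
            n_mut = int(rng.integers(0, 12))
            seq = _mutate(small_refs[genus], rng.choice(254, n_mut, replace=False))
            contigs.append(Contig(f"c{i}", seq, "s"))
        batch = assign_genera(contigs, small_refs)
        scalar = [assign_genus(c, small_refs) for c in contigs]
        assert batch == scalar


class TestTabulate:
    def test_noiseless_roundtrip(self, small_refs):
        cfg = SimulationConfig(seed=6, error_rate=0.0)
        counts = pd.DataFrame(
            {"g_alpha": [3, 0], "g_beta": [0, 5], "g_gamma": [2, 0]},
            index=["s1", "s2"],
        )
        batches = counts_to_read_pairs(counts, small_refs, cfg)
        contigs = {
            sid: join_batch(b)[0] for sid, b in batches.items()
        }
        mat = tabulate_counts(contigs, small_refs, genus_universe=counts.columns)
        assert drop_unassigned(mat).equals(counts)

    def test_zero_retained_sample_keeps_row(self, small_refs):
        mat = tabulate_counts({"empty": []}, small_refs)
        assert "empty" in mat.index
        assert mat.loc["empty"].sum() == 0

    def test_order_invariance(self, small_refs):
        contigs = [
            Contig("a", small_refs["g_alpha"], "s"),
            Contig("b", small_refs["g_beta"], "s"),
            Contig("c", small_refs["g_alpha"], "s"),
        ]
        m1 = tabulate_counts({"s": contigs}, small_refs)
        m2 = tabulate_counts({"s": contigs[::-1]}, small_refs)
        assert m1.equals(m2)


def test_fastq_roundtrip(tmp_path, small_refs):
    cfg = SimulationConfig(seed=2, error_rate=0.01)
    counts = pd.DataFrame({"g_alpha": [7]}, index=["sampleZ"])
    batches = counts_to_read_pairs(counts, small_refs, cfg)
    write_fastq_pairs(batches, tmp_path)
    pairs = read_fastq_pairs(
        tmp_path / "sampleZ_R1.fastq", tmp_path / "sampleZ_R2.fastq", "sampleZ"
    )
    assert len(pairs) == 7
    back = pairs_to_batch(pairs, "sampleZ")
    assert np.array_equal(back.fwd, batches["sampleZ"].fwd)
    assert np.array_equal(back.rev, batches["sampleZ"].rev)
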