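"""Read merging, identity, the filter cascade, and sample-level accounting."""

import random

import numpy as np
import pytest

from Bio.Seq import reverse_complement

from brainmeth.amplicon import AmpliconAssay
from brainmeth.readcall import (
    CallerConfig,
    FastqRead,
    align_and_identity,
    call_read,
    merge_pair,
    process_sample,
    write_calls_tsv,
)
from brainmeth.simulate import (
    NoiseModel,
    default_profiles,
    generate_reads,
    write_fastq,
)

CFG = CallerConfig()


def _read(seq, qual=None, rid="r"):
    return FastqRead(rid, seq, qual or "I" * len(seq))


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestMergePair:
    def test_identical_reads_fully_overlap(self):
        rng = random.Random(0)
        seq = _random_seq(rng, 150)
        merged = merge_pair(_read(seq), _read(reverse_complement(seq)), CFG)
        assert merged is not None
        assert merged.seq == seq

    def test_fifty_bp_overlap_yields_250bp_merge(self):
        rng = random.Random(1)
        amplicon = _random_seq(rng, 250)
        r1 = _read(amplicon[:150])
        r2 = _read(reverse_complement(amplicon[100:]))
        merged = merge_pair(r1, r2, CFG)
        assert merged is not None
        assert merged.seq == amplicon
        assert len(merged.seq) == 250

    def test_overlap_below_minimum_fails(self):
        rng = random.Random(2)
        amplicon = _random_seq(rng, 290)
        r1 = _read(amplicon[:150])
        r2 = _read(reverse_complement(amplicon[140:]))  # 10 bp overlap
        assert merge_pair(r1, r2, CFG) is None

    def test_disagreement_resolved_by_quality_then_r1(self):
        rng = random.Random(3)
        amplicon = _random_seq(rng, 200)
        r1_seq = amplicon[:150]
        r2_region = amplicon[50:]
        # corrupt one overlap base on R2; R2 higher quality there wins
        pos = 100  # inside the overlap [50, 150)
        base = "A" if amplicon[pos] != "A" else "G"
        r2_corrupt = r2_region[: pos - 50] + base + r2_region[pos - 50 + 1 :]
        r1 = _read(r1_seq, qual="5" * 150)
        r2 = _read(reverse_complement(r2_corrupt), qual="I" * 150)
        merged = merge_pair(r1, r2, CFG)
        assert merged.seq[pos] == base
        # equal quality: R1 wins
        r2_eq = _read(reverse_complement(r2_corrupt), qual="5" * 150)
        merged_eq = merge_pair(r1, r2_eq, CFG)
        assert merged_eq.seq[pos] == amplicon[pos]


@pytest.fixture(scope="module")
def toy_assay():
    # 120 bp amplicon, CpG-free primer landing sites, 4 CpGs
    rng = random.Random(99)
    while True:
        seq = "".join(rng.choice("ACGT") for _ in range(120))
        core = list(seq)
        for i in range(119):
            if core[i] == "C" and core[i + 1] == "G":
                core[i + 1] = "A"
        for o in (30, 50, 70, 90):
            core[o], core[o + 1] = "C", "G"
            if core[o - 1] == "C":
                core[o - 1] = "A"
            if core[o + 2] == "G":
                core[o + 2] = "A"
        seq = "".join(core)
        from brainmeth.amplicon import enumerate_cpg_sites

        if enumerate_cpg_sites(seq) == [30, 50, 70, 90]:
            break
    from brainmeth.amplicon import bisulfite_convert_reference

    conv = bisulfite_convert_reference(seq)
    return AmpliconAssay(
        name="toy", region_type="hypo", chrom="chr1", start=0, end=120,
        forward_primer=conv[:20], reverse_primer=reverse_complement(conv[-20:]),
        reference_seq=seq,
    )


def _molecule(assay, methylated_offsets=()):
    """Noiselessly converted molecule with the given CpGs methylated."""
    seq = list(assay.reference_seq)
    cpg = set(assay.cpg_offsets)
    for i, b in enumerate(seq):
        if b == "C" and i not in cpg:
            seq[i] = "T"
    for o in cpg:
        if o not in methylated_offsets:
            seq[o] = "T"
    return "".join(seq)


class TestAlignIdentity:
    def test_fully_converted_read_has_identity_one(self, toy_assay):
        read = _molecule(toy_assay)
        identity, _ = align_and_identity(read, toy_assay, CFG)
        assert identity == 1.0

    def test_substitutions_counted_outside_cpg_columns(self, toy_assay):
        read = list(_molecule(toy_assay))
        # ten substitutions at non-CpG, non-dinucleotide positions
        cpg_cols = set()
        for o in toy_assay.cpg_offsets:
            cpg_cols.update((o, o + 1))
        targets = [i for i in range(120) if i not in cpg_cols][:10]
        for i in targets:
            read[i] = "A" if read[i] != "A" else "G"
        identity, _ = align_and_identity("".join(read), toy_assay, CFG)
        n_nonY = 120 - len(toy_assay.cpg_offsets)
        assert identity == pytest.approx((n_nonY - 10) / n_nonY)

    def test_cpg_cytosine_state_never_penalized(self, toy_assay):
        fully_methylated = _molecule(toy_assay, methylated_offsets=toy_assay.cpg_offsets)
        fully_converted = _molecule(toy_assay)
        for read in (fully_methylated, fully_converted):
            identity, _ = align_and_identity(read, toy_assay, CFG)
            assert identity == 1.0

    def test_deletion_handled_by_global_alignment(self, toy_assay):
        read = _molecule(toy_assay)
        read = read[:10] + read[11:]  # 1 bp deletion outside CpGs
        identity, ref2read = align_and_identity(read, toy_assay, CFG)
        assert identity > CFG.min_identity
        assert ref2read[10] == -1 or (np.sum(ref2read < 0) == 1)
        # CpG positions still mapped
        for o in toy_assay.cpg_offsets:
            assert ref2read[o] >= 0

    def test_empty_read_rejected(self, toy_assay):
        with pytest.raises(ValueError):
            align_and_identity("", toy_assay, CFG)


class TestCallRead:
    def test_fully_methylated_molecule_calls_percent_one(self, toy_assay):
        read = _read(_molecule(toy_assay, toy_assay.cpg_offsets))
        call = call_read(read, toy_assay, CFG)
        assert call.valid
        assert call.methylation_percent == 1.0
        assert call.states.states == (True,) * 4

    def test_half_methylated_percent(self, toy_assay):
        read = _read(_molecule(toy_assay, toy_assay.cpg_offsets[:2]))
        call = call_read(read, toy_assay, CFG)
        assert call.valid
        assert call.methylation_percent == 0.5

    def test_non_cg_tg_dinucleotide_is_invalid_state(self, toy_assay):
        seq = list(_molecule(toy_assay))
        o = toy_assay.cpg_offsets[0]
        seq[o] = "A"  # AG at the CpG
        call = call_read(_read("".join(seq)), toy_assay, CFG)
        assert call.rejection_reason == "invalid_cpg_state"

    def test_literal_ct_mode_flag(self, toy_assay):
        # literal reading: unmethylated CpGs appear as "CT", not "TG"
        cfg = CallerConfig(literal_ct_mode=True)
        seq = list(_molecule(toy_assay))
        for o in toy_assay.cpg_offsets:
            seq[o], seq[o + 1] = "C", "T"
        call = call_read(_read("".join(seq)), toy_assay, cfg)
        assert call.valid
        assert call.states.states == (False,) * 4
        # the same read is invalid under the chemistry-expected default rule
        assert call_read(_read("".join(seq)), toy_assay, CFG).rejection_reason == (
            "invalid_cpg_state"
        )

    def test_primer_mismatch_detected_first(self, toy_assay):
        seq = "A" + _molecule(toy_assay)[1:]
        if toy_assay.forward_primer[0] == "A":
            seq = "G" + seq[1:]
        call = call_read(_read(seq), toy_assay, CFG)
        assert call.rejection_reason == "primer_mismatch"

    def test_truncated_read_fails_cpg_coverage(self, toy_assay):
        read = _read(_molecule(toy_assay)[:60])  # covers CpGs at 30, 50 only
        call = call_read(read, toy_assay, CFG)
        assert call.rejection_reason == "incomplete_cpg_coverage"

    def test_heavy_substitution_fails_identity(self, toy_assay):
        seq = list(_molecule(toy_assay))
        cpg_cols = set()
        for o in toy_assay.cpg_offsets:
            cpg_cols.update((o, o + 1))
        # corrupt 30 of the non-CpG columns after the primer region; steep
        # gap penalties keep the alignment gapless so identity is decisive
        targets = [i for i in range(20, 120) if i not in cpg_cols][:30]
        for i in targets:
            seq[i] = "A" if seq[i] != "A" else "G"
        cfg = CallerConfig(align_gap_open=-50, align_gap_extend=-50)
        call = call_read(_read("".join(seq)), toy_assay, cfg)
        assert call.rejection_reason == "low_identity"
        assert call.identity == pytest.approx((116 - 30) / 116)


class TestProcessSample:
    @pytest.fixture()
    def fastq_pair(self, tmp_path, hypo_assay, profiles):
        brain, _ = profiles[hypo_assay.name]
        r1s, r2s, truth = generate_reads(
            brain, hypo_assay, 120, NoiseModel.noiseless(), seed=7
        )
        p1 = write_fastq(r1s, tmp_path / "r1.fastq")
        p2 = write_fastq(r2s, tmp_path / "r2.fastq")
        return p1, p2, truth

    def test_accounting_and_not_discarded(self, fastq_pair, hypo_assay):
        p1, p2, truth = fastq_pair
        rs = process_sample(p1, p2, hypo_assay, CFG, sample_id="s")
        assert rs.n_total == 120
        assert rs.n_valid + sum(rs.rejection_counts.values()) == rs.n_total
        assert rs.n_valid >= 100
        assert not rs.discarded
        # recovered patterns equal the generator's truth
        for call, t in zip(rs.valid_calls, truth):
            assert call.states == t

    def test_discard_boundary_is_strictly_fewer_than_minimum(self):
        from brainmeth.readcall import SampleReadSet

        just_enough = SampleReadSet("s", "a", [None] * 100, {}, 100)
        one_short = SampleReadSet("s", "a", [None] * 99, {"low_identity": 1}, 100)
        assert not just_enough.discarded
        assert one_short.discarded

    def test_zero_reads_empty_and_discarded(self, tmp_path, hypo_assay):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        rs = process_sample(p, None, hypo_assay, CFG)
        assert rs.n_total == 0
        assert rs.discarded

    def test_mismatched_record_counts_rejected(self, tmp_path, hypo_assay, profiles):
        brain, _ = profiles[hypo_assay.name]
        r1s, r2s, _ = generate_reads(brain, hypo_assay, 5, NoiseModel.noiseless(), seed=1)
        p1 = write_fastq(r1s, tmp_path / "r1.fastq")
        p2 = write_fastq(r2s[:4], tmp_path / "r2.fastq")
        with pytest.raises(ValueError, match="more records"):
            process_sample(p1, p2, hypo_assay, CFG)

    def test_read_order_does_not_change_counts(self, tmp_path, hypo_assay, profiles):
        brain, _ = profiles[hypo_assay.name]
        r1s, r2s, _ = generate_reads(brain, hypo_assay, 60, NoiseModel(), seed=3)
        order = np.random.default_rng(0).permutation(60)
        p1 = write_fastq(r1s, tmp_path / "a1.fastq")
        p2 = write_fastq(r2s, tmp_path / "a2.fastq")
        q1 = write_fastq([r1s[i] for i in order], tmp_path / "b1.fastq")
        q2 = write_fastq([r2s[i] for i in order], tmp_path / "b2.fastq")
        rs_a = process_sample(p1, p2, hypo_assay, CFG)
        rs_b = process_sample(q1, q2, hypo_assay, CFG)
        assert rs_a.rejection_counts == rs_b.rejection_counts
        assert rs_a.n_valid == rs_b.n_valid

    def test_mean_percent_tracks_profile_expectation(self, tmp_path, hypo_assay, profiles):
        brain, _ = profiles[hypo_assay.name]
        r1s, r2s, _ = generate_reads(
            brain, hypo_assay, 400, NoiseModel.noiseless(), seed=11
        )
        p1 = write_fastq(r1s, tmp_path / "r1.fastq")
        p2 = write_fastq(r2s, tmp_path / "r2.fastq")
        rs = process_sample(p1, p2, hypo_assay, CFG)
        expected = float(np.mean(brain.expected_methylation()))
        # 3 binomial SEs on the per-read mean (reads avg over k CpGs, so
        # the per-CpG binomial bound is conservative)
        se = np.sqrt(expected * (1 - expected) / rs.n_valid)
        assert abs(rs.percents.mean() - expected) <= 3 * se

    def test_calls_tsv_written(self, fastq_pair, hypo_assay, tmp_path):
        p1, p2, _ = fastq_pair
        rs = process_sample(p1, p2, hypo_assay, CFG)
        out = write_calls_tsv(rs.valid_calls, tmp_path / "calls.tsv")
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == [
            "read_id", "assay", "pattern", "methylation_percent", "identity", "reason",
        ]
        assert len(lines) == rs.n_valid + 1
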