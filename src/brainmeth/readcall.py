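"""Per-read validation and methylation-pattern calling for amplicon assays.

Each read (or read pair) is screened against its assay through a fixed
filter cascade, so every read receives exactly one rejection reason:

1. ``primer_mismatch``   — R1 must start with the genome-specific forward
   primer, matched exactly under IUPAC expansion (zero mismatches).
2. ``unmergeable_pair``  — paired reads are merged on their best ungapped
   3' overlap (>= 20 bp, >= 90% agreement by default).
3. ``incomplete_cpg_coverage`` — every CpG dinucleotide of the assay must be
   covered by aligned read bases.
4. ``low_identity``      — global alignment identity against the converted
   reference must exceed 85%, with CpG cytosine columns excluded from both
   numerator and denominator (their C/T state is biology, not error).
5. ``invalid_cpg_state`` — each CpG must read CG (methylated) or TG
   (unmethylated); any other dinucleotide invalidates the read.

Valid reads yield a :class:`~brainmeth.amplicon.MoleculePattern` and a
per-read methylation percent (methylated CpGs / total CpGs) — the per-
molecule epiallele information the downstream classifier consumes.  A sample
with fewer than 100 valid reads is discarded.

Identity is computed on a gapless fast path when the merged read and the
converted reference have equal length and already agree above the threshold;
otherwise a global affine-gap alignment (match +1, mismatch -1, gap open -2,
extend -1) decides coverage and identity.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .amplicon import AmpliconAssay, MoleculePattern, match_primer

__all__ = [
    "CallerConfig",
    "FastqRead",
    "ReadCall",
    "SampleReadSet",
    "REJECTION_REASONS",
    "merge_pair",
    "align_and_identity",
    "call_read",
    "process_sample",
    "read_fastq",
    "write_calls_tsv",
    "write_sample_summary_json",
]

REJECTION_REASONS = (
    "primer_mismatch",
    "unmergeable_pair",
    "incomplete_cpg_coverage",
    "low_identity",
    "invalid_cpg_state",
    "none",
)


@dataclass(frozen=True)
class CallerConfig:
    """Read-validation parameters.

    ``min_identity`` is a strict lower bound (identity must *exceed* it).
    ``literal_ct_mode`` switches the CpG-state rule from the
    chemistry-expected CG/TG dinucleotides to a literal CG/CT reading.
    """

    min_identity: float = 0.85
    min_valid_reads: int = 100
    merge_min_overlap: int = 20
    merge_min_agreement: float = 0.9
    align_match: int = 1
    align_mismatch: int = -1
    align_gap_open: int = -2
    align_gap_extend: int = -1
    literal_ct_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity < 1.0:
            raise ValueError("min_identity must be in (0, 1)")
        if self.merge_min_overlap < 1:
            raise ValueError("merge_min_overlap must be >= 1")
        if not 0.0 < self.merge_min_agreement <= 1.0:
            raise ValueError("merge_min_agreement must be in (0, 1]")


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class ReadCall:
    """Outcome of calling one read (or merged pair) against one assay."""

    read_id: str
    assay_name: str
    rejection_reason: str
    states: MoleculePattern | None = None
    methylation_percent: float | None = None
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.rejection_reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.rejection_reason!r}")
        if self.valid and (self.states is None or self.methylation_percent is None):
            raise ValueError("valid calls must carry states and percent")

    @property
    def valid(self) -> bool:
        return self.rejection_reason == "none"


@dataclass
class SampleReadSet:
    """All calls of one sample against one assay, plus rejection accounting."""

    sample_id: str
    assay_name: str
    valid_calls: list[ReadCall]
    rejection_counts: dict[str, int]
    n_total: int
    min_valid_reads: int = 100

    @property
    def n_valid(self) -> int:
        return len(self.valid_calls)

    @property
    def discarded(self) -> bool:
        return self.n_valid < self.min_valid_reads

    @property
    def percents(self) -> np.ndarray:
        return np.array(
            [c.methylation_percent for c in self.valid_calls], dtype=float
        )

    def check_accounting(self) -> None:
        total = self.n_valid + sum(self.rejection_counts.values())
        if total != self.n_total:
            raise AssertionError(
                f"read accounting broken: {total} != {self.n_total}"
            )


_PHRED_OFFSET = 33


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def merge_pair(
    r1: FastqRead, r2: FastqRead, config: CallerConfig = CallerConfig()
) -> FastqRead | None:
    """Merge a read pair on its best ungapped 3' overlap.

    ``r2`` is given in sequencing orientation and is reverse-complemented
    first.  Overlap lengths from the longest possible down to
    ``merge_min_overlap`` are scanned; the one with the highest agreement
    (longest on ties) wins and must reach ``merge_min_agreement``.
    Disagreeing overlap bases take the higher-quality base, ties the R1 base.
    Returns None when no qualifying overlap exists.
    """
    s1, q1 = r1.seq.upper(), r1.qual
    s2 = reverse_complement(r2.seq.upper())
    q2 = r2.qual[::-1]
    a, b = _encode(s1), _encode(s2)
    qa = _encode(q1)
    qb = _encode(q2)
    n1, n2 = len(a), len(b)

    best_len = 0
    best_agree = -1.0
    for L in range(min(n1, n2), config.merge_min_overlap - 1, -1):
        matches = int(np.count_nonzero(a[n1 - L :] == b[:L]))
        agree = matches / L
        if agree > best_agree:
            best_agree = agree
            best_len = L
            if agree == 1.0:
                break
    if best_len == 0 or best_agree < config.merge_min_agreement:
        return None

    L = best_len
    ov_a, ov_b = a[n1 - L :].copy(), b[:L]
    ov_qa, ov_qb = qa[n1 - L :].copy(), qb[:L]
    use_b = (ov_a != ov_b) & (ov_qb > ov_qa)  # quality tie -> R1 base
    ov_a[use_b] = ov_b[use_b]
    ov_qa = np.maximum(ov_qa, ov_qb)

    seq = s1[: n1 - L] + ov_a.tobytes().decode("ascii") + s2[L:]
    qual = q1[: n1 - L] + ov_qa.tobytes().decode("ascii") + q2[L:]
    return FastqRead(r1.read_id, seq, qual)


class _AssayAligner:
    """Cached global aligner + reference encodings for one assay."""

    def __init__(self, assay: AmpliconAssay, config: CallerConfig):
        if assay.converted_ref is None:
            raise ValueError(f"assay {assay.name} has no reference sequence")
        self.assay = assay
        self.config = config
        self.ref = assay.converted_ref
        self.ref_arr = _encode(self.ref)
        self.is_y = self.ref_arr == ord("Y")
        self.n_nonY = int(np.sum(~self.is_y))

        alphabet = "ACGTNY"
        m = substitution_matrices.Array(alphabet, dims=2)
        for x in alphabet:
            for y in alphabet:
                m[x, y] = config.align_match if x == y else config.align_mismatch
        for x in "CT":  # CpG cytosine wildcard: C or T at no cost
            m["Y", x] = config.align_match
            m[x, "Y"] = config.align_match
        for x in alphabet:
            m["N", x] = 0.0
            m[x, "N"] = 0.0
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = m
        aligner.open_gap_score = config.align_gap_open
        aligner.extend_gap_score = config.align_gap_extend
        self.aligner = aligner

    def gapless(self, read: str) -> tuple[float, np.ndarray] | None:
        """Equal-length columnwise identity; None when lengths differ."""
        if len(read) != len(self.ref):
            return None
        arr = _encode(read.upper())
        eq = arr == self.ref_arr
        y_ok = self.is_y & ((arr == ord("C")) | (arr == ord("T")))
        matches = int(np.count_nonzero((eq | y_ok) & ~self.is_y))
        identity = matches / self.n_nonY if self.n_nonY else 1.0
        return identity, np.arange(len(self.ref))

    def align(self, read: str) -> tuple[float, np.ndarray]:
        """Global alignment; returns (identity, ref->read position map).

        The map holds, for each reference offset, the read position aligned
        to it, or -1 where the reference base is deleted in the read.
        Identity excludes CpG cytosine (Y) columns from numerator and
        denominator; read-insertion and gap columns count as mismatches.
        """
        read = read.upper()
        aln = self.aligner.align(self.ref, read)[0]
        ref_blocks, read_blocks = aln.aligned
        ref2read = np.full(len(self.ref), -1, dtype=int)
        matches = 0
        for (rs, re), (qs, qe) in zip(ref_blocks, read_blocks):
            ref2read[rs:re] = np.arange(qs, qe)
            seg_ref = self.ref_arr[rs:re]
            seg_read = _encode(read[qs:qe])
            seg_y = self.is_y[rs:re]
            eq = seg_ref == seg_read
            matches += int(np.count_nonzero(eq & ~seg_y))
        total_columns = aln.shape[1]
        n_y = int(np.sum(self.is_y))
        denom = total_columns - n_y
        identity = matches / denom if denom > 0 else 1.0
        return identity, ref2read


def align_and_identity(
    read: str, assay: AmpliconAssay, config: CallerConfig = CallerConfig()
) -> tuple[float, np.ndarray]:
    """Align a merged read to the assay's converted reference.

    Returns (identity, ref->read map); see :class:`_AssayAligner.align`.
    A gapless comparison short-circuits the aligner when it already clears
    ``min_identity``.
    """
    if not read:
        raise ValueError("empty read")
    engine = _AssayAligner(assay, config)
    fast = engine.gapless(read)
    if fast is not None and fast[0] > config.min_identity:
        return fast
    return engine.align(read)


def _call_merged(
    read_id: str,
    merged: str,
    engine: _AssayAligner,
    config: CallerConfig,
) -> ReadCall:
    assay = engine.assay
    fast = engine.gapless(merged)
    if fast is not None and fast[0] > config.min_identity:
        identity, ref2read = fast
    else:
        identity, ref2read = engine.align(merged)

    # CpG coverage: both bases of each CpG dinucleotide must be aligned
    for o in assay.cpg_offsets:
        if ref2read[o] < 0 or o + 1 >= len(ref2read) or ref2read[o + 1] < 0:
            return ReadCall(read_id, assay.name, "incomplete_cpg_coverage", identity=identity)

    if identity <= config.min_identity:
        return ReadCall(read_id, assay.name, "low_identity", identity=identity)

    unmeth_dinuc = "CT" if config.literal_ct_mode else "TG"
    states = []
    for o in assay.cpg_offsets:
        dinuc = merged[ref2read[o]] + merged[ref2read[o + 1]]
        if dinuc == "CG":
            states.append(True)
        elif dinuc == unmeth_dinuc:
            states.append(False)
        else:
            return ReadCall(read_id, assay.name, "invalid_cpg_state", identity=identity)
    pattern = MoleculePattern(tuple(states))
    return ReadCall(
        read_id,
        assay.name,
        "none",
        states=pattern,
        methylation_percent=pattern.methylation_percent,
        identity=identity,
    )


def call_read(
    read: FastqRead | tuple[FastqRead, FastqRead],
    assay: AmpliconAssay,
    config: CallerConfig = CallerConfig(),
    _engine: _AssayAligner | None = None,
) -> ReadCall:
    """Run the full filter cascade on a read or read pair."""
    engine = _engine or _AssayAligner(assay, config)
    if isinstance(read, tuple):
        r1, r2 = read
        read_id = r1.read_id
        if not match_primer(r1.seq, assay.forward_primer):
            return ReadCall(read_id, assay.name, "primer_mismatch")
        merged = merge_pair(r1, r2, config)
        if merged is None:
            return ReadCall(read_id, assay.name, "unmergeable_pair")
        return _call_merged(read_id, merged.seq.upper(), engine, config)
    if not match_primer(read.seq, assay.forward_primer):
        return ReadCall(read.read_id, assay.name, "primer_mismatch")
    return _call_merged(read.read_id, read.seq.upper(), engine, config)


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream a (optionally gzipped) FASTQ file."""
    with _open_maybe_gzip(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield FastqRead(title.split()[0], seq, qual)


def process_sample(
    fastq_r1: str | Path,
    fastq_r2: str | Path | None,
    assay: AmpliconAssay,
    config: CallerConfig = CallerConfig(),
    sample_id: str | None = None,
) -> SampleReadSet:
    """Call every read (pair) of a sample and tally rejection reasons.

    Single-end input is allowed when individual reads span all CpGs.  Raises
    on mismatched R1/R2 record counts.  The accounting invariant
    ``n_valid + sum(rejections) == n_total`` always holds.
    """
    sample_id = sample_id or Path(fastq_r1).stem
    engine = _AssayAligner(assay, config)
    valid: list[ReadCall] = []
    rejections: Counter[str] = Counter()
    n_total = 0

    if fastq_r2 is None:
        for read in read_fastq(fastq_r1):
            n_total += 1
            call = call_read(read, assay, config, _engine=engine)
            (valid.append(call) if call.valid else rejections.update([call.rejection_reason]))
    else:
        it1, it2 = read_fastq(fastq_r1), read_fastq(fastq_r2)
        for r1 in it1:
            r2 = next(it2, None)
            if r2 is None:
                raise ValueError("R1 has more records than R2")
            n_total += 1
            call = call_read((r1, r2), assay, config, _engine=engine)
            (valid.append(call) if call.valid else rejections.update([call.rejection_reason]))
        if next(it2, None) is not None:
            raise ValueError("R2 has more records than R1")

    out = SampleReadSet(
        sample_id=sample_id,
        assay_name=assay.name,
        valid_calls=valid,
        rejection_counts=dict(rejections),
        n_total=n_total,
        min_valid_reads=config.min_valid_reads,
    )
    out.check_accounting()
    return out


def write_calls_tsv(calls: Iterable[ReadCall], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\tassay\tpattern\tmethylation_percent\tidentity\treason\n")
        for c in calls:
            pattern = c.states.bitstring() if c.states is not None else "."
            pct = f"{c.methylation_percent:.6g}" if c.methylation_percent is not None else "."
            ident = f"{c.identity:.4f}" if c.identity is not None else "."
            fh.write(
                f"{c.read_id}\t{c.assay_name}\t{pattern}\t{pct}\t{ident}"
                f"\t{c.rejection_reason}\n"
            )
    return path


def write_sample_summary_json(read_set: SampleReadSet, path: str | Path) -> Path:
    path = Path(path)
    percents = read_set.percents
    payload = {
        "sample_id": read_set.sample_id,
        "assay": read_set.assay_name,
        "n_total": read_set.n_total,
        "n_valid": read_set.n_valid,
        "discarded": read_set.discarded,
        "rejection_counts": read_set.rejection_counts,
        "mean_methylation_percent": float(percents.mean()) if len(percents) else None,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
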