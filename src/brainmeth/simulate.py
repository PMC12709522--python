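"""Synthetic inputs with the statistical structure the pipeline assumes.

Two families of data are generated, both seed-deterministic:

* **Amplicon reads.**  Per-molecule methylation patterns are drawn from a
  tissue profile — a mixture of *archetypes*, each an independent-Bernoulli
  vector of per-CpG methylation probabilities.  Brain tissue at a diagnostic
  locus is modelled as 90% brain-archetype molecules (near-fully unmethylated
  for hypo assays, near-fully methylated for hyper assays) plus 10%
  background; decoy tissues are background only.  This reproduces the
  bimodal per-read methylation distributions that make the assays work.
  Molecules are bisulfite-converted in silico with configurable conversion
  efficiency and inappropriate-conversion rates, sprinkled with substitution
  sequencing error, and emitted as 150-bp paired-end FASTQ with a truth table
  of every molecule's pattern.

* **Methylome compendia.**  Per-position, per-sample methylation fractions
  with brain-specific regions planted on an otherwise tissue-shared
  background, written as one bedGraph per sample plus a manifest and a truth
  BED — the input of the marker-discovery stage.

Mixtures (reads resampled from component samples by weight) and environmental
degradation (depth loss, molecule truncation, elevated error) are modelled as
transformations of FASTQ pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .amplicon import AmpliconAssay, MoleculePattern, enumerate_cpg_sites
from .io import (
    MethylationSiteRecord,
    SampleManifestEntry,
    write_manifest,
    write_methylation_table,
)
from .readcall import FastqRead, read_fastq

__all__ = [
    "TissueProfile",
    "NoiseModel",
    "DegradationSpec",
    "PlantedRegion",
    "CompendiumSimSpec",
    "sample_molecule",
    "simulate_molecule_seq",
    "generate_reads",
    "mix_read_sets",
    "apply_degradation",
    "generate_compendium",
    "default_assay_panel",
    "default_profiles",
    "sample_percent_pool",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TissueProfile:
    """Mixture of methylation archetypes for one tissue at one assay.

    ``archetypes`` is a sequence of (weight, per-CpG methylation probability
    vector); weights must sum to 1.
    """

    assay_name: str
    tissue_label: str
    archetypes: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        weights = [w for w, _ in self.archetypes]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"archetype weights must sum to 1, got {sum(weights)}")
        n = {len(p) for _, p in self.archetypes}
        if len(n) != 1:
            raise ValueError("all archetypes must cover the same CpGs")
        for w, probs in self.archetypes:
            if w < 0 or any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError("weights and probabilities must be in [0, 1]")

    @property
    def n_cpg(self) -> int:
        return len(self.archetypes[0][1])

    def expected_methylation(self) -> np.ndarray:
        """Per-CpG marginal methylation probability of the mixture."""
        out = np.zeros(self.n_cpg)
        for w, probs in self.archetypes:
            out += w * np.asarray(probs)
        return out


@dataclass(frozen=True)
class NoiseModel:
    """Bisulfite and sequencing noise rates.

    conversion_efficiency: probability an unmethylated C is read as T.
    inappropriate_conversion: probability a methylated C is read as T.
    seq_error: per-base substitution probability (uniform over other bases).
    base_quality: constant Phred score written to FASTQ.
    """

    conversion_efficiency: float = 0.99
    inappropriate_conversion: float = 0.005
    seq_error: float = 0.002
    base_quality: int = 35

    def __post_init__(self) -> None:
        for r in (self.conversion_efficiency, self.inappropriate_conversion, self.seq_error):
            if not 0.0 <= r <= 1.0:
                raise ValueError("noise rates must be in [0, 1]")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(conversion_efficiency=1.0, inappropriate_conversion=0.0, seq_error=0.0)


@dataclass(frozen=True)
class DegradationSpec:
    """Environmental degradation applied to a sequenced sample.

    depth_factor: fraction of read pairs surviving.
    truncation_prob: probability a surviving molecule is 3'-truncated below
        full CpG coverage (reads cut to ``truncate_to`` bases).
    error_multiplier: factor on the substitution error rate; the extra error
        injected is ``(error_multiplier - 1) * base_seq_error``.
    """

    depth_factor: float = 0.3
    truncation_prob: float = 0.2
    error_multiplier: float = 3.0
    truncate_to: int = 60
    base_seq_error: float = 0.002

    def __post_init__(self) -> None:
        if not 0.0 < self.depth_factor <= 1.0:
            raise ValueError("depth_factor must be in (0, 1]")
        if not 0.0 <= self.truncation_prob < 1.0:
            raise ValueError("truncation_prob must be in [0, 1)")
        if self.error_multiplier < 1.0:
            raise ValueError("error_multiplier must be >= 1")


@dataclass(frozen=True)
class PlantedRegion:
    """A brain-specific differentially methylated region to plant."""

    position_indices: tuple[int, ...]
    mode: str  # "hypo" or "hyper"
    brain_level: float
    decoy_level: float

    def __post_init__(self) -> None:
        if self.mode not in ("hypo", "hyper"):
            raise ValueError(f"bad mode {self.mode!r}")
        if len(self.position_indices) < 2:
            raise ValueError("planted region needs >= 2 positions")


@dataclass(frozen=True)
class CompendiumSimSpec:
    """Specification of a synthetic multi-tissue methylome compendium.

    Background methylation is tissue-shared by default (methylation outside
    differentially methylated regions is largely common across somatic
    tissues): each position draws one background mean from ``brain_beta``
    used for both groups, and each sample jitters around it with
    concentration ``jitter_kappa``.  With ``shared_background=False`` the
    groups draw independent means from their own Beta distributions, which
    deliberately produces chance brain/decoy contrasts.  Planted regions
    override the means with the stated brain/decoy levels.
    """

    n_positions: int = 500
    brain_samples: int = 4
    decoy_samples: int = 8
    brain_beta: tuple[float, float] = (0.4, 0.4)
    decoy_beta: tuple[float, float] = (0.4, 0.4)
    shared_background: bool = True
    jitter_kappa: float = 50.0
    min_gap: int = 20
    max_gap: int = 60
    chrom: str = "chr1"
    planted_regions: tuple[PlantedRegion, ...] = ()
    decoy_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in self.planted_regions:
            if max(r.position_indices) >= self.n_positions:
                raise ValueError("planted region index out of range")


def sample_molecule(profile: TissueProfile, rng: np.random.Generator) -> MoleculePattern:
    """Draw one molecule's methylation pattern from a tissue profile."""
    weights = np.array([w for w, _ in profile.archetypes])
    idx = rng.choice(len(weights), p=weights)
    probs = np.asarray(profile.archetypes[idx][1])
    states = rng.random(len(probs)) < probs
    return MoleculePattern(tuple(bool(s) for s in states))


def _sample_patterns(
    profile: TissueProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw of n molecule patterns (n x n_cpg boolean array)."""
    weights = np.array([w for w, _ in profile.archetypes])
    probs = np.array([p for _, p in profile.archetypes])  # (n_arch, n_cpg)
    arch = rng.choice(len(weights), size=n, p=weights)
    return rng.random((n, probs.shape[1])) < probs[arch]


def sample_percent_pool(
    profile: TissueProfile, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-read methylation percents of n molecules drawn from a profile."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patterns = _sample_patterns(profile, n, rng)
    return patterns.mean(axis=1)


def simulate_molecule_seq(
    assay: AmpliconAssay,
    pattern: MoleculePattern,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> str:
    """Bisulfite-converted, error-bearing sequence of one molecule.

    Non-CpG cytosines are assumed unmethylated and convert with probability
    ``conversion_efficiency``; CpG cytosines follow the molecule's pattern,
    with failed conversion (unmethylated C kept) at rate 1 - efficiency and
    inappropriate conversion (methylated C lost) at the configured rate.
    Substitution errors are applied uniformly afterwards.
    """
    if assay.reference_seq is None:
        raise ValueError(f"assay {assay.name} has no reference sequence")
    seq = np.frombuffer(assay.reference_seq.encode("ascii"), dtype=np.uint8).copy()
    is_c = seq == ord("C")
    cpg = np.zeros(len(seq), dtype=bool)
    cpg[list(assay.cpg_offsets)] = True

    # non-CpG C: unmethylated by assumption
    noncpg_c = is_c & ~cpg
    convert = rng.random(len(seq)) < noise.conversion_efficiency
    seq[noncpg_c & convert] = ord("T")

    for offset, methylated in zip(assay.cpg_offsets, pattern.states):
        if methylated:
            if rng.random() < noise.inappropriate_conversion:
                seq[offset] = ord("T")
        else:
            if rng.random() < noise.conversion_efficiency:
                seq[offset] = ord("T")

    if noise.seq_error > 0:
        hit = rng.random(len(seq)) < noise.seq_error
        if np.any(hit):
            idx = np.where(hit)[0]
            for i in idx:
                choices = _BASES[_BASES != seq[i]]
                seq[i] = rng.choice(choices)
    return seq.tobytes().decode("ascii")


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
    return path


def generate_reads(
    profile: TissueProfile,
    assay: AmpliconAssay,
    n: int,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    out_prefix: str | Path | None = None,
    read_length: int = 150,
) -> tuple[list[FastqRead], list[FastqRead], list[MoleculePattern]]:
    """Simulate n amplicon molecules as paired-end reads plus a truth table.

    R1 starts at the amplicon 5' end (forward-primer anchored); R2 is the
    reverse complement of the amplicon 3' end.  Byte-for-byte deterministic
    given the seed.  When ``out_prefix`` is given, writes
    ``<prefix>_R1.fastq``, ``<prefix>_R2.fastq`` and ``<prefix>_truth.tsv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if profile.n_cpg != assay.n_cpg:
        raise ValueError(
            f"profile covers {profile.n_cpg} CpGs but assay {assay.name} has {assay.n_cpg}"
        )
    rng = np.random.default_rng(seed)
    qual_char = chr(noise.base_quality + 33)
    r1s: list[FastqRead] = []
    r2s: list[FastqRead] = []
    truth: list[MoleculePattern] = []
    for i in range(n):
        pattern = sample_molecule(profile, rng)
        mol = simulate_molecule_seq(assay, pattern, noise, rng)
        r1 = mol[:read_length]
        r2 = reverse_complement(mol)[:read_length]
        read_id = f"{assay.name}:{profile.tissue_label}:{i}"
        r1s.append(FastqRead(read_id, r1, qual_char * len(r1)))
        r2s.append(FastqRead(read_id, r2, qual_char * len(r2)))
        truth.append(pattern)

    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        write_fastq(r1s, out_prefix.parent / f"{out_prefix.name}_R1.fastq")
        write_fastq(r2s, out_prefix.parent / f"{out_prefix.name}_R2.fastq")
        with open(out_prefix.parent / f"{out_prefix.name}_truth.tsv", "w") as fh:
            fh.write("read_id\tpattern\tmethylation_percent\n")
            for r, p in zip(r1s, truth):
                fh.write(f"{r.read_id}\t{p.bitstring()}\t{p.methylation_percent:.6g}\n")
    return r1s, r2s, truth


def mix_read_sets(
    components: Sequence[tuple[list[FastqRead], list[FastqRead], float]],
    n_total: int,
    seed: int = 0,
) -> tuple[list[FastqRead], list[FastqRead]]:
    """Resample a tissue mixture from component read sets.

    ``components`` are (R1 reads, R2 reads, weight) triples with weights
    summing to 1.  Each output pair is drawn with replacement from component
    i with probability weight_i; provenance is appended to the read id as
    ``|src=<component index>``.
    """
    weights = np.array([w for _, _, w in components], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1")
    for r1s, r2s, _ in components:
        if not r1s or len(r1s) != len(r2s):
            raise ValueError("components must be non-empty with paired R1/R2")
    rng = np.random.default_rng(seed)
    comp_idx = rng.choice(len(components), size=n_total, p=weights)
    out1: list[FastqRead] = []
    out2: list[FastqRead] = []
    for j, ci in enumerate(comp_idx):
        r1s, r2s, _ = components[ci]
        k = int(rng.integers(len(r1s)))
        rid = f"{r1s[k].read_id}|src={ci}|mix={j}"
        out1.append(FastqRead(rid, r1s[k].seq, r1s[k].qual))
        out2.append(FastqRead(rid, r2s[k].seq, r2s[k].qual))
    return out1, out2


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.where(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def apply_degradation(
    r1s: Sequence[FastqRead],
    r2s: Sequence[FastqRead],
    spec: DegradationSpec = DegradationSpec(),
    seed: int = 0,
) -> tuple[list[FastqRead], list[FastqRead]]:
    """Emulate environmental damage on a sequenced sample.

    Pairs survive with probability ``depth_factor``; surviving molecules are
    truncated (both mates cut to ``truncate_to`` bases) with probability
    ``truncation_prob``; all surviving bases receive the extra substitution
    error implied by ``error_multiplier``.
    """
    rng = np.random.default_rng(seed)
    extra_error = (spec.error_multiplier - 1.0) * spec.base_seq_error
    out1: list[FastqRead] = []
    out2: list[FastqRead] = []
    for r1, r2 in zip(r1s, r2s, strict=True):
        if rng.random() >= spec.depth_factor:
            continue
        s1, q1, s2, q2 = r1.seq, r1.qual, r2.seq, r2.qual
        if rng.random() < spec.truncation_prob:
            t = spec.truncate_to
            s1, q1, s2, q2 = s1[:t], q1[:t], s2[:t], q2[:t]
        s1 = _substitute(s1, extra_error, rng)
        s2 = _substitute(s2, extra_error, rng)
        out1.append(FastqRead(r1.read_id, s1, q1))
        out2.append(FastqRead(r2.read_id, s2, q2))
    return out1, out2


def _random_amplicon(
    rng: np.random.Generator,
    length: int,
    cpg_offsets: Sequence[int],
    primer_len: int = 24,
) -> str:
    """Random amplicon with CpGs exactly at the requested interior offsets."""
    seq = rng.choice(_BASES, size=length)
    s = list(seq.tobytes().decode("ascii"))
    # erase accidental CpGs, then plant the requested ones
    for i in range(length - 1):
        if s[i] == "C" and s[i + 1] == "G":
            s[i + 1] = "A"
    for o in cpg_offsets:
        if not primer_len <= o < length - primer_len - 1:
            raise ValueError("CpG offsets must avoid primer regions")
        s[o], s[o + 1] = "C", "G"
        if o > 0 and s[o - 1] == "C":
            s[o - 1] = "A"  # avoid creating an unplanned upstream CpG
        if s[o + 2] == "G":
            s[o + 2] = "A"
    out = "".join(s)
    got = enumerate_cpg_sites(out)
    if got != sorted(cpg_offsets):
        raise AssertionError(f"CpG planting failed: {got} != {sorted(cpg_offsets)}")
    return out


def _primer_pair_from_reference(ref: str, primer_len: int = 24) -> tuple[str, str]:
    """Bisulfite-specific primers: converted top-strand ends of the amplicon.

    The forward primer equals the converted reference prefix (CpG cytosines
    degenerate as Y); the reverse primer is the reverse complement of the
    converted suffix (CpG degeneracy becomes R).
    """
    from .amplicon import bisulfite_convert_reference

    conv = bisulfite_convert_reference(ref)
    fwd = conv[:primer_len]
    rev = reverse_complement(conv[-primer_len:])
    return fwd, rev


def default_assay_panel(panel_seed: int = 7_2025) -> list[AmpliconAssay]:
    """Four synthetic diagnostic assays (two hypo, two hyper).

    Geometry loosely follows the deployed panel: amplicons of 200-260 bp
    carrying 8-12 CpGs, primer regions kept CpG-free.  Deterministic for a
    given ``panel_seed``; coordinates are placed on a synthetic contig.
    """
    rng = np.random.default_rng(panel_seed)
    specs = [
        ("syn1", "hypo", 240, 10),
        ("syn2", "hypo", 220, 8),
        ("syn3", "hyper", 260, 12),
        ("syn4", "hyper", 200, 9),
    ]
    assays = []
    offset = 10_000
    for name, rtype, length, n_cpg in specs:
        lo, hi = 28, length - 30
        positions = np.sort(rng.choice(np.arange(lo, hi, 3), size=n_cpg, replace=False))
        ref = _random_amplicon(rng, length, [int(p) for p in positions])
        fwd, rev = _primer_pair_from_reference(ref)
        assays.append(
            AmpliconAssay(
                name=name,
                region_type=rtype,
                chrom="synth1",
                start=offset,
                end=offset + length,
                forward_primer=fwd,
                reverse_primer=rev,
                forward_overhang="TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG",
                reverse_overhang="GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG",
                reference_seq=ref,
            )
        )
        offset += 10_000
    return assays


def default_profiles(
    assay: AmpliconAssay,
    brain_archetype_weight: float = 0.9,
    p_extreme: float = 0.03,
    p_background: float = 0.9,
) -> tuple[TissueProfile, TissueProfile]:
    """Brain and decoy tissue profiles for a synthetic assay.

    For a hypo assay the brain archetype is near-fully unmethylated
    (per-CpG probability ``p_extreme``) against a highly methylated
    background (``p_background``); hyper assays are mirrored.  Brain is
    ``brain_archetype_weight`` archetype + remainder background; decoys are
    background only.
    """
    k = assay.n_cpg
    if assay.region_type == "hypo":
        arch, back = p_extreme, p_background
    else:
        arch, back = 1.0 - p_extreme, 1.0 - p_background
    brain = TissueProfile(
        assay_name=assay.name,
        tissue_label="brain",
        archetypes=(
            (brain_archetype_weight, (arch,) * k),
            (1.0 - brain_archetype_weight, (back,) * k),
        ),
    )
    decoy = TissueProfile(
        assay_name=assay.name,
        tissue_label="decoy",
        archetypes=((1.0, (back,) * k),),
    )
    return brain, decoy


def generate_compendium(
    spec: CompendiumSimSpec,
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Write a synthetic compendium: per-sample bedGraphs, manifest, truth BED.

    Returns (manifest path, truth BED path).  Deterministic given
    ``spec.seed``: same spec -> identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    gaps = rng.integers(spec.min_gap, spec.max_gap + 1, size=spec.n_positions)
    # keep planted members close enough that any 5 of them sit within 300 bp
    tight_hi = min(36, spec.max_gap + 1)
    for region in spec.planted_regions:
        idx = sorted(region.position_indices)
        for i in idx[1:]:
            gaps[i] = rng.integers(spec.min_gap, tight_hi)
    positions = 1000 + np.cumsum(gaps)
    for region in spec.planted_regions:
        idx = sorted(region.position_indices)
        spans = [
            positions[idx[i + 4]] - positions[idx[i]]
            for i in range(len(idx) - 4)
        ]
        if not spans or min(spans) > 300:
            raise ValueError(
                "planted region violates the >=5 CpGs within 300 bp invariant"
            )

    a_b, b_b = spec.brain_beta
    a_d, b_d = spec.decoy_beta
    brain_mean = rng.beta(a_b, b_b, size=spec.n_positions)
    if spec.shared_background:
        decoy_mean = brain_mean.copy()
    else:
        decoy_mean = rng.beta(a_d, b_d, size=spec.n_positions)
    for region in spec.planted_regions:
        idx = list(region.position_indices)
        brain_mean[idx] = region.brain_level
        decoy_mean[idx] = region.decoy_level

    def jitter(mean: np.ndarray, size: int) -> np.ndarray:
        kappa = spec.jitter_kappa
        a = np.clip(mean, 1e-3, 1 - 1e-3) * kappa
        b = kappa - a
        return rng.beta(np.tile(a, (size, 1)), np.tile(b, (size, 1)))

    brain_vals = jitter(brain_mean, spec.brain_samples)   # (samples, positions)
    decoy_vals = jitter(decoy_mean, spec.decoy_samples)

    entries: list[SampleManifestEntry] = []
    for g, (vals, n) in (
        ("brain", (brain_vals, spec.brain_samples)),
        ("decoy", (decoy_vals, spec.decoy_samples)),
    ):
        for s in range(n):
            sample_id = f"{g}{s + 1}"
            table = outdir / f"{sample_id}.bedgraph"
            records = []
            for p in range(spec.n_positions):
                if g == "decoy" and spec.decoy_missing_rate > 0:
                    if rng.random() < spec.decoy_missing_rate:
                        continue
                records.append(
                    MethylationSiteRecord(
                        spec.chrom,
                        int(positions[p]),
                        int(positions[p]) + 1,
                        float(vals[s, p]),
                    )
                )
            write_methylation_table(records, table)
            entries.append(SampleManifestEntry(sample_id, sample_id, g, table))

    manifest_path = write_manifest(entries, outdir / "manifest.tsv")
    truth_path = outdir / "truth_regions.bed"
    with open(truth_path, "w") as fh:
        for i, region in enumerate(spec.planted_regions, start=1):
            idx = list(region.position_indices)
            start = int(positions[min(idx)])
            end = int(positions[max(idx)]) + 1
            fh.write(f"{spec.chrom}\t{start}\t{end}\tplanted{i}_{region.mode}\t0\t.\n")
    return manifest_path, truth_path
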