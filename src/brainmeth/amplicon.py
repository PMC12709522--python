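"""Targeted bisulfite amplicon assays: primers, converted references, CpG maps.

An :class:`AmpliconAssay` bundles everything the read caller needs for one
diagnostic locus: the genome-specific primer pair (IUPAC degeneracy allowed,
adapter overhangs stored separately), the untreated amplicon reference, the
in-silico bisulfite-converted top strand, and the offsets of every CpG
cytosine in the amplicon.

Bisulfite conversion turns every unmethylated cytosine into thymine (via
uracil) while 5-methylcytosine stays cytosine.  Because essentially all
mammalian methylation sits on CpG dinucleotides, the converted reference is
deterministic except at CpG cytosines, which are represented by the IUPAC
wildcard ``Y`` (C if the molecule was methylated, T otherwise).  Assays are
modelled on the bisulfite top strand selected by the forward primer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "AmpliconAssay",
    "MoleculePattern",
    "IUPAC_CODES",
    "enumerate_cpg_sites",
    "bisulfite_convert_reference",
    "iupac_match",
    "match_primer",
    "load_assay_table",
    "packaged_assay_table",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def enumerate_cpg_sites(seq: str) -> list[int]:
    """Offsets of every CpG cytosine (a C immediately followed by G)."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def bisulfite_convert_reference(seq: str) -> str:
    """In-silico bisulfite conversion of the top strand.

    Non-CpG cytosines become T (assumed unmethylated); CpG cytosines become
    the wildcard Y (methylation-dependent C/T); everything else is unchanged.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    cpg = set(enumerate_cpg_sites(seq))
    return "".join(
        ("Y" if i in cpg else "T") if base == "C" else base
        for i, base in enumerate(seq)
    )


def iupac_match(read_base: str, code: str) -> bool:
    """True iff ``read_base`` belongs to the expansion of the IUPAC ``code``."""
    code = code.upper()
    if code not in IUPAC_CODES:
        raise ValueError(f"invalid IUPAC code {code!r}")
    return read_base.upper() in IUPAC_CODES[code]


def match_primer(read_prefix: str, primer: str) -> bool:
    """Exact primer check: every position must match under IUPAC expansion.

    Zero mismatches are allowed — amplicon reads must start with the expected
    genome-specific primer sequence.
    """
    if len(read_prefix) < len(primer):
        return False
    return all(
        iupac_match(b, p) for b, p in zip(read_prefix[: len(primer)], primer)
    )


@dataclass(frozen=True)
class MoleculePattern:
    """Ordered methylation states of one molecule over an assay's CpGs."""

    states: tuple[bool, ...]  # True = methylated

    @property
    def n_methylated(self) -> int:
        return sum(self.states)

    @property
    def methylation_percent(self) -> float:
        return self.n_methylated / len(self.states)

    def bitstring(self) -> str:
        return "".join("M" if s else "u" for s in self.states)

    @classmethod
    def from_bitstring(cls, s: str) -> "MoleculePattern":
        return cls(tuple(ch in "M1" for ch in s))


@dataclass(frozen=True)
class AmpliconAssay:
    """One targeted assay: locus, primer pair, reference, and CpG geometry."""

    name: str
    region_type: str  # "hypo" or "hyper"
    chrom: str
    start: int
    end: int
    forward_primer: str
    reverse_primer: str
    forward_overhang: str = ""
    reverse_overhang: str = ""
    reference_seq: str | None = None
    converted_ref: str | None = None
    cpg_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.region_type not in ("hypo", "hyper"):
            raise ValueError(f"bad region_type {self.region_type!r}")
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start >= end")
        if self.reference_seq is not None:
            ref = self.reference_seq.upper()
            object.__setattr__(self, "reference_seq", ref)
            conv = bisulfite_convert_reference(ref)
            object.__setattr__(self, "converted_ref", conv)
            object.__setattr__(
                self, "cpg_offsets", tuple(enumerate_cpg_sites(ref))
            )
        if self.cpg_offsets and list(self.cpg_offsets) != sorted(set(self.cpg_offsets)):
            raise ValueError("cpg_offsets must be strictly increasing")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_offsets)

    def converted_reverse_primer_site(self) -> str | None:
        """Converted-top-strand segment the reverse primer anneals to."""
        if self.converted_ref is None:
            return None
        return self.converted_ref[-len(self.reverse_primer) :]


def _split_overhang(primer_field: str, assay: str, which: str) -> tuple[str, str]:
    """Split '(OVERHANG) GENOMIC' into (overhang, genomic primer)."""
    s = primer_field.strip()
    if s.startswith("("):
        close = s.find(")")
        if close > 0:
            return s[1:close].strip(), s[close + 1 :].replace(" ", "").strip()
    if "(" in s or ")" in s:
        warnings.warn(
            f"{assay}: unparseable overhang parentheses in {which} primer; "
            "treating the whole field as genome-specific",
            stacklevel=3,
        )
    return "", s.replace(" ", "")


def load_assay_table(
    path: str | Path,
    reference_fasta: str | Path | None = None,
) -> list[AmpliconAssay]:
    """Load an assay definition table.

    The table is TSV with header columns ``name``, ``forward_primer`` (adapter
    overhang in parentheses), ``reverse_primer``, ``type`` (hypo/hyper),
    ``chrom``, ``start``, ``end``.  Coordinates are 0-based half-open, so
    ``end - start`` is the locus length.  Amplicon reference sequences may be
    supplied via a FASTA whose record ids equal assay names; assays present
    in the FASTA get converted references and CpG offsets.
    """
    path = Path(path)
    refs: dict[str, str] = {}
    if reference_fasta is not None:
        refs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(reference_fasta), "fasta")
        }

    assays: list[AmpliconAssay] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = ["name", "forward_primer", "reverse_primer", "type", "chrom", "start", "end"]
        missing = [c for c in required if c not in idx]
        if missing:
            raise ValueError(f"{path}: assay table missing columns {missing}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[idx["name"]].strip()
            fwd_over, fwd = _split_overhang(fields[idx["forward_primer"]], name, "forward")
            rev_over, rev = _split_overhang(fields[idx["reverse_primer"]], name, "reverse")
            rtype = fields[idx["type"]].strip().lower()
            start = int(fields[idx["start"]].replace(",", ""))
            end = int(fields[idx["end"]].replace(",", ""))
            assays.append(
                AmpliconAssay(
                    name=name,
                    region_type=rtype,
                    chrom=fields[idx["chrom"]].strip(),
                    start=start,
                    end=end,
                    forward_primer=fwd,
                    reverse_primer=rev,
                    forward_overhang=fwd_over,
                    reverse_overhang=rev_over,
                    reference_seq=refs.get(name),
                )
            )
    return assays


def packaged_assay_table() -> Path:
    """Path to the bundled 13-assay brain panel definition table (hg19 loci)."""
    return Path(resources.files("brainmeth") / "data" / "assays.tsv")
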