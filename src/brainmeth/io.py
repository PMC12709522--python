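"""Per-position methylome tables, sample manifests, and the brain/decoy compendium.

Marker discovery starts from one bedGraph-style table per tissue sample
(``chrom  start  end  methylation  [coverage]``, 0-based half-open) plus a
manifest labelling each sample ``brain`` or ``decoy``.  This module parses and
writes those tables and assembles them into a positions-by-samples matrix
(:class:`CompendiumMatrix`) that the scoring code consumes.

Scale handling
--------------
Methylation columns occur in two dialects in the wild: percent (0-100, the
Bismark ``bedGraph`` convention) and fraction (0-1).  By default the reader
auto-detects: a file containing any value > 1 is taken to be percent-scaled.
Pass ``percent_scale=True``/``False`` to force a dialect.  The writer defaults
to fraction scale because that representation round-trips floating-point
values exactly; percent output is available for interop with genome browsers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleManifestEntry",
    "MethylationSiteRecord",
    "CompendiumMatrix",
    "read_methylation_table",
    "write_methylation_table",
    "read_manifest",
    "write_manifest",
    "collapse_strands",
    "build_compendium",
]

GROUPS = ("brain", "decoy")


class MethylomeParseError(ValueError):
    """A malformed line in a methylation table."""


@dataclass(frozen=True)
class SampleManifestEntry:
    """One sample of the multi-tissue compendium."""

    sample_id: str
    tissue_label: str
    group: str  # "brain" or "decoy"
    table_path: Path

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"group must be one of {GROUPS}, got {self.group!r}"
            )
        object.__setattr__(self, "table_path", Path(self.table_path))


@dataclass(frozen=True)
class MethylationSiteRecord:
    """Methylation level of one sample at one covered position.

    Coordinates are 0-based half-open; a single CpG is keyed by the
    plus-strand cytosine, so ``end - start == 1`` for per-CpG records.
    ``methylation_fraction`` is always stored on the 0-1 scale regardless of
    the on-disk dialect.
    """

    chrom: str
    start: int
    end: int
    methylation_fraction: float
    coverage: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got {self.start} >= {self.end} "
                f"({self.chrom})"
            )
        if not 0.0 <= self.methylation_fraction <= 1.0:
            raise ValueError(
                f"methylation_fraction outside [0, 1]: "
                f"{self.methylation_fraction}"
            )
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(f"negative coverage: {self.coverage}")


@dataclass
class CompendiumMatrix:
    """Positions-by-samples methylation fractions with brain/decoy labels.

    ``values`` is a DataFrame indexed by ``(chrom, start)`` (sorted, unique)
    with one column per sample; missing entries are NaN.  ``groups`` maps
    sample_id -> "brain"/"decoy" for every column.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        bad = [g for g in self.groups.values() if g not in GROUPS]
        if bad:
            raise ValueError(f"invalid group labels: {bad}")
        with np.errstate(invalid="ignore"):
            vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
            raise ValueError("methylation fractions outside [0, 1]")

    @property
    def positions(self) -> list[tuple[str, int]]:
        return list(self.values.index)

    def sample_ids(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.values.columns)
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def brain(self) -> pd.DataFrame:
        return self.values[self.sample_ids("brain")]

    @property
    def decoy(self) -> pd.DataFrame:
        return self.values[self.sample_ids("decoy")]


def _is_track_line(line: str) -> bool:
    s = line.strip()
    return (not s) or s.startswith("#") or s.startswith("track") or s.startswith("browser")


def read_methylation_table(
    path: str | Path,
    percent_scale: bool | None = None,
) -> Iterator[MethylationSiteRecord]:
    """Parse a bedGraph-style methylation table.

    Parameters
    ----------
    path:
        TSV/whitespace table with >= 4 columns: chrom, start, end,
        methylation, and optionally coverage.  ``track``/``#`` header lines
        are skipped.
    percent_scale:
        True -> methylation column is percent (divided by 100); False ->
        already a fraction; None (default) -> auto-detect, treating the file
        as percent when any value exceeds 1.

    Yields records in file order.  Raises :class:`MethylomeParseError` naming
    the offending line on non-numeric fields, and ``ValueError`` when a value
    is outside [0, 100] or an interval is empty/inverted.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, float, int | None, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_track_line(line):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise MethylomeParseError(
                    f"{path}:{lineno}: expected >= 4 fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise MethylomeParseError(
                    f"{path}:{lineno}: non-numeric coordinate: {exc}"
                ) from None
            try:
                meth = float(fields[3])
            except ValueError:
                raise MethylomeParseError(
                    f"{path}:{lineno}: non-numeric methylation value "
                    f"{fields[3]!r}"
                ) from None
            if not math.isfinite(meth) or not 0.0 <= meth <= 100.0:
                raise ValueError(
                    f"{path}:{lineno}: methylation value {meth} outside [0, 100]"
                )
            coverage: int | None = None
            if len(fields) >= 5:
                try:
                    coverage = int(fields[4])
                except ValueError:
                    raise MethylomeParseError(
                        f"{path}:{lineno}: non-numeric coverage {fields[4]!r}"
                    ) from None
            rows.append((chrom, start, end, meth, coverage, lineno))

    if percent_scale is None:
        percent_scale = any(r[3] > 1.0 for r in rows)

    for chrom, start, end, meth, coverage, lineno in rows:
        frac = meth / 100.0 if percent_scale else meth
        if frac > 1.0:
            raise ValueError(
                f"{path}:{lineno}: fraction-scale value {meth} exceeds 1 "
                "(pass percent_scale=True?)"
            )
        yield MethylationSiteRecord(chrom, start, end, frac, coverage)


def write_methylation_table(
    records: Iterable[MethylationSiteRecord],
    path: str | Path,
    percent_scale: bool = False,
) -> Path:
    """Write records as a bedGraph-style table.

    With the default fraction scale, ``read_methylation_table(write(...))``
    reproduces the input exactly (full-precision ``repr`` output).  Percent
    scale matches the Bismark convention but multiplies/divides by 100, which
    is not bit-exact for arbitrary floats.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            value = rec.methylation_fraction * 100.0 if percent_scale else rec.methylation_fraction
            cols = [rec.chrom, str(rec.start), str(rec.end), repr(float(value))]
            if rec.coverage is not None:
                cols.append(str(rec.coverage))
            fh.write("\t".join(cols) + "\n")
    return path


MANIFEST_COLUMNS = ["sample_id", "tissue_label", "group", "path"]


def read_manifest(path: str | Path) -> list[SampleManifestEntry]:
    """Read a sample manifest TSV (columns sample_id, tissue_label, group, path).

    Relative table paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id values {dupes}")
    entries = []
    for row in df.itertuples(index=False):
        table = Path(row.path)
        if not table.is_absolute():
            table = path.parent / table
        entries.append(
            SampleManifestEntry(row.sample_id, row.tissue_label, row.group, table)
        )
    return entries


def write_manifest(entries: Sequence[SampleManifestEntry], path: str | Path) -> Path:
    """Write a manifest TSV; table paths inside the manifest's directory are
    stored relative, keeping generated trees relocatable."""
    path = Path(path)

    def fmt(p: Path) -> str:
        try:
            return str(p.resolve().relative_to(path.parent.resolve()))
        except ValueError:
            return str(p)

    df = pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in entries],
            "tissue_label": [e.tissue_label for e in entries],
            "group": [e.group for e in entries],
            "path": [fmt(e.table_path) for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def collapse_strands(
    records: Iterable[MethylationSiteRecord],
) -> list[MethylationSiteRecord]:
    """Collapse strand-split CpG records onto the plus-strand cytosine.

    CpG methylation is strand-symmetric, so callers that report the G-strand
    cytosine separately (at coordinate C+1) carry redundant information.  Any
    single-base record whose start equals another record's start + 1 on the
    same chromosome is treated as the minus-strand mate: it is re-keyed to
    C and averaged with the plus-strand record, coverage-weighted when both
    coverages are present, unweighted otherwise.
    """
    recs = list(records)
    by_key: dict[tuple[str, int], MethylationSiteRecord] = {}
    order: list[tuple[str, int]] = []
    singles = {(r.chrom, r.start) for r in recs if r.end - r.start == 1}
    for r in recs:
        key = (r.chrom, r.start)
        if r.end - r.start == 1 and (r.chrom, r.start - 1) in singles:
            key = (r.chrom, r.start - 1)  # minus-strand mate of the C at start-1
            r = MethylationSiteRecord(
                r.chrom, r.start - 1, r.end - 1, r.methylation_fraction, r.coverage
            )
        if key not in by_key:
            by_key[key] = r
            order.append(key)
        else:
            a, b = by_key[key], r
            if a.coverage is not None and b.coverage is not None and a.coverage + b.coverage > 0:
                total = a.coverage + b.coverage
                frac = (
                    a.methylation_fraction * a.coverage
                    + b.methylation_fraction * b.coverage
                ) / total
                cov: int | None = total
            else:
                frac = (a.methylation_fraction + b.methylation_fraction) / 2.0
                cov = None
            by_key[key] = MethylationSiteRecord(a.chrom, a.start, a.end, frac, cov)
    return [by_key[k] for k in order]


def build_compendium(
    manifest: Sequence[SampleManifestEntry],
    min_decoy_coverage_fraction: float = 0.8,
    percent_scale: bool | None = None,
) -> CompendiumMatrix:
    """Assemble per-sample tables into a positions-by-samples matrix.

    A position is retained iff it is covered (present) in *every* brain
    sample and in at least ``min_decoy_coverage_fraction`` of decoy samples
    (default 0.8).  Decoy entries absent at a retained position stay NaN and
    are ignored downstream by the scoring means.
    """
    brains = [e for e in manifest if e.group == "brain"]
    decoys = [e for e in manifest if e.group == "decoy"]
    if not brains:
        raise ValueError("manifest contains no brain samples")
    if not decoys:
        raise ValueError("manifest contains no decoy samples")
    if not 0.0 <= min_decoy_coverage_fraction <= 1.0:
        raise ValueError("min_decoy_coverage_fraction must be in [0, 1]")

    columns = {}
    for entry in manifest:
        recs = read_methylation_table(entry.table_path, percent_scale=percent_scale)
        series: dict[tuple[str, int], float] = {}
        for r in recs:
            series[(r.chrom, r.start)] = r.methylation_fraction
        columns[entry.sample_id] = pd.Series(series, dtype=float)

    values = pd.DataFrame(columns)
    values.index = pd.MultiIndex.from_tuples(values.index, names=["chrom", "start"])
    values = values.sort_index()

    brain_ids = [e.sample_id for e in brains]
    decoy_ids = [e.sample_id for e in decoys]
    covered_all_brain = values[brain_ids].notna().all(axis=1)
    decoy_cov = values[decoy_ids].notna().mean(axis=1)
    # >= with a float tolerance so e.g. 4/5 samples passes a 0.8 requirement
    keep = covered_all_brain & (decoy_cov >= min_decoy_coverage_fraction - 1e-12)
    values = values.loc[keep]

    groups = {e.sample_id: e.group for e in manifest}
    return CompendiumMatrix(values=values, groups=groups)
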