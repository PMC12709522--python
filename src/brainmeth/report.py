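"""Distribution summaries, assay metric tables, and run-configuration records.

Per-read methylation percents are summarized as histograms over [0, 1]
(10 equal bins by default, last bin right-inclusive) — the per-assay
"distribution of reads by methylation %" view used for sample diagnostics.
Any kernel-density smoothing is presentation-only; classification always
operates on the raw per-read percents.

``assay_metrics_table`` assembles the panel evaluation report (assay name,
locus length, type, per-read precision/recall, CpG count) from tree metrics,
and ``write_run_config`` serializes the effective configuration and seed
alongside every artifact so that deterministic stages can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .amplicon import AmpliconAssay
from .classify import TreeMetrics

__all__ = [
    "DistributionSummary",
    "summarize_distribution",
    "assay_metrics_table",
    "write_run_config",
    "plot_distributions",
]


@dataclass(frozen=True)
class DistributionSummary:
    """Binned distribution of per-read methylation percents for one sample."""

    assay_name: str
    sample_id: str
    bin_edges: tuple[float, ...]
    bin_fractions: tuple[float, ...]
    n_reads: int

    def __post_init__(self) -> None:
        if abs(sum(self.bin_fractions) - 1.0) > 1e-9:
            raise ValueError("bin fractions must sum to 1")


def summarize_distribution(
    percents: Sequence[float],
    n_bins: int = 10,
    assay_name: str = "assay",
    sample_id: str = "sample",
) -> DistributionSummary:
    """Histogram of per-read percents over [0, 1] with equal bins.

    The final bin is right-inclusive (a percent of exactly 1.0 lands in the
    last bin).  Raises on empty input or out-of-range percents.
    """
    arr = np.asarray(percents, dtype=float)
    if arr.size == 0:
        raise ValueError("no percents to summarize")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("percents must be in [0, 1]")
    counts, edges = np.histogram(arr, bins=n_bins, range=(0.0, 1.0))
    return DistributionSummary(
        assay_name=assay_name,
        sample_id=sample_id,
        bin_edges=tuple(float(e) for e in edges),
        bin_fractions=tuple(float(c) / arr.size for c in counts),
        n_reads=int(arr.size),
    )


def assay_metrics_table(
    rows: Sequence[tuple[AmpliconAssay, TreeMetrics]],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Panel evaluation report: name, length, type, precision, recall, n CpG.

    Precision/recall are the per-read held-out values for the brain class,
    printed as percentages.  Optionally written as TSV.
    """
    df = pd.DataFrame(
        {
            "name": [a.name for a, _ in rows],
            "length": [a.length for a, _ in rows],
            "type": [a.region_type for a, _ in rows],
            "precision": [round(100.0 * m.precision) for _, m in rows],
            "recall": [round(100.0 * m.recall) for _, m in rows],
            "n_cpg": [a.n_cpg for a, _ in rows],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def _to_plain(value: Any) -> Any:
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, Mapping):
        return {k: _to_plain(v) for k, v in value.items()}
    if isinstance(value, Path):
        return str(value)
    if isinstance(value, (list, tuple)):
        return [_to_plain(v) for v in value]
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    return value


def write_run_config(path: str | Path, seed: int | None = None, **blocks: Any) -> Path:
    """Serialize the effective run configuration (YAML) next to an artifact."""
    path = Path(path)
    payload = {"brainmeth_version": _pkg_version, "seed": seed}
    payload.update({k: _to_plain(v) for k, v in blocks.items()})
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def plot_distributions(
    summaries: Sequence[DistributionSummary],
    path: str | Path,
) -> Path:
    """Overlay per-sample methylation-percent histograms (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in summaries:
        centers = [
            (a + b) / 2 for a, b in zip(s.bin_edges[:-1], s.bin_edges[1:])
        ]
        ax.plot(centers, s.bin_fractions, marker="o", label=s.sample_id)
    ax.set_xlabel("methylation fraction per read")
    ax.set_ylabel("fraction of reads")
    if summaries:
        ax.set_title(summaries[0].assay_name)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
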