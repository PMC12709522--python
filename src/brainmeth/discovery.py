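"""Brain-specific marker discovery: per-position scoring and region ranking.

Every compendium position receives a *hypo* score (how close it is to being
completely unmethylated in all brain samples and completely methylated in all
decoys), a *hyper* score (the mirror image), and an *informativeness* score
(the better of the two).  Scores are weighted distances from the ideal
contrast, so the best attainable value is exactly 0 and everything else is
negative.  Major exceptions — a decoy sample that looks like brain, or vice
versa — are penalized logistically on top of the linear distance, so a single
badly-behaved sample costs far more than diffuse moderate noise.

Penalty
-------
For a deviation ``d`` in [0, 1] from the ideal methylation level::

    L(d) = d + A * (sigmoid(k * (d - c)) - sigmoid(-k * c))

with amplitude ``A`` (default 4), steepness ``k`` (default 15) and midpoint
``c`` (default 0.5).  ``L(0) = 0`` and ``L`` is strictly increasing, so the
position score ``-(w_b * mean L(brain devs) + w_d * mean L(decoy devs))`` is
<= 0 with equality only at the ideal position.

Candidate diagnostic regions are maximal runs of qualifying CpGs (score above
a floor, default -2) containing at least ``min_cpg`` sites (default 5) within
``max_span_bp`` (default 300), ranked by the mean informativeness of their
best 50% of CpGs plus a CpG-count bonus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import CompendiumMatrix

__all__ = [
    "ScoringConfig",
    "PositionScore",
    "CandidateRegion",
    "penalty",
    "score_position",
    "score_compendium",
    "find_candidate_regions",
    "rank_regions",
    "write_scores_tsv",
    "write_regions_bed",
    "write_regions_fasta",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the scoring and region-selection scheme.

    penalty_amplitude/steepness/midpoint : the logistic exception penalty
        (A, k, c above).
    weight_brain / weight_decoy : group weights in the position score.
    score_floor : minimum informativeness for a CpG to join a region
        (default -2, the tail where the genome-wide score distribution
        becomes vanishingly thin).
    min_cpg / max_span_bp : region admission rule (>= 5 CpGs within 300 bp).
    top_fraction : fraction of best member CpGs averaged in the region score.
    cpg_count_bonus : gamma in the additive bonus ``gamma * log2(n/min_cpg)``.
    """

    penalty_amplitude: float = 4.0
    penalty_steepness: float = 15.0
    penalty_midpoint: float = 0.5
    weight_brain: float = 1.0
    weight_decoy: float = 1.0
    score_floor: float = -2.0
    min_cpg: int = 5
    max_span_bp: int = 300
    top_fraction: float = 0.5
    cpg_count_bonus: float = 0.5

    def __post_init__(self) -> None:
        if self.penalty_amplitude <= 0 or self.penalty_steepness <= 0:
            raise ValueError("penalty amplitude and steepness must be > 0")
        if not 0.0 < self.penalty_midpoint < 1.0:
            raise ValueError("penalty midpoint must be in (0, 1)")
        if self.min_cpg < 2:
            raise ValueError("min_cpg must be >= 2")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.cpg_count_bonus < 0:
            raise ValueError("cpg_count_bonus must be >= 0")


@dataclass(frozen=True)
class PositionScore:
    """Hypo/hyper/informativeness scores of one genomic position (all <= 0)."""

    chrom: str
    pos: int
    hypo_score: float
    hyper_score: float

    @property
    def informativeness(self) -> float:
        return max(self.hypo_score, self.hyper_score)

    @property
    def best_mode(self) -> str:
        # tie -> hypo
        return "hypo" if self.hypo_score >= self.hyper_score else "hyper"


@dataclass(frozen=True)
class CandidateRegion:
    """A candidate diagnostic window over consecutive qualifying CpGs.

    ``start``/``end`` are 0-based half-open over the first-to-last member
    CpG cytosine.  ``cpg_scores`` holds each member's informativeness in
    ``cpg_positions`` order; ``region_score`` is filled by the ranking
    formula.
    """

    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]
    cpg_scores: tuple[float, ...]
    region_type: str  # "hypo" or "hyper"
    region_score: float

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def span(self) -> int:
        return self.cpg_positions[-1] - self.cpg_positions[0]

    def __post_init__(self) -> None:
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise ValueError("cpg_positions must be strictly increasing")
        if len(self.cpg_scores) != len(self.cpg_positions):
            raise ValueError("one score per member CpG required")
        if self.region_type not in ("hypo", "hyper"):
            raise ValueError(f"bad region_type {self.region_type!r}")


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def penalty(d: float | np.ndarray, config: ScoringConfig = ScoringConfig()):
    """Logistic exception penalty L(d) for a deviation d in [0, 1].

    Anchored at L(0) = 0 and strictly increasing; deviations beyond the
    midpoint (a sample on the wrong side of the contrast) incur most of the
    amplitude.  Accepts scalars or arrays.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("deviation must be in [0, 1]")
    A, k, c = (
        config.penalty_amplitude,
        config.penalty_steepness,
        config.penalty_midpoint,
    )
    out = arr + A * (_sigmoid(k * (arr - c)) - _sigmoid(-k * c))
    return float(out) if np.isscalar(d) or np.ndim(d) == 0 else out


def score_position(
    brain_fracs: Sequence[float],
    decoy_fracs: Sequence[float],
    mode: str,
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """Score one position in hypo or hyper mode; <= 0, and 0 only when ideal.

    Hypo mode measures distance from (brain fully unmethylated, decoys fully
    methylated); hyper mode from the mirrored ideal.
    """
    b = np.asarray(brain_fracs, dtype=float)
    d = np.asarray(decoy_fracs, dtype=float)
    if b.size == 0 or d.size == 0:
        raise ValueError("both brain and decoy groups must be non-empty")
    if np.any((b < 0) | (b > 1)) or np.any((d < 0) | (d > 1)):
        raise ValueError("methylation fractions must be in [0, 1]")
    if mode == "hypo":
        b_dev, d_dev = b, 1.0 - d
    elif mode == "hyper":
        b_dev, d_dev = 1.0 - b, d
    else:
        raise ValueError(f"mode must be 'hypo' or 'hyper', got {mode!r}")
    total = (
        config.weight_brain * np.mean(penalty(b_dev, config))
        + config.weight_decoy * np.mean(penalty(d_dev, config))
    )
    return float(-total + 0.0)  # normalize -0.0


def score_compendium(
    matrix: CompendiumMatrix,
    config: ScoringConfig = ScoringConfig(),
) -> list[PositionScore]:
    """Score every compendium position in both modes (vectorized).

    Missing decoy entries are ignored (means over the present values).  A
    position with zero present decoy values is skipped with a warning.
    """
    brain = matrix.brain.to_numpy(dtype=float)
    decoy = matrix.decoy.to_numpy(dtype=float)
    index = matrix.values.index

    n_decoy = np.sum(~np.isnan(decoy), axis=1)
    usable = n_decoy > 0
    if not np.all(usable):
        warnings.warn(
            f"skipping {int(np.sum(~usable))} position(s) with no decoy values",
            stacklevel=2,
        )

    def mean_penalty(dev: np.ndarray) -> np.ndarray:
        A, k, c = (
            config.penalty_amplitude,
            config.penalty_steepness,
            config.penalty_midpoint,
        )
        pen = dev + A * (_sigmoid(k * (dev - c)) - _sigmoid(-k * c))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(pen, axis=1)

    hypo = -(
        config.weight_brain * mean_penalty(brain)
        + config.weight_decoy * mean_penalty(1.0 - decoy)
    )
    hyper = -(
        config.weight_brain * mean_penalty(1.0 - brain)
        + config.weight_decoy * mean_penalty(decoy)
    )

    out = []
    for i, (chrom, pos) in enumerate(index):
        if not usable[i]:
            continue
        out.append(PositionScore(chrom, int(pos), float(hypo[i]), float(hyper[i])))
    return out


def _region_score(scores: Sequence[float], config: ScoringConfig) -> float:
    """Mean of the best ``top_fraction`` member scores plus the count bonus."""
    vals = np.sort(np.asarray(scores, dtype=float))[::-1]
    k = int(np.ceil(config.top_fraction * len(vals)))
    bonus = config.cpg_count_bonus * np.log2(len(vals) / config.min_cpg)
    return float(np.mean(vals[:k]) + bonus)


def _region_type(members: Sequence[PositionScore]) -> str:
    hypo_votes = sum(1 for m in members if m.best_mode == "hypo")
    return "hypo" if hypo_votes * 2 >= len(members) else "hyper"


def _make_region(members: Sequence[PositionScore], config: ScoringConfig) -> CandidateRegion:
    positions = tuple(m.pos for m in members)
    scores = tuple(m.informativeness for m in members)
    return CandidateRegion(
        chrom=members[0].chrom,
        start=positions[0],
        end=positions[-1] + 1,
        cpg_positions=positions,
        cpg_scores=scores,
        region_type=_region_type(members),
        region_score=_region_score(scores, config),
    )


def find_candidate_regions(
    scores: Sequence[PositionScore],
    config: ScoringConfig = ScoringConfig(),
) -> list[CandidateRegion]:
    """Select candidate diagnostic regions from sorted per-position scores.

    Only positions with informativeness above ``score_floor`` qualify.  A
    candidate is a maximal run of consecutive qualifying CpGs on one
    chromosome whose first-to-last distance is <= ``max_span_bp`` and which
    contains >= ``min_cpg`` members.  Overlapping candidates are resolved
    greedily, keeping the higher region score (ties: more CpGs, then
    leftmost).
    """
    for a, b in zip(scores, scores[1:]):
        if (a.chrom, a.pos) >= (b.chrom, b.pos):
            raise ValueError("scores must be sorted by (chrom, pos)")

    qualifying = [s for s in scores if s.informativeness > config.score_floor]
    candidates: list[CandidateRegion] = []

    # group by chromosome, keep file order
    by_chrom: dict[str, list[PositionScore]] = {}
    for s in qualifying:
        by_chrom.setdefault(s.chrom, []).append(s)

    for chrom_scores in by_chrom.values():
        pos = [s.pos for s in chrom_scores]
        n = len(pos)
        # two-pointer maximal windows under the span constraint
        windows = []
        for i in range(n):
            j = i
            while j + 1 < n and pos[j + 1] - pos[i] <= config.max_span_bp:
                j += 1
            windows.append((i, j))
        # a window is maximal iff no other window contains it
        for i, j in windows:
            if i > 0:
                pi, pj = windows[i - 1]
                if pi <= i and pj >= j:
                    continue  # contained in the window starting one earlier
            if j - i + 1 >= config.min_cpg:
                candidates.append(_make_region(chrom_scores[i : j + 1], config))

    # overlap resolution: best score first, ties by more CpGs then leftmost
    candidates.sort(
        key=lambda r: (-r.region_score, -r.n_cpg, r.chrom, r.start)
    )
    kept: list[CandidateRegion] = []
    for cand in candidates:
        if all(
            cand.chrom != k.chrom or cand.end <= k.start or cand.start >= k.end
            for k in kept
        ):
            kept.append(cand)
    kept.sort(key=lambda r: (r.chrom, r.start))
    return kept


def rank_regions(
    regions: Sequence[CandidateRegion],
    config: ScoringConfig = ScoringConfig(),
) -> list[CandidateRegion]:
    """Order candidate regions best-first by region score.

    The score is recomputed from the stored member informativeness values:
    mean of the top ``ceil(top_fraction * n)`` values plus
    ``cpg_count_bonus * log2(n / min_cpg)``.  Ties break by CpG count, then
    coordinate.
    """
    rescored = [
        replace(r, region_score=_region_score(r.cpg_scores, config))
        for r in regions
    ]
    rescored.sort(key=lambda r: (-r.region_score, -r.n_cpg, r.chrom, r.start))
    return rescored


def write_scores_tsv(scores: Iterable[PositionScore], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\thypo_score\thyper_score\tinformativeness\n")
        for s in scores:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.hypo_score:.6g}\t{s.hyper_score:.6g}"
                f"\t{s.informativeness:.6g}\n"
            )
    return path


def write_regions_bed(
    regions: Sequence[CandidateRegion], path: str | Path
) -> Path:
    """Write ranked regions as BED6 (name = rank, score = scaled region score)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rank, r in enumerate(regions, start=1):
            # BED score column: clamp -5..0 onto 0..1000, best = 1000
            bed_score = int(round(max(0.0, min(1.0, 1.0 + r.region_score / 5.0)) * 1000))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\trank{rank}_{r.region_type}"
                f"\t{bed_score}\t.\n"
            )
    return path


def write_regions_fasta(
    regions: Sequence[CandidateRegion],
    genome: Mapping[str, str],
    path: str | Path,
) -> Path:
    """Emit region sequences for external screening (e.g. a BLAST specificity check)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rank, r in enumerate(regions, start=1):
            seq = genome[r.chrom][r.start : r.end]
            fh.write(f">rank{rank}_{r.chrom}:{r.start}-{r.end}_{r.region_type}\n")
            fh.write(seq + "\n")
    return path
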