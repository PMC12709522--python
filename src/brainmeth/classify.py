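"""Sample-level diagnosis from per-read methylation percentages.

The deployed decision rule is deliberately simple.  For a hypo-methylated
assay a read "passes" when its methylation percent is <= 0.1; for a
hyper-methylated assay when it is >= 0.9.  A sample is called brain-positive
when at least 5% of its valid reads pass (all boundaries inclusive).  These
thresholds exploit the bimodal per-molecule methylation landscape: brain
molecules sit at one extreme of the distribution, everything else at the
other, so even a small brain admixture contributes a visible passing tail.

The module also provides

* a depth-limited decision tree over per-CpG binary states, trained and
  evaluated on a held-out split, with an explicit percent-threshold baseline
  — used to check whether multi-CpG *patterns* carry signal beyond the
  simple per-read percent (for exchangeable CpG states they cannot);
* a read-resampling detection-sensitivity simulation over brain fractions;
* a multi-assay consensus rule: verdicts must be unanimous, any
  positive/negative contradiction rejects the run, and positives confined to
  a single assay chemistry (only hypo or only hyper) raise a
  bisulfite-efficiency flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .readcall import ReadCall, SampleReadSet

__all__ = [
    "ClassifierConfig",
    "SampleVerdict",
    "TreeMetrics",
    "ConsensusReport",
    "passing_mask",
    "classify_sample",
    "classify_percents",
    "train_read_classifier",
    "simulate_detection",
    "consensus_verdict",
    "write_verdicts_tsv",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and evaluation parameters for sample classification."""

    hypo_read_threshold: float = 0.1
    hyper_read_threshold: float = 0.9
    min_passing_fraction: float = 0.05
    test_fraction: float = 0.2
    tree_max_depth: int = 3
    resample_reads: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.hypo_read_threshold, self.hyper_read_threshold, self.min_passing_fraction):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must be in [0, 1]")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.tree_max_depth < 1:
            raise ValueError("tree_max_depth must be >= 1")


@dataclass(frozen=True)
class SampleVerdict:
    """Per-assay classification of one sample."""

    sample_id: str
    assay_name: str
    assay_type: str  # "hypo" or "hyper"
    n_valid: int
    passing_fraction: float
    verdict: str  # "positive", "negative", "discarded"
    qc_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TreeMetrics:
    """Held-out metrics of the per-read tree vs the percent-threshold baseline."""

    precision: float
    recall: float
    f1: float
    baseline_precision: float
    baseline_recall: float
    baseline_f1: float
    tree_improves: bool


@dataclass(frozen=True)
class ConsensusReport:
    """Combined multi-assay verdict with QC flags."""

    per_assay: tuple[SampleVerdict, ...]
    overall: str  # "brain_detected", "brain_not_detected", "rejected"
    qc_flags: tuple[str, ...]


def passing_mask(
    percents: np.ndarray, assay_type: str, config: ClassifierConfig = ClassifierConfig()
) -> np.ndarray:
    """Boolean mask of reads crossing the assay's passing threshold (inclusive)."""
    percents = np.asarray(percents, dtype=float)
    if assay_type == "hypo":
        return percents <= config.hypo_read_threshold
    if assay_type == "hyper":
        return percents >= config.hyper_read_threshold
    raise ValueError(f"assay_type must be 'hypo' or 'hyper', got {assay_type!r}")


def classify_percents(
    percents: Sequence[float],
    assay_type: str,
    config: ClassifierConfig = ClassifierConfig(),
    sample_id: str = "sample",
    assay_name: str = "assay",
    discarded: bool | None = None,
) -> SampleVerdict:
    """Threshold rule on a bare vector of per-read methylation percents."""
    percents = np.asarray(percents, dtype=float)
    n = len(percents)
    if discarded is None:
        discarded = False
    if n == 0:
        return SampleVerdict(
            sample_id, assay_name, assay_type, 0, 0.0, "discarded",
            qc_flags=("no valid reads",),
        )
    frac = float(np.mean(passing_mask(percents, assay_type, config)))
    if discarded:
        verdict = "discarded"
    else:
        verdict = "positive" if frac >= config.min_passing_fraction else "negative"
    return SampleVerdict(sample_id, assay_name, assay_type, n, frac, verdict)


def classify_sample(
    read_set: SampleReadSet,
    assay_type: str,
    config: ClassifierConfig = ClassifierConfig(),
) -> SampleVerdict:
    """Classify a called sample: passing-read fraction against the 5% rule.

    A sample below the valid-read minimum is reported ``discarded`` (its
    passing fraction is still shown for QC).
    """
    return classify_percents(
        read_set.percents,
        assay_type,
        config,
        sample_id=read_set.sample_id,
        assay_name=read_set.assay_name,
        discarded=read_set.discarded,
    )


def _states_matrix(calls: Sequence[ReadCall]) -> np.ndarray:
    X = np.array([c.states.states for c in calls], dtype=int)
    if X.ndim != 2:
        raise ValueError("all calls must share the same CpG count")
    return X


def _best_threshold_classifier(
    percents: np.ndarray, y: np.ndarray
) -> tuple[float, int]:
    """F1-optimal single threshold on percent, searched on training data.

    Returns (threshold, direction); direction +1 predicts brain when
    percent >= threshold, -1 when percent <= threshold.
    """
    candidates = np.unique(percents)
    best = (0.5, 1)
    best_f1 = -1.0
    for thr in candidates:
        for direction in (1, -1):
            pred = percents >= thr if direction == 1 else percents <= thr
            f1 = f1_score(y, pred, zero_division=0)
            if f1 > best_f1:
                best_f1 = f1
                best = (float(thr), direction)
    return best


def train_read_classifier(
    calls: Sequence[ReadCall],
    labels: Sequence[int],
    config: ClassifierConfig = ClassifierConfig(),
) -> TreeMetrics:
    """Train/evaluate the per-read decision tree against the percent baseline.

    Features are the binary methylation states of each CpG; the label is
    brain (1) vs non-brain (0).  A stratified ``test_fraction`` split is held
    out at the configured seed; precision/recall/F1 are reported for the
    brain class.  The baseline is the training-F1-optimal single threshold on
    per-read methylation percent.  ``tree_improves`` is True only when the
    tree's held-out F1 beats the baseline's by more than 0.01.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("need both brain and non-brain reads to train")
    X = _states_matrix(calls)
    percents = X.mean(axis=1)

    X_tr, X_te, p_tr, p_te, y_tr, y_te = train_test_split(
        X, percents, y,
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed,
    )
    tree = DecisionTreeClassifier(
        max_depth=config.tree_max_depth, random_state=config.seed
    )
    tree.fit(X_tr, y_tr)
    pred = tree.predict(X_te)

    thr, direction = _best_threshold_classifier(p_tr, y_tr)
    base_pred = p_te >= thr if direction == 1 else p_te <= thr

    tree_f1 = f1_score(y_te, pred, zero_division=0)
    base_f1 = f1_score(y_te, base_pred, zero_division=0)
    return TreeMetrics(
        precision=float(precision_score(y_te, pred, zero_division=0)),
        recall=float(recall_score(y_te, pred, zero_division=0)),
        f1=float(tree_f1),
        baseline_precision=float(precision_score(y_te, base_pred, zero_division=0)),
        baseline_recall=float(recall_score(y_te, base_pred, zero_division=0)),
        baseline_f1=float(base_f1),
        tree_improves=bool(tree_f1 - base_f1 > 0.01),
    )


def simulate_detection(
    brain_pool: Sequence[float],
    decoy_pool: Sequence[float],
    brain_fraction: float,
    reps: int,
    assay_type: str,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int | None = None,
) -> float:
    """Detection rate under read resampling at a given brain fraction.

    Each replicate draws ``config.resample_reads`` reads with replacement,
    each taken from the brain pool with probability ``brain_fraction`` and
    from the decoy pool otherwise, then applies the sample threshold rule.
    Returns the fraction of replicates called positive.  Deterministic for a
    given seed (defaults to ``config.seed``).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 <= brain_fraction <= 1.0:
        raise ValueError("brain_fraction must be in [0, 1]")
    brain = np.asarray(brain_pool, dtype=float)
    decoy = np.asarray(decoy_pool, dtype=float)
    if brain.size == 0 or decoy.size == 0:
        raise ValueError("both pools must be non-empty")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.resample_reads
    # only the pass/fail state of each drawn read matters
    brain_pass = passing_mask(brain, assay_type, config)
    decoy_pass = passing_mask(decoy, assay_type, config)
    positives = 0
    for _ in range(reps):
        n_brain = rng.binomial(n, brain_fraction)
        k = 0
        if n_brain:
            k += int(np.sum(rng.choice(brain_pass, size=n_brain, replace=True)))
        if n - n_brain:
            k += int(np.sum(rng.choice(decoy_pass, size=n - n_brain, replace=True)))
        if k / n >= config.min_passing_fraction:
            positives += 1
    return positives / reps


def consensus_verdict(verdicts: Sequence[SampleVerdict]) -> ConsensusReport:
    """Combine per-assay verdicts; any contradiction rejects the result.

    All non-discarded assays positive -> ``brain_detected``; all negative ->
    ``brain_not_detected``; a positive/negative split -> ``rejected``.  When
    every positive comes from a single assay chemistry while the other
    chemistry was tested and negative, a bisulfite-efficiency QC flag is
    added (a conversion artifact can only fake one chemistry).
    """
    if not verdicts:
        raise ValueError("no verdicts to combine")
    flags: list[str] = []
    active = [v for v in verdicts if v.verdict != "discarded"]
    if not active:
        return ConsensusReport(
            per_assay=tuple(verdicts),
            overall="rejected",
            qc_flags=("insufficient valid reads",),
        )
    pos = [v for v in active if v.verdict == "positive"]
    neg = [v for v in active if v.verdict == "negative"]
    if len(verdicts) != len(active):
        flags.append(f"{len(verdicts) - len(active)} assay(s) discarded")

    pos_types = {v.assay_type for v in pos}
    neg_types = {v.assay_type for v in neg}
    if pos and len(pos_types) == 1 and (neg_types - pos_types):
        flags.append("possible bisulfite-efficiency artifact")

    if pos and neg:
        flags.insert(0, "contradictory assay verdicts")
        overall = "rejected"
    elif pos:
        overall = "brain_detected"
    else:
        overall = "brain_not_detected"
    return ConsensusReport(
        per_assay=tuple(verdicts), overall=overall, qc_flags=tuple(flags)
    )


def write_verdicts_tsv(verdicts: Iterable[SampleVerdict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tassay\tassay_type\tn_valid\tpassing_fraction\tverdict\tflags\n"
        )
        for v in verdicts:
            fh.write(
                f"{v.sample_id}\t{v.assay_name}\t{v.assay_type}\t{v.n_valid}"
                f"\t{v.passing_fraction:.6g}\t{v.verdict}\t{';'.join(v.qc_flags) or '.'}\n"
            )
    return path
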