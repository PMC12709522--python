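# Methods

This note documents the models, parameters and numerical choices behind
`brainmeth`, and what the synthetic data does and does not establish.

## Position scoring and region selection

Each compendium position carries a hypo score, a hyper score, and their
maximum (informativeness), all ≤ 0. The score is the negated weighted mean
of a penalty applied to every sample's deviation from the ideal contrast
(brain fully unmethylated and decoys fully methylated for hypo, mirrored for
hyper):

    L(d) = d + A·[σ(k(d − c)) − σ(−kc)],  d ∈ [0, 1].

The subtraction of σ(−kc) anchors L(0) = 0, so the ideal position scores
exactly 0 and the score can never be positive; the logistic term makes a
single sample on the wrong side of the midpoint *c* cost close to the full
amplitude *A*, while diffuse moderate noise costs roughly its linear
distance. The published description of the scoring constrains its shape (a
weighted distance with a ceiling of 0 and logistic penalization of major
exceptions) but not its algebra; this closed form is this package's
declared formulation satisfying those properties, with A, k, c, and the
group weights configurable (defaults 4, 15, 0.5, 1, 1).

Region selection admits CpGs with informativeness above `score_floor`
(default −2, where the genome-wide score distribution has thinned to a few
parts in 10⁵) and forms maximal runs of consecutive qualifying CpGs with
≥ `min_cpg` (5) members whose first-to-last span is ≤ `max_span_bp` (300).
Region rank is

    mean(top ⌈n/2⌉ informativeness values) + γ·log₂(n / min_cpg),

an additive count bonus (γ = 0.5) that keeps region scores on the
informativeness scale while rewarding CpG-dense regions; the two-ingredient
ranking (count and best-half mean) is as published, the combination rule is
this package's. Overlapping candidates are resolved greedily best-first
(ties: more CpGs, then leftmost); correctness of the window search is
checked against exhaustive enumeration in the test suite. Missing decoy
values at a position are excluded from the mean; positions with no decoy
values are skipped with a warning.

Degenerate inputs: strand-split CpG records can be collapsed onto the
plus-strand cytosine (coverage-weighted mean when coverages are present);
compendium retention requires presence in every brain sample and in ≥ 80%
of decoy samples by default, a policy choice the upstream data do not pin
down.

## Amplicon model and read calling

Assays are modelled on the bisulfite top strand. The converted reference
replaces every non-CpG C with T and every CpG C with the wildcard Y, so
alignment is conversion-agnostic at methylation-informative positions.
Adapter overhangs are stored but never matched; reads are expected
adapter-trimmed.

The filter cascade has a fixed order — forward primer (exact IUPAC match),
pair merge, CpG coverage, alignment identity, CpG dinucleotide state — so
every read has exactly one rejection reason and shuffling input order
changes no counts. Pair merging scans ungapped overlaps from longest to
shortest (minimum 20 bp, agreement ≥ 0.9, best agreement wins with longer
preferred on ties) and resolves disagreements by base quality, then R1.
Alignment is global with affine gaps (match +1, mismatch −1, open −2,
extend −1) via Biopython's PairwiseAligner over an ACGTNY alphabet in which
Y matches C and T at full score. Identity excludes Y columns from both
numerator and denominator and counts gap columns as mismatches; the bound
is strict (> 0.85). As a numerical shortcut, an equal-length gapless
comparison that already clears the bound short-circuits the aligner; reads
that fail it fall through to the full alignment, so the shortcut can only
affect which of two passing alignments supplies the (identical) CpG map.

CpG states are read as CG = methylated, TG = unmethylated on the read
strand — the dinucleotides bisulfite chemistry actually produces, since the
G of a CpG is untouched by conversion. `CallerConfig(literal_ct_mode=True)`
switches to a literal CG/CT reading for comparison. Anything else at a CpG
invalidates the read. Samples with fewer than 100 valid reads are
discarded (100 exactly is kept).

## Sample classification

A read passes at methylation percent ≤ 0.1 (hypo) or ≥ 0.9 (hyper); a
sample is positive at passing fraction ≥ 5%. All three boundaries are
inclusive. The read-resampling sensitivity simulation draws each of
`resample_reads` reads from the brain pool with probability *f* (else the
decoy pool), classifies the resampled sample, and reports the positive
fraction over replicates; it is seeded and reproducible.

The decision-tree evaluation (depth ≤ 3, stratified 20% held-out split at a
fixed seed) reports brain-class precision and recall, compared against an
explicit baseline: the single percent threshold (direction and cut chosen
on the training split to maximize F1). The tree is credited with an
improvement only beyond 0.01 held-out F1. For exchangeable per-CpG states
the Bayes rule is a function of the percent alone, so the tree cannot beat
the baseline beyond noise — the test suite checks exactly this, mirroring
the finding that pattern structure adds nothing over per-read percent.

Consensus over assays requires unanimity among non-discarded verdicts; any
positive/negative split is rejected outright. Positives confined to one
chemistry while the other chemistry tested negative add a
bisulfite-efficiency QC flag, because aberrant conversion can inflate only
one assay type.

## Synthetic data: what it emulates, and what it does not

**Reads.** A tissue is a mixture of archetypes; each archetype is an
independent-Bernoulli vector of per-CpG methylation probabilities. Defaults
reproduce the qualitative bimodal per-read distributions of real brain
panels: brain = 90% brain-archetype molecules (per-CpG 0.03 for hypo
assays) + 10% background (0.9); decoys = background only; hyper assays
mirrored. These weights are declared generator conditions, not measured
tissue parameters. The noise model has conversion efficiency 0.99 (a
typical kit specification), inappropriate conversion 0.005, substitution
error 0.002/base (MiSeq scale), constant Phred 35. Non-CpG cytosines are
modelled as fully unmethylated, so conversion failures surface as non-CpG
C's — precisely what the identity filter must tolerate at rate 1 − η.
Degradation reduces depth (default ×0.3), truncates molecules below CpG
coverage (p = 0.2, cut to 60 bp), and triples substitution error.

The generator does not model PCR duplicates or chimeras, realistic quality
profiles, indel sequencing error, non-CpG methylation, or within-archetype
CpG correlation. Passing tests therefore demonstrate the pipeline's logic
and statistics under its stated assumptions, not performance on real
libraries.

**Compendia.** Positions are spaced 20–60 bp apart; each draws one
background mean from Beta(0.4, 0.4) shared by both groups (methylation
outside differentially methylated regions is largely tissue-shared), and
samples jitter around it with concentration κ = 50. Planted regions
override the means (e.g. brain 0.02 / decoy 0.95 for hypo). The shared
background is a deliberate design choice: with independent per-group means,
chance contrasts qualify a third of background positions and spurious
regions abound, which contradicts how genuinely tissue-shared methylomes
behave; `shared_background=False` restores fully independent groups for
stress testing. Gaps between planted member CpGs are drawn from a tightened
range (≤ 35 bp) so every planted region satisfies the ≥ 5-CpGs-in-300-bp
admission rule by construction.

## Detection sensitivity at the 5% boundary

With the default generator and default thresholds, the expected passing
fraction of a sample with brain fraction *f* is *f·r_b + (1 − f)·r_d*,
where the brain-pool passing rate is bounded by
r_b = 0.9 · P(Bin(k, 0.03) ≤ ⌊0.1·k⌋) < 0.9 for every CpG count k (≈ 0.87
at k = 10) and r_d ≈ 0. At *f* = 0.05 the expected passing fraction is
therefore ≈ 0.043 — strictly below the 0.05 positivity threshold, by ~23
binomial standard deviations at 10⁴ reads — so detection at exactly 5%
brain content fails under these generator conditions even though it
succeeds from *f* = 0.10 upward (and at *f* = 0 the false-positive rate is
0). This is a property of the declared synthetic conditions, not of the
method: a sample whose brain molecules pass at rate ~1 (or a threshold
calibrated to the measured brain passing rate) detects 5% admixtures
reliably. The corresponding test is left asserting the idealized claim and
documents the failure at the 0.05 point; no generator parameter or
threshold was adjusted to mask it.

## Problem sizes

Default test and demonstration scales: 10⁴ reads per simulated sample,
5 × 10³-read percent pools, 50 resampling replicates per brain fraction,
compendia of 200–500 positions × 12 samples, 40 recovery replicates for
planted-region discovery. These desk scales keep the full suite around ten
seconds while leaving every statistical check with comfortable margins
(binomial standard errors an order of magnitude below the asserted
tolerances).

## Known limitations

* Bottom-strand amplicon chemistry is out of scope; assays are modelled on
  the top strand selected by the forward primer.
* The per-read identity denominator counts gap columns as mismatches;
  tools that ignore terminal gaps will report slightly higher identities
  for truncated reads (such reads fail CpG coverage here anyway).
* Genome-scale discovery (~7.5 × 10⁷ positions) is not performance-tuned;
  the scoring is vectorized but the compendium is held in memory, targeting
  desk-scale inputs.
* Published panel coordinates are stored as printed; for several loci the
  coordinate span exceeds the reported amplicon length (primers included in
  coordinates, presumably), and only the two externally sourced loci
  (n11, n12) are internally consistent — these are the ones asserted in
  tests.
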