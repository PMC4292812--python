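# Methods

`pdxmeth` quantifies how faithfully a patient-derived tumour xenograft (PDX)
preserves the DNA methylome of the patient tumour it was grown from, working
from Infinium 450K-style beta-value matrices, and simulates how group size
protects two-group comparisons from the tumour-specific methylation changes
that xenografting introduces.  This note documents the models, the defaults
and the numerical choices.

## The reversal statistic

For a (patient, xenograft) pair the per-probe difference is
Δβ = β_patient − β_xenograft, always in that order.  A probe counts as a
*reversed methylation* event when |Δβ| ≥ t, boundary inclusive.  The default
threshold derives from the empirical beta ranges of the two committed
methylation states: 95% of fully unmethylated probes have β ≤ 0.31 and fully
methylated probes have β ≥ 0.82, so the smallest difference compatible with
a true state switch is t = 0.82 − 0.31 = 0.51.  `calibrate_threshold`
recomputes both bounds from user-supplied reference distributions using
nearest-rank (type-1) quantiles — chosen because they are unambiguous on
small vectors and checkable by an explicit sort; an epsilon of 1e-9 in the
rank computation guards against float fuzz in expressions like `1 - 0.95`.
Percentages of reversing probes are always reported against the QC-retained
probe count, never the raw array size.

ΔΔβ concordance (`substitute_concordance`) compares two pairs via
|Δβ_ref| − |Δβ_test| per probe.  The summary fraction counts probes with
|ΔΔβ| below a tolerance; no canonical value for "close to zero" exists, so
the default (0.1) is an explicit, configurable choice.

## Probe quality control

Rules run in a fixed order — detection, bead counts, sex chromosomes, mouse
mask — with the first removing rule claiming each probe in the report; the
final retained set is the complement of the union and therefore
order-invariant (tested).  Conventions:

- *Detection*: a probe passes in a sample when detection p < 0.01 (strictly).
  A probe failing in **any** sample is removed.  Ties at the threshold fail.
- *Beads*: probes with fewer than 3 beads in ≥ 5% of samples are removed
  (the common array-QC reading of a "bead cutoff of 0.05"); the boundary
  counts (1 low sample of 20 removes the probe).
- *Sex chromosomes*: chrX/chrY per the annotation manifest.
- *Mouse mask*: probes with detection p < 0.01 in a single mouse-only
  sample are removed from all xenografts — cross-hybridisation to host DNA
  would otherwise contaminate the xenograft signal.  Ties at the threshold
  count as not detected in the mouse.

## Enrichment and overlap resampling

Each probe's genomic feature (TSS1500, TSS200, 5'UTR, 1st exon, body,
3'UTR, intergenic) and CpG-island relation (island, shore, shelf, open sea)
combine into one category.  Enrichment of a target set draws |target|
probes uniformly without replacement from the universe per repetition
(default 1,000); this is sampled exactly as a multivariate hypergeometric
draw over category counts, which is equivalent and much faster than
materialising probe sets.  Two-sided empirical p-values double the smaller
tail count, cap at n_reps and apply the add-one estimator
(r + 1)/(n_reps + 1), so p is never zero and the floor is 1/(n_reps + 1).
Probes without annotation are excluded from both target and universe with a
logged count.

Overlap significance redraws every set uniformly from the universe with its
size preserved and counts repetitions whose full intersection is at least
the observed one.  Because the redrawn sets are independent and uniform,
the running intersection after each set is hypergeometric given the
previous one; the null is sampled through that chain without materialising
sets.  Overlap percentages use the smallest set as the denominator for every
pairwise and full-intersection figure, matching how overlaps between sibling
PDXs of one tumour are usually quoted.

## Xenograft read classification

A read pair is *aligned* to a genome when both mates map, are flagged
properly paired, and are neither duplicates nor secondary/supplementary
records (`--mate-mode any` relaxes this to one mapped mate).  Pairs flagged
duplicate in either genome are excluded before classification; duplicate
flags are trusted from the aligner rather than recomputed.  The keep rule:
human-only and human+mouse pairs are kept; mouse-only pairs (host
contamination) and pairs aligning to neither genome are discarded — the
latter contribute nothing downstream, and the rule is stated as a set
identity (kept = all − mouse_only − neither) and tested as such.
`keepset_concordance` reports Jaccard and containment fractions between two
kept sets, e.g. against a k-mer classifier's output.

## Synthetic methylome generator

The generator is the package's stand-in for real 450K cohorts and defines
the conditions under which everything is tested.  What it emulates:

- **Bimodality with feature dependence.** Each probe draws a latent state
  (unmethylated / intermediate / methylated) from a mixture whose weights
  depend on its combined category: island promoters (0.94, 0.04, 0.02),
  island non-promoters (0.75, 0.13, 0.12), shores (0.45, 0.25, 0.30),
  shelves (0.15, 0.15, 0.70), open-sea promoters (0.25, 0.20, 0.55),
  open-sea bodies/intergenic (0.06, 0.10, 0.84).  Probe-level mean betas
  come from Beta(1.5, 20), Beta(3, 3) and Beta(20, 1.5) respectively.
  These weights are chosen so that island promoters are ≥ 90% unmethylated
  and the per-sample fraction of intermediate betas (0.2–0.8) stays below
  0.35, the qualitative shape of real 450K data.
- **Per-sample noise** is Gaussian on the logit scale (default sd 0.5,
  roughly ±0.12 beta at mid-range), applied to the probe mean and mapped
  back through the inverse logit — values stay strictly inside (0, 1) with
  no clipping artifacts.  The default is meant to represent a
  mixed-tissue reference pool, where cross-sample variability is larger
  than within a tissue.
- **Planted pairs.** A xenograft derives from its patient by shifting
  round(0.027 × n_probes) probes by at least 0.51, directions chosen only
  where the full magnitude fits inside [0, 1] (feasible-direction
  selection, not post-hoc clipping, so every planted change genuinely
  meets the magnitude contract).  Unplanted probes are copied unchanged,
  which makes the planted set exactly recoverable by thresholding —
  the ground-truth property the fidelity tests rely on.  Sibling PDXs
  share a configurable fraction (default 0.86) of the first sibling's
  planted probes.
- **Mouse QC vector**: exactly round(frac × n) probes get detection
  p < 0.01.  **Read fixtures**: multinomial class draws written as paired
  SAM files that round-trip through ingestion.

What it does **not** emulate: probe type I/II chemistry differences,
spatial/batch effects, realistic tissue composition of public repositories,
or correlated methylation along the genome.  Passing tests therefore
demonstrate the correctness of the statistics under the stated generative
model, not their behaviour on any particular clinical cohort.

Determinism: one master seed expands into per-component child streams via
`numpy.random.SeedSequence` spawn keys (`pdxmeth._seeds`), so every
generator and resampling routine is a pure function of (parameters, seed)
and adding a consumer never shifts another component's stream.

## Group-size simulation

The design question: when comparing two groups of PDXs probe-by-probe, how
many samples per group make the tumour-specific xenografting changes
negligible?  Per repetition, n methylomes are drawn without replacement
from a pool of 2,000; each sample independently shifts 11,110 of its
463,558 beta values by 0.51 (5,555 up, 5,555 down) at probes chosen
uniformly at random — independence across samples reflects the tumour
specificity of the changes; a shared target set would make the perturbed
probes trivially significant at moderate n.  Every probe is then tested
original-group vs modified-group with a two-sided Wilcoxon rank-sum test
and counted when p ≤ 0.05 (non-adjusted).  The grid is n = 5…50 with five
repetitions per n; the curve reports means and standard errors.

Numerical choices:

- The pool is virtual: probe-level means are drawn once and sample columns
  materialise on demand as pure functions of (seed, column index), so the
  nominal 463,558 × 2,000 pool costs only the columns actually drawn.
- Per-probe tests use a vectorised tie-corrected normal approximation with
  continuity correction (identical to the scalar asymptotic formula, which
  tests cross-check against scipy and against exhaustive enumeration).
  Ties are structural here: unperturbed samples contribute identical
  values to both groups.
- Probes perturbed in **no** sample are skipped (their groups are
  identical; p = 1 exactly).  Probes perturbed in exactly **one** sample
  are also skipped when α ≤ 0.1: with a single displaced value the
  rank-sum deviation is bounded by n − 1/2 while the tie-corrected
  standard deviation never falls below n/2 (the largest possible tie block
  is 2n − 1), and an adversarial sweep over tie patterns puts the minimum
  attainable p near 0.21.  The skip is a pure optimisation, guarded by a
  config flag and verified against the unskipped computation in tests.
- Up-shifts are only planted where β ≤ 0.49 and down-shifts where
  β ≥ 0.51, so all values stay in [0, 1] at full magnitude; a `clip` mode
  exists for sensitivity analysis.

At full scale the default grid runs in about six minutes on one CPU.  The
test suite exercises a 50,000-probe pool with the perturbed fraction held
fixed and counts rescaled by the probe ratio, which preserves the per-probe
perturbation process exactly and keeps the suite fast.

## Known limitations

- The reversal threshold treats all probes identically; real type I/II
  probes differ in dynamic range.
- The enrichment null conditions only on set size, not on probe-level
  covariates (e.g. probe density per gene).
- The simulation's significant-probe counts depend on the pool's
  cross-sample variability; the synthetic default represents a
  heterogeneous multi-tissue pool, and cohorts with tighter within-group
  variance would show somewhat different absolute counts (the qualitative
  decline with n is structural).
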