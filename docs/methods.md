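# Methods

## The measurement problem

Isopycnic (CsCl) centrifugation separates DNA by buoyant density (BD).
Density increases with GC content and with heavy-isotope incorporation, so a
genome that assimilated a 13C- or 18O-labeled substrate bands slightly
heavier in the isotope treatment than in an unlabeled control. SIP
metagenomics sequences each collected density fraction and reconstructs, for
every genome, its abundance profile along the gradient. Two quantities are
derived: a per-genome atom fraction excess (AFE, the enrichment of the
genome's DNA above natural isotope abundance) and a binary incorporator
call. Both hinge on accurate per-fraction abundances, which is why the
package treats normalization, QC, estimation and calling as one workflow.

## Abundance normalization

Sequencing depth varies per fraction library, so raw coverage is not
comparable across fractions. The primary route regresses the known
concentrations of sequin internal standards against their observed coverages
within each library, then applies the fitted linear map to genome coverage:

* Sequin concentration groups whose coverage coefficient of variation
  (100·sd/mean, sample sd) exceeds 250% are dropped before fitting. The CoV
  is computed per concentration group within each library; a group where
  most sequins dropped out (zeros) fails this gate.
* The regression is OLS on untransformed coverage vs concentration by
  default (a log–log option exists, as is common in the sequin-standard
  literature). With Cook's-distance filtering enabled, points with
  D > 4/n are removed and the model refit once; a single refit keeps the
  procedure deterministic. The conventional 4/n cutoff is the default; the
  alternative literal reading n/4 is available as configuration
  (`cooks_rule="n/4"`). Robust fitting (IRLS, Huber loss) is the other
  supported method. A perfect fit (zero residual sum of squares relative to
  total) skips Cook's filtering, since influence statistics degenerate.
* Negative scaled abundances are clamped to zero: the weighted-BD estimator
  requires non-negative weights.

Alternative measures — relative coverage (per-library fractions summing
to 1), and relative coverage or length-weighted relative abundance
multiplied by the fraction's measured DNA concentration — are implemented
for method comparison; all downstream estimators accept any of them.

**Spike-in QC.** Pre-centrifugation spike-ins each band at a distinct,
predictable density. Per sample, the observed peak of each spike-in is the
density of its argmax fraction (no smoothing — the simplest deterministic
reading of "peak"); the sample passes iff the observed peak ranking matches
the expected ranking and every spike-in is detected. QC runs before
normalization in the pipeline so sequin regressions never include failed
samples, and excluding a failed sample provably leaves all other samples'
weighted BDs untouched (each W_ij depends only on its own sample's
fractions).

## AFE estimation

The qSIP model converts the weighted-BD shift into AFE through DNA molecular
weight; see the README for the equations. Implementation notes:

* W_Light and W_Lab are unweighted arithmetic means of per-replicate W_ij
  over the samples of each condition; abundance-weighted pooling is
  available as an option. A genome with zero abundance throughout a
  replicate contributes no W_ij for that replicate (rather than a spurious
  zero).
* The per-isotope natural-abundance terms are 0.01111233 (13C) and
  0.002000429 (18O). The maximum-labeling mass gain (9.974564 −
  0.4987282·G) is applied to both isotopes by default; because that offset
  derives from the 13C formulation, the constants are overridable per
  isotope (`IsotopeParams`).
* The AFE point estimate is not clamped at zero. Labeling decisions are made
  entirely by comparing the lower CI bound to a threshold (default 0).
* ΔBD divides the same shift by I_max, the maximum BD shift at 100%
  labeling. I_max depends on isotope and gradient medium and has no
  universal default; it is a required user parameter.

**Bootstrap.** Whole biological replicates are resampled with replacement,
independently within control and treatment; W means and AFE are recomputed
per draw (n_boot default 1000); intervals are percentile intervals, chosen
over BCa for determinism and simplicity. Draws in which a genome is absent
from every resampled replicate of a condition are discarded and counted;
more than 50% discards flags the estimate unstable. Percentile intervals
undercover at very small replicate numbers (with 3 + 3 replicates only a few
dozen distinct resamples exist); the suite therefore checks empirical
coverage at 8 + 8 replicates against a 0.85 floor rather than asserting
nominal 95% at n = 3.

**Multiplicity.** Bonferroni recomputes every interval at level 1 − α/m.
FCR adjustment selects the R of m genomes whose unadjusted interval lies
above the threshold and recomputes their intervals at level 1 − R·q/m.
"Interval excludes the threshold" is interpreted one-sidedly (lower bound
above threshold), matching the labeling rule used everywhere else; a
two-sided reading would also select strongly negative AFEs, which are never
called labeled.

## Incorporator identification

HR-SIP tests each genome for higher absolute abundance in a heavy window
(default from 1.71 g/mL — the theoretical band of GC-0.504 DNA is at
1.709 g/mL — to the maximum treatment density). MW-HR-SIP repeats the test
in overlapping windows (1.71–1.74, 1.72–1.75, 1.73–1.76 g/mL) and calls a
genome labeled if any window is significant after BH correction pooled
across all window × genome tests (the pooling scope is a package choice).

* The default two-group test is a one-sided Welch t-test on log1p-transformed
  *per-sample window totals*. The biological replicate is the unit of
  replication; pooling individual window fractions as observations would
  treat the shape of the density profile as replication and inflate the
  variance. The reference implementations use a negative-binomial Wald test
  (DESeq2); the test backend is pluggable (`test=callable(treat, ctrl)`) for
  users who want that. Degenerate inputs are defined: when both groups are
  constant, equality gives p = 1 and strict treatment excess gives p = 0.
* "Present" for the sparsity filter means strictly positive abundance; a
  genome must be present in more than s% of all window fractions (both
  conditions pooled). The scan covers s ∈ {0, 5, …, 30}% and keeps the
  threshold rejecting the most hypotheses (ties go to the smallest s).
* The sequential workflow runs MW-HR-SIP first, then bootstrap qSIP only on
  the stage-1 positives, with interval adjustment over m = number of
  candidates. Shrinking m tightens the adjusted intervals, which is the
  point of running the tools in series. Final calls require both stages.
* Consensus default is intersection (labeled by both methods): false
  positives of unrelated methods rarely coincide, so requiring agreement
  removes them; union is available.
* The coverage filter retains genomes whose mean over samples of total
  per-sample coverage is ≥ the threshold (inclusive boundary), and raising
  either the coverage or the minimum-AFE threshold can only shrink the
  labeled set.

Scoring uses specificity = TN/(FP+TN), sensitivity = TP/(TP+FN), balanced
accuracy = their mean. Table-style reporting rounds half away from zero.

## MAG dereplication

Given a precomputed pairwise gANI/alignment-fraction table, genomes are
clustered by single linkage with an edge iff the minimum over both
comparison orientations satisfies gANI ≥ 96.5 and AF ≥ 30 (inclusive, the
species-level convention). Representatives are chosen by highest
completeness, then lowest contamination, then greatest length — the three
criteria are standard, their order here is a fixed package choice.

## Simulator

The generator emulates the experimental design the package targets: 3
control + 3 treatment replicates, a 16-fraction gradient spanning
1.67–1.77 g/mL, sequins in concentration groups spanning three orders of
magnitude, and six spike-ins with distinct peaks.

* Each genome's DNA mass is a Gaussian over the density grid centered at
  the density its GC and AFE imply (the center inverts the qSIP equations
  exactly, so noiseless data round-trip to the configured truth).
  Gaussian weights are renormalized over the truncated grid, conserving
  mass. The genome band width `peak_sd` defaults to 0.006 g/mL, spreading a
  genome over roughly 4–6 fractions; no empirical dispersion model is
  implied.
* Mixtures of unlabeled and labeled DNA of one organism are sums of
  component Gaussians weighted by mass fraction; because band centers are
  linear in AFE, a mixture's weighted BD equals that of uniformly labeled
  DNA at the mass-weighted mean AFE, and the pipeline recovers the
  effective AFE (e.g. 40% unlabeled + 60% at 54% AFE → 32.4%).
* Coverage is mass × a per-library lognormal depth factor (σ default 0.3)
  × multiplicative lognormal noise with configurable CV (mean-1
  parameterization). Sequins respond linearly through the same per-library
  factor, which is exactly the variability sequin regression corrects.
  Sequins are dosed uniformly across fractions so each carries a single
  known concentration; wet protocols dose middle fractions more heavily to
  offset DNA-recovery differences, a step with no analog here.
* Spike-in bands use their own width (`spikein_peak_sd`, default
  0.003 g/mL) so the argmax peak call stays unambiguous at the default
  noise level. `disturb_gradient(mode="swap_adjacent")` swaps the two
  fractions carrying the peaks of two neighboring spike-ins — a
  deterministic involution that inverts their observed order, which is the
  disturbance signature the QC is designed to catch; `shuffle` permutes all
  of a sample's fractions. `dilute_coverage` converts coverage to an
  equivalent read count (coverage × genome length / 150 bp), Poisson-thins
  it, and converts back, so heavily thinned fractions drop to exactly zero.
* **Gradient window.** The collected density window must contain both the
  light and the heavy band of every genome of interest: a GC-0.7 genome at
  AFE 0.5 bands near 1.756 g/mL, inside the truncation zone of the default
  1.67–1.77 window. Exact-recovery validation therefore uses a 20-fraction
  1.66–1.78 g/mL gradient, placing all peaks at least three band widths
  inside the window; with that geometry the discretization error of the
  weighted mean is below 1e-6 in AFE.

**What the simulator does not model** — and hence what passing tests do not
show about real data: read-level artifacts (mapping bias, assembly
chimerism, GC-dependent depth), compositional coupling between genomes in a
library, gradient-shape distortions other than fraction permutations,
sequin pipetting error, or diffusion broadening differences between
genomes. Synthetic results validate the estimators' correctness and error
control under the stated noise model, not sequencing reality.

## Problem sizes in the validation suite

The bundled checks run at desk scale: the noiseless recovery grid uses 15
genomes (3 GC × 5 AFE levels); stochastic recovery averages Spearman
correlations over 20 seeded simulations of a 7-level enrichment series;
null specificity uses 20 simulations of 50-genome unlabeled communities;
dilution sensitivity uses 8 seeds per factor over {1, 0.1, 0.01, 0.001};
bootstrap checks use 200–500 draws in tests and default to 1000 in the API.

## Known limitations

* The Welch-on-totals default differs from the DESeq2-based reference
  implementations of HR-SIP/MW-HR-SIP; with few replicates the
  negative-binomial machinery can be more powerful for low-abundance
  genomes. Use the pluggable test hook if that matters.
* Percentile bootstrap intervals at 3 replicates per condition are
  optimistic; treat "labeled" calls at n = 3 as screening, or use the
  sequential workflow, which adds an independent first-stage filter.
* The printed maximum-labeling constants follow the 13C derivation; for 18O
  work, review and, if needed, override `IsotopeParams`.
* ΔBD requires a user-supplied I_max; results scale inversely with it.
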