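# Methods

## The measurement principle

During transient co-expression of Cas9 and a guide RNA in plant tissue, each
target locus is in one of three states: intact wild-type (cuttable), intact
but mutated (repaired with an indel; no longer recognised by the guide) or
broken (an unrepaired double-strand break). A qPCR amplicon that spans the
predicted cut site amplifies the first two pools but not the third, so the
broken fraction is observable as an amplification delay relative to
untreated wild-type tissue.

With test (edited) and control (wild-type) samples, each measured at the
target amplicon and at an internal single-copy reference amplicon, the
double difference

    ΔΔCt = (Ct_T − Ct_T,ref) − (Ct_C − Ct_C,ref)

cancels template loading and assay-specific offsets. At perfect per-cycle
amplification efficiency the intact (amplifiable) fraction is 2^−ΔΔCt and
the broken fraction 1 − 2^−ΔΔCt. Because the amount of breakage depends on
how much Cas9 a given transformation delivered, the cutting efficiency of a
*site* is defined as the broken-DNA abundance divided by the Cas9 transcript
abundance 2^−(Ct_Cas − Ct_ref), measured on cDNA from the same tissue.
Efficiencies are then fold-normalised so the weakest site reads 1, which is
how multi-site comparisons are conventionally displayed.

### The two broken-DNA conventions

The raw relative-quantification quantity 2^−ΔΔCt *falls* as cutting rises;
treating it directly as "broken-DNA abundance" inverts the ranking of
strongly and weakly cut sites. The package therefore exposes both
conventions and makes the self-consistent one the default:

* `canonical` — broken = 1 − 2^−ΔΔCt. Consistent with the in vitro
  estimator below and with the anchor that ΔΔCt = 2 corresponds to 75%
  broken DNA.
* `literal` — the raw 2^−ΔΔCt fold-change itself, for users who want the
  untransformed relative abundance.

The CLI reports both, labelled by a `mode` column.

### The in vitro assay

Digesting a purified amplicon with recombinant Cas9/gRNA and re-amplifying
a cut-site-spanning region against a reference region on the same product
gives efficiency = 1 − 2^−(Ct_a − Ct_ref) — the identical closed form as
the canonical in vivo estimator, which is the internal-consistency property
the tests assert (`in_vitro_efficiency(x+d, x)` equals the canonical broken
fraction at ΔΔCt = d for all d).

## Replicate handling and statistics

The estimators are defined on single Ct values; an experiment carries
biological replicates. One efficiency is computed per test replicate.
Pairing against the control group is an open design choice, so both options
are provided:

* `mean_control` (default) — each test replicate is compared with the
  control-group *mean* Ct. Controls are untreated wild-type plants with no
  natural one-to-one pairing to test plants, so this is the default.
* `per_replicate` — index-matched pairing, for designs where control
  replicates were processed in parallel batches with test replicates.

Per target the package reports the mean ΔΔCt (and its implied
intact/broken fractions — this Ct-mean route is unbiased under symmetric Ct
noise), the mean and SD of the per-replicate efficiencies (the quantity
fold-normalisation acts on), and n. Condition groups (e.g. a heat-treated
vs an untreated batch) are compared with a two-sided, equal-variance
Student's t-test on per-replicate efficiencies at α = 0.05, with no
multiple-testing correction; zero-variance degenerate inputs resolve to
t = 0, p = 1 when the means agree.

Noise can push a weak target's mean efficiency to or below zero.
Fold-normalisation requires positivity, so non-positive means are clamped
to a floor (default 1e−6) and flagged rather than discarded (discarding
would bias the survivors upward). If *every* target is flagged the
experiment has no usable signal and a `NormalizationError` is raised with
the partial results attached.

## Target-site scanning

SpCas9 requires an NGG protospacer-adjacent motif and cuts bluntly 3 bp
5′ of it. The scanner reports every position on the requested strands where
the strand-local context reads `[spacer_len bases][PAM]` (default spacer
length 20 nt, PAM pattern NGG, IUPAC codes accepted in the pattern).
Conventions:

* 0-based coordinates, half-open intervals; `cut_pos` is an inter-base
  index on the forward strand (a cut between bases i−1 and i is `i`), so
  "does an amplicon span the cut" is a strict-interior test with no
  boundary ambiguity — an amplicon ending exactly at the cut does not span
  it and can serve as a reference amplicon.
* N is accepted in input sequences but never in a reported spacer or PAM
  (qPCR primers cannot target ambiguous bases); such sites are skipped with
  a warning.
* Overlapping sites are all reported; downstream filtering is the user's
  choice.

A target-spanning quantification amplicon is valid when it both straddles
the cut and contains the whole spacer (so repaired-but-mutated template is
still counted as amplifiable); a reference amplicon is valid when it avoids
the cut.

Because no public per-site sequence set accompanies the assay,
`synthetic_site_fixture` builds test sequences with an exactly known site
content: backgrounds and spacers are drawn from {A, T} and PAMs are TGG, so
GG occurs only inside planted PAMs and CC never occurs — the planted
forward-strand sites are provably the only sites present.

## The simulator

### Cut/repair kinetics

Population fractions follow a linear three-state system:

    d f_wt/dt     = −k f_wt + ρ (1 − μ) f_broken
    d f_broken/dt =  k f_wt − ρ f_broken
    d f_mut/dt    =  ρ μ f_broken

with effective cutting rate k = k_cut × delivery_scale, repair rate ρ and
per-repair mutation probability μ. Error-free repair recycles template into
the cuttable pool; mutated repair is absorbing (a mutated protospacer is
not re-cut). Integration is deterministic fixed-step RK4 from (1, 0, 0),
with a stability guard (step ≤ 1/(k + ρ)) and conservation of the pool sum
enforced to 1e−8 per step. Deterministic population ODEs rather than
per-molecule stochastic simulation: qPCR observes population fractions, and
desk-scale tests need bit-reproducibility. Closed-form oracles used in
tests: with μ = 0 the system is two-state with steady state
f_broken → k/(k+ρ); with μ = 1 and ρ ≫ k the mutant pool absorbs
everything.

Defaults — k_cut 0.1/h, ρ 0.2/h, μ 0.3, t_end 48 h (the harvest time after
transformation), cas9_level 1, delivery_scale 1 — keep f_broken in the
experimentally observable range. They are model settings chosen for that
purpose, not measured constants; all are configurable.

A consequence worth knowing: with μ > 0, a larger cutting rate raises
f_broken only up to a crossing time (≈ 34 h for k 0.1→0.3 at the defaults),
beyond which the heavier-cutting population has already converted more
template to the mutant pool and carries *less* broken DNA. Strict
monotonicity of f_broken in k at every t holds exactly only for μ = 0; at
the 48-h harvest it holds for sub-saturating rates (k·μ·t ≪ 1). The test
suite asserts both the exact two-state property and the saturation
crossing.

### qPCR readout

A state is converted to a long-format Ct table with one row per well. The
cut-spanning amplicon sees amplifiable template q = f_wt + f_mut, so the
test-group target well sits −log(q)/log(1+E) cycles above the control
baseline, where E ∈ (0, 1] is the per-cycle amplification efficiency
(default 1; the estimators themselves always assume E = 1, matching their
base-2 closed forms — a deliberately modelled mismatch when E < 1).
Reference wells and control-group wells sit at the baseline; the Cas9
transcript well sits log(cas9_level × delivery_scale)/log(1+E) cycles below
its reference, which is how a delivery-boosting treatment (sonication)
raises both observed broken DNA and observed Cas9 while leaving the
normalised efficiency invariant. Independent Gaussian noise (default
SD 0.2 cycles — a typical replicate-level qPCR spread) is added to every
well from a single seeded generator, so identical configurations give
byte-identical tables.

`simulate_experiment` is a shortcut that plants true broken fractions
directly (state (1−f, 0, f)); noiseless canonical quantification of its
output returns the planted fractions to machine precision, which is the
end-to-end oracle for the estimator chain.

### What the simulator does and does not emulate

It emulates the measurement chain (three-pool template competition,
log-linear qPCR response, well-level Gaussian Ct noise, delivery scaling).
It does not emulate per-assay amplification-efficiency differences between
target and reference amplicons, pipetting/batch covariance between wells of
one sample, indel spectra or primer-binding disruption by mutations (the
mutant pool amplifies normally), cell-to-cell delivery heterogeneity, or
Cas9 expression dynamics (the transcript level is constant over the
window). Passing parameter-recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not robustness
to every real-world artefact.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale designs: 1–5 targets, 3 replicates
for experiment-level checks, 200 replicates for parameter-recovery checks
(recovering true broken fractions 0.1–0.75 within 0.02 at 0.2-cycle well
noise), kinetics over 48–300 h at step 0.05 h. The sonication-invariance
check at the kinetics level uses k_cut = 0.01/h over 24 h — the
sub-saturating regime in which broken DNA is proportional to delivered
activity and the efficiency ratio stays within ~10% of 1 while broken DNA
and Cas9 both rise; at the estimator level the invariance is exact and is
asserted to machine precision.

## Known limitations

* The in vivo estimator reads *standing* breakage; it cannot separate a
  fast cut-and-repair equilibrium from slow cutting with slow repair, and
  it does not measure editing (mutation) outcomes.
* Negative broken fractions from noise are statistically informative but
  physically impossible; they are retained for statistics and clamped only
  for fold-normalisation. With very weak targets and few replicates the
  normalised fold-range is right-skewed and seed-sensitive.
* Fold-normalisation to the weakest target propagates that target's
  (largest relative) error into every reported fold value.
* The amplification-efficiency parameter E applies per experiment, not per
  assay; assay-specific E differences would bias ΔΔCt in ways the package
  does not model.
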