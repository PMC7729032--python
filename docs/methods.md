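# Methods

## The measurement and the estimator

Bottom-up HDX-MS follows the exchange of backbone amide hydrogens with
solvent deuterium. A protein is diluted into D₂O buffer, quenched after a
labelling time *t*, digested into overlapping peptides, and each peptide's
centroid mass is read out per replicate. Two controls anchor the scale: the
undeuterated sample (mass *M*<sub>ex0</sub>) and a 24 h out-exchange control
driven to completion (mass *M*<sub>ex100</sub>). The deuterated fraction of
a labelled observation *M*<sub>ex</sub> is

  D = (M<sub>ex</sub> − M<sub>ex0</sub>) / (M<sub>ex100</sub> − M<sub>ex0</sub>).

Deuterium lost back to protiated solvent during quench, digestion and
chromatography (back-exchange) attenuates the labelled sample and the
out-exchange control by the same multiplicative factor, so it cancels in the
ratio: D is an unbiased estimate of the true exchanged fraction. This is the
entire reason for using an experimental 100% control rather than the
theoretical maximum uptake, and the package treats it as an invariant worth
testing: on noise-free synthetic data the estimated D is identical to 1e-9
across back-exchange levels 0.6–1.0.

Controls are averaged over replicates **and over states**. The undeuterated
mass of a peptide does not depend on the binding state, and the 24 h control
exchanges even complexed regions to completion, so pooling is physically
sound. It also matters statistically: the pooled control masses enter both
states' D values as the same affine constants, so control noise cancels
exactly in the state-vs-state difference and the Welch test below sees only
genuine replicate variation. Per-state controls would shift all replicates
of a state coherently and inflate the false-positive rate beyond what the
test models.

D is never clamped to [0, 1]. Values outside [−0.05, 1.05] are flagged
(`out_of_range`), not altered — truncation would bias the differential test.
A peptide whose controls are separated by less than half a deuterium mass
(0.5 × 1.00627675 Da) is rejected as uninformative rather than divided
through by a near-zero denominator.

## Differential comparison

For each peptide and exposure shared by two states:

- ΔD = D<sub>state</sub> − D<sub>control</sub>, with the complex as the
  first argument so protection appears as ΔD < 0;
- propagated error se = √(sd<sub>a</sub>² + sd<sub>b</sub>²), the square
  root of the sum of the per-state variances (sample sd, n−1 denominator);
- a two-sided Welch t-test from the summary statistics, with
  Welch–Satterthwaite degrees of freedom. Degenerate zero-variance pairs are
  resolved by convention (equal means → p = 1; unequal → p = 0, flagged by
  an infinite t).

No multiple-testing correction is applied by default — per-peptide raw
p < 0.05 is the customary criterion in interaction footprinting, where
spatial clustering of significant peptides, not any single p-value, carries
the conclusion. Benjamini–Hochberg FDR is available (`correction="bh"`) for
users who want a genome-style error rate. The test is two-sided because
deprotection (allosteric loosening) must be detectable, and no extra
magnitude threshold is imposed (`min_abs_delta` defaults to 0).

A caveat the test suite quantifies rather than hides: with n = 3 replicates
per state the Welch test is conservative. Its true size at the nominal 0.05
level is ≈ 0.036 (the Satterthwaite degrees-of-freedom approximation
under-rejects in tiny samples; an independent reference implementation gives
the same number). The null-calibration test therefore checks the empirical
rejection rate against the band [0.03, 0.07] and checks *exact* agreement
with the reference implementation, which is the sharper statement about
correctness. Two-replicate data are accepted — common in this experiment
type — but trigger a warning, since df ≈ 2 leaves the test with little
power.

## Region calling

Peptide-level significance is consolidated onto residues. A significant
peptide supports the residues it actually reports on: its first residue
(whose amide back-exchanges too fast to observe) and its prolines (no amide
hydrogen) are excluded; the same convention defines the exchangeable-amide
count N = L − 1 − #prolines(2..L) used everywhere in the package. Maximal
runs of residues with at least `min_support` distinct significant peptides
in one direction, significant at at least `min_exposures` labelling times,
become regions; runs separated by at most `merge_gap` unsupported residues
merge. Defaults (1 / 1 / 2) are deliberately permissive — the run of
overlapping significant bars in a difference plot is usually obvious to the
eye, and the knobs let the analyst demand more.

Two properties govern interpretation:

- **Boundary resolution is peptide-limited.** A called region can overhang
  the true interface by up to the span of the longest overlapping peptide;
  nothing finer can be claimed without residue-level deconvolution, which
  this package deliberately does not attempt.
- **False-positive peptides cluster.** At α = 0.05 uncorrected, a few
  percent of null peptide-exposure pairs are significant by construction;
  with redundant peptide maps these occasionally overlap and produce short
  spurious support-2 regions. Requiring reproducibility across two labelling
  times (`min_exposures=2`) suppresses most of this, and the validation
  suite uses exactly that setting for recovery studies. Users should treat
  short, single-exposure regions with suspicion.

When the analysed construct is a fragment of a larger protein, a residue
offset maps local coordinates into parent numbering at the reporting stage
only (a 69-residue construct with offset 320 reports regions as aa325–336,
etc.); the data table stays in construct coordinates so sequence validation
against the construct FASTA still holds.

## The simulator

The generator exists to make every stage falsifiable against known truth,
reproducing the statistical structure of a two-state footprinting
experiment, not the physics of any particular protein.

- **Kinetics.** Per-residue single-exponential Linderstrøm-Lang exchange in
  the EX2 limit: residue *i* with protection factor P<sub>i</sub> ≥ 1 and
  intrinsic rate k<sub>int</sub> has exchanged 1 − exp(−k<sub>int</sub>·t /
  P<sub>i</sub>) after time *t*; a peptide's true uptake is the mean over
  its observable amides. k<sub>int</sub> is a single configurable constant
  (default 1 s⁻¹) for all residues — the analysis is agnostic to
  sequence-dependent intrinsic rates, so modelling them would add
  realism but no test power. With P = 1 and k<sub>int</sub>t ≥ 20 a residue
  is fully exchanged to within 1e-8, which reproduces the hallmark of
  disordered regions: complete exchange at the shortest (10 s) time point.
- **States and footprints.** Each state is a protection-factor profile: a
  baseline (default 1) times multiplicative footprint factors over residue
  intervals. A complex-only footprint with factor 20 emulates an interaction
  interface; the ground-truth object records the planted intervals and
  direction so recovery can be scored.
- **Measurement model.** Centroid mass = monoisotopic peptide mass (via
  pyteomics) + back_exchange × uptake × N<sub>amides</sub> × 1.00627675 Da +
  Gaussian(0, noise_sd). Defaults: back-exchange 0.7 (typical mid-range
  retention), noise_sd 0.05 Da (consistent with replicate scatter of
  peptide-level HDX error bars), 3 replicates, exposures 10/60/300 s plus
  undeuterated (exposure 0) and 24 h out-exchange (exposure −1 sentinel)
  controls per state.
- **Digestion.** Generative, not enzymatic: Gaussian window lengths (mean
  10, sd 2.5) with starts stratified along the sequence to hit a per-residue
  redundancy target (default 3), first window anchored at residue 1 and last
  at the C-terminus. This yields ≥ 95% coverage at redundancy ≥ 3 and
  redundancy within 20% of target, matching real pepsin maps statistically
  without modelling cleavage specificity.
- **Determinism.** All randomness flows from one integer seed through
  spawned generator streams; a fixed seed reproduces the dataset
  byte-identically.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: EX1 bimodality, isotopic envelope shape and
charge-state effects, sequence-dependent intrinsic rates, retention-time or
drift-time artefacts, carry-over, and non-uniform back-exchange across
peptides. Conclusions about those failure modes need real instrument data.

## Fixtures and validation studies

Three embedded templates mirror the canonical situations: a disordered
protein with one rigid segment (186–220, protection factor 10⁴ — at 10 s the
disordered part is ≥ 99% exchanged, the rigid part ≤ 5%); a 472-residue
two-state experiment with a 20× footprint at 385–410; and a 69-residue
fragment (offset 320) with two nearby footprints at parent coordinates
325–336 and 380–389. Sequences are random with fixed seeds and ~5% proline.

The validation suite runs the full pipeline over 20 reseeded replicates of
the footprint fixtures: the planted 385–410 interface is recovered with
Jaccard ≥ 0.5 in ≥ 18/20 seeds with boundaries within the peptide-limited
bound, and the two fragment footprints resolve as exactly two regions in
≥ 18/20 seeds. Problem sizes (proteins of 69–472 residues, a ~3,300-peptide
null study for calibration) were chosen so the entire suite runs in seconds
on a laptop while keeping Monte-Carlo intervals tight enough to be
meaningful.

## Numerical choices

- Δm(D−H) = 1.00627675 Da; proton mass 1.00728 Da for m/z → neutral mass.
- Sample sd uses the n−1 denominator throughout (unbiased variance, as the
  Welch test assumes).
- Welch df computed in double precision; p = 2·SF(|t|, df) from the t
  distribution.
- Region runs are found on integer support arrays; ties and adjacency are
  exact, no floating-point tolerances involved.
- CSV masses are written at full repr precision so write→read round trips
  are exact.
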