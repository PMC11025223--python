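# Methods

This note records the models behind molclass, the defaults that matter, and
the choices made where the design was genuinely open. Units throughout:
concentrations in nM (panel concentrations in pM where stated), time in s,
bimolecular rate constants in nM⁻¹s⁻¹.

## Mass-action simulator (`molclass.crn`)

Networks are lists of elementary reactions of order 1–3; the simulator
integrates d[s]/dt = Σ_r ν_{s,r}·k_r·Π_reactants[·] with SciPy's BDF method
(rtol 1e-8, atol 1e-10). Steady state is declared when max|d[s]/dt| falls
below 1e-6 nM/s at the horizon; because every quantity of interest here is
a t→∞ limit, the horizon auto-doubles up to 8× when that test fails.
Solver undershoot below zero is clipped (observed magnitude ≲1e-9 nM) and a
clip larger than 1e-6 nM raises a warning. Declared conservation laws can
be audited over any trace (`check_conservation`). The default bimolecular
constant, 1e-4 nM⁻¹s⁻¹ (~1e5 M⁻¹s⁻¹), is typical of toehold-mediated
strand displacement; absolute rates only set the time scale — mass action
is invariant under (k, t) → (2k, t/2), a symmetry the test suite checks.
Stochastic simulation, spatial effects and temperature dependence are out
of scope.

## Competitive-inhibition weighting (`molclass.compiler`)

The weight unit

    Input + Amplifier → Input + Output   (k)
    Input + Inhibitor → Waste            (k)

has an exact endpoint: d(ln A)/dt = d(ln Z)/dt (A amplifier, Z inhibitor)
forces A∞/A₀ = Z∞/Z₀, and the inhibitor consumes the input 1:1, so for
Input₀ ≤ Inhibitor₀ the output converges to Input₀·Amplifier₀/Inhibitor₀.
The compiler's ideal mapping is therefore Inhibitor₀ = Amplifier₀/|W|
(amplifier default 100 nM). A user-supplied calibration table
(|W| → Inhibitor₀) can override the mapping to mimic bench-calibrated
pairs, but is never defaulted: published experimental pairs are
internally inconsistent between figures and reflect instrument
calibration, not the model. Beyond the linear regime
(Input₀ > Inhibitor₀) the inhibitor exhausts and the output runs toward
the amplifier ceiling; the compiler warns when an input can approach 80%
of its inhibitor. The entropy-driven amplifier is modeled as this single
effective catalytic step, not at intermediate-complex resolution.

Weights and bias are stored in the classifier's *input space* (nM), the
space the training module exports to, so the molecular HEX−ROX margin and
the in-silico score coincide by construction. The bias is realized as a
constant auxiliary input of |b| nM on a weight-1 unit routed to the
sign(b) channel — the literature does not prescribe a molecular
realization of an SVM threshold, so this is a model commitment of the
compiler.

### Annihilation and reporting

Subtraction uses the two-step cooperative-hybridization scheme
OutNeg + Annihilator ⇌ Intermediate (k_on = k_off = 1e-2),
Intermediate + OutPos → 2 Waste (k_collapse = 5e-2), with the annihilator
supplied at 2× the larger channel capacity. Reporters displace at
1e-5 nM⁻¹s⁻¹. The 5000:1 collapse:reporting ratio is the concentration-
level expression of the design rule that the annihilator toehold must be
long enough to consume every minority strand: with faster reporters the
transiently unpaired majority leaks into its fluorophore before pairing,
and (by conservation, ROX − HEX = margin) near-tie inputs then light a
channel. At the chosen ratio the full 6×6 truth table of the two-input
demonstration classifier behaves correctly: cells with |margin| above the
call threshold fire exactly the channel of sign(margin), near-tie cells
fire neither.

The call threshold δ defaults to 5% of the total input capacity
(Σ|Wᵢ|·input_max + |b|); |HEX − ROX| < δ is reported as *indeterminate*.
No published value exists for this threshold; it is a documented free
parameter.

## Asymmetric PCR front end (`molclass.pcr`)

A discrete per-cycle recurrence over concentrations (fractional amounts
allowed). Defaults: limiting primer L = 25 nM, excess primer X = 1000 nM,
per-cycle efficiency E = 1, RT yield 1, readout at cycle 52. In the
exponential phase each new duplex consumes one limiting and one excess
primer, capped by the remaining limiting primer; once the limiting primer
is exhausted, each cycle adds E·(final duplex count) of excess-strand
ssDNA, capped by the remaining excess primer. Because exhaustion takes
~log₂(L/N₀) cycles, the readout is a staircase approximation to a line in
log₂(N₀) with step L per cycle.

The reverse-transcription product is single-stranded cDNA, so the first
thermal cycle can only synthesize its complement (consuming one excess
primer); exponential duplication begins at cycle 2. This one-cycle offset
matters: counting a doubling in cycle 1 pushes the top of the 0.1–10 pM
range into the excess-primer cap at cycle 52 (the 10 pM readout would
demand 40 linear cycles × 25 nM = 1000 nM against the ~975 nM available)
and visibly flattens the dilution series, whereas the second-strand
convention keeps the whole published range linear (R² = 0.999999 over
seven log-spaced points). Duplex templates (`initial_template="dsdna"`)
skip the synthesis cycle and duplicate immediately. The two-temperature
bench protocol is collapsed into this single effective-efficiency model;
sequence-specific priming, primer dimers and melting-temperature effects
are not modeled.

## Converter (`molclass.transform`)

The two-splint association and downstream displacement are collapsed into
one effective bimolecular step ssDNA + Converter → γ·Input, with yield
γ = 1 and zeroth-order leak λ = 0 by default (the optimized-condition
values); both are configurable to study non-ideality. The leak term λ·t is
added analytically to the CRN endpoint because the network representation
is restricted to elementary orders 1–3. The default converter supply
(2000 nM) exceeds the maximum ssDNA the default PCR can produce (~975 nM),
keeping the composed front end in its linear regime; conversion saturates
(with a warning) when ssDNA exceeds the supply.

## Training (`molclass.training`)

Stratified 50/50 train/validation split (seeded). The fourfold screen
retains features with |log₂FC| ≥ 2 between class means. Ranking uses a
500-tree random forest: permutation importance (accuracy scoring,
10 repeats) as Mean Decrease Accuracy, impurity importances as Mean
Decrease Gini tiebreak. Linear SVMs (C = 1; the value is not specified by
the training recipe this emulates) are fitted on standardized features for
k = 1..10 panels with class weights 2:1 in favor of the positive class;
weights are mapped back through the standardization and the shared affine
input scale to nM space, jointly rescaled so max|W| = 2.5 (the midpoint of
the published weight-magnitude range — joint rescaling of (W, b) leaves
decisions unchanged), and rounded to one decimal *after* model selection,
with AUCs re-computed under the rounded weights (the published recipe is
ambiguous about the ordering; the suite checks the rounding costs < 0.01
AUC). Selection takes the highest validation AUC, ties to the smaller
panel.

## Synthetic data (`molclass.synth`)

The expression generator emulates a serum-miRNA case/control study:
345 positive / 958 negative samples, 250 features, baselines uniform on
log₂ ∈ [4, 12], Gaussian within-class noise on the log₂ scale (the
marginal distribution of the emulated repository data is not published;
log-normality is an assumption), and five planted effects
(2.3, 2.6, −2.4, −2.8, −3.0 log₂ units — 4–8-fold, mixed directions).
The defaults are calibrated to the emulated study's operating point: a
five-feature panel should be needed to reach AUC ≈ 0.99. With noise much
below σ = 1.2 the synthetic task is cleaner than the real one — validation
AUC saturates at exactly 1.0 by k = 2 and the smaller-panel tie-break then
(correctly) stops growing the panel — so σ = 1.2 is the default; effects
sit far enough above the fourfold threshold that sampling noise in the
empirical fold change cannot drop a planted feature. What passing recovery
tests show is that the pipeline identifies planted log-linear structure of
realistic strength; they do not certify performance on real microarray
data with platform artifacts, correlated features or batch effects, which
the generator does not emulate.

Patient panels are drawn in log₂-concentration space within the PCR model's
linear range (0.1–10 pM), shifted per feature along sign(Wᵢ) for the true
class, and resampled until the in-silico score is class-consistent with
|score| ≥ 0.3× the classifier's score scale (borderline mode instead
targets near-zero scores and flags the panel). The confident margin is
deliberate and mirrors the emulated validation design, which replicated
only patients the classifier called correctly; it also dominates the error
budget of the molecular path: the integer-cycle PCR staircase quantizes the
recovered log₂ concentration to about ±0.5, i.e. up to ±Σ|Wᵢ|·0.5·a nM of
score error (a the input-scale slope), which must stay below the drawn
margin minus δ for end-to-end concordance to be structural rather than
lucky.

Standard curves are linear a.u./nM maps (slope 150–250, intercept 20–60,
optional proportional noise), invertible by construction.

## Pipeline (`molclass.pipeline`)

Per sample: PCR per feature → converter → recovery of log₂ concentration
against a *simulated dilution standard* (the same model run on seven known
concentrations, OLS-fitted — the in-silico analogue of normalizing against
a standard curve) → affine input scale → compiled network ODEs → reporter
standard curves → margin call. Confusion statistics use exact rational
arithmetic with percentages formatted at one decimal, round half up;
indeterminate calls count as misclassifications (conservative: the
emulated clinical table has no indeterminate category).

## Problem sizes

Defaults were chosen so the whole suite exercises the full pipeline at
realistic scale while staying lightweight: the training cohort is the full
emulated 1303-sample / 250-feature matrix; end-to-end concordance runs a
10+10-patient cohort; the truth table covers all 36 input cells; oracle
checks use 50 random weight units. The acceptance script completes in
seconds on one CPU.

## Known limitations

* Sequence-level design (thermodynamics, leak pathways, crosstalk between
  non-orthogonal strands) enters only through scalar yield/leak/rate
  parameters.
* Rate constants are not fitted to experimental fluorescence; a
  calibration table hook exists for the weight units but no experimental
  dataset ships with the package.
* The PCR model's integer-cycle staircase limits log₂ recovery to about
  half a cycle; efficiencies below 1 additionally de-align the staircase
  from a uniform dilution grid.
* The real repository cohort (GEO GSE113740) is never downloaded; an
  adapter reads a user-exported CSV, and all shipped results are synthetic.
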