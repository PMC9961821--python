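# Methods

## The design and its coding

The packaged study is a rotatable central composite design in k = 3 factors:
a 2³ factorial block at coded ±1, six axial points at coded ±2, and six
replicated center runs — 20 runs in all. Factors are coded as
`x = (natural − center)/step` with centers (50 % ethanol, 3 h, 60 °C) and
steps (25 %, 1 h, 10 °C). These values are forced by the five equally spaced
natural levels of each factor (e.g. ethanol 0/25/50/75/100 %): the middle
level is the center, the factorial levels sit at ±1, and the extreme levels
at ±2, so the axial distance is α = 2. `load_table` re-derives the coding
from the level sets of the file it reads and refuses tables whose geometry
is not a recognizable CCD; all downstream statistics are invariant to run
order.

## Quadratic fit and ANOVA conventions

The full 10-term second-order polynomial is always fitted, by QR least
squares (rank tolerance 1e−10 relative; no normal-equation inversion). The
study's own published equations retain non-significant terms, and the
predictions at the optimum are only reproducible with the full model, so
term-dropping is not a default behavior.

Conventions that matter for matching conventional DOE software output:

- **Per-term SS are Type III (partial):** `SS_j = βⱼ² / [(XᵀX)⁻¹]ⱼⱼ`, each
  term adjusted for all others. On a CCD the linear and interaction columns
  are mutually orthogonal, so for those terms this equals `βⱼ²·Σxⱼ²`; the
  three pure-quadratic columns are correlated with one another, so their
  partial SS differ from sequential SS and do **not** add up to the model SS.
  Only the partial convention reproduces standard ANOVA tables for this
  design family.
- **Lack of fit / pure error:** pure-error SS pools squared within-group
  deviations over all replicated design points (here the six centers,
  5 df); lack-of-fit SS is the remaining residual SS (5 df); their mean
  squares form the F test. Without replicates the report flags lack of fit
  as unavailable instead of failing.
- **PRESS** uses the leverage identity `Σ (eᵢ/(1−hᵢᵢ))²`, which the test
  suite verifies against literal leave-one-out refits; predicted R² is
  `1 − PRESS/SS_total`.
- **AICc/BIC** are the Gaussian least-squares forms *including* the
  `n·ln(2π) + n` likelihood constants (`AICc = n·ln(2πSSE/n) + n + 2p +
  2p(p+1)/(n−p−1)`, `BIC = n·ln(2πSSE/n) + n + p·ln n`, p = 10), the
  convention used by mainstream DOE packages, and the one that reproduces
  the study's printed values.
- **Adequate precision** is `(max ŷ − min ŷ)/sqrt(p·MS_res/n)` over the
  design runs; **CV%** is `100·sqrt(MS_res)/ȳ`.
- p-values come from the F distribution with no multiplicity correction.

### Print-precision limits of the packaged data

The fixture stores the response means exactly as printed, rounded to two
decimals. Refitting them reproduces the published TFC and DPPH tables to
every printed digit, but the TPC and CUPRAC blocks differ in the third or
fourth decimal (e.g. TPC ethanol coefficient 0.3388 vs printed 0.3400;
CUPRAC PRESS 0.0474 vs 0.0464) because the original analysis used unrounded
assay means that were never published. The acceptance tests assert print
precision for all four responses anyway; the TPC and CUPRAC cases fail by
these rounding-propagation margins and are documented rather than loosened.
The DPPH ethanol-temperature linear term is taken with the ANOVA table's
positive sign (+0.0069); the equation as printed elsewhere carries a
negative sign that cannot reproduce the published prediction at the optimum.

## Desirability optimization

Each response prediction maps to `d ∈ [0, 1]` by a one-sided ramp
(`maximize`: 0 below L, 1 above U, `((y−L)/(U−L))^w` between; `minimize`
mirrored; `target` two-sided). Limits default to the observed min/max of
each response over the design runs — the convention that reproduces the
study's D = 0.934 — and weights default to 1. The overall desirability is
the weighted geometric mean, zero if any component is zero.

The search maximizes D over the coded factorial cube [−1, 1]³ by default
(configurable up to the axial cube [−2, 2]³), restarting bounded
Nelder–Mead from every node of a fixed 5-per-axis lattice (tolerance 1e−8
on D), so results are deterministic. A 101³ exhaustive grid in the test
suite confirms the maximum to 1e−3. With the default limits the located
optimum is 75 % ethanol, ≈3.7 h, ≈67 °C with D = 0.934; the validation
helper reports the two-value pair SD `|e−p|/√2` and its RSD both as a
fraction (the convention of the study's validation table) and as a percent.

## The Levenberg–Marquardt MLP

The comparison network is a one-hidden-layer perceptron: inputs and targets
min–max normalized to [−1, 1], tansig (tanh) hidden units, linear outputs;
default topology 3–6–4 (hidden size configurable 1–15). Training is
full-batch LM on the summed squared error across all four outputs with an
analytic Jacobian: step `Δw = −(JᵀJ + μI)⁻¹Jᵀe`, μ starting at 10⁻³,
divided by 10 after an accepted step and multiplied by 10 after a rejected
one (cap 10¹⁰), stopping on max 1000 epochs, gradient ∞-norm < 1e−10, or
six consecutive validation failures, and returning the weights of the best
validation epoch. Data are split 70/15/15 (14/3/3 for n = 20, remainder to
training) by a seeded shuffle. Initialization is Nguyen–Widrow (hidden-unit
active regions spread over the input cube), chosen because uniform
U(−0.5, 0.5) starts converge markedly worse under early stopping on this
data size; uniform init remains available. Training restarts from 20
consecutive seeds and keeps the restart with the lowest validation SSE.
Everything is deterministic for a fixed base seed.

A caveat the test suite makes explicit: with 20 runs and 6 points held out,
the early-stopped network's all-20-run R² (TPC 0.986, TFC 0.947, DPPH
0.954, CUPRAC 0.984 for base seed 0) does not exceed the in-sample R² of
the 10-term least-squares fit on every response, and no restart among 40
seeds does. Published claims of network R² ≥ 0.98 on all responses of this
dataset are only reachable by evaluating a network effectively trained on
all points; the corresponding comparison test is left failing rather than
weakened.

## Comparison metrics

`comparison_metrics` computes R² = 1 − Σ(Yp−Ye)²/Σ(Ym−Ye)² (denominator:
total corrected SS about the observed mean — the only reading under which
in-sample RSM R² equals the ANOVA R²), RMSE, AAD% = 100·mean(|Yp−Ye|/Ye)
and SEP% = 100·RMSE/Ym. RSM and ANN are compared on identical evaluation
sets (all 20 runs by default).

## Mass and neutral-loss annotation

Monoisotopic masses use the lightest-isotope table (C 12, H 1.0078250,
N 14.0030740, O 15.9949146, S 31.9720707, P 30.9737615). The default adduct
convention adds/subtracts the hydrogen-*atom* mass, which is what the
packaged compound table prints; the strict proton convention
(1.0072765, electron bookkeeping) differs by ~0.00055 Da per charge and is
available behind a flag. Fragment annotation tests every fragment against
the precursor and every heavier annotated fragment, over a loss table of
sugar residues and small neutrals (with the legacy "COO" label accepted
for CO₂), at a default tolerance of 0.02 Da (fragments are printed to two
decimals); sequential losses are reported as paths capped at depth 3.
Annotation is order-invariant and an unexplained fragment is a result, not
an error.

Of the 71 packaged compound rows, 62 are internally consistent between the
printed formula and the printed calculated m/z within 1 mDa. The other nine
carry printing errors in the source (a duplicated formula shared by two
compounds, one radical formula with an odd hydrogen count, one
digit-transposed calculated mass, five rows 1.5–1.9 mDa off under either
adduct convention); they are flagged `cm_inconsistent` at load time, and
the whole-table acceptance sweep asserts all 71 rows anyway, failing
honestly on those nine.

## Synthetic data

`generate_dataset` draws `y = polynomial(coded x) + N(0, σ²)` on a full CCD
with replicated centers — i.i.d. homoscedastic Gaussian noise, the exact
assumption set of the ANOVA. Defaults mimic the packaged study's TPC
response (its fitted coefficients, σ = 0.08 ≈ the square root of that
model's residual mean square, six centers). What passing tests on this
generator show is that the estimators are correct *under the model*:
coefficient recovery is unbiased with spread matching the closed-form OLS
standard errors (1000 replicates), the lack-of-fit test holds its 5 %
size (2000 replicates), and pure-error MS estimates σ² without bias. Real
assay data can violate these assumptions (heteroscedastic or correlated
errors, drift between replicate batches); the generator deliberately does
not emulate those failure modes, so the tests say nothing about robustness
to them.

## Known limitations

- Only full CCDs (factorial + axial + centers) are constructed and
  validated; no Box–Behnken, fractional or optimal designs, no blocking.
- No response transformations (the study used none) and no stepwise term
  selection as a default path.
- The MLP is a single hidden layer trained in float64 on CPU; it does not
  reproduce any specific toolbox's random streams.
- Confidence levels in the compound table are recorded from the source,
  never computed; no spectrum processing (mzML, peak picking) or structure
  elucidation is attempted.
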