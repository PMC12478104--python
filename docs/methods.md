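# Methods

This note documents the models implemented in `amyloidscan`, the
conventions and tunable parameters of each stage, what the synthetic
generator does and does not emulate, and the numerical choices that a
user re-deriving results should know about.

## The selection readout

The assayed construct couples aggregation of a peptide of interest
(POI) to β-lactamase activity: an aggregating POI depletes functional
enzyme and lowers the ampicillin concentration at which its host cell
survives. A site-saturation library over an L-residue POI contains
19·L substitutions plus wild type (799 for the 42-residue Aβ42).
Sequenced amplicons cover the invariant 28-residue Gly/Ser linker plus
the POI, at fixed offsets; positions are 1-based within the POI
(Asp1 … Ala42 for Aβ42).

## Synthetic data generator

The generator is first-class, tested code: it defines the study
conditions under which the pipeline's recovery guarantees are stated.

**Planted landscape.** Substitution effects are class-based:
within an aggregation-prone region (APR; defaults L17–A21 and I31–I41
for Aβ42), replacing a hydrophobic residue by a charged/polar residue or
by Pro/Gly relieves aggregation (effect +`effect_scale`, charged ×1.2);
introducing a hydrophobic residue where none was is deleterious (−1×
inside an APR, −0.6× anywhere). Gaussian jitter (sd `jitter_sd`) makes
effects variant-specific; scores are clipped to ±4.5, matching the
spread observed in real deep mutational scans of Aβ42. Defaults:
`effect_scale = 2.8`, `jitter_sd = 0.7` (truth sd ≈ 1.7). Wild type is
exactly 0.

**Survival model.** Ampicillin resistance is a fold-change (MIC-like)
phenotype, so the survival midpoint scales exponentially with fitness,

    midpoint(v) = wt_midpoint · 2^(midpoint_log2_scale · fitness(v)),

and survival is logistic in log2 concentration with a shared slope:
`p(c) = expit((log2 midpoint − log2 c)/width)`, with `p(0) = 1` (no
antibiotic, no selection). Defaults: `wt_midpoint = 20` µg/mL,
`midpoint_log2_scale = 0.9` (≈1.9-fold MIC shift per fitness unit),
`width = 0.35` log2 units. The default concentration series is the
standard two-fold dilution design 0, 6.25, 12.5, 25, 50, 100 µg/mL,
which samples the fold-change scale uniformly; these choices place the
whole planted landscape inside the assayed window, so the log2-AUC
score resolves both tails. An additive-midpoint, linear-dose variant
was considered and rejected during design: within a 0–100 µg/mL window
it saturates the fitness tails and wastes most of the grid on the
transition of a single class of variants.

**Sequencing model.** The unselected library composition is
Dirichlet-multinomial around uniform (`library_alpha = 50`, i.e. ≈14%
compositional CV, emulating uneven cloning); an optional
`library_dropout` fraction of substitutions is absent everywhere. Each
(concentration, replicate) plate is a multinomial draw of `read_depth`
reads from the survival-reweighted library — plates are sequenced to
equal depth, so selection is encoded in frequencies, not totals. Reads
are synthesised from one preferred E. coli codon per residue and
corrupted by independent per-base substitutions (uniform over the three
alternative bases) at `per_base_error`, which creates apparent variants
in both the POI and the invariant linker. Not emulated: realistic
Illumina quality/error profiles, PCR jackpots, indels (the library is
substitution-only by design), paired-end structure, epistasis. Passing
recovery tests therefore demonstrates correctness of the scoring
machinery under multinomial counting noise, not robustness to every
artifact of real sequencing.

**In vitro observables.** Stability profiles are the inverted
per-position mean planted fitness, affinely rescaled to −3…+1 kcal/mol
(FoldX-like per-residue contributions, negative = stabilising) plus
Gaussian noise per structure. Kinetic traces evaluate the closed-form
mass model below plus Gaussian noise; endpoint titrations follow
`signal = max(0, slope·(m0 − C_crit)) + noise`.

All generators are deterministic given their seed.

## Genotyping

Strict read-level rules: exact window length (shorter → `truncated`,
longer → `indel-length`); any non-ACGT base → `ambiguous-base`;
standard-table translation of the POI; stop codon → `premature-stop`;
0 amino-acid differences → WT, exactly 1 → that variant, ≥2 →
`multi-substitution` (attributing a multi-error read to a variant would
convert sequencing error into phantom signal). Counts plus discard
tallies equal reads processed per condition, and calling is invariant
to read order. Identical reads are memoised, so deep, low-diversity
conditions genotype in seconds.

The misread floor counts apparent canonical substitutions in the
invariant linker: per condition, total apparent-variant events divided
by the 28 linker positions; the reporting threshold is the ceiling of
the mean over conditions. The floor is applied as "a variant must
exceed the threshold in the unselected (c = 0) library of a replicate
to be scored in that replicate" — the unselected library is where
presence/absence is decided, so that is where the noise floor bites.

## Fitness scoring

Frequencies use a pseudocount (default 0.5) shared by numerator and
denominator: `f = (n + p)/(N + pV)` with V the site-saturation library
size. Enrichment is anchored at the unselected library (`e(0) = 1`);
the AUC is the composite trapezoid over the actual (possibly uneven)
grid; the score is `log2(AUC_v/AUC_WT)`, hence exactly 0 for WT in
every replicate. Scores (not AUCs) are averaged across replicates, with
SEM and pairwise replicate Pearson correlations reported. The landscape
summary reports the substitution matrix (rows = introduced residue,
columns = position), per-position and per-residue means, the fractions
with score ≥ +1 / ≤ −1 / in between, and the distribution centre as
both mean and median (conventions differ across studies; both are
cheap, so both are emitted).

## Stability comparison

Both the (optionally inverted) per-position mean fitness profile and
each structure's per-residue ΔG⁰ contributions are smoothed with a
centred five-residue running mean whose windows shrink to the available
residues at profile edges (no padding — padding would fabricate
terminal values). Missing positions are excluded pairwise, never
imputed; structures overlapping the fitness profile at fewer than 3
residues are skipped with a warning. The sign convention (fitness ×−1
so that stabilising, negative ΔG aligns with low fitness) is a flag,
because the sign convention of input ΔG tables varies.

## Thermokinetics

**C_crit.** Ordinary least squares on titration points above a
detection floor (default 0); C_crit is the x-intercept, a non-positive
slope is rejected, and a percentile bootstrap over points (default
B = 1000) gives the interval. Meaningful relative precision requires a
titration bracketing the intercept (m0 within a few-fold of C_crit);
the recovery statistics are computed under that design.

**Integrated rate law.** `model_mass` implements the standard
fixed-point closed-form solution for nucleated polymerisation with
secondary nucleation, written entirely in the composite rates
λ (primary) and κ (secondary) and reaction orders (nc, n2, defaults
2, 2). Numerics: the bracket is evaluated in log space with a
stabilised `log(B + C₊e^{κt})` so large κt cannot overflow; for
κ ≤ 10⁻⁶·λ the expression degenerates catastrophically and the
primary-only (Oosawa) form `1 − sech^{2/nc}(√(nc/2)·λt)` is used
instead (continuity at the switch is covered by a test). The closed
form reproduces the linearised early-time solution
`(λ/κ)²(cosh κt − 1)` to ~10⁻⁶ but is an *approximate* solution of the
full moment equations: against direct numerical integration of

    dP/dt = kn·m^nc + k2·m^n2·M,   dM/dt = 2·k+·m·P,   m = m0 − M,

its deviation is ~0.5% of the plateau in the strongly
secondary-dominated regime and grows to ~5% at λ/κ = 0.25 — a known
property of this solution family, pinned by the ODE-oracle test at its
achievable tolerance. Parameter *recovery* is unaffected: fitting the
closed form to traces generated by the closed form returns λ and κ to
≈1% median relative error at 1% signal noise.

**Fitting.** Nonlinear least squares in log-parameter space from a
deterministic 5×5 log-spaced multi-start grid (default bounds
10⁻³–10³ per rate); the lowest-RSS converged start wins, and if none
converges the fit is flagged failed rather than defaulted. Optional
trace normalisation uses baseline = mean of the first 3 points and
plateau = mean of the last 5.

## Predictor

The encoding is deliberately length-independent — site one-hots (wt and
introduced residue), relative position, dipeptide composition of the
full variant sequence (400 fractions), sequence means and site deltas
on four scales (Kyte–Doolittle hydropathy; Zimmerman polarity;
Chou–Fasman β-sheet propensity; Zimmerman bulkiness) — so a model
trained on one peptide transfers to IDP sequences of any length. No
explicit higher-order (i + n) pairings are encoded: with ~800
observations, 449 features is already generous, and pair terms would
explode the feature-to-sample ratio. Regression is a random forest
(default 300 trees; CV controls in tests use 40–100 trees for speed)
with seeded, shuffled k-fold cross-validation; fold assignment,
per-fold R², mean/median/SEM and the seed are recorded. A constant
target leaves R² undefined and is flagged rather than scored.

Attribution uses permutation feature importance (with the sign of the
feature-prediction correlation attached), the package's chosen
attribution method: it is model-agnostic, exact to implement with the
installed stack, and for the rank-level statements made here (which
feature family dominates, with which sign) it carries the same
information as Shapley-style attributions. Note that `mean_<scale>` and
`delta_<scale>` are collinear over a single-substitution library
(the sequence mean shifts by delta/L), so credit may land on either
member of a pair; conclusions should be drawn at the feature-family
level. Landscape prediction featurises all 19·L substitutions of an
input sequence and reports the per-position mean predicted score,
optionally inverted, smoothed with the same five-residue window as the
stability comparison.

## Problem sizes and tolerances used in the checks

The test suite and `scripts/acceptance.py` use: full 799-variant
libraries at read depth 10⁴ (3 replicates, six two-fold dilutions
0–100 µg/mL) for recovery statistics; depth 10⁵ single-condition runs
at per-base error 10⁻³ for the misread floor, compared against the
exact codon-level expectation under a Poisson interval; 50-seed
ensembles for kinetic (1% noise, 100 points) and C_crit (5% noise,
6-point bracketing titration) recovery; 21 synthetic structures with a
100-permutation null for stability correlations; and 10-fold CV with
100-tree forests for the predictor's planted-signal and
permuted-target controls. Trapezoid AUC is checked against fine-grid
integration of the piecewise-linear interpolant (breakpoints included)
at 10⁻⁹ on 1,000 random curves.

## Known limitations

* The generator's class-based landscape has no epistasis and a single
  shared dose-response slope; it validates the scoring machinery, not
  biological completeness.
* The closed-form rate law is approximate away from the
  secondary-dominated regime (see above); microscopic rates (k+, kn,
  k2) are not identifiable from a single trace and are not reported.
* Scoring assumes equal-depth conditions are comparable after frequency
  normalisation; batch effects between sequencing runs are out of
  scope.
* The misread floor treats linker and POI error rates as exchangeable,
  which holds for the uniform error model but only approximately for
  real context-dependent errors.
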