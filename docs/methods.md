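# Methods

This note records the models, numerical choices, and open design decisions
behind `entfkit`, and what the synthetic-data generators do and do not
emulate.

## Peptide masses and fragment ions

Masses are sums of the standard monoisotopic residue masses plus water
(18.01056 Da); b ions add one proton per charge, y ions add water and
protons. An intramolecular disulfide bridge removes two hydrogens
(2.01565 Da). The correction is applied to a fragment only when **both**
cysteines of a bridge lie inside the fragment span: a fragment that severs a
bridge is returned uncorrected and flagged `contains_disulfide=False`,
because the sequence alone does not determine the state of a broken bridge.
EntF\* defaults to Cys6–Cys14 bonded — the convention under which the
confirmatory y₁₁/y₁₂ ions sit 2.016 Da below their open-chain values — and
the bridge is a constructor argument, so the reduced form is one call away.

Computed fragment m/z agree with the instrument-reported values to their
0.01 Th print precision: b₂ 202.082, b₃ 315.166, y₁₁ 1315.617, y₁₂ 1414.686.
Note y₁₁ rounds to 1315.62 where 1315.61 is reported; the 7 mTh discrepancy
is within the print precision and likely reflects the measured rather than
theoretical value.

MRM precursor m/z values (865.7 for EntF\*, 667.1 for EntF) are stored
method constants, not recomputed: the printed numbers are not reconcilable
with a single mass convention (865.7 on the triple quadrupole versus the
865.157 fixed quadrupole mass on the high-resolution instruments), so the
package treats them as instrument settings and never derives results from
them.

## Detection rules

The rule engines transcribe the validated method criteria over
already-integrated features (retention time, per-transition areas and S/N,
high-resolution ion lists); no raw-signal processing is attempted. Choices:

- A zero qualifier area fails the ratio rule with the distinct identifier
  `ratio_undefined` instead of raising a division error.
- The HILIC serum criteria carry no concentration rule (`loq_pm=None`).
- High-resolution ion matching is greedy nearest-within-tolerance with each
  reference ion consumable once and ties broken toward the lower observed
  m/z. Which peaks count as "the most abundant isotope parent peaks" is not
  fixed by the method description, so the reference lists are caller-supplied.
- Concentrations are assumed to come from an external linear single-analyte
  calibration; the engine only compares them to the LOQ.
- Failed rules are reported as a set, so verdicts cannot depend on rule
  order, and relaxing any single threshold can only shrink the failure set.

## Kinetics

**Formation.** The reported formation rate (% min⁻¹) is the initial slope
F∞·k of a first-order model F(t) = F∞(1 − e^(−kt)) fitted by least squares
(trust-region, non-negative bounds). A raw linear fit is not self-consistent
here: a rate of 1.71 % min⁻¹ cannot persist over a 180-min incubation, while
the first-order initial slope reproduces it exactly when the data follow the
model. All-zero responses return the degenerate fit r = 0 rather than an
error; negative responses are rejected.

**Permeability.** P_app = slope/(A·C₀) with the slope from OLS of cumulative
receiver amount against time in seconds. When the input is receiver
concentrations, amounts are first corrected for sampling:
Q_k = C_k·V_receiver + Σ_{j<k} C_j·V_sample, which is exact for
aliquot-with-buffer-replacement protocols. Default geometry: area 1.12 cm²,
C₀ = 1 µM, receiver 1500 µL, aliquot 300 µL at 30/60/90/120 min — all
overridable; sink conditions are assumed (donor depletion over 2 h at
P_app ≈ 4 × 10⁻⁹ cm s⁻¹ is negligible).

**Serum kinetics and exposure.** The biexponential profile is fitted
phase-wise by log-linear regression — (A, α) on 0–30 min, (B, β) on
30–180 min — with the breakpoint fixed at 30 min, not estimated. Exposure
over [0, x] uses the closed form A/α(1 − e^(−30α)) + B/β(e^(−30β) − e^(−βx)),
verified against adaptive quadrature to 1 × 10⁻⁶ relative. The endogenous
daily exposure is modeled as a constant serum level times the window
(0.329 nM × 1440 min by default) — the simplest model consistent with a
steady natural background; the exposure ratio is the treated integral over
that product.

## Alanine scan

Lanes are normalized to their total-protein loading and scaled so the
placebo-group mean is 100 %. One pooled one-way ANOVA across all groups
(placebo, EntF\*, every analog) supplies the MSE and error df for Fisher's
LSD pairwise t-tests — pooling is an assumption; per-analog ANOVAs would be
an alternative reading. LSD tests are two-sided by default with a sidedness
flag. The per-position combined score (1 − P_PBS vs ALA)·P_EntF\* vs ALA is
near 0 when the analog behaves like placebo (important position) and near 1
when it behaves like EntF\*.

**Classification scale.** Positions are cut into K = 5 classes by Ward
clustering with a Jenks natural-breaks assignment computed alongside; any
disagreement is reported, never silently resolved. The clustering axis
matters: combined scores are products of p-values, and both the raw and
log₁₀ axes have sampling spreads that vary by orders of magnitude across
score magnitudes, so class boundaries on those axes chase noise. The default
axis is therefore a variance-stabilized significance scale: z = Φ⁻¹(score)
puts every score near its underlying t statistic (sampling spread ≈ 1
everywhere), and the final sign(z)·√|z| compression tightens the far tail so
the class budget resolves structure among weakly affected positions instead
of splitting sampling noise within strongly significant groups. `linear`,
`log10`, and `probit` axes remain available. Classes are numbered by
ascending mean score (class 1 = most important), forced by the score's
semantics; class 1 confers alignment weight ×3 and class 2 weight ×2.

Effect-size helpers follow the standard forms: Cohen's d with the pooled SD,
Hedges' g = d·(1 − 3/(4n − 9)), percentile-bootstrap median differences
(B = 1000, seeded), exact Mann-Whitney p for small tie-free samples and the
tie-corrected normal approximation otherwise (all-tied data give p = 1), and
slope comparison via a pooled-variance t-test with df = n₁ + n₂ − 4
(equivalent to the group-by-time interaction test in a pooled OLS).

## Weighted local alignment

Smith-Waterman with BLOSUM62 and affine gaps; a gap of length L costs
open + extend·L (defaults 10 and 0.5, the canonical EMBOSS-style values —
the method description names a gap-penalty function without values). The
importance adjustment multiplies the substitution score of any aligned
(non-gap) residue pair at a weighted query position — "match" is read as
aligned pair, not identity; in the CXCL12 worked example the weighted pairs
happen to be identities, so both readings coincide. By default the weights
are applied inside the dynamic program (the optimum is over adjusted
scores); a `post` mode instead re-scores the unweighted optimum. Both modes
give 27 on the CXCL12 example. Traceback is deterministic: highest-scoring
cell with the lowest query index, diagonal preferred over vertical over
horizontal. Scores are kept in full precision; with integer matrices and
half-integer gap extends all DP values are exact dyadic rationals. Screen
rankings sort by adjusted score descending with alphabetical tie-breaks.

## qPCR

Standard curves are OLS fits of Cq on log₁₀(copies) over a ≥3-point serial
dilution (a −3.32 slope corresponds to 100 % efficiency). Below-LOD
replicates are treated as **left-censored** — the number of failed reactions
per sample is known, so the likelihood keeps a Φ((LOD − µ)/σ) factor per
censored replicate rather than truncating them away. Censoring is modeled on
the log₁₀-copies scale, where normality is more defensible than on raw
copies; because Cq is an affine function of log copies, a Cq-scale fit is
the same model. The optimizer is a Nelder-Mead simplex over (µ, log σ) from
moment-based starts (tolerance 1 × 10⁻⁸ on the log-likelihood), flagged on
non-convergence, and cross-checked against a two-dimensional grid search in
the tests. All replicates of a sample are pooled into one fit.

## Synthetic data

Generators are pure functions of (seed, parameters); a single global seed
expands into fixed per-scenario substreams, so adding a scenario never
perturbs existing draws. Defaults encode the study conditions: formation
rates 1.71 (n = 4) and 0.11 % min⁻¹ (n = 7) on the 0/5/10/30/60/120/180-min
grid; P_app 3.67 × 10⁻⁹ cm s⁻¹ with the Transwell geometry above (n = 6);
a serum profile whose 24-h integral encodes a 5-fold ratio over 0.329 nM;
blot groups at placebo 100 %, EntF\* 62 %, analogs 95 % (positions 1/2/10),
80 % (3/9), and 65 % elsewhere, 15 lanes per group; and normal log₁₀-copy
draws censored at the LOD with six replicates per sample.

Noise models, none of which are dictated by the assays: additive Gaussian
with SD 2 % of the noiseless dynamic range for time courses, multiplicative
lognormal with 10 % CV for blot intensities (5 % CV loading variation on the
normalizers), 5 % CV lognormal for serum concentrations, Gaussian on the
log₁₀-copies scale for qPCR. Time-course draws are floored at zero, as
measured percentages are; this adds a small positive bias at early
time points that is well inside the replicate SEM at these noise levels.

What the generators do **not** emulate: chromatographic peak shapes and
integration, matrix effects and adsorption losses, inter-animal variability
structure, blot saturation and background subtraction, and amplification
efficiency drift. Passing recovery tests therefore shows the estimators are
correct and unbiased under the stated statistical structure — not that real
instrument data meet that structure.

## Problem sizes and limitations

The test suite and the acceptance script run at the study's own sample sizes
(4–7 kinetic replicates, 6 Transwell runs, 15 lanes per blot group, 100
scan replicates for the recovery rate, 100 censored observations), which the
package's estimators handle in seconds. Known limitations: the formation
model assumes a single first-order pathway (no EntF\* degradation term); the
exposure model ignores endogenous kinetics; the scan classification assumes
one analog per position and a shared error variance across groups; the
ligand screen's score has no significance model — it ranks, it does not
test; and the serum survey, in vivo effect sizes, and external-database
alignment figures of the source study require data (animal measurements,
curated domain tables) that no desk-side computation can regenerate.
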