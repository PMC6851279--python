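# Methods

## Promoter model

The input function is a statistical-mechanics promoter-occupancy model.
CRP activity is a Hill function of cAMP, A(C) = C^n/(Km_cAMP^n + C^n);
LacI activity (fraction of repressor not bound by IPTG) is
R(I) = 1/(1 + (I/Km_IPTG)^m).  The promoter partition function enumerates
four states — empty, RNAP bound (weight a), cAMP-CRP bound (weight d·A),
and RNAP + cAMP-CRP with fold-stabilization η (weight a·d·η·A) — giving
the RNAP occupancy P_act = (a + a·d·η·A)/(1 + a + d·A + a·d·η·A).
Repression enters as an independent occupancy factor F_rep = 1/(1 + b·R),
and expression is G = γ + α·P_act·F_rep.  Assumptions: equilibrium
occupancy maps linearly onto steady-state reporter signal; activator and
repressor binding are thermodynamically independent (repression multiplies
the activated rate rather than entering the same partition function); DNA
looping by LacI tetramers is omitted.  For η ≥ 1 the surface is
non-decreasing in both inducers and bounded in [γ, γ + α] — both are
property-tested.

Parameters and units: α, γ in arbitrary fluorescence units (AFU); a, b, d,
η dimensionless; n, m dimensionless Hill exponents; Km_cAMP in mM;
Km_IPTG in µM.  The duplicated use of one symbol for both the CRP and the
LacI binding weight in informal descriptions of this model family is
resolved here as d (CRP) and b (LacI).

## Logic phenotypes

"Low" and "high" on each axis are the minimum and maximum concentrations
present in the grid (0 and 40 mM cAMP, 0 and 200 µM IPTG on the standard
grid).  Because a ratio of logarithms depends on units, the landscape is
first rescaled so its maximum is 100; π_i = log10(max(E_i, 1))/log10(100)
at the three non-maximal corners (the clamp at 1 keeps the ratio in [0,1]
and makes a cell at or below 1% of maximum count as fully off).  This
normalization is a convention of this package, fixed once.  The
single-inducer fractions f_IPTG and f_cAMP are corner ratios to the
both-high corner, and synergy = 1 − (f_IPTG + f_cAMP − f_IPTG·f_cAMP),
the share of maximal expression not explained by Bliss-independent
combination of the single-inducer effects.  A constant landscape maps to
π = (1,1,1), f = 1, synergy = 0.

Landscape comparison uses Euclidean distance between max-normalized value
matrices (shape, not brightness, distinguishes strains whose reporter
scales differ), followed by average-linkage hierarchical clustering with
merge heights equal to average inter-cluster distance.

## Fitting

The objective is the RMSE between observed and predicted landscapes, both
divided by the observed maximum (so the fit is invariant to AFU
rescaling; a log10 residual scale is available).  All ten parameters are
optimized in log10 space, which enforces positivity without constrained
optimization.  Multistart: one heuristic start read off the data plus 50
Latin-hypercube starts (default) over documented log-uniform ranges
(a, b, d ∈ [1e-3, 1e4]; η ∈ [1, 1e3]; n, m ∈ [0.5, 6]; Km_cAMP ∈ [0.05,
100] mM; Km_IPTG ∈ [0.1, 1000] µM; α, γ relative to the observed
maximum), Nelder-Mead per start (objective tolerance 1e-10, at most 5000
evaluations).  The three best local optima are then polished by
alternating Powell and simplex restarts — in practice different basins
polish to very different depths, so pursuing several and keeping the best
is what lets noiseless self-fits reach the 1e-4 RMSE regime.  Ties between
equally good starts resolve to the lowest start index; the whole procedure
is a pure function of the seed.

The ten-parameter model has soft non-identifiabilities (most prominently
a–η trade-offs), so parameter recovery is assessed on the surface that is
identifiable: the predicted landscape and its logic phenotype.  A profile
check flags any parameter whose ±10% perturbation changes the objective by
less than 1e-6 as weakly identified.

## Growth curves

The modified Gompertz model (Zwietering parameterization)
y(t) = baseline + A_max·exp(−exp((μ_max·e/A_max)(λ_lag − t) + 1)) is fit
per well by bounded least squares from a data-derived start (baseline from
the 5th percentile, μ_max from the steepest smoothed difference quotient,
λ_lag from the tangent construction) plus a few seeded perturbed restarts.
The tangent at the inflection has slope μ_max and crosses the baseline at
t = λ_lag, which is the operational definition of lag used throughout.
Wells with OD range below 0.02 are flagged no-growth and excluded rather
than raising.  Replicates aggregate as a weighted mean with weights
1/RMSE² (fit quality), with a weighted standard error; a strain with no
accepted wells yields a missing value.

## Phylogenetic statistics

Pagel's λ: the trait is modelled as N(μ·1, σ²C(λ)) with C(λ) carrying
root-to-tip distances on the diagonal and λ × shared root-to-MRCA path
lengths off it; μ and σ² are profiled analytically by GLS and λ is
maximized over [0, 1] (PSD-safe) by bounded search with both endpoints
checked.  The λ = 0 null is tested by likelihood ratio.  The reference
distribution matters: on shallow trees (e.g. 64-tip pure-birth trees
scaled to unit depth) the GLS mean absorbs most of the covariance added by
λ, the score at λ = 0 is negative in expectation, and the estimate sits on
the boundary far more than half the time — both the χ²₁ convention and
the boundary 50:50 mixture are then severely conservative (empirical size
< 1% at nominal 5%).  The committed convention is therefore a simulated
null: under H₀ the LRT is pivotal (μ, σ² profiled out), so one reference
distribution of null LRTs per tree, simulated from iid normal tips,
serves every trait tested on that tree and yields an exactly calibrated
Monte-Carlo p-value.  χ²₁ and the mixture remain available as cheap
asymptotic options.  Star phylogenies make λ unidentifiable; the result is
flagged and given p = 1.  Strains missing from tree or trait are pruned,
not imputed.

Mantel tests correlate upper-triangle entries of two distance matrices,
with the null built by simultaneous row/column permutation;
p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1), one- or two-tailed.

Phylogenetic diversity (PD) of a tip subset is the branch length of the
minimal spanning subtree, excluding edges above the subset MRCA
(configurable conventions exist; this one was chosen and fixed).  The
representativeness bootstrap reports the fraction of equal-size random
subsets with strictly lower PD.

## Association statistics

Mutual information uses plug-in estimation between the allele category
(gaps are a legitimate category) and the parameter discretized into
equal-frequency bins — 2 bins below 24 strains, 3 otherwise — which
bounds small-sample bias and makes MI invariant to monotone parameter
transforms.  Scale parameters (α, γ, a, b, d, η, Km's) enter association
analyses as log10; Hill exponents stay linear.  Family-wise correction
across sites within a parameter uses the max-statistic permutation null
(the maximum MI across all sites per permutation of the parameter
values), which is the standard scan correction and naturally produces the
flat significance profile across linked sites.  Because the plug-in MI on
few strains is heavily tied, ties between the observed statistic and a
permutation maximum are broken by auxiliary uniform draws (a randomized
test); without this the discrete null makes the scan arbitrarily
conservative.  All permutation p-values are ≥ 1/(n_perm + 1) and
deterministic given the seed.

PLS1 (NIPALS) regresses lag time on the z-scored parameter table:
components maximize covariance with the centered response, with X
deflation; variance explained per component is the reduction in residual
response sum of squares (cumulative, it equals the OLS R² at full rank —
an identity used as a test oracle); the contribution of variable j to a
component is 100·w_j² (weights are unit vectors).  Significance comes from
permuting the response: p-values for component-1 variance explained and
for the summed contribution of the observed top-2 variables.  Pearson
correlations per parameter are reported without multiplicity correction
(the number of tests is logged).

## Synthetic data generator

The generator emulates the measured design: 8 cAMP levels (0–40 mM) × 10
IPTG levels (0–200 µM), 3 replicates, multiplicative lognormal
measurement noise with 5% CV (fluorescence noise is scale-proportional;
each replicate cell is truth × LogNormal(0, σ) with σ matched to the CV);
a pure-birth strain phylogeny scaled to unit depth (tips extended by the
exponential waiting time to the next birth event so the process is
observed between speciations and no zero-length cherries occur); traits
drawn from N(μ·1, σ²C(λ_true)) by Cholesky factorization; and growth
curves read every 3 min for 24 h with Gaussian OD noise (sd 0.002).

Regulatory parameters are sampled log-uniformly from ranges narrower than
the fitting search bounds — Km's inside the measured concentration
decades, appreciable repression and activation (see
`simulate.SAMPLING_RANGES`) — chosen once so sampled strains span the
AND-to-OR morphological range that motivates the analysis rather than the
degenerate flat landscapes most of the full search volume produces.  An
option imposes the negative a–η correlation seen across strains via a
shared latent variable.

SNP matrices: causal sites threshold the chosen parameter at its median
with probit label noise — each strain flips with probability
Φ(−effect_size) — so effect_size = 0 gives purely random labels and
effect_size = 3 an essentially clean split; each causal site carries
exact-copy linked sites (the linkage signature).  Neutral sites draw
minor-allele counts from the folded neutral site-frequency spectrum,
P(j) ∝ 1/j + 1/(n−j), so most sites are rare variants as in real
alignments.  True lag per strain is β₀ + β_a·z(log a) + β_η·z(log η) + ε
(defaults 300, −60, +60, σ_ε = 20 min), floored at zero; the signs encode
the direction the growth analysis is designed to detect.

What the generator does not emulate: sequence evolution (no substitution
models — linked sites are exact copies), flow-cytometry gating artefacts,
inducer exclusion and lactose metabolism, diauxie or multi-phase growth,
and any dependence of expression noise on growth state.  Passing tests
therefore demonstrate correctness of the estimators and calibration of
the tests under the stated noise models, not robustness to those
unmodelled features of real data.

## Problem sizes and numerical choices

The test suite runs the recovery study at 20 strains on the full 8×10
grid (24 multistarts per fit), calibration studies at 500 null / 200–300
signal replicates with 199–999 permutations, and the end-to-end lag
directionality study at 100 seeded runs of 20 strains — sizes chosen so
the binomial confidence intervals on calibration rates are meaningful
while the whole suite stays a desk-scale computation.  The acceptance
script uses 20 strains (the study's panel size), 24 multistarts, 999
Mantel/PLS permutations and 499 MI permutations.  Degenerate inputs have
defined behaviour throughout: all-zero landscapes are unfittable, constant
traits and constant responses raise, monomorphic sites are filtered before
MI, no-growth wells are flagged, and star trees report non-identifiability
rather than a spurious λ.

## Known limitations

Raw parameter values are only weakly identified in places (a–η); analyses
that need strain-level parameters should prefer logic phenotypes or
predicted landscapes.  The simulated-null Pagel test's resolution is
bounded by the reference size (p ≥ 1/(n_sim + 1)).  The MI scan's
randomized tie-breaking trades a deterministic (but very conservative)
decision for exact calibration; with seeds fixed the whole analysis
remains reproducible bit for bit.
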