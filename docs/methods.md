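# Methods

This note documents the models, algorithmic choices and limitations of the
package, module by module. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic experiments (`phenolome.simdata`)

The generator emulates a factorial drought study: 8 spring-barley varieties
(5 European, 3 Syrian), water-deficit treatments applied at the three-leaf
stage (I), the flag-leaf stage (II) or both (I+II), leaf sampling after 3,
6 and 10 days of deficit (plus day 1 for I+II), matched controls harvested
on the same days, and 4 replicates per cell for metabolite profiling (2 for
phenotyping). `make_design` builds the complete balanced table; sample
masses are drawn uniformly from 80–120 mg (typical ~100 mg leaf extracts).

**Signal model.** Each "metabolite" is one chromatographic peak at a fixed
latent retention time. Peaks are exponentially modified Gaussians (Gaussian
σ convolved with an exponential tail τ; τ = 0 recovers the Gaussian), the
standard model for chromatographic tailing, with area = A·σ·√(2π) so that
scaling the amplitude scales the area proportionally. Defaults, chosen once
as the package's study conditions: a uniform grid of 1 500 points over
0–30 min (the real instrument grid is > 10 000 points; the smaller default
keeps the test suite fast and is configurable), amplitudes 2–6 AU, widths
σ = 0.08–0.15 min, tails τ ≤ 0.04 min, linear drifting baselines (slope
±0.02 AU/min, intercept 0.5–2 AU), additive iid Gaussian noise with
sd 0.01 AU (signal-to-noise ≳ 100 on major peaks, realistic for UPLC-PDA
absorbance traces of abundant phenolics), and per-sample monotone
piecewise-linear retention-time warps with node displacements uniform in
±0.05 min and fixed endpoints. The warp class deliberately matches COW's
segmentwise-linear warping class so that alignment recovery is well posed.
Baselines are linear (no curvature) by default: differentiation maps them
exactly to a constant, which is the design point of the baseline-removal
step; a global curvature term would make the entire noiseless trace weakly
concave and is not part of the default conditions.

**Planted drought effects** are multiplicative on peak area — drought area
= 2^effect × control area — hence additive on the log₂ scale on which the
statistics run. Category semantics: D = effect constant over varieties and
days; VD / TD = effect varies with variety only / day only (per-level
coefficients ±U(0.5, 1.5) × effect size); VD_TD = additive variety and day
components; VTD = outer product of variety and day scores (non-additive);
NoEffect = all zeros. These make the ANOVA families identifiable by
construction. The default effect size is 2 log₂ units.

`GroundTruth` records, per metabolite, the category, the (variety × day)
effect map, the latent retention time *and* the observable apex (the mode
of the tailed peak shape, which sits right of the Gaussian center) — peak
recovery is judged against the observable apex.

**Phenotypes.** Trait value = variety baseline + treatment effect + noise.
Traits may carry a common effect per treatment, a variety-specific
perturbation (creating VD structure), and/or a link to a metabolite:
variety effect = slope × (that metabolite's day-averaged variety effect) +
perturbation, which plants a cross-variety Pearson correlation of
ρ = slope·σ_met / √(slope²σ_met² + σ_perturbation²).

**What the generator does not emulate:** full-spectrum PDA data, co-eluting
peak overlap, heteroscedastic or drifting detector noise, saturation,
missing injections, and retention drift beyond the piecewise-linear warp.
Passing tests demonstrate algorithmic correctness under the stated signal
model, not instrument-level fidelity.

## Preprocessing (`phenolome.chromproc`)

Stage order: mass normalization → differentiation → COW → peak detection →
common peaks → integration → wavelength merging.

- **Differentiation** uses `numpy.gradient` w.r.t. grid index (central
  differences, one-sided ends). First order suffices: a linear baseline
  becomes a constant, which neither creates concave runs nor (being small
  for slow drifts) disturbs the intensity filter.
- **COW.** The reference — the pointwise median of the normalized,
  differentiated traces per wavelength (robust to outlying samples;
  configurable) — is split into ⌈(N−1)/segment_len⌉ segments. Interior
  boundary *i* of the signal sits at bᵢ + uᵢ with |uᵢ| ≤ slack; endpoints
  are fixed and monotonicity (≥ 1 point per segment) is enforced. The DP is
  exact over this class because segment scores couple only adjacent nodes.
  Degenerate (constant) segments score 0 rather than erroring. Ties are
  broken toward the smallest |uᵢ|, so the identity warp wins when nothing
  is gained. Defaults segment_len = 30 points, slack = 8 points on the
  1 500-point grid (slack must exceed the simulated warp of ±0.05 min =
  2.5 points; both config-exposed).
- **Peak detection.** A cubic least-squares spline with 520 uniformly
  spaced knots (the protocol constant; must be < N) is fitted to the
  differentiated, warped signal and differentiated analytically, giving a
  smoothed second derivative of the original trace. Candidate peaks are
  maximal strictly-negative runs (concave regions). Runs of length 1 are
  artifacts and are dropped; so are runs whose max |differentiated signal|
  is below the 5·10⁻⁴ tolerance, interpreted on the
  normalized-derivative-per-index scale since filtering happens after
  differentiation and warping. The apex is the most concave point.
- **Common peaks** are unions of overlapping individual intervals
  (transitive closure; half-open 0-based indices, so touching intervals do
  not merge), with support = number of distinct contributing samples;
  support < c₁ drops the peak. c₁ defaults to 50% of the chromatograms
  (the protocol chooses it so desired compounds are not lost while cells
  stay analyzable; config-exposed as a count or fraction).
- **Integration** is the trapezoid of the rectified (max(·, 0))
  differentiated signal over the interval with spacing `dx` (default 1 =
  index spacing). For a clean peak the rectified per-index derivative
  integrates to the cumulative rise — the peak height — which is monotone
  in the true area at fixed shape and baseline-free by construction.
- **Wavelength merging.** Common peaks at 280 and 330 nm whose aligned
  intervals overlap are treated as the two absorption maxima of one
  compound and summed into one variable (automatic retention-time
  matching stands in for the manual MS-based naming of the original
  workflow); co-eluting names are kept as `"X;Y"` labels; unmatched peaks
  pass through.

## Effect statistics (`phenolome.effects`, `phenolome.anova`)

Values are transformed by log₂(10⁹·x); zeros are replaced by half the
smallest positive value of the variable, with a warning.

The ANOVA engine computes classical balanced-factorial sums of squares
directly from cell means by inclusion–exclusion over factor subsets,
vectorized over all metabolites at once, and refuses unbalanced or
single-replicate layouts. With a balanced all-fixed design these F-tests
coincide with REML Wald-F tests, so no mixed-model machinery is used; a
replication-block random effect is not modeled (blocks never enter the
reported analyses).

Per treatment (day levels are treatment-specific; I+II adds day 1), the
model variety × day × condition is fitted per metabolite. Bonferroni is
applied within each effect family across the *m* metabolites (p < α/m,
α = 0.05), controlling the FWER separately per family — this is the
guarantee the test suite checks under the global null. Categories follow
the precedence VTD > VD&TD > TD > VD > D > NoEffect, matching mutually
exclusive reporting columns.

Treatment effects are drought − control cell means on the log₂ scale;
marginal effects average cell effects; cells without a matched control are
flagged missing and excluded from marginals.

Time-profile clustering maximizes between-group SS (equivalently minimizes
within-group SS) with k = 4: exhaustive enumeration of set partitions into
k non-empty groups up to 12 profiles (global optimum guaranteed), k-means
with seeded restarts above that. Cluster labels A–D are assigned by
descending cluster mean at the first day — an arbitrary but reproducible
rule. Mahalanobis distances use the pooled within-cluster covariance with
a ridge of 1e-8·trace(S)/p added when singular (error if the ridge is
disabled).

The permutation χ² draws fixed-margin tables by Patefield sampling
(`scipy.stats.random_table`) and reports
p = (1 + #{χ²_sim ≥ χ²_obs}) / (1 + n_perm), which is a valid p-value by
construction. All-zero margins are dropped before sampling.

## Phenotypes (`phenolome.phenocorr`)

Traits are measured at maturity, so the per-treatment model is
variety × drought (no time factor); VD requires the interaction at
p < 0.01, D the main effect. Percent effects are 100·(drought −
control)/control mean, with a zero control mean an error. Biplots use the
SVD of the column-centered variety × trait effect matrix; scores carry the
singular values (principal-component scaling), loadings are unit vectors,
and variance explained is s²ᵢ/Σs². Metabolite–phenotype screening
correlates variety-specific effects; the metabolite effect entering the
screen is the day-averaged effect (the final-day effect is available by
configuration), and the default inclusion rule is metabolites with
variety-specific categories (VD, VD_TD, VTD), which is also what the
pipeline runner uses. With 8 varieties the |r| threshold for two-sided
p < 0.01 is ≈ 0.834 (t with 6 df).

## Neutral-loss annotation (`phenolome.fragannot`)

Nominal integer masses throughout, matching how such losses are reported;
the residue table covers hexose 162, deoxyhexose/coumaroyl 146, pentose
132, feruloyl 176, hydroxyferuloyl 192, sinapoyl 206, sinapic acid 224,
malonyl CO₂ 44, malonyl ketene 204, ketene 42, water 18 and the
C-glycoside cross-ring fragments 120/90/162, and is extensible. The
146-amu deoxyhexose/coumaroyl ambiguity is preserved — both decompositions
are returned (in the original workflow it is resolved by elution order).
Decomposition is a bounded DFS over residues in lexicographic order;
results are ranked by multiset size then lexicographically, a rule
invented for determinism. Ladder annotation decomposes each consecutive
mass difference, matches the terminal ion against the aglycone library
directly and through the +24 amu [Agly+(42−18)−H]⁻ marker offset, and
enumerates every consistent path; unexplained steps are reported, not
raised. Mass conservation (precursor − Σ losses = terminal ion) holds
exactly for every path. Out of scope: isotope patterns, multiple charges,
positive mode, structure elucidation beyond residue multisets.

## Numerical and testing choices

- Intervals are half-open and 0-based on the aligned grid everywhere.
- The default test grid (1 500 points) and the benchmark design (20
  metabolites, 2 varieties × 3 days × 2 conditions × 2 replicates, both
  wavelengths) are the package's chosen problem sizes; every simulation
  parameter above is config-exposed.
- Monte-Carlo checks in the suite use fixed seeds; family-wise error
  control is verified across 500 simulated null datasets of 104
  metabolites, classification power across 100 datasets at effect size 2
  and noise sd 0.25, correlation recovery across 200 datasets, and COW and
  clustering optimality against exhaustive enumeration on small instances.
- Known limitations: COW assumes a shared grid length and a reasonable
  reference (a median over heavily mis-aligned traces can smear); peak
  detection assumes peaks are concave at the chosen smoothing scale, so
  shoulders merging into one concave run are reported as one peak
  (co-elution), consistent with the multi-name labeling downstream; the
  exhaustive clustering route is exponential and capped at 12 profiles.
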