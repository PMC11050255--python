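# Methods

## The models

`hutchgs` implements genomic best linear unbiased prediction (GBLUP) for a
half-sib livestock population. The univariate linear mixed model for one
trait is

    y = X b + Z a + e,      a ~ N(0, G σa²),      e ~ N(0, I σe²)

where `y` holds one record per phenotyped animal, `b` are categorical fixed
effects (sex, batch, optionally year and an extra environmental factor),
`Z` maps records to animals, and `G` is the VanRaden method-1 genomic
relationship matrix computed from SNP dosages: with allele frequencies
`p_j` estimated from the analysed animals and `W = dosage − 2p`,

    G = W W' / (2 Σ_j p_j (1 − p_j)).

Heritability is `h² = σa²/(σa² + σe²)`.

The multivariate model stacks `t` traits with genetic covariance `M ⊗ G`
and residual covariance `R ⊗ I` (residuals of different animals are
independent; residuals of different traits on the same animal have
covariance `R_ij`). The genetic correlation between traits `i` and `j` is
`r_G = M_ij / √(M_ii M_jj)`. Per-trait record sets may differ — a trait
recorded on only part of the herd contributes whatever information it has,
and the genetic covariance stays estimable through `G` even when two traits
share no phenotyped animal.

## REML estimation

*Univariate.* `Z G Z'` is eigendecomposed once; `y` and `X` are rotated
into the eigenbasis, which diagonalises the covariance for every variance
ratio `δ = σa²/σe²`. The residual variance is profiled out analytically and
the restricted likelihood is maximised over `log δ` by bounded Brent search
(domain ±25 on the log scale, converged at `xatol = 1e-10`). A ratio pushed
to the search boundary is reported with `boundary=True` and `h² ≈ 0` (or
≈ 1) rather than as an error; variance components are floored at
`1e-10 ×` the phenotypic variance. Standard errors come from the inverse
average-information (AI) matrix at the optimum; the `h²` standard error is
delta-method.

*Multivariate.* EM-REML with AI acceleration over the distinct elements of
`(M, R)`. EM updates are the classic conditional-expectation forms
`M ← E[A'G⁻¹A | y]/q`, `R ← E[E'E | y]/q` and never decrease the restricted
likelihood; after five EM steps (or earlier once the relative likelihood
change falls below 1e-3) an AI step `θ + AI⁻¹s` is attempted each
iteration, accepted only if it does not decrease the likelihood, and
otherwise halved up to six times before falling back to the EM update.
Iterates are kept inside the PSD cone by eigenvalue clipping at
`1e-8 × trace`. Convergence is a relative log-likelihood change below 1e-8
(default cap 200 iterations); non-convergence returns the last iterate with
`converged=False` and a warning rather than raising. Genetic correlations
carry delta-method standard errors from the inverse AI matrix.

Two interchangeable backends evaluate the likelihood and the EM/AI
quantities, and agree to machine precision on balanced data:

- **balanced** (all traits recorded on the same animals with the same
  fixed-effect design): everything factorises into `q` independent `t × t`
  blocks in the eigenbasis of `G`, plus a low-rank fixed-effect correction —
  `O(q t³)` per iteration, which is what makes twenty-seed recovery sweeps
  at `n = 1000` cheap;
- **general** (arbitrary per-trait missingness, e.g. cross-validation masks
  or the slaughter-trait subset): dense record-level `V`, intended for the
  moderate problem sizes where it is used.

A subtlety both backends respect: `E[A'G⁻¹A]` is computed through the
selection identity `G⁻¹ Cov(a, y) = (M ⊗ I)` restricted to record columns,
so no `G⁻¹` is ever formed. This matters because the VanRaden `G` is always
singular — column-centering gives it the all-ones null vector.

## BLUP

For the same reason, the mixed-model equations are solved in their
equivalent variance form,

    b̂ = (X'V⁻¹X)⁻¹ X'V⁻¹y,      â = (M ⊗ G) Z' V⁻¹ (y − X b̂),

with `V` built over the kept records only. This is exact for singular `G`
(and singular `M`), needs no bending in normal operation, and returns GEBVs
for *every* animal in the GRM — unphenotyped and masked animals are
predicted through their genomic relationships, which is precisely the
channel that lets a multivariate model use an auxiliary phenotype of a
validation animal to sharpen its focal-trait GEBV. If the record covariance
cannot be factorised, one ridge of `1e-10 ×` its mean diagonal is attempted
before erroring.

## The synthetic populations

No rabbit data ship with the package; every analysis runs on populations
the `simulate` module generates.

- **Pedigree**: a paternal half-sib design — each sire mated to several
  dams, one litter per dam. Defaults aim at ~1,000–1,500 offspring (the
  recovery scale is 20 sires × 5 dams × 10 kits = 1,000). The mating counts
  are deliberate conventions, not estimates: the study system is described
  only as a parent herd with half-sib offspring.
- **Genomes**: founders draw haplotypes allele-by-allele at frequencies
  uniform on `[maf_floor, 1 − maf_floor]` (default floor 0.05); offspring
  receive gametes with Poisson-distributed crossovers (mean = chromosome
  length in Morgans, positions uniform on the genetic map; 1 cM ≡ 1 Mb for
  physical coordinates). Dosages are exact {0,1,2} unless the optional
  `dosage_noise` switch blurs them toward imputed expected dosages.
- **Traits**: `n_qtl` markers (default 500) are drawn as *shared* causal
  loci for all traits; per-QTL effect vectors are multivariate normal with
  the target genetic-correlation matrix. Correlation therefore lives at the
  marker level — a GRM built from a marker subset faces a genuine genetic
  architecture, which is what makes the marker-density experiment
  meaningful. True breeding values are rescaled per trait so the additive
  variance equals `h²` on a unit-phenotypic-variance scale; residuals are
  Gaussian with variance `1 − h²` and diagonal covariance by default (the
  multivariate REML still estimates a full `R`, and recovery tests check
  its off-diagonals near zero). Categorical fixed effects (default: sex
  with 2 levels, SD 0.2; batch with 5 levels, SD 0.15 — magnitudes chosen
  as plausible nuisance effects a breeder would fit) are added on top, and
  each trait is masked independently with probability
  `1 − phenotyped_fraction` (the slaughter-trait preset uses 798/1159,
  matching the fraction of the study herd that was slaughtered).
- **Truth presets**: the nine published heritabilities (0.054–0.258) and
  the published genetic correlations (−0.246–0.914) are bundled in
  `presets`. Correlations were published only for pairs involving the three
  weight traits; the remaining slaughter-trait pairs are completed
  synthetically by a single-factor rule through W70
  (`r_ij = r_iW70 · r_jW70`) and the matrix is bent to the nearest PSD
  correlation matrix. That completion is a modelling convenience, clearly
  synthetic, and only affects the 9-trait fixture — the recovery targets
  use published pairs exclusively.

What the generator does **not** emulate: linkage disequilibrium beyond what
one generation of gene dropping creates, imputation error structure beyond
the dosage-noise switch, dominance/epistasis, maternal or litter
environmental effects, selection, and structured (non-random) missingness.
Passing recovery tests therefore show the estimators are correct under the
stated model, not that real rabbit data meet that model.

## The experiments

- **Cross-validation**: animals phenotyped for the focal trait are split
  into `k = 10` folds (sizes within 1). Per fold the focal phenotypes of
  the validation animals are masked, variance components are re-estimated
  on the remaining records (the strict default; `reestimate_per_fold=False`
  offers the cheaper estimate-once shortcut), GEBVs are solved, and the
  validation predictions are pooled. Accuracy is the Pearson correlation of
  pooled validation GEBVs with raw phenotypes — one `r` per full 10-fold
  cycle; mean-of-fold-correlations is available as a method, and
  correlating against fixed-effect-adjusted phenotypes is deliberately not
  the default. In multivariate runs only the focal trait is masked;
  auxiliary traits of validation animals stay observed, the only reading
  under which multi-trait gains of the observed size are possible.
- **Density titration**: for each density in the grid and each of (by
  default) 30 replicates, a uniform random marker subset is drawn, the GRM
  rebuilt, `h²` re-estimated and a fresh cross-validation run. Subsets are
  a pure function of `(base_seed, density, replicate)`; fold assignments
  are re-randomised per replicate with seeds derived from the same triple.
  Replicate means ± SDs (the ± values are treated as SDs, not SEs) shape
  the rise-and-plateau curves.
- **Comparison tests**: accuracy vectors are compared with a Welch
  (unequal-variance) two-sample t-test by default — the pooled Student
  variant sits behind `equal_var=True`. Zero-variance degenerate limits are
  handled exactly (`t = 0, p = 1` for identical constants).

## Numerical and design choices

- Allele frequencies for `G` are always recomputed from the analysed
  animals (VanRaden method 1 practice; no base-population frequencies are
  available). Monomorphism is `p(1−p) ≤ 1e-12`; no MAF filter by default,
  a `--maf` flag exists. If a numerically indefinite `G` ever blocks a
  factorisation, `ε I` with `ε = 1e-6 ×` mean diagonal is added and logged
  loudly.
- Fixed factors are coded with an intercept and treatment contrasts
  (first observed level as reference); levels emptied by missingness are
  dropped with a warning, and rank-deficient designs error naming the
  aliased columns. Factors are crossed, not nested.
- The residual covariance symbol overlap in two-trait notation (σe12) is
  read as the residual *covariance* between traits 1 and 2.
- Repeated records per animal and trait do not occur, so `Z` is a
  selection matrix; the code nevertheless keeps the general record-to-
  animal mapping to handle masking.
- In cross-validation the per-fold REML is warm-started from the full-data
  fit. The warm start only sets the initial iterate of an optimisation run
  entirely on training records; it does not move the optimum.
- Problem sizes used by the shipped checks were chosen to keep a full run
  on one CPU comfortable: recovery sweeps at `n = 1000` with 5,000 markers
  and 20 seeds; the model-comparison repetition at `n = 400` with 2,000
  markers; the density grid at `n = 500` over 250–8,000 of 10,000 markers
  with 10 replicates. These are scaled-down analogues of the study's
  0.5K–2M grid and 30 replicates; the claims they check are directional
  (rise, plateau, multi-trait superiority), which survive scaling.

## Known limitations

- Heritability estimates carry a small downward bias (order 0.01–0.02)
  when only 500 of the markers are causal: the GBLUP prior spreads variance
  over all markers. With a fully polygenic architecture the estimates are
  unbiased.
- Genetic-correlation estimates for trait pairs involving a very
  low-heritability trait (e.g. a feed-conversion-ratio-like trait at
  h² ≈ 0.05) have a wide sampling distribution at `n = 1000` and a
  small-sample bias away from zero — the correlation denominator is noisy
  near the variance boundary. The bias shrinks with population size; it is
  a property of REML at this scale, not of the implementation (the
  optimiser has been checked against direct likelihood maximisation).
- The AI standard errors are asymptotic; near boundaries they understate
  uncertainty.
- Single-step (pedigree + genomic) models, Bayesian marker models,
  dominance and genotype-by-environment interactions are out of scope.
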