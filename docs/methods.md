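# Methods

## The problem and the criterion

Microbiome–metabolome association studies cannot by themselves distinguish a
metabolite concentration that is *caused* by microbial secretion from one
that merely *covaries* with the microbiome through shared host factors
(diet, age, disease state). `fluxpattern` implements a criterion that makes
this distinction from observational data by bringing in a second, knowledge-
based source of information: constraint-based (COBRA) community models,
which predict each sample's net metabolite secretion capacity from its
community composition alone, under diet constraints held fixed across all
samples. Because the flux predictions are a deterministic function of
composition, they cannot carry host confounding; if the *pattern* of
species–flux associations across species correlates with the pattern of
species–concentration associations, variance flowing from the community into
the metabolite pool is the only available explanation.

Formally, for sample vectors of relative abundances `a` (on the simplex,
length L), latent host factors `h` (length K), net secretion fluxes `f`
(length J) and concentrations `c` (length J), the package's generative model
is the linear structural system

    a = B_ah h + u
    f = B_fa a
    c = B_cf f + B_ch h + eps

with `u ⫫ h`, `eps ⫫ (h, f)`, `B_cf` diagonal, and two structural
constraints:

* **zero column sums** — each column of `B_ah` sums to 0, because host
  effects displace mass *within* the simplex (the abundances of all species
  always sum to one, so whatever a host factor adds to some species it must
  remove from others);
* **orthogonality** — `B_fa B_ah = 0`: the flux map is derived from genome
  content and knows nothing about host factors.

Define per-species association statistics with standardized abundances
(`VAR(a_l) = 1`): `b_ca(l) = COV(c_j, a_l)` (in vivo) and
`b_fa(l) = COV(f_j, a_l)` (in silico). Under the constraints above,

    COV_across_species(b_ca, b_fa) != 0  <=>  B_cf[j,j] != 0,

i.e. the species-wise covariance of the two patterns is nonzero exactly when
the flux causally feeds the concentration. A positive pattern slope reads as
net secretion; a systematically inverted pattern reads as net consumption
(the "secretion capacity" of a bidirectionally transportable metabolite then
acts as a consumption metric). Standardization is not cosmetic: without it
both statistics scale with the per-species abundance variances, which would
manufacture covariance between the patterns.

## Pipeline

1. **In vivo screen** — per (species, metabolite): OLS of log concentration
   on species presence (0/1) or standardized abundance, adjusting for the
   study covariates, with heteroscedasticity-robust (HC1, optionally HC3)
   standard errors. Zero concentrations are below-detection values and are
   dropped under the log. Species present in < 10% of samples and
   metabolites detected in < 50% of samples are excluded. BH-FDR across the
   whole screen.
2. **In silico screen** — identical regressions with the community
   net-secretion capacity (maxProd) as response, untransformed (flux
   distributions are not consistently right-skewed), all samples kept.
3. **Pattern analysis** — per metabolite, OLS of the in vivo pattern on the
   in silico pattern across species. Because the per-species coefficients
   are mutually dependent (compositional data, correlated metabolites), the
   parametric F-test of the slope is too liberal. Significance is assessed
   by shuffling the metabolite's flux vector across samples and recomputing
   the whole in silico screen per permutation; the statistic is
   `F = R²/(1−R²)·(n−2)` with the add-one rule
   `p = (1 + #{F_perm ≥ F_obs}) / (B + 1)` (p is never 0 and never below
   1/(B+1)). The sign table of the two patterns is tested against the same
   permutation distribution, both tails separately (concordance and
   discordance are both findings); the single reported sign p-value is the
   two-sided `2·min(tails)` capped at 1. Classification: significant
   (either test, default α = 0.05) with positive slope and majority sign
   agreement → concordant; significant with negative slope → discordant;
   otherwise none. A metabolite called concordant in one comparison set and
   discordant in another is flagged as inconsistent rather than silently
   kept. Permutation p-values are additionally BH-adjusted across
   metabolites within each comparison set.

The permutation engine computes per-species adjusted coefficients by
Frisch–Waugh–Lovell residualization (residualize the predictors against the
covariates once; each coefficient is then a ratio of inner products). This
is algebraically identical to the full OLS coefficient — asserted to 1e-10
against statsmodels in the tests — and makes thousands of permutations a
sequence of small matrix products. Reported (non-permutation) rows always go
through statsmodels with robust covariance.

## Community models and FVA

The toy-scale community engine follows the mgPipe construction. Pan-species
models are reaction unions over strains (identical reaction ids must agree
in stoichiometry; bounds merge to the widest interval) with the biomass
stoichiometry averaged over all members. A sample's community model joins
the present microbes (zero-abundance microbes are excluded entirely, not
included at weight zero) through a shared lumen: each microbe's exchange
reactions become lumen-transfer (IEX) reactions; every lumen metabolite gets
one diet sink and one fecal sink; a community biomass reaction consumes
abundance-weighted per-microbe biomass carriers, which enforces
`v_bm_i = a_i · v_cm` by mass balance; and coupling constraints
`|v_IEX| ≤ 400·v_bm` pin each microbe's exchanges to its biomass flux.
Community biomass is bounded to [0.4, 1] mmol/person/day (fecal excretion
once every three days to daily).

Sign conventions: sinks are written `metabolite → ∅` with positive flux
leaving the compartment; diet supply enters as a *negative* diet-sink flux,
so a diet of 10 units sets diet-sink bounds [−10, 0], and un-supplied diet
sinks stay closed at [0, 0]. Fecal sinks default to [0, 1000], leaving the
excretion side effectively unconstrained (the upper bound is configurable). Diet and fecal compartments are realized as
these tagged sink reactions directly on the lumen metabolite — intermediate
carrier metabolites and pass-through transports would enlarge the matrix
without changing the feasible flux polytope.

FBA maximizes community biomass (optimum `w`); FVA then fixes the biomass
reaction to `[w, w]` (a `biomass_fraction γ` option gives the common
`≥ γ·w` relaxation) and minimizes/maximizes the four sink fluxes of each
lumen metabolite independently. The net capacities are
`maxProd = |maxFaecal + minDiet|` and `maxUpt = |minFaecal + maxDiet|`.
All LPs go through HiGHS (scipy.optimize.linprog) at 1e-9 feasibility and
optimality tolerances; FVA values below 1e-8 are reported as exact zeros so
the absolute values above cannot flip on solver noise. Numerically stuck
FVA subproblems are retried once with the biomass lower bound relaxed by a
factor (1 − 1e-6).

## The simulator's defaults and what they emulate

The generator emulates: compositional abundances driven by latent host
factors; fluxes that are exact linear functions of abundances;
concentrations as flux effect + host confounding + noise; and zero-inflated
right-skewed concentration marginals (the structural `c` lives on the log
scale; the emitted metabolome is `exp(c)` with the lowest 5% of each
metabolite censored to zero as below-detection values).

* `h ~ N(0, I_K)`; `u ~ symmetric Dirichlet(α)`, α default 1 (flat on the
  simplex — a maximally dispersed community); `eps ~ N(0, σ_eps²)`,
  σ_eps default 1 on the log-concentration scale.
* `B_ah`: standard-normal columns projected onto the zero-sum subspace,
  unit column norm × `confound_scale` (default 1). `B_fa`: standard-normal
  rows projected onto the orthogonal complement of the `B_ah` column span,
  row norm `flux_scale` = 10 — net-secretion fluxes (mmol/person/day) sit
  two to three orders of magnitude above relative abundances. An
  `ortho_noise` knob re-injects a within-span component to probe the
  "approximate orthogonality" relaxation (default 0 = exact).
* `B_cf` diagonal: `+effect_scale` (secretion), `−effect_scale`
  (consumption), 0 (null), random signs (mixed). The slope-detectable grid
  used in the operating-characteristic tests is `effect_scale ∈ {0.5, 1,
  2}`, corresponding to microbiome-attributable shares of log-concentration
  variance from a few percent to ≈ 20% — the regime the method is meant for.
* Simplex reconciliation: the linear host displacement `s·B_ah h` is added
  to `u` and rows are repaired (clip at 0, renormalize). The scale `s` is
  auto-halved until < 5% of rows need repair; passing an explicit `s` that
  forces repair on > 50% of rows is an error. Because a flat Dirichlet puts
  substantial mass near zero abundances, the auto rule yields small `s` —
  host effects displace composition by a small fraction of its intrinsic
  variation, which keeps the repair bias negligible while leaving the
  confounding channel active. The realized (post-repair) coefficients are
  re-estimated by per-species regression and reported alongside the nominal
  matrix in the truth sidecar.

One consequence of the flat-Dirichlet choice: simulated abundances are
strictly positive except where the simplex repair clips them, so species
*presence* varies only through those few clipped zeros and presence-based
screens carry little signal on simulated cohorts — the abundance-based
comparison sets are the informative ones there. On real data, where
absence is common, both predictor encodings are informative and
complementary (absence changes the community model structurally).

What the generator does **not** emulate: nonlinear structural equations,
host←microbiome feedback, time dynamics, measurement error in abundances,
and the discrete model-structure changes that species absence induces in
real community models (simulated fluxes are globally linear in abundance).
Passing tests therefore validate the statistical machinery and the
identification logic, not the biological fidelity of any particular
reconstruction set.

## Numerical and design choices

* Robust covariance flavor is HC1 by default (HC3 selectable) — the
  conventional small-sample sandwich correction in this literature.
* Natural log for concentrations; the base only rescales coefficients and
  cancels in the pattern slope's significance.
* Standardization uses the n−1 sample variance with mean centering.
* Prevalence/detection boundaries are inclusive ("at least"): a species in
  exactly 10% of samples and a metabolite detected in exactly half are kept.
* The pattern regression uses **all** species by default; a
  `significant_only` option restricts the response to species whose in vivo
  association reached q < α (then the permutation comparison is restricted
  to the same species set).
* Permutation counting uses `≥` (conservative) and one master seed;
  per-metabolite substreams are spawned from (seed, comparison-set index,
  metabolite index) so results are reproducible under any execution order.
* Ties in the sign table: coefficients exactly zero are excluded from the
  table (and noted via the table margin summing below the species count).
* Degenerate inputs: constant responses return a zero coefficient with
  p = 1; zero-variance predictors are dropped from standardization;
  constant flux columns and zero-variance in silico patterns raise a
  degenerate-pattern error, reported as classification "none".
* Test and acceptance problem sizes: operating characteristics are
  estimated at n = 2,000, L = 40, K = 3, J = 5 with 50–500 replicates and
  B = 200–500 permutations; the per-cohort analytic identities use
  n = 10,000. These sizes give Monte-Carlo errors comfortably below the
  asserted margins while keeping the default suite quick.

## Known limitations

Causal claims are community-level: the method cannot attribute causality to
individual species (ecological causation and ecological confounding are not
separable in the community model), and it cannot detect causal metabolites
whose in vivo variance is dominated by absorption or host physiology. A
missing pattern is uninformative — low power, measurement error, incomplete
reconstructions and behavioral confounding all produce the same null
outcome. The LP engine is deliberately toy-scale: dense matrices, one LP
per FVA bound; it is correct (vertex-enumeration-exact on small models) but
not engineered for hundreds of species.
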