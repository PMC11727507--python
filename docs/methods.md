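# Methods

## Model and decomposition

The pedigree inbreeding coefficient of animal j is F_j = ½ a(s_j, d_j),
half the additive relationship of its parents.  Running the tabular
recursion

    A(j, m) = ½ (A(s_j, m) + A(d_j, m))            (m earlier than j)
    A(j, j) = ½ (A(j, s_j) + A(j, d_j)) + φ_jj

with the Mendelian-sampling diagonal

    φ_jj = ¼(1−F_s) + ¼(1−F_d)   (both parents known)
         = ½ + ¼(1−F_l)          (one parent l known)
         = 1                     (founder)

and φ zeroed everywhere except at one ancestor k produces the partial
relationship matrix A^(k); the partial inbreeding coefficient is
F_j(k) = ½ A^(k)(s_j, d_j).  Algebraically A^(k) = m_k L_{:,k} L_{:,k}',
the k-th term of the LDL' factorisation of A, so Σ_k F_j(k) = F_j exactly
— this is a decomposition of the Mendelian-sampling *variance*, not a
partition by coalescence location.  The distinction matters: in a pedigree
where inbreeding is created through a non-founder ancestor, part of the
coefficient is credited to that ancestor's own sampling term and part to
its parents, even though every identity-by-descent event physically
coalesces in the non-founder.  The test suite contains a gene-dropping
oracle that samples exactly this decomposition by a with-replacement
attribution cascade whose mass at each animal equals its φ term.

Implementation notes:

- The per-ancestor recursion is restricted to the sub-pedigree of k and
  its descendants; entries of A^(k) outside it are provably zero.  Only
  ancestors present on both parental sides of some inbred animal are swept
  (candidate screening via packed ancestor bitsets); the unrestricted sweep
  is verified to give identical triplets.
- Total inbreeding is computed either by the dense tabular method (small
  pedigrees) or by per-animal ancestor tracing over the L-row identity
  1 + F_j = Σ_k L²_jk m_k; both agree to 1e−12 and with the decomposition
  closure to 1e−10.
- Unknown parents are unrelated founders; no unknown-parent groups.
  Selfing is accepted with a warning (the recursion applies unchanged);
  an animal appearing as both sire and dam is rejected only when sex codes
  are supplied.
- Pedigree ordering is a stable topological sort keyed by (birth year if
  present, input order), so all sparse structures are reproducible.

The load design is K = T(I−P) with T the partial coefficients and P the
parent-pointer matrix (0.5 per known parent slot).  K is computed exactly
as a sparse product, then entries with |K| ≤ 0.01 are dropped (the default
cutoff, configurable; the synthetic-data generator uses 0 so that the
generative model is exact).  T is kept unthresholded for diagnostics, and
strict lower-triangularity of K is asserted, not assumed.

## Single-locus theory conventions

The variance components printed by `locus_moments`,

    σ²_i  = 2pq α_F²,
    σ²_u  = 2pq a² + 2pq (q−p)² d²,
    σ_u,i = −4pq F/(1+F) (q−p)² d²,

follow the gene-action decomposition: σ²_u is the sum of the
Hardy-Weinberg variances of the additive part (g−2p)a and the dominance
part (g−2p)(q−p)d of the breeding value, and σ_u,i is the covariance of
the dominance part with the load (g−2p)α_F.  Cross-terms between the a-
and d-components (which appear in the raw single-locus genotype variance
when both are non-zero) are not included; with this convention the squared
correlation r²_ui reduces to the dominance fraction of σ²_u and is free of
F.  σ²_i is on the transmitted (HW) scale; the realized load variance
among genotypes drawn at inbred frequencies is (1+F)·σ²_i, which is what
the simulation check `empirical_check` compares against.  r²_ui is defined
0 (flagged) when either variance vanishes.

## REML

Both models are fitted by maximizing the restricted likelihood through the
mixed-model equations: −2logL = (n−p)log 2π + log|R| + log|Σ| + log|C| +
y'Py, evaluated with one sparse factorization of the symmetric coefficient
matrix C per trial point (SuperLU, MMD ordering in symmetric mode;
log|A| = Σ log m_j from the Henderson decomposition).  The optimizer is a
Newton iteration preconditioned by the average-information matrix
(AI_jk = ½ f_j'P f_k with f_j = ∂V/∂θ_j · Py, each P·f one extra solve on
the current factorization); the score vector is obtained by forward finite
differences of −2logL.  Safeguards:

- variances floored at 1e−8 of the phenotypic variance; σ²_i may reach 0
  exactly, where the full model degenerates to the reduced one and the
  likelihood is evaluated on the reduced structure;
- G is bent back to the PSD cone (eigenvalue floor 1e−8·trace) after every
  trial step; parameters pinned at a floor with an outward score are
  dropped from the Newton system (active set);
- step halving on the Newton direction, then a small scaled-gradient step;
  convergence when |Δ(−2logL)| < 1e−8·(1+|−2logL|) together with a maximum
  relative parameter change below 1e−6, or after consecutive stationary
  steps on a flat ridge (degenerate PSD-cone edges produce parameter drift
  at no likelihood gain);
- every full-model fit ends with a boundary polish: the reduced-model
  optimum (σ²_i = 0 lies inside the full parameter space) is located and
  taken when it beats the interior search.  Passing the components of an
  already-fitted reduced model (`rm_components`) seeds that polish, which
  guarantees FM ≥ RM likelihood numerically and hence a non-negative LRT.
- standard errors come from the inverse AI matrix at convergence; at the
  σ²_i = 0 boundary the AI of the full parameter vector is evaluated with
  the reduced-model projection (∂V/∂σ²_i exists there), so boundary
  estimates carry finite SEs.

An EM fallback is not used: EM updates require traces of blocks of the MME
inverse, which the available sparse solvers cannot produce selectively;
the active-set/step-halving combination plays the same stabilizing role.

b enters as a fixed covariate on the total inbreeding f ∈ [0, 1], so b̂ is
per fully inbred descendant; a constant covariate is dropped with a
warning.  Fixed factors are made full rank by dropping the last level.
Load effects i are carried for all pedigree animals (they share A with u),
so animals without inbred progeny still receive predictions through
relatives.  The LRT of FM against RM uses the boundary mixture:
p = ½ Pr(χ²₁ ≥ LRT), p = 1 at 0; statistics below −1e−6 raise (nesting
violation), tiny negatives are clipped with a warning.

## Synthetic data

The generator emulates a managed dairy-sheep-like population:

- overlapping generations (parents drawn from the previous two cohorts),
  few sires, many dams, sexes assigned at birth (default ratio ½), records
  only for females;
- the `avoid_common_grandparents` policy excludes any pair sharing an
  ancestor within two generations (self, parents, grandparents).  A
  literal common-grandparent check would still admit parent–offspring and
  founder-offspring sib matings (founders have no recorded grandparents),
  so the stronger form is used; the closest permitted loops then lie
  deeper than two generations and no partial coefficient above 0.125 can
  arise from them.  Infeasible pairings fall back to a random sire with a
  logged count;
- genetic effects (u, i) are simulated by Mendelian-sampling recursion
  down the pedigree — founders N(0, G), non-founders parent average plus a
  residual with covariance m_j G — which is exact in distribution for
  N(0, G ⊗ A) without any dense factor of A;
- records follow y = μ + flock-year-parity effect + f b + u + (K i) + p +
  e, with the number of lactations per ewe 1 + Poisson(r − 1) around the
  default r = 3.7;
- default population shape (120 founders, 10 generations, 12 sires and
  110 dams per generation, 3 offspring per dam, ≈ 2 900 animals) was
  chosen to reproduce the published inbreeding structure under the
  avoidance policy: mean F ≈ 0.013, ≈ 55% of animals inbred, inbreeding
  arising through multi-generation loops with > 95% of partial
  coefficients below 0.01.  Default variance components (σ²_u = 800,
  σ²_i = 10 000, σ_u,i = −300, σ²_p = 400, σ²_e = 1300 L², b = −110 L,
  mean 193 L) sit on the published milk-yield scale.

What the generator does not emulate: selection and purging dynamics,
progeny-testing structure, genomic (locus-level) variation, heterogeneous
flock sizes, or missing-pedigree patterns.  Passing tests therefore show
that the estimator recovers the model it assumes at desk scale, not that
real data satisfy that model.

## Simulation studies and their sizes

All stochastic suites run at sizes chosen for a single desktop CPU:

- *Recovery*: 20 replicates of ≈ 2 900 animals, 2 records per ewe, truth
  as above; each component must lie within ±2 reported SE of truth in
  ≥ 80% of replicates.  Random mating is used here: under the avoidance
  policy partial coefficients are so small that σ²_i is estimated at the
  boundary in most replicates and the coverage check would be vacuous
  (huge SEs cover everything).  Random mating keeps closer loops in the
  design and gives the experiment actual discriminating power.
- *Null calibration*: 200 replicates of ≈ 500 animals under σ²_i = 0; the
  rate of LRT > 2.71 is compared with the mixture's nominal 5% by an exact
  binomial test (acceptance at p > 0.01).  Observed behaviour: ≈ 7% with
  about half the replicates exactly at 0, consistent with the ½χ²₀ + ½χ²₁
  reference.
- *Sign recovery*: the u–i covariance carries very little information at
  desk scale (a few log-likelihood units across the whole PSD range even
  at |r| ≈ 0.9), so the sign-recovery property is checked where it is
  identifiable: 10 replicates at ≈ 2 900 animals, 3.7 records per ewe and
  σ_u,i = −2500; replicates with an interior σ̂²_i must recover the
  negative sign in the majority.
- *Oracles*: decomposition closure on 200 random pedigrees (|ΣF_j(k) −
  F_j| < 1e−10); gene-dropping at 10⁶ replicates within 3 Monte-Carlo SE
  on ≤ 12-animal pedigrees; dense-algebra checks of A⁻¹, the restricted
  likelihood and BLUP solutions at 1e−8–1e−6; single-locus moments against
  genotype enumeration at 1e−12 over 10⁴ parameter draws.

## Known limitations

- The per-ancestor sweep is quadratic in the descendant-set size per
  candidate; it is comfortable at 10³–10⁴ animals but would need blocking
  or compiled kernels at national-evaluation scale.
- Individual load predictions at desk scale are very inaccurate (SEs of
  σ²_i are of the order of the estimate or larger); this mirrors the
  published analysis, where significance required millions of records.
- The LRT mixture treats σ²_i as the single boundary parameter; the
  covariance σ_u,i vanishes with it (|σ_u,i| ≤ √(σ²_u σ²_i)), and the
  finite-sample null is slightly heavier than ½χ²₁ in the upper tail,
  visible as the ≈ 7% exceedance above.
- Fixed-effect identifiability uses drop-last dummies; rank-deficient
  designs beyond that (e.g. empty factor cells combined with the f
  covariate) are not repaired automatically.
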