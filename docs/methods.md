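# Methods

## Model and exactness guarantee

`tierblup` works with the single-trait animal model

    y = Xβ + Zu + e,   u ~ N(0, K σ²_u),   e ~ N(0, I σ²_e),

with K the numerator relationship matrix A implied by the pedigree, or
the combined pedigree–genomic matrix H in single-step analyses. Variance
components are user inputs throughout; no REML is attempted. Fixed
effects carry a flat prior, so Henderson's mixed-model equations (MME)
deliver the posterior means of (β, u) and the inverse of the coefficient
matrix their posterior covariance (the prediction-error covariance,
PEV).

The updating result rests on a structural condition on the pedigree.
Partition the animals into distant external ancestors *d*, parents of
current animals *a*, and current animals *c*. If no animal in *d* is a
parent of an animal in *c*, and no d-animal shares offspring with a
c-animal, the (d, c) block of the sparse inverse relationship matrix is
exactly zero. Then the posterior of (β_common, u_a) from an external
evaluation of d ∪ a — its mean (β̃, ũ_a) and covariance C — together
with the aa-block E^aa of the external-pedigree inverse, is a
*sufficient* summary: the current-tier MME assembled from the current
least-squares equations, the precision blocks of C⁻¹, and the
full-pedigree inverse blocks (F^aa − E^aa), F^ac, F^cc reproduce the
joint-analysis solutions and PEV exactly. The same holds under an
H-prior external analysis when genotyping is confined to the external
set, because H⁻¹ then differs from the pedigree inverse only inside the
external block, leaving H^ac = F^ac and H^cc = F^cc.

Two consequences shape the interfaces:

- The posterior package (means, C, E^aa, variance components, id order)
  is the *only* object crossing the external→current boundary. The
  current analysis never sees external phenotypes, genotypes, or
  anything about the d-animals beyond what E^aa encodes.
- Current phenotypes on a- or d-animals would violate the conditional
  independence the derivation assumes, so they are rejected with an
  error rather than silently absorbed.

An equivalent non-Bayesian route — absorbing the d-equations of the
joint MME by a Schur complement and substituting the inverse external
PEV — is implemented as `mme.absorb` and checked matrix-by-matrix
against the updating system in the tests; it requires no normality
assumptions.

## Pedigree handling

Pedigrees are topologically ordered at construction (Kahn's algorithm);
cycles and self-parenting are hard errors, and parents never declared as
animals are auto-registered as founders with a warning. Unknown parents
are founders with prior variance σ²_u; unknown-parent groups are not
implemented.

The d/a/c partition is represented as integer index arrays into the
topologically ordered pedigree, and all block extraction is by fancy
indexing. We deliberately do not reorder equations into contiguous
d, a, c blocks: an a-animal may have offspring in *d* (a nucleus parent
whose other progeny stay in the nucleus), so that block arrangement is
not in general topological, while index arrays are order-agnostic and
equally cheap.

`partition_tiers` derives a = {known parents of c} \ c and d = the rest.
Any known parent of a c-animal is thereby promoted into *a*, including
grandparents of other current animals when the current set spans
generations; the hard errors are reserved for genuine violations — a
current animal that parents an external animal, or a hand-built
partition that leaves a parent of a c-animal in *d*.

## Relationship machinery

- **Inbreeding** uses the Meuwissen–Luo algorithm (exact, founder F = 0).
  Mendelian-sampling variance is d_i = ½ − ¼(F_s + F_d) with both
  parents known, ¾ − ¼ F_known with one, 1 with none; the one-parent
  convention is validated against the dense tabular A rather than taken
  on authority.
- **Sparse A-inverse** follows Henderson's rules with m_i = 1/d_i; the
  classic 2 / 4⁄3 / 1 constants remain available (`with_inbreeding=False`)
  for textbook reproduction, but the inbreeding-aware rules are the
  default — the exactness identities require one consistent A on both
  sides of every equation.
- **F^aa − E^aa** can be accumulated in a single pass over the current
  animals (only their (parent, parent) Henderson contributions with both
  parents in *a* survive the difference). The updating MME itself
  consumes E^aa from the posterior package and subtracts it from F^aa:
  the package is the authoritative boundary object, and the updated
  solutions are sharply sensitive to its content — corrupting a single
  entry measurably breaks the joint-analysis agreement, which the
  verification path exploits as a guard. The single-pass construction is
  exposed and cross-checked against the subtraction in the tests.
- **G** is VanRaden method 1 with observed allele frequencies by
  default, blended as 0.95·G + 0.05·A_gg for positive definiteness. The
  exactness theorems hold for *any* positive-definite H of the stated
  support, so the blend weight is a conditioning choice, not a modelling
  one; the test suite treats G as a free input.
- **H⁻¹** adds (G⁻¹ − A_gg⁻¹) on the genotyped block of F⁻¹ and refuses
  numerically singular G or A_gg with a hint to blend harder.

The dense tabular A (the recursive textbook construction) is retained
purely as the independent oracle; it is capped at 4000 animals.

## Solvers and posterior covariance

Direct solves use scipy's sparse LU factorization — for these symmetric
positive-definite systems it is exact to the same precision as a
Cholesky factorization. PCG with a Jacobi preconditioner is provided
because organisations that cannot factorize can still reconstruct the
few needed PEV columns by solving against unit right-hand sides one
column at a time; `posterior_covariance` implements both routes and the
tests confirm they agree. PEV blocks are symmetrized after extraction.

The single-site Gibbs sampler draws each location effect from its full
conditional normal at fixed variance components, matching the MCMC
route to posterior means and covariances; it is seeded and
reproducible, and the acceptance script compares it against the direct
solver using batch-means Monte-Carlo standard errors (100 batches).

Tolerance for "identical": 1e-8 relative to the largest PEV diagonal,
reflecting double-precision direct solves; measured discrepancies on the
study designs sit near 1e-13.

## Simulator

The generator emulates the data structure the method is exact for: a
closed-nucleus scheme in which a nucleus tier under within-generation
truncation selection (on phenotype or on P-BLUP EBV) supplies parents to
a commercial tier that never contributes descendants back. Defaults
produce 400 nucleus animals (40 founders, 3 generations of 40 matings ×
3 offspring) and 200 commercial animals (50 matings × 4 offspring),
with σ²_u = 0.3, σ²_e = 0.7, phenotype selection of the top half — the
population size at which joint and updated analyses are compared; the
matrix-identity sweep uses 50 smaller populations (≤ 200 animals) so
dense oracles stay trivial. True breeding values follow the
infinitesimal model (founders N(0, σ²_u), offspring mid-parent plus
Mendelian sampling with inbreeding-adjusted variance tracked through an
exact kinship table); an optional marker-effect mode sums additive
effects of unlinked biallelic markers instead. Phenotypes add an overall
mean (tier-specific), an optional shared covariate with stated
coefficient (a heterosis-style effect present in both tiers' models),
and normal residuals. Multi-generation commercial tiers mate nucleus
sires to commercial dams, exercising current animals that parent other
current animals.

What the simulator does *not* emulate — linkage and genome structure,
overlapping generations, litter/maternal environments, heterogeneous
residual variances, genotyping errors or missingness — does not limit
what the passing tests show: the equivalence being tested is an
algebraic identity conditional on the pedigree structure and holds for
any data generated under the stated model, so the simulator's job is to
produce structurally valid populations under selection, not to be
demographically realistic. Conclusions about *statistical performance*
on real livestock data (e.g. the size of pre-selection bias) should not
be read off these simulations; only the directional bias demonstration
is intended.

## Numerical and design choices

- Effect estimability is enforced by requiring a declared full-column-
  rank fixed design (a QR-pivoted rank check names a dependent column);
  external-only fixed effects are marginalized out of C — the current
  model never references them, and Gaussian marginals are exactly what
  the updating MME consumes.
- Single trait, homoscedastic residuals; multi-trait, maternal,
  random-regression and threshold models, variance-component
  estimation, and genotyped animals in the *current* tier are out of
  scope (the last because single-step imputation of current genotypes
  draws on all pedigree relatives, which the boundary object cannot
  carry).
- All randomness flows from explicit seeds; CLI outputs carry user
  labels and 12 significant digits so exactness checks are meaningful.
- Absorption forms the Schur complement densely on the retained block;
  systems where that block is large should absorb in stages (tested
  associative) or avoid absorption in favour of the updating MME.
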