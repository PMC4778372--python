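# Methods

## Model and assumptions

The quantity predicted throughout is the conditional reliability of the molecular
score of one unphenotyped selection candidate,
r² = v(q̂_c|X)/v(q_c|X), under genomic BLUP with i.i.d. marker effects:

* bi-allelic markers coded x = a − 2p (centered) or x = (a − 2p)/σ_m
  (standardized), with per-locus variance σ²_m = 2p(1−p) under Hardy–Weinberg;
* marker effects β ~ i.i.d. (0, σ²_β) with σ²_β = σ²_q/τ, τ = Σ_m σ²_m
  (τ is replaced by n_M under the standardized coding);
* phenotypes only in the reference population; the candidate enters through its
  genotype row and its pedigree relationship to the reference individuals;
* no residual polygenic term: reliabilities refer to the molecular score, not to
  the total genetic value.  The fraction of genetic variance captured by markers
  is handled separately through the factor b (see below).

The exact reliability is computed by a Cholesky solve on whichever side of the
system is smaller (individuals or markers).  The two series approximations and
their closed-form expectations are described in the README; the expectations
require, for each candidate–reference pair, the coefficients (a, α¹¹, α¹³, γ¹³,
α²², γ²²) that express genotype product moments up to order four as linear forms
of the 15 detailed identity-by-descent state probabilities of the pair's four
gametes.

## Relationship presets

Identity-state vectors are hard-coded for the canonical non-inbred relationships
(unrelated, parent–offspring, half sibs, full sibs, and the self pair via exponent
contraction) and validated against gene-dropping oracles; the state ordering is
documented in `gsrel.moments`.  Arbitrary (in particular inbred) pedigrees are
deliberately not solved symbolically: the A matrix always comes from the tabular
kinship recursion, but moment coefficients for non-canonical pairs must be supplied
by the user.  Two conventions coexist and are kept explicit: A has unit diagonal
for non-inbred individuals, while the pairwise coefficient a is a coancestry with
a = 1/2 for a non-inbred self pair.

The half-sib preset places the common sire outside the reference set, so half sibs
of the candidate are also half sibs of each other; this yields the ξI + ψJ
structure of T with ξ = 4/(4 + 3γ).

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| ν² | variance fraction of the molecular score | 0.4 (simulations) | mid-range heritability where the contrast between the two series is sharpest |
| σ² | phenotypic variance | 1 trait unit² | reliabilities are scale-free |
| order | series truncation | 2 (pedigree-factor), 1 (marker-factor) | the orders whose expectations have closed forms; order 10 serves as the convergence check |
| n_reps | replicates per scenario | 50 | Monte-Carlo SE ≲ 0.005 on a reliability |
| N_e | effective size for frequency spectra | n_r in simulations | the inverse-transform sampler's kernel uses the reference size |
| k | U-shaped constant | 1/ln(2N_e) | natural logarithm, consistent with the sampler kernel (2n_r−1)^(2u−1) |
| support bound | truncation of the U-shaped spectrum | 1/(2N_e) (sampler) | closed-form expectations neglect the truncation, which is O(1/N_e), except ζ (below) |
| r_ml | joint-IBD weight in the sire two-locus moment | 1 − c_ml | recombination-based default; exposed because the quantity is not identified by the closed forms alone (see limitations) |

## Synthetic-data generator

`generate_genotypes` draws founder gametes as independent Bernoulli(p_m) alleles
and transmits one uniformly chosen allele per parent per locus (gene dropping with
free recombination).  Allele frequencies are re-drawn each replicate from the
U-shaped spectrum via the inverse transform p = (2n_r−1)^(2u−1)/(1+(2n_r−1)^(2u−1));
a `fix_freqs` switch holds them constant across replicates.

What the generator does **not** emulate: within-genome linkage (LD is handled
analytically in `gsrel.ld`, not simulated in the panel generator), mutation,
selection, non-equilibrium base populations, genotyping error, and multi-breed
structure.  Passing tests therefore demonstrate internal consistency of the
formulas under their own sampling assumptions, not robustness to real-data
violations of Hardy–Weinberg or of the assumed frequency spectrum.

## Numerical choices

* All inverses (T, the GBLUP system, trace terms) are computed by Cholesky
  factorization; the scalar closed forms that exist for special T structures are
  used only as test oracles, because the circulating printed versions of the
  sire-case scalars are mutually inconsistent (the direct 2×2 inversion gives
  denominator (1+γ)² − γ²/4).
* Spectral radii are computed on symmetrized similar matrices (L′PL with T = LL′
  for the pedigree series; C^{−1/2}(X′X − n_r diag)C^{−1/2} for the marker series)
  by dense `eigvalsh` up to 3000×3000 and by Lanczos / power iteration beyond.
  Neumann truncation error scales as ρ^(order+1)/(1−ρ); order-10 agreement with a
  direct inverse at 1e−8 therefore holds for ρ ≲ 0.15, and divergence (ρ ≥ 1) is
  reported on the result object, never raised.
* The Sved-structure trace U uses a dense Cholesky up to 5000 loci and a
  matrix-free Hutchinson estimate (FFT Toeplitz products + conjugate gradients)
  beyond; the stochastic estimator carries O(1/√probes) error and is labelled as
  such.
* Frequency-model expectations: closed forms for the uniform and U-shaped spectra
  (validated against adaptive quadrature at 1e−6 relative); the uniform E[ρ²]
  entry was derived here by differentiating the antiderivative of 1/(h+p(1−p))
  with respect to h, E[ρ²] = 1 − 4hθ/ω + 2h/ω² + 4h²θ/ω³, because a commonly
  quoted variant fails the quadrature check.  Beta-model expectations go through
  `scipy.integrate.quad` at 1e−8.
* ζ = mean of 1/σ²_m diverges as the support bound shrinks, so its value is tied
  to the bound convention; the closed forms use the exact truncated integrals at
  bound 1/N_e (uniform: ln(N_e−1); U-shaped:
  (k/4)[4ln(N_e−1) + 2N_e(N_e−2)/(N_e−1)]).
* The Beta calibration of the U-shaped spectrum minimizes a chi-square-style
  discrepancy Σ(q_Beta − q_U)²/q_U over 50 equal-width bins of (0,1) with a
  bounded scalar optimizer; the fitted shape decreases with population size.  The
  binning is a documented choice: the fitted value at very large n_r is mildly
  sensitive to it.
* Degenerate inputs: a candidate with all-zero coded genotypes raises
  `UndefinedReliabilityError` (zero score variance); monomorphic frequencies raise
  at panel construction; n_M = 0 returns reliability 1 in the closed-form
  expectation (no shrinkage term); h = 0 (zero ridge) is rejected in the spectrum
  expectations.
* Replicate streams derive from `numpy.random.SeedSequence` spawning (one child
  per replicate), making every table cell bitwise reproducible under its seed.

## Interpreting the reference comparisons

The replication columns are: "approximation" = order-2 (pedigree-factor) or
order-1 (marker-factor) truncation on realized genotypes; "order 10" = the same
series at order 10; "E[·]" = the closed-form expectation.  The paired
variance-ratio table compares E[v̂/v] with E[v̂]/E[v] where v̂ is the order-2
pedigree-factor prediction variance and v the realized candidate score variance —
this is the only reading under which the tabulated values (some above 1) are
reproduced.  Simulation sizes in the test suite are the original ones (up to
n_r = 2000, n_M = 2500, 50 replicates); smaller sizes are used only for structural
property checks where the property is size-free.

## Known limitations

* **Two-locus aggregates under LD.**  The conditional two-locus expectations by
  IBD state and parental origin are exact (validated by enumeration), but the
  aggregate sire-case formula exposed by `four_value_expectation` — a weighted
  combination with weight r_ml — does not coincide with the gene-dropping
  expectation for any affine mapping between r_ml and the recombination fraction;
  the no-IBD configuration's closed value is likewise inconsistent with
  enumeration (the exact value for two independent within-gamete LD pairs is Δ²).
  The aggregate forms are retained as the documented closed expressions, r_ml is a
  user parameter, and `two_locus_gene_drop` provides the empirical route; the
  discrepancy is order Δ² and negligible in the weak-LD regime the expectation
  formulas target.
* **Equivalent-loci trace form.**  The general-matrix expression
  (`equivalent_loci_exact`) does not reduce algebraically to n_M under linkage
  equilibrium, while the Sved-structure form does; both are exposed and the
  disagreement is reported, not reconciled.
* **First-approximation expectations** exist only for the unrelated and
  sire-in-reference relationships: other presets would need quadruple identity
  coefficients that are not tabulated, and such requests raise.
* The marker-factor series keeps only first-order algebra in its closed
  expectation, so within-reference relationship structure does not enter: k half
  sibs contribute exactly k times one half sib.  This linearity is a real
  limitation of the approximation, visible in the half-sib preset.
* Reliabilities refer to the molecular score; converting to total-genetic-value
  reliability requires multiplying by the captured fraction
  b = n_M/(2N_eL) ln(1 + 2N_eL/n_M), which assumes one QTL per marker segment and
  Sved's drift LD.
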