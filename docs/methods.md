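# Methods

`poolgs` simulates a two-trait aquaculture breeding program in which the
sib-trait information enters selection exclusively through DNA pools, and
measures what that design costs and buys: selection accuracy, genetic gain,
and the rate of pedigree inbreeding.

## Historical population and genome

The base population is produced by a forward-in-time neutral Wright–Fisher
simulation of `ne` diploids (equal sexes, random mating with replacement,
non-overlapping generations) run for `n_history_generations` generations so
that mutation, drift and recombination reach a realistic linkage-
disequilibrium structure. The genome has `n_chromosomes` chromosomes of
`chrom_length` Morgans. Mutation follows the infinite-sites model: each
gamete receives Poisson-many new biallelic SNPs with mean
`mutation_rate × nt_per_cM × total cM` (one per gamete at the full-scale
defaults of 10 × 100 cM, 10⁻⁹/nt, 10⁶ nt/cM), each at a fresh uniform map
position (float64 positions; exact collisions are resampled). Recombination
uses the Haldane model — crossover counts Poisson(map length), positions
uniform, no interference — and a fair coin chooses the starting haplotype of
every chromosome. Sites fixed or lost are purged each generation, so the
haplotype matrix only ever holds segregating sites.

Implementation note: transmission is a per-gamete segment copy driven by the
sorted switch-point columns (numba-compiled, with an equivalent pure-numpy
parity-cumsum fallback; the two paths are bit-identical and tested as such).
At a chromosome start the carried haplotype parity is re-randomized by
adding an independent fair coin, which is distributionally identical to an
independent start per chromosome.

From the final historical generation, per chromosome and per trait,
`n_qtl_per_chrom` QTL are drawn without replacement from sites with minor
allele frequency above `maf_threshold`; the two traits' QTL sets are kept
disjoint (no pleiotropy at the default zero effect correlation). From the
remaining sites, the `n_markers_full / n_chromosomes` highest-MAF sites per
chromosome form the marker panel; choosing per chromosome (rather than
genome-wide) guarantees even map coverage. Sparser panels keep every
`step`-th marker in genome order. MAF is evaluated in the final historical
generation, where the panel is actually built.

QTL allelic effects are drawn as Gamma(0.4, scale 1.66) magnitudes with
fair-coin signs, independently per allele and trait; an optional correlated
mode replaces the gamma draw with a bivariate standard normal of given
correlation across traits (sharing QTL positions between the traits, which
such a correlation requires). Effects are then rescaled per trait so the
true-breeding-value (TBV) variance of the base generation is exactly 1 —
all gains are therefore in base-generation genetic-standard-deviation units
by construction.

## Breeding scheme

Each cycle: `n_fam` sires × `n_fam` dams are mated one-to-one by a uniform
random perfect matching (no kinship avoidance). Every family produces
`n_cand/n_fam` selection candidates and `n_test/n_fam` test individuals,
half male and half female within each role. Families are partitioned
uniformly at random into rearing groups of `n_fam_per_group`, and a
family's candidates share the group of its test sibs. Phenotypes are
TBV + N(0, σ²ₑ) with σ²ₑ = (1−h²)/h² (base genetic variance 1): GROWTH
(h² = 0.4) is recorded on candidates only, the sib trait (h² = 0.4 or 0.1)
on test individuals only, which are sacrificed for it.

Selection is two-stage. First, mass preselection across all families keeps
the `n_presel/2` candidates of each sex with the highest GROWTH phenotype
(preselecting per sex guarantees that `n_fam` parents of each sex exist
downstream; ties break by id). Only these preselected candidates are
genotyped. Second, the `n_fam` candidates per sex with the highest sib-trait
GEBV become the next parents. During the five scheme generations no new
mutations are introduced and only the QTL ∪ marker sites are tracked —
mutational input over five generations is negligible for both traits and
panel.

## Marker effects from DNA pools

Within each group, test individuals are split at the sib-trait phenotype
median: top half H-pool, bottom half L-pool (ties by id). Pool genotyping
returns each pool's marker allele frequencies; with technical error
`Vt > 0`, independent N(0, Vt/m) noise is added per pool frequency (mean of
m replicate poolings) and clamped to [0, 1]. The helper
`effective_pool_size` maps (N, Vt, p, m) to the pool size with equivalent
pure sampling variance, [1/N + Vt/(p(1−p)m)]⁻¹.

Marker effects solve the SNP-BLUP (ridge) normal equations
(X'X + Iλ)a = X'y on the binary pool-membership phenotype y (variance 0.25
at the 50/50 split), with genotypes standardized as (dosage − 2p)/√H,
H = 2p(1−p). Neither X'X nor X'y is observable for the pooled test
individuals, so both are reconstructed:

* X'X ≈ n·Cov(Xj, Xk), the covariance of standardized genotypes of the
  preselected candidates (1/n normalization, means subtracted). The 1/n
  choice keeps the X'y reconstruction exactly consistent.
* X'y ≈ n·0.25·Δx, where Δx is the H-minus-L pool frequency difference
  converted to the standardized scale, 2Δp/√H, averaged over groups
  weighted by group test count. For equal-size pools without technical
  noise, 0.25·Δx equals the pooled within-group genotype–label covariance
  *exactly* (a counting identity, tested to machine precision).

Markers monomorphic in the candidate sample get zero rows/columns and hence
zero effects; λ keeps the system positive definite and the solve is a
deterministic symmetric-positive-definite factorization.

λ is the residual-to-per-SNP variance ratio on the 0/1 scale, with the
per-SNP variance equal to the genetic variance divided by the panel size.
The continuous-scale h² is converted to the observed binary scale at 50%
incidence by h²₀₁ = h²·z²/0.25 (z = φ(0) ≈ 0.3989), the standard
liability-to-observed transformation; a `direct` mode that uses h²
unchanged exists for sensitivity analysis. Allele frequencies p for
standardization come from the preselected candidates (the only individually
genotyped animals); a pool-frequency alternative is configurable.

Candidate scores Σⱼ X­ᵢⱼaⱼ are rescaled by b = Cov(score, TBV)/Var(score),
computed against the simulated TBV (an idealization; regressing on
phenotypes is the deployable variant and is available). Two GEBV variants
are provided: marker-only, GEBV = b·score, in which group means are implicit
in the marker effects; and phenotypic-group-mean,
GEBV = b(score − μ_GEBV(group)) + μ_p(group), where μ_p is the group's test
phenotype mean and μ_GEBV the mean score of the group's preselected
candidates (the only genotyped ones). With a single group the two variants
differ by a constant, so rankings, selection and accuracy coincide — used
as a consistency check.

## Statistics

Selection accuracy is the Pearson correlation between TBV and GEBV among
the preselected candidates, computed each round and summarized as the mean
over rounds (a steadier estimator than any single round; per-round values
are retained). Inbreeding uses Wright's memoized kinship recursion over the
pedigree with G0 parents as unrelated founders; because all members of a
family share F = kinship(sire, dam) and families are equal-sized, cohort
means reduce to family means. ΔF is the mean of (F_t − F_{t−1})/(1 − F_{t−1})
over the offspring-cohort sequence starting at G1 — the G0→G1 transition is
structurally zero (founders are unrelated by assumption) and is excluded so
that a random-selection control with 100 + 100 parents reproduces the
classical expectation 1/(8N_m) + 1/(8N_f) = 0.0025. Genetic gain is the
change in cohort mean TBV from the G0 parents to the final cohort, in units
of the G0 parents' TBV standard deviation; cumulative and per-generation
variants are both reported. Scenario summaries give replicate means with
standard errors (sd/√n).

## Scale profiles and the desk battery

The `paper` profile is the full-scale study condition set (Ne = 1000, 4000
historical generations, 100 families, 20 000 candidates, up to 50 000 test
individuals, 10 000 markers, 100 replicates); running it is a matter of
hours per scenario. The `desk` profile is the package's reduced condition
set for interactive work and the test suite: Ne = 200 with 400 historical
generations and a ×10 mutation multiplier (holding 4·Ne·μ per cM at the
full-scale value of 4), 50 families, 2000 candidates, 2000 test
individuals, 400 preselected, a 500-marker panel, 10 replicates. The desk
battery (`desk_comparison_grid`) varies one factor at a time around this
base — 200 test individuals, single-family groups, a thinned 50-marker
panel, sib h² = 0.1, and marker-estimated group means — and shares the
historical population across scenarios within a replicate, so scenario
contrasts are paired and tested with paired one-sided t-tests.

What the reduced scale preserves: the mutation–drift–recombination
equilibrium character of the base LD, unit base genetic variance, the
two-stage selection structure, and the qualitative design-factor effects,
which the test suite asserts with paired one-sided tests. What it does not:
absolute accuracy and ΔF levels, which depend on cohort sizes, panel
density relative to LD extent, and selection intensities; desk numbers are
therefore compared only with each other, never directly with full-scale
values.

The synthetic data emulate idealized hatchery conditions: exact 50/50 sex
ratios, equal family sizes, no common-environment group effects, no
genotyping or phenotyping errors (unless Vt > 0), discrete generations and
full survival. Real programs violate all of these to some degree — notably
skewed parental contributions under mass spawning and tank effects that
would bias phenotypic group means — so passing tests demonstrate
correctness of the method under its own assumptions, not field performance.

## Numerical and design choices

* Random streams: one seed per replicate feeds three documented substreams
  (history, architecture, breeding), so precomputed histories or base
  populations can be substituted without disturbing downstream randomness;
  grid runs derive seeds from (master seed, scenario id, replicate).
* All order-dependent selections (preselection, parent selection, pool
  splits, marker MAF ranking) break ties deterministically by id/position.
* Degenerate cases: zero-variance GEBVs yield b = 0 with a warning and an
  undefined (NaN, counted) accuracy rather than an error; monomorphic
  markers are zeroed; h² = 0 and λ ≤ 0 are rejected.
* The kinship cache persists across the replicate, making the exact
  recursion affordable for pedigrees with tens of thousands of offspring
  (only parent-pair ancestries are ever expanded).
* `n_presel/2 ≥ n_fam` and per-role even family sizes are enforced at
  configuration time; they are what makes the per-sex selection steps
  well-defined.

## Known limitations

* The bias regression b uses simulated TBV; deploying the scheme requires a
  phenotype-based estimate, which will cost some accuracy.
* Only the 50/50 median pool split is implemented; optimizing the
  phenotypic selection differential between pools (e.g. discarding
  mid-phenotype fish) is out of scope.
* Pedigree-based F only; marker-based inbreeding measures are not computed.
* No overlapping generations, mass-spawning contribution skew, economic
  weighting, or Bayesian variable-selection estimators.
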