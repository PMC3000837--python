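"""The two-trait breeding scheme with communal rearing and DNA pooling.

Each generation, ``n_fam`` sires and ``n_fam`` dams are mated one-to-one
(random perfect matching).  Every family is split into selection candidates
and test individuals and reared in groups of ``n_fam_per_group`` families,
the same family partnering applying to both roles.  Candidates are
mass-preselected across families on their own GROWTH phenotype; test
individuals are sacrificed to record the sib trait and contribute only
pooled marker allele frequencies.  Marker effects estimated from the pools
(:mod:`poolgs.pooling`) give each preselected candidate a sib-trait GEBV, and
the top ``n_fam`` candidates per sex become the next generation's parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import pooling
from .genome import (
    FEMALE,
    GROWTH,
    MALE,
    N_TRAITS,
    SIB_TRAIT,
    GenomeConfig,
    HaplotypePopulation,
    TraitArchitecture,
    _gamete_batch,
    _tbv_from_dosage,
    sample_qtl_effects,
    select_qtl_and_markers,
    simulate_history,
    thin_markers,
)
from .metrics import (
    KinshipCalculator,
    Pedigree,
    ReplicateResult,
    selection_accuracy,
)

logger = logging.getLogger(__name__)

CANDIDATE = 0
TEST = 1


@dataclass(frozen=True)
class SchemeConfig:
    """Breeding-scheme parameters.

    Defaults are the full-scale reference scheme: 100 families in groups of
    10, 20 000 candidates and 20 000 test individuals, 1000 candidates
    preselected on GROWTH (h2 = 0.4), sib-trait h2 = 0.4, the full 10 000
    marker panel, and five selection rounds.  ``gebv_equation`` chooses how
    group means enter the GEBV: ``phenotypic_group_mean`` adds the group's
    observed test-phenotype mean to within-group marker deviations, while
    ``marker_group_mean`` relies on the marker effects alone.
    """

    n_fam: int = 100
    n_fam_per_group: int = 10
    n_cand: int = 20_000
    n_test: int = 20_000
    n_presel: int = 1000
    n_markers: int = 10_000
    h2_growth: float = 0.4
    h2_sib: float = 0.4
    gebv_equation: str = pooling.EQ_PHENOTYPIC
    n_generations: int = 5
    selection: str = "gebv"  # or "random" (drift control)
    vt: float = 0.0
    m_pools: int = 1
    lambda_mode: str = "liability"
    pool_scope: str = "per_group"
    freq_source: str = "candidates"  # or "pools"

    def __post_init__(self) -> None:
        errors = []
        if self.n_fam <= 0:
            errors.append("n_fam must be positive")
        elif self.n_fam % self.n_fam_per_group:
            errors.append("n_fam must be divisible by n_fam_per_group")
        if self.n_cand <= 0 or self.n_cand % self.n_fam:
            errors.append("n_cand must be positive and divisible by n_fam")
        elif (self.n_cand // self.n_fam) % 2:
            errors.append("candidates per family must be even (equal sexes)")
        if self.n_test < 0 or self.n_test % self.n_fam:
            errors.append("n_test must be non-negative and divisible by n_fam")
        elif (self.n_test // self.n_fam) % 2:
            errors.append("test individuals per family must be even (equal sexes)")
        if self.n_presel > self.n_cand:
            errors.append("n_presel cannot exceed n_cand")
        if self.n_presel % 2:
            errors.append("n_presel must be even (preselection is per sex)")
        if self.n_presel // 2 < self.n_fam:
            errors.append("n_presel/2 must be >= n_fam to supply parents of each sex")
        if self.n_markers < 1:
            errors.append("n_markers must be >= 1")
        for name, h2 in (("h2_growth", self.h2_growth), ("h2_sib", self.h2_sib)):
            if not 0.0 < h2 <= 1.0:
                errors.append(f"{name} must lie in (0, 1]")
        if self.gebv_equation not in (pooling.EQ_PHENOTYPIC, pooling.EQ_MARKER_ONLY):
            errors.append(f"unknown gebv_equation {self.gebv_equation!r}")
        if self.selection not in ("gebv", "random"):
            errors.append(f"unknown selection mode {self.selection!r}")
        if self.n_generations < 0:
            errors.append("n_generations must be >= 0")
        if self.vt < 0:
            errors.append("vt must be non-negative")
        if self.m_pools < 1:
            errors.append("m_pools must be >= 1")
        if self.selection == "gebv" and self.n_test == 0:
            errors.append("GEBV selection requires test individuals (n_test > 0)")
        if self.freq_source not in ("candidates", "pools"):
            errors.append(f"unknown freq_source {self.freq_source!r}")
        if errors:
            raise ValueError("invalid scheme configuration: " + "; ".join(errors))


@dataclass
class BasePopulation:
    """Founder generation restricted to the tracked (QTL + marker) sites."""

    population: HaplotypePopulation  # final historical generation, tracked sites
    architecture: TraitArchitecture  # site indices refer to the tracked list
    n_chromosomes: int
    chrom_length: float
    n_markers_full: int


@dataclass
class ParentCohort:
    """Selected parents of one generation (haplotypes at tracked sites)."""

    ids: np.ndarray  # (P,) pedigree ids
    sex: np.ndarray  # (P,)
    haps: np.ndarray  # (2P, S_tracked)


@dataclass
class BreedingCohort:
    """One generation of offspring: candidates and test individuals."""

    generation: int
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    family: np.ndarray
    group: np.ndarray
    role: np.ndarray  # CANDIDATE / TEST
    sex: np.ndarray
    haps: np.ndarray  # (2N, S_tracked)
    tbv: np.ndarray | None = None  # (N, 2)
    phen: np.ndarray | None = None  # (N, 2), NaN where unrecorded

    @property
    def n_individuals(self) -> int:
        return self.ids.size

    def dosage(self, sites: np.ndarray) -> np.ndarray:
        h = self.haps[:, sites]
        return (h[0::2].astype(np.int16) + h[1::2]).astype(np.int16)

    def candidates(self) -> np.ndarray:
        return np.flatnonzero(self.role == CANDIDATE)

    def tests(self) -> np.ndarray:
        return np.flatnonzero(self.role == TEST)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids + 1,
                "sire": self.sire + 1,
                "dam": self.dam + 1,
                "family": self.family,
                "group": self.group,
                "role": np.where(self.role == CANDIDATE, "candidate", "test"),
                "sex": np.where(self.sex == MALE, "M", "F"),
                "tbv_growth": self.tbv[:, GROWTH] if self.tbv is not None else np.nan,
                "tbv_sib": self.tbv[:, SIB_TRAIT] if self.tbv is not None else np.nan,
                "phen_growth": self.phen[:, GROWTH] if self.phen is not None else np.nan,
                "phen_sib": self.phen[:, SIB_TRAIT] if self.phen is not None else np.nan,
            }
        )


def build_base_population(
    history: HaplotypePopulation, genome_config: GenomeConfig, seed=None
) -> BasePopulation:
    """Select QTL and markers, sample standardized effects, and restrict the
    final historical generation to the tracked sites."""
    rng = np.random.default_rng(seed)
    skeleton = select_qtl_and_markers(history, genome_config, rng)
    arch = sample_qtl_effects(
        skeleton,
        history,
        shape=genome_config.gamma_shape,
        scale=genome_config.gamma_scale,
        effect_correlation=genome_config.effect_correlation,
        rng=rng,
    )
    tracked = np.unique(
        np.concatenate([arch.qtl_sites[GROWTH], arch.qtl_sites[SIB_TRAIT], arch.marker_sites])
    )
    site_map = {int(s): i for i, s in enumerate(tracked)}
    return BasePopulation(
        population=history.subset_sites(tracked),
        architecture=arch.remap(site_map),
        n_chromosomes=genome_config.n_chromosomes,
        chrom_length=genome_config.chrom_length,
        n_markers_full=genome_config.n_markers_full,
    )


def found_parents(
    base: BasePopulation, n_fam: int, rng: np.random.Generator, pedigree: Pedigree
) -> ParentCohort:
    """Sample n_fam sires and n_fam dams without replacement from the base
    population and register them as pedigree founders."""
    pop = base.population
    males = pop.males()
    females = pop.females()
    if males.size < n_fam or females.size < n_fam:
        raise ValueError(
            f"base population has {males.size} males / {females.size} females; "
            f"need {n_fam} of each"
        )
    sires = np.sort(rng.choice(males, size=n_fam, replace=False))
    dams = np.sort(rng.choice(females, size=n_fam, replace=False))
    chosen = np.concatenate([sires, dams])
    ids = pedigree.add_founders(chosen.size, generation=0)
    rows = np.empty(2 * chosen.size, dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    sex = np.concatenate([np.full(n_fam, MALE, np.uint8), np.full(n_fam, FEMALE, np.uint8)])
    return ParentCohort(ids=ids, sex=sex, haps=np.ascontiguousarray(pop.haps[rows]))


def mate_and_split(
    parents: ParentCohort,
    config: SchemeConfig,
    base: BasePopulation,
    rng: np.random.Generator,
    pedigree: Pedigree,
    generation: int,
) -> BreedingCohort:
    """Mate sires and dams one-to-one and produce the offspring cohort.

    Mating is a uniform random perfect matching (sampling without
    replacement, no kinship avoidance).  Each family contributes
    ``n_cand/n_fam`` candidates and ``n_test/n_fam`` test individuals, half
    male and half female within each role, via independent meioses (no new
    mutations over the few scheme generations).  Families are partitioned
    uniformly at random into groups of ``n_fam_per_group``; candidates
    inherit their family's test-group partnering.
    """
    sire_idx = np.flatnonzero(parents.sex == MALE)
    dam_idx = np.flatnonzero(parents.sex == FEMALE)
    if sire_idx.size != dam_idx.size:
        raise ValueError("unequal numbers of sires and dams")
    n_fam = config.n_fam
    if sire_idx.size != n_fam:
        raise ValueError(f"expected {n_fam} parents per sex, got {sire_idx.size}")
    dam_idx = dam_idx[rng.permutation(n_fam)]

    cpf = config.n_cand // n_fam
    tpf = config.n_test // n_fam
    fam_size = cpf + tpf
    n_off = n_fam * fam_size

    family = np.repeat(np.arange(n_fam), fam_size)
    off_sire = np.repeat(sire_idx, fam_size)
    off_dam = np.repeat(dam_idx, fam_size)

    parent_rows = np.empty(2 * n_off, dtype=np.int64)
    parent_rows[0::2] = off_sire
    parent_rows[1::2] = off_dam
    haps = _gamete_batch(
        parents.haps,
        parent_rows,
        base.population.chrom,
        base.population.pos,
        base.n_chromosomes,
        base.chrom_length,
        rng,
    )

    role = np.empty(n_off, dtype=np.uint8)
    sex = np.empty(n_off, dtype=np.uint8)
    one_fam_role = np.concatenate(
        [np.full(cpf, CANDIDATE, np.uint8), np.full(tpf, TEST, np.uint8)]
    )
    one_fam_sex = np.concatenate(
        [
            np.tile([MALE, FEMALE], cpf // 2).astype(np.uint8),
            np.tile([MALE, FEMALE], tpf // 2).astype(np.uint8),
        ]
    )
    role[:] = np.tile(one_fam_role, n_fam)
    sex[:] = np.tile(one_fam_sex, n_fam)

    # random partition of families into groups; candidates and test sibs of
    # a family share the group
    group_of_family = np.empty(n_fam, dtype=np.int64)
    group_of_family[rng.permutation(n_fam)] = (
        np.arange(n_fam) // config.n_fam_per_group
    )
    group = group_of_family[family]

    ids = pedigree.add(parents.ids[off_sire], parents.ids[off_dam], generation)
    return BreedingCohort(
        generation=generation,
        ids=ids,
        sire=parents.ids[off_sire],
        dam=parents.ids[off_dam],
        family=family,
        group=group,
        role=role,
        sex=sex,
        haps=haps,
    )


def compute_tbv(cohort: BreedingCohort, arch: TraitArchitecture) -> np.ndarray:
    """True breeding values: sum over QTL of allele copies times effects."""
    n = cohort.n_individuals
    tbv = np.empty((n, N_TRAITS))
    for t in range(N_TRAITS):
        if arch.qtl_sites[t].max(initial=-1) >= cohort.haps.shape[1]:
            raise ValueError("cohort genotypes do not cover all QTL sites")
        dos = cohort.dosage(arch.qtl_sites[t]).astype(np.float64)
        tbv[:, t] = _tbv_from_dosage(dos, arch.effects[t])
    cohort.tbv = tbv
    return tbv


def assign_phenotypes(
    cohort: BreedingCohort,
    h2_growth: float,
    h2_sib: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotype = TBV + N(0, (1-h2)/h2) noise, with base genetic variance 1.

    GROWTH is recorded on candidates only, the sib trait on test individuals
    only; other entries stay NaN.
    """
    if cohort.tbv is None:
        raise ValueError("compute TBV before phenotypes")
    for h2 in (h2_growth, h2_sib):
        if not 0.0 < h2 <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")
    n = cohort.n_individuals
    phen = np.full((n, N_TRAITS), np.nan)
    cand = cohort.candidates()
    test = cohort.tests()
    for t, h2, idx in ((GROWTH, h2_growth, cand), (SIB_TRAIT, h2_sib, test)):
        sigma_e = np.sqrt((1.0 - h2) / h2)
        phen[idx, t] = cohort.tbv[idx, t] + rng.normal(0.0, sigma_e, idx.size)
    cohort.phen = phen
    return phen


def preselect_on_growth(cohort: BreedingCohort, n_presel: int) -> np.ndarray:
    """Mass preselection: per sex, the n_presel/2 candidates with the highest
    GROWTH phenotype across all families and groups (ties broken by id)."""
    if cohort.phen is None:
        raise ValueError("phenotypes required for preselection")
    cand = cohort.candidates()
    if n_presel > cand.size:
        raise ValueError("n_presel exceeds the number of candidates")
    per_sex = n_presel // 2
    chosen = []
    for s in (MALE, FEMALE):
        idx = cand[cohort.sex[cand] == s]
        if idx.size < per_sex:
            raise ValueError(
                f"only {idx.size} candidates of sex {s}, need {per_sex}"
            )
        order = idx[np.lexsort((cohort.ids[idx], -cohort.phen[idx, GROWTH]))]
        chosen.append(order[:per_sex])
    return np.sort(np.concatenate(chosen))


def select_parents(
    cohort: BreedingCohort,
    preselected: np.ndarray,
    gebv: np.ndarray,
    n_fam: int,
) -> ParentCohort:
    """Truncation selection across families and groups: the n_fam candidates
    per sex with the highest sib-trait GEBV (ties broken by id)."""
    parents = []
    for s in (MALE, FEMALE):
        mask = cohort.sex[preselected] == s
        idx = preselected[mask]
        if idx.size < n_fam:
            raise ValueError(f"only {idx.size} preselected candidates of sex {s}")
        order = np.lexsort((cohort.ids[idx], -gebv[mask]))
        parents.append(idx[order[:n_fam]])
    sel = np.concatenate(parents)
    rows = np.empty(2 * sel.size, dtype=np.int64)
    rows[0::2] = 2 * sel
    rows[1::2] = 2 * sel + 1
    return ParentCohort(
        ids=cohort.ids[sel], sex=cohort.sex[sel], haps=np.ascontiguousarray(cohort.haps[rows])
    )


def estimate_round_gebv(
    cohort: BreedingCohort,
    preselected: np.ndarray,
    marker_cols: np.ndarray,
    config: SchemeConfig,
    rng: np.random.Generator,
):
    """One round of pooled marker-effect estimation and GEBV prediction.

    Returns (GEBVResult for the preselected candidates, MarkerModel,
    PoolSummary).
    """
    test = cohort.tests()
    test_dos = cohort.dosage(marker_cols)[test]
    pools = pooling.form_pools(
        cohort.phen[test, SIB_TRAIT],
        cohort.group[test],
        test_dos,
        vt=config.vt,
        m=config.m_pools,
        rng=rng,
        scope=config.pool_scope,
    )
    cand_dos = cohort.dosage(marker_cols)[preselected]
    if config.freq_source == "candidates":
        p = cand_dos.mean(axis=0, dtype=np.float64) / 2.0
    else:
        w = pools.test_count.astype(np.float64)
        p = (w @ (0.5 * (pools.freq_h + pools.freq_l))) / w.sum()

    dx = pooling.standardized_pool_delta(pools, p)
    xtx = pooling.estimate_xtx(cand_dos, p, test.size)
    lam = pooling.ridge_lambda(config.h2_sib, marker_cols.size, config.lambda_mode)
    a = pooling.solve_marker_effects(xtx, dx, lam, test.size)

    x_cand = pooling.standardize_genotypes(cand_dos, p)
    scores = x_cand @ a
    b = pooling.bias_regression_b(scores, cohort.tbv[preselected, SIB_TRAIT])

    cand_group = cohort.group[preselected]
    if config.gebv_equation == pooling.EQ_PHENOTYPIC:
        mu_p = {
            int(g): float(np.nanmean(cohort.phen[test, SIB_TRAIT][cohort.group[test] == g]))
            for g in np.unique(cand_group)
        }
        result = pooling.gebv_with_group_mean(scores, b, cand_group, mu_p)
    else:
        result = pooling.gebv_marker_only(scores, b, cand_group)

    model = pooling.MarkerModel(
        p=p, effects=a, ridge_lambda=lam, b=b, n_test=test.size
    )
    return result, model, pools


def run_replicate(
    genome_config: GenomeConfig,
    scheme_config: SchemeConfig,
    seed,
    scenario_id: str = "scenario",
    history: HaplotypePopulation | None = None,
    base: BasePopulation | None = None,
) -> ReplicateResult:
    """Run one full replicate: history, founding, and the selection rounds.

    ``seed`` feeds three independent substreams (history, trait architecture,
    breeding scheme) so a precomputed ``history`` or ``base`` population can
    be substituted without disturbing downstream randomness.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_hist, s_arch, s_breed = ss.spawn(3)
    if base is None:
        if history is None:
            history = simulate_history(genome_config, seed=s_hist)
        base = build_base_population(history, genome_config, seed=s_arch)

    if base.n_markers_full % scheme_config.n_markers:
        raise ValueError(
            f"n_markers={scheme_config.n_markers} must divide the full panel "
            f"of {base.n_markers_full}"
        )
    step = base.n_markers_full // scheme_config.n_markers
    marker_cols = thin_markers(base.architecture.marker_sites, step)

    rng = np.random.default_rng(s_breed)
    pedigree = Pedigree()
    kinship = KinshipCalculator(pedigree)
    parents = found_parents(base, scheme_config.n_fam, rng, pedigree)

    # G0 baseline: parental cohort TBV mean and genetic s.d.
    parent_cohort = BreedingCohort(
        generation=0,
        ids=parents.ids,
        sire=np.full(parents.ids.size, -1),
        dam=np.full(parents.ids.size, -1),
        family=np.full(parents.ids.size, -1),
        group=np.full(parents.ids.size, -1),
        role=np.full(parents.ids.size, CANDIDATE, np.uint8),
        sex=parents.sex,
        haps=parents.haps,
    )
    tbv0 = compute_tbv(parent_cohort, base.architecture)
    sigma_a0 = tbv0.std(axis=0)
    if np.any(sigma_a0 <= 0):
        raise ValueError("degenerate G0 genetic variance")

    n_gen = scheme_config.n_generations
    acc = np.full(n_gen, np.nan)
    mean_tbv = np.empty((n_gen + 1, N_TRAITS))
    mean_tbv[0] = tbv0.mean(axis=0)
    mean_f = np.empty(n_gen)

    for g in range(1, n_gen + 1):
        try:
            cohort = mate_and_split(
                parents, scheme_config, base, rng, pedigree, generation=g
            )
            compute_tbv(cohort, base.architecture)
            assign_phenotypes(
                cohort, scheme_config.h2_growth, scheme_config.h2_sib, rng
            )
            mean_tbv[g] = cohort.tbv.mean(axis=0)
            # all members of a family share F = kinship(sire, dam); families
            # are equal-sized, so the cohort mean is the family mean
            fam_f = np.array(
                [
                    kinship.kinship(int(s), int(d))
                    for s, d in zip(
                        cohort.sire[:: cohort.n_individuals // scheme_config.n_fam],
                        cohort.dam[:: cohort.n_individuals // scheme_config.n_fam],
                    )
                ]
            )
            mean_f[g - 1] = fam_f.mean()

            preselected = preselect_on_growth(cohort, scheme_config.n_presel)
            if scheme_config.selection == "gebv":
                result, model, _ = estimate_round_gebv(
                    cohort, preselected, marker_cols, scheme_config, rng
                )
                gebv = result.gebv
                acc[g - 1] = selection_accuracy(
                    cohort.tbv[preselected, SIB_TRAIT], gebv
                )
            else:
                gebv = rng.standard_normal(preselected.size)
            parents = select_parents(cohort, preselected, gebv, scheme_config.n_fam)
        except Exception as exc:
            raise RuntimeError(f"replicate failed in generation {g}: {exc}") from exc
        logger.debug(
            "scenario=%s gen=%d acc=%.4f meanF=%.5f", scenario_id, g, acc[g - 1], mean_f[g - 1]
        )

    return ReplicateResult(
        scenario_id=scenario_id,
        seed=int(ss.entropy) if np.ndim(ss.entropy) == 0 else 0,
        acc=acc,
        mean_tbv=mean_tbv,
        mean_f=mean_f,
        sigma_a0=sigma_a0,
        meta={"n_markers": int(marker_cols.size)},
    )
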