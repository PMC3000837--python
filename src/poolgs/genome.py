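"""Forward-in-time neutral genome simulation and trait architecture.

A diploid Wright--Fisher population is simulated forward for a fixed number
of non-overlapping generations with infinite-sites mutation and Haldane
(no-interference) recombination.  The final generation supplies the base
population of a breeding scheme together with its marker panel and QTL
architecture: per chromosome, QTL are drawn from the sites passing a minor
allele frequency (MAF) filter and markers are the highest-MAF remaining
sites.  QTL allelic effects are drawn from a reflected gamma distribution
(or a correlated bivariate normal) and rescaled so that the true-breeding-
value variance of the base generation is exactly 1 per trait.

Haplotypes are stored as a dense ``uint8`` matrix over the currently
segregating sites (two rows per individual); fixed and lost sites are purged
every generation and the matrix is repacked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GROWTH = 0
SIB_TRAIT = 1
N_TRAITS = 2

# sex codes
MALE = 0
FEMALE = 1


@dataclass(frozen=True)
class GenomeConfig:
    """Genome structure and historical-population parameters.

    Defaults are the full-scale study conditions: 10 chromosomes of 1 Morgan
    each, 1e6 nucleotides per cM, a per-nucleotide per-meiosis mutation rate
    of 1e-9 (one expected mutation per gamete genome-wide), Ne = 1000 for
    4000 historical generations, 50 QTL per chromosome per trait drawn from
    sites with MAF > 0.05, and a full panel of 10 000 markers.

    ``mutation_multiplier`` rescales the mutation rate for reduced-scale
    runs so that the population-scaled diversity 4*Ne*mu per cM can be held
    roughly constant when ``ne`` is reduced.
    """

    n_chromosomes: int = 10
    chrom_length: float = 1.0  # Morgans
    nt_per_cm: int = 1_000_000
    mutation_rate: float = 1e-9  # per nucleotide per meiosis
    mutation_multiplier: float = 1.0
    maf_threshold: float = 0.05
    n_qtl_per_chrom: int = 50
    n_markers_full: int = 10_000
    ne: int = 1000
    n_history_generations: int = 4000
    gamma_shape: float = 0.4
    gamma_scale: float = 1.66
    effect_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.n_qtl_per_chrom <= 0 or self.n_markers_full <= 0:
            raise ValueError("chromosome, QTL and marker counts must be positive")
        if self.chrom_length < 0:
            raise ValueError("chrom_length must be non-negative")
        if self.nt_per_cm <= 0:
            raise ValueError("nt_per_cm must be positive")
        if not 0.0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5)")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in [0, 1)")
        if self.mutation_multiplier < 0:
            raise ValueError("mutation_multiplier must be non-negative")
        if self.ne <= 0:
            raise ValueError("ne must be positive")
        if self.ne % 2:
            raise ValueError("ne must be even (equal numbers of males and females)")
        if self.n_markers_full % self.n_chromosomes:
            raise ValueError("n_markers_full must be divisible by n_chromosomes")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if abs(self.effect_correlation) > 1:
            raise ValueError("effect_correlation must lie in [-1, 1]")

    @property
    def mutations_per_gamete(self) -> float:
        """Expected number of new mutations per transmitted gamete."""
        total_cm = self.n_chromosomes * self.chrom_length * 100.0
        return self.mutation_rate * self.mutation_multiplier * self.nt_per_cm * total_cm


@dataclass
class HaplotypePopulation:
    """One generation of diploid individuals over segregating biallelic sites.

    ``haps`` has two rows per individual (rows ``2i`` and ``2i+1``) and one
    column per site; a 1 denotes the derived (mutant) allele.  Sites are
    sorted by (chromosome, map position).
    """

    chrom: np.ndarray  # (S,) int16, chromosome index per site
    pos: np.ndarray  # (S,) float64, map position in Morgans within chromosome
    haps: np.ndarray  # (2N, S) uint8
    sex: np.ndarray  # (N,) uint8, MALE/FEMALE
    generation_index: int = 0

    @property
    def n_individuals(self) -> int:
        return self.haps.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the derived allele at each site."""
        return self.haps.mean(axis=0, dtype=np.float64)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def dosage(self, sites: np.ndarray | None = None) -> np.ndarray:
        """Per-individual derived-allele counts, shape (N, S)."""
        h = self.haps if sites is None else self.haps[:, sites]
        return (h[0::2].astype(np.int16) + h[1::2]).astype(np.int16)

    def subset_sites(self, sites: np.ndarray) -> "HaplotypePopulation":
        return HaplotypePopulation(
            chrom=self.chrom[sites].copy(),
            pos=self.pos[sites].copy(),
            haps=np.ascontiguousarray(self.haps[:, sites]),
            sex=self.sex.copy(),
            generation_index=self.generation_index,
        )

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    # -- persistence ------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Archive the population state (npz with a format-version field)."""
        np.savez_compressed(
            path,
            version=np.array([self.FORMAT_VERSION]),
            chrom=self.chrom,
            pos=self.pos,
            haps=self.haps,
            sex=self.sex,
            generation_index=np.array([self.generation_index]),
        )

    @classmethod
    def load(cls, path) -> "HaplotypePopulation":
        with np.load(path) as z:
            version = int(z["version"][0])
            if version != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported population archive version {version}")
            return cls(
                chrom=z["chrom"],
                pos=z["pos"],
                haps=z["haps"],
                sex=z["sex"],
                generation_index=int(z["generation_index"][0]),
            )

    # -- standard-format export -------------------------------------------

    def to_vcf(self, path, nt_per_cm: int = 1_000_000, sites: np.ndarray | None = None) -> None:
        """Write genotypes as an uncompressed biallelic-SNP VCF.

        Physical coordinates are derived from the genetic map as
        ``round(pos_in_cM * nt_per_cm)``, 1-based.  Alleles are written as
        REF=A (ancestral) and ALT=T (derived).
        """
        idx = np.arange(self.n_sites) if sites is None else np.asarray(sites)
        n = self.n_individuals
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=poolgs\n")
            for c in range(int(self.chrom.max(initial=-1)) + 1):
                fh.write(f"##contig=<ID=chr{c + 1}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(f"ind{i}" for i in range(n))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            for j in idx:
                bp = max(1, int(round(self.pos[j] * 100.0 * nt_per_cm)))
                gts = "\t".join(
                    f"{self.haps[2 * i, j]}|{self.haps[2 * i + 1, j]}" for i in range(n)
                )
                fh.write(
                    f"chr{self.chrom[j] + 1}\t{bp}\tsite{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
                )

    def to_plink_map(self, path, nt_per_cm: int = 1_000_000, sites: np.ndarray | None = None) -> None:
        """Write the genetic map in PLINK .map layout (chrom, id, cM, bp)."""
        idx = np.arange(self.n_sites) if sites is None else np.asarray(sites)
        with open(path, "w") as fh:
            for j in idx:
                cm = self.pos[j] * 100.0
                bp = max(1, int(round(cm * nt_per_cm)))
                fh.write(f"{self.chrom[j] + 1}\tsite{j}\t{cm:.6f}\t{bp}\n")


@dataclass
class TraitArchitecture:
    """QTL positions and allelic effects for the two traits.

    ``qtl_sites[t]`` indexes sites of the *tracked* site list of the
    population the architecture was built on.  ``effects[t]`` has one row
    per QTL and two columns: the additive effect of the ancestral allele
    (``g_j1``) and of the derived allele (``g_j2``).  Effects include the
    per-trait standardization factor that makes the base-generation TBV
    variance equal 1.
    """

    qtl_sites: list  # [ (Q,) int array per trait ]
    effects: list  # [ (Q, 2) float array per trait ]
    marker_sites: np.ndarray  # (M,) int, disjoint from all QTL sites
    standardization_factor: np.ndarray = field(
        default_factory=lambda: np.ones(N_TRAITS)
    )
    effect_correlation: float = 0.0

    def remap(self, site_map: dict) -> "TraitArchitecture":
        """Re-index QTL and marker sites through ``site_map`` (old -> new)."""
        lut = np.vectorize(site_map.__getitem__)
        return TraitArchitecture(
            qtl_sites=[lut(q) for q in self.qtl_sites],
            effects=[e.copy() for e in self.effects],
            marker_sites=lut(self.marker_sites),
            standardization_factor=self.standardization_factor.copy(),
            effect_correlation=self.effect_correlation,
        )


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def _chrom_site_offsets(chrom: np.ndarray, n_chromosomes: int) -> np.ndarray:
    """Start index of each chromosome's site block (length n_chromosomes+1)."""
    return np.searchsorted(chrom, np.arange(n_chromosomes + 1))


_transmit_kernel = None


def _get_transmit_kernel():
    """Compile (once) the numba segment-copy kernel; None if numba is absent."""
    global _transmit_kernel
    if _transmit_kernel is None:
        try:
            from numba import njit
        except ImportError:  # pragma: no cover - numba is an optional accelerator
            _transmit_kernel = False
            return None

        @njit(cache=False)
        def kernel(haps, parent_idx, ptr, cols, out):  # pragma: no cover - compiled
            n_sites = haps.shape[1]
            for g in range(parent_idx.size):
                p = 2 * parent_idx[g]
                cur = 0
                prev = 0
                for k in range(ptr[g], ptr[g + 1]):
                    c = cols[k]
                    if c > prev:
                        out[g, prev:c] = haps[p + cur, prev:c]
                        prev = c
                    cur ^= 1
                if prev < n_sites:
                    out[g, prev:n_sites] = haps[p + cur, prev:n_sites]

        _transmit_kernel = kernel
    return _transmit_kernel or None


def _switch_columns(
    n_gam: int,
    offsets: np.ndarray,
    pos: np.ndarray,
    n_chromosomes: int,
    chrom_length: float,
    rng: np.random.Generator,
):
    """Per-gamete sorted site columns at which the transmitted haplotype flips.

    Two kinds of events are merged: a fair-coin toggle at the start of every
    chromosome block (re-randomizing the carried parity is equivalent to an
    independent starting-haplotype choice) and one toggle at the first site
    at or beyond each crossover, with crossover counts Poisson(map length)
    and positions uniform (Haldane model, no interference).

    Returns (ptr, cols): ``cols[ptr[g]:ptr[g+1]]`` are gamete ``g``'s switch
    columns in increasing order.
    """
    coins = rng.integers(0, 2, size=(n_gam, n_chromosomes), dtype=np.uint8)
    gi, ci = np.nonzero(coins)
    ev_gam = [gi]
    ev_col = [offsets[ci]]

    if chrom_length > 0:
        n_xo = rng.poisson(chrom_length, size=(n_gam, n_chromosomes))
        total = int(n_xo.sum())
        if total:
            order_c = n_xo.T.ravel()  # chromosome-major
            gam_ids = np.repeat(np.tile(np.arange(n_gam), n_chromosomes), order_c)
            chrom_ids = np.repeat(np.arange(n_chromosomes), n_xo.sum(axis=0))
            xo_pos = rng.uniform(0.0, chrom_length, size=total)
            col = np.empty(total, dtype=np.int64)
            for c in range(n_chromosomes):
                sel = chrom_ids == c
                if sel.any():
                    lo, hi = offsets[c], offsets[c + 1]
                    col[sel] = lo + np.searchsorted(pos[lo:hi], xo_pos[sel])
            ev_gam.append(gam_ids)
            ev_col.append(col)

    gids = np.concatenate(ev_gam)
    cols = np.concatenate(ev_col).astype(np.int64)
    order = np.lexsort((cols, gids))
    gids = gids[order]
    cols = cols[order]
    ptr = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(np.bincount(gids, minlength=n_gam), out=ptr[1:])
    return ptr, cols


def _gamete_batch(
    haps: np.ndarray,
    parent_idx: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    n_chromosomes: int,
    chrom_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one recombinant gamete per entry of ``parent_idx``.

    Crossovers per chromosome are Poisson(map length in Morgans) with
    positions uniform on the chromosome (Haldane model, no interference);
    the starting haplotype of each chromosome is a fair coin.
    """
    parent_idx = np.ascontiguousarray(parent_idx, dtype=np.int64)
    n_gam = parent_idx.size
    n_sites = haps.shape[1]
    offsets = _chrom_site_offsets(chrom, n_chromosomes)
    ptr, cols = _switch_columns(
        n_gam, offsets, pos, n_chromosomes, chrom_length, rng
    )
    # drop events beyond the last site (crossovers past the final site of the
    # last chromosome change nothing)
    out = np.empty((n_gam, n_sites), dtype=np.uint8)
    kernel = _get_transmit_kernel()
    if kernel is not None:
        kernel(np.ascontiguousarray(haps), parent_idx, ptr, cols, out)
        return out
    # pure-numpy fallback: switch-count parity via running cumsum
    delta = np.zeros((n_gam, n_sites + 1), dtype=np.uint8)
    np.add.at(delta, (np.repeat(np.arange(n_gam), np.diff(ptr)), np.minimum(cols, n_sites)), 1)
    choose = np.cumsum(delta[:, :-1], axis=1, dtype=np.uint8) & 1
    hap_a = haps[2 * parent_idx]
    hap_b = haps[2 * parent_idx + 1]
    np.copyto(out, hap_a ^ ((hap_a ^ hap_b) & choose))
    return out


def meiosis(
    parent_haplopair: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    n_chromosomes: int,
    chrom_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a diploid parent given as a (2, S) haplotype pair."""
    parent_haplopair = np.asarray(parent_haplopair, dtype=np.uint8)
    if parent_haplopair.ndim != 2 or parent_haplopair.shape[0] != 2:
        raise ValueError("parent_haplopair must have shape (2, n_sites)")
    return _gamete_batch(
        parent_haplopair, np.array([0]), np.asarray(chrom), np.asarray(pos),
        n_chromosomes, chrom_length, rng,
    )[0]


# ---------------------------------------------------------------------------
# Historical population
# ---------------------------------------------------------------------------


def _mutate(
    config: GenomeConfig, n_gam: int, existing: tuple, rng: np.random.Generator
) -> tuple:
    """Sample new infinite-sites mutations for a batch of gametes.

    Returns (chrom, pos, gamete_index) per mutation; positions colliding with
    an existing site (or another new mutation) are resampled.
    """
    lam = config.mutations_per_gamete
    if lam == 0.0:
        e = np.empty(0)
        return e.astype(np.int16), e, e.astype(np.int64)
    counts = rng.poisson(lam, size=n_gam)
    total = int(counts.sum())
    gam_ids = np.repeat(np.arange(n_gam), counts)
    mchrom = rng.integers(0, config.n_chromosomes, size=total).astype(np.int16)
    mpos = rng.uniform(0.0, config.chrom_length, size=total)
    old_chrom, old_pos = existing
    # infinite-sites guard: resample any exact collision (vanishingly rare
    # with float64 positions, but enforced)
    for _ in range(10):
        key = mchrom.astype(np.float64) * (config.chrom_length + 1.0) + mpos
        old_key = old_chrom.astype(np.float64) * (config.chrom_length + 1.0) + old_pos
        dup = np.isin(key, old_key)
        uniq, first = np.unique(key, return_index=True)
        internal_dup = np.ones(total, dtype=bool)
        internal_dup[first] = False
        bad = dup | internal_dup
        if not bad.any():
            break
        nb = int(bad.sum())
        mchrom[bad] = rng.integers(0, config.n_chromosomes, size=nb).astype(np.int16)
        mpos[bad] = rng.uniform(0.0, config.chrom_length, size=nb)
    return mchrom, mpos, gam_ids


def _next_generation(
    pop: HaplotypePopulation,
    config: GenomeConfig,
    n_offspring: int,
    rng: np.random.Generator,
    mutate: bool = True,
) -> HaplotypePopulation:
    """One Wright--Fisher generation: random mating with replacement."""
    males = pop.males()
    females = pop.females()
    sires = rng.choice(males, size=n_offspring, replace=True)
    dams = rng.choice(females, size=n_offspring, replace=True)
    parent_idx = np.empty(2 * n_offspring, dtype=np.int64)
    parent_idx[0::2] = sires
    parent_idx[1::2] = dams
    gametes = _gamete_batch(
        pop.haps, parent_idx, pop.chrom, pop.pos,
        config.n_chromosomes, config.chrom_length, rng,
    )

    if mutate:
        mchrom, mpos, gam_ids = _mutate(
            config, 2 * n_offspring, (pop.chrom, pop.pos), rng
        )
    else:
        mchrom = np.empty(0, dtype=np.int16)
        mpos = np.empty(0)
        gam_ids = np.empty(0, dtype=np.int64)

    # purge fixed/lost old sites, then merge the new mutation columns
    # (every new mutation is carried by exactly one gamete, hence segregating)
    counts = gametes.sum(axis=0, dtype=np.int64)
    old_keep = np.flatnonzero((counts > 0) & (counts < 2 * n_offspring))
    chrom = np.concatenate([pop.chrom[old_keep], mchrom])
    pos = np.concatenate([pop.pos[old_keep], mpos])
    order = np.lexsort((pos, chrom))
    chrom = np.ascontiguousarray(chrom[order])
    pos = np.ascontiguousarray(pos[order])

    n_old = old_keep.size
    from_old = order < n_old
    # map every output column to a source column of `gametes`; new-mutation
    # columns point at a trailing all-zero dummy column and get their single
    # carrier scattered in afterwards
    src = np.where(from_old, np.concatenate([old_keep, np.zeros(mchrom.size, dtype=np.int64)])[order], gametes.shape[1])
    gametes = np.concatenate(
        [gametes, np.zeros((2 * n_offspring, 1), dtype=np.uint8)], axis=1
    )
    haps = gametes.take(src, axis=1)
    if mchrom.size:
        new_dest = np.empty(mchrom.size, dtype=np.int64)
        new_dest[order[~from_old] - n_old] = np.flatnonzero(~from_old)
        haps[gam_ids, new_dest] = 1

    sex = np.empty(n_offspring, dtype=np.uint8)
    sex[: n_offspring // 2] = MALE
    sex[n_offspring // 2:] = FEMALE
    return HaplotypePopulation(
        chrom=chrom, pos=pos, haps=haps, sex=sex,
        generation_index=pop.generation_index + 1,
    )


def simulate_history(
    config: GenomeConfig,
    ne: int | None = None,
    n_generations: int | None = None,
    seed=None,
) -> HaplotypePopulation:
    """Simulate the neutral historical population and return its final
    generation.

    The population starts from ``ne`` identical (mutation-free) founders and
    evolves under random mating with replacement (``ne/2`` males, ``ne/2``
    females), infinite-sites mutation and Haldane recombination.  Sites fixed
    or lost are removed each generation.
    """
    ne = config.ne if ne is None else ne
    n_generations = (
        config.n_history_generations if n_generations is None else n_generations
    )
    if ne <= 0:
        raise ValueError("ne must be positive")
    if ne % 2:
        raise ValueError("ne must be even")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)

    sex = np.empty(ne, dtype=np.uint8)
    sex[: ne // 2] = MALE
    sex[ne // 2:] = FEMALE
    pop = HaplotypePopulation(
        chrom=np.empty(0, dtype=np.int16),
        pos=np.empty(0),
        haps=np.zeros((2 * ne, 0), dtype=np.uint8),
        sex=sex,
        generation_index=0,
    )
    for _ in range(n_generations):
        pop = _next_generation(pop, config, ne, rng)
    return pop


# ---------------------------------------------------------------------------
# Marker panel and QTL architecture
# ---------------------------------------------------------------------------


def select_qtl_and_markers(
    pop: HaplotypePopulation, config: GenomeConfig, rng: np.random.Generator
) -> TraitArchitecture:
    """Draw per-chromosome QTL and the highest-MAF marker panel.

    Per chromosome and per trait, ``n_qtl_per_chrom`` QTL are sampled without
    replacement from sites with MAF above the threshold; the two traits'
    QTL sets are disjoint (no pleiotropy).  From the remaining sites the
    ``n_markers_full / n_chromosomes`` highest-MAF sites per chromosome form
    the marker panel (ties broken by map position).  MAF is computed in the
    supplied (final historical) generation.

    Returns an effect-free architecture skeleton; effects are attached by
    :func:`sample_qtl_effects`.
    """
    maf = pop.maf()
    offsets = _chrom_site_offsets(pop.chrom, config.n_chromosomes)
    m_per_chrom = config.n_markers_full // config.n_chromosomes
    qtl = [[] for _ in range(N_TRAITS)]
    markers = []
    for c in range(config.n_chromosomes):
        lo, hi = offsets[c], offsets[c + 1]
        sites = np.arange(lo, hi)
        eligible = sites[maf[lo:hi] > config.maf_threshold]
        need = N_TRAITS * config.n_qtl_per_chrom
        if eligible.size < need:
            raise ValueError(
                f"chromosome {c + 1}: only {eligible.size} sites with "
                f"MAF > {config.maf_threshold}, need {need} for QTL"
            )
        drawn = rng.choice(eligible, size=need, replace=False)
        for t in range(N_TRAITS):
            qtl[t].append(
                np.sort(drawn[t * config.n_qtl_per_chrom:(t + 1) * config.n_qtl_per_chrom])
            )
        rest = np.setdiff1d(sites, drawn)
        if rest.size < m_per_chrom:
            raise ValueError(
                f"chromosome {c + 1}: only {rest.size} non-QTL sites, "
                f"need {m_per_chrom} markers"
            )
        # highest MAF first; ties resolved by site (map) order
        order = np.lexsort((rest, -maf[rest]))
        markers.append(np.sort(rest[order[:m_per_chrom]]))
    return TraitArchitecture(
        qtl_sites=[np.concatenate(q) for q in qtl],
        effects=[np.zeros((config.n_qtl_per_chrom * config.n_chromosomes, 2)) for _ in range(N_TRAITS)],
        marker_sites=np.concatenate(markers),
    )


def thin_markers(marker_ids: np.ndarray, step: int) -> np.ndarray:
    """Keep every ``step``-th marker in genome order (ordinals 0, step, ...)."""
    if step < 1:
        raise ValueError("step must be >= 1")
    return np.asarray(marker_ids)[::step]


def _tbv_from_dosage(dosage: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """TBV = sum over QTL of copies-of-each-allele times allelic effect."""
    g_anc, g_der = effects[:, 0], effects[:, 1]
    return (2.0 - dosage) @ g_anc + dosage @ g_der


def sample_qtl_effects(
    skeleton: TraitArchitecture,
    pop: HaplotypePopulation,
    shape: float = 0.4,
    scale: float = 1.66,
    effect_correlation: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TraitArchitecture:
    """Attach QTL allelic effects and standardize base genetic variance to 1.

    Default mode: each allele's effect magnitude ~ Gamma(shape, scale) with a
    fair-coin sign, independently per trait.  Correlated mode
    (``effect_correlation != 0``): per QTL allele, the two traits' effects are
    bivariate standard normal with the given correlation.  Afterwards each
    trait's effects are rescaled so that Var(TBV) over ``pop`` equals 1.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    if abs(effect_correlation) > 1:
        raise ValueError("effect_correlation must lie in [-1, 1]")
    rng = np.random.default_rng() if rng is None else rng

    effects = []
    if effect_correlation == 0.0:
        for t in range(N_TRAITS):
            q = skeleton.qtl_sites[t].size
            mag = rng.gamma(shape, scale, size=(q, 2))
            sign = rng.choice([-1.0, 1.0], size=(q, 2))
            effects.append(mag * sign)
    else:
        cov = np.array([[1.0, effect_correlation], [effect_correlation, 1.0]])
        chol = np.linalg.cholesky(cov)
        # shared QTL positions are required for cross-trait effect correlation
        if not np.array_equal(skeleton.qtl_sites[GROWTH], skeleton.qtl_sites[SIB_TRAIT]):
            qtl = skeleton.qtl_sites[GROWTH]
            skeleton = replace(skeleton, qtl_sites=[qtl, qtl.copy()])
        q = skeleton.qtl_sites[GROWTH].size
        z = rng.standard_normal(size=(q, 2, 2))  # (qtl, allele, trait)
        corr = z @ chol.T
        effects = [corr[:, :, GROWTH], corr[:, :, SIB_TRAIT]]

    factors = np.empty(N_TRAITS)
    for t in range(N_TRAITS):
        dos = pop.dosage(skeleton.qtl_sites[t]).astype(np.float64)
        tbv = _tbv_from_dosage(dos, effects[t])
        sd = tbv.std()
        if sd == 0:
            raise ValueError(f"trait {t}: zero TBV variance in base generation")
        factors[t] = 1.0 / sd
        effects[t] = effects[t] * factors[t]

    return TraitArchitecture(
        qtl_sites=[q.copy() for q in skeleton.qtl_sites],
        effects=effects,
        marker_sites=skeleton.marker_sites.copy(),
        standardization_factor=factors,
        effect_correlation=effect_correlation,
    )
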