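"""SNP-BLUP marker-effect estimation from pooled DNA allele frequencies.

Test individuals are never genotyped individually.  Within each rearing
group, the half with the highest sib-trait phenotypes forms the H-pool and
the other half the L-pool; pooled genotyping yields each pool's marker
allele frequencies.  Treating pool membership as a binary phenotype y (1 for
H, 0 for L, variance 0.25 at the 50/50 split), the ridge-regression
("SNP-BLUP") normal equations

    (X'X + I*lambda) a = X'y

are reconstructed without individual test genotypes:

* X'X ~= n * Cov(X_j, X_k), the covariance matrix of standardized genotypes
  estimated from the individually genotyped (preselected) candidates;
* X'y ~= n * Cov(X_j, y) with Cov(X_j, y) = 0.25 * dx_j, where dx_j is the
  H-minus-L difference in pool allele frequency converted to the
  standardized-genotype scale (2*dp/sqrt(H_j)); for equal-size pools this
  identity is exact.

Genotypes are standardized as (dosage - 2p)/sqrt(H) with H = 2p(1-p).
Estimated effects are summed into a raw score per candidate, rescaled by the
regression b of true breeding value on raw score, and optionally combined
with the group phenotype mean (which is the better family-mean estimate when
only one family is reared per group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

#: standard normal density at zero, the 50%-incidence liability factor
_Z50 = 1.0 / np.sqrt(2.0 * np.pi)

EQ_MARKER_ONLY = "marker_group_mean"  # group means implicit in marker effects
EQ_PHENOTYPIC = "phenotypic_group_mean"  # group means from test phenotypes


@dataclass
class PoolSummary:
    """Per-group H/L pool allele frequencies at the marker loci."""

    group_ids: np.ndarray  # (G,)
    freq_h: np.ndarray  # (G, M)
    freq_l: np.ndarray  # (G, M)
    pool_size: np.ndarray  # (G,) individuals per pool (= test count / 2)
    vt: float = 0.0  # technical error variance per pool frequency
    m: int = 1  # replicate poolings averaged

    @property
    def test_count(self) -> np.ndarray:
        return 2 * self.pool_size

    def to_frame(self):
        """Long-format table (group, marker, freq_H, freq_L)."""
        import pandas as pd

        n_g, n_m = self.freq_h.shape
        return pd.DataFrame(
            {
                "group": np.repeat(self.group_ids, n_m),
                "marker": np.tile(np.arange(n_m), n_g),
                "freq_H": self.freq_h.ravel(),
                "freq_L": self.freq_l.ravel(),
            }
        )


@dataclass
class MarkerModel:
    """Fitted marker-effect model for one selection round."""

    p: np.ndarray  # (M,) allele frequencies used for standardization
    effects: np.ndarray  # (M,) estimated marker effects a_j
    ridge_lambda: float
    b: float  # bias-correction regression coefficient
    n_test: int

    @property
    def heterozygosity(self) -> np.ndarray:
        return 2.0 * self.p * (1.0 - self.p)

    def to_frame(self, chrom=None, pos=None):
        import pandas as pd

        d = {"marker": np.arange(self.p.size), "effect": self.effects, "p": self.p}
        if chrom is not None:
            d["chrom"] = chrom
        if pos is not None:
            d["pos_morgan"] = pos
        return pd.DataFrame(d)


@dataclass
class GEBVResult:
    """Genome-wide breeding-value estimates for the preselected candidates."""

    raw_score: np.ndarray  # sum_j X_ij a_j
    gebv: np.ndarray  # final estimate on the continuous trait scale
    group: np.ndarray


def standardize_genotypes(dosage: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Standardized genotype codes -2p/sqrt(H), (1-2p)/sqrt(H), 2(1-p)/sqrt(H).

    Columns with zero heterozygosity are set to 0 (their effects are forced
    to zero downstream).
    """
    p = np.asarray(p, dtype=np.float64)
    h = 2.0 * p * (1.0 - p)
    s = np.sqrt(np.where(h > 0, h, 1.0))
    x = (np.asarray(dosage, dtype=np.float64) - 2.0 * p) / s
    x[:, h <= 0] = 0.0
    return x


def form_pools(
    phenotype: np.ndarray,
    group: np.ndarray,
    dosage: np.ndarray,
    vt: float = 0.0,
    m: int = 1,
    rng: np.random.Generator | None = None,
    scope: str = "per_group",
) -> PoolSummary:
    """Split each group's test individuals at the phenotype median into H/L
    pools and return pooled allele frequencies.

    Ties in phenotype are broken by position (id) so the split is
    deterministic.  With ``vt > 0`` independent Normal(0, vt/m) technical
    noise is added to every pool frequency (the mean of ``m`` replicate
    poolings), then clamped to [0, 1].  ``scope='global'`` ignores the group
    structure and forms a single genome-wide pool pair.
    """
    phenotype = np.asarray(phenotype, dtype=np.float64)
    group = np.zeros(phenotype.size, dtype=np.int64) if scope == "global" else np.asarray(group)
    if scope not in ("per_group", "global"):
        raise ValueError(f"unknown pool scope {scope!r}")
    if m < 1:
        raise ValueError("number of replicate poolings m must be >= 1")
    gids = np.unique(group)
    n_markers = dosage.shape[1]
    freq_h = np.empty((gids.size, n_markers))
    freq_l = np.empty((gids.size, n_markers))
    size = np.empty(gids.size, dtype=np.int64)
    for gi, gid in enumerate(gids):
        idx = np.flatnonzero(group == gid)
        if idx.size % 2:
            raise ValueError(f"group {gid} has an odd number of test individuals")
        half = idx.size // 2
        # highest phenotypes first; ties resolved by id
        order = idx[np.lexsort((idx, -phenotype[idx]))]
        h_idx, l_idx = order[:half], order[half:]
        freq_h[gi] = dosage[h_idx].sum(axis=0, dtype=np.float64) / (2.0 * half)
        freq_l[gi] = dosage[l_idx].sum(axis=0, dtype=np.float64) / (2.0 * half)
        size[gi] = half
    if vt > 0:
        rng = np.random.default_rng() if rng is None else rng
        sd = np.sqrt(vt / m)
        freq_h = np.clip(freq_h + rng.normal(0.0, sd, freq_h.shape), 0.0, 1.0)
        freq_l = np.clip(freq_l + rng.normal(0.0, sd, freq_l.shape), 0.0, 1.0)
    return PoolSummary(
        group_ids=gids, freq_h=freq_h, freq_l=freq_l, pool_size=size, vt=vt, m=m
    )


def standardized_pool_delta(pools: PoolSummary, p: np.ndarray) -> np.ndarray:
    """H-minus-L pool frequency difference on the standardized-genotype scale.

    Per group g, delta_gj = 2 (freq_H - freq_L) / sqrt(H_j); the result is
    the average over groups weighted by group test count.  0.25 times this
    quantity estimates (exactly, for equal pools without technical noise) the
    within-group-pooled covariance between standardized genotype and the 0/1
    pool label.
    """
    p = np.asarray(p, dtype=np.float64)
    h = 2.0 * p * (1.0 - p)
    s = np.sqrt(np.where(h > 0, h, 1.0))
    delta = 2.0 * (pools.freq_h - pools.freq_l) / s
    delta[:, h <= 0] = 0.0
    w = pools.test_count.astype(np.float64)
    return (w @ delta) / w.sum()


def estimate_xtx(
    cand_dosage: np.ndarray, p: np.ndarray, n_test: int
) -> np.ndarray:
    """Reconstruct X'X as n_test times the candidates' genotype covariance.

    The covariance matrix uses 1/n normalization with means subtracted,
    which keeps the companion X'y reconstruction (0.25 * dx) on a consistent
    scale.  Markers monomorphic among the candidates contribute zero rows
    and columns (the ridge keeps the system positive definite and forces
    their effects to zero).
    """
    if cand_dosage.shape[0] < 2:
        raise ValueError("need at least 2 genotyped candidates to estimate X'X")
    x = standardize_genotypes(cand_dosage, p)
    xc = x - x.mean(axis=0)
    c = (xc.T @ xc) / x.shape[0]
    return n_test * c


def ridge_lambda(h2_sib: float, n_markers: int, mode: str = "liability") -> float:
    """Ridge parameter for the binary (pool-membership) phenotype scale.

    The 0/1 label has total variance 0.25.  In ``liability`` mode (default)
    the continuous-scale heritability is converted to the observed binary
    scale at 50% incidence, h2_01 = h2 * z^2 / 0.25 with z the standard
    normal density at the threshold (z = 0.3989); ``direct`` mode uses h2 on
    the 0/1 scale unchanged.  lambda = residual variance / per-SNP variance,
    with per-SNP variance = genetic variance / number of markers.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0.0 < h2_sib <= 1.0:
        raise ValueError("h2_sib must lie in (0, 1]")
    if mode == "liability":
        h2_01 = h2_sib * _Z50**2 / 0.25
    elif mode == "direct":
        h2_01 = h2_sib
    else:
        raise ValueError(f"unknown lambda mode {mode!r}")
    sg01 = 0.25 * h2_01
    if sg01 >= 0.25:
        raise ValueError("binary-scale genetic variance reaches the phenotypic variance")
    return (0.25 - sg01) / (sg01 / n_markers)


def solve_marker_effects(
    xtx: np.ndarray, dx: np.ndarray, ridge: float, n_test: int
) -> np.ndarray:
    """Solve (X'X + I*lambda) a = X'y with X'y = n_test * 0.25 * dx."""
    if ridge <= 0:
        raise ValueError("ridge parameter must be positive")
    if not (np.all(np.isfinite(xtx)) and np.all(np.isfinite(dx))):
        raise ValueError("non-finite values in the normal equations")
    lhs = xtx + ridge * np.eye(xtx.shape[0])
    rhs = n_test * 0.25 * np.asarray(dx, dtype=np.float64)
    return linalg.solve(lhs, rhs, assume_a="pos")


def bias_regression_b(raw_scores: np.ndarray, reference: np.ndarray) -> float:
    """Least-squares slope of the reference values on the raw GEBV scores.

    The reference is the simulated true breeding value by default (an
    idealization; regressing on phenotypes is the field-deployable variant).
    A zero-variance score vector yields b = 0 with a warning.
    """
    raw_scores = np.asarray(raw_scores, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if raw_scores.size < 2:
        raise ValueError("need at least 2 candidates for the bias regression")
    var = raw_scores.var()
    if var == 0:
        warnings.warn("zero variance of raw GEBV scores; bias regression b set to 0")
        return 0.0
    cov = np.mean((raw_scores - raw_scores.mean()) * (reference - reference.mean()))
    return float(cov / var)


def gebv_marker_only(
    raw_scores: np.ndarray, b: float, group: np.ndarray
) -> GEBVResult:
    """GEBV = b * sum_j X_ij a_j (group means implicit in marker effects)."""
    raw_scores = np.asarray(raw_scores, dtype=np.float64)
    return GEBVResult(raw_score=raw_scores, gebv=b * raw_scores, group=np.asarray(group))


def gebv_with_group_mean(
    raw_scores: np.ndarray,
    b: float,
    group: np.ndarray,
    group_phen_mean: dict,
) -> GEBVResult:
    """GEBV = b * (sum_j X_ij a_j - mu_GEBV(group)) + mu_p(group).

    mu_GEBV is the mean raw score of the group's (preselected) candidates and
    mu_p the mean sib-trait phenotype of the group's test individuals; the
    within-group mean GEBV therefore equals the group phenotype mean by
    construction.
    """
    raw_scores = np.asarray(raw_scores, dtype=np.float64)
    group = np.asarray(group)
    gebv = np.empty_like(raw_scores)
    for gid in np.unique(group):
        sel = group == gid
        mu_gebv = raw_scores[sel].mean()
        gebv[sel] = b * (raw_scores[sel] - mu_gebv) + group_phen_mean[gid]
    return GEBVResult(raw_score=raw_scores, gebv=gebv, group=group)


def effective_pool_size(n: int, vt: float, p: float, m: int = 1) -> float:
    """Effective number of pooled individuals, [1/N + Vt/(p(1-p)m)]^-1.

    Combines the binomial sampling variance p(1-p)/N of a pool of N
    individuals with the technical error Vt/m of m replicate poolings into
    the pool size whose pure sampling variance would match.
    """
    if n <= 0:
        raise ValueError("N must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    if vt < 0:
        raise ValueError("Vt must be non-negative")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    return 1.0 / (1.0 / n + vt / (p * (1.0 - p) * m))
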