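"""Evaluation statistics: selection accuracy, pedigree inbreeding, genetic
gain and replicate aggregation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

UNKNOWN = -1  # parent code for pedigree founders


class Pedigree:
    """Append-only pedigree; parents must be recorded before their offspring.

    Individuals are integer ids in insertion order; ``UNKNOWN`` (-1) marks a
    founder parent.
    """

    def __init__(self) -> None:
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.generation: list[int] = []

    def __len__(self) -> int:
        return len(self.sire)

    def add(self, sires, dams, generation: int) -> np.ndarray:
        """Append offspring with the given parent ids; returns the new ids."""
        sires = np.atleast_1d(np.asarray(sires, dtype=np.int64))
        dams = np.atleast_1d(np.asarray(dams, dtype=np.int64))
        if sires.size != dams.size:
            raise ValueError("sire and dam arrays must have equal length")
        n = len(self)
        if np.any(sires >= n) or np.any(dams >= n):
            raise ValueError("parents must be recorded before their offspring")
        ids = np.arange(n, n + sires.size, dtype=np.int64)
        self.sire.extend(int(s) for s in sires)
        self.dam.extend(int(d) for d in dams)
        self.generation.extend([generation] * sires.size)
        return ids

    def add_founders(self, n: int, generation: int = 0) -> np.ndarray:
        return self.add([UNKNOWN] * n, [UNKNOWN] * n, generation)

    def to_frame(self):
        """Three-column table (id, sire, dam); 0 denotes an unknown parent."""
        import pandas as pd

        sire = np.asarray(self.sire) + 1
        dam = np.asarray(self.dam) + 1
        return pd.DataFrame(
            {
                "id": np.arange(1, len(self) + 1),
                "sire": np.where(sire > 0, sire, 0),
                "dam": np.where(dam > 0, dam, 0),
            }
        )


class KinshipCalculator:
    """Memoized Wright kinship (coancestry) recursion over a pedigree.

    kinship(a, a) = 0.5 (1 + F_a) with F_a the kinship of a's parents;
    kinship(a, b) for a younger than b is the mean kinship of a's parents
    with b.  Founders are unrelated and non-inbred.  The cache remains valid
    as the pedigree is appended to.
    """

    def __init__(self, pedigree: Pedigree) -> None:
        self.ped = pedigree
        self._cache: dict = {}

    def kinship(self, a: int, b: int) -> float:
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        if a < b:
            a, b = b, a
        key = (a, b)
        val = self._cache.get(key)
        if val is not None:
            return val
        sire, dam = self.ped.sire[a], self.ped.dam[a]
        if sire == a or dam == a:
            raise ValueError(f"individual {a} is its own ancestor")
        if a == b:
            val = 0.5 * (1.0 + self.kinship(sire, dam))
        else:
            # a has the larger id, hence cannot be an ancestor of b
            val = 0.5 * (self.kinship(sire, b) + self.kinship(dam, b))
        self._cache[key] = val
        return val

    def inbreeding(self, individual: int) -> float:
        return self.kinship(self.ped.sire[individual], self.ped.dam[individual])


def pedigree_inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Wright's inbreeding coefficient for every individual (founders: 0)."""
    calc = KinshipCalculator(pedigree)
    return np.array([calc.inbreeding(i) for i in range(len(pedigree))])


def selection_accuracy(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between true and estimated breeding values.

    Intended to be evaluated on the preselected candidates.  Degenerate
    inputs (zero variance) yield NaN with a warning; aggregation excludes
    and counts such values.
    """
    tbv = np.asarray(tbv, dtype=np.float64)
    gebv = np.asarray(gebv, dtype=np.float64)
    if tbv.size != gebv.size or tbv.size < 2:
        raise ValueError("need >= 2 paired values")
    if tbv.std() == 0 or gebv.std() == 0:
        warnings.warn("zero variance in TBV or GEBV; accuracy undefined")
        return float("nan")
    return float(np.corrcoef(tbv, gebv)[0, 1])


def rate_of_inbreeding(mean_f: np.ndarray) -> float:
    """Mean per-generation rate dF = (F_t - F_{t-1}) / (1 - F_{t-1})."""
    f = np.asarray(mean_f, dtype=np.float64)
    if f.size < 2:
        raise ValueError("need mean F for at least 2 generations")
    if np.any(f >= 1.0):
        raise ValueError("inbreeding coefficients must be < 1")
    rates = (f[1:] - f[:-1]) / (1.0 - f[:-1])
    return float(rates.mean())


def genetic_gain(mean_tbv: np.ndarray, sigma_a0: float) -> tuple[float, float]:
    """Gain in base-generation genetic-standard-deviation units.

    Returns (cumulative, per_generation): the cumulative change of mean TBV
    from the first to the last entry divided by sigma_a0, and the same
    divided by the number of generation steps.
    """
    if sigma_a0 <= 0:
        raise ValueError("sigma_a0 must be positive")
    tbv = np.asarray(mean_tbv, dtype=np.float64)
    cumulative = (tbv[-1] - tbv[0]) / sigma_a0
    per_gen = cumulative / max(tbv.size - 1, 1)
    return float(cumulative), float(per_gen)


@dataclass
class ReplicateResult:
    """Per-generation outcomes of one simulated breeding-scheme replicate.

    ``mean_tbv`` has one row per cohort starting at the G0 parents; ``acc``
    and ``mean_f`` cover the offspring cohorts G1..Gn.  ``sigma_a0`` is the
    per-trait TBV standard deviation of the G0 parents, the unit in which
    gains are expressed.
    """

    scenario_id: str
    seed: int
    acc: np.ndarray  # (n_gen,) accuracy among preselected candidates
    mean_tbv: np.ndarray  # (n_gen + 1, 2) per-trait cohort means, row 0 = G0
    mean_f: np.ndarray  # (n_gen,) mean pedigree F of cohorts G1..Gn
    sigma_a0: np.ndarray  # (2,)
    meta: dict = field(default_factory=dict)

    @property
    def acc_mean(self) -> float:
        """Accuracy averaged over the selection rounds (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(self.acc))

    @property
    def delta_f(self) -> float:
        return rate_of_inbreeding(self.mean_f)

    def gain(self, trait: int) -> tuple[float, float]:
        return genetic_gain(self.mean_tbv[:, trait], self.sigma_a0[trait])


@dataclass
class ScenarioSummary:
    """Replicate means and standard errors for one scenario."""

    scenario_id: str
    n_replicates: int
    acc: float
    acc_se: float
    delta_f: float
    delta_f_se: float
    gain_sib: float
    gain_sib_se: float
    gain_growth: float
    gain_growth_se: float
    n_missing_acc: int = 0

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_id,
            "n_replicates": self.n_replicates,
            "acc_sib": self.acc,
            "acc_sib_se": self.acc_se,
            "delta_f": self.delta_f,
            "delta_f_se": self.delta_f_se,
            "gain_sib": self.gain_sib,
            "gain_sib_se": self.gain_sib_se,
            "gain_growth": self.gain_growth,
            "gain_growth_se": self.gain_growth_se,
            "n_missing_acc": self.n_missing_acc,
        }


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    se = values.std(ddof=1) / np.sqrt(values.size) if values.size > 1 else float("nan")
    return float(values.mean()), float(se)


def summarize_replicates(results: list[ReplicateResult]) -> ScenarioSummary:
    """Aggregate replicates of one scenario into means and standard errors.

    Gains are the cumulative change at the final generation.  Replicates
    with undefined (NaN) accuracy are excluded from the accuracy mean and
    counted in ``n_missing_acc``.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 replicates to summarize")
    ids = {r.scenario_id for r in results}
    if len(ids) != 1:
        raise ValueError(f"mixed scenarios in one summary: {sorted(ids)}")
    from . import genome as _genome

    acc = np.array([r.acc_mean for r in results])
    df = np.array([r.delta_f for r in results])
    g_sib = np.array([r.gain(_genome.SIB_TRAIT)[0] for r in results])
    g_gro = np.array([r.gain(_genome.GROWTH)[0] for r in results])
    acc_m, acc_se = _mean_se(acc)
    df_m, df_se = _mean_se(df)
    gs_m, gs_se = _mean_se(g_sib)
    gg_m, gg_se = _mean_se(g_gro)
    return ScenarioSummary(
        scenario_id=results[0].scenario_id,
        n_replicates=len(results),
        acc=acc_m,
        acc_se=acc_se,
        delta_f=df_m,
        delta_f_se=df_se,
        gain_sib=gs_m,
        gain_sib_se=gs_se,
        gain_growth=gg_m,
        gain_growth_se=gg_se,
        n_missing_acc=int(np.isnan(acc).sum()),
    )
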