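"""Shared fixtures: reduced-scale populations reused across test modules.

The expensive session fixtures simulate once and are read-only; tests that
mutate state build their own objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from poolgs import GenomeConfig, build_base_population, simulate_history
from poolgs.experiment import desk_comparison_grid, run_grid


@pytest.fixture(scope="session")
def small_genome() -> GenomeConfig:
    """Reduced genome keeping 4*Ne*mu per cM in the study's range."""
    return GenomeConfig(
        n_chromosomes=5,
        ne=100,
        n_history_generations=150,
        mutation_multiplier=20.0,
        n_qtl_per_chrom=20,
        n_markers_full=200,
    )


@pytest.fixture(scope="session")
def small_history(small_genome):
    return simulate_history(small_genome, seed=2026)


@pytest.fixture(scope="session")
def small_base(small_genome, small_history):
    return build_base_population(small_history, small_genome, seed=2027)


@pytest.fixture(scope="session")
def micro_genome() -> GenomeConfig:
    """Minutes-scale genome for determinism and orchestration tests."""
    return GenomeConfig(
        n_chromosomes=2,
        chrom_length=0.5,
        ne=40,
        n_history_generations=40,
        mutation_multiplier=50.0,
        n_qtl_per_chrom=5,
        n_markers_full=20,
        maf_threshold=0.05,
    )


@pytest.fixture(scope="session")
def desk_base():
    """One desk-scale base population (history + panel + effects)."""
    genome, _ = __import__("poolgs").experiment.PRESETS["desk"]
    hist = simulate_history(genome, seed=909)
    return genome, build_base_population(hist, genome, seed=910)


@pytest.fixture(scope="session")
def desk_battery():
    """The desk-scale scenario battery: 6 scenarios x 10 paired replicates.

    Scenarios share the per-replicate historical population, so replicate-
    wise differences between scenarios are paired observations.
    """
    grid = desk_comparison_grid(replicates=10, master_seed=1)
    results, summaries = run_grid(grid)
    by_scenario: dict[str, list] = {}
    for r in results:
        by_scenario.setdefault(r.scenario_id, []).append(r)
    for sid, rs in by_scenario.items():
        assert len(rs) == 10, f"scenario {sid} lost replicates"
        rs.sort(key=lambda r: r.meta["replicate"])
    return by_scenario


def paired_acc(battery, scenario_a: str, scenario_b: str):
    """Replicate-paired mean accuracies of two scenarios."""
    a = np.array([r.acc_mean for r in battery[scenario_a]])
    b = np.array([r.acc_mean for r in battery[scenario_b]])
    return a, b
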