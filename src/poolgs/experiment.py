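"""Scenario grids, configuration files, seeds and replicate orchestration.

A scenario grid pairs a genome configuration with a list of scheme
configurations (scenarios) and runs each for a number of replicates with
deterministically derived seeds: the triple (master seed, scenario id,
replicate index) fully determines a replicate's output.  Historical
populations — by far the most expensive step — can be shared across
scenarios of the same replicate index, which also pairs the scenarios for
low-variance comparisons.

Configuration files are YAML with a ``version`` field; unknown keys are
rejected and all validation errors are reported together before any
computation starts.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass

import numpy as np
import yaml

from .genome import GenomeConfig, simulate_history
from .metrics import ReplicateResult, ScenarioSummary, summarize_replicates
from .scheme import SchemeConfig, build_base_population, run_replicate

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1

#: named scale profiles: full study conditions and a desk-scale profile that
#: keeps the population-scaled diversity 4*Ne*mu per cM constant while
#: shrinking the historical burn-in and cohort sizes
PRESETS = {
    "paper": (GenomeConfig(), SchemeConfig()),
    "desk": (
        GenomeConfig(
            ne=200,
            n_history_generations=400,
            mutation_multiplier=10.0,
            n_markers_full=500,
        ),
        SchemeConfig(
            n_fam=50,
            n_fam_per_group=10,
            n_cand=2000,
            n_test=2000,
            n_presel=400,
            n_markers=500,
        ),
    ),
}


class ConfigError(ValueError):
    """Invalid or inconsistent scenario-grid configuration."""


@dataclass
class Scenario:
    scenario_id: str
    genome: GenomeConfig
    scheme: SchemeConfig


@dataclass
class ScenarioGrid:
    scenarios: list[Scenario]
    replicates: int = 10
    master_seed: int = 1
    share_history: bool = True

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ConfigError("scenario grid is empty")
        ids = [s.scenario_id for s in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ConfigError("scenario ids must be unique")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


def _apply_overrides(cfg, overrides: dict, context: str, errors: list):
    if not overrides:
        return cfg
    known = {f.name for f in dataclasses.fields(cfg)}
    unknown = set(overrides) - known
    if unknown:
        errors.append(f"{context}: unknown keys {sorted(unknown)}")
        return cfg
    try:
        return dataclasses.replace(cfg, **overrides)
    except ValueError as exc:
        errors.append(f"{context}: {exc}")
        return cfg


def grid_from_dict(raw: dict) -> ScenarioGrid:
    """Build and fully validate a grid from a parsed configuration mapping."""
    errors: list[str] = []
    known_top = {
        "version", "preset", "replicates", "master_seed", "share_history",
        "genome", "scheme", "scenarios",
    }
    unknown = set(raw) - known_top
    if unknown:
        errors.append(f"unknown top-level keys {sorted(unknown)}")
    version = raw.get("version")
    if version != CONFIG_VERSION:
        errors.append(f"config version must be {CONFIG_VERSION}, got {version!r}")
    preset = raw.get("preset", "paper")
    if preset not in PRESETS:
        errors.append(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        preset = "paper"
    genome0, scheme0 = PRESETS[preset]
    genome0 = _apply_overrides(genome0, raw.get("genome") or {}, "genome", errors)
    scheme0 = _apply_overrides(scheme0, raw.get("scheme") or {}, "scheme", errors)

    entries = raw.get("scenarios")
    scenarios: list[Scenario] = []
    if not entries:
        errors.append("no scenarios defined")
    else:
        for i, entry in enumerate(entries):
            if not isinstance(entry, dict):
                errors.append(f"scenario #{i}: expected a mapping")
                continue
            unknown = set(entry) - {"id", "genome", "scheme"}
            if unknown:
                errors.append(f"scenario #{i}: unknown keys {sorted(unknown)}")
            sid = str(entry.get("id", f"scenario{i}"))
            g = _apply_overrides(genome0, entry.get("genome") or {}, f"scenario {sid} genome", errors)
            s = _apply_overrides(scheme0, entry.get("scheme") or {}, f"scenario {sid} scheme", errors)
            if g.n_markers_full % s.n_markers:
                errors.append(
                    f"scenario {sid}: n_markers={s.n_markers} does not divide "
                    f"the full panel of {g.n_markers_full}"
                )
            scenarios.append(Scenario(sid, g, s))
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return ScenarioGrid(
        scenarios=scenarios,
        replicates=int(raw.get("replicates", 10)),
        master_seed=int(raw.get("master_seed", 1)),
        share_history=bool(raw.get("share_history", True)),
    )


def load_config(path) -> ScenarioGrid:
    """Load and validate a YAML scenario-grid configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a YAML mapping")
    return grid_from_dict(raw)


def _scenario_tag(scenario_id: str) -> int:
    """Stable 31-bit tag of a scenario id for seed derivation."""
    return zlib.crc32(scenario_id.encode()) & 0x7FFFFFFF


def _history_key(g: GenomeConfig) -> tuple:
    """Fields that determine the historical population (not the panel)."""
    return (
        g.n_chromosomes, g.chrom_length, g.nt_per_cm, g.mutation_rate,
        g.mutation_multiplier, g.ne, g.n_history_generations,
    )


def _base_key(g: GenomeConfig) -> tuple:
    """Fields that additionally determine panel, QTL and effects."""
    return _history_key(g) + (
        g.maf_threshold, g.n_qtl_per_chrom, g.n_markers_full,
        g.gamma_shape, g.gamma_scale, g.effect_correlation,
    )


def replicate_seed(master_seed: int, scenario_id: str, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(master_seed), _scenario_tag(scenario_id), int(replicate)]
    )


def run_grid(
    grid: ScenarioGrid, out_dir=None, progress: bool = False
) -> tuple[list[ReplicateResult], list[ScenarioSummary]]:
    """Run every scenario of the grid for every replicate.

    With ``share_history`` the historical population (and the trait
    architecture built on it, when the panel parameters agree) is computed
    once per replicate index and reused by all scenarios, pairing the
    scenarios on the same base population.  Failing replicates are logged
    and skipped; summaries record how many replicates completed.
    """
    results: list[ReplicateResult] = []
    summaries: list[ScenarioSummary] = []
    by_scenario: dict[str, list[ReplicateResult]] = {s.scenario_id: [] for s in grid.scenarios}

    for rep in range(grid.replicates):
        histories: dict = {}
        bases: dict = {}
        for scn in grid.scenarios:
            seed = replicate_seed(grid.master_seed, scn.scenario_id, rep)
            t0 = time.perf_counter()
            try:
                base = None
                if grid.share_history:
                    hkey = _history_key(scn.genome)
                    bkey = _base_key(scn.genome)
                    if bkey not in bases:
                        if hkey not in histories:
                            hist_ss = np.random.SeedSequence(
                                [int(grid.master_seed), 0x48495354, rep]
                            )
                            histories[hkey] = simulate_history(scn.genome, seed=hist_ss)
                        arch_ss = np.random.SeedSequence(
                            [int(grid.master_seed), 0x41524348, rep]
                        )
                        bases[bkey] = build_base_population(
                            histories[hkey], scn.genome, seed=arch_ss
                        )
                    base = bases[bkey]
                res = run_replicate(
                    scn.genome, scn.scheme, seed,
                    scenario_id=scn.scenario_id, base=base,
                )
            except Exception:
                logger.exception(
                    "replicate %d of scenario %s failed", rep, scn.scenario_id
                )
                continue
            res.meta["replicate"] = rep
            res.meta["runtime_s"] = round(time.perf_counter() - t0, 3)
            results.append(res)
            by_scenario[scn.scenario_id].append(res)
            if progress:
                print(
                    f"[{scn.scenario_id} rep {rep}] acc={res.acc_mean:.3f} "
                    f"dF={res.delta_f:.4f} ({res.meta['runtime_s']}s)",
                    flush=True,
                )

    for scn in grid.scenarios:
        done = by_scenario[scn.scenario_id]
        if len(done) >= 2:
            summaries.append(summarize_replicates(done))
        else:
            logger.warning(
                "scenario %s: only %d completed replicates, no summary",
                scn.scenario_id, len(done),
            )

    if out_dir is not None:
        write_results(grid, results, summaries, out_dir)
    return results, summaries


def results_frame(results: list[ReplicateResult]):
    """Per-replicate long table of the headline statistics."""
    import pandas as pd

    from .genome import GROWTH, SIB_TRAIT

    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.scenario_id,
                "replicate": r.meta.get("replicate", -1),
                "acc_sib": r.acc_mean,
                "delta_f": r.delta_f,
                "gain_sib": r.gain(SIB_TRAIT)[0],
                "gain_growth": r.gain(GROWTH)[0],
                "acc_sib_final": r.acc[-1] if r.acc.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summary_frame(summaries: list[ScenarioSummary]):
    import pandas as pd

    return pd.DataFrame([s.to_dict() for s in summaries])


def write_results(grid, results, summaries, out_dir) -> None:
    """Write per-replicate and per-scenario delimited tables."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    header = f"# poolgs results; master_seed={grid.master_seed}; replicates={grid.replicates}\n"
    for name, frame in (
        ("replicates.csv", results_frame(results)),
        ("summary.csv", summary_frame(summaries)),
    ):
        path = os.path.join(out_dir, name)
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)


def paper_table1_grid(replicates: int = 100, master_seed: int = 1) -> ScenarioGrid:
    """The main full-scale comparison grid: Ntest in {2000, 20000, 50000} by
    Nfampergroup in {1, 10, 100} by marker panels ({500, 10000}; additionally
    5000 at Ntest=20000), 21 scenarios."""
    genome, scheme0 = PRESETS["paper"]
    scenarios = []
    for n_test in (2000, 20_000, 50_000):
        panels = (500, 5000, 10_000) if n_test == 20_000 else (500, 10_000)
        for nfpg in (1, 10, 100):
            for n_markers in panels:
                sid = f"ntest{n_test}_nfpg{nfpg}_m{n_markers}"
                scenarios.append(
                    Scenario(
                        sid,
                        genome,
                        dataclasses.replace(
                            scheme0,
                            n_test=n_test,
                            n_fam_per_group=nfpg,
                            n_markers=n_markers,
                        ),
                    )
                )
    return ScenarioGrid(
        scenarios=scenarios, replicates=replicates, master_seed=master_seed
    )


def desk_comparison_grid(replicates: int = 10, master_seed: int = 1) -> ScenarioGrid:
    """Desk-scale scenario battery probing the main design contrasts.

    Relative to the desk base scenario (Ntest = 2000, 10 families per group,
    500 markers, h2_sib = 0.4, phenotypic group means), one factor changes
    per scenario: fewer test individuals, single-family groups, a thinned
    50-marker panel, low sib-trait heritability, and marker-estimated group
    means at one family per group.
    """
    genome, base = PRESETS["desk"]

    def scn(sid, **kw):
        return Scenario(sid, genome, dataclasses.replace(base, **kw))

    scenarios = [
        scn("base"),
        scn("ntest_low", n_test=200),
        scn("nfpg1", n_fam_per_group=1),
        scn("markers_low", n_markers=50),
        scn("h2_low", h2_sib=0.1),
        scn("nfpg1_eq2", n_fam_per_group=1, gebv_equation="marker_group_mean"),
    ]
    return ScenarioGrid(
        scenarios=scenarios, replicates=replicates, master_seed=master_seed,
        share_history=True,
    )
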