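"""Recurrent-program orchestration: burn-in, breeding cycles, replicate runs.

A program starts from a common randomised burn-in cycle: a random crossing
plan among the founders, one pass through the testing ladder, and the top
D clones joining the founders as candidate parents.  Every later cycle
scores the legal candidate crosses with the configured criterion, plans the
top crosses, simulates their seedlings, runs the ladder, records metrics at
the D stage, and refreshes the candidate-parent pool (new top D clones in,
randomly chosen unused parents out).

Randomness is hierarchical: a master seed spawns independent streams per
run and per cycle (and separate streams for founder generation, trait
architecture and scoring), so any stage is replayable in isolation and the
burn-in state is shared across criteria for paired comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .containers import HaplotypeSet
from .crossing import CrossSelector, candidate_crosses, select_crossing_plan
from .founders import generate_founders
from .metrics import genetic_gain, progeny_mean_accuracy, qtl_fixation_counts
from .meiosis import progeny_for_crosses
from .phenogs import GSProxy, calibrate_variances, simulate_phenotypes
from .selection import STRATEGY_PRESETS, run_stage_ladder
from .traits import derive_auxiliary_architecture, sample_architecture, true_values

logger = logging.getLogger(__name__)

# Stream namespaces under the master seed.
_NS_FOUNDERS = 0
_NS_ARCH = 1
_NS_BURNIN = 2
_NS_CYCLE = 3
_NS_SCORE = 4


def stream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for a hierarchical stream key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class ProgramState:
    """Mutable bookkeeping of one simulation run."""

    cycle: int
    pool: HaplotypeSet  # candidate parents (founder-panel markers)
    new_ids: list[str]  # most recent parent cohort
    used: set[frozenset]
    founder_mean_tgv: float
    arch_t: object
    arch_a: object
    vm: object
    gs: GSProxy
    metrics: list[dict] = field(default_factory=list)
    census_logs: list[pd.DataFrame] = field(default_factory=list)
    plans: list[pd.DataFrame] = field(default_factory=list)


def _selector(config: ScenarioConfig) -> CrossSelector:
    return CrossSelector(
        method=config.criterion,
        w1=config.w1,
        w2=config.w2,
        n_sim=config.n_sim_cross,
        pa=config.pa,
        per_cross_selected=config.per_cross_selected,
        he_panel=config.he_panel,
        sigma_from_proxy=config.sigma_from_proxy,
    )


def _strategy(config: ScenarioConfig):
    return STRATEGY_PRESETS[config.strategy](n_sl=config.n_sl, n_d=config.n_d)


def _simulate_plan_progeny(
    pool: HaplotypeSet,
    plan: pd.DataFrame,
    n_per_cross: int,
    cycle: int,
    rng: np.random.Generator,
) -> HaplotypeSet:
    pairs = np.stack(
        [pool.index_of(plan["parent1"]), pool.index_of(plan["parent2"])], axis=1
    )
    hap = progeny_for_crosses(pool, pairs, n_per_cross, rng)
    ids = np.array(
        [f"C{cycle:02d}S{i:06d}" for i in range(hap.shape[0])], dtype=object
    )
    return HaplotypeSet(hap, ids, pool.gmap)


def _record_metrics(
    state: ProgramState,
    config: ScenarioConfig,
    d_pop: HaplotypeSet,
    predicted_mu: np.ndarray,
    realized_mu: np.ndarray,
    cycle: int,
) -> None:
    tv_d = true_values(d_pop, state.arch_t, "Tt")
    fixed, lost = qtl_fixation_counts(d_pop, state.arch_t)
    state.metrics.append(
        {
            "cycle": cycle,
            "gain": genetic_gain(tv_d.tgv, state.founder_mean_tgv),
            "variance": float(np.var(tv_d.tgv, ddof=1)),
            "he": d_pop.expected_heterozygosity(),
            "n_fixed": fixed,
            "n_lost": lost,
            "accuracy": progeny_mean_accuracy(predicted_mu, realized_mu),
        }
    )


def run_burn_in(
    founders: HaplotypeSet, config: ScenarioConfig, run: int
) -> ProgramState:
    """Common randomised starting cycle; returns the post-burn-in state."""
    if founders.n_clones < 2:
        raise ValueError("need at least two founders")
    seed = config.seed
    rng_arch = stream(seed, run, _NS_ARCH)
    arch_t = sample_architecture(
        config.n_qtl, founders, rng_arch, dominance_scale=config.dominance
    )
    arch_a = derive_auxiliary_architecture(arch_t, config.r_aux, founders, rng_arch)
    gs = GSProxy(config.pa)

    rng = stream(seed, run, _NS_BURNIN)
    candidates = candidate_crosses(0, list(founders.ids), [])
    if len(candidates) < config.n_plan:
        raise ValueError("not enough founder crosses for the burn-in plan")
    pick = rng.choice(len(candidates), size=config.n_plan, replace=False)
    plan_pairs = [candidates[i] for i in sorted(pick)]
    plan = pd.DataFrame(
        {"parent1": [p[0] for p in plan_pairs], "parent2": [p[1] for p in plan_pairs]}
    )

    sl_pop = _simulate_plan_progeny(founders, plan, config.progeny_per_cross, 0, rng)
    tv_sl_t = true_values(sl_pop, arch_t, "Tt")
    tv_sl_a = true_values(sl_pop, arch_a, "Ta")
    vm = calibrate_variances(
        tv_sl_t, tv_sl_a, config.variance_ratio, config.h2_ta, config.locations
    )

    strategy = _strategy(config)
    ladder = run_stage_ladder(sl_pop, strategy, arch_t, arch_a, vm, gs, rng)
    d_pop, d_phen = ladder.d_population, ladder.d_phenotypes

    top = np.sort(np.argsort(-d_phen, kind="stable")[: config.n_parents_new])
    new_clones = d_pop.subset_clones(top)
    new_ids = [f"C00D{cid}" for cid in new_clones.ids]
    new_clones = HaplotypeSet(
        new_clones.haplotypes, np.asarray(new_ids, dtype=object), new_clones.gmap
    )
    pool = HaplotypeSet.concatenate([founders, new_clones])

    founder_mean = float(true_values(founders, arch_t, "Tt").tgv.mean())
    state = ProgramState(
        cycle=0,
        pool=pool,
        new_ids=new_ids,
        used={frozenset(p) for p in plan_pairs},
        founder_mean_tgv=founder_mean,
        arch_t=arch_t,
        arch_a=arch_a,
        vm=vm,
        gs=gs,
    )
    state.census_logs.append(ladder.census_log.assign(cycle=0))
    state.plans.append(plan.assign(cycle=0))

    # progeny-mean prediction accuracy of the configured criterion on the
    # burn-in plan (the plan itself was random, not criterion-selected)
    rng_sc = stream(seed, run, _NS_SCORE, 0)
    founder_phen = simulate_phenotypes(
        true_values(founders, arch_t, "Tt").tgv, vm, "D", rng_sc
    )
    scores = _selector(config).score(
        founders, plan_pairs, arch_t, rng_sc, parent_phenotypes=founder_phen
    )
    realized = (
        true_values(sl_pop, arch_t, "Tt").tgv
        .reshape(config.n_plan, config.progeny_per_cross)
        .mean(axis=1)
    )
    _record_metrics(state, config, d_pop, scores["mu"].to_numpy(), realized, 0)
    return state


def update_candidate_parents(
    pool: HaplotypeSet,
    usage: np.ndarray,
    new_clones: HaplotypeSet,
    n_remove: int,
    rng: np.random.Generator,
) -> HaplotypeSet:
    """Drop ``n_remove`` little-used parents and admit the new cohort.

    Removal candidates are the parents unused in the current plan; if fewer
    than ``n_remove`` exist the pool is extended to parents used once, then
    twice.  A remaining shortfall removes every available candidate and is
    logged.
    """
    removable = np.array([], dtype=np.intp)
    for cap in (0, 1, 2):
        removable = np.flatnonzero(usage <= cap)
        if removable.size >= n_remove:
            break
    if removable.size < n_remove:
        logger.warning(
            "removal shortfall: only %d of %d candidate parents removable",
            removable.size,
            n_remove,
        )
        drop = removable
    else:
        drop = removable[
            np.sort(rng.choice(removable.size, size=n_remove, replace=False))
        ]
    keep = np.setdiff1d(np.arange(pool.n_clones), drop)
    return HaplotypeSet.concatenate([pool.subset_clones(keep), new_clones])


def run_cycle(state: ProgramState, config: ScenarioConfig, run: int) -> ProgramState:
    """Advance the program by one breeding cycle (in place) and return it."""
    t = state.cycle + 1
    rng = stream(config.seed, run, _NS_CYCLE, t)
    pool_ids = list(state.pool.ids)
    if t == 1:
        old = [i for i in pool_ids if i not in set(state.new_ids)]
        candidates = candidate_crosses(1, old, state.new_ids, state.used)
    else:
        old = [i for i in pool_ids if i not in set(state.new_ids)]
        candidates = candidate_crosses(t, old, state.new_ids, state.used)

    selector = _selector(config)
    parent_phen = None
    if selector.needs_parent_phenotypes:
        pool_tgv = true_values(state.pool, state.arch_t, "Tt").tgv
        parent_phen = simulate_phenotypes(pool_tgv, state.vm, "D", rng)
    scores = selector.score(
        state.pool, candidates, state.arch_t, rng, parent_phenotypes=parent_phen
    )
    plan = select_crossing_plan(scores, config.n_plan)
    plan_pairs = list(zip(plan["parent1"], plan["parent2"]))
    state.used |= {frozenset(p) for p in plan_pairs}

    id_pos = {cid: i for i, cid in enumerate(pool_ids)}
    usage = np.zeros(state.pool.n_clones, dtype=np.int64)
    for p1, p2 in plan_pairs:
        usage[id_pos[p1]] += 1
        usage[id_pos[p2]] += 1

    sl_pop = _simulate_plan_progeny(state.pool, plan, config.progeny_per_cross, t, rng)
    tv_sl = true_values(sl_pop, state.arch_t, "Tt")
    state.vm.update_sigma_g(float(np.var(tv_sl.tgv, ddof=1)))

    strategy = _strategy(config)
    ladder = run_stage_ladder(
        sl_pop, strategy, state.arch_t, state.arch_a, state.vm, state.gs, rng
    )
    d_pop, d_phen = ladder.d_population, ladder.d_phenotypes
    state.census_logs.append(ladder.census_log.assign(cycle=t))
    state.plans.append(plan.assign(cycle=t))

    realized = tv_sl.tgv.reshape(config.n_plan, config.progeny_per_cross).mean(axis=1)
    _record_metrics(state, config, d_pop, plan["mu"].to_numpy(), realized, t)

    top = np.sort(np.argsort(-d_phen, kind="stable")[: config.n_parents_new])
    new_clones = d_pop.subset_clones(top)
    new_ids = [f"C{t:02d}D{cid}" for cid in new_clones.ids]
    new_clones = HaplotypeSet(
        new_clones.haplotypes, np.asarray(new_ids, dtype=object), new_clones.gmap
    )
    state.pool = update_candidate_parents(
        state.pool, usage, new_clones, config.n_parents_new, rng
    )
    state.new_ids = new_ids
    state.cycle = t
    return state


@dataclass
class ExperimentResult:
    """Per-run-per-cycle metrics and their across-run aggregate."""

    config: ScenarioConfig
    per_run: pd.DataFrame  # columns: run, cycle, gain, variance, he, ...
    aggregate: pd.DataFrame  # per cycle: mean and sd of each metric

    def trajectory(self, metric: str) -> pd.Series:
        """Run-averaged series of a metric indexed by cycle."""
        return self.aggregate.set_index("cycle")[f"{metric}_mean"]


def _aggregate(per_run: pd.DataFrame) -> pd.DataFrame:
    metrics = [c for c in per_run.columns if c not in ("run", "cycle")]
    grouped = per_run.groupby("cycle")[metrics].agg(["mean", "std"])
    grouped.columns = [f"{m}_{s}" for m, s in grouped.columns]
    return grouped.reset_index()


def run_single(config: ScenarioConfig, run: int, founders: HaplotypeSet) -> ProgramState:
    """One complete run: burn-in plus ``n_cycles`` breeding cycles."""
    state = run_burn_in(founders, config, run)
    for _ in range(config.n_cycles):
        run_cycle(state, config, run)
    return state


def make_founders(config: ScenarioConfig) -> HaplotypeSet:
    """Founder panel of an experiment (one panel shared by all runs)."""
    return generate_founders(
        n_founders=config.n_founders,
        n_chrom=config.n_chrom,
        markers_per_chrom=config.markers_per_chrom,
        map_length_per_chrom=config.map_length_per_chrom,
        maf_min=config.maf_min,
        burnin_generations=config.burnin_generations,
        seed=stream(config.seed, _NS_FOUNDERS),
    )


def run_experiment(
    config: ScenarioConfig,
    out_dir: str | Path | None = None,
    founders: HaplotypeSet | None = None,
) -> ExperimentResult:
    """Run all replicates of a scenario and aggregate the metrics.

    When ``out_dir`` is given, per-run metric tables are written as
    ``run_<i>.tsv`` as soon as each run completes, and runs whose table is
    already present are loaded instead of re-simulated, which makes an
    interrupted experiment resumable.
    """
    if founders is None:
        founders = make_founders(config)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    frames = []
    for run in range(config.n_runs):
        cache = out_path / f"run_{run:03d}.tsv" if out_path is not None else None
        if cache is not None and cache.exists():
            frames.append(pd.read_csv(cache, sep="\t"))
            continue
        state = run_single(config, run, founders)
        frame = pd.DataFrame(state.metrics)
        frame.insert(0, "run", run)
        if cache is not None:
            frame.to_csv(cache, sep="\t", index=False)
        frames.append(frame)
    per_run = pd.concat(frames, ignore_index=True)
    return ExperimentResult(config, per_run, _aggregate(per_run))
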