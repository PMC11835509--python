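"""Stage-wise truncation selection through the clonal testing ladder.

A breeding cycle tests material through six stages — seedling (SL), single
hill (SH), A, B, C and D clones — with five selection events (p1..p5)
between them.  The first three stages are selected on phenotypes of the
auxiliary trait; B and C are selected on multi-location phenotypes of the
target trait.  Under the genomic-selection strategy the SH and A selection
events use a two-step filter: a fraction ``alpha_k`` of the stage's clones
is pre-screened by auxiliary-trait phenotype and genotyped, and the stage's
selected proportion is then met by ranking that genotyped subset on
estimated genetic values of the target trait.

Three named strategy presets are shipped.  Exact stage proportions of the
program they emulate are not public, so the presets are documented package
defaults: the standard scheme culls hard in the early auxiliary-trait
stages; the optimised phenotypic scheme shifts intensity onto the
target-trait stages; and the optimised genomic scheme concentrates
intensity at the genotyped SH and A stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import HaplotypeSet
from .phenogs import GSProxy, VarianceModel, simulate_phenotypes
from .traits import TraitArchitecture, true_values

#: Selection events in ladder order; the trait each one selects on.
STAGE_ORDER = ("SL", "SH", "A", "B", "C")
STAGE_TRAIT = {"SL": "Ta", "SH": "Ta", "A": "Ta", "B": "Tt", "C": "Tt"}


def selection_intensity(p: float) -> float:
    """Standardised truncation selection intensity ``i = phi(z) / p``.

    ``z`` is the standard-normal quantile at ``1 - p``; ``p = 0.1`` gives
    the classical 1.755.
    """
    if not 0 < p <= 1:
        raise ValueError("selected proportion must lie in (0, 1]")
    if p == 1.0:
        return 0.0
    return float(norm.pdf(norm.ppf(1.0 - p)) / p)


def truncate(values: np.ndarray, p: float) -> np.ndarray:
    """Indices of the top ``ceil(p * n)`` values, ties broken by index order."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot select from an empty set")
    if not np.all(np.isfinite(values)):
        raise ValueError("selection values must be finite")
    if not 0 < p <= 1:
        raise ValueError("selected proportion must lie in (0, 1]")
    k = math.ceil(p * values.size)
    order = np.argsort(-values, kind="stable")
    return np.sort(order[:k])


def _top_k(values: np.ndarray, k: int) -> np.ndarray:
    order = np.argsort(-np.asarray(values, dtype=np.float64), kind="stable")
    return np.sort(order[:k])


@dataclass
class SelectionStrategy:
    """Stage proportions, genotyping fractions and censuses of one strategy."""

    kind: str  # 'standard-ps' | 'optimal-ps' | 'optimal-gs'
    proportions: dict[str, float]  # stage -> p for SL, SH, A, B, C
    n_sl: int = 3000  # census entering the seedling stage
    n_d: int = 60  # census at the D clone stage
    gs_stages: tuple[str, ...] = ()
    alpha: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in STAGE_ORDER:
            if s not in self.proportions:
                raise ValueError(f"missing selected proportion for stage {s}")
            if not 0 < self.proportions[s] <= 1:
                raise ValueError(f"selected proportion at {s} must lie in (0, 1]")
        for s in self.gs_stages:
            a = self.alpha.get(s)
            if a is None or not 0 < a <= 1:
                raise ValueError(f"GS stage {s} needs alpha in (0, 1]")
            if self.proportions[s] > a:
                raise ValueError(
                    f"stage {s}: selected proportion {self.proportions[s]} exceeds "
                    f"the genotyped fraction alpha={a}"
                )
        if self.n_sl < self.n_d:
            raise ValueError("seedling census must be at least the D census")

    def expected_census(self) -> dict[str, int]:
        """Census entering each stage under ceiling rounding."""
        census = {"SL": self.n_sl}
        n = self.n_sl
        for prev, nxt in zip(STAGE_ORDER, ("SH", "A", "B", "C", "D")):
            n = self.n_d if nxt == "D" else math.ceil(self.proportions[prev] * n)
            census[nxt] = n
        return census


def standard_ps(n_sl: int = 3000, n_d: int = 60) -> SelectionStrategy:
    """Benchmark phenotypic scheme: heavy early culling on the auxiliary trait."""
    return SelectionStrategy(
        kind="standard-ps",
        proportions={"SL": 0.2, "SH": 0.4, "A": 0.5, "B": 0.7, "C": 60 / 84},
        n_sl=n_sl,
        n_d=n_d,
    )


def optimal_ps(n_sl: int = 3000, n_d: int = 60) -> SelectionStrategy:
    """Optimised phenotypic scheme: intensity shifted to the target-trait stages."""
    return SelectionStrategy(
        kind="optimal-ps",
        proportions={"SL": 0.5, "SH": 0.5, "A": 8 / 15, "B": 0.3, "C": 0.5},
        n_sl=n_sl,
        n_d=n_d,
    )


def optimal_gs(n_sl: int = 3000, n_d: int = 60) -> SelectionStrategy:
    """Genomic scheme: two-step PS+GS selection at the SH and A stages."""
    return SelectionStrategy(
        kind="optimal-gs",
        proportions={"SL": 0.5, "SH": 0.2, "A": 0.5, "B": 0.6, "C": 2 / 3},
        n_sl=n_sl,
        n_d=n_d,
        gs_stages=("SH", "A"),
        alpha={"SH": 0.4, "A": 1.0},
    )


STRATEGY_PRESETS = {
    "standard-ps": standard_ps,
    "optimal-ps": optimal_ps,
    "optimal-gs": optimal_gs,
}


@dataclass
class LadderResult:
    """Outcome of one pass through the testing ladder."""

    d_population: HaplotypeSet
    d_phenotypes: np.ndarray  # D-stage multi-location target-trait phenotypes
    census_log: pd.DataFrame


def run_stage_ladder(
    sl_pop: HaplotypeSet,
    strategy: SelectionStrategy,
    arch_t: TraitArchitecture,
    arch_a: TraitArchitecture,
    vm: VarianceModel,
    gs: GSProxy | None,
    rng: np.random.Generator,
) -> LadderResult:
    """Run SL -> D truncation selection and phenotype the D clones.

    ``gs`` may be ``None`` for purely phenotypic strategies; it is required
    (and only consulted) at the strategy's GS stages.  Phenotype noise is
    fresh at every stage.  The final selection event returns exactly
    ``strategy.n_d`` clones.
    """
    if sl_pop.n_clones < strategy.n_d:
        raise ValueError("seedling population smaller than the D census")
    pop = sl_pop
    rows = []
    for stage_i, stage in enumerate(STAGE_ORDER):
        n = pop.n_clones
        p = strategy.proportions[stage]
        last = stage_i == len(STAGE_ORDER) - 1
        k = strategy.n_d if last else math.ceil(p * n)
        if k > n:
            raise ValueError(f"stage {stage}: cannot select {k} from {n} clones")
        if STAGE_TRAIT[stage] == "Ta":
            tgv = true_values(pop, arch_a, "Ta").tgv
        else:
            tgv = true_values(pop, arch_t, "Tt").tgv
        phen = simulate_phenotypes(tgv, vm, stage, rng)
        mode = "PS"
        if stage in strategy.gs_stages and strategy.kind == "optimal-gs":
            if gs is None:
                raise ValueError("the genomic strategy needs a GSProxy")
            k_geno = max(math.ceil(strategy.alpha[stage] * n), k, 3)
            genotyped = _top_k(phen, k_geno)
            tgv_t = true_values(pop.subset_clones(genotyped), arch_t, "Tt").tgv
            egv = gs.estimate(tgv_t, rng)
            sel = genotyped[_top_k(egv, k)]
            mode = f"PS+GS(alpha={strategy.alpha[stage]:g})"
        else:
            sel = _top_k(phen, k)
        rows.append({"stage": stage, "n_entering": n, "n_selected": k, "p": p, "mode": mode})
        pop = pop.subset_clones(sel)
    d_tgv = true_values(pop, arch_t, "Tt").tgv
    d_phen = simulate_phenotypes(d_tgv, vm, "D", rng)
    rows.append(
        {"stage": "D", "n_entering": pop.n_clones, "n_selected": pop.n_clones,
         "p": 1.0, "mode": "phenotyped"}
    )
    return LadderResult(pop, d_phen, pd.DataFrame(rows))
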