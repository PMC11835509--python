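"""Cross-candidate enumeration and the cross-selection criteria.

Seven families of criteria rank candidate crosses:

* ``MPV`` — mean of the two parents' multi-location target-trait phenotypes;
* ``MEBV-P`` / ``MEGV-P`` — mean of the two parents' estimated breeding /
  genetic values from the GS proxy;
* ``MEBV-O`` / ``MEGV-O`` — mean estimated breeding / genetic value among
  in-silico progenies of the cross, simulated through tetraploid meiosis;
* ``EUC`` — extended usefulness criterion
  ``mu + w1 * i * PA * sigma_G`` with ``mu`` from MEGV-O, ``sigma_G`` the
  standard deviation of the true genetic values among the simulated
  progenies, ``i`` the per-cross selection intensity (1.755 for a selected
  proportion of 0.1) and ``PA`` the GS prediction accuracy (``w1 = 1``
  recovers the classical usefulness criterion);
* ``EUCD`` — ``EUC`` plus ``w2 * He_per_cross``, the expected
  heterozygosity among the simulated progenies, weighting genome-wide
  diversity into the ranking.

One shared in-silico progeny sample per candidate cross serves ``mu``,
``sigma_G`` and ``He``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import HaplotypeSet, expected_heterozygosity
from .meiosis import progeny_for_crosses
from .phenogs import GSProxy
from .selection import selection_intensity
from .traits import TraitArchitecture, values_from_dosage

MEAN_METHODS = ("MPV", "MEBV-P", "MEGV-P", "MEBV-O", "MEGV-O")
CRITERIA = MEAN_METHODS + ("EUC", "EUCD")

#: Per-cross selected proportion assumed inside the usefulness criteria.
PER_CROSS_SELECTED = 0.1


def candidate_crosses(
    cycle: int,
    old_parents,
    new_parents,
    used: set[frozenset] | None = None,
) -> list[tuple[str, str]]:
    """Enumerate the legal candidate crosses of a cycle.

    * burn-in (cycle 0): the half-diallel among ``old_parents``;
    * cycle 1: the half-diallel among ``old_parents + new_parents`` minus
      crosses already used;
    * cycle t > 1: old-by-new crosses plus the half-diallel among the new
      cohort, minus crosses already used.

    Pairs are unordered, self-crosses excluded, and the enumeration order
    is deterministic in the input order (it provides the tie-break for
    plan selection).
    """
    old_parents = list(old_parents)
    new_parents = list(new_parents)
    if set(old_parents) & set(new_parents):
        raise ValueError("old and new parent pools overlap")
    used = used or set()
    if cycle == 0:
        pairs = list(combinations(old_parents, 2))
    elif cycle == 1:
        pairs = list(combinations(old_parents + new_parents, 2))
    else:
        pairs = [(o, n) for o in old_parents for n in new_parents]
        pairs += list(combinations(new_parents, 2))
    return [p for p in pairs if frozenset(p) not in used]


def he_per_cross(progeny: HaplotypeSet) -> float:
    """Expected heterozygosity among the progenies of one cross."""
    return expected_heterozygosity(progeny.allele_freq())


def score_euc(mu: float, sigma_g: float, w1: float = 1.0,
              intensity: float = 1.755, pa: float = 0.5) -> float:
    """Extended usefulness criterion ``mu + w1 * i * PA * sigma_G``."""
    if sigma_g < 0:
        raise ValueError("sigma_g must be non-negative")
    return mu + w1 * intensity * pa * sigma_g


def score_eucd(mu: float, sigma_g: float, he: float, w1: float = 1.0,
               w2: float = 50.0, intensity: float = 1.755, pa: float = 0.5) -> float:
    """Diversity-weighted usefulness criterion: EUC plus ``w2 * He``."""
    if not 0 <= he < 1:
        raise ValueError("He must lie in [0, 1)")
    return score_euc(mu, sigma_g, w1, intensity, pa) + w2 * he


def score_mpv(parent_phen: tuple[float, float]) -> float:
    """Mid-parent phenotypic value."""
    return 0.5 * (parent_phen[0] + parent_phen[1])


@dataclass
class CrossSelector:
    """Configured cross-selection criterion.

    ``he_panel`` optionally restricts the per-cross heterozygosity to an
    evenly spaced subsample of that many panel markers (the full panel is
    used when ``None``); ``sigma_from_proxy`` makes ``sigma_G`` use the
    noisy proxy values instead of the true genetic values.
    """

    method: str = "MEGV-O"
    w1: float = 1.0
    w2: float = 50.0
    n_sim: int = 200
    pa: float = 0.5
    per_cross_selected: float = PER_CROSS_SELECTED
    he_panel: int | None = None
    sigma_from_proxy: bool = False
    chunk_size: int = 256

    def __post_init__(self) -> None:
        if self.method not in CRITERIA:
            raise ValueError(f"unknown criterion {self.method!r}; choose from {CRITERIA}")
        if self.n_sim < 2:
            raise ValueError("n_sim must be at least 2 (progeny SD undefined otherwise)")

    @property
    def intensity(self) -> float:
        return selection_intensity(self.per_cross_selected)

    @property
    def needs_parent_phenotypes(self) -> bool:
        return self.method == "MPV"

    @property
    def simulates_progeny(self) -> bool:
        return self.method in ("MEBV-O", "MEGV-O", "EUC", "EUCD")

    def score(
        self,
        pool: HaplotypeSet,
        pairs: list[tuple[str, str]],
        arch_t: TraitArchitecture,
        rng: np.random.Generator,
        parent_phenotypes: np.ndarray | None = None,
    ) -> pd.DataFrame:
        """Score candidate crosses; returns one row per cross, input order.

        ``parent_phenotypes`` (one value per pool clone, aligned with
        ``pool.ids``) is required for MPV.  Columns: parent1, parent2, mu,
        sigma_g, he, score.
        """
        if not pairs:
            raise ValueError("no candidate crosses to score")
        idx = np.stack(
            [pool.index_of([p[0] for p in pairs]), pool.index_of([p[1] for p in pairs])],
            axis=1,
        )
        if self.method == "MPV":
            if parent_phenotypes is None:
                raise ValueError("MPV needs parental phenotypes")
            phen = np.asarray(parent_phenotypes, dtype=np.float64)
            mu = 0.5 * (phen[idx[:, 0]] + phen[idx[:, 1]])
            sigma = np.full(len(pairs), np.nan)
            he = np.full(len(pairs), np.nan)
            score = mu
        elif self.method in ("MEBV-P", "MEGV-P"):
            tv = values_from_dosage(arch_t.favorable_dosage(pool), arch_t)
            vals = tv.tbv if self.method == "MEBV-P" else tv.tgv
            est = GSProxy(self.pa).estimate(vals, rng)
            mu = 0.5 * (est[idx[:, 0]] + est[idx[:, 1]])
            sigma = np.full(len(pairs), np.nan)
            he = np.full(len(pairs), np.nan)
            score = mu
        else:
            mu, sigma, he = self._score_offspring(pool, idx, arch_t, rng)
            if self.method == "EUC":
                score = mu + self.w1 * self.intensity * self.pa * sigma
            elif self.method == "EUCD":
                score = mu + self.w1 * self.intensity * self.pa * sigma
                if self.w2 != 0:
                    score = score + self.w2 * he
            else:
                score = mu
        return pd.DataFrame(
            {
                "parent1": [p[0] for p in pairs],
                "parent2": [p[1] for p in pairs],
                "mu": mu,
                "sigma_g": sigma,
                "he": he,
                "score": score,
            }
        )

    def _he_columns(self, n_markers: int) -> np.ndarray:
        if self.he_panel is None or self.he_panel >= n_markers:
            return np.arange(n_markers, dtype=np.intp)
        return np.unique(
            np.linspace(0, n_markers - 1, self.he_panel).round().astype(np.intp)
        )

    def _score_offspring(
        self,
        pool: HaplotypeSet,
        idx: np.ndarray,
        arch_t: TraitArchitecture,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Shared in-silico progeny sample -> (mu, sigma_g, he) per cross."""
        n_cross = idx.shape[0]
        # He enters the score only for a diversity-weighted criterion; with
        # w2 = 0 the progeny sample (and hence the ranking) must match EUC
        need_he = self.method == "EUCD" and self.w2 != 0
        qtl = arch_t.qtl_idx.astype(np.intp)
        if need_he:
            cols = np.union1d(qtl, self._he_columns(pool.n_markers))
            he_pos = np.searchsorted(cols, self._he_columns(pool.n_markers))
        else:
            cols = qtl
            he_pos = None
        qtl_pos = np.searchsorted(cols, qtl)
        fav = arch_t.favorable[None, :]
        if self.pa < 1.0 and self.n_sim < 3:
            raise ValueError("proxy noise needs at least 3 simulated progenies per cross")
        fac = (1.0 - self.pa**2) / self.pa**2

        mu = np.empty(n_cross)
        sigma = np.empty(n_cross)
        he = np.full(n_cross, np.nan)
        for start in range(0, n_cross, self.chunk_size):
            sub = idx[start : start + self.chunk_size]
            nc = sub.shape[0]
            prog = progeny_for_crosses(pool, sub, self.n_sim, rng, marker_idx=cols)
            dos = prog[:, :, qtl_pos].sum(axis=1, dtype=np.int16)
            dos = np.where(fav == 1, dos, 4 - dos)
            tv = values_from_dosage(dos, arch_t)
            base = tv.tbv if self.method == "MEBV-O" else tv.tgv
            base = base.reshape(nc, self.n_sim)
            tgv = tv.tgv.reshape(nc, self.n_sim)
            if self.pa < 1.0:
                centered = base - base.mean(axis=1, keepdims=True)
                var = fac * (centered**2).sum(axis=1) / (self.n_sim - 2)
                est = base + rng.normal(size=base.shape) * np.sqrt(var)[:, None]
            else:
                est = base
            mu[start : start + nc] = est.mean(axis=1)
            sigma_source = est if self.sigma_from_proxy else tgv
            sigma[start : start + nc] = sigma_source.std(axis=1, ddof=1)
            if need_he:
                freq = prog[:, :, he_pos].reshape(nc, self.n_sim * 4, -1).mean(axis=1)
                he[start : start + nc] = (1.0 - freq**4 - (1.0 - freq) ** 4).mean(axis=1)
        return mu, sigma, he


def select_crossing_plan(scores: pd.DataFrame, n_plan: int) -> pd.DataFrame:
    """Top ``n_plan`` crosses by criterion value, ties broken by input order."""
    if len(scores) < n_plan:
        raise ValueError(f"only {len(scores)} candidates for a plan of {n_plan}")
    order = np.argsort(-scores["score"].to_numpy(), kind="stable")[:n_plan]
    return scores.iloc[order].reset_index(drop=True)
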