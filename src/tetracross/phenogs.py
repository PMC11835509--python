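"""Phenotype simulation and the accuracy-controlled genomic-selection proxy.

Phenotypes are ``P = TGV + e`` with stage-specific normal noise.  For the
target trait the non-genetic variance at stage ``j`` is
``(sigma_gxl + sigma_trial) / L_j`` — genotype-by-location interaction plus
trial error averaged over the stage's ``L_j`` locations; the variance
components follow the fixed ratio ``sigma_g : sigma_gxl : sigma_trial =
1 : 1 : 0.5`` anchored to the genetic variance estimated at the seedling
stage of the burn-in cycle.  Trial error stays frozen after that
calibration while the genetic and interaction variances are re-anchored at
the seedling stage of every cycle.  The auxiliary trait uses a single
trial-error variance fixed from its heritability (default 0.6).

Genomic selection is represented by a noise proxy instead of an explicit
marker model: estimated values equal the true values plus normal noise
whose variance is set from the target prediction accuracy ``PA`` and the
spread of the true values over the genotyped set, so that
``corr(EBV, TBV)`` converges to ``PA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traits import TraitValues

#: Stages whose selection trait is the auxiliary trait.
TA_STAGES = ("SL", "SH", "A")
#: Stages phenotyped for the target trait across multiple locations.
TT_STAGES = ("B", "C", "D")

DEFAULT_LOCATIONS = {"B": 1, "C": 2, "D": 4}
DEFAULT_RATIO = (1.0, 1.0, 0.5)


@dataclass
class VarianceModel:
    """Variance components governing stage-wise phenotype noise."""

    sigma_g_tt: float  # current-cycle genetic variance of the target trait
    sigma_gxl_tt: float  # genotype-by-location variance (tracks sigma_g_tt)
    sigma_trial_tt: float  # trial error, frozen at burn-in calibration
    sigma_g_ta: float
    sigma_trial_ta: float  # frozen auxiliary-trait error (from its h2)
    ratio: tuple[float, float, float] = DEFAULT_RATIO
    h2_ta: float = 0.6
    locations: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LOCATIONS))

    def update_sigma_g(self, sigma_g_tt: float) -> None:
        """Re-anchor the genetic variance; interaction follows the ratio,
        trial error stays frozen."""
        self.sigma_g_tt = float(sigma_g_tt)
        self.sigma_gxl_tt = self.ratio[1] / self.ratio[0] * self.sigma_g_tt


def calibrate_variances(
    tv_tt: TraitValues,
    tv_ta: TraitValues,
    ratio: tuple[float, float, float] = DEFAULT_RATIO,
    h2_ta: float = 0.6,
    locations: dict[str, int] | None = None,
) -> VarianceModel:
    """Anchor the variance model at the seedling stage of the burn-in cycle.

    The genetic variances are the sample variances of the true genetic
    values in the seedling population; the trial error for the target trait
    is fixed at ``ratio[2]/ratio[0]`` of its genetic variance, and the
    auxiliary-trait error at ``(1 - h2) / h2`` of its genetic variance.
    """
    if tv_tt.tgv.size < 2 or tv_ta.tgv.size < 2:
        raise ValueError("calibration needs at least two clones")
    if not 0 < h2_ta <= 1:
        raise ValueError("h2_ta must lie in (0, 1]")
    sg_tt = float(np.var(tv_tt.tgv, ddof=1))
    sg_ta = float(np.var(tv_ta.tgv, ddof=1))
    return VarianceModel(
        sigma_g_tt=sg_tt,
        sigma_gxl_tt=ratio[1] / ratio[0] * sg_tt,
        sigma_trial_tt=ratio[2] / ratio[0] * sg_tt,
        sigma_g_ta=sg_ta,
        sigma_trial_ta=(1.0 - h2_ta) / h2_ta * sg_ta,
        ratio=tuple(ratio),
        h2_ta=h2_ta,
        locations=dict(locations or DEFAULT_LOCATIONS),
    )


def stage_error_variance(vm: VarianceModel, stage: str) -> float:
    """Non-genetic phenotype variance at a breeding stage."""
    if stage in TA_STAGES:
        return vm.sigma_trial_ta
    if stage in TT_STAGES:
        loc = vm.locations.get(stage)
        if loc is None or loc < 1:
            raise ValueError(f"stage {stage!r} needs at least one location")
        return (vm.sigma_gxl_tt + vm.sigma_trial_tt) / loc
    raise ValueError(f"unknown stage {stage!r}")


def heritability_at(vm: VarianceModel, stage: str) -> float:
    """Entry-mean heritability of the stage's selection trait."""
    err = stage_error_variance(vm, stage)
    sg = vm.sigma_g_ta if stage in TA_STAGES else vm.sigma_g_tt
    total = sg + err
    if total <= 0:
        raise ValueError("total variance must be positive")
    return sg / total


def simulate_phenotypes(
    tgv: np.ndarray, vm: VarianceModel, stage: str, rng: np.random.Generator
) -> np.ndarray:
    """Phenotypes ``TGV + N(0, stage error variance)``, fresh noise per call."""
    err = stage_error_variance(vm, stage)
    if err == 0:
        return np.asarray(tgv, dtype=np.float64).copy()
    return np.asarray(tgv, dtype=np.float64) + rng.normal(0.0, np.sqrt(err), size=len(tgv))


@dataclass(frozen=True)
class GSProxy:
    """Prediction-accuracy-controlled noise proxy for genomic selection."""

    pa: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.pa <= 1:
            raise ValueError("prediction accuracy must lie in (0, 1]")

    def error_variance(self, true_values: np.ndarray) -> float:
        """Proxy noise variance for a genotyped set of clones.

        ``(1 / (n' - 2)) * ((1 - PA^2) / PA^2) * sum((x_i - mean(x))^2)``
        over the ``n'`` genotyped clones' true values ``x``.
        """
        x = np.asarray(true_values, dtype=np.float64)
        n = x.size
        if n < 3:
            raise ValueError("the proxy needs at least three genotyped clones")
        if self.pa == 1.0:
            return 0.0
        ss = float(np.sum((x - x.mean()) ** 2))
        return ss / (n - 2) * (1.0 - self.pa**2) / self.pa**2

    def estimate(self, true_values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """True values plus fresh proxy noise (EBV from TBV, EGV from TGV)."""
        x = np.asarray(true_values, dtype=np.float64)
        var = self.error_variance(x)
        if var == 0.0:
            return x.copy()
        return x + rng.normal(0.0, np.sqrt(var), size=x.size)


def proxy_ebv(tv: TraitValues, pa: float, rng: np.random.Generator) -> np.ndarray:
    """Estimated breeding values: TBV plus accuracy-controlled noise."""
    return GSProxy(pa).estimate(tv.tbv, rng)


def proxy_egv(tv: TraitValues, pa: float, rng: np.random.Generator) -> np.ndarray:
    """Estimated genetic values: TGV plus accuracy-controlled noise."""
    return GSProxy(pa).estimate(tv.tgv, rng)
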