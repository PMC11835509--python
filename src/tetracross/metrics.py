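"""Per-cycle evaluation metrics and cross-cycle summaries.

All program-level quantities are assessed on the D-clone population of each
cycle: genetic gain relative to the burn-in founders, genetic variance of
the target trait, genome-wide expected heterozygosity, counts of QTLs whose
favorable allele has been fixed or lost, and the accuracy of the cycle's
progeny-mean predictions.  The conversion efficiency summarises a whole
trajectory as gain realised per unit of genetic standard deviation lost
between the first and last cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import HaplotypeSet
from .traits import TraitArchitecture

logger = logging.getLogger(__name__)


def genetic_gain(d_tgv: np.ndarray, founder_mean_tgv: float) -> float:
    """Mean target-trait TGV at D minus the frozen founder reference mean."""
    d_tgv = np.asarray(d_tgv, dtype=np.float64)
    if d_tgv.size == 0:
        raise ValueError("empty D population")
    return float(d_tgv.mean() - founder_mean_tgv)


def qtl_fixation_counts(
    d_pop: HaplotypeSet, arch: TraitArchitecture
) -> tuple[int, int]:
    """(fixed, lost) QTL counts among the D clones.

    A QTL is fixed when every clone carries four favorable alleles and lost
    when every clone carries none; segregating QTLs count in neither set.
    """
    dos = arch.favorable_dosage(d_pop)
    fixed = int(np.all(dos == 4, axis=0).sum())
    lost = int(np.all(dos == 0, axis=0).sum())
    return fixed, lost


def progeny_mean_accuracy(predicted: np.ndarray, realized: np.ndarray) -> float:
    """Pearson correlation between predicted and realised progeny means.

    Returns NaN (with a warning) when either vector is constant.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    realized = np.asarray(realized, dtype=np.float64)
    if predicted.size != realized.size or predicted.size < 3:
        raise ValueError("need at least three crosses with matching predictions")
    if np.std(predicted) == 0 or np.std(realized) == 0:
        logger.warning("progeny-mean accuracy undefined: constant predictions or outcomes")
        return float("nan")
    return float(np.corrcoef(predicted, realized)[0, 1])


@dataclass(frozen=True)
class EfficiencySummary:
    """Gain realised per unit of genetic standard deviation lost."""

    gain_change: float  # run-averaged gain at the last cycle minus the first
    sd_loss: float  # run-averaged genetic SD at the first cycle minus the last
    efficiency: float  # two-point slope gain_change / sd_loss (NaN if undefined)
    regression_slope: float  # per-cycle regression diagnostic
    regression_intercept: float


def conversion_efficiency(
    gain_by_cycle: np.ndarray, sd_by_cycle: np.ndarray
) -> EfficiencySummary:
    """Efficiency of converting diversity into gain over a trajectory.

    ``gain_by_cycle`` and ``sd_by_cycle`` are run-averaged series indexed by
    cycle (first entry = burn-in).  The headline efficiency is the two-point
    slope between the endpoints; a regression of per-cycle gain change on
    per-cycle SD loss is included as a diagnostic.
    """
    gain = np.asarray(gain_by_cycle, dtype=np.float64)
    sd = np.asarray(sd_by_cycle, dtype=np.float64)
    if gain.size != sd.size or gain.size < 2:
        raise ValueError("series must cover at least two cycles and match in length")
    y = float(gain[-1] - gain[0])
    x = float(sd[0] - sd[-1])
    if x == 0:
        logger.warning("no diversity loss between endpoints; efficiency undefined")
        eff = float("nan")
    else:
        eff = y / x
    y_t = gain - gain[0]
    x_t = sd[0] - sd
    if np.std(x_t) > 0:
        reg = stats.linregress(x_t, y_t)
        slope, intercept = float(reg.slope), float(reg.intercept)
    else:
        slope, intercept = float("nan"), float("nan")
    return EfficiencySummary(y, x, eff, slope, intercept)
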