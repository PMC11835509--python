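"""QTL architectures and true breeding / genetic values for tetraploid traits.

Each QTL is a biallelic marker with a non-negative additive effect ``a``
drawn from Gamma(shape=2, scale=0.2) and a degree of dominance ``delta``
drawn from N(1, 1).  The five dosage classes of the favorable allele map to
breeding value ``dosage * a`` and genetic value ``dosage * a + d_class``,
where the heterozygous classes 1..3 receive the dominance deviations
``d1, d2, d3`` and the homozygous classes none.  A single dominance
deviation ``d = delta * a`` is shared by the three heterozygous classes;
the four dominance regimes scale the base ``delta`` draw by 0, 1, 2 or 3
(none, mild, moderate, strong).

The favorable allele is assigned to the reference or alternate allele
uniformly at random per QTL so that founder allele frequencies are not
systematically aligned with effect direction.

An auxiliary, purely additive trait correlated with the target trait can be
derived with :func:`derive_auxiliary_architecture`; it mixes the target's
signed effects with an independent same-distribution draw and calibrates the
mixing angle against the realised founder-level correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import HaplotypeSet

DOMINANCE_SCALES = {"none": 0.0, "mild": 1.0, "moderate": 2.0, "strong": 3.0}

#: Default gamma parameters of the additive-effect distribution.
GAMMA_SHAPE = 2.0
GAMMA_SCALE = 0.2


@dataclass
class TraitArchitecture:
    """QTL positions and effects for one trait."""

    qtl_idx: np.ndarray  # (n_qtl,) marker panel indices
    a: np.ndarray  # (n_qtl,) additive effects, >= 0
    delta: np.ndarray  # (n_qtl,) degree of dominance (already regime-scaled)
    d1: np.ndarray  # (n_qtl,) dominance deviation of the simplex class
    d2: np.ndarray
    d3: np.ndarray
    favorable: np.ndarray  # (n_qtl,) allele (0 or 1) that is favorable
    dominance_scale: str = "none"

    def __post_init__(self) -> None:
        if np.any(self.a < 0):
            raise ValueError("additive effects must be non-negative")
        if self.dominance_scale not in DOMINANCE_SCALES:
            raise ValueError(f"unknown dominance scale {self.dominance_scale!r}")

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_idx.size)

    def favorable_dosage(self, hs: HaplotypeSet) -> np.ndarray:
        """Favorable-allele dosage (0..4) per clone at the trait's QTLs."""
        dos = hs.dosage(self.qtl_idx)
        return np.where(self.favorable[None, :] == 1, dos, 4 - dos)

    def dominance_matrix(self) -> np.ndarray:
        """(5, n_qtl) dominance deviation per dosage class."""
        zero = np.zeros(self.n_qtl)
        return np.stack([zero, self.d1, self.d2, self.d3, zero])

    def to_frame(self, gmap=None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "qtl_index": self.qtl_idx,
                "a": self.a,
                "delta": self.delta,
                "d1": self.d1,
                "d2": self.d2,
                "d3": self.d3,
                "favorable_allele": self.favorable,
            }
        )
        if gmap is not None:
            out.insert(1, "chrom", gmap.chrom[self.qtl_idx])
            out.insert(2, "pos_bp", gmap.pos_bp[self.qtl_idx])
        return out


@dataclass
class TraitValues:
    """True breeding and genetic values of a clone set for one trait."""

    tbv: np.ndarray
    tgv: np.ndarray
    trait: str = "Tt"


def sample_architecture(
    n_qtl: int,
    hs: HaplotypeSet,
    seed: int,
    gamma_shape: float = GAMMA_SHAPE,
    gamma_scale: float = GAMMA_SCALE,
    dominance_scale: str = "none",
) -> TraitArchitecture:
    """Sample a QTL architecture on the marker panel of ``hs``.

    For a fixed seed the QTL positions, additive effects and base dominance
    draw are identical across the four regimes; only the scaling of
    ``delta`` differs.
    """
    if n_qtl > hs.n_markers:
        raise ValueError("n_qtl exceeds the number of markers")
    if n_qtl < 1:
        raise ValueError("n_qtl must be positive")
    if gamma_shape <= 0 or gamma_scale <= 0:
        raise ValueError("gamma parameters must be positive")
    scale = DOMINANCE_SCALES[dominance_scale]
    rng = np.random.default_rng(seed)
    qtl_idx = np.sort(rng.choice(hs.n_markers, size=n_qtl, replace=False))
    a = rng.gamma(gamma_shape, gamma_scale, size=n_qtl)
    delta_base = rng.normal(1.0, 1.0, size=n_qtl)
    favorable = rng.integers(0, 2, size=n_qtl).astype(np.uint8)
    delta = scale * delta_base
    d = delta * a
    return TraitArchitecture(
        qtl_idx=qtl_idx,
        a=a,
        delta=delta,
        d1=d.copy(),
        d2=d.copy(),
        d3=d.copy(),
        favorable=favorable,
        dominance_scale=dominance_scale,
    )


def _check_dosage(dosage: np.ndarray) -> np.ndarray:
    dosage = np.asarray(dosage)
    if dosage.size and (dosage.min() < 0 or dosage.max() > 4):
        raise ValueError("dosages must lie in 0..4")
    return dosage


def breeding_value(dosage: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Sum of additive dosage effects; dosage counted on the favorable allele.

    Accepts ``(n_qtl,)`` or ``(n_clones, n_qtl)`` favorable-allele dosages.
    """
    dosage = _check_dosage(dosage)
    return dosage @ arch.a


def genetic_value(dosage: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Breeding value plus the per-class dominance deviation.

    Dosage classes 1, 2, 3 contribute ``d1, d2, d3``; classes 0 and 4
    contribute no dominance.
    """
    dosage = _check_dosage(dosage)
    dmat = arch.dominance_matrix()  # (5, n_qtl)
    if dosage.ndim == 1:
        dom = dmat[dosage.astype(np.intp), np.arange(arch.n_qtl)]
        return float(dosage @ arch.a + dom.sum())
    dom = dmat[dosage.astype(np.intp), np.arange(arch.n_qtl)[None, :]]
    return dosage @ arch.a + dom.sum(axis=1)


def true_values(hs: HaplotypeSet, arch: TraitArchitecture, trait: str = "Tt") -> TraitValues:
    """TBV and TGV of every clone in ``hs`` under ``arch``."""
    dos = arch.favorable_dosage(hs)
    tbv = dos @ arch.a
    dmat = arch.dominance_matrix()
    dom = dmat[dos, np.arange(arch.n_qtl)[None, :]].sum(axis=1)
    return TraitValues(tbv=tbv, tgv=tbv + dom, trait=trait)


def values_from_dosage(dos: np.ndarray, arch: TraitArchitecture) -> TraitValues:
    """TBV/TGV from a precomputed favorable-allele dosage matrix."""
    tbv = dos @ arch.a
    dom = arch.dominance_matrix()[dos, np.arange(arch.n_qtl)[None, :]].sum(axis=1)
    return TraitValues(tbv=tbv, tgv=tbv + dom)


def _signed_effects(arch: TraitArchitecture) -> np.ndarray:
    """Additive effect of the coded (allele-1) dosage, signed by orientation."""
    return np.where(arch.favorable == 1, arch.a, -arch.a)


def derive_auxiliary_architecture(
    arch_t: TraitArchitecture,
    r: float,
    hs: HaplotypeSet,
    seed: int,
    tol: float = 0.03,
    max_iter: int = 100,
) -> TraitArchitecture:
    """Auxiliary purely additive trait with founder-level correlation ``r``.

    The auxiliary effects are a calibrated mixture
    ``b(theta) = cos(theta) * s_t / sd_t + sin(theta) * s_e / sd_e`` of the
    target trait's signed effects ``s_t`` and an independent draw ``s_e``
    from the same distribution, where the normalisers are the founder-level
    standard deviations of the two score vectors.  ``theta`` is solved so
    that ``corr(TGV_Ta, TGV_Tt)`` over the founders equals ``r``; the
    realised correlation must land within ``tol`` of the request.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    s_t = _signed_effects(arch_t)
    sign_e = rng.choice([-1.0, 1.0], size=arch_t.n_qtl)
    s_e = rng.gamma(GAMMA_SHAPE, GAMMA_SCALE, size=arch_t.n_qtl) * sign_e

    dos1 = hs.dosage(arch_t.qtl_idx).astype(np.float64)  # coded-allele dosage
    target = true_values(hs, arch_t).tgv
    x = dos1 @ s_t
    y = dos1 @ s_e
    sd_x, sd_y = np.std(x), np.std(y)
    if sd_x == 0 or sd_y == 0:
        raise RuntimeError("degenerate founder scores; cannot calibrate auxiliary trait")

    def realized(theta: float) -> float:
        score = np.cos(theta) * x / sd_x + np.sin(theta) * y / sd_y
        return float(np.corrcoef(score, target)[0, 1])

    # the correlation is continuous but not necessarily monotone in theta
    # (under dominance the additive score may even anti-correlate with the
    # target TGV), so bracket a root on a grid before refining
    grid = np.linspace(0.0, np.pi, 181)
    vals = np.array([realized(t) for t in grid])
    f = vals - r
    best = int(np.argmin(np.abs(f)))
    brackets = np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)
    if abs(f[best]) <= 1e-12 or brackets.size == 0:
        theta = float(grid[best])
    else:
        lo = brackets[np.argmin(np.abs(brackets - best))]
        theta = brentq(
            lambda t: realized(t) - r, grid[lo], grid[lo + 1], maxiter=max_iter
        )
    got = realized(theta)
    if abs(got - r) > tol:
        raise RuntimeError(
            f"auxiliary-trait calibration failed: requested r={r:.3f}, "
            f"achieved {got:.3f} (attainable range about "
            f"[{vals.min():.3f}, {vals.max():.3f}])"
        )
    b = np.cos(theta) * s_t / sd_x + np.sin(theta) * s_e / sd_y
    return TraitArchitecture(
        qtl_idx=arch_t.qtl_idx.copy(),
        a=np.abs(b),
        delta=np.zeros_like(b),
        d1=np.zeros_like(b),
        d2=np.zeros_like(b),
        d3=np.zeros_like(b),
        favorable=(b > 0).astype(np.uint8),
        dominance_scale="none",
    )
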