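"""Scenario configuration: strategy, criterion, sizes, seeds and presets."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .crossing import CRITERIA
from .selection import STRATEGY_PRESETS

#: Table of criterion-weight presets for the usefulness-criterion grid:
#: four EUC scales (weight on progeny SD) and four EUCD scales (weight on
#: per-cross expected heterozygosity, with w1 fixed to 1).
EUC_W1_GRID = (1.0, 10.0, 50.0, 100.0)
EUCD_W2_GRID = (50.0, 500.0, 2500.0, 5000.0)

DOMINANCE_REGIMES = ("none", "mild", "moderate", "strong")


@dataclass
class ScenarioConfig:
    """Complete description of one simulated breeding-program scenario."""

    # program structure
    strategy: str = "optimal-gs"
    criterion: str = "MEGV-O"
    w1: float = 1.0
    w2: float = 50.0
    dominance: str = "none"
    n_cycles: int = 30
    n_runs: int = 30
    n_plan: int = 300
    n_parents_new: int = 20
    # founder panel
    n_founders: int = 80
    n_chrom: int = 12
    markers_per_chrom: int = 200
    map_length_per_chrom: float = 1.0
    maf_min: float = 0.05
    burnin_generations: int = 10
    # trait architecture and noise
    n_qtl: int = 2000
    pa: float = 0.5
    r_aux: float = 0.15
    h2_ta: float = 0.6
    variance_ratio: tuple[float, float, float] = (1.0, 1.0, 0.5)
    locations: dict[str, int] = field(default_factory=lambda: {"B": 1, "C": 2, "D": 4})
    # ladder censuses
    n_sl: int = 3000
    n_d: int = 60
    # in-silico cross scoring
    n_sim_cross: int = 200
    per_cross_selected: float = 0.1
    he_panel: int | None = None
    sigma_from_proxy: bool = False
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_PRESETS:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; choose from {sorted(STRATEGY_PRESETS)}"
            )
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}; choose from {CRITERIA}")
        if self.dominance not in DOMINANCE_REGIMES:
            raise ValueError(
                f"unknown dominance regime {self.dominance!r}; choose from {DOMINANCE_REGIMES}"
            )
        for name in (
            "n_cycles", "n_runs", "n_plan", "n_parents_new", "n_founders",
            "n_chrom", "markers_per_chrom", "n_qtl", "n_sl", "n_d", "n_sim_cross",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sl // self.n_plan < 1:
            raise ValueError("n_sl must allow at least one seedling per planned cross")
        if self.n_parents_new > self.n_d:
            raise ValueError("cannot select more new parents than D clones")
        if self.n_qtl > self.n_chrom * self.markers_per_chrom:
            raise ValueError("n_qtl exceeds the marker panel size")

    @property
    def pool_size(self) -> int:
        """Candidate-parent pool size maintained from cycle 1 on."""
        return self.n_founders + self.n_parents_new

    @property
    def progeny_per_cross(self) -> int:
        """Seedlings simulated per planned cross (remainder dropped)."""
        return self.n_sl // self.n_plan

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variance_ratio"] = list(self.variance_ratio)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
        data = dict(data)
        if "variance_ratio" in data:
            data["variance_ratio"] = tuple(data["variance_ratio"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def desk_preset(**overrides) -> ScenarioConfig:
    """Desk-scale scenario: full founder panel sizes, shortened program.

    Runs in minutes on one CPU while keeping the founder-panel dimensions
    (80 clones, 12 chromosomes, 200 markers each) of the default setup.
    """
    base = dict(
        n_cycles=10,
        n_runs=5,
        n_qtl=200,
        n_sim_cross=50,
        he_panel=480,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


PRESETS = {
    "desk": desk_preset,
    "strategies-desk": lambda **kw: desk_preset(criterion="MPV", **kw),
    "diversity-desk": lambda **kw: desk_preset(criterion="EUCD", w2=5000.0, **kw),
}
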