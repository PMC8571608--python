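"""Scenario configuration and the preset experiment grids.

A :class:`ScenarioConfig` bundles everything one simulation scenario
needs: the demographic and environmental constants, the emigration
strategy and patch-selection process, whether the emigration loci
evolve (they always do for prospecting ``n_p``), the prospecting
mortality cost, and run-length/seeding controls.  Configs can be read
from flat YAML files; the two preset grids enumerate the published
experiment designs (3 strategies x 3 selection processes x 2 costs,
with emigration fixed or co-evolving).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterator, List

import yaml

from .dispersal import PROCESSES, STRATEGIES

#: Prospecting mortality costs per patch used in the experiments.
COSTS = (0.0, 0.01)


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    Defaults are the common parameterization of the experiments:
    25 patches of baseline capacity ``K0 = 100``; maximum mean fecundity
    ``Off_max = 2``; stage survivals ``S_J = 0.6``, ``S_I = 0.7``,
    ``S_A = 0.85``; environment noise ``sigma = 1`` with temporal
    autocorrelation ``alpha = 0.8``; mean recruitment age ``R = 5``;
    mutation probability ``mu = 0.01`` per locus per generation.
    """

    # environment
    n_patches: int = 25
    k0: float = 100.0
    sigma: float = 1.0
    autocorr: float = 0.8
    # demography
    off_max: float = 2.0
    s_j: float = 0.6
    s_i: float = 0.7
    s_a: float = 0.85
    r_mean: float = 5.0
    # genetics
    mu: float = 0.01
    # dispersal scenario
    strategy: str = "uninformed"
    process: str = "inaccurate"
    m: float = 0.0
    evolve_emigration: bool = True
    fixed: Dict[str, float] = field(default_factory=dict)
    # run controls
    years: int = 20000
    replicates: int = 10
    seed: int = 0
    summary_every: int = 100
    initial_adults_per_patch: int | None = None
    halt_on_extinction: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.process not in PROCESSES:
            raise ValueError(f"unknown patch selection process {self.process!r}")
        for name in ("s_j", "s_i", "s_a", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.years < 1 or self.replicates < 1:
            raise ValueError("years and replicates must be >= 1")
        if self.off_max < 1:
            raise ValueError(f"off_max must be >= 1, got {self.off_max}")
        if self.m < 0 or self.m * (self.n_patches - 1) > 1.0:
            raise ValueError(
                "prospecting cost M must satisfy 0 <= M * (n_patches - 1) <= 1"
            )

    @property
    def label(self) -> str:
        """Short scenario tag, e.g. ``personal-accurate-cost0.01-evolving``."""
        emi = "evolving" if self.evolve_emigration else "fixed"
        return f"{self.strategy}-{self.process}-cost{self.m:g}-{emi}"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def experiment_grid(
    evolve_emigration: bool, **overrides
) -> List[ScenarioConfig]:
    """The 3 x 3 x 2 scenario grid of either experiment.

    Experiment 1 (``evolve_emigration=False``): only prospecting
    ``n_p`` evolves, emigration parameters fixed at the standard
    constants.  Experiment 2 (``True``): the strategy's emigration loci
    co-evolve with ``n_p``.
    """
    return [
        ScenarioConfig(
            strategy=s,
            process=p,
            m=c,
            evolve_emigration=evolve_emigration,
            **overrides,
        )
        for s in STRATEGIES
        for p in PROCESSES
        for c in COSTS
    ]


def iter_experiments(**overrides) -> Iterator[ScenarioConfig]:
    """All 36 scenarios of both experiments."""
    yield from experiment_grid(False, **overrides)
    yield from experiment_grid(True, **overrides)
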