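"""Haploid dispersal genetics: loci, initialization, maternal inheritance.

Individuals are haploid females carrying one locus per dispersal trait:

* ``e`` — uninformed emigration probability,
* ``e_succ`` / ``e_fail`` — emigration probabilities conditional on the
  individual's own breeding outcome (personal information),
* ``beta_succ`` / ``alpha_succ`` and ``beta_fail`` / ``alpha_fail`` —
  intercept and slope of the status-specific linear reaction norm
  mapping local conspecific breeding success (LBS, public information)
  to emigration probability,
* ``n_p`` — the number of patches prospected before settling (discrete,
  0..n_patches-1).

Only the loci declared *evolving* by the scenario vary between
individuals; the rest hold the scenario's fixed constant.  Offspring
inherit each allele from their mother and mutate per locus,
independently, with probability ``mu``: continuous alleles gain an
``N(0, 0.1)`` increment, the discrete ``n_p`` allele steps by +/-1
(equiprobable).  Every mutation proposal is clamped to the locus's legal
interval (probabilities to [0, 1], reaction-norm slopes to [-1, 0],
``n_p`` to 0..n_patches-1): allele values outside those intervals are
behaviorally indistinguishable from the boundary, so leaving them
unbounded would let alleles diffuse neutrally beyond the range and make
population allele means meaningless as probabilities.

Genotypes are stored columnar — a mapping from locus name to a value
array over individuals — because the simulation is vectorized over the
whole roster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

#: Continuous emigration loci, in canonical column order.
CONTINUOUS_LOCI = (
    "e",
    "e_succ",
    "e_fail",
    "beta_succ",
    "alpha_succ",
    "beta_fail",
    "alpha_fail",
)

#: The discrete prospecting locus.
NP_LOCUS = "n_p"

ALL_LOCI = CONTINUOUS_LOCI + (NP_LOCUS,)

#: Fixed emigration constants used when a locus does not evolve
#: (the non-evolving strategy parameterization of the first experiment).
DEFAULT_FIXED = {
    "e": 0.5,
    "e_succ": 0.05,
    "e_fail": 0.5,
    "beta_succ": 0.05,
    "alpha_succ": 0.0,
    "beta_fail": 0.5,
    "alpha_fail": -0.45,
}

#: Loci read (and, when emigration evolves, evolving) per strategy.
STRATEGY_LOCI = {
    "uninformed": ("e",),
    "personal": ("e_succ", "e_fail"),
    "personal_public": ("beta_succ", "alpha_succ", "beta_fail", "alpha_fail"),
}


@dataclass(frozen=True)
class TraitSpec:
    """Per-locus evolutionary specification.

    ``kernel`` is ``"increment"`` (continuous: add N(0, sd)) or ``"step"``
    (discrete: +/-1 clamped to [0, np_max]).
    """

    name: str
    evolving: bool
    init_low: float
    init_high: float
    kernel: str = "increment"
    mu: float = 0.01
    sd: float = 0.1
    fixed_value: float = 0.0
    np_max: int = 24

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mutation probability must be in [0,1], got {self.mu}")
        if self.kernel not in ("increment", "step"):
            raise ValueError(f"unknown mutation kernel {self.kernel!r}")


def trait_specs(
    strategy: str,
    evolve_emigration: bool,
    mu: float = 0.01,
    fixed: Mapping[str, float] | None = None,
    np_max: int = 24,
) -> Dict[str, TraitSpec]:
    """Build the per-locus specs for a scenario.

    The prospecting locus ``n_p`` always evolves (uniform integer
    initialization over 0..np_max).  The emigration loci of ``strategy``
    evolve only when ``evolve_emigration`` is set; evolving continuous
    loci initialize uniform on [0, 1], except the reaction-norm slopes
    ``alpha_fail`` / ``alpha_succ`` which initialize uniform on [-1, 0].
    Loci not read by the strategy, and read loci when emigration is
    fixed, hold the constants in ``fixed``.
    """
    if strategy not in STRATEGY_LOCI:
        raise ValueError(f"unknown strategy {strategy!r}")
    constants = dict(DEFAULT_FIXED)
    if fixed:
        constants.update(fixed)
    specs: Dict[str, TraitSpec] = {}
    evolving_loci = set(STRATEGY_LOCI[strategy]) if evolve_emigration else set()
    for name in CONTINUOUS_LOCI:
        if name in evolving_loci:
            lo, hi = (-1.0, 0.0) if name.startswith("alpha") else (0.0, 1.0)
            specs[name] = TraitSpec(name, True, lo, hi, "increment", mu)
        else:
            c = constants[name]
            specs[name] = TraitSpec(name, False, c, c, "increment", mu, fixed_value=c)
    specs[NP_LOCUS] = TraitSpec(
        NP_LOCUS, True, 0, np_max, "step", mu, np_max=np_max
    )
    return specs


def init_genotypes(
    n: int, specs: Mapping[str, TraitSpec], rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Random founder genotypes for ``n`` individuals, columnar.

    Non-evolving loci are population-wide constants and are stored as
    scalars (they broadcast wherever an allele column is expected).
    """
    geno: Dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        if spec.kernel == "step":
            geno[name] = rng.integers(0, spec.np_max + 1, size=n).astype(np.int64)
        elif spec.evolving:
            geno[name] = rng.uniform(spec.init_low, spec.init_high, size=n)
        else:
            geno[name] = float(spec.fixed_value)
    return geno


def inherit_and_mutate(
    mother_genotypes: Mapping[str, np.ndarray],
    mother_index: np.ndarray,
    specs: Mapping[str, TraitSpec],
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Offspring genotypes by maternal copy plus per-locus mutation.

    ``mother_index[j]`` is the roster position of offspring ``j``'s
    mother (repeated indices produce full sibs).  Each evolving locus
    mutates independently with probability ``spec.mu``; non-evolving
    loci are copied verbatim.
    """
    mother_index = np.asarray(mother_index)
    n = mother_index.size
    child: Dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        mother = mother_genotypes[name]
        if np.ndim(mother) == 0:
            # population-wide constant (non-evolving locus): pass through
            child[name] = mother
            continue
        allele = np.asarray(mother)[mother_index].copy()
        if spec.evolving and spec.mu > 0 and n > 0:
            hit = rng.random(n) < spec.mu
            n_hit = int(hit.sum())
            if n_hit:
                if spec.kernel == "increment":
                    allele[hit] = np.clip(
                        allele[hit] + rng.normal(0.0, spec.sd, size=n_hit),
                        spec.init_low,
                        spec.init_high,
                    )
                else:  # step kernel: +/-1, clamped to the valid range
                    step = rng.choice((-1, 1), size=n_hit)
                    allele[hit] = np.clip(allele[hit] + step, 0, spec.np_max)
        child[name] = allele
    return child
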