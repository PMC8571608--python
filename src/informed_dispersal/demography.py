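"""Reproduction, breeding success, stage structure and survival.

The life cycle has three female stages — juvenile, pre-breeder, adult —
with overlapping generations.  The year starts with reproduction: each
adult in an occupied patch draws a Poisson number of offspring with mean

    mu_off = Off_max / (1 + (Off_max - 1) * N / K)

where ``N`` is the adult count in the patch at breeding and ``K`` the
current carrying capacity, so fecundity declines smoothly from
``Off_max`` at zero density to 1 at ``N = K`` (and to 0 when ``K <= 0``).
An adult producing at least one offspring is a *successful breeder*;
local breeding success (LBS) is the fraction of successful breeders
among a patch's adults, the public cue read by prospectors and informed
emigrants.

Offspring are juveniles; they survive their first year with probability
``S_J`` to become pre-breeders, then survive annually with ``S_I`` until
reaching a recruitment age drawn at birth from Poisson(R) (floored at 2
so every bird spends at least one full year in each immature stage).
Adults survive annually with ``S_A``.  Pre-breeders neither breed nor
disperse and do not count toward the density ``N``.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

import numpy as np

from .genetics import TraitSpec, inherit_and_mutate

# Stage codes used throughout the columnar roster.
JUVENILE, PRE_BREEDER, ADULT = 0, 1, 2
STAGE_NAMES = {JUVENILE: "juvenile", PRE_BREEDER: "pre_breeder", ADULT: "adult"}

# Breeding-status codes.
STATUS_NONE, STATUS_FAILED, STATUS_SUCCESSFUL = 0, 1, 2
STATUS_NAMES = {STATUS_NONE: "none", STATUS_FAILED: "failed", STATUS_SUCCESSFUL: "successful"}

#: Minimum recruitment age: one full year as juvenile, one as pre-breeder.
MIN_RECRUITMENT_AGE = 2


def mean_fecundity(n, k, off_max: float):
    """Expected offspring per female under negative density dependence.

    Elementwise on arrays; returns 0 where ``k <= 0`` (uninhabitable
    patch). ``k`` is used real-valued, exactly as the environment emits it.
    """
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = off_max / (1.0 + (off_max - 1.0) * n / k)
    return np.where(k > 0, mu, 0.0)


def draw_recruitment_age(r: float, rng: np.random.Generator, size=None):
    """Recruitment age ~ Poisson(R), with draws below 2 raised to 2."""
    if r < 0:
        raise ValueError(f"mean recruitment age must be >= 0, got {r}")
    return np.maximum(rng.poisson(r, size=size), MIN_RECRUITMENT_AGE)


def local_breeding_success(statuses: np.ndarray) -> float:
    """Fraction of successful breeders among a patch's adults (N > 0)."""
    statuses = np.asarray(statuses)
    if statuses.size == 0:
        raise ValueError("LBS is undefined in a patch with no adults")
    return float(np.mean(statuses == STATUS_SUCCESSFUL))


def reproduce_adults(
    adult_patch: np.ndarray,
    mu_off_by_patch: np.ndarray,
    genotypes: Mapping[str, np.ndarray],
    specs: Mapping[str, TraitSpec],
    r_mean: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, np.ndarray], np.ndarray]:
    """Vectorized reproduction for every adult at once.

    Parameters
    ----------
    adult_patch
        Patch index of each adult (defines its fecundity mean).
    mu_off_by_patch
        Per-patch Poisson mean from :func:`mean_fecundity`.
    genotypes
        Columnar alleles of the adults (mothers).
    specs, r_mean, rng
        Mutation specs, mean recruitment age, random stream.

    Returns
    -------
    statuses
        Per-adult breeding status (successful iff >= 1 offspring, from
        the raw draw, before any juvenile mortality).
    mother_index
        Roster position of each offspring's mother.
    offspring_genotypes
        Columnar alleles of the offspring (maternal copy + mutation).
    recruitment_ages
        Per-offspring recruitment age drawn at birth.
    """
    counts = rng.poisson(mu_off_by_patch[adult_patch])
    statuses = np.where(counts >= 1, STATUS_SUCCESSFUL, STATUS_FAILED).astype(np.int8)
    mother_index = np.repeat(np.arange(adult_patch.size), counts)
    offspring = inherit_and_mutate(genotypes, mother_index, specs, rng)
    recruit_age = draw_recruitment_age(r_mean, rng, size=mother_index.size)
    return statuses, mother_index, offspring, recruit_age


def reproduce_patch(
    n_adults: int,
    k: float,
    off_max: float,
    genotypes: Mapping[str, np.ndarray],
    specs: Mapping[str, TraitSpec],
    r_mean: float,
    rng: np.random.Generator,
):
    """Single-patch convenience wrapper around :func:`reproduce_adults`."""
    if n_adults <= 0:
        raise ValueError("reproduction requires an occupied patch (N > 0)")
    mu = np.asarray([mean_fecundity(n_adults, k, off_max)], dtype=float)
    patch = np.zeros(n_adults, dtype=np.int64)
    return reproduce_adults(patch, mu, genotypes, specs, r_mean, rng)


def survival_probabilities(
    stages: np.ndarray, s_j: float, s_i: float, s_a: float
) -> np.ndarray:
    """Stage-specific annual survival probability per individual."""
    for name, s in (("S_J", s_j), ("S_I", s_i), ("S_A", s_a)):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {s}")
    table = np.array([s_j, s_i, s_a])
    return table[np.asarray(stages)]


def apply_survival(
    stages: np.ndarray,
    s_j: float,
    s_i: float,
    s_a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Bernoulli survival; returns the boolean survivor mask."""
    p = survival_probabilities(stages, s_j, s_i, s_a)
    return rng.random(stages.size) < p
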