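"""Annual-cycle orchestration, replicates, and seeding.

The yearly sequence, applied to a columnar roster of individuals:

1. advance the environment (AR(1) quality step; year 0 initializes it)
   and derive carrying capacities;
2. reproduction in every occupied patch, assigning each adult a
   breeding status and creating juvenile offspring with inherited,
   possibly mutated genotypes;
3. freeze the pre-movement snapshot: patch occupancy (adults present at
   breeding) and local breeding success (LBS);
4. dispersal of all adults and of this year's new recruits
   (pre-breeders that reached their recruitment age, who settle before
   their first breeding season): emigration decision, prospecting
   mortality, settlement — all against the frozen snapshot, so the
   processing order of individuals is immaterial;
5. stage-specific survival and promotion (surviving juveniles become
   pre-breeders; recruits were promoted to adults when they settled);
6. ages increment.

Every replicate runs on an independent child stream of the master seed,
and the roster is kept sorted by individual identifier before any draw,
so a scenario is bit-reproducible and invariant to roster permutations.
Global extinction is a legal state: the roster stays empty while the
environment keeps advancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from . import demography as dem
from . import dispersal as disp
from .config import ScenarioConfig
from .environment import EnvironmentGrid, init_quality, step_quality
from .genetics import ALL_LOCI, NP_LOCUS, init_genotypes, trait_specs


@dataclass
class SimulationState:
    """Columnar roster plus environment for one replicate."""

    grid: EnvironmentGrid
    ids: np.ndarray
    stage: np.ndarray
    age: np.ndarray
    recruit_age: np.ndarray
    status: np.ndarray
    patch: np.ndarray
    genotypes: Dict[str, np.ndarray]
    next_id: int
    year: int = 0
    lbs_by_patch: np.ndarray = field(default=None, repr=False)
    n_by_patch: np.ndarray = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return self.ids.size

    def adults(self) -> np.ndarray:
        return self.stage == dem.ADULT

    def keep(self, mask: np.ndarray) -> None:
        self.ids = self.ids[mask]
        self.stage = self.stage[mask]
        self.age = self.age[mask]
        self.recruit_age = self.recruit_age[mask]
        self.status = self.status[mask]
        self.patch = self.patch[mask]
        self.genotypes = {
            k: (v if np.ndim(v) == 0 else v[mask]) for k, v in self.genotypes.items()
        }

    def sort_by_id(self) -> None:
        """Canonical order: draws are consumed in id order, so any
        external permutation of the roster is undone here."""
        if self.ids.size > 1 and np.any(np.diff(self.ids) < 0):
            self.keep(np.argsort(self.ids, kind="stable"))


def init_state(config: ScenarioConfig, rng: np.random.Generator) -> SimulationState:
    """Fresh replicate state: every patch starts occupied at ``K0`` adults.

    Founders get ages uniform on 2..10, no breeding history, and random
    genotypes; the demographic transient this induces dies out within a
    few decades and is negligible on evolutionary run lengths.
    """
    grid = EnvironmentGrid(
        n_patches=config.n_patches,
        sigma=config.sigma,
        autocorr=config.autocorr,
        k0=config.k0,
    )
    per_patch = config.initial_adults_per_patch
    if per_patch is None:
        per_patch = int(round(config.k0))
    n = per_patch * config.n_patches
    specs = trait_specs(
        config.strategy,
        config.evolve_emigration,
        mu=config.mu,
        fixed=config.fixed,
        np_max=config.n_patches - 1,
    )
    return SimulationState(
        grid=grid,
        ids=np.arange(n, dtype=np.int64),
        stage=np.full(n, dem.ADULT, dtype=np.int8),
        age=rng.integers(2, 11, size=n).astype(np.int16),
        recruit_age=np.full(n, dem.MIN_RECRUITMENT_AGE, dtype=np.int16),
        status=np.full(n, dem.STATUS_NONE, dtype=np.int8),
        patch=np.repeat(np.arange(config.n_patches), per_patch).astype(np.int16),
        genotypes=init_genotypes(n, specs, rng),
        next_id=n,
    )


def run_year(
    state: SimulationState, config: ScenarioConfig, rng: np.random.Generator
) -> Dict[str, int]:
    """Advance one full year in place; returns bookkeeping counters."""
    state.sort_by_id()
    specs = trait_specs(
        config.strategy,
        config.evolve_emigration,
        mu=config.mu,
        fixed=config.fixed,
        np_max=config.n_patches - 1,
    )

    # (1) environment
    if state.grid.q is None:
        init_quality(state.grid, rng)
    else:
        step_quality(state.grid, rng)
    k = state.grid.k

    counters = {"births": 0, "prospect_deaths": 0, "deaths": 0}
    n_before = state.size

    # (2) reproduction and breeding status
    adults = state.adults()
    n_by_patch = np.bincount(
        state.patch[adults], minlength=config.n_patches
    ).astype(float)
    mu_off = dem.mean_fecundity(n_by_patch, k, config.off_max)
    adult_idx = np.flatnonzero(adults)
    if adult_idx.size:
        mother_geno = {
            name: (g if np.ndim(g) == 0 else g[adult_idx])
            for name, g in state.genotypes.items()
        }
        statuses, mother_index, off_geno, off_recruit_age = dem.reproduce_adults(
            state.patch[adult_idx], mu_off, mother_geno, specs, config.r_mean, rng
        )
        state.status[adult_idx] = statuses
        off_patch = state.patch[adult_idx][mother_index]
        successes = np.bincount(
            state.patch[adult_idx][statuses == dem.STATUS_SUCCESSFUL],
            minlength=config.n_patches,
        )
    else:
        mother_index = np.empty(0, dtype=np.int64)
        off_geno = {name: np.empty(0) for name in ALL_LOCI}
        off_recruit_age = np.empty(0, dtype=np.int64)
        off_patch = np.empty(0, dtype=np.int16)
        successes = np.zeros(config.n_patches, dtype=np.int64)
    counters["births"] = int(mother_index.size)

    # (3) pre-movement snapshot: occupancy and LBS
    occupied = n_by_patch > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        lbs_by_patch = np.where(occupied, successes / n_by_patch, np.nan)
    state.n_by_patch = n_by_patch
    state.lbs_by_patch = lbs_by_patch

    # (4) dispersal: adults and this year's recruits, on the snapshot
    recruits = (state.stage == dem.PRE_BREEDER) & (
        state.age >= state.recruit_age
    )
    movers = adults | recruits
    mover_idx = np.flatnonzero(movers)
    prospect_dead_idx = np.empty(0, dtype=np.int64)
    if mover_idx.size:
        mover_geno = {
            name: (g if np.ndim(g) == 0 else g[mover_idx])
            for name, g in state.genotypes.items()
        }
        lbs_local = np.nan_to_num(lbs_by_patch, nan=0.0)[state.patch[mover_idx]]
        p_emigrate = disp.emigration_probability(
            mover_geno, config.strategy, state.status[mover_idx], lbs_local
        )
        emigrate = rng.random(mover_idx.size) < p_emigrate
        em_idx = mover_idx[emigrate]
        if em_idx.size:
            dest, died = disp.disperse_batch(
                state.patch[em_idx],
                state.genotypes[NP_LOCUS][em_idx],
                lbs_by_patch,
                config.process,
                config.m,
                rng,
            )
            state.patch[em_idx] = dest.astype(state.patch.dtype)
            prospect_dead_idx = em_idx[died]
        # promotion at settlement: recruits are adults from now on
        state.stage[recruits] = dem.ADULT
    counters["prospect_deaths"] = int(prospect_dead_idx.size)

    # (5) offspring enter the roster, then stage-specific survival
    n_off = mother_index.size
    if n_off:
        state.ids = np.concatenate(
            [state.ids, np.arange(state.next_id, state.next_id + n_off)]
        )
        state.next_id += n_off
        state.stage = np.concatenate(
            [state.stage, np.full(n_off, dem.JUVENILE, dtype=np.int8)]
        )
        state.age = np.concatenate([state.age, np.zeros(n_off, dtype=np.int16)])
        state.recruit_age = np.concatenate(
            [state.recruit_age, off_recruit_age.astype(np.int16)]
        )
        state.status = np.concatenate(
            [state.status, np.full(n_off, dem.STATUS_NONE, dtype=np.int8)]
        )
        state.patch = np.concatenate(
            [state.patch, off_patch.astype(np.int16)]
        )
        state.genotypes = {
            name: (
                g
                if np.ndim(g) == 0
                else np.concatenate([g, off_geno[name]])
            )
            for name, g in state.genotypes.items()
        }

    survive = dem.apply_survival(state.stage, config.s_j, config.s_i, config.s_a, rng)
    if prospect_dead_idx.size:
        survive[prospect_dead_idx] = False
    counters["deaths"] = int(state.size - survive.sum()) - counters["prospect_deaths"]
    state.keep(survive)

    # (6) promotion of surviving juveniles; ages increment
    state.stage[state.stage == dem.JUVENILE] = dem.PRE_BREEDER
    state.age += 1
    state.year += 1

    assert state.size == n_before + counters["births"] - counters["deaths"] - counters[
        "prospect_deaths"
    ]
    return counters


@dataclass
class ScenarioResult:
    """Outputs of :func:`run_scenario`.

    ``yearly``: population-level series per replicate at the summary
    cadence; ``patches``: per-patch long table at the same cadence
    (N and LBS are the breeding-time snapshot, Q and K the year's
    environment); ``snapshot``: every individual alive at the end of the
    final year, with its alleles and its patch's final-year LBS.
    """

    config: ScenarioConfig
    yearly: pd.DataFrame
    patches: pd.DataFrame
    snapshot: pd.DataFrame


def _yearly_row(state: SimulationState, replicate: int) -> dict:
    adults = state.adults()
    row = {
        "replicate": replicate,
        "year": state.year,
        "n_total": state.size,
        "n_adults": int(adults.sum()),
        "n_occupied": int(np.unique(state.patch[adults]).size),
    }
    for name in ALL_LOCI:
        g = state.genotypes[name]
        if not row["n_adults"]:
            row[f"mean_{name}"] = np.nan
        elif np.ndim(g) == 0:
            row[f"mean_{name}"] = float(g)
        else:
            row[f"mean_{name}"] = float(g[adults].mean())
    return row


def _patch_rows(state: SimulationState, replicate: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate": replicate,
            "year": state.year,
            "patch": np.arange(state.grid.n_patches),
            "q": state.grid.q,
            "k": state.grid.k,
            "n_adults": state.n_by_patch,
            "lbs": state.lbs_by_patch,
        }
    )


def snapshot_frame(state: SimulationState, replicate: int) -> pd.DataFrame:
    """Individual-level snapshot of the current roster."""
    lbs = np.nan_to_num(state.lbs_by_patch, nan=0.0) if state.lbs_by_patch is not None else np.zeros(state.grid.n_patches)
    df = pd.DataFrame(
        {
            "replicate": replicate,
            "id": state.ids,
            "stage": pd.Categorical.from_codes(
                state.stage, categories=[dem.STAGE_NAMES[c] for c in (0, 1, 2)]
            ),
            "age": state.age,
            "patch": state.patch,
            "status": pd.Categorical.from_codes(
                state.status, categories=[dem.STATUS_NAMES[c] for c in (0, 1, 2)]
            ),
            "lbs_patch": lbs[state.patch],
        }
    )
    for name in ALL_LOCI:
        df[name] = state.genotypes[name]
    return df


def run_replicate(
    config: ScenarioConfig, replicate: int, seed_seq: np.random.SeedSequence
) -> ScenarioResult:
    """One replicate: returns the same frames as a scenario, for one stream."""
    rng = np.random.default_rng(seed_seq)
    state = init_state(config, rng)
    yearly: List[dict] = []
    patches: List[pd.DataFrame] = []
    for _ in range(config.years):
        run_year(state, config, rng)
        if state.year % config.summary_every == 0 or state.year == config.years:
            yearly.append(_yearly_row(state, replicate))
            patches.append(_patch_rows(state, replicate))
        if config.halt_on_extinction and state.size == 0:
            yearly.append(_yearly_row(state, replicate))
            patches.append(_patch_rows(state, replicate))
            break
    return ScenarioResult(
        config=config,
        yearly=pd.DataFrame(yearly).drop_duplicates(["replicate", "year"]),
        patches=pd.concat(patches, ignore_index=True).drop_duplicates(
            ["replicate", "year", "patch"]
        ),
        snapshot=snapshot_frame(state, replicate),
    )


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """All replicates of a scenario on independent child streams.

    Identical ``(config, seed)`` pairs give bit-identical outputs.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    results = [run_replicate(config, i, s) for i, s in enumerate(children)]
    return ScenarioResult(
        config=config,
        yearly=pd.concat([r.yearly for r in results], ignore_index=True),
        patches=pd.concat([r.patches for r in results], ignore_index=True),
        snapshot=pd.concat([r.snapshot for r in results], ignore_index=True),
    )
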