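"""Headline evolved-trait statistics of the joint-evolution experiment.

Each entry of :data:`HEADLINE_RUNS` is one scenario of the second
experiment (emigration loci co-evolving with prospecting ``n_p``) whose
end-state summarizes how informed emigration evolves: the cross-replicate
mean of an evolved emigration allele among adults at the final year, or
— for the personal-plus-public strategy — the mean realized emigration
probability of successful breeders (their reaction norm evaluated at the
LBS they actually experience, clamped to [0, 1]).

These statistics are stochastic equilibria; the run length and replicate
count are arguments so callers can trade precision for runtime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np

from .config import ScenarioConfig
from .engine import ScenarioResult, run_scenario
from .reporting import evolved_trait_mean, modal_np, realized_emigration_mean


@dataclass(frozen=True)
class HeadlineRun:
    """One scenario and the statistic summarizing its evolved outcome."""

    key: str
    strategy: str
    process: str
    m: float
    statistic: str  # locus name, or "p_succ_realized"

    def config(self, years: int, replicates: int, seed: int) -> ScenarioConfig:
        return ScenarioConfig(
            strategy=self.strategy,
            process=self.process,
            m=self.m,
            evolve_emigration=True,
            years=years,
            replicates=replicates,
            seed=seed,
            summary_every=max(1, years // 10),
        )

    def evaluate(self, result: ScenarioResult) -> Tuple[float, float]:
        if self.statistic == "p_succ_realized":
            return realized_emigration_mean(result.snapshot, "successful")
        return evolved_trait_mean(result.snapshot, self.statistic)


#: The scenario grid behind the published evolved emigration values.
HEADLINE_RUNS = (
    HeadlineRun("e_inaccurate_costless", "uninformed", "inaccurate", 0.0, "e"),
    HeadlineRun("e_accurate_costless", "uninformed", "accurate", 0.0, "e"),
    HeadlineRun("e_fail_inaccurate_costless", "personal", "inaccurate", 0.0, "e_fail"),
    HeadlineRun("e_fail_accurate_costless", "personal", "accurate", 0.0, "e_fail"),
    HeadlineRun("e_accurate_costly", "uninformed", "accurate", 0.01, "e"),
    HeadlineRun("e_fail_accurate_costly", "personal", "accurate", 0.01, "e_fail"),
    HeadlineRun("e_fail_inaccurate_costly", "personal", "inaccurate", 0.01, "e_fail"),
    HeadlineRun("p_succ_costless", "personal_public", "accurate", 0.0, "p_succ_realized"),
    HeadlineRun("p_succ_costly", "personal_public", "accurate", 0.01, "p_succ_realized"),
)


def run_headline(
    run: HeadlineRun, years: int, replicates: int, seed: int
) -> Dict[str, float]:
    """Run one scenario and return its headline statistic and context."""
    result = run_scenario(run.config(years, replicates, seed))
    mean, se = run.evaluate(result)
    return {
        "value": mean,
        "se": se,
        "modal_np": modal_np(result.snapshot),
        "years": years,
        "replicates": replicates,
    }


def headline_statistics(
    seed: int,
    years: int = 8000,
    replicates: int = 4,
    runs: Tuple[HeadlineRun, ...] = HEADLINE_RUNS,
    progress: Callable[[str], None] | None = None,
) -> Dict[str, Dict[str, float]]:
    """All headline scenario statistics on independent seeds.

    Per-scenario seeds are derived from ``seed`` so scenarios are
    independent but the whole set is reproducible.
    """
    child = np.random.SeedSequence(seed).generate_state(len(runs)) & 0x7FFFFFFF
    out: Dict[str, Dict[str, float]] = {}
    for run, s in zip(runs, child):
        out[run.key] = run_headline(run, years, replicates, int(s))
        if progress is not None:
            progress(f"{run.key}: {out[run.key]['value']:.3f}")
    return out
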