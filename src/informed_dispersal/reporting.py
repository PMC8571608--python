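"""Summary surfaces over simulation output.

All functions here are pure transforms of the frames a scenario run
emits (yearly series, per-patch tables, individual snapshots), so
re-running them on the same files is bit-identical.  Cross-replicate
standard errors use the n-1 denominator.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .dispersal import clamp01
from .genetics import NP_LOCUS


def _mean_se(values: np.ndarray) -> Tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, se


def np_frequency_and_mode(
    np_alleles: np.ndarray, np_max: int = 24
) -> Tuple[np.ndarray, int]:
    """Allele frequency spectrum of the prospecting trait and its mode.

    Frequencies over ``n_p = 0..np_max`` for a set of adults; the mode
    is the argmax (smallest value on ties).
    """
    np_alleles = np.asarray(np_alleles)
    if np_alleles.size == 0:
        raise ValueError("spectrum requires at least one adult")
    counts = np.bincount(np_alleles.astype(int), minlength=np_max + 1)
    freqs = counts / counts.sum()
    return freqs, int(np.argmax(freqs))


def np_spectrum(snapshot: pd.DataFrame, np_max: int = 24) -> pd.DataFrame:
    """Mean (+SE across replicates) prospecting-allele frequencies.

    Frequencies are computed per replicate over its adults, then
    averaged, matching how the spectra are reported.
    """
    adults = snapshot[snapshot["stage"] == "adult"]
    rows = []
    for rep, grp in adults.groupby("replicate", observed=True):
        freqs, _ = np_frequency_and_mode(grp[NP_LOCUS].to_numpy(), np_max)
        rows.append(freqs)
    mat = np.vstack(rows)
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros(np_max + 1)
    return pd.DataFrame(
        {"n_p": np.arange(np_max + 1), "frequency": mean, "se": se, "mode_flag": mean == mean.max()}
    )


def modal_np(snapshot: pd.DataFrame, np_max: int = 24) -> int:
    """Mode of the replicate-averaged prospecting spectrum."""
    spec = np_spectrum(snapshot, np_max)
    return int(spec["n_p"][spec["frequency"].idxmax()])


def evolved_trait_mean(snapshot: pd.DataFrame, locus: str) -> Tuple[float, float]:
    """Final adult allele mean of ``locus``: per-replicate mean of the
    adult population, then mean +/- SE across replicates."""
    adults = snapshot[snapshot["stage"] == "adult"]
    if adults.empty:
        raise ValueError("no adults in snapshot")
    per_rep = adults.groupby("replicate", observed=True)[locus].mean().to_numpy()
    return _mean_se(per_rep)


def realized_emigration_mean(
    snapshot: pd.DataFrame, status: str = "successful"
) -> Tuple[float, float]:
    """Mean realized emigration probability of the reaction norm.

    Evaluates each adult's status-specific norm ``beta + alpha * LBS``
    at the realized LBS of its patch, clamps to [0, 1], averages per
    replicate, then across replicates.
    """
    adults = snapshot[snapshot["stage"] == "adult"].copy()
    if adults.empty:
        raise ValueError("no adults in snapshot")
    beta, alpha = f"beta_{'succ' if status == 'successful' else 'fail'}", (
        f"alpha_{'succ' if status == 'successful' else 'fail'}"
    )
    adults["p_emig"] = clamp01(
        adults[beta].to_numpy() + adults[alpha].to_numpy() * adults["lbs_patch"].to_numpy()
    )
    per_rep = adults.groupby("replicate", observed=True)["p_emig"].mean().to_numpy()
    return _mean_se(per_rep)


def reaction_norm_summary(
    snapshot: pd.DataFrame,
    n_individuals: int = 20,
    n_points: int = 51,
    rng: np.random.Generator | None = None,
) -> Dict[str, pd.DataFrame]:
    """Mean and sampled individual emigration reaction norms.

    For each breeding status, returns the population-mean intercept and
    slope, the mean norm ``clamp01(beta + alpha * LBS)`` on a grid of
    LBS values (with a flag where the raw line exits [0, 1]), and a
    random sample of individual norms.
    """
    adults = snapshot[snapshot["stage"] == "adult"]
    if adults.empty:
        raise ValueError("no adults in snapshot")
    if rng is None:
        rng = np.random.default_rng(0)
    lbs = np.linspace(0.0, 1.0, n_points)
    out: Dict[str, pd.DataFrame] = {}
    means = {}
    for status, tag in (("failed", "fail"), ("successful", "succ")):
        beta = adults[f"beta_{tag}"].to_numpy()
        alpha = adults[f"alpha_{tag}"].to_numpy()
        means[status] = {"beta": float(beta.mean()), "alpha": float(alpha.mean())}
        raw = means[status]["beta"] + means[status]["alpha"] * lbs
        mean_norm = pd.DataFrame(
            {"lbs": lbs, "p_emig": clamp01(raw), "clamped": (raw < 0) | (raw > 1)}
        )
        take = rng.choice(
            adults.index.to_numpy(), size=min(n_individuals, len(adults)), replace=False
        )
        indiv = pd.concat(
            [
                pd.DataFrame(
                    {
                        "individual": i,
                        "lbs": lbs,
                        "p_emig": clamp01(
                            adults.at[i, f"beta_{tag}"] + adults.at[i, f"alpha_{tag}"] * lbs
                        ),
                    }
                )
                for i in take
            ],
            ignore_index=True,
        )
        out[status] = mean_norm
        out[f"{status}_individuals"] = indiv
    out["means"] = pd.DataFrame(means).T.rename_axis("status").reset_index()
    return out


def density_by_quality(patches: pd.DataFrame, bin_width: float = 0.5) -> pd.DataFrame:
    """Mean adult count (+/- SE) per environmental-quality bin.

    Pools patch-years; empty bins are simply absent from the output.
    """
    df = patches.copy()
    df["q_bin"] = np.floor(df["q"] / bin_width) * bin_width + bin_width / 2
    grouped = df.groupby("q_bin")["n_adults"]
    out = grouped.agg(
        mean_n="mean",
        se_n=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n_patch_years="count",
    ).reset_index()
    return out


def trait_means_table(snapshot: pd.DataFrame, loci) -> pd.DataFrame:
    """Tidy table of evolved allele means (+/- SE across replicates)."""
    rows = []
    for locus in loci:
        mean, se = evolved_trait_mean(snapshot, locus)
        rows.append({"locus": locus, "mean": mean, "se": se})
    return pd.DataFrame(rows)
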