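"""Emigration, prospecting and settlement.

Dispersal has three phases, each resolved on a *pre-movement snapshot*
of the patch network (occupancy and local breeding success, LBS, as they
stand after reproduction and before anyone moves), so outcomes do not
depend on the order in which individuals are processed.

**Emigration.**  Three information regimes:

* ``uninformed`` — everyone emigrates with the same probability ``E``;
* ``personal`` — ``E_succ`` after a successful season, ``E_fail`` after
  a failed one;
* ``personal_public`` — a status-specific linear reaction norm on the
  local breeding success, ``beta + alpha * LBS``.

New recruits have no breeding history and use the failed-breeder rule,
reading the LBS of their natal patch.  Reaction-norm outputs (and
evolving alleles generally) are clamped to [0, 1] only here, at the
point of use as a probability.

**Prospecting.**  An emigrant visits a uniform random subset of
``N_p`` candidate patches (every patch other than its own; truncated
when fewer are available) and pays a mortality cost
``M * n_prospected`` before settling.

**Settlement.**  The prospected patches' LBS values map to settlement
probabilities through one of three patch-selection processes:
``inaccurate`` (probability proportional to LBS), ``accurate`` (softmax
with accuracy coefficient 50 on LBS), or ``deterministic`` (always the
highest-LBS patch, ties uniform).  Non-prospectors (``N_p = 0``) settle
uniformly at random among candidates; prospecting a single patch is
likewise equivalent to random settlement.  A patch empty at the
snapshot carries LBS 0, so informed settlers almost never choose one —
but random settlers can, which is the metapopulation's only
recolonization route and is what keeps the 25-patch network alive over
evolutionary time.  An emigrant can never return to its immediately
previous patch; if no other patch exists it stays put.
"""

from __future__ import annotations


import numpy as np

from .demography import STATUS_SUCCESSFUL

PROCESSES = ("inaccurate", "accurate", "deterministic")
STRATEGIES = ("uninformed", "personal", "personal_public")

#: Accuracy coefficient of the softmax ("accurate") patch-selection process.
ACCURACY_COEF = 50.0


def clamp01(x):
    """Clamp an allele value to [0, 1] for use as a probability."""
    return np.clip(x, 0.0, 1.0)


def emigration_probability(
    genotype,
    strategy: str,
    status,
    lbs_local=None,
):
    """Per-individual emigration probability under a strategy.

    ``genotype`` is a mapping from locus name to scalar or array;
    ``status`` is the breeding-status code (recruits pass
    ``STATUS_NONE`` or ``STATUS_FAILED`` — both resolve to the
    failed-breeder rule, since only ``STATUS_SUCCESSFUL`` selects the
    successful branch).  ``lbs_local`` is required for the
    ``personal_public`` strategy and is the snapshot LBS of the
    individual's current patch.
    """
    status = np.asarray(status)
    success = status == STATUS_SUCCESSFUL
    if strategy == "uninformed":
        e, _ = np.broadcast_arrays(np.asarray(genotype["e"], dtype=float), status)
        return clamp01(e)
    if strategy == "personal":
        return clamp01(np.where(success, genotype["e_succ"], genotype["e_fail"]))
    if strategy == "personal_public":
        if lbs_local is None:
            raise ValueError("personal_public strategy requires the local LBS")
        lbs = np.asarray(lbs_local, dtype=float)
        raw = np.where(
            success,
            np.asarray(genotype["beta_succ"]) + np.asarray(genotype["alpha_succ"]) * lbs,
            np.asarray(genotype["beta_fail"]) + np.asarray(genotype["alpha_fail"]) * lbs,
        )
        return clamp01(raw)
    raise ValueError(f"unknown emigration strategy {strategy!r}")


def candidate_patches(current_patch: int, n_patches: int) -> np.ndarray:
    """Eligible destinations: every patch except the current one.

    Emigrants may not return to the patch they just left; any other
    patch — occupied or empty — can be prospected or settled (empty
    patches carry LBS 0 and are therefore shunned by informed
    settlement, but reachable by random settlement).
    """
    cand = np.arange(n_patches)
    return cand[cand != current_patch]


def draw_prospected_set(
    candidates: np.ndarray, n_p: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random subset of min(n_p, len(candidates)) candidates."""
    if n_p < 0:
        raise ValueError(f"n_p must be >= 0, got {n_p}")
    candidates = np.asarray(candidates)
    k = min(int(n_p), candidates.size)
    if k == 0:
        return candidates[:0]
    return rng.choice(candidates, size=k, replace=False)


def settlement_probabilities(
    lbs_values: np.ndarray, process: str, accuracy: float = ACCURACY_COEF
) -> np.ndarray:
    """Settlement probability vector over the prospected patches.

    ``inaccurate``: p_i = LBS_i / sum(LBS) (uniform when all LBS are 0);
    ``accurate``:   p_i = exp(accuracy * LBS_i) / sum(exp(accuracy * LBS));
    ``deterministic``: unit mass on the maximal-LBS patch (ties uniform).
    """
    lbs = np.asarray(lbs_values, dtype=float)
    if lbs.size == 0:
        raise ValueError("settlement requires at least one prospected patch")
    if process == "inaccurate":
        total = lbs.sum()
        if total <= 0:
            return np.full(lbs.size, 1.0 / lbs.size)
        return lbs / total
    if process == "accurate":
        z = accuracy * lbs
        z = z - z.max()  # stable softmax
        w = np.exp(z)
        return w / w.sum()
    if process == "deterministic":
        best = lbs == lbs.max()
        return best / best.sum()
    raise ValueError(f"unknown patch selection process {process!r}")


def prospecting_survival(
    n_prospected, m: float, rng: np.random.Generator
):
    """Bernoulli survival of the prospecting trip (death prob M * n).

    Elementwise on arrays. ``m * n`` must not exceed 1.
    """
    n_prospected = np.asarray(n_prospected)
    cost = m * n_prospected
    if np.any(cost > 1.0) or m < 0:
        raise ValueError("prospecting mortality M * n_p must lie in [0, 1]")
    return rng.random(n_prospected.shape) >= cost


def settle(
    current_patch: int,
    candidates: np.ndarray,
    prospected: np.ndarray,
    lbs_by_patch: np.ndarray,
    process: str,
    rng: np.random.Generator,
) -> int:
    """Destination of one surviving emigrant.

    Non-prospectors choose uniformly among candidates; prospectors
    sample from :func:`settlement_probabilities` over their prospected
    set.  With no candidates the emigrant stays in ``current_patch``.
    """
    candidates = np.asarray(candidates)
    if candidates.size == 0:
        return int(current_patch)
    prospected = np.asarray(prospected)
    if prospected.size == 0:
        return int(rng.choice(candidates))
    p = settlement_probabilities(lbs_by_patch[prospected], process)
    return int(rng.choice(prospected, p=p))


def disperse_batch(
    patch: np.ndarray,
    n_p: np.ndarray,
    lbs_by_patch: np.ndarray,
    process: str,
    m: float,
    rng: np.random.Generator,
    accuracy: float = ACCURACY_COEF,
):
    """Prospecting + settlement for every emigrant of a year at once.

    All emigrants share the snapshot ``lbs_by_patch`` (NaN for patches
    without adults, treated as 0).  Returns ``(destination, died)``:
    per-emigrant destination patch (current patch when no candidate
    exists) and prospecting-death mask.

    The random subset of prospected patches is drawn with the ranking
    trick: give every patch an i.i.d. uniform key (non-candidates get
    +inf), rank keys within each emigrant, and prospect the patches
    ranked below min(n_p, n_candidates) — a uniform subset without
    replacement, vectorized across emigrants.
    """
    if process not in PROCESSES:
        raise ValueError(f"unknown patch selection process {process!r}")
    patch = np.asarray(patch)
    n_em = patch.size
    n_patches = np.asarray(lbs_by_patch).size
    dest = patch.copy()
    died = np.zeros(n_em, dtype=bool)
    if n_em == 0:
        return dest, died

    cand = np.ones((n_em, n_patches), dtype=bool)
    cand[np.arange(n_em), patch] = False
    n_cand = cand.sum(axis=1)
    k = np.minimum(np.asarray(n_p), n_cand)

    if m * np.max(np.asarray(n_p), initial=0) > 1.0:
        raise ValueError("prospecting mortality M * n_p must lie in [0, 1]")
    died = rng.random(n_em) < m * k

    # Uniform subset of size k: a candidate is prospected iff its key is
    # below the k-th smallest key in its row (keys are a.s. distinct).
    keys = rng.random((n_em, n_patches))
    keys[~cand] = np.inf
    sorted_keys = np.sort(keys, axis=1)
    threshold = sorted_keys[np.arange(n_em), np.minimum(k, n_patches - 1)]
    threshold[k == 0] = -np.inf
    prospected = keys < threshold[:, None]

    lbs = np.where(np.isnan(lbs_by_patch), 0.0, lbs_by_patch)
    if process == "inaccurate":
        w = np.where(prospected, lbs, 0.0)
        empty = w.sum(axis=1) <= 0
        w[empty] = prospected[empty]
    elif process == "accurate":
        z = accuracy * np.broadcast_to(lbs, (n_em, n_patches)) - np.where(
            prospected, 0.0, np.inf
        )
        zmax = np.max(z, axis=1, keepdims=True)
        zmax[~np.isfinite(zmax)] = 0.0
        w = np.exp(z - zmax)
        w[~prospected] = 0.0
    else:  # deterministic
        masked = np.where(prospected, lbs, -np.inf)
        best = masked.max(axis=1, keepdims=True)
        w = (masked == best) & prospected

    # Non-prospectors (k == 0) settle uniformly among candidates.
    random_rows = k == 0
    w = w.astype(float)
    w[random_rows] = cand[random_rows]
    # Emigrants with no candidate at all keep their current patch.
    stuck = n_cand == 0
    w[stuck] = 0.0
    w[stuck, patch[stuck]] = 1.0

    cum = np.cumsum(w, axis=1)
    u = rng.random(n_em) * cum[:, -1]
    dest = np.minimum((cum <= u[:, None]).sum(axis=1), n_patches - 1)
    return dest, died
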