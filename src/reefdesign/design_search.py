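"""Candidate-design construction, coordinate-exchange optimization, and
design-efficiency evaluation.

Two monitoring questions drive the candidate sets:

* which reef location could be dropped from the next survey with the
  least loss of information — seven candidate designs, each omitting
  all three sites of one reef (:func:`enumerate_drop_one_reef`),
  evaluated exhaustively; and
* which single site per reef location is most informative — a space of
  3^7 = 2187 one-site-per-reef designs searched by the coordinate-
  exchange algorithm from five random starting designs
  (:func:`coordinate_exchange`).

Designs are scored against the full 21-unit design d_L by the design
efficiency Eff = E[u(d)] / E[u(d_L)] (1 = no information loss), with
the two expected utilities evaluated repeatedly (20 replicates by
default) to damp the Monte Carlo noise of the utility estimator; by
default replicate j of d shares its random substream with replicate j
of d_L (paired evaluation), and an unpaired mode matching fully
independent repetitions is available.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .design_utility import (
    Design,
    DesignError,
    Scenario,
    SeedLike,
    UtilityEstimate,
    _seed_key,
    expected_utility,
)
from .inference import GaussianApprox, InferenceError
from .model import DesignMatrices, HistoricalDataset, ModelConfig
from .survey_data import REEFS, SITES_PER_REEF

__all__ = [
    "EfficiencyResult",
    "SearchResult",
    "enumerate_drop_one_reef",
    "coordinate_exchange",
    "drop_one_reef_efficiencies",
    "efficiency",
]


@dataclasses.dataclass
class EfficiencyResult:
    """Per-replicate efficiency ratios for one design against d_L."""

    design: Design
    ratios: np.ndarray
    seeds: tuple[int, ...]
    utilities: list[tuple[UtilityEstimate, UtilityEstimate]] = dataclasses.field(
        default_factory=list, repr=False
    )

    @property
    def mean(self) -> float:
        return float(self.ratios.mean())

    @property
    def sd(self) -> float:
        return float(self.ratios.std(ddof=1)) if self.ratios.size > 1 else 0.0


@dataclasses.dataclass
class SearchResult:
    """Outcome of a coordinate-exchange search."""

    best_design: Design
    best_utility: float
    trajectories: list[list[float]]
    n_starts: int
    start_results: list[tuple[Design, float]] = dataclasses.field(
        default_factory=list, repr=False
    )


def enumerate_drop_one_reef(
    reefs: Sequence[str] = REEFS,
    sites: Sequence[int] = tuple(range(1, SITES_PER_REEF + 1)),
) -> list[Design]:
    """The seven drop-one-reef candidate designs.

    The design labelled by a reef omits all of that reef's sites and
    keeps every site of the six remaining reefs (ns = 18).
    """
    designs = []
    for omitted in reefs:
        units = tuple((r, s) for r in reefs if r != omitted for s in sites)
        designs.append(Design(units, label=str(omitted)))
    return designs


def _one_site_design(assignment: dict[str, int], reefs: Sequence[str]) -> Design:
    units = tuple((r, assignment[r]) for r in reefs)
    label = ",".join(f"{r}:{assignment[r]}" for r in reefs)
    return Design(units, label=label)


def coordinate_exchange(
    utility_fn: Callable[[Design, SeedLike], float],
    reefs: Sequence[str] = REEFS,
    sites: Sequence[int] = tuple(range(1, SITES_PER_REEF + 1)),
    n_starts: int = 5,
    seed: SeedLike = 0,
    max_sweeps: int = 10,
) -> SearchResult:
    """Coordinate-exchange search over one-site-per-reef designs.

    From each random starting design, reefs are swept in randomized
    order and the chosen site is exchanged for the utility-maximizing
    alternative; a sweep evaluates every candidate exchange with the
    same random substream (common random numbers), the incumbent is
    kept on ties, and the search stops when a full sweep makes no
    exchange.  Fresh substreams between sweeps avoid a systematic seed
    bias; because re-estimated utilities of near-tied designs can keep
    toggling exchanges indefinitely, each start is capped at
    ``max_sweeps`` sweeps.  Final designs from all starts are re-scored
    with one shared substream and the best is returned (ties broken by
    the lexicographically smallest site assignment).
    """
    key = _seed_key(seed)
    trajectories: list[list[float]] = []
    finals: list[Design] = []
    failures: list[str] = []
    for s in range(n_starts):
        rng = np.random.default_rng(key + (s,))
        assignment = {r: int(rng.choice(list(sites))) for r in reefs}
        traj: list[float] = []
        try:
            for sweep in range(max_sweeps):
                sweep_seed = key + (s, sweep)
                current = utility_fn(_one_site_design(assignment, reefs), sweep_seed)
                changed = False
                for r in rng.permutation(np.asarray(reefs, dtype=object)):
                    best_site, best_u = assignment[r], current
                    for cand_site in sites:
                        if cand_site == assignment[r]:
                            continue
                        cand = dict(assignment, **{r: int(cand_site)})
                        u = utility_fn(_one_site_design(cand, reefs), sweep_seed)
                        if u > best_u:
                            best_site, best_u = int(cand_site), u
                    if best_site != assignment[r]:
                        assignment[r] = best_site
                        current = best_u
                        changed = True
                traj.append(current)
                if not changed:
                    break
        except (InferenceError, np.linalg.LinAlgError) as exc:
            failures.append(f"start {s}: {exc}")
            continue
        trajectories.append(traj)
        finals.append(_one_site_design(assignment, reefs))
    if not finals:
        raise InferenceError(
            f"all {n_starts} coordinate-exchange starts failed: {failures}"
        )

    final_seed = key + (n_starts, 0)
    scored = [(d, utility_fn(d, final_seed)) for d in finals]
    best_u = max(u for _, u in scored)
    tied = [d for d, u in scored if u == best_u]
    best = min(tied, key=lambda d: tuple(s for _, s in d.units))
    return SearchResult(best, best_u, trajectories, n_starts, scored)


def drop_one_reef_efficiencies(
    scenario: Scenario,
    prior: GaussianApprox,
    dataset: HistoricalDataset | DesignMatrices,
    J: int = 100,
    reps: int = 20,
    seed: SeedLike = 0,
    config: ModelConfig | None = None,
    **utility_kwargs,
) -> list[EfficiencyResult]:
    """Paired efficiencies of all seven drop-one-reef candidate designs.

    Equivalent to calling :func:`efficiency` on each candidate with the
    same seed, but the full-design reference utilities are evaluated
    once per replicate and shared across candidates.
    """
    key = _seed_key(seed)
    if isinstance(dataset, DesignMatrices):
        units = dataset.units
    else:
        units = tuple(dataset.units)
    reference = Design(tuple(units), label="d_L")
    ref_utils = [
        expected_utility(
            reference, scenario, prior, dataset, J=J, seed=key + (r, 0),
            config=config, **utility_kwargs,
        )
        for r in range(reps)
    ]
    results = []
    for design in enumerate_drop_one_reef():
        ratios = []
        utilities = []
        for r in range(reps):
            u_d = expected_utility(
                design, scenario, prior, dataset, J=J, seed=key + (r, 0),
                config=config, **utility_kwargs,
            )
            ratios.append(u_d.mean / ref_utils[r].mean)
            utilities.append((u_d, ref_utils[r]))
        results.append(EfficiencyResult(design, np.asarray(ratios), key, utilities))
    return results


def efficiency(
    design: Design,
    scenario: Scenario,
    prior: GaussianApprox,
    dataset: HistoricalDataset | DesignMatrices,
    J: int = 100,
    reps: int = 20,
    seed: SeedLike = 0,
    paired: bool = True,
    config: ModelConfig | None = None,
    reference: Design | None = None,
    **utility_kwargs,
) -> EfficiencyResult:
    """Design efficiency of ``design`` relative to the full design d_L.

    Each replicate evaluates the expected utility of the design and of
    d_L and forms their ratio; the result carries all replicate ratios
    plus their mean and standard deviation.  With ``paired=True``
    (default) replicate r of both designs shares one substream, so the
    ratio cancels most of the Monte Carlo noise; ``paired=False``
    reproduces fully independent repetitions.
    """
    if reps < 1:
        raise DesignError("reps must be >= 1")
    if reference is None:
        if isinstance(dataset, DesignMatrices):
            units = dataset.units
        else:
            units = tuple(dataset.units)
        reference = Design(tuple(units), label="d_L")
    key = _seed_key(seed)
    ratios = []
    utilities = []
    errors: list[str] = []
    for r in range(reps):
        seed_d = key + (r, 0)
        seed_ref = key + (r, 0) if paired else key + (r, 1)
        try:
            u_d = expected_utility(
                design, scenario, prior, dataset, J=J, seed=seed_d,
                config=config, **utility_kwargs,
            )
            u_ref = expected_utility(
                reference, scenario, prior, dataset, J=J, seed=seed_ref,
                config=config, **utility_kwargs,
            )
        except (InferenceError, np.linalg.LinAlgError) as exc:
            errors.append(f"replicate {r}: {exc}")
            continue
        if u_ref.mean <= 0:
            errors.append(f"replicate {r}: reference utility {u_ref.mean} <= 0")
            continue
        ratios.append(u_d.mean / u_ref.mean)
        utilities.append((u_d, u_ref))
    if len(ratios) < max(1, reps // 2):
        raise InferenceError(
            f"efficiency evaluation failed in {reps - len(ratios)}/{reps} "
            f"replicates: {errors[:5]}"
        )
    return EfficiencyResult(design, np.asarray(ratios), key, utilities)
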