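"""Generator of Scott-Reef-like datasets with known parameters.

Emulates the structure of the monitoring data: 7 reef locations
(SL1..SL4, SS1..SS3) x 3 nested sites, ~25 irregularly spaced surveys
over 1994.83-2016.08 with 1250 binomial trials per site, a mass
bleaching event interrupting the trend in 1998 (pre/post surveys in
January and October 1998), reef-heterogeneous disturbance-exposure
dummies, and occasional cyclone exposure.  Counts are drawn from the
full model — nested reef/site random effects, the thin-plate spline
smooth of centered time, disturbance covariates, and the interrupted
time-series level/slope terms — so every downstream stage (fitting,
Gaussian summarization, design evaluation) can be exercised against a
known truth without any external data.

The default true parameters are illustrative, chosen so cover
trajectories fall roughly in the 0.05-0.6 range with the
characteristic post-1998 collapse and slow recovery; they are not
estimates from the real monitoring data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design_utility import Scenario
from .model import (
    ModelConfig,
    ParameterVector,
    build_design_matrices,
    success_prob,
)
from .survey_data import DEFAULT_TRIALS, REEFS, HistoricalDataset, SurveyDataError

__all__ = [
    "GeneratorConfig",
    "default_true_params",
    "generate_dataset",
    "make_scenario",
    "write_synthetic_tables",
]

#: Default disturbance-exposure classes (heterogeneous, as at Scott
#: Reef where exposure differed between reef locations).  A reef in the
#: cyclone/bleaching class is exposed in the corresponding event years;
#: the severe class additionally takes a severe-cyclone hit in the
#: largest cyclone year.
DEFAULT_CYCLONE_REEFS = ("SL3", "SL4", "SS2")
DEFAULT_SEVERE_REEFS = ("SL4",)
DEFAULT_BLEACHING_REEFS = ("SL1", "SL2", "SS1", "SS2")

#: Default true fixed effects (model scale, centered covariates):
#: a weak secular trend, negative disturbance effects, a large level
#: drop at the 1998 event, and a positive post-event recovery slope.
DEFAULT_TRUE_BETA = {
    "intercept": 0.3,
    "time": 0.01,
    "bleaching": -0.25,
    "sqrt_cyclone": -0.06,
    "interaction": -0.04,
    "cyclone_loc": -0.2,
    "severe_cyclone_loc": -0.3,
    "bleaching_loc": -0.2,
    "ble98": -1.8,
    "time98": 0.08,
}

#: Default true standard deviations for the random components.  The
#: standardized spline basis columns are O(100) over a two-decade time
#: window, so a coefficient sd of 0.01 corresponds to a smooth trend
#: component of roughly +/- one logit unit.
DEFAULT_TRUE_SDS = {"sigma_delta": 0.01, "sigma_reef": 0.3, "sigma_site": 0.2}


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic monitoring program.

    ``true_beta``/``true_sds`` override individual true parameter
    values; the disturbance schedule assigns the bleaching indicator
    and cyclone hours per survey year.  ``jitter`` perturbs the
    October survey dates (anchor surveys — the 1994 baseline, the 1998
    pre/post-bleaching pair, and the 2016 final survey — are never
    jittered), mimicking the year-to-year variation in survey timing.
    """

    reefs: tuple[str, ...] = REEFS
    sites_per_reef: int = 3
    start_year: int = 1994
    end_year: int = 2016
    n_trials: int = DEFAULT_TRIALS
    event_time: float = 1998.83
    jitter: float = 0.05
    true_beta: tuple[tuple[str, float], ...] = ()
    true_sds: tuple[tuple[str, float], ...] = ()
    model: ModelConfig = ModelConfig()
    cyclone_years: tuple[tuple[int, float], ...] = ((2004, 40.0), (2010, 30.0), (2012, 25.0))
    bleaching_years: tuple[int, ...] = (1998, 2010)
    seed: int = 0

    def beta(self) -> dict[str, float]:
        return {**DEFAULT_TRUE_BETA, **dict(self.true_beta)}

    def sds(self) -> dict[str, float]:
        return {**DEFAULT_TRUE_SDS, **dict(self.true_sds)}


def default_true_params() -> dict[str, float]:
    """The default true parameter values (fixed effects and sds)."""
    return {**DEFAULT_TRUE_BETA, **DEFAULT_TRUE_SDS}


def _survey_times(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Irregular survey schedule: jittered Octobers plus anchor surveys.

    Anchors: the baseline (start_year.83), the January 1998 pre-
    bleaching survey, the October 1998 post-bleaching survey, one
    mid-year survey (2004.33), and the final end_year.08 survey —
    giving 25 surveys for the default 1994-2016 window.
    """
    lo, hi = config.start_year + 0.83, config.end_year + 0.08
    anchors = {lo, hi}
    for t in (1998.08, 1998.83, 2004.33):
        if lo <= t <= hi:
            anchors.add(t)
    times = set(anchors)
    for year in range(config.start_year + 1, config.end_year):
        if year == 1998:
            continue
        t = year + 0.83
        if config.jitter > 0:
            t += float(rng.uniform(-config.jitter, config.jitter))
        times.add(round(t, 2))
    return np.array(sorted(times))


def _covariate_table(config: GeneratorConfig, times: np.ndarray) -> pd.DataFrame:
    cyclone = dict(config.cyclone_years)
    rows = []
    for t in times:
        year = int(np.floor(t))
        rows.append(
            {
                "time": t,
                "bleaching": int(year in config.bleaching_years and t >= year + 0.5),
                "cyclone_hours": float(cyclone.get(year, 0.0)),
            }
        )
    # the January 1998 survey precedes the October bleaching event, so
    # only surveys from mid-year onwards carry the indicator
    return pd.DataFrame(rows)


def _dummy_table(config: GeneratorConfig, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-(reef, time) exposure dummies aligned with the covariate table.

    A reef is exposed in an interval when the whole-of-reef disturbance
    was active there and the reef belongs to the corresponding exposure
    class; the severe-cyclone dummy fires for severe-class reefs in the
    year with the largest cyclone exposure.
    """
    cyclone_years = dict(config.cyclone_years)
    worst_year = (
        max(cyclone_years, key=cyclone_years.get) if cyclone_years else None
    )
    rows = []
    for i, reef in enumerate(config.reefs):
        in_cyc = reef in DEFAULT_CYCLONE_REEFS or (
            reef not in REEFS and i % 2 == 0
        )
        in_sev = reef in DEFAULT_SEVERE_REEFS
        in_ble = reef in DEFAULT_BLEACHING_REEFS or (
            reef not in REEFS and (i + 1) % 2 == 0
        )
        for _, cov in covariates.iterrows():
            year = int(np.floor(cov["time"]))
            rows.append(
                {
                    "reef": reef,
                    "time": float(cov["time"]),
                    "cyclone_loc": int(in_cyc and cov["cyclone_hours"] > 0),
                    "severe_cyclone_loc": int(
                        in_sev and cov["cyclone_hours"] > 0 and year == worst_year
                    ),
                    "bleaching_loc": int(in_ble and cov["bleaching"] == 1),
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[HistoricalDataset, ParameterVector]:
    """Draw a synthetic historical dataset and return it with its truth.

    Reef effects lambda_r, site effects gamma_sr and spline
    coefficients delta are drawn from their assumed normal
    distributions; the linear predictor follows the full model
    (including the interrupted time-series drop at ``event_time``) and
    counts are Binomial(n_trials, logistic(mu)).  Identical
    configurations (including the seed) give bitwise-identical
    datasets.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    times = _survey_times(config, rng)
    covariates = _covariate_table(config, times)
    dummies = _dummy_table(config, covariates)

    sites = range(1, config.sites_per_reef + 1)
    skeleton = pd.DataFrame(
        [
            {"reef": r, "site": s, "time": t, "y": 0, "n": config.n_trials}
            for r in config.reefs
            for s in sites
            for t in times
        ]
    )
    base = HistoricalDataset(
        skeleton, covariates, dummies, event_time=config.event_time
    )
    matrices = build_design_matrices(base, config.model)
    idx = matrices.index

    beta_true = config.beta()
    sds = config.sds()
    theta = np.zeros(idx.n_theta)
    for i, name in enumerate(idx.beta_names):
        theta[i] = beta_true[name]
    if config.model.smooth:
        theta[idx.sl_delta] = sds["sigma_delta"] * rng.standard_normal(idx.K)
        theta[idx.theta_names.index("log_sigma_delta")] = np.log(sds["sigma_delta"])
    if config.model.nested_random_effects:
        theta[idx.theta_names.index("log_sigma_reef")] = np.log(sds["sigma_reef"])
        theta[idx.theta_names.index("log_sigma_site")] = np.log(sds["sigma_site"])
        lam = sds["sigma_reef"] * rng.standard_normal(len(idx.lambda_names))
        gam = lam[matrices.unit_reef_index] + sds["sigma_site"] * rng.standard_normal(
            len(idx.gamma_names)
        )
        xi = np.concatenate([lam, gam])
    else:
        xi = np.empty(0)

    mu = matrices.mu(theta, xi)
    pi = success_prob(mu)
    y = rng.binomial(config.n_trials, pi)
    surveys = matrices.records.copy()
    surveys["y"] = y
    dataset = HistoricalDataset(
        surveys, covariates, dummies, event_time=config.event_time
    )
    truth = ParameterVector(idx, theta, xi)
    return dataset, truth


def make_scenario(
    kind: str,
    dataset: HistoricalDataset,
    t_next: float = 2016.33,
    cyclone_hours: float | None = None,
    bleaching: float | None = None,
) -> Scenario:
    """Disturbance scenario for the next survey time.

    The disturbance covariates — including the per-reef exposure
    dummies — describe what happens in the interval before the next
    survey, so they are scenario settings, not static reef attributes.
    ``kind='a'`` continues the time-varying covariates observed at the
    last survey and withdraws all cyclone and location exposures (the
    prevailing-conditions scenario); ``kind='b'`` activates bleaching
    and cyclone exposure with their interaction at every reef location
    (cyclone and bleaching location dummies forced to 1 everywhere,
    cyclone hours defaulting to the historical mean of the nonzero
    exposures).
    """
    cov = dataset.covariates.sort_values("time")
    last = cov.iloc[-1]
    reefs = tuple(dataset.dummies["reef"])
    if kind == "a":
        overrides = tuple(
            (reef, (("cyclone_loc", 0), ("severe_cyclone_loc", 0),
                    ("bleaching_loc", 0)))
            for reef in reefs
        )
        return Scenario(
            label="a",
            t_next=t_next,
            bleaching=float(last["bleaching"] if bleaching is None else bleaching),
            cyclone_hours=0.0 if cyclone_hours is None else float(cyclone_hours),
            dummy_overrides=overrides,
        )
    if kind == "b":
        nonzero = cov.loc[cov["cyclone_hours"] > 0, "cyclone_hours"]
        hours = (
            float(nonzero.mean())
            if cyclone_hours is None
            else float(cyclone_hours)
        )
        if not np.isfinite(hours):
            hours = 0.0
        overrides = tuple(
            (reef, (("cyclone_loc", 1), ("severe_cyclone_loc", 0),
                    ("bleaching_loc", 1)))
            for reef in reefs
        )
        return Scenario(
            label="b",
            t_next=t_next,
            bleaching=1.0 if bleaching is None else float(bleaching),
            cyclone_hours=hours,
            dummy_overrides=overrides,
        )
    raise SurveyDataError(f"unknown scenario kind {kind!r} (expected 'a' or 'b')")


def write_synthetic_tables(
    directory: str | Path, config: GeneratorConfig | None = None
) -> dict[str, Path]:
    """Generate a dataset and write its CSVs plus a JSON truth file."""
    config = config or GeneratorConfig()
    dataset, truth = generate_dataset(config)
    paths = dataset.write_tables(directory)
    truth_path = Path(directory) / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "seed": config.seed,
                "event_time": config.event_time,
                "theta": dict(zip(truth.index.theta_names, truth.theta.tolist())),
                "xi": dict(zip(truth.index.xi_names, truth.xi.tolist())),
            },
            indent=2,
        )
    )
    paths["truth"] = truth_path
    return paths
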