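"""Expected information gain of candidate monitoring designs.

A design is a subset of the 21 (reef, site) sampling units to visit at
the next survey time (2016.33 by default).  Its value is the expected
Kullback-Leibler divergence from the design prior (the posterior of the
historical fit, in Gaussian form) to the posterior after observing the
new counts — the expected information gain about the model parameters.

The expectation has no closed form, so it is approximated by Monte
Carlo: draw parameters from the design prior, simulate next-survey
counts under them, update the posterior by a Laplace approximation, and
average the Gaussian KLD over draws (J >= 100 draws by default).  The
mean response at the future time is extrapolated by a first-order
bivariate Taylor expansion of the time-dependent part of the linear
predictor (the spline trend and the post-disturbance slope term) around
the last historical survey; all other covariate terms are evaluated
directly at the scenario's covariate values.

Common random numbers: the j-th Monte Carlo draw is keyed by (seed, j)
and simulates counts for all 21 units in a fixed order, so two designs
evaluated with the same seed share parameter draws and unit-level
counts — paired comparisons between designs then have much smaller
Monte Carlo error.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, Sequence

import numpy as np

from scipy.special import expit

from .inference import (
    BinomialRows,
    GaussianApprox,
    InferenceError,
    _marginal_laplace,
    _Posterior,
)
from .model import (
    DesignMatrices,
    HistoricalDataset,
    ModelConfig,
    ModelError,
    build_design_matrices,
    success_prob,
)
from .survey_data import REEFS, SITES_PER_REEF, DEFAULT_TRIALS

__all__ = [
    "Design",
    "Scenario",
    "TaylorCenter",
    "UtilityEstimate",
    "DesignError",
    "full_design",
    "kld_gaussian",
    "taylor_mean_response",
    "simulate_future_data",
    "expected_utility",
    "expected_kld_gain",
]

SeedLike = int | Sequence[int]


class DesignError(ValueError):
    """Raised for invalid designs or scenarios."""


def _seed_key(seed: SeedLike) -> tuple[int, ...]:
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


@dataclasses.dataclass(frozen=True)
class Design:
    """An ordered set of (reef, site) units to sample at the next survey."""

    units: tuple[tuple[str, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        units = tuple((str(r), int(s)) for r, s in self.units)
        object.__setattr__(self, "units", units)
        if len(set(units)) != len(units):
            raise DesignError(f"design {self.label!r} has duplicate units")

    @property
    def ns(self) -> int:
        return len(self.units)

    def __contains__(self, unit: tuple[str, int]) -> bool:
        return (str(unit[0]), int(unit[1])) in self.units


def full_design(
    reefs: Sequence[str] = REEFS, sites: Sequence[int] = range(1, SITES_PER_REEF + 1)
) -> Design:
    """The all-units design d_L (every site of every reef; ns = 21)."""
    return Design(tuple((r, s) for r in reefs for s in sites), label="d_L")


@dataclasses.dataclass(frozen=True)
class Scenario:
    """Disturbance scenario at the next survey time.

    ``bleaching`` and ``cyclone_hours`` are whole-of-reef covariate
    values on the raw data scale (transformed and centered internally);
    ``dummy_overrides`` maps reef -> {dummy column: 0/1} for
    scenario-specific exposure settings, defaulting to the historical
    dummy table.
    """

    label: str = "custom"
    t_next: float = 2016.33
    bleaching: float = 0.0
    cyclone_hours: float = 0.0
    dummy_overrides: tuple[tuple[str, tuple[tuple[str, int], ...]], ...] = ()

    def overrides_dict(self) -> dict[str, dict[str, float]]:
        return {reef: dict(vals) for reef, vals in self.dummy_overrides}


@dataclasses.dataclass(frozen=True)
class TaylorCenter:
    """Expansion point for the future-time Taylor extrapolation.

    ``a`` is the centered time of the last historical survey and ``b``
    its Time98 value, so the expansion is anchored at an observed
    survey and extrapolates forward from it.
    """

    a: float
    b: float

    @classmethod
    def from_matrices(cls, matrices: DesignMatrices) -> "TaylorCenter":
        from .survey_data import build_its, center

        t_last = matrices.dataset.last_time
        a = float(center([t_last], matrices.centering, "time")[0])
        b = build_its(t_last, matrices.event_time).time98 if matrices.config.its else 0.0
        return cls(a, b)


@dataclasses.dataclass
class UtilityEstimate:
    """Monte Carlo expected utility with its standard error."""

    mean: float
    se: float
    J: int
    seed: tuple[int, ...]
    n_failed: int = 0
    values: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean,
                "se": self.se,
                "J": self.J,
                "seed": list(self.seed),
                "n_failed": self.n_failed,
            }
        )


# ---------------------------------------------------------------------
# KLD utility
# ---------------------------------------------------------------------

def kld_gaussian(posterior: GaussianApprox, prior: GaussianApprox) -> float:
    """Closed-form KL(posterior || prior) for multivariate Gaussians.

    0.5 [ tr(S0^-1 S1) + (m0-m1)' S0^-1 (m0-m1) - k + ln det S0/det S1 ]
    with (m1, S1) the posterior and (m0, S0) the prior.  Measures how
    far the updated belief has moved from the design prior; larger
    means more has been learned.
    """
    if posterior.dim != prior.dim:
        raise DesignError(
            f"dimension mismatch: posterior {posterior.dim}, prior {prior.dim}"
        )
    if posterior.names != prior.names:
        if set(posterior.names) != set(prior.names):
            raise DesignError("posterior and prior parameter names differ")
        posterior = posterior.marginal(prior.names)
    k = prior.dim
    try:
        chol0 = np.linalg.cholesky(prior.cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("prior covariance is singular") from exc
    solve = np.linalg.solve
    m = solve(chol0, (prior.mean - posterior.mean))
    a = solve(chol0, posterior.cov)
    a = solve(chol0, a.T)  # S0^-1 S1 (via two triangular-ish solves)
    trace = float(np.trace(a))
    maha = float(m @ m)
    sign1, logdet1 = np.linalg.slogdet(posterior.cov)
    logdet0 = 2.0 * float(np.sum(np.log(np.diag(chol0))))
    if sign1 <= 0:
        raise np.linalg.LinAlgError("posterior covariance is not positive definite")
    return 0.5 * (trace + maha - k + logdet0 - float(logdet1))


# ---------------------------------------------------------------------
# Taylor extrapolation of the mean response
# ---------------------------------------------------------------------

def _taylor_fixed_row(
    matrices: DesignMatrices,
    reef: str,
    scenario: Scenario,
    centerpt: TaylorCenter,
) -> np.ndarray:
    """Effective coefficient row at t_next for c = (beta, delta).

    The fixed-effect part is the scenario covariate row at t_next.  The
    spline block is linearized around the last survey: B(a) + B'(a)
    (x_next - a).  All terms that are linear in time (the time slope
    and the post-disturbance slope Time98) are exact under a first-
    order expansion, so they are evaluated directly.
    """
    from .survey_data import center

    if scenario.t_next <= matrices.dataset.last_time:
        raise DesignError(
            f"t_next = {scenario.t_next} must exceed the last historical survey "
            f"time {matrices.dataset.last_time}"
        )
    fixed = matrices.fixed_row(
        reef,
        scenario.t_next,
        scenario.bleaching,
        scenario.cyclone_hours,
        scenario.overrides_dict(),
    )
    x_next = float(center([scenario.t_next], matrices.centering, "time")[0])
    if matrices.config.smooth:
        b_a = matrices.spline_basis(np.array([centerpt.a]))[0]
        db_a = matrices.spline_basis_deriv(np.array([centerpt.a]))[0]
        spline_row = b_a + db_a * (x_next - centerpt.a)
    else:
        spline_row = np.empty(0)
    return np.concatenate([fixed, spline_row])


def taylor_mean_response(
    theta: np.ndarray,
    xi: np.ndarray,
    unit: tuple[str, int],
    scenario: Scenario,
    centerpt: TaylorCenter | None,
    matrices: DesignMatrices,
) -> float:
    """Extrapolated linear predictor mu for ``unit`` at the next survey.

    First-order bivariate expansion of the time-dependent part of the
    predictor (smooth trend f(x) and the Time98 slope term) around the
    last historical survey (a, b); for a model with all spline
    coefficients zero the expansion is exact.
    """
    centerpt = centerpt or TaylorCenter.from_matrices(matrices)
    reef, site = unit
    row = _taylor_fixed_row(matrices, reef, scenario, centerpt)
    idx = matrices.index
    c = theta[: idx.n_beta + idx.K]
    mu = float(row @ c)
    if idx.config.nested_random_effects:
        try:
            upos = matrices.units.index((reef, int(site)))
        except ValueError:
            raise ModelError(f"unit {unit!r} not in the dataset") from None
        mu += float(xi[idx.sl_gamma][upos])
    return mu


def simulate_future_data(
    design: Design,
    scenario: Scenario,
    theta: np.ndarray,
    xi: np.ndarray,
    n: int = DEFAULT_TRIALS,
    seed: SeedLike = 0,
    matrices: DesignMatrices | None = None,
    centerpt: TaylorCenter | None = None,
) -> np.ndarray:
    """Binomial counts for each design unit at the next survey time.

    Counts for all dataset units are drawn in a fixed order and then
    subset to the design, so designs sharing a seed share unit-level
    counts (common random numbers).
    """
    if matrices is None:
        raise DesignError("simulate_future_data requires design matrices")
    rng = np.random.default_rng(_seed_key(seed))
    centerpt = centerpt or TaylorCenter.from_matrices(matrices)
    mus = np.array(
        [
            taylor_mean_response(theta, xi, u, scenario, centerpt, matrices)
            for u in matrices.units
        ]
    )
    all_counts = rng.binomial(int(n), success_prob(mus))
    keep = [matrices.units.index((r, int(s))) for r, s in design.units]
    return all_counts[keep]


# ---------------------------------------------------------------------
# Monte Carlo expected utility (generic core + coral-model wrapper)
# ---------------------------------------------------------------------

def _joint_laplace_update(
    Xc: np.ndarray,
    gamma_pos: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    prior_mean: np.ndarray,
    prior_prec: np.ndarray,
    n_c: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Laplace update of a joint Gaussian prior by new binomial counts.

    The state v stacks all model parameters and latent effects; each new
    observation contributes mu = Xc_row . c + v[gamma_pos_row].  With
    the canonical logit link the observed information is exact
    (prior precision + J' W J with W = n pi (1 - pi)), so a damped
    Newton ascent converges in a few iterations; the objective is
    strictly concave.  Returns (mode, covariance).
    """
    nv = prior_mean.size
    v = prior_mean.copy()
    val = 0.0
    H = prior_prec
    for _ in range(100):
        c = v[:n_c]
        mu = Xc @ c
        if gamma_pos.size:
            mu = mu + v[gamma_pos]
        pi = expit(mu)
        w = n * pi * (1.0 - pi)
        resid = y - n * pi
        d = v - prior_mean
        pd_ = prior_prec @ d
        val = float(np.sum(y * mu - n * np.logaddexp(0.0, mu))) - 0.5 * float(
            d @ pd_
        )
        grad = -pd_
        grad[:n_c] += Xc.T @ resid
        np.add.at(grad, gamma_pos, resid)
        H = prior_prec.copy()
        XW = Xc * w[:, None]
        H[:n_c, :n_c] += Xc.T @ XW
        for i, g in enumerate(gamma_pos):
            H[:n_c, g] += XW[i]
            H[g, :n_c] += XW[i]
            H[g, g] += w[i]
        step = np.linalg.solve(H, grad)
        pred = 0.5 * float(grad @ step)
        if pred < 1e-10:
            break
        for _ in range(30):
            v_new = v + step
            c = v_new[:n_c]
            mu = Xc @ c
            if gamma_pos.size:
                mu = mu + v_new[gamma_pos]
            d = v_new - prior_mean
            val_new = float(
                np.sum(y * mu - n * np.logaddexp(0.0, mu))
            ) - 0.5 * float(d @ (prior_prec @ d))
            if val_new > val - 1e-12:
                break
            step *= 0.5
        v = v + step
    return v, np.linalg.inv(H)

def expected_kld_gain(
    prior: GaussianApprox,
    simulate: Callable[[np.ndarray, np.random.Generator], object],
    posterior_update: Callable[[object], GaussianApprox],
    J: int,
    seed: SeedLike = 0,
    max_failure_frac: float = 0.1,
    kld_prior: GaussianApprox | None = None,
) -> UtilityEstimate:
    """Generic Monte Carlo estimator of expected KLD information gain.

    For j = 1..J: draw parameters from ``prior`` (substream keyed by
    (seed, j)), simulate data with ``simulate``, compute the updated
    Gaussian with ``posterior_update``, and score KL(posterior ||
    prior).  Returns the average with its Monte Carlo standard error.
    ``kld_prior`` (default: ``prior``) is the reference Gaussian of the
    divergence — supply a marginal of the drawing prior to score
    information about a parameter subset.  Draws whose posterior update
    fails are skipped and counted; more than ``max_failure_frac``
    failures is an error.
    """
    if J < 1:
        raise DesignError("J must be >= 1")
    reference = prior if kld_prior is None else kld_prior
    key = _seed_key(seed)
    values = []
    failures: list[tuple[int, str]] = []
    for j in range(J):
        rng = np.random.default_rng(key + (j,))
        draw = prior.rvs(rng)
        data = simulate(draw, rng)
        try:
            post = posterior_update(data)
            values.append(kld_gaussian(post, reference))
        except (InferenceError, np.linalg.LinAlgError) as exc:
            failures.append((j, str(exc)))
    if len(failures) > max_failure_frac * J:
        raise InferenceError(
            f"posterior update failed for {len(failures)}/{J} draws: "
            f"{failures[:5]}"
        )
    vals = np.asarray(values)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    if mean < -1e-6:
        raise InferenceError(f"mean KLD is significantly negative: {mean}")
    return UtilityEstimate(mean, se, J, key, len(failures), vals)


def expected_utility(
    design: Design,
    scenario: Scenario,
    prior: GaussianApprox,
    dataset: HistoricalDataset | DesignMatrices,
    J: int = 100,
    seed: SeedLike = 0,
    config: ModelConfig | None = None,
    n_trials: int | None = None,
    fd_step: float = 1e-5,
) -> UtilityEstimate:
    """Expected KLD information gain of ``design`` under ``scenario``.

    Implements the Monte Carlo scheme: draw (theta_j, xi_j) from the
    design prior, simulate the next-survey counts through the
    Taylor-extrapolated mean response, update the prior with a Laplace
    approximation given the simulated counts, and average
    KL(posterior || prior) over draws.  The utility always scores
    information about theta (fixed effects, spline coefficients, log
    standard deviations); the latent reef/site effects are
    marginalized out of the compared Gaussians.

    The design prior may take two forms:

    * a joint Gaussian over (theta, xi) — the recommended form, from
      ``summarize_gaussian(samples, scope='all')``: (theta_j, xi_j)
      are drawn jointly from the fitted posterior, and the update is a
      conjugate-style Laplace with exact observed information (the
      latent effects stay informed by the historical data);
    * a Gaussian over theta only: xi_j is then drawn from the nested
      hierarchy given theta_j's log standard deviations, and the
      update re-estimates the latent effects from the new counts alone
      (a sensitivity mode that discards the historical information
      about the random effects).
    """
    matrices = (
        dataset
        if isinstance(dataset, DesignMatrices)
        else build_design_matrices(dataset, config or ModelConfig())
    )
    idx = matrices.index
    joint_prior = tuple(prior.names) == idx.names
    if not joint_prior and tuple(prior.names) != idx.theta_names:
        raise DesignError(
            "design prior names must match the model's theta layout or the "
            "joint (theta, xi) layout"
        )
    known = set(matrices.units)
    missing = [u for u in design.units if u not in known]
    if missing:
        raise DesignError(f"design units {missing} are not dataset units")
    n = int(n_trials if n_trials is not None else round(float(np.median(matrices.n))))
    centerpt = TaylorCenter.from_matrices(matrices)

    nre = idx.config.nested_random_effects
    pos_lr = idx.theta_names.index("log_sigma_reef") if nre else -1
    pos_ls = idx.theta_names.index("log_sigma_site") if nre else -1
    unit_reef = matrices.unit_reef_index
    n_lam, n_gam = len(idx.lambda_names), len(idx.gamma_names)

    # per-unit covariate rows at the next survey time (cached on the
    # matrices object: designs over the same scenario share them)
    cache = getattr(matrices, "_taylor_row_cache", None)
    if cache is None:
        cache = matrices._taylor_row_cache = {}
    cache_key = (scenario, centerpt)
    all_rows = cache.get(cache_key)
    if all_rows is None:
        all_rows = np.array(
            [
                _taylor_fixed_row(matrices, r, scenario, centerpt)
                for r, _ in matrices.units
            ]
        )
        cache[cache_key] = all_rows
    keep = [matrices.units.index((r, int(s))) for r, s in design.units]
    unit_index = np.array(keep, dtype=int)
    Xc = (
        all_rows[unit_index]
        if design.ns
        else np.empty((0, idx.n_beta + idx.K))
    )
    n_arr = np.full(design.ns, float(n))
    n_c = idx.n_beta + idx.K

    if joint_prior:
        kld_prior = prior.marginal(list(idx.theta_names))
        prior_prec = prior.precision()
        gamma_pos = (
            idx.n_theta + idx.sl_gamma.start + unit_index
            if nre
            else np.empty(0, dtype=int)
        )

        def simulate(v_j: np.ndarray, rng: np.random.Generator) -> tuple:
            mu_all = all_rows @ v_j[:n_c]
            if nre:
                mu_all = mu_all + v_j[idx.n_theta + idx.sl_gamma.start :]
            y_all = rng.binomial(int(n), success_prob(mu_all))
            return y_all[unit_index].astype(float), None

        def update(data: tuple) -> GaussianApprox:
            y_new, _ = data
            mode, cov = _joint_laplace_update(
                Xc, gamma_pos, y_new, n_arr, prior.mean, prior_prec, n_c
            )
            full = GaussianApprox(mode, cov, idx.names)
            return full.marginal(list(idx.theta_names))

        return expected_kld_gain(
            prior, simulate, update, J, seed, kld_prior=kld_prior
        )

    def simulate(theta_j: np.ndarray, rng: np.random.Generator) -> tuple:
        if nre:
            sig_r = float(np.exp(theta_j[pos_lr]))
            sig_s = float(np.exp(theta_j[pos_ls]))
            lam = sig_r * rng.standard_normal(n_lam)
            gam = lam[unit_reef] + sig_s * rng.standard_normal(n_gam)
            xi_j = np.concatenate([lam, gam])
        else:
            xi_j = np.empty(0)
        c = theta_j[:n_c]
        mu_all = all_rows @ c + (xi_j[idx.sl_gamma] if nre else 0.0)
        y_all = rng.binomial(int(n), success_prob(mu_all))
        return y_all[unit_index].astype(float), xi_j

    def update(data: tuple) -> GaussianApprox:
        y_new, _ = data
        rows = BinomialRows(Xc, unit_index, y_new, n_arr)
        post = _Posterior(rows, idx, prior)
        if nre:
            post.attach_reef_map(unit_reef)
        return _marginal_laplace(post, prior.mean.copy(), fd_step=fd_step)

    return expected_kld_gain(prior, simulate, update, J, seed)
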