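"""Semiparametric binomial model for coral-cover trends.

The site-level count of coral-positive photo points is modelled as

    y_srt ~ Binomial(n, pi_srt),   logit(pi_srt) = mu_srt,

with linear predictor

    mu_srt = gamma_sr + beta_t' z_t + beta_d' d_r + f(x_srt)
             + beta_l BLE98_srt + beta_s Time98_srt,

where ``gamma_sr`` are site random effects nested in reef effects
``lambda_r`` (gamma_sr ~ N(lambda_r, sigma_s^2), lambda_r ~ N(0,
sigma_r^2)), ``z_t`` are whole-of-reef time-varying disturbance
covariates, ``d_r`` per-reef exposure dummies, BLE98/Time98 the
interrupted time-series level and slope terms for the 1998 mass
bleaching event, and ``f`` a low-rank thin-plate spline smooth of
centered survey time:

    f(x) = beta_0 + beta_1 x + sum_k delta_k |x - eta_k|^3,

with knots ``eta_k`` at the k/(K+1) sample quantiles of centered survey
time and random coefficients delta_k ~ N(0, sigma_delta^2).

Because the raw cubic radial basis ``|x - eta_k|^3`` is badly
conditioned, the default basis post-multiplies it by the inverse matrix
square root of Omega, Omega_kk' = |eta_k - eta_k'|^3 (the standard
low-rank thin-plate construction); this is an invertible linear
reparameterization, so fitted mean responses are identical between the
two modes for correspondingly transformed delta.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.special import expit, gammaln

from .survey_data import (
    REEFS,
    CenteringInfo,
    HistoricalDataset,
    build_its,
    center,
)

__all__ = [
    "ModelConfig",
    "ModelError",
    "RankDeficiencyWarning",
    "ParameterIndex",
    "ParameterVector",
    "DesignMatrices",
    "place_knots",
    "spline_value",
    "build_design_matrices",
    "linear_predictor",
    "success_prob",
    "log_likelihood",
]

#: Frozen fixed-effect column order (version 1); ParameterVector indices
#: are stable across runs for a given configuration.
FIXED_COLUMN_ORDER = (
    "intercept",
    "time",
    "bleaching",
    "sqrt_cyclone",
    "interaction",
    "cyclone_loc",
    "severe_cyclone_loc",
    "bleaching_loc",
    "ble98",
    "time98",
)


class ModelError(ValueError):
    """Raised for invalid model configuration or inputs."""


class RankDeficiencyWarning(UserWarning):
    """Fixed-effect matrix is rank deficient (e.g. constant dummy columns)."""


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Structural configuration of the coral-cover model.

    ``covariates`` and ``dummies`` select the time-varying and per-reef
    columns entering the linear predictor; ``its`` toggles the
    interrupted time-series terms; ``smooth`` the spline component;
    ``nested_random_effects`` the site-in-reef random intercepts.
    The defaults give the full nine-coefficient candidate model
    (time, bleaching, sqrt-cyclone, their interaction, three location
    dummies, and the two interruption terms) with a K = 3 knot smooth.
    """

    n_knots: int = 3
    basis_mode: str = "omega_standardized"
    covariates: tuple[str, ...] = ("bleaching", "sqrt_cyclone", "interaction")
    dummies: tuple[str, ...] = ("cyclone_loc", "severe_cyclone_loc", "bleaching_loc")
    its: bool = True
    smooth: bool = True
    nested_random_effects: bool = True

    def __post_init__(self) -> None:
        if self.basis_mode not in ("raw", "omega_standardized"):
            raise ModelError(f"unknown basis_mode {self.basis_mode!r}")
        if self.smooth and self.n_knots < 1:
            raise ModelError("smooth model requires n_knots >= 1")
        known = {"bleaching", "sqrt_cyclone", "interaction"}
        bad = set(self.covariates) - known
        if bad:
            raise ModelError(f"unknown time-varying covariates {sorted(bad)}")
        known_d = {"cyclone_loc", "severe_cyclone_loc", "bleaching_loc"}
        bad = set(self.dummies) - known_d
        if bad:
            raise ModelError(f"unknown dummy columns {sorted(bad)}")

    @property
    def beta_names(self) -> tuple[str, ...]:
        names = ["intercept", "time"]
        names += [c for c in FIXED_COLUMN_ORDER if c in self.covariates]
        names += [d for d in FIXED_COLUMN_ORDER if d in self.dummies]
        if self.its:
            names += ["ble98", "time98"]
        return tuple(names)


class ParameterIndex:
    """Name <-> position map for the packed parameter vector.

    Layout (theta): fixed effects beta, spline coefficients delta_1..K,
    then log standard deviations (log_sigma_delta, log_sigma_reef,
    log_sigma_site as applicable).  Random effects (xi): one lambda per
    reef, then one gamma per (reef, site) unit.
    """

    def __init__(
        self,
        config: ModelConfig,
        reefs: tuple[str, ...],
        units: tuple[tuple[str, int], ...],
    ) -> None:
        self.config = config
        self.reefs = tuple(reefs)
        self.units = tuple(units)
        self.beta_names = config.beta_names
        self.n_beta = len(self.beta_names)
        self.K = config.n_knots if config.smooth else 0

        theta_names = list(self.beta_names)
        theta_names += [f"delta_{k + 1}" for k in range(self.K)]
        self.sl_beta = slice(0, self.n_beta)
        self.sl_delta = slice(self.n_beta, self.n_beta + self.K)
        logsd_names = []
        if config.smooth:
            logsd_names.append("log_sigma_delta")
        if config.nested_random_effects:
            logsd_names += ["log_sigma_reef", "log_sigma_site"]
        self.sl_logsd = slice(len(theta_names), len(theta_names) + len(logsd_names))
        theta_names += logsd_names
        self.theta_names = tuple(theta_names)
        self.n_theta = len(theta_names)

        if config.nested_random_effects:
            self.lambda_names = tuple(f"lambda_{r}" for r in self.reefs)
            self.gamma_names = tuple(f"gamma_{r}_{s}" for r, s in self.units)
        else:
            self.lambda_names = ()
            self.gamma_names = ()
        self.xi_names = self.lambda_names + self.gamma_names
        self.n_xi = len(self.xi_names)
        self.sl_lambda = slice(0, len(self.lambda_names))
        self.sl_gamma = slice(len(self.lambda_names), self.n_xi)
        self.names = self.theta_names + self.xi_names
        self.position = {name: i for i, name in enumerate(self.names)}

    def pos(self, name: str) -> int:
        try:
            return self.position[name]
        except KeyError:
            raise ModelError(f"unknown parameter name {name!r}") from None

    @property
    def n_total(self) -> int:
        return self.n_theta + self.n_xi


@dataclasses.dataclass
class ParameterVector:
    """Packed parameter values with their index map.

    ``theta`` holds fixed effects, spline coefficients, and log standard
    deviations; ``xi`` the reef and site random effects.  ``pack`` /
    ``split`` are exact inverses.
    """

    index: ParameterIndex
    theta: np.ndarray
    xi: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.theta.shape != (self.index.n_theta,):
            raise ModelError(
                f"theta has shape {self.theta.shape}, expected ({self.index.n_theta},)"
            )
        if self.xi.shape != (self.index.n_xi,):
            raise ModelError(
                f"xi has shape {self.xi.shape}, expected ({self.index.n_xi},)"
            )

    @classmethod
    def zeros(cls, index: ParameterIndex) -> "ParameterVector":
        return cls(index, np.zeros(index.n_theta), np.zeros(index.n_xi))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.theta, self.xi])

    @classmethod
    def split(cls, index: ParameterIndex, packed: np.ndarray) -> "ParameterVector":
        packed = np.asarray(packed, dtype=float)
        if packed.shape != (index.n_total,):
            raise ModelError(
                f"packed vector has shape {packed.shape}, expected ({index.n_total},)"
            )
        return cls(index, packed[: index.n_theta].copy(), packed[index.n_theta :].copy())

    def __getitem__(self, name: str) -> float:
        i = self.index.pos(name)
        if i < self.index.n_theta:
            return float(self.theta[i])
        return float(self.xi[i - self.index.n_theta])

    def __setitem__(self, name: str, value: float) -> None:
        i = self.index.pos(name)
        if i < self.index.n_theta:
            self.theta[i] = value
        else:
            self.xi[i - self.index.n_theta] = value

    @property
    def beta(self) -> np.ndarray:
        return self.theta[self.index.sl_beta]

    @property
    def delta(self) -> np.ndarray:
        return self.theta[self.index.sl_delta]

    @property
    def log_sds(self) -> np.ndarray:
        return self.theta[self.index.sl_logsd]


# ---------------------------------------------------------------------
# Spline primitives
# ---------------------------------------------------------------------

def place_knots(times: np.ndarray, K: int) -> np.ndarray:
    """Knots at the k/(K+1) sample quantiles of ``times``, k = 1..K.

    Quantiles use the order-statistics convention with linear
    interpolation between adjacent order statistics (numpy's default,
    ``method='linear'``): for sorted x_(1) <= ... <= x_(m) the quantile
    at probability p is x_(j) + g (x_(j+1) - x_(j)) with
    j = floor(1 + (m - 1) p) and g the fractional part.
    """
    times = np.asarray(times, dtype=float)
    distinct = np.unique(times)
    if K < 1:
        raise ModelError("K must be >= 1")
    if distinct.size < K + 1:
        raise ModelError(
            f"need at least K + 1 = {K + 1} distinct times for K = {K} knots, "
            f"got {distinct.size}"
        )
    probs = np.arange(1, K + 1) / (K + 1)
    knots = np.quantile(distinct, probs)
    if np.any(np.diff(knots) <= 0):
        raise ModelError(f"knots are not strictly increasing: {knots}")
    return knots


def spline_value(
    x: float | np.ndarray,
    beta0: float,
    beta1: float,
    delta: np.ndarray,
    knots: np.ndarray,
) -> float | np.ndarray:
    """Raw-basis smooth f(x) = beta0 + beta1 x + sum_k delta_k |x - eta_k|^3."""
    x = np.asarray(x, dtype=float)
    delta = np.asarray(delta, dtype=float)
    knots = np.asarray(knots, dtype=float)
    basis = np.abs(x[..., None] - knots) ** 3
    out = beta0 + beta1 * x + basis @ delta
    return out if out.ndim else float(out)


def _omega_sqrt(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matrix square root of Omega_kk' = |eta_k - eta_k'|^3 and its inverse.

    Omega is symmetric but indefinite for cubic radial kernels, so the
    square root is taken through the SVD (U sqrt(D) V'), the standard
    conditioning device for this basis; any invertible linear map of the
    basis leaves the fitted mean response unchanged.
    """
    omega = np.abs(knots[:, None] - knots[None, :]) ** 3
    u, d, vt = np.linalg.svd(omega)
    if np.any(d <= 0):
        raise ModelError("Omega is singular; knots must be distinct")
    s = u @ np.diag(np.sqrt(d)) @ vt
    s_inv = vt.T @ np.diag(1.0 / np.sqrt(d)) @ u.T
    return s, s_inv


def success_prob(mu: float | np.ndarray) -> float | np.ndarray:
    """Logistic success probability pi = 1 / (1 + exp(-mu)), overflow safe."""
    out = expit(np.asarray(mu, dtype=float))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------

class DesignMatrices:
    """Model matrices and incidence maps for one dataset + configuration.

    Attributes
    ----------
    X : (records, p) fixed-effect matrix in the frozen column order.
    B : (records, K) spline basis in the configured mode.
    site_index : record -> gamma position.
    unit_reef_index : gamma position -> lambda position.
    """

    def __init__(self, dataset: HistoricalDataset, config: ModelConfig) -> None:
        self.dataset = dataset
        self.config = config
        self.centering: CenteringInfo = dataset.centering
        self.event_time = dataset.event_time

        surveys = dataset.surveys.copy()
        reefs = tuple(r for r in REEFS if r in set(surveys["reef"]))
        extra = tuple(sorted(set(surveys["reef"]) - set(REEFS)))
        self.reefs = reefs + extra
        reef_rank = {r: i for i, r in enumerate(self.reefs)}
        surveys["_reef_rank"] = surveys["reef"].map(reef_rank)
        surveys = surveys.sort_values(["_reef_rank", "site", "time"]).drop(
            columns="_reef_rank"
        )
        self.records = surveys.reset_index(drop=True)
        self.units = tuple(
            (r, int(s))
            for r in self.reefs
            for s in sorted(surveys.loc[surveys["reef"] == r, "site"].unique())
        )
        unit_pos = {u: i for i, u in enumerate(self.units)}
        self.site_index = np.array(
            [unit_pos[(r, int(s))] for r, s in zip(self.records["reef"], self.records["site"])]
        )
        self.unit_reef_index = np.array([reef_rank[r] for r, _ in self.units])

        self.index = ParameterIndex(config, self.reefs, self.units)

        self.y = self.records["y"].to_numpy(dtype=float)
        self.n = self.records["n"].to_numpy(dtype=float)
        self.log_binom_const = float(
            np.sum(
                gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)
            )
        )

        cov = dataset.covariate_model_table().set_index("time")
        rec_t = self.records["time"].to_numpy(dtype=float)
        self.x_centered = np.asarray(center(rec_t, self.centering, "time"))

        if config.smooth:
            distinct_x = np.unique(
                np.asarray(center(dataset.times, self.centering, "time"))
            )
            self.knots = place_knots(distinct_x, config.n_knots)
            if config.basis_mode == "omega_standardized":
                self.S, self.S_inv = _omega_sqrt(self.knots)
            else:
                self.S = self.S_inv = np.eye(config.n_knots)
        else:
            self.knots = np.empty(0)
            self.S = self.S_inv = np.empty((0, 0))

        cols = {"intercept": np.ones(len(self.records)), "time": self.x_centered}
        for name in config.covariates:
            raw = cov.loc[rec_t, name].to_numpy(dtype=float)
            cols[name] = np.asarray(center(raw, self.centering, name))
        if dataset.dummies_time_varying:
            dummies = dataset.dummies.set_index(["reef", "time"])
            keys = list(zip(self.records["reef"], rec_t))
            for name in config.dummies:
                cols[name] = dummies.loc[keys, name].to_numpy(dtype=float)
        else:
            dummies = dataset.dummies.set_index("reef")
            for name in config.dummies:
                cols[name] = dummies.loc[self.records["reef"], name].to_numpy(
                    dtype=float
                )
        if config.its:
            its = np.array(
                [
                    (v.ble98, v.time98)
                    for v in (build_its(t, self.event_time) for t in rec_t)
                ],
                dtype=float,
            )
            cols["ble98"] = its[:, 0]
            cols["time98"] = its[:, 1]
        self.fixed_columns = self.index.beta_names
        self.X = np.column_stack([cols[c] for c in self.fixed_columns])
        self.B = self.spline_basis(self.x_centered)

        rank = np.linalg.matrix_rank(self.X) if len(self.records) else 0
        if len(self.records) and rank < self.X.shape[1]:
            suspect = [
                c
                for c, colv in zip(self.fixed_columns, self.X.T)
                if c != "intercept" and np.ptp(colv) == 0
            ]
            warnings.warn(
                f"fixed-effect matrix is rank deficient (rank {rank} < "
                f"{self.X.shape[1]}); constant columns: {suspect}",
                RankDeficiencyWarning,
                stacklevel=2,
            )

    # -- basis --------------------------------------------------------

    def spline_basis(self, x: np.ndarray) -> np.ndarray:
        """Spline basis rows at centered times ``x`` in the configured mode."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not self.config.smooth:
            return np.empty((x.size, 0))
        raw = np.abs(x[:, None] - self.knots[None, :]) ** 3
        return raw @ self.S_inv

    def spline_basis_deriv(self, x: np.ndarray) -> np.ndarray:
        """d/dx of the basis rows (for Taylor extrapolation of the smooth)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not self.config.smooth:
            return np.empty((x.size, 0))
        diff = x[:, None] - self.knots[None, :]
        raw = 3.0 * np.abs(diff) * diff
        return raw @ self.S_inv

    # -- covariate rows at arbitrary times ----------------------------

    def fixed_row(
        self,
        reef: str,
        time: float,
        bleaching: float,
        cyclone_hours: float,
        dummy_overrides: dict[str, dict[str, float]] | None = None,
    ) -> np.ndarray:
        """Fixed-effect covariate row for ``reef`` at ``time``.

        ``bleaching`` and ``cyclone_hours`` are on the raw data scale;
        the square-root transform and frozen historical centering are
        applied here.  ``dummy_overrides`` maps reef -> {dummy: value}
        for scenario-specific exposure settings; a dummy without an
        override defaults to the reef's static attribute, or to 0 (no
        exposure in the upcoming interval) when the historical dummies
        are time varying.
        """
        sqrt_cyc = float(np.sqrt(cyclone_hours))
        raw = {
            "bleaching": float(bleaching),
            "sqrt_cyclone": sqrt_cyc,
            "interaction": float(bleaching) * sqrt_cyc,
        }
        if self.dataset.dummies_time_varying:
            defaults = {name: 0.0 for name in self.config.dummies}
        else:
            static = self.dataset.dummies.set_index("reef")
            defaults = {
                name: float(static.loc[reef, name]) for name in self.config.dummies
            }
        over = (dummy_overrides or {}).get(reef, {})
        vals = {"intercept": 1.0, "time": float(center([time], self.centering, "time")[0])}
        for name in self.config.covariates:
            vals[name] = float(center([raw[name]], self.centering, name)[0])
        for name in self.config.dummies:
            vals[name] = float(over.get(name, defaults[name]))
        if self.config.its:
            its = build_its(time, self.event_time)
            vals["ble98"] = float(its.ble98)
            vals["time98"] = its.time98
        return np.array([vals[c] for c in self.fixed_columns])

    # -- predictor and likelihood --------------------------------------

    def mu(self, theta: np.ndarray, xi: np.ndarray) -> np.ndarray:
        """Linear predictor for every record, vectorized."""
        idx = self.index
        out = self.X @ theta[idx.sl_beta]
        if idx.K:
            out = out + self.B @ theta[idx.sl_delta]
        if self.config.nested_random_effects:
            gamma = xi[idx.sl_gamma]
            out = out + gamma[self.site_index]
        return out

    def log_likelihood(self, theta: np.ndarray, xi: np.ndarray) -> float:
        """Binomial log likelihood, including the combinatorial constant."""
        mu = self.mu(theta, xi)
        return float(
            self.log_binom_const
            + np.sum(self.y * mu - self.n * np.logaddexp(0.0, mu))
        )


def build_design_matrices(dataset: HistoricalDataset, config: ModelConfig | None = None) -> DesignMatrices:
    """Build fixed-effect and spline matrices plus incidence maps."""
    return DesignMatrices(dataset, config or ModelConfig())


def linear_predictor(
    record: int | tuple[str, int, float],
    params: ParameterVector,
    matrices: DesignMatrices,
) -> float:
    """Linear predictor mu for one record (by row index or (reef, site, time))."""
    if isinstance(record, tuple):
        reef, site, time = record
        mask = (
            (matrices.records["reef"] == reef)
            & (matrices.records["site"] == int(site))
            & (matrices.records["time"] == time)
        )
        pos = np.flatnonzero(mask.to_numpy())
        if pos.size != 1:
            raise ModelError(f"record {record!r} not found in dataset")
        record = int(pos[0])
    return float(matrices.mu(params.theta, params.xi)[record])


def log_likelihood(
    dataset: HistoricalDataset | DesignMatrices,
    params: ParameterVector,
    config: ModelConfig | None = None,
) -> float:
    """Binomial log likelihood of ``dataset`` under ``params``."""
    matrices = (
        dataset
        if isinstance(dataset, DesignMatrices)
        else build_design_matrices(dataset, config or params.index.config)
    )
    return matrices.log_likelihood(params.theta, params.xi)
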