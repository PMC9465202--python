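"""Posterior inference for the coral-cover model.

Stages implemented here:

* vague-but-proper priors for the regression coefficients and the log
  standard deviations (:class:`PriorSpec`);
* posterior sampling by an adaptive random-walk Metropolis scheme within
  blocked Gibbs (:func:`fit_mcmc`), with conjugate Gibbs updates for the
  reef effects and vectorized single-site updates for the site effects;
* deviance information criterion for candidate-model comparison
  (:func:`compute_dic`);
* Laplace (mode + inverse negative Hessian) Gaussian approximation of
  the posterior (:func:`laplace_approx`), the workhorse of the design
  stage where thousands of posterior updates are required;
* moment-matched Gaussian summarization of MCMC draws
  (:func:`summarize_gaussian`) — the fitted posterior in this form
  becomes the prior for design selection.

The returned Gaussian covers the parameters theta (fixed effects,
spline coefficients, log standard deviations) by default; the latent
reef/site effects xi are integrated out by a nested Laplace (an inner
Newton finds their conditional mode at each theta, and the outer
objective carries the corresponding log-determinant correction), which
is exact in the no-data limit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model import (
    DesignMatrices,
    HistoricalDataset,
    ModelConfig,
    ParameterIndex,
    build_design_matrices,
)

__all__ = [
    "PriorSpec",
    "PosteriorSamples",
    "GaussianApprox",
    "InferenceError",
    "ConvergenceWarning",
    "LaplaceWarning",
    "fit_mcmc",
    "compute_dic",
    "laplace_approx",
    "laplace_from_logpost",
    "summarize_gaussian",
]


class InferenceError(RuntimeError):
    """Raised when an inference stage fails."""


class ConvergenceWarning(UserWarning):
    """Split-chain R-hat above threshold on at least one parameter."""


class LaplaceWarning(UserWarning):
    """Ill-conditioned or repaired curvature in a Laplace approximation."""


# ---------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Independent proper priors for the model parameters.

    Regression and spline-block coefficients get Normal(mean, sd)
    priors; the three log standard deviations get Normal priors on the
    log scale (a half-Normal-type shrinkage on each sd).  The spline
    coefficients delta are hierarchical, delta_k ~ N(0, sigma_delta^2)
    with sigma_delta = exp(log_sigma_delta), so they are excluded from
    the fixed Gaussian block.  Defaults are vague on the logit scale;
    every value can be overridden per parameter name.
    """

    coef_mean: float = 0.0
    coef_sd: float = 10.0
    logsd_mean: float = 0.0
    logsd_sd: float = 1.0
    overrides: tuple[tuple[str, tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        if self.coef_sd <= 0 or self.logsd_sd <= 0:
            raise InferenceError("prior standard deviations must be positive")
        for name, (_, sd) in self.overrides:
            if sd <= 0:
                raise InferenceError(f"prior sd for {name!r} must be positive")

    def moments(self, index: ParameterIndex) -> tuple[np.ndarray, np.ndarray]:
        """Prior (mean, sd) arrays for the non-hierarchical theta entries.

        Entries in the delta block get NaN (their prior is hierarchical).
        """
        over = dict(self.overrides)
        mean = np.empty(index.n_theta)
        sd = np.empty(index.n_theta)
        for i, name in enumerate(index.theta_names):
            if name.startswith("delta_"):
                mean[i] = sd[i] = np.nan
            elif name.startswith("log_sigma"):
                mean[i], sd[i] = over.get(name, (self.logsd_mean, self.logsd_sd))
            else:
                mean[i], sd[i] = over.get(name, (self.coef_mean, self.coef_sd))
        return mean, sd


# ---------------------------------------------------------------------
# Gaussian summaries
# ---------------------------------------------------------------------

class GaussianApprox:
    """Multivariate Gaussian summary (mean, covariance, parameter names).

    Used both as the moment-matched design prior and as the Laplace
    posterior.  The covariance is symmetrized on construction; negative
    eigenvalues below -1e-10 are an error, anything smaller is clipped
    to give a positive semidefinite matrix.
    """

    def __init__(self, mean: np.ndarray, cov: np.ndarray, names: Sequence[str]) -> None:
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if mean.ndim != 1 or cov.shape != (mean.size, mean.size):
            raise InferenceError(
                f"inconsistent Gaussian dimensions: mean {mean.shape}, cov {cov.shape}"
            )
        if len(names) != mean.size:
            raise InferenceError("name list does not match dimension")
        cov = 0.5 * (cov + cov.T)
        w, v = np.linalg.eigh(cov)
        if w.min(initial=0.0) < -1e-10 * max(1.0, float(np.abs(w).max(initial=1.0))):
            raise InferenceError(
                f"covariance has a significantly negative eigenvalue: {w.min()}"
            )
        if w.min(initial=0.0) < 0.0:
            warnings.warn(
                "covariance clipped to positive semidefinite", LaplaceWarning,
                stacklevel=2,
            )
            cov = (v * np.clip(w, 0.0, None)) @ v.T
        self.mean = mean
        self.cov = cov
        self.names = tuple(names)

    @property
    def dim(self) -> int:
        return self.mean.size

    def sds(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def marginal(self, names: Sequence[str]) -> "GaussianApprox":
        idx = [self.names.index(n) for n in names]
        return GaussianApprox(
            self.mean[idx], self.cov[np.ix_(idx, idx)], [self.names[i] for i in idx]
        )

    def rvs(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draws via eigendecomposition (valid for singular covariances)."""
        root = getattr(self, "_root", None)
        if root is None:
            w, v = np.linalg.eigh(self.cov)
            root = self._root = v * np.sqrt(np.clip(w, 0.0, None))
        m = 1 if size is None else size
        z = rng.standard_normal((m, self.dim))
        out = self.mean + z @ root.T
        return out[0] if size is None else out

    def precision(self) -> np.ndarray:
        """Inverse covariance (errors if singular; cached)."""
        prec = getattr(self, "_prec", None)
        if prec is None:
            try:
                prec = self._prec = np.linalg.inv(self.cov)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
                raise InferenceError("prior covariance is singular") from exc
        return prec

    # -- serialization ------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "names": list(self.names),
                "mean": self.mean.tolist(),
                "cov": self.cov.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "GaussianApprox":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(np.array(data["mean"]), np.array(data["cov"]), data["names"])


# ---------------------------------------------------------------------
# Log posterior and gradient (shared by MCMC and Laplace)
# ---------------------------------------------------------------------

@dataclasses.dataclass
class BinomialRows:
    """Binomial observations expressed as rows of a logistic regression.

    ``Xc`` multiplies the coefficient vector c = (beta, delta) on its
    effective model-scale columns; ``unit_index`` maps each row to a
    site-effect position (or -1 for none).
    """

    Xc: np.ndarray
    unit_index: np.ndarray
    y: np.ndarray
    n: np.ndarray

    @classmethod
    def from_matrices(cls, matrices: DesignMatrices) -> "BinomialRows":
        Xc = np.hstack([matrices.X, matrices.B])
        return cls(Xc, matrices.site_index, matrices.y, matrices.n)


def _logsd_positions(index: ParameterIndex) -> dict[str, int | None]:
    names = index.theta_names
    return {
        key: (names.index(key) if key in names else None)
        for key in ("log_sigma_delta", "log_sigma_reef", "log_sigma_site")
    }


class _Posterior:
    """Joint log posterior over u = (theta, xi) with analytic gradient.

    Two prior modes:

    * ``fit`` — the MCMC prior: independent Normals on beta and the log
      sds (:class:`PriorSpec`), hierarchical delta | sigma_delta.
    * ``design`` — a joint Gaussian prior over all of theta (the design
      prior); delta's hierarchy is already folded into that Gaussian.

    In both modes the latent effects keep their nested hierarchy
    lambda_r ~ N(0, sigma_r^2), gamma_sr ~ N(lambda_r, sigma_s^2).
    """

    def __init__(
        self,
        rows: BinomialRows,
        index: ParameterIndex,
        prior: PriorSpec | GaussianApprox,
    ) -> None:
        self.rows = rows
        self.index = index
        self.pos = _logsd_positions(index)
        self.nre = index.config.nested_random_effects
        self.n_lambda = len(index.lambda_names)
        self.n_gamma = len(index.gamma_names)
        self.unit_reef: np.ndarray | None = None
        self.design_mode = isinstance(prior, GaussianApprox)
        if self.design_mode:
            if tuple(prior.names) != index.theta_names:
                raise InferenceError(
                    "design prior names do not match the model's theta layout"
                )
            self.prior_mean = prior.mean
            self.prior_prec = prior.precision()
        else:
            mean, sd = prior.moments(index)
            self.g_mean, self.g_sd = mean, sd
            self.g_mask = ~np.isnan(sd)
        n_c = index.n_beta + index.K
        self.sl_c = slice(0, n_c)
        self._use = rows.unit_index >= 0
        self._u_of_row = np.clip(rows.unit_index, 0, None)

    def attach_reef_map(self, unit_reef_index: np.ndarray) -> None:
        self.unit_reef = np.asarray(unit_reef_index)

    # -- pieces -------------------------------------------------------

    def _split(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return u[: self.index.n_theta], u[self.index.n_theta :]

    def value_grad(self, u: np.ndarray) -> tuple[float, np.ndarray]:
        idx = self.index
        theta, xi = self._split(u)
        c = theta[: idx.n_beta + idx.K]
        grad = np.zeros_like(u)

        mu = self.rows.Xc @ c
        if self.nre and self.n_gamma:
            gamma = xi[idx.sl_gamma]
            mu = mu + np.where(self._use, gamma[self._u_of_row], 0.0)
        pi = 1.0 / (1.0 + np.exp(-mu))
        val = float(np.sum(self.rows.y * mu - self.rows.n * np.logaddexp(0.0, mu)))
        resid = self.rows.y - self.rows.n * pi
        grad[self.sl_c] += self.rows.Xc.T @ resid
        if self.nre and self.n_gamma:
            g_gamma = np.bincount(
                self._u_of_row,
                weights=np.where(self._use, resid, 0.0),
                minlength=self.n_gamma,
            )
            grad[idx.n_theta + idx.sl_gamma.start : idx.n_theta + idx.sl_gamma.stop] += g_gamma

        # prior over theta
        if self.design_mode:
            d = theta - self.prior_mean
            pd_ = self.prior_prec @ d
            val += -0.5 * float(d @ pd_)
            grad[: idx.n_theta] += -pd_
        else:
            d = np.where(self.g_mask, theta - self.g_mean, 0.0)
            sd = np.where(self.g_mask, self.g_sd, 1.0)
            val += -0.5 * float(np.sum((d / sd) ** 2))
            grad[: idx.n_theta] += -d / sd**2
            if idx.K:
                p_ld = self.pos["log_sigma_delta"]
                ld = theta[p_ld]
                delta = theta[idx.sl_delta]
                v2 = np.exp(-2.0 * ld)
                val += -idx.K * ld - 0.5 * v2 * float(delta @ delta)
                grad[idx.sl_delta] += -delta * v2
                grad[p_ld] += -idx.K + v2 * float(delta @ delta)

        # hierarchy over xi
        if self.nre and self.n_lambda:
            if self.unit_reef is None:
                raise InferenceError("unit -> reef map not attached")
            p_lr, p_ls = self.pos["log_sigma_reef"], self.pos["log_sigma_site"]
            lr, ls = theta[p_lr], theta[p_ls]
            vr, vs = np.exp(-2.0 * lr), np.exp(-2.0 * ls)
            lam = xi[idx.sl_lambda]
            gam = xi[idx.sl_gamma]
            resid_g = gam - lam[self.unit_reef]
            val += -self.n_lambda * lr - 0.5 * vr * float(lam @ lam)
            val += -self.n_gamma * ls - 0.5 * vs * float(resid_g @ resid_g)
            g_lam = -lam * vr + vs * np.bincount(
                self.unit_reef, weights=resid_g, minlength=self.n_lambda
            )
            g_gam = -resid_g * vs
            o = idx.n_theta
            grad[o + idx.sl_lambda.start : o + idx.sl_lambda.stop] += g_lam
            grad[o + idx.sl_gamma.start : o + idx.sl_gamma.stop] += g_gam
            grad[p_lr] += -self.n_lambda + vr * float(lam @ lam)
            grad[p_ls] += -self.n_gamma + vs * float(resid_g @ resid_g)

        return val, grad

    def value(self, u: np.ndarray) -> float:
        return self.value_grad(u)[0]

    # -- latent-effect (xi) curvature for the nested Laplace ----------

    def xi_neg_hessian(self, theta: np.ndarray, xi: np.ndarray) -> np.ndarray:
        """Negative Hessian of the log posterior in xi at fixed theta.

        Block structure: lambda diag(1/sr^2 + n_r/ss^2), gamma
        diag(1/ss^2 + sum_rows n pi (1-pi)), lambda-gamma cross
        -1/ss^2 on the nesting incidence.
        """
        idx = self.index
        p_lr, p_ls = self.pos["log_sigma_reef"], self.pos["log_sigma_site"]
        vr, vs = np.exp(-2.0 * theta[p_lr]), np.exp(-2.0 * theta[p_ls])
        c = theta[: idx.n_beta + idx.K]
        mu = self.rows.Xc @ c
        gamma = xi[idx.sl_gamma]
        mu = mu + np.where(self._use, gamma[self._u_of_row], 0.0)
        pi = 1.0 / (1.0 + np.exp(-mu))
        w = self.rows.n * pi * (1.0 - pi)
        w_unit = np.bincount(
            self._u_of_row,
            weights=np.where(self._use, w, 0.0),
            minlength=self.n_gamma,
        )
        n_per = np.bincount(self.unit_reef, minlength=self.n_lambda)
        m = self.n_lambda + self.n_gamma
        nH = np.zeros((m, m))
        lam_ix = np.arange(self.n_lambda)
        gam_ix = self.n_lambda + np.arange(self.n_gamma)
        nH[lam_ix, lam_ix] = vr + n_per * vs
        nH[gam_ix, gam_ix] = vs + w_unit
        nH[self.unit_reef, gam_ix] = -vs
        nH[gam_ix, self.unit_reef] = -vs
        return nH


def _inner_xi_mode(
    post: _Posterior, theta: np.ndarray, xi0: np.ndarray, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton ascent over xi at fixed theta (the objective is concave).

    Returns (xi_hat, negative Hessian at xi_hat, log posterior value and
    full gradient at (theta, xi_hat)).
    """
    idx = post.index
    xi = xi0.copy()
    u = np.concatenate([theta, xi])
    val, grad = post.value_grad(u)
    for _ in range(60):
        g_xi = grad[idx.n_theta :]
        if np.max(np.abs(g_xi), initial=0.0) < tol:
            break
        nH = post.xi_neg_hessian(theta, xi)
        step = np.linalg.solve(nH, g_xi)
        # backtracking in case a full Newton step overshoots early on
        improved = False
        for _ in range(30):
            xi_new = xi + step
            u_new = np.concatenate([theta, xi_new])
            val_new, grad_new = post.value_grad(u_new)
            if val_new >= val - 1e-12:
                improved = abs(val_new - val) > 1e-12
                xi, val, grad = xi_new, val_new, grad_new
                break
            step *= 0.5
        if not improved:
            break
    return xi, post.xi_neg_hessian(theta, xi), val, grad


_LOG_2PI = float(np.log(2.0 * np.pi))


class _MarginalPosterior:
    """Laplace-marginal log posterior l(theta) with analytic gradient.

    l(theta) = log p(theta, xi_hat(theta)) + (n_xi/2) ln 2pi
               - 0.5 ln det(-H_xi(theta, xi_hat)),

    the latent reef/site effects integrated out by an inner Laplace at
    their conditional mode.  The inner integral is exact when there are
    no observations (the hierarchy is Gaussian), so with no data
    l(theta) is exactly the log prior.  The gradient combines the
    envelope term (the theta-gradient of the joint at xi_hat) with the
    total derivative of the log-determinant, including the implicit
    dependence of xi_hat on theta.
    """

    def __init__(self, post: _Posterior) -> None:
        self.post = post
        self.idx = post.index
        self.has_xi = self.idx.n_xi > 0
        self.warm = np.zeros(self.idx.n_xi)

    def value(self, theta: np.ndarray) -> float:
        return self.value_grad(theta)[0]

    def value_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        post, idx = self.post, self.idx
        if not self.has_xi:
            val, grad = post.value_grad(theta)
            return val, grad[: idx.n_theta]
        xi_hat, nH, val, grad_full = _inner_xi_mode(post, theta, self.warm)
        self.warm = xi_hat
        sign, logdet = np.linalg.slogdet(nH)
        if sign <= 0:  # pragma: no cover - nH is PD by construction
            raise InferenceError("latent-effect curvature lost positive definiteness")
        lval = val + 0.5 * idx.n_xi * _LOG_2PI - 0.5 * logdet
        f_theta = grad_full[: idx.n_theta]

        # pieces shared by the log-det derivatives
        A = np.linalg.inv(nH)
        R, U = post.n_lambda, post.n_gamma
        p_lr, p_ls = post.pos["log_sigma_reef"], post.pos["log_sigma_site"]
        vr, vs = np.exp(-2.0 * theta[p_lr]), np.exp(-2.0 * theta[p_ls])
        c = theta[: idx.n_beta + idx.K]
        rows = post.rows
        use = rows.unit_index >= 0
        u_of_row = np.clip(rows.unit_index, 0, None)
        gam = xi_hat[idx.sl_gamma]
        lam = xi_hat[idx.sl_lambda]
        mu = rows.Xc @ c + np.where(use, gam[u_of_row], 0.0)
        pi = 1.0 / (1.0 + np.exp(-mu))
        w_row = rows.n * pi * (1.0 - pi)
        t_row = w_row * (1.0 - 2.0 * pi)
        t_row = np.where(use, t_row, 0.0)
        w_row = np.where(use, w_row, 0.0)
        resid_g = gam - lam[post.unit_reef]
        n_per = np.bincount(post.unit_reef, minlength=R)
        a_rr = np.diag(A)[:R]
        a_gg = np.diag(A)[R:]
        a_rg = A[post.unit_reef, R + np.arange(U)]

        # explicit part: tr(A dnH/dtheta_i)
        expl = np.zeros(idx.n_theta)
        expl[: idx.n_beta + idx.K] = rows.Xc.T @ (a_gg[u_of_row] * t_row)
        expl[p_lr] = -2.0 * vr * float(a_rr.sum())
        expl[p_ls] = (
            -2.0 * vs * float((n_per * a_rr).sum() + a_gg.sum())
            + 4.0 * vs * float(a_rg.sum())
        )

        # implicit part: s' A F_xi_theta with s_k = tr(A dnH/dxi_k)
        s = np.zeros(idx.n_xi)
        t_unit = np.bincount(u_of_row, weights=t_row, minlength=U)
        s[idx.sl_gamma] = a_gg * t_unit
        q = A @ s
        q_lam, q_gam = q[:R], q[R:]
        impl = np.zeros(idx.n_theta)
        impl[: idx.n_beta + idx.K] = -rows.Xc.T @ (w_row * q_gam[u_of_row])
        impl[p_lr] = 2.0 * vr * float(lam @ q_lam)
        S_r = np.bincount(post.unit_reef, weights=resid_g, minlength=R)
        impl[p_ls] = -2.0 * vs * float(S_r @ q_lam) + 2.0 * vs * float(
            resid_g @ q_gam
        )

        grad = f_theta - 0.5 * (expl + impl)
        return lval, grad


def _marginal_laplace(
    post: _Posterior,
    start_theta: np.ndarray,
    fd_step: float = 1e-5,
) -> GaussianApprox:
    """Laplace approximation of the theta-marginal posterior.

    Quasi-Newton ascent of the Laplace-marginal log posterior (latent
    effects integrated out by an inner Newton at each theta), then a
    central finite-difference Hessian of its analytic gradient at the
    mode; a non-positive-definite curvature is repaired by eigenvalue
    clipping (with a warning).
    """
    marg = _MarginalPosterior(post)
    mode = np.asarray(start_theta, dtype=float).copy()
    d = mode.size

    h_cache: dict[str, np.ndarray] = {}

    def fd_hessian(x: np.ndarray) -> np.ndarray:
        # two-pass central differences: a pilot step per coordinate, then
        # a curvature-scaled step — coordinate curvatures span many
        # orders of magnitude (binomial information on the spline block
        # vs prior-dominated variance parameters), and a common step
        # drowns the weak directions in rounding noise.  The scaled
        # steps are cached across calls (curvature changes little
        # between Newton iterates), skipping the pilot pass after the
        # first call.
        def one_pass(h: np.ndarray) -> np.ndarray:
            H = np.empty((d, d))
            for i in range(d):
                e = np.zeros(d)
                e[i] = h[i]
                H[i] = (
                    marg.value_grad(x + e)[1] - marg.value_grad(x - e)[1]
                ) / (2.0 * h[i])
            return 0.5 * (H + H.T)

        h0 = h_cache.get("h", fd_step * (1.0 + np.abs(x)))
        H = one_pass(h0)
        h1 = np.clip(0.1 / np.sqrt(np.abs(np.diag(H)) + 1.0), 1e-7, 0.3)
        if np.max(np.abs(np.log(h1 / h0))) > 0.5:
            H = one_pass(h1)
        h_cache["h"] = h1
        return H

    # damped saddle-free Newton with the measured Hessian: quasi-Newton
    # methods stall on this surface (coordinate curvatures spread over
    # ~1e9), while Newton with per-coordinate FD steps converges in a
    # handful of iterations; one quasi-Newton rescue is attempted if a
    # step fails to improve
    val, grad = marg.value_grad(mode)
    if not np.isfinite(val):
        raise InferenceError(
            f"marginal log posterior not finite at the start (value {val})"
        )
    H = fd_hessian(mode)
    rescued = False
    for _ in range(60):
        w, v = np.linalg.eigh(-H)
        w_abs = np.maximum(np.abs(w), 1e-10 * np.abs(w).max())
        step = v @ ((v.T @ grad) / w_abs)
        pred = 0.5 * float(grad @ step)
        if pred < 1e-9:
            break
        ok = False
        for _ in range(25):
            val_new, grad_new = marg.value_grad(mode + step)
            if np.isfinite(val_new) and val_new > val + 1e-12:
                ok = True
                break
            step *= 0.5
        if not ok:
            if rescued:
                break
            rescued = True
            res = optimize.minimize(
                lambda th: tuple(-x for x in marg.value_grad(th)),
                mode,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 300, "ftol": 1e-13, "gtol": 1e-8},
            )
            if np.all(np.isfinite(res.x)) and -res.fun > val:
                mode = np.asarray(res.x, dtype=float)
                val, grad = marg.value_grad(mode)
                H = fd_hessian(mode)
                continue
            break
        mode, val, grad = mode + step, val_new, grad_new
        H = fd_hessian(mode)
    neg = -H
    w, v = np.linalg.eigh(neg)
    clipped = bool(w.min() <= 0)
    if clipped:
        warnings.warn(
            f"non-positive curvature direction (min eigenvalue {w.min():.3g}); "
            "clipped — posterior is flat or ill-conditioned along it",
            LaplaceWarning,
            stacklevel=2,
        )
    w = np.clip(w, 1e-8, None)
    cov = (v / w) @ v.T
    out = GaussianApprox(mode, cov, post.index.theta_names)
    out.clipped = clipped
    return out


# ---------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------

@dataclasses.dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws with provenance and diagnostics.

    ``draws`` has shape (chains, kept_iterations, n_parameters); columns
    follow ``index.names`` (theta then xi).
    """

    index: ParameterIndex
    draws: np.ndarray
    seed: int
    rhat: dict[str, float]
    accept_rates: dict[str, float]

    @property
    def names(self) -> tuple[str, ...]:
        return self.index.names

    def stacked(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.stacked(), columns=list(self.names))

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write draws as CSV plus a JSON sidecar with seed/diagnostics."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / "posterior_draws.csv"
        meta_path = directory / "posterior_meta.json"
        self.to_dataframe().to_csv(csv_path, index=False)
        meta = {
            "seed": self.seed,
            "chains": int(self.draws.shape[0]),
            "kept_iterations": int(self.draws.shape[1]),
            "rhat": self.rhat,
            "accept_rates": self.accept_rates,
        }
        meta_path.write_text(json.dumps(meta, indent=2))
        return {"draws": csv_path, "meta": meta_path}


def _split_rhat(draws: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    """Split-chain R-hat per parameter via arviz; draws is
    (chains, iterations, parameters)."""
    import arviz  # deferred: the import is slow and only fits need it

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = arviz.from_dict(
            posterior={name: draws[:, :, i] for i, name in enumerate(names)}
        )
        r = arviz.rhat(data)
    return {name: float(r[name].values) for name in names}


class _AdaptiveBlock:
    """Adaptive multivariate random-walk proposal for one parameter block."""

    def __init__(
        self, dim: int, rng: np.random.Generator, chol0: np.ndarray | None = None
    ) -> None:
        self.dim = dim
        self.rng = rng
        if chol0 is not None:
            self.log_scale = 0.0
            self.chol = chol0
        else:
            self.log_scale = np.log(0.1 / np.sqrt(dim))
            self.chol = np.eye(dim)
        self.history: list[np.ndarray] = []
        self.accepted = 0
        self.proposed = 0

    def propose(self, current: np.ndarray) -> np.ndarray:
        step = np.exp(self.log_scale) * (self.chol @ self.rng.standard_normal(self.dim))
        return current + step

    def update(self, accepted: bool, current: np.ndarray, adapting: bool) -> None:
        self.proposed += 1
        self.accepted += accepted
        if not adapting:
            return
        self.history.append(current.copy())
        rate = 1.0 if accepted else 0.0
        self.log_scale += (rate - 0.234) / max(1, len(self.history)) ** 0.6
        if len(self.history) >= 200 and len(self.history) % 100 == 0:
            hist = np.asarray(self.history[-1000:])
            if np.all(np.ptp(hist, axis=0) > 0):  # skip while frozen
                cov = np.cov(hist.T).reshape(self.dim, self.dim)
                cov = 2.38**2 / self.dim * cov + 1e-10 * np.eye(self.dim)
                try:
                    self.chol = np.linalg.cholesky(cov)
                    self.log_scale = min(self.log_scale, 0.0)
                except np.linalg.LinAlgError:  # pragma: no cover - degenerate
                    pass

    @property
    def rate(self) -> float:
        return self.accepted / max(1, self.proposed)


def fit_mcmc(
    dataset: HistoricalDataset | DesignMatrices,
    model: ModelConfig | None = None,
    priors: PriorSpec | None = None,
    chains: int = 4,
    iterations: int = 10_000,
    seed: int = 0,
    burnin: float = 0.5,
    rhat_threshold: float = 1.05,
) -> PosteriorSamples:
    """Sample the joint posterior p(theta, xi | data) by adaptive MCMC.

    Blocked scheme per iteration: multivariate random-walk Metropolis on
    the fixed effects, the spline coefficients and the log sds (each
    block with Haario-style covariance adaptation during burn-in),
    conjugate Gibbs for the reef effects lambda, and vectorized
    single-site Metropolis for the site effects gamma (their full
    conditionals are independent given lambda and theta).  Identical
    seeds give identical draws.
    """
    model = model or ModelConfig()
    priors = priors or PriorSpec()
    matrices = (
        dataset
        if isinstance(dataset, DesignMatrices)
        else build_design_matrices(dataset, model)
    )
    index = matrices.index
    rows = BinomialRows.from_matrices(matrices)
    post = _Posterior(rows, index, priors)
    if index.config.nested_random_effects:
        post.attach_reef_map(matrices.unit_reef_index)

    n_burn = int(round(iterations * burnin))
    kept = iterations - n_burn
    if kept < 2:
        raise InferenceError("too few post-burn-in iterations")

    pos = _logsd_positions(index)
    sl_logsd = index.sl_logsd
    o = index.n_theta
    nre = index.config.nested_random_effects and index.n_xi > 0

    # likelihood helpers for the gamma block
    Xc = rows.Xc
    y, n_tr = rows.y, rows.n
    site_idx = rows.unit_index
    n_gamma = len(index.gamma_names)

    def unit_loglik(gamma: np.ndarray, base_mu: np.ndarray) -> np.ndarray:
        mu = base_mu + gamma[site_idx]
        ll = y * mu - n_tr * np.logaddexp(0.0, mu)
        return np.bincount(site_idx, weights=ll, minlength=n_gamma)

    # fixed-effect columns that are constant within sampling units trade
    # off exactly against the site (and, if also reef-constant, reef)
    # effects; those likelihood-invariant directions get Gibbs sweeps
    sweep_cols: list[tuple[int, np.ndarray, np.ndarray | None]] = []
    if nre and len(y):
        g_mean, g_sd = priors.moments(index)
        for j in range(index.n_beta):
            col = Xc[:, j]
            d_u = np.empty(n_gamma)
            const = True
            for u_pos in range(n_gamma):
                vals = col[site_idx == u_pos]
                if vals.size == 0 or np.ptp(vals) > 0:
                    const = False
                    break
                d_u[u_pos] = vals[0]
            if not const or not np.any(d_u):
                continue
            n_lambda = len(index.lambda_names)
            d_r = np.empty(n_lambda)
            reef_const = True
            for r_pos in range(n_lambda):
                vals = d_u[matrices.unit_reef_index == r_pos]
                if vals.size == 0 or np.ptp(vals) > 0:
                    reef_const = False
                    break
                d_r[r_pos] = vals[0]
            sweep_cols.append((j, d_u, d_r if reef_const else None))

    root_ss = np.random.SeedSequence(seed)
    chain_seeds = root_ss.spawn(chains)
    all_draws = np.empty((chains, kept, index.n_total))
    accept: dict[str, float] = {}

    # initialization: start at the Laplace mode with the Laplace
    # covariance preconditioning the block proposals (the posterior is
    # far too concentrated at n = 1250 for unit-scale random walks)
    u0 = np.zeros(index.n_total)
    tot_y, tot_n = float(np.sum(y)), float(np.sum(n_tr))
    if tot_n > 0:
        p_emp = min(max(tot_y / tot_n, 1e-4), 1 - 1e-4)
        u0[index.theta_names.index("intercept")] = np.log(p_emp / (1 - p_emp))
    theta_cov0: np.ndarray | None = None
    if len(y):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", LaplaceWarning)
                lap0 = _marginal_laplace(post, u0[: index.n_theta].copy())
            u0[: index.n_theta] = lap0.mean
            if index.n_xi:
                u0[index.n_theta :] = _inner_xi_mode(
                    post, lap0.mean, np.zeros(index.n_xi)
                )[0]
            if not getattr(lap0, "clipped", False):
                theta_cov0 = lap0.cov
        except (InferenceError, np.linalg.LinAlgError):
            theta_cov0 = None
    v0 = post.value(u0)
    if not np.isfinite(v0):
        raise InferenceError(
            f"log posterior not finite at initialization (value {v0}); "
            f"theta start {u0[: index.n_theta]}"
        )

    def _block_chol(sl: slice) -> np.ndarray | None:
        if theta_cov0 is None:
            return None
        sub = theta_cov0[sl, sl]
        d = sl.stop - sl.start
        try:
            return np.linalg.cholesky(2.38**2 / d * sub + 1e-12 * np.eye(d))
        except np.linalg.LinAlgError:  # pragma: no cover - PSD-clipped cov
            return None

    # independence proposal built on the Laplace approximation: theta
    # from a tail-inflated Laplace Gaussian, xi from its conditional
    # Gaussian given theta; Metropolis-corrected, it jumps across the
    # posterior's long correlated ridges that random walks crawl along
    indep: dict | None = None
    if theta_cov0 is not None and len(y):
        infl = 1.2
        w_q, v_q = np.linalg.eigh(theta_cov0)
        w_q = np.clip(w_q, 1e-12, None)
        indep = {
            "mean": u0[: index.n_theta].copy(),
            "root": v_q * (infl * np.sqrt(w_q)),
            "logdet": float(np.sum(np.log(infl**2 * w_q))),
            "prec": (v_q / (infl**2 * w_q)) @ v_q.T,
        }

    def _indep_theta_logq(theta: np.ndarray) -> float:
        dlt = theta - indep["mean"]
        return -0.5 * (
            index.n_theta * _LOG_2PI
            + indep["logdet"]
            + float(dlt @ indep["prec"] @ dlt)
        )

    def _indep_xi_parts(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        xi_hat, nH = _inner_xi_mode(post, theta, np.zeros(index.n_xi))[:2]
        chol = np.linalg.cholesky(nH)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        return xi_hat, chol, logdet

    def _indep_logq(u: np.ndarray) -> float:
        out = _indep_theta_logq(u[: index.n_theta])
        if index.n_xi:
            xi_hat, chol, logdet = _indep_xi_parts(u[: index.n_theta])
            r = chol.T @ (u[index.n_theta :] - xi_hat)
            out += -0.5 * (index.n_xi * _LOG_2PI - logdet + float(r @ r))
        return out

    jitter_sd = np.full(index.n_total, 0.05)
    if theta_cov0 is not None:
        jitter_sd[: index.n_theta] = np.sqrt(
            np.clip(np.diag(theta_cov0), 1e-12, None)
        )
    for ci, css in enumerate(chain_seeds):
        rng = np.random.default_rng(css)
        u = u0 + jitter_sd * rng.standard_normal(index.n_total)
        logp = post.value(u)
        if not np.isfinite(logp):  # pragma: no cover - extreme jitter
            u, logp = u0.copy(), v0
        blocks: dict[str, tuple[slice, _AdaptiveBlock]] = {}
        # beta and delta move as one block so the adapted proposal can
        # capture the strong time/spline/interruption correlations
        sl_coef = slice(0, index.n_beta + index.K)
        blocks["coef"] = (
            sl_coef,
            _AdaptiveBlock(index.n_beta + index.K, rng, _block_chol(sl_coef)),
        )
        if sl_logsd.stop > sl_logsd.start:
            blocks["logsd"] = (
                sl_logsd,
                _AdaptiveBlock(sl_logsd.stop - sl_logsd.start, rng, _block_chol(sl_logsd)),
            )
        gamma_scale = np.full(n_gamma, 0.2)
        gamma_acc = np.zeros(n_gamma)
        gamma_tries = 0
        indep_acc = 0
        indep_tries = 0

        for it in range(iterations):
            adapting = it < n_burn
            for _, (sl, block) in blocks.items():
                prop = u.copy()
                prop[sl] = block.propose(u[sl])
                logp_prop = post.value(prop)
                ok = np.log(rng.uniform()) < logp_prop - logp
                if ok:
                    u, logp = prop, logp_prop
                block.update(bool(ok), u[sl], adapting)

            if nre:
                theta = u[: index.n_theta]
                lam = u[o + index.sl_lambda.start : o + index.sl_lambda.stop]
                gam = u[o + index.sl_gamma.start : o + index.sl_gamma.stop]
                vr = np.exp(-2.0 * theta[pos["log_sigma_reef"]])
                vs = np.exp(-2.0 * theta[pos["log_sigma_site"]])

                # Gibbs for lambda_r | gamma, sigmas
                n_per = np.bincount(post.unit_reef, minlength=post.n_lambda)
                s_per = np.bincount(
                    post.unit_reef, weights=gam, minlength=post.n_lambda
                )
                prec = vr + n_per * vs
                mean = (vs * s_per) / prec
                lam_new = mean + rng.standard_normal(post.n_lambda) / np.sqrt(prec)
                u[o + index.sl_lambda.start : o + index.sl_lambda.stop] = lam_new
                lam = lam_new

                # vectorized single-site Metropolis for gamma
                c = theta[: index.n_beta + index.K]
                base_mu = Xc @ c
                cur_ll = unit_loglik(gam, base_mu)
                prop_g = gam + gamma_scale * rng.standard_normal(n_gamma)
                prop_ll = unit_loglik(prop_g, base_mu)
                cur_pr = -0.5 * vs * (gam - lam[post.unit_reef]) ** 2
                prop_pr = -0.5 * vs * (prop_g - lam[post.unit_reef]) ** 2
                acc = np.log(rng.uniform(size=n_gamma)) < (
                    prop_ll + prop_pr - cur_ll - cur_pr
                )
                gam = np.where(acc, prop_g, gam)
                u[o + index.sl_gamma.start : o + index.sl_gamma.stop] = gam
                gamma_tries += 1
                gamma_acc += acc
                if adapting:
                    gamma_scale *= np.exp(
                        (acc.astype(float) - 0.44) / max(1, gamma_tries) ** 0.6
                    )

                # translation sweeps: unit-constant fixed-effect columns
                # trade off exactly against the site / reef effect
                # levels (the likelihood is invariant along these
                # directions, only the Gaussian priors constrain them),
                # so the shift along each is Gibbs-sampled
                for j, d_u, d_r in sweep_cols:
                    m0, s0 = post.g_mean[j], post.g_sd[j]
                    lam = u[o + index.sl_lambda.start : o + index.sl_lambda.stop]
                    gam = u[o + index.sl_gamma.start : o + index.sl_gamma.stop]
                    resid_g = gam - lam[post.unit_reef]
                    # beta_j + e, gamma_u -= e d_u
                    prec = 1.0 / s0**2 + vs * float(d_u @ d_u)
                    mean_e = (
                        -(u[j] - m0) / s0**2 + vs * float(d_u @ resid_g)
                    ) / prec
                    e = mean_e + rng.standard_normal() / np.sqrt(prec)
                    u[j] += e
                    u[o + index.sl_gamma.start : o + index.sl_gamma.stop] -= e * d_u
                    if d_r is None:
                        continue
                    # beta_j + e, lambda_r -= e d_r, gamma_u -= e d_r(u):
                    # site-level residuals are invariant too, so only the
                    # coefficient and reef-effect priors constrain e
                    lam = u[o + index.sl_lambda.start : o + index.sl_lambda.stop]
                    prec2 = 1.0 / s0**2 + vr * float(d_r @ d_r)
                    mean_e2 = (
                        -(u[j] - m0) / s0**2 + vr * float(d_r @ lam)
                    ) / prec2
                    e2 = mean_e2 + rng.standard_normal() / np.sqrt(prec2)
                    u[j] += e2
                    u[o + index.sl_lambda.start : o + index.sl_lambda.stop] -= e2 * d_r
                    u[o + index.sl_gamma.start : o + index.sl_gamma.stop] -= (
                        e2 * d_r[post.unit_reef]
                    )
                logp = post.value(u)

            # funnel moves: rescale a log-sd jointly with its effects
            # (epsilon-shift of the log-sd, multiplicative stretch of the
            # effects; the log-Jacobian of the stretch enters the ratio)
            if index.K:
                p_ld = pos["log_sigma_delta"]
                eps = 0.3 * rng.standard_normal()
                prop = u.copy()
                prop[p_ld] += eps
                prop[index.sl_delta] = u[index.sl_delta] * np.exp(eps)
                logp_prop = post.value(prop)
                if np.log(rng.uniform()) < logp_prop - logp + index.K * eps:
                    u, logp = prop, logp_prop
            if nre:
                # site-effect residual scale
                eps = 0.3 * rng.standard_normal()
                prop = u.copy()
                prop[pos["log_sigma_site"]] += eps
                lam_c = u[o + index.sl_lambda.start : o + index.sl_lambda.stop]
                gam_c = u[o + index.sl_gamma.start : o + index.sl_gamma.stop]
                prop[o + index.sl_gamma.start : o + index.sl_gamma.stop] = (
                    lam_c[post.unit_reef]
                    + (gam_c - lam_c[post.unit_reef]) * np.exp(eps)
                )
                logp_prop = post.value(prop)
                if np.log(rng.uniform()) < logp_prop - logp + n_gamma * eps:
                    u, logp = prop, logp_prop
                # reef-effect scale (site effects shift to keep residuals)
                eps = 0.3 * rng.standard_normal()
                prop = u.copy()
                prop[pos["log_sigma_reef"]] += eps
                lam_c = u[o + index.sl_lambda.start : o + index.sl_lambda.stop]
                lam_new = lam_c * np.exp(eps)
                prop[o + index.sl_lambda.start : o + index.sl_lambda.stop] = lam_new
                prop[o + index.sl_gamma.start : o + index.sl_gamma.stop] = (
                    u[o + index.sl_gamma.start : o + index.sl_gamma.stop]
                    + (lam_new - lam_c)[post.unit_reef]
                )
                logp_prop = post.value(prop)
                if np.log(rng.uniform()) < logp_prop - logp + post.n_lambda * eps:
                    u, logp = prop, logp_prop

            if indep is not None and it % 5 == 0:
                theta_p = indep["mean"] + indep["root"] @ rng.standard_normal(
                    index.n_theta
                )
                logq_p = _indep_theta_logq(theta_p)
                prop = np.empty_like(u)
                prop[: index.n_theta] = theta_p
                if index.n_xi:
                    xi_hat_p, chol_p, logdet_p = _indep_xi_parts(theta_p)
                    z = rng.standard_normal(index.n_xi)
                    prop[index.n_theta :] = xi_hat_p + np.linalg.solve(chol_p.T, z)
                    logq_p += -0.5 * (
                        index.n_xi * _LOG_2PI - logdet_p + float(z @ z)
                    )
                logp_prop = post.value(prop)
                if np.isfinite(logp_prop):
                    logq_cur = _indep_logq(u)
                    ok = np.log(rng.uniform()) < (
                        (logp_prop - logq_p) - (logp - logq_cur)
                    )
                    if ok:
                        u, logp = prop, logp_prop
                    indep_acc += ok
                indep_tries += 1

            if it >= n_burn:
                all_draws[ci, it - n_burn] = u

        for name, (_, block) in blocks.items():
            accept[f"chain{ci}_{name}"] = block.rate
        if nre and gamma_tries:
            accept[f"chain{ci}_gamma"] = float(np.mean(gamma_acc / gamma_tries))
        if indep_tries:
            accept[f"chain{ci}_indep"] = indep_acc / indep_tries

    rhat = _split_rhat(all_draws, index.names)
    worst = max((v for v in rhat.values() if np.isfinite(v)), default=1.0)
    if worst > rhat_threshold:
        bad = [k for k, v in rhat.items() if np.isfinite(v) and v > rhat_threshold]
        warnings.warn(
            f"split-chain R-hat above {rhat_threshold} for {bad} (max {worst:.3f})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return PosteriorSamples(index, all_draws, seed, rhat, accept)


# ---------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------

def compute_dic(
    samples: PosteriorSamples,
    dataset: HistoricalDataset | DesignMatrices,
) -> tuple[float, float, float]:
    """Deviance information criterion: (DIC, pD, Dbar).

    Dbar is the posterior mean deviance, pD = Dbar - D(posterior mean of
    the parameters), DIC = Dbar + pD.  Smaller DIC is preferred in the
    candidate-model comparison.
    """
    matrices = (
        dataset
        if isinstance(dataset, DesignMatrices)
        else build_design_matrices(dataset, samples.index.config)
    )
    draws = samples.stacked()
    if draws.shape[0] < 500:
        warnings.warn(
            f"only {draws.shape[0]} draws; deviance means may be unstable",
            ConvergenceWarning,
            stacklevel=2,
        )
    n_theta = samples.index.n_theta
    devs = np.empty(draws.shape[0])
    for i, u in enumerate(draws):
        devs[i] = -2.0 * matrices.log_likelihood(u[:n_theta], u[n_theta:])
        if not np.isfinite(devs[i]):
            raise InferenceError(f"non-finite deviance at draw {i}")
    dbar = float(devs.mean())
    u_mean = draws.mean(axis=0)
    dhat = -2.0 * matrices.log_likelihood(u_mean[:n_theta], u_mean[n_theta:])
    if not np.isfinite(dhat):
        raise InferenceError("non-finite deviance at the posterior mean")
    pd_ = dbar - float(dhat)
    return dbar + pd_, pd_, dbar


# ---------------------------------------------------------------------
# Laplace approximation
# ---------------------------------------------------------------------

def _fd_hessian(
    grad: Callable[[np.ndarray], np.ndarray], x: np.ndarray, step: float = 1e-5
) -> np.ndarray:
    """Central finite-difference Hessian from an analytic gradient."""
    d = x.size
    h = step * (1.0 + np.abs(x))
    H = np.empty((d, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = h[i]
        H[i] = (grad(x + e) - grad(x - e)) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def laplace_from_logpost(
    logpost: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    start: np.ndarray,
    names: Sequence[str],
    scope: Sequence[str] | None = None,
    restarts: int = 3,
    fd_step: float = 1e-5,
    seed: int = 0,
) -> GaussianApprox:
    """Laplace approximation of a generic log posterior.

    Quasi-Newton ascent to the mode, covariance from the inverse
    negative finite-difference Hessian of the analytic gradient, then
    (optionally) marginalization to the ``scope`` coordinates by taking
    the corresponding block of the full covariance.  A non-positive-
    definite curvature is repaired by eigenvalue clipping at 1e-8 (with
    a warning); optimizer failures are retried from jittered starts.
    """
    start = np.asarray(start, dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(restarts + 1):
        x0 = start if attempt == 0 else start + 0.1 * attempt * rng.standard_normal(start.size)
        res = optimize.minimize(
            lambda u: -logpost(u),
            x0,
            jac=lambda u: -grad(u),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success or np.linalg.norm(res.jac, np.inf) < 1e-5:
            best = res
            break
    else:
        if best is None or not np.all(np.isfinite(best.x)):
            raise InferenceError("Laplace mode search failed on all restarts")
    mode = best.x
    neg_hess = -_fd_hessian(grad, mode, fd_step)
    w, v = np.linalg.eigh(neg_hess)
    floor = 1e-8
    if w.min() <= floor:
        warnings.warn(
            f"flat or ill-conditioned curvature direction (min eigenvalue "
            f"{w.min():.3g}); clipped",
            LaplaceWarning,
            stacklevel=2,
        )
    w = np.clip(w, floor, None)
    cov = (v / w) @ v.T
    full = GaussianApprox(mode, cov, names)
    if scope is not None:
        return full.marginal(scope)
    return full


def laplace_approx(
    dataset: HistoricalDataset | DesignMatrices | BinomialRows,
    model: ModelConfig | ParameterIndex | None = None,
    prior: PriorSpec | GaussianApprox | None = None,
    start: np.ndarray | None = None,
    scope: str = "theta",
    fd_step: float = 1e-5,
) -> GaussianApprox:
    """Laplace Gaussian approximation of the coral-model posterior.

    With a :class:`PriorSpec` prior this targets the same posterior as
    :func:`fit_mcmc`; with a :class:`GaussianApprox` prior it performs
    the design-stage update, where the Gaussian (the posterior from the
    historical fit) is the prior and the supplied observations are the
    new data.  ``scope='theta'`` (default) marginalizes the latent reef
    and site effects out of the returned Gaussian; ``scope='all'``
    returns the joint.
    """
    prior = prior if prior is not None else PriorSpec()
    if isinstance(dataset, BinomialRows):
        if not isinstance(model, ParameterIndex):
            raise InferenceError("BinomialRows input requires a ParameterIndex")
        index, rows = model, dataset
        unit_reef = getattr(model, "_unit_reef_index", None)
    else:
        matrices = (
            dataset
            if isinstance(dataset, DesignMatrices)
            else build_design_matrices(dataset, model or ModelConfig())
        )
        index = matrices.index
        rows = BinomialRows.from_matrices(matrices)
        unit_reef = matrices.unit_reef_index
    post = _Posterior(rows, index, prior)
    if index.config.nested_random_effects and index.n_xi:
        if unit_reef is None:
            raise InferenceError("unit -> reef map required for nested effects")
        post.attach_reef_map(unit_reef)

    if start is None:
        start = np.zeros(index.n_total)
        if isinstance(prior, GaussianApprox):
            start[: index.n_theta] = prior.mean
    if scope == "theta":
        return _marginal_laplace(post, start[: index.n_theta], fd_step=fd_step)
    value_grad = post.value_grad
    return laplace_from_logpost(
        lambda u: value_grad(u)[0],
        lambda u: value_grad(u)[1],
        start,
        index.names,
        scope=list(index.names),
        fd_step=fd_step,
    )


def summarize_gaussian(
    samples: PosteriorSamples, scope: Sequence[str] | str = "theta"
) -> GaussianApprox:
    """Moment-matched Gaussian over the requested parameter scope.

    ``scope`` may be 'theta' (fixed effects + spline coefficients + log
    sds; the design-parameter scope), 'all', or an explicit name list.
    This is the posterior-becomes-prior step: the fitted posterior in
    Gaussian form is the prior for all subsequent design evaluation.
    """
    if isinstance(scope, str):
        if scope == "theta":
            names = list(samples.index.theta_names)
        elif scope == "all":
            names = list(samples.names)
        else:
            raise InferenceError(f"unknown scope {scope!r}")
    else:
        names = list(scope)
    missing = [n for n in names if n not in samples.index.position]
    if missing:
        raise KeyError(f"scope names not in the parameter index: {missing}")
    draws = samples.stacked()
    if draws.shape[0] < 2:
        raise InferenceError("need at least 2 draws to moment match")
    cols = [samples.index.pos(n) for n in names]
    sub = draws[:, cols]
    mean = sub.mean(axis=0)
    cov = np.cov(sub.T).reshape(len(cols), len(cols))
    w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if w.min() <= 0:
        warnings.warn(
            "moment-matched covariance is singular; clipped to PSD",
            LaplaceWarning,
            stacklevel=2,
        )
        ww, v = np.linalg.eigh(0.5 * (cov + cov.T))
        cov = (v * np.clip(ww, 0.0, None)) @ v.T
    return GaussianApprox(mean, cov, names)
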