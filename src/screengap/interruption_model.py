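"""Bayesian state-space model for weekly screening-encounter counts.

The observed weekly count ``y_it`` for group *i* in week *t* is modeled as
Poisson with a log-normal mixed log-mean ("log-normal Poisson"):

    log E[y_it] = mu_it + H_t * beta_H + S_t' beta_S + eps_it,
    eps_it ~ Normal(0, sigma_eps^2),

where ``H_t`` is a 0/1 holiday-week indicator, ``S_t`` holds K annual
sin/cos harmonics, and the mean process ``mu_it`` mixes two latent
group-specific random-walk levels:

    mu_it = tau_it * beta_it + (1 - tau_it) * omega_it.

``beta_it`` is the undisturbed ("no acute pandemic") level and ``omega_it``
the depressed level; ``tau_it`` in (0,1) is an averaging weight that equals
1 outside an early-pandemic envelope and dips toward 0 inside a smooth
pulse delimited by two continuous change-points ``d0 < d1`` with logistic
ramps. The change-points are constrained to calendar windows (onset in
[2020-03-01, 2020-04-15), offset in [2020-04-15, 2020-08-01]) so that the
interruption is identified from data rather than fixed a priori, while
label switching is ruled out.

All model terms except the shared holiday and seasonal effects are
group-specific. The joint log-density and its analytic gradient are
exposed in unconstrained coordinates for gradient-based sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, digamma
from scipy import stats

from .data_io import HolidayCalendar, WeeklyCounts

#: Mean length of the year in weeks (annual period of the harmonics).
WEEKS_PER_YEAR = 52.1775

#: Calendar envelope within which the interruption weight may differ from 1.
ENVELOPE = (pd.Timestamp("2020-03-01"), pd.Timestamp("2020-08-31"))
#: Allowed calendar window for the interruption onset d0.
D0_BOUNDS = (pd.Timestamp("2020-03-01"), pd.Timestamp("2020-04-15"))
#: Allowed calendar window for the interruption offset d1.
D1_BOUNDS = (pd.Timestamp("2020-04-15"), pd.Timestamp("2020-08-01"))


@dataclass
class ModelSpec:
    """Priors and structural switches for the count model.

    Scales are standard deviations. ``family`` selects the observation
    model: ``"poisson-lognormal"`` (per-week latent Gaussian noise on the
    log-mean; the default) or ``"negbin"`` (the noise marginalized into a
    moment-matched negative-binomial, cheaper because it removes one latent
    per group-week).
    """

    K: int = 2
    beta_H_scale: float = 1.0
    beta_S_scale: float = 1.0
    beta0_scale: float = 1.0
    omega0_offset: float = -3.0
    omega0_scale: float = 2.0
    rw_scale_prior: float = 0.2
    eps_scale_prior: float = 0.5
    ramp_weeks: float = 0.08
    family: str = "poisson-lognormal"
    envelope: tuple = ENVELOPE
    d0_bounds: tuple = D0_BOUNDS
    d1_bounds: tuple = D1_BOUNDS

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("K must be >= 0")
        for name in ("beta_H_scale", "beta_S_scale", "beta0_scale", "omega0_scale",
                     "rw_scale_prior", "eps_scale_prior", "ramp_weeks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.family not in ("poisson-lognormal", "negbin"):
            raise ValueError(f"unknown observation family {self.family!r}")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        for k in ("envelope", "d0_bounds", "d1_bounds"):
            d[k] = [str(pd.Timestamp(v).date()) for v in d[k]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for k in ("envelope", "d0_bounds", "d1_bounds"):
            if k in d:
                d[k] = tuple(pd.Timestamp(v) for v in d[k])
        return cls(**d)


@dataclass
class DesignMatrices:
    """Per-week covariates: holiday indicator and seasonal harmonic basis."""

    week_starts: pd.DatetimeIndex
    holiday: np.ndarray  # (T,), 0/1
    seasonal: np.ndarray  # (T, 2K): [sin 1, cos 1, ..., sin K, cos K]

    def __post_init__(self):
        T = len(self.week_starts)
        if self.holiday.shape != (T,) or self.seasonal.shape[0] != T:
            raise ValueError("design row count does not match week grid")

    def to_frame(self) -> pd.DataFrame:
        """Inspectable table: week_start, holiday, sin_k/cos_k columns."""
        cols = {"week_start": self.week_starts.strftime("%Y-%m-%d"),
                "holiday": self.holiday}
        for j in range(self.seasonal.shape[1]):
            k = j // 2 + 1
            cols[f"{'sin' if j % 2 == 0 else 'cos'}_{k}"] = self.seasonal[:, j]
        return pd.DataFrame(cols)


def build_design(week_starts, calendar: HolidayCalendar, K: int) -> DesignMatrices:
    """Holiday indicator and K annual sin/cos harmonic columns.

    Harmonic k at week index w is ``sin(2 pi k w / P), cos(2 pi k w / P)``
    with P = 52.1775 weeks, so the basis has an exact one-year period.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    week_starts = pd.DatetimeIndex(week_starts)
    w = np.arange(len(week_starts), dtype=float)
    cols = []
    for k in range(1, K + 1):
        ang = 2.0 * np.pi * k * w / WEEKS_PER_YEAR
        cols.extend([np.sin(ang), np.cos(ang)])
    seasonal = np.column_stack(cols) if cols else np.empty((len(w), 0))
    return DesignMatrices(week_starts, calendar.indicator(week_starts), seasonal)


def interruption_weight(t, d0, d1, ramp_weeks: float):
    """Smooth interruption pulse tau(t) = 1 - sigma((t-d0)/s) sigma((d1-t)/s).

    ``t``, ``d0``, ``d1`` are in continuous week units on a common origin.
    tau -> 1 far from the window; inside a window much wider than the ramp
    scale ``s`` it approaches 0; as s -> 0 it converges to the step
    indicator of (d0, d1).
    """
    if ramp_weeks <= 0:
        raise ValueError("ramp_weeks must be > 0")
    t = np.asarray(t, dtype=float)
    return 1.0 - expit((t - d0) / ramp_weeks) * expit((d1 - t) / ramp_weeks)


def mean_process(tau, x_beta, x_omega):
    """Affine mix mu = tau * x_beta + (1 - tau) * x_omega (elementwise)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0) or np.any(tau > 1):
        raise ValueError("tau must lie in [0, 1]")
    return tau * np.asarray(x_beta, float) + (1.0 - tau) * np.asarray(x_omega, float)


def observation_logdensity(y, mu, H, S, beta_H, beta_S, eps, sigma_eps):
    """Poisson log-pmf at log-mean mu + H*beta_H + S'beta_S + eps, plus the
    Normal(0, sigma_eps) log-density of eps (the log-normal mixing term)."""
    if sigma_eps <= 0:
        raise ValueError("sigma_eps must be > 0")
    log_lam = np.asarray(mu, float) + np.asarray(H, float) * beta_H \
        + np.asarray(S, float) @ np.atleast_1d(beta_S) + np.asarray(eps, float)
    lam = np.exp(log_lam)
    y = np.asarray(y)
    pois = y * log_lam - lam - gammaln(y + 1.0)
    noise = stats.norm.logpdf(np.asarray(eps, float), 0.0, sigma_eps)
    return float(np.sum(pois) + np.sum(noise))


def state_transition_logdensity(level_prev, level_curr, scale):
    """Gaussian random-walk increment density between consecutive weeks."""
    if scale <= 0:
        raise ValueError("innovation scale must be > 0")
    inc = np.asarray(level_curr, float) - np.asarray(level_prev, float)
    return float(np.sum(stats.norm.logpdf(inc, 0.0, scale)))


def _weeks_since(origin: pd.Timestamp, when) -> float:
    return (pd.Timestamp(when) - origin) / pd.Timedelta(days=7)


class CountModel:
    """Joint posterior density (and gradient) of the count model.

    Parameters live in an unconstrained vector ``theta``, in centered
    (natural) coordinates for the latent paths -- appropriate here because
    weekly counts in the hundreds-to-thousands inform the paths strongly:

    - ``beta`` (G*T): undisturbed log-levels
    - ``omega`` (G*T): depressed log-levels
    - ``eps`` (G*T): per-week log-mean noise (poisson-lognormal only)
    - ``u0``, ``u1`` (G each): logit-warped change points within bounds
    - ``beta_H`` (1), ``beta_S`` (2K): shared holiday/seasonal effects
    - ``lsb``, ``lsw``, ``lse`` (1 each): log innovation/noise scales
    """

    def __init__(self, series: WeeklyCounts, calendar: HolidayCalendar,
                 spec: ModelSpec | None = None):
        self.spec = spec = spec if spec is not None else ModelSpec()
        self.series = series
        self.y = series.counts.astype(float)
        self.G, self.T = self.y.shape
        if np.any(self.y.sum(axis=1) == 0):
            bad = [series.groups[i] for i in np.flatnonzero(self.y.sum(axis=1) == 0)]
            raise ValueError(f"group(s) with all-zero counts cannot be fit: {bad}")
        self.design = build_design(series.week_starts, calendar, spec.K)
        self.H = self.design.holiday
        self.S = self.design.seasonal
        origin = series.week_starts[0]
        self.t_weeks = np.arange(self.T, dtype=float)
        self.envelope_mask = np.asarray(
            (series.week_starts >= pd.Timestamp(spec.envelope[0]))
            & (series.week_starts <= pd.Timestamp(spec.envelope[1])),
            dtype=float,
        )
        self.d0_lo = _weeks_since(origin, spec.d0_bounds[0])
        self.d0_w = _weeks_since(origin, spec.d0_bounds[1]) - self.d0_lo
        self.d1_lo = _weeks_since(origin, spec.d1_bounds[0])
        self.d1_w = _weeks_since(origin, spec.d1_bounds[1]) - self.d1_lo
        # anchor for the initial levels: log mean weekly count over the first year
        first = self.y[:, : min(self.T, 52)]
        self.b0_loc = np.log(np.maximum(first.mean(axis=1), 0.5))
        self.has_eps = spec.family == "poisson-lognormal"
        nK = 2 * spec.K
        sizes = {
            "beta": self.G * self.T,
            "omega": self.G * self.T,
            "eps": self.G * self.T if self.has_eps else 0,
            "u0": self.G,
            "u1": self.G,
            "beta_H": 1,
            "beta_S": nK,
            "lsb": 1,
            "lsw": 1,
            "lse": 1,
        }
        self.slices = {}
        off = 0
        for name, size in sizes.items():
            self.slices[name] = slice(off, off + size)
            off += size
        self.dim = off

    # -- parameter bookkeeping ------------------------------------------

    def _split(self, theta: np.ndarray) -> dict:
        out = {}
        for name, sl in self.slices.items():
            block = theta[sl]
            if name in ("beta", "omega", "eps") and block.size:
                block = block.reshape(self.G, self.T)
            out[name] = block
        return out

    def initial_theta(self, rng: np.random.Generator) -> np.ndarray:
        """Data-guided start: log observed counts, window weeks bridged."""
        theta = np.zeros(self.dim)
        logy = np.log(np.maximum(self.y, 0.5))
        env = self.envelope_mask.astype(bool)
        beta0 = logy.copy()
        if env.any() and (~env).any():
            idx = np.flatnonzero(~env)
            for i in range(self.G):
                beta0[i, env] = np.interp(np.flatnonzero(env), idx, logy[i, idx])
        omega0 = np.where(env[None, :], logy, (self.b0_loc + self.spec.omega0_offset)[:, None])
        jitter = 0.05 * rng.standard_normal((self.G, self.T))
        theta[self.slices["beta"]] = (beta0 + jitter).ravel()
        theta[self.slices["omega"]] = (omega0 + jitter[:, ::-1]).ravel()
        theta[self.slices["lsb"]] = np.log(0.1)
        theta[self.slices["lsw"]] = np.log(0.1)
        theta[self.slices["lse"]] = np.log(0.05)
        theta[self.slices["u0"]] = 0.2 * rng.standard_normal(self.G)
        theta[self.slices["u1"]] = 0.2 * rng.standard_normal(self.G)
        return theta

    def _paths(self, p: dict) -> tuple:
        # numpy scalars: overflow must propagate as inf, not raise
        sigma_b = np.exp(p["lsb"][0])
        sigma_w = np.exp(p["lsw"][0])
        sigma_e = np.exp(p["lse"][0])
        d0 = self.d0_lo + self.d0_w * expit(p["u0"])
        d1 = self.d1_lo + self.d1_w * expit(p["u1"])
        s = self.spec.ramp_weeks
        A = expit((self.t_weeks[None, :] - d0[:, None]) / s)
        B = expit((d1[:, None] - self.t_weeks[None, :]) / s)
        tau = 1.0 - self.envelope_mask[None, :] * A * B
        return sigma_b, sigma_w, sigma_e, d0, d1, A, B, tau

    def constrain(self, theta: np.ndarray) -> dict:
        """Map an unconstrained vector to named natural-scale quantities."""
        p = self._split(theta)
        sigma_b, sigma_w, sigma_e, d0, d1, A, B, tau = self._paths(p)
        beta, omega = p["beta"], p["omega"]
        eps = p["eps"] if self.has_eps else np.zeros((self.G, self.T))
        mu = tau * beta + (1.0 - tau) * omega
        eta = mu + self.H[None, :] * p["beta_H"][0] + (self.S @ p["beta_S"])[None, :] + eps
        origin = self.series.week_starts[0]
        return {
            "beta": beta.copy(), "omega": omega.copy(), "tau": tau, "mu": mu,
            "eps": eps.copy(), "eta": eta, "lam": np.exp(eta),
            "beta_H": float(p["beta_H"][0]), "beta_S": p["beta_S"].copy(),
            "sigma_beta": sigma_b, "sigma_omega": sigma_w, "sigma_eps": sigma_e,
            "d0": d0, "d1": d1,
            "d0_date": origin + pd.to_timedelta(d0 * 7, unit="D"),
            "d1_date": origin + pd.to_timedelta(d1 * 7, unit="D"),
        }

    # -- joint density and gradient -------------------------------------

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = self._split(theta)
        spec = self.spec
        G, T = self.G, self.T
        s = spec.ramp_weeks
        LOG2PI = np.log(2.0 * np.pi)
        y = self.y

        lsb, lsw, lse = p["lsb"][0], p["lsw"][0], p["lse"][0]
        sigma_b, sigma_w, sigma_e, d0, d1, A, B, tau = self._paths(p)
        beta, omega = p["beta"], p["omega"]
        E = self.envelope_mask[None, :]

        mu = tau * beta + (1.0 - tau) * omega
        eps = p["eps"] if self.has_eps else 0.0
        eta = mu + self.H[None, :] * p["beta_H"][0] + (self.S @ p["beta_S"])[None, :] + eps
        lam = np.exp(eta)

        grad = np.zeros_like(theta)

        if self.has_eps:
            logp = float(np.sum(y * eta - lam - gammaln(y + 1.0)))
            score = y - lam  # dlogp/deta
        else:
            sig2 = sigma_e ** 2
            alpha = np.expm1(sig2)  # moment-matched NB dispersion
            r = 1.0 / max(alpha, 1e-12)
            logp = float(np.sum(
                gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
                + r * (np.log(r) - np.log(r + lam)) + y * (eta - np.log(r + lam))
            ))
            score = y - (y + r) * lam / (r + lam)
            dl_dr = float(np.sum(
                digamma(y + r) - digamma(r) + np.log(r) - np.log(r + lam)
                + 1.0 - (y + r) / (r + lam)
            ))

        # random-walk priors on the level paths (centered coordinates)
        g_beta = score * tau
        g_omega = score * (1.0 - tau)
        vb, vw = sigma_b ** 2, sigma_w ** 2
        for (path, gpath, loc0, s0, var, nm) in (
            (beta, g_beta, self.b0_loc, spec.beta0_scale, vb, "beta"),
            (omega, g_omega, self.b0_loc + spec.omega0_offset, spec.omega0_scale, vw, "omega"),
        ):
            inc = np.diff(path, axis=1)
            dev0 = path[:, 0] - loc0
            logp += float(
                -0.5 * np.sum(dev0 ** 2) / s0 ** 2 - G * (0.5 * LOG2PI + np.log(s0))
                - 0.5 * np.sum(inc ** 2) / var - G * (T - 1) * (0.5 * LOG2PI + 0.5 * np.log(var))
            )
            gp = gpath.copy()
            gp[:, 0] -= dev0 / s0 ** 2
            gp[:, :-1] += inc / var
            gp[:, 1:] -= inc / var
            grad[self.slices[nm]] += gp.ravel()

        if self.has_eps:
            sig2e = sigma_e ** 2
            logp += float(-0.5 * np.sum(p["eps"] ** 2) / sig2e
                          - G * T * (0.5 * LOG2PI + np.log(sigma_e)))
            grad[self.slices["eps"]] += (score - p["eps"] / sig2e).ravel()

        bH = p["beta_H"][0]
        logp -= 0.5 * bH ** 2 / spec.beta_H_scale ** 2 \
            + 0.5 * LOG2PI + np.log(spec.beta_H_scale)
        grad[self.slices["beta_H"]] += np.sum(score * self.H[None, :]) - bH / spec.beta_H_scale ** 2
        nS = p["beta_S"].size
        logp -= 0.5 * float(np.sum(p["beta_S"] ** 2)) / spec.beta_S_scale ** 2 \
            + 0.5 * nS * LOG2PI + nS * np.log(spec.beta_S_scale)
        grad[self.slices["beta_S"]] += self.S.T @ score.sum(axis=0) - p["beta_S"] / spec.beta_S_scale ** 2

        # half-Normal priors on the scales via log transform
        def halfnorm_term(sig, scale, ls):
            return (np.log(2.0) - np.log(scale) - 0.5 * LOG2PI
                    - 0.5 * sig ** 2 / scale ** 2 + ls)

        pr = spec.rw_scale_prior ** 2
        logp += halfnorm_term(sigma_b, spec.rw_scale_prior, lsb)
        logp += halfnorm_term(sigma_w, spec.rw_scale_prior, lsw)
        inc_b = np.diff(beta, axis=1)
        inc_w = np.diff(omega, axis=1)
        grad[self.slices["lsb"]] += float(np.sum(inc_b ** 2) / vb) - G * (T - 1) \
            + 1.0 - sigma_b ** 2 / pr
        grad[self.slices["lsw"]] += float(np.sum(inc_w ** 2) / vw) - G * (T - 1) \
            + 1.0 - sigma_w ** 2 / pr

        pe = spec.eps_scale_prior ** 2
        logp += halfnorm_term(sigma_e, spec.eps_scale_prior, lse)
        if self.has_eps:
            grad[self.slices["lse"]] += float(np.sum(p["eps"] ** 2) / sigma_e ** 2) - G * T \
                + 1.0 - sigma_e ** 2 / pe
        else:
            # d r / d lse through alpha = expm1(sigma^2), r = 1/alpha
            dr_dlse = -(1.0 / max(alpha, 1e-12) ** 2) * np.exp(sig2) * 2.0 * sig2
            grad[self.slices["lse"]] += dl_dr * dr_dlse + 1.0 - sigma_e ** 2 / pe

        # change points: pulse derivative, then logit-interval jacobian;
        # the uniform prior's 1/width cancels the width factor of the jacobian
        e0, e1 = expit(p["u0"]), expit(p["u1"])
        g_tau = score * (beta - omega) * E
        dtau_dd0 = A * (1.0 - A) * B / s
        dtau_dd1 = -A * B * (1.0 - B) / s
        g_d0 = np.sum(g_tau * dtau_dd0, axis=1)
        g_d1 = np.sum(g_tau * dtau_dd1, axis=1)
        logp += float(np.sum(np.log(e0) + np.log1p(-e0) + np.log(e1) + np.log1p(-e1)))
        grad[self.slices["u0"]] += g_d0 * self.d0_w * e0 * (1.0 - e0) + (1.0 - 2.0 * e0)
        grad[self.slices["u1"]] += g_d1 * self.d1_w * e1 * (1.0 - e1) + (1.0 - 2.0 * e1)

        return logp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_and_grad(theta)[0]


def brute_force_joint_logp(model: CountModel, theta: np.ndarray) -> float:
    """Independent term-by-term evaluation of the joint log-density.

    Works in the natural coordinates (levels, noise, scales, change-point
    dates), summing observation, transition, and prior contributions one
    scalar at a time with scipy distributions; scale and change-point
    coordinates add their log-transform jacobians. Deliberately naive and
    loop-based; validates the vectorized ``CountModel.logp_and_grad``.
    Poisson-lognormal family only.
    """
    if not model.has_eps:
        raise ValueError("brute-force oracle covers the poisson-lognormal family only")
    c = model.constrain(theta)
    p = model._split(theta)
    spec = model.spec
    total = 0.0
    # observations (Poisson terms plus the Normal density of each eps)
    for i in range(model.G):
        total += observation_logdensity(
            model.y[i], c["mu"][i], model.H, model.S, c["beta_H"], c["beta_S"],
            c["eps"][i], c["sigma_eps"],
        )
    # initial levels and random-walk transitions
    for i in range(model.G):
        total += stats.norm.logpdf(c["beta"][i, 0], model.b0_loc[i], spec.beta0_scale)
        total += stats.norm.logpdf(
            c["omega"][i, 0], model.b0_loc[i] + spec.omega0_offset, spec.omega0_scale
        )
        for t in range(1, model.T):
            total += state_transition_logdensity(c["beta"][i, t - 1], c["beta"][i, t], c["sigma_beta"])
            total += state_transition_logdensity(c["omega"][i, t - 1], c["omega"][i, t], c["sigma_omega"])
    # effect priors
    total += stats.norm.logpdf(c["beta_H"], 0.0, spec.beta_H_scale)
    total += float(np.sum(stats.norm.logpdf(c["beta_S"], 0.0, spec.beta_S_scale)))
    # half-normal priors on scales, with log-transform jacobians
    for sig, scale, ls in (
        (c["sigma_beta"], spec.rw_scale_prior, p["lsb"][0]),
        (c["sigma_omega"], spec.rw_scale_prior, p["lsw"][0]),
        (c["sigma_eps"], spec.eps_scale_prior, p["lse"][0]),
    ):
        total += stats.halfnorm.logpdf(sig, scale=scale) + ls
    # uniform change-point priors over their calendar windows, plus the
    # interval-logit jacobian width * e * (1 - e)
    for u, width in ((p["u0"], model.d0_w), (p["u1"], model.d1_w)):
        e = expit(u)
        total -= len(u) * np.log(width)  # uniform density over the interval
        total += float(np.sum(np.log(width * e * (1.0 - e))))
    return float(total)
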