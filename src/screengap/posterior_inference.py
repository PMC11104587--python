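"""MCMC fitting and posterior summaries for the count model.

Provides the fit entry point (adaptive HMC over the model's unconstrained
parameter vector), the counterfactual "no acute pandemic" posterior
predictive, missed/delayed-visit estimates with 95% credible intervals,
the data-driven interruption-window report, and a posterior Wald-type test
for equality of group drop percentages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import HolidayCalendar, WeeklyCounts, build_holiday_calendar
from .interruption_model import CountModel, ModelSpec
from .sampler import sample_chain

logger = logging.getLogger(__name__)

#: Marker value used when no week meets the interruption-window rule.
NO_INTERRUPTION = "no interruption detected"


@dataclass
class MCMCSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    max_leapfrog: int = 64
    target_accept: float = 0.85


@dataclass
class PosteriorDraws:
    """Posterior draws of all latent paths and effects, with chain structure.

    Path arrays (``beta``, ``omega``, ``tau``, ``eps``) have shape
    (chains, draws, groups, weeks); scalar effects drop the trailing axes.
    ``d0``/``d1`` are change points in continuous week units from the first
    grid Sunday.
    """

    model: CountModel
    thetas: np.ndarray  # (chains, draws, dim)
    params: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None
    chain_stats: pd.DataFrame | None = None

    @property
    def groups(self) -> list[str]:
        return self.model.series.groups

    @property
    def week_starts(self) -> pd.DatetimeIndex:
        return self.model.series.week_starts

    def flat(self, name: str) -> np.ndarray:
        """Draws of ``name`` with the chain axis folded into the draw axis."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])


def _constrain_all(model: CountModel, thetas: np.ndarray) -> dict:
    C, D, _ = thetas.shape
    G, T = model.G, model.T
    nS = 2 * model.spec.K
    out = {
        "beta": np.empty((C, D, G, T)),
        "omega": np.empty((C, D, G, T)),
        "tau": np.empty((C, D, G, T)),
        "eps": np.empty((C, D, G, T)),
        "beta_H": np.empty((C, D)),
        "beta_S": np.empty((C, D, nS)),
        "sigma_beta": np.empty((C, D)),
        "sigma_omega": np.empty((C, D)),
        "sigma_eps": np.empty((C, D)),
        "d0": np.empty((C, D, G)),
        "d1": np.empty((C, D, G)),
    }
    for c in range(C):
        for d in range(D):
            con = model.constrain(thetas[c, d])
            for k in out:
                out[k][c, d] = con[k]
    return out


def fit(
    series: WeeklyCounts,
    spec: ModelSpec | None = None,
    mcmc: MCMCSettings | None = None,
    calendar: HolidayCalendar | None = None,
) -> PosteriorDraws:
    """Fit the state-space count model by adaptive HMC.

    Runs ``mcmc.chains`` independent chains from jittered starts; chain
    randomness derives from ``mcmc.seed`` through named substreams, so a
    fixed seed and configuration reproduce the draws exactly. Split R-hat
    and effective sample size for the monitored scalars (change points,
    scales, holiday effect) are attached as ``diagnostics``.
    """
    spec = spec if spec is not None else ModelSpec()
    mcmc = mcmc if mcmc is not None else MCMCSettings()
    if calendar is None:
        years = series.week_starts
        calendar = build_holiday_calendar(years[0].year, years[-1].year + 1)
    model = CountModel(series, calendar, spec)

    results = []
    for c in range(mcmc.chains):
        # the "fit" substream family: disjoint from the generator streams
        rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 1000 + c]))
        init = model.initial_theta(rng)
        res = sample_chain(
            model.logp_and_grad, init, rng,
            warmup=mcmc.warmup, draws=mcmc.draws,
            max_leapfrog=mcmc.max_leapfrog, target_accept=mcmc.target_accept,
        )
        logger.info(
            "chain %d: accept=%.2f step=%.3g divergent=%d",
            c, res.accept_rate, res.step_size, res.n_divergent,
        )
        results.append(res)

    thetas = np.stack([r.samples for r in results])
    draws = PosteriorDraws(model=model, thetas=thetas)
    draws.params = _constrain_all(model, thetas)
    draws.chain_stats = pd.DataFrame(
        {
            "chain": range(mcmc.chains),
            "accept_rate": [r.accept_rate for r in results],
            "step_size": [r.step_size for r in results],
            "n_divergent": [r.n_divergent for r in results],
        }
    )
    draws.diagnostics = _diagnostics(draws)
    return draws


def _diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    import arviz as az

    monitored = {}
    for name in ("sigma_beta", "sigma_omega", "sigma_eps", "beta_H"):
        monitored[name] = draws.params[name]
    for g, label in enumerate(draws.groups):
        monitored[f"d0[{label}]"] = draws.params["d0"][:, :, g]
        monitored[f"d1[{label}]"] = draws.params["d1"][:, :, g]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=monitored)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = [
        {
            "parameter": name,
            "rhat": float(rhat[name].values),
            "ess_bulk": float(ess[name].values),
        }
        for name in monitored
    ]
    return pd.DataFrame(rows)


def rhat_of(draws_matrix: np.ndarray) -> float:
    """Split R-hat of a (chains, draws) array of a scalar quantity."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(az.from_dict(posterior={"x": draws_matrix}))["x"].values)


# ---------------------------------------------------------------------------
# counterfactual posterior predictive


@dataclass
class CounterfactualPrediction:
    """Posterior-predictive draws under the full and no-interruption models.

    ``yhat`` is drawn from the fitted model, ``yhat_o`` from the
    undisturbed level alone (tau forced to 1) with the same holiday,
    seasonal, and per-draw noise terms, so ``ydiff = yhat_o - yhat``
    isolates the interruption effect. Where the two Poisson means agree
    (every week outside the interruption envelope) the same variate is
    used, making ``ydiff`` exactly zero there.
    """

    yhat: np.ndarray  # (chains, draws, groups, weeks)
    yhat_o: np.ndarray
    ydiff: np.ndarray
    weights: np.ndarray  # 1 - tau per draw
    groups: list[str]
    week_starts: pd.DatetimeIndex


def counterfactual(draws: PosteriorDraws, seed: int | None = None) -> CounterfactualPrediction:
    """Generate paired posterior-predictive draws y-hat and y-hat-naught."""
    p = draws.params
    model = draws.model
    H = model.H[None, None, None, :]
    sterm = np.einsum("tk,cdk->cdt", model.S, p["beta_S"])[:, :, None, :]
    shared = H * p["beta_H"][:, :, None, None] + sterm + p["eps"]
    mu_full = p["tau"] * p["beta"] + (1.0 - p["tau"]) * p["omega"]
    lam_full = np.exp(mu_full + shared)
    lam_cf = np.exp(p["beta"] + shared)
    rng = np.random.default_rng(
        np.random.SeedSequence([draws.model.G, 7, seed if seed is not None else 0])
    )
    yhat_o = rng.poisson(lam_cf).astype(float)
    same = lam_full == lam_cf
    yhat = np.where(same, yhat_o, rng.poisson(lam_full)).astype(float)
    return CounterfactualPrediction(
        yhat=yhat,
        yhat_o=yhat_o,
        ydiff=yhat_o - yhat,
        weights=1.0 - p["tau"],
        groups=list(draws.groups),
        week_starts=draws.week_starts,
    )


# ---------------------------------------------------------------------------
# missed/delayed visit estimates


@dataclass
class MissedVisitEstimate:
    """Missed-visit totals and percentages, point estimates and 95% CrIs.

    ``table`` has one row per group (plus ``overall`` when several groups
    are present); ``pct_draws`` keeps the per-draw percentage paths
    (chains, draws, groups[+overall]) for downstream group contrasts.
    """

    table: pd.DataFrame
    pct_draws: np.ndarray
    labels: list[str]


def credible_interval(x, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail interval from empirical percentiles of MCMC draws."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no draws supplied")
    half = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(x, [half, 100.0 - half])
    return float(lo), float(hi)


def missed_visits(cf: CounterfactualPrediction, level: float = 0.95) -> MissedVisitEstimate:
    """Interruption-weighted missed-visit sums and percentage drops.

    Per draw, the number missed in group *i* is ``sum_t (1 - tau_t) *
    ydiff_it`` and the percentage is 100 times that over the matching
    weighted counterfactual sum; point estimates are posterior means and
    intervals come from the 2.5th/97.5th draw percentiles with the upper
    bound truncated at 100%.
    """
    w = cf.weights
    num = np.sum(w * cf.ydiff, axis=3)  # (C, D, G)
    den = np.sum(w * cf.yhat_o, axis=3)
    if np.any(den == 0):
        raise ValueError("zero counterfactual denominator: no interruption-weighted mass")
    labels = list(cf.groups)
    if len(labels) > 1:
        num = np.concatenate([num, num.sum(axis=2, keepdims=True)], axis=2)
        den = np.concatenate([den, den.sum(axis=2, keepdims=True)], axis=2)
        labels = labels + ["overall"]
    pct = 100.0 * num / den
    rows = []
    for g, label in enumerate(labels):
        lo, hi = credible_interval(pct[:, :, g], level)
        rows.append(
            {
                "group": label,
                "n_missed": float(num[:, :, g].mean()),
                "pct_missed": float(np.clip(pct[:, :, g].mean(), 0.0, 100.0)),
                "pct_lo": float(np.clip(lo, 0.0, 100.0)),
                "pct_hi": float(min(hi, 100.0)),
            }
        )
    return MissedVisitEstimate(table=pd.DataFrame(rows), pct_draws=pct, labels=labels)


# ---------------------------------------------------------------------------
# interruption window


def estimate_window(
    draws: PosteriorDraws,
    tau_threshold: float = 0.5,
    prob_threshold: float = 0.975,
) -> pd.DataFrame:
    """Report, per group, the first and last interrupted week.

    A week counts as interrupted when the posterior probability that the
    interruption weight ``1 - tau_t`` exceeds ``tau_threshold`` is at least
    ``prob_threshold``. Groups where no week qualifies get
    ``"no interruption detected"``.
    """
    pr = np.mean(1.0 - draws.params["tau"] > tau_threshold, axis=(0, 1))  # (G, T)
    rows = []
    for g, label in enumerate(draws.groups):
        hits = np.flatnonzero(pr[g] >= prob_threshold)
        if hits.size == 0:
            rows.append({"group": label, "detected": False,
                         "first_week": NO_INTERRUPTION, "last_week": NO_INTERRUPTION})
        else:
            rows.append({
                "group": label,
                "detected": True,
                "first_week": str(draws.week_starts[hits[0]].date()),
                "last_week": str(draws.week_starts[hits[-1]].date()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group contrast test


@dataclass
class GroupContrastTest:
    statistic: float
    df: int
    p_value: float
    reference: str
    rank: int


def wald_group_test(
    pct_draws: np.ndarray, groups: list[str], reference: str | None = None
) -> GroupContrastTest:
    """Posterior Wald-type chi-square test of equal group drop percentages.

    Builds the (G-1)-vector of posterior-mean differences of each group's
    drop percentage from the reference group, and the posterior covariance
    of those per-draw differences; the statistic ``c' Sigma^-1 c`` is
    referred to a chi-square with G-1 degrees of freedom.
    """
    pct = np.asarray(pct_draws, dtype=float)
    pct = pct.reshape(-1, pct.shape[-1])
    if len(groups) < 2:
        raise ValueError("need at least two groups to contrast")
    if reference is None:
        reference = sorted(groups)[0]
    ref_idx = groups.index(reference)
    others = [g for g in range(len(groups)) if g != ref_idx]
    contrasts = pct[:, others] - pct[:, [ref_idx]]  # (N, G-1)
    c = contrasts.mean(axis=0)
    sigma = np.cov(contrasts, rowvar=False).reshape(len(others), len(others))
    rank = int(np.linalg.matrix_rank(sigma))
    if rank < len(others):
        warnings.warn(
            f"singular contrast covariance (rank {rank} of {len(others)}); using pseudo-inverse"
        )
        stat = float(c @ np.linalg.pinv(sigma) @ c)
    else:
        stat = float(c @ np.linalg.solve(sigma, c))
    stat = max(stat, 0.0)
    dof = len(others)
    return GroupContrastTest(
        statistic=stat, df=dof, p_value=float(stats.chi2.sf(stat, dof)),
        reference=reference, rank=rank,
    )


# ---------------------------------------------------------------------------
# tidy exports


def weekly_prediction_summary(cf: CounterfactualPrediction, series: WeeklyCounts) -> pd.DataFrame:
    """Per group-week posterior mean and 95% bands of y-hat and y-hat-naught."""
    rows = []
    for g, label in enumerate(cf.groups):
        for t, wk in enumerate(cf.week_starts):
            yh = cf.yhat[:, :, g, t].ravel()
            yo = cf.yhat_o[:, :, g, t].ravel()
            rows.append({
                "group": label,
                "week_start": str(pd.Timestamp(wk).date()),
                "observed": int(series.counts[g, t]),
                "yhat_mean": yh.mean(),
                "yhat_lo": np.percentile(yh, 2.5),
                "yhat_hi": np.percentile(yh, 97.5),
                "yhat_cf_mean": yo.mean(),
                "yhat_cf_lo": np.percentile(yo, 2.5),
                "yhat_cf_hi": np.percentile(yo, 97.5),
            })
    return pd.DataFrame(rows)


def fit_summary(
    draws: PosteriorDraws,
    cf: CounterfactualPrediction,
    tau_threshold: float = 0.5,
    prob_threshold: float = 0.975,
) -> dict:
    """Assemble the per-group window/missed-visit summary as a JSON-able dict."""
    window = estimate_window(draws, tau_threshold, prob_threshold)
    missed = missed_visits(cf)
    out = {"groups": {}, "diagnostics": draws.diagnostics.to_dict("records")}
    for _, row in missed.table.iterrows():
        out["groups"][row["group"]] = {
            "n_missed": row["n_missed"],
            "pct_missed": row["pct_missed"],
            "pct_ci": [row["pct_lo"], row["pct_hi"]],
        }
    for _, row in window.iterrows():
        out["groups"][row["group"]].update(
            first_week=row["first_week"], last_week=row["last_week"],
            detected=bool(row["detected"]),
        )
    if len(draws.groups) > 1:
        g_idx = [missed.labels.index(g) for g in draws.groups]
        test = wald_group_test(missed.pct_draws[:, :, g_idx], list(draws.groups))
        out["group_test"] = {
            "statistic": test.statistic, "df": test.df,
            "p_value": test.p_value, "reference": test.reference,
        }
    return out
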