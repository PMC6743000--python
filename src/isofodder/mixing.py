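"""Bayesian two-source, single-tracer stable-isotope mixing model.

Estimates the C4 (millet) dietary fraction ``p`` of a consumer group from
spacing-corrected dietary delta13C observations.  Each observation ``x_i`` is
modelled as

    x_i ~ Normal( p*mu_C4 + (1-p)*mu_C3,
                  p^2*sd_C4^2 + (1-p)^2*sd_C3^2 + sigma_res^2 )

with a uniform prior on ``p`` over [0, 1] (the two-source Dirichlet(1, 1)
default of isotope mixing practice) and a uniform prior on the residual
standard deviation ``sigma_res`` over [0, sigma_max].  Source means and
standard deviations are treated as known summaries of the end-member data.
Groups (site x period x bimonth, or "lifetime") are fully independent fixed
effects: no pooling.

Two engines return identical summaries within Monte-Carlo error:

``grid``
    Deterministic 2-D trapezoid quadrature over (p, sigma_res); the
    reference/oracle engine.
``mcmc``
    Random-walk Metropolis on (logit p, log sigma_res), several chains with
    the first half of each discarded as warm-up, with split-R-hat and
    effective-sample-size diagnostics.  Runs failing R-hat <= 1.01 are
    flagged, never silently returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .sources import DietSource

__all__ = [
    "MixResult",
    "TwoSourceMixingModel",
    "posterior_c4_fraction",
    "run_mixing_by_group",
    "sensitivity_scan",
    "split_rhat",
    "effective_sample_size",
]

RHAT_THRESHOLD = 1.01


@dataclass
class MixResult:
    """Posterior summary for one group's C4 dietary fraction."""

    group: dict
    n_obs: int
    p_mean: float
    p_median: float
    p_lo90: float
    p_hi90: float
    sigma_res_mean: float
    engine: str
    chains: int = 0
    draws: int = 0
    rhat_p: float = float("nan")
    rhat_sigma: float = float("nan")
    ess_p: float = float("nan")
    ess_sigma: float = float("nan")
    seed: int | None = None
    converged: bool = True

    def to_row(self) -> dict:
        row = dict(self.group)
        row.update(
            n=self.n_obs,
            p_mean=self.p_mean,
            p_median=self.p_median,
            p_lo90=self.p_lo90,
            p_hi90=self.p_hi90,
            sigma_res_mean=self.sigma_res_mean,
            engine=self.engine,
            rhat=max(
                self.rhat_p if math.isfinite(self.rhat_p) else 1.0,
                self.rhat_sigma if math.isfinite(self.rhat_sigma) else 1.0,
            ),
            seed=self.seed,
            converged=self.converged,
        )
        return row


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat potential-scale-reduction diagnostic.

    `chains` has shape (n_chains, n_draws); each chain is split in half so
    within-chain drift also inflates the statistic.
    """
    chains = np.asarray(chains, dtype=float)
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial-positive-sequence estimator."""
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    centered = chains - chains.mean(axis=1, keepdims=True)
    # per-chain autocovariance by FFT, averaged over chains
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    fft = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(fft * np.conj(fft), n=size, axis=1)[:, :n].real
    acov /= n
    var = acov[:, 0].mean()
    if var <= 0:
        return float(m * n)
    rho = acov.mean(axis=0) / var
    # sum consecutive pairs while they stay positive
    tau = 1.0
    for lag in range(1, n - 1, 2):
        pair = rho[lag] + rho[lag + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(m * n / tau)


class TwoSourceMixingModel(BaseEstimator):
    """Scikit-learn-style estimator for the two-source mixing posterior.

    Parameters
    ----------
    c3, c4 : DietSource
        Dietary end-members; ``c4.mean`` must exceed ``c3.mean``.
    engine : {"grid", "mcmc"}
        Deterministic quadrature or random-walk Metropolis.
    sigma_max : float, default 5.0
        Upper bound of the uniform prior on the residual sd, permil.
    grid_size : int, default 401
        Nodes per axis for the quadrature engine.
    draws : int, default 20000
        MCMC iterations per chain (first half discarded as warm-up).
    chains : int, default 6
    random_state : int or None
        Seed for the MCMC engine; the grid engine is deterministic.

    Attributes (after ``fit``)
    --------------------------
    p_mean_, p_median_, p_lo90_, p_hi90_, sigma_res_mean_ : float
    rhat_p_, rhat_sigma_, ess_p_, ess_sigma_ : float (MCMC only)
    converged_ : bool
    result_ : MixResult
    """

    def __init__(
        self,
        c3: DietSource = None,
        c4: DietSource = None,
        engine: str = "grid",
        sigma_max: float = 5.0,
        grid_size: int = 401,
        draws: int = 20000,
        chains: int = 6,
        random_state=None,
    ):
        self.c3 = c3
        self.c4 = c4
        self.engine = engine
        self.sigma_max = sigma_max
        self.grid_size = grid_size
        self.draws = draws
        self.chains = chains
        self.random_state = random_state

    # -- model ---------------------------------------------------------------

    def _check_sources(self):
        if self.c3 is None or self.c4 is None:
            raise ValueError("both c3 and c4 sources are required")
        if not self.c4.mean > self.c3.mean:
            raise ValueError(
                "sources not separable: C4 mean must exceed C3 mean "
                f"({self.c4.mean} <= {self.c3.mean})"
            )

    def _loglik(self, x, p, sigma2):
        """Summed log-likelihood; `p` and `sigma2` broadcast together."""
        mean = p * self.c4.mean + (1.0 - p) * self.c3.mean
        var = p**2 * self.c4.sd**2 + (1.0 - p) ** 2 * self.c3.sd**2 + sigma2
        out = 0.0
        for xi in x:
            out = out - 0.5 * ((xi - mean) ** 2 / var + np.log(2.0 * np.pi * var))
        return out

    # -- engines -------------------------------------------------------------

    def _fit_grid(self, x):
        gp = np.linspace(0.0, 1.0, self.grid_size)
        gs = np.linspace(0.0, self.sigma_max, self.grid_size)
        ll = self._loglik(x, gp[:, None], gs[None, :] ** 2)
        post = np.exp(ll - ll.max())
        margin_p = np.trapezoid(post, gs, axis=1)
        margin_s = np.trapezoid(post, gp, axis=0)
        zp = np.trapezoid(margin_p, gp)
        dens = margin_p / zp
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(gp))]
        )
        cdf /= cdf[-1]

        def quantile(q):
            return float(np.interp(q, cdf, gp))

        self.p_mean_ = float(np.trapezoid(gp * dens, gp))
        self.p_median_ = quantile(0.5)
        self.p_lo90_ = quantile(0.05)
        self.p_hi90_ = quantile(0.95)
        zs = np.trapezoid(margin_s, gs)
        self.sigma_res_mean_ = float(np.trapezoid(gs * margin_s / zs, gs))
        self.rhat_p_ = self.rhat_sigma_ = float("nan")
        self.ess_p_ = self.ess_sigma_ = float("nan")
        self.converged_ = True
        self.n_draws_kept_ = 0

    def _log_posterior(self, x, logit_p, log_sigma):
        p = 1.0 / (1.0 + np.exp(-logit_p))
        sigma = np.exp(log_sigma)
        lp = self._loglik(x, p, sigma**2)
        # Jacobians: uniform p -> logit scale adds log p(1-p); uniform sigma
        # on (0, sigma_max] -> log scale adds log sigma.
        lp = lp + np.log(p) + np.log1p(-p) + log_sigma
        return np.where(sigma < self.sigma_max, lp, -np.inf)

    def _fit_mcmc(self, x):
        rng = np.random.default_rng(self.random_state)
        n_chains = int(self.chains)
        if n_chains < 3:
            raise ValueError("mcmc engine requires >= 3 chains")
        draws = int(self.draws)
        warmup = draws // 2
        # over-dispersed starts
        theta = np.column_stack(
            [
                rng.uniform(-2.0, 2.0, n_chains),
                np.log(rng.uniform(0.2, 0.8 * self.sigma_max, n_chains)),
            ]
        )
        logp = self._log_posterior(x, theta[:, 0], theta[:, 1])
        # adaptive-covariance random walk: during warm-up the proposal
        # covariance tracks the pooled chain covariance (scaled by the
        # classic 2.38^2/d factor) and a per-chain scalar is tuned to a
        # ~30% acceptance rate; both are frozen after warm-up
        chol = 0.5 * np.eye(2)
        log_scale = np.zeros(n_chains)
        kept = np.empty((n_chains, draws - warmup, 2))
        warm_hist = np.empty((n_chains, warmup, 2))
        accept_win = np.zeros(n_chains)
        adapt_block = 100
        for it in range(draws):
            step = (rng.standard_normal((n_chains, 2)) @ chol.T) * np.exp(
                log_scale
            )[:, None]
            prop = theta + step
            logp_prop = self._log_posterior(x, prop[:, 0], prop[:, 1])
            accept = np.log(rng.uniform(size=n_chains)) < logp_prop - logp
            theta[accept] = prop[accept]
            logp[accept] = logp_prop[accept]
            accept_win += accept
            if it < warmup:
                warm_hist[:, it] = theta
                if (it + 1) % adapt_block == 0:
                    rate = accept_win / adapt_block
                    log_scale += 0.7 * (rate - 0.3)
                    accept_win[:] = 0.0
                    if it + 1 >= warmup // 2:
                        recent = warm_hist[:, (it + 1) // 2 : it + 1].reshape(-1, 2)
                        cov = np.cov(recent.T) + 1e-10 * np.eye(2)
                        chol = np.linalg.cholesky(cov * (2.38**2 / 2.0))
            else:
                kept[:, it - warmup] = theta
        p_draws = 1.0 / (1.0 + np.exp(-kept[..., 0]))
        s_draws = np.exp(kept[..., 1])
        self.rhat_p_ = split_rhat(p_draws)
        self.rhat_sigma_ = split_rhat(s_draws)
        self.ess_p_ = effective_sample_size(p_draws)
        self.ess_sigma_ = effective_sample_size(s_draws)
        self.converged_ = bool(
            self.rhat_p_ <= RHAT_THRESHOLD and self.rhat_sigma_ <= RHAT_THRESHOLD
        )
        flat = p_draws.reshape(-1)
        self.p_mean_ = float(flat.mean())
        self.p_median_ = float(np.median(flat))
        self.p_lo90_ = float(np.quantile(flat, 0.05))
        self.p_hi90_ = float(np.quantile(flat, 0.95))
        self.sigma_res_mean_ = float(s_draws.mean())
        self.n_draws_kept_ = int(flat.size)

    # -- API -----------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the posterior to dietary delta13C observations (1-d array)."""
        self._check_sources()
        x = np.asarray(X, dtype=float).reshape(-1)
        if x.size < 1:
            raise ValueError("need at least one observation")
        if not np.isfinite(x).all():
            raise ValueError("non-finite observations")
        if self.engine == "grid":
            if self.grid_size < 400:
                raise ValueError("grid engine requires >= 400 nodes per axis")
            self._fit_grid(x)
        elif self.engine == "mcmc":
            self._fit_mcmc(x)
        else:
            raise ValueError(f"unknown engine {self.engine!r}")
        self.n_obs_ = int(x.size)
        self.result_ = MixResult(
            group={},
            n_obs=self.n_obs_,
            p_mean=self.p_mean_,
            p_median=self.p_median_,
            p_lo90=self.p_lo90_,
            p_hi90=self.p_hi90_,
            sigma_res_mean=self.sigma_res_mean_,
            engine=self.engine,
            chains=self.chains if self.engine == "mcmc" else 0,
            draws=self.draws if self.engine == "mcmc" else 0,
            rhat_p=self.rhat_p_,
            rhat_sigma=self.rhat_sigma_,
            ess_p=self.ess_p_,
            ess_sigma=self.ess_sigma_,
            seed=self.random_state,
            converged=self.converged_,
        )
        return self

    def predict(self, X=None):
        """Posterior-mean mixture delta13C (a convenience for pipelines)."""
        p = self.p_mean_
        value = p * self.c4.mean + (1.0 - p) * self.c3.mean
        if X is None:
            return value
        return np.full(np.asarray(X).shape[0], value)


def posterior_c4_fraction(
    observations,
    sources: tuple[DietSource, DietSource],
    sigma_max: float = 5.0,
    engine: str = "grid",
    seed=None,
    draws: int = 20000,
    chains: int = 6,
    grid_size: int = 401,
    group: dict | None = None,
) -> MixResult:
    """Posterior C4 dietary fraction for one group of dietary delta13C values.

    ``sources`` is the (C3, C4) pair.  See :class:`TwoSourceMixingModel` for
    the model and engines.
    """
    c3, c4 = sources
    model = TwoSourceMixingModel(
        c3=c3,
        c4=c4,
        engine=engine,
        sigma_max=sigma_max,
        grid_size=grid_size,
        draws=draws,
        chains=chains,
        random_state=seed,
    ).fit(observations)
    result = model.result_
    result.group = dict(group or {})
    return result


def run_mixing_by_group(
    table: pd.DataFrame,
    sources: tuple[DietSource, DietSource],
    group_cols=("site", "period", "bimonth"),
    value_col: str = "dietary_d13C",
    sigma_max: float = 5.0,
    engine: str = "grid",
    seed=None,
    draws: int = 20000,
    chains: int = 6,
    logger=None,
) -> list[MixResult]:
    """Independent mixing posteriors per group (fixed-effects semantics).

    Each distinct combination of `group_cols` is fitted in isolation; groups
    with no finite observations are skipped with a logged warning.  When the
    mcmc engine is used, per-group seeds are derived deterministically from
    `seed` and the group key so groups remain independent and reproducible.
    """
    results = []
    keys = list(group_cols)
    for i, (key, sub) in enumerate(sorted(table.groupby(keys, sort=True))):
        if not isinstance(key, tuple):
            key = (key,)
        values = sub[value_col].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        group = dict(zip(keys, key))
        if values.size == 0:
            if logger is not None:
                logger.warning("skipping empty group %s", group)
            continue
        group_seed = None if seed is None else (int(seed) + 7919 * i) % (2**31)
        results.append(
            posterior_c4_fraction(
                values,
                sources,
                sigma_max=sigma_max,
                engine=engine,
                seed=group_seed,
                draws=draws,
                chains=chains,
                group=group,
            )
        )
    return results


def results_table(results: list[MixResult]) -> pd.DataFrame:
    """Flatten MixResults into the output table schema."""
    return pd.DataFrame([r.to_row() for r in results])


def sensitivity_scan(
    tissue_value: float,
    spacings,
    c3_sources,
    c4_sources,
    tissue_kind: str = "enamel",
    sigma_max: float = 5.0,
    grid_size: int = 401,
) -> pd.DataFrame:
    """Posterior C4 fraction of one tissue value across parameterizations.

    Because diet–tissue spacing factors and end-member summaries are the
    least constrained inputs, this deterministic scan documents which
    combinations of spacing and source parameters map a given tissue
    delta13C (for example the winter enamel exemplar of -6 permil) to which
    posterior C4 fractions.  Pure function of its inputs (grid engine only).

    Returns a frame with one row per (spacing, C3 source, C4 source)
    combination: the parameterization, the implied dietary delta13C, and the
    posterior mean/median/90% interval.
    """
    spacings = list(spacings)
    c3_sources = list(c3_sources)
    c4_sources = list(c4_sources)
    if not (spacings and c3_sources and c4_sources):
        raise ValueError("empty sensitivity grid")
    rows = []
    for spacing in spacings:
        diet = float(tissue_value) - float(spacing)
        for c3 in c3_sources:
            for c4 in c4_sources:
                res = posterior_c4_fraction(
                    [diet],
                    (c3, c4),
                    sigma_max=sigma_max,
                    engine="grid",
                    grid_size=grid_size,
                )
                rows.append(
                    {
                        "tissue_value": float(tissue_value),
                        "tissue_kind": tissue_kind,
                        "spacing": float(spacing),
                        "c3_mean": c3.mean,
                        "c3_sd": c3.sd,
                        "c4_mean": c4.mean,
                        "c4_sd": c4.sd,
                        "dietary_d13C": diet,
                        "p_mean": res.p_mean,
                        "p_median": res.p_median,
                        "p_lo90": res.p_lo90,
                        "p_hi90": res.p_hi90,
                    }
                )
    return pd.DataFrame(rows)
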