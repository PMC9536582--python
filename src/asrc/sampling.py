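"""Posterior sampling for the per-participant model families.

The sampler is an adaptive Metropolis-within-Gibbs scheme over per-
participant parameter vectors, run in two modes:

* ``independent`` — each participant's parameters get a fixed weakly
  informative prior (uniform over the support for interval-valued
  parameters, Normal(0, sd) for unconstrained ones) and are updated
  component-wise by random-walk Metropolis;
* ``hierarchical`` — interval-valued parameters (mapped affinely onto the
  unit interval) are given Beta population distributions and unconstrained
  parameters Normal population distributions, whose hyperparameters are
  sampled alongside the individual parameters with their own Metropolis
  moves on the log scale.

Proposal scales adapt during warmup toward a 0.44 acceptance rate (the
optimum for one-dimensional updates) and are frozen afterwards.  Given a
seed, runs are exactly reproducible.  Convergence diagnostics (split-R-hat
and effective sample size) are computed with ArviZ; R-hat above 1.05
triggers a warning, not a failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

__all__ = ["ParamSpec", "PopulationPrior", "PosteriorSamples", "sample_posterior"]

_TARGET_ACCEPT = 0.44
_ADAPT_WINDOW = 25
RHAT_WARN = 1.05


@dataclass(frozen=True)
class ParamSpec:
    """Names and supports of one participant's parameter vector.

    Supports are ``('unit',)`` for [0, 1] parameters, ``('interval', lo,
    hi)`` for other bounded parameters, and ``('real',)`` for unconstrained
    ones.  ``real_prior_sd`` is the prior scale used for unconstrained
    parameters in independent fits.
    """

    names: Sequence[str]
    supports: Sequence[tuple]
    real_prior_sd: float = 1.0

    def __post_init__(self) -> None:
        if len(self.names) != len(self.supports):
            raise ValueError("names and supports must have equal length")
        for s in self.supports:
            if s[0] not in ("unit", "interval", "real"):
                raise ValueError(f"unknown support {s!r}")

    @property
    def k(self) -> int:
        return len(self.names)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(self.k)
        hi = np.empty(self.k)
        for i, s in enumerate(self.supports):
            if s[0] == "unit":
                lo[i], hi[i] = 0.0, 1.0
            elif s[0] == "interval":
                lo[i], hi[i] = s[1], s[2]
            else:
                lo[i], hi[i] = -np.inf, np.inf
        return lo, hi


@dataclass(frozen=True)
class PopulationPrior:
    """Hyperpriors of the hierarchical mode.

    Beta hyperparameters (for interval-valued parameters) get Gamma(shape,
    scale) priors; Normal population means get Normal(0, ``mu_scale``) and
    population standard deviations half-Normal(``sigma_scale``) priors.
    """

    gamma_shape: float = 2.0
    gamma_scale: float = 2.0
    mu_scale: float = 5.0
    sigma_scale: float = 2.5

    def __post_init__(self) -> None:
        if min(self.gamma_shape, self.gamma_scale, self.mu_scale, self.sigma_scale) <= 0:
            raise ValueError("all hyperprior scales must be > 0")


@dataclass
class PosteriorSamples:
    """Posterior draws plus sampler metadata.

    ``individual`` has shape (chains, draws, participants, params) in the
    parameters' native spaces; ``hyper`` (hierarchical mode only) has shape
    (chains, draws, params, 2) holding (a, b) for Beta-distributed and
    (mu, sigma) for Normal-distributed parameters.
    """

    individual: np.ndarray
    hyper: np.ndarray | None
    param_spec: ParamSpec
    mode: str
    seed: int
    config: dict
    n_rejected_nonfinite: int = 0
    _diagnostics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.individual.shape[0]

    @property
    def n_draws(self) -> int:
        return self.individual.shape[1]

    @property
    def individual_flat(self) -> np.ndarray:
        """(samples, participants, params), chains concatenated."""
        c, d, p, k = self.individual.shape
        return self.individual.reshape(c * d, p, k)

    @property
    def hyper_flat(self) -> np.ndarray | None:
        if self.hyper is None:
            return None
        c, d, k, two = self.hyper.shape
        return self.hyper.reshape(c * d, k, two)

    def diagnostics(self) -> pd.DataFrame:
        """Split-R-hat and bulk ESS per (participant, parameter)."""
        if self._diagnostics is None:
            import arviz as az

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = az.rhat(az.convert_to_dataset(self.individual))["x"].values
                ess = az.ess(az.convert_to_dataset(self.individual))["x"].values
            p, k = rhat.shape
            self._diagnostics = pd.DataFrame(
                {
                    "participant": np.repeat(np.arange(p), k),
                    "param": np.tile(np.asarray(self.param_spec.names), p),
                    "rhat": rhat.ravel(),
                    "ess": ess.ravel(),
                }
            )
        return self._diagnostics

    def posterior_mean(self) -> np.ndarray:
        """(participants, params) arithmetic mean over all samples."""
        return self.individual_flat.mean(axis=0)

    def summary(self) -> pd.DataFrame:
        """Per-parameter summary pooled across participants."""
        flat = self.individual_flat  # (S, P, K)
        diag = self.diagnostics()
        rows = []
        for i, name in enumerate(self.param_spec.names):
            d = diag[diag["param"] == name]
            rows.append(
                {
                    "param": name,
                    "mean": float(flat[:, :, i].mean()),
                    "sd": float(flat[:, :, i].std(ddof=1)),
                    "rhat_max": float(d["rhat"].max()),
                    "ess_min": float(d["ess"].min()),
                }
            )
        return pd.DataFrame(rows).set_index("param")


def _beta_logpdf(u: np.ndarray, a: float, b: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - 1.0) * np.log(u) + (b - 1.0) * np.log1p(-u) - betaln(a, b)
    return np.where((u > 0) & (u < 1), out, -np.inf)


def _gamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return (shape - 1.0) * np.log(x) - x / scale - gammaln(shape) - shape * np.log(scale)


def sample_posterior(
    loglik: Callable[[int, np.ndarray], float],
    n_participants: int,
    param_spec: ParamSpec,
    mode: str = "hierarchical",
    draws: int = 300,
    warmup: int | None = None,
    chains: int = 2,
    seed: int = 0,
    hyperprior: PopulationPrior | None = None,
) -> PosteriorSamples:
    """Draw posterior samples for all participants.

    ``loglik(p, theta)`` must return the log-likelihood of participant
    ``p``'s data under parameter vector ``theta`` (native space).  Non-
    finite proposals are rejected and counted; a count above zero raises a
    warning at the end rather than failing the run.
    """
    if mode not in ("hierarchical", "independent"):
        raise ValueError("mode must be 'hierarchical' or 'independent'")
    if n_participants < 1:
        raise ValueError("at least one participant is required")
    if draws < 2:
        raise ValueError("need at least 2 draws")
    if warmup is None:
        warmup = draws
    if chains < 1:
        raise ValueError("need at least 1 chain")
    hp = hyperprior or PopulationPrior()
    k = param_spec.k
    lo, hi = param_spec.bounds()
    is_bounded = np.isfinite(lo)
    width = np.where(is_bounded, hi - lo, 1.0)

    seeds = np.random.SeedSequence(seed).spawn(chains)
    ind_chains = np.empty((chains, draws, n_participants, k))
    hyp_chains = np.empty((chains, draws, k, 2)) if mode == "hierarchical" else None
    n_nonfinite = 0

    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        theta = np.empty((n_participants, k))
        for i in range(k):
            if is_bounded[i]:
                theta[:, i] = lo[i] + width[i] * rng.uniform(0.35, 0.65, size=n_participants)
            else:
                theta[:, i] = 0.1 * rng.standard_normal(n_participants)
        # hyper[i] = (a, b) for bounded params, (mu, sigma) for real params
        hyper = np.empty((k, 2))
        hyper[is_bounded] = (2.0, 2.0)
        hyper[~is_bounded] = (0.0, 1.0)

        def log_prior_one(i: int, x: float) -> float:
            if is_bounded[i]:
                if not (lo[i] < x < hi[i]):
                    return -np.inf
                u = (x - lo[i]) / width[i]
                if mode == "independent":
                    return 0.0
                return float(_beta_logpdf(np.asarray(u), hyper[i, 0], hyper[i, 1]))
            if mode == "independent":
                sd = param_spec.real_prior_sd
            else:
                x = x - hyper[i, 0]
                sd = hyper[i, 1]
            return float(-0.5 * (x / sd) ** 2 - np.log(sd))

        cur_ll = np.empty(n_participants)
        for p in range(n_participants):
            cur_ll[p] = loglik(p, theta[p])
            if not np.isfinite(cur_ll[p]):
                raise RuntimeError(f"non-finite log-likelihood at initialisation (participant {p})")

        scales = np.where(is_bounded[None, :], 0.1 * width[None, :], 0.5) * np.ones(
            (n_participants, k)
        )
        hyper_scales = np.full((k, 2), 0.3)
        acc = np.zeros((n_participants, k))
        hyper_acc = np.zeros((k, 2))

        total_iters = warmup + draws
        for it in range(total_iters):
            adapting = it < warmup
            # --- individual parameters, component-wise random walk ---
            noise = rng.standard_normal((n_participants, k))
            unif = rng.random((n_participants, k))
            for p in range(n_participants):
                for i in range(k):
                    x_old = theta[p, i]
                    x_new = x_old + scales[p, i] * noise[p, i]
                    lp_new = log_prior_one(i, x_new)
                    if lp_new == -np.inf:
                        continue
                    lp_old = log_prior_one(i, x_old)
                    theta[p, i] = x_new
                    ll_new = loglik(p, theta[p])
                    if not np.isfinite(ll_new):
                        n_nonfinite += 1
                        theta[p, i] = x_old
                        continue
                    if np.log(unif[p, i]) < (ll_new + lp_new) - (cur_ll[p] + lp_old):
                        cur_ll[p] = ll_new
                        acc[p, i] += 1
                    else:
                        theta[p, i] = x_old

            # --- hyperparameters (hierarchical mode) ---
            if mode == "hierarchical":
                for i in range(k):
                    if is_bounded[i]:
                        u = (theta[:, i] - lo[i]) / width[i]
                        for j in range(2):  # a then b
                            old = hyper[i, j]
                            new = old * np.exp(hyper_scales[i, j] * rng.standard_normal())
                            ab_new = hyper[i].copy()
                            ab_new[j] = new
                            t_old = (
                                _beta_logpdf(u, hyper[i, 0], hyper[i, 1]).sum()
                                + _gamma_logpdf(old, hp.gamma_shape, hp.gamma_scale)
                                + np.log(old)
                            )
                            t_new = (
                                _beta_logpdf(u, ab_new[0], ab_new[1]).sum()
                                + _gamma_logpdf(new, hp.gamma_shape, hp.gamma_scale)
                                + np.log(new)
                            )
                            if np.log(rng.random()) < t_new - t_old:
                                hyper[i, j] = new
                                hyper_acc[i, j] += 1
                    else:
                        x = theta[:, i]
                        mu, sig = hyper[i]
                        # mu: linear random walk
                        mu_new = mu + hyper_scales[i, 0] * rng.standard_normal()
                        t_old = (
                            -0.5 * np.sum(((x - mu) / sig) ** 2)
                            - 0.5 * (mu / hp.mu_scale) ** 2
                        )
                        t_new = (
                            -0.5 * np.sum(((x - mu_new) / sig) ** 2)
                            - 0.5 * (mu_new / hp.mu_scale) ** 2
                        )
                        if np.log(rng.random()) < t_new - t_old:
                            hyper[i, 0] = mu = mu_new
                            hyper_acc[i, 0] += 1
                        # sigma: log-scale random walk with half-Normal prior
                        sig_new = sig * np.exp(hyper_scales[i, 1] * rng.standard_normal())
                        def _sig_target(s):
                            return (
                                -0.5 * np.sum(((x - mu) / s) ** 2)
                                - len(x) * np.log(s)
                                - 0.5 * (s / hp.sigma_scale) ** 2
                                + np.log(s)  # Jacobian of the log-scale walk
                            )
                        if np.log(rng.random()) < _sig_target(sig_new) - _sig_target(sig):
                            hyper[i, 1] = sig_new
                            hyper_acc[i, 1] += 1

            # --- adaptation ---
            if adapting and (it + 1) % _ADAPT_WINDOW == 0:
                rate = acc / _ADAPT_WINDOW
                scales *= np.exp(rate - _TARGET_ACCEPT)
                np.clip(scales, 1e-4, 10.0, out=scales)
                acc[:] = 0
                if mode == "hierarchical":
                    hrate = hyper_acc / _ADAPT_WINDOW
                    hyper_scales *= np.exp(hrate - _TARGET_ACCEPT)
                    np.clip(hyper_scales, 1e-3, 5.0, out=hyper_scales)
                    hyper_acc[:] = 0

            if not adapting:
                d = it - warmup
                ind_chains[c, d] = theta
                if hyp_chains is not None:
                    hyp_chains[c, d] = hyper

    if n_nonfinite:
        warnings.warn(
            f"{n_nonfinite} proposals rejected due to non-finite log-likelihood",
            RuntimeWarning,
        )
    result = PosteriorSamples(
        individual=ind_chains,
        hyper=hyp_chains,
        param_spec=param_spec,
        mode=mode,
        seed=seed,
        config={"draws": draws, "warmup": warmup, "chains": chains},
        n_rejected_nonfinite=n_nonfinite,
    )
    if chains >= 2:
        max_rhat = float(result.diagnostics()["rhat"].max())
        if np.isfinite(max_rhat) and max_rhat > RHAT_WARN:
            warnings.warn(
                f"split-R-hat up to {max_rhat:.3f} exceeds {RHAT_WARN}; "
                "consider more iterations",
                RuntimeWarning,
            )
    return result
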