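"""Rescorla-Wagner models of trial-by-trial skill reports.

A participant is assumed to maintain a latent skill estimate ``s_t`` on the
slider scale [0, 1], updated after every probed outcome by a fraction of the
prediction error ``delta_t = o_t - s_{t-1}``:

    s_t = s_{t-1} + alpha * delta_t          (plus an offset ``beta`` at the
                                              first probe of session 2)

The reported slider value is a noisy Gaussian reading of ``s_t`` with fixed
standard deviation (0.1 by default).  The family contains eight members,
differing only in how the learning rate ``alpha`` is indexed: by session
(S), by outcome valence (O), by attribution class (A: internal / external /
missing), and all combinations, from the single-rate baseline ``b`` up to
``SAO`` with 12 rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SkillModelSpec",
    "SkillParams",
    "LatentTrajectory",
    "SKILL_SPECS",
    "learning_rate_index",
    "predict_trajectory",
    "log_likelihood",
    "SkillModel",
]

_ATTR_CLASSES = ("internal", "external", "missing")
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SkillModelSpec:
    """One member of the eight-model family.

    The number of learning rates is the product of the active factor sizes:
    2 (session) x 2 (outcome) x 3 (attribution class).
    """

    vary_by_session: bool = False
    vary_by_outcome: bool = False
    vary_by_attribution: bool = False

    @property
    def name(self) -> str:
        s = ("S" if self.vary_by_session else "") + (
            "A" if self.vary_by_attribution else ""
        ) + ("O" if self.vary_by_outcome else "")
        return s or "b"

    @property
    def n_rates(self) -> int:
        return (
            (2 if self.vary_by_session else 1)
            * (2 if self.vary_by_outcome else 1)
            * (3 if self.vary_by_attribution else 1)
        )

    @property
    def n_params(self) -> int:
        """Learning rates plus initial skill and session offset."""
        return self.n_rates + 2

    def rate_labels(self) -> list[str]:
        labels = []
        for sess in (1, 2) if self.vary_by_session else (None,):
            for att in _ATTR_CLASSES if self.vary_by_attribution else (None,):
                for out in ("loss", "win") if self.vary_by_outcome else (None,):
                    parts = [p for p in (
                        f"s{sess}" if sess else None,
                        att,
                        out,
                    ) if p]
                    labels.append("alpha[" + ",".join(parts) + "]" if parts else "alpha")
        return labels

    @classmethod
    def from_name(cls, name: str) -> "SkillModelSpec":
        if name == "b":
            return cls()
        if not name or set(name) - set("SAO") or len(set(name)) != len(name):
            raise ValueError(f"unknown skill model name: {name!r}")
        return cls(
            vary_by_session="S" in name,
            vary_by_outcome="O" in name,
            vary_by_attribution="A" in name,
        )


SKILL_SPECS: dict[str, SkillModelSpec] = {
    n: SkillModelSpec.from_name(n) for n in ("b", "S", "O", "A", "SA", "SO", "AO", "SAO")
}


def learning_rate_index(
    spec: SkillModelSpec, session: int, outcome: int, attribution_class: str
) -> int:
    """Deterministic bijection from an (S, O, A) combination to 0..K-1.

    Factors are ordered session-major, then attribution class, then outcome,
    matching :meth:`SkillModelSpec.rate_labels`.  For specs without the A
    factor the attribution class is ignored (any class, including missing,
    is accepted).
    """
    if session not in (1, 2):
        raise ValueError("session must be 1 or 2")
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    if attribution_class not in _ATTR_CLASSES:
        raise ValueError(f"unknown attribution class: {attribution_class!r}")
    idx = 0
    if spec.vary_by_session:
        idx = session - 1
    if spec.vary_by_attribution:
        idx = idx * 3 + _ATTR_CLASSES.index(attribution_class)
    if spec.vary_by_outcome:
        idx = idx * 2 + outcome
    return idx


@dataclass(frozen=True)
class SkillParams:
    """Parameters of one participant under a given spec.

    ``alphas`` is the learning-rate vector (length ``spec.n_rates``), each
    entry in [0, 1]; ``s0`` is the initial latent skill on the slider scale;
    ``session_offset`` is the additive jump applied at the first probe of
    session 2; ``report_noise_sd`` is the fixed Gaussian report noise.
    """

    alphas: np.ndarray
    s0: float = 0.5
    session_offset: float = 0.0
    report_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("all learning rates must lie in [0, 1]")
        if not (0.0 <= self.s0 <= 1.0):
            raise ValueError("s0 must lie in [0, 1]")
        if self.report_noise_sd <= 0:
            raise ValueError("report_noise_sd must be > 0")
        object.__setattr__(self, "alphas", arr)


@dataclass(frozen=True)
class LatentTrajectory:
    latent: np.ndarray  # s_t per probe
    prediction_error: np.ndarray  # delta_t per probe


def _probe_arrays(spec: SkillModelSpec, dataset) -> tuple[np.ndarray, ...]:
    """Precompute (outcome, rate index, session-2-entry flag) per probe."""
    outcome = np.asarray(dataset.outcome, dtype=int)
    session = np.asarray(dataset.session, dtype=int)
    classes = dataset.attribution_class  # array of 'internal'/'external'/'missing'
    idx = np.fromiter(
        (
            learning_rate_index(spec, int(s), int(o), str(c))
            for s, o, c in zip(session, outcome, classes)
        ),
        dtype=int,
        count=len(outcome),
    )
    t0 = np.zeros(len(outcome), dtype=bool)
    second = np.flatnonzero(session == 2)
    if second.size:
        t0[second[0]] = True
    return outcome, idx, t0


def _recursion(
    alphas: np.ndarray,
    s0: float,
    offset: float,
    outcome: np.ndarray,
    idx: np.ndarray,
    t0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(outcome)
    latent = np.empty(n)
    deltas = np.empty(n)
    s = s0
    for t in range(n):
        d = outcome[t] - s
        s = s + alphas[idx[t]] * d
        if t0[t]:
            s += offset
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
        latent[t] = s
        deltas[t] = d
    return latent, deltas


def predict_trajectory(params: SkillParams, spec: SkillModelSpec, dataset) -> LatentTrajectory:
    """Run the update recursion over a participant's probes.

    The latent skill is clipped to the slider range [0, 1] after each
    update; the prediction error is computed from the pre-update value.
    """
    if len(params.alphas) != spec.n_rates:
        raise ValueError(
            f"spec {spec.name} requires {spec.n_rates} learning rates, got {len(params.alphas)}"
        )
    outcome, idx, t0 = _probe_arrays(spec, dataset)
    latent, deltas = _recursion(
        params.alphas, params.s0, params.session_offset, outcome, idx, t0
    )
    return LatentTrajectory(latent=latent, prediction_error=deltas)


def _gauss_loglik(residuals: np.ndarray, sd: float) -> float:
    n = residuals.size
    return float(-0.5 * np.sum(residuals**2) / sd**2 - n * (np.log(sd) + 0.5 * _LOG_2PI))


def log_likelihood(params: SkillParams, spec: SkillModelSpec, dataset) -> float:
    """Exact Gaussian report log-likelihood of a participant's skill reports.

    Probes with a missing skill report contribute nothing, but the latent
    recursion still advances through them.
    """
    traj = predict_trajectory(params, spec, dataset)
    reports = np.asarray(dataset.skill_report, dtype=float)
    valid = np.isfinite(reports)
    ll = _gauss_loglik(reports[valid] - traj.latent[valid], params.report_noise_sd)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite skill log-likelihood")
    return ll


class SkillModel:
    """Skill-report model for a cohort of participants.

    Parameters
    ----------
    datasets : sequence of ParticipantDataset
        Probe-aligned observations, one per participant.
    spec : SkillModelSpec or str
        Which member of the family to fit (e.g. ``"SAO"``).
    report_noise_sd : float
        Fixed report-noise standard deviation (not a free parameter).

    ``fit`` draws posterior samples either independently per participant or
    hierarchically, with Beta population distributions over each parameter
    (the session offset is mapped to the unit interval as ``(beta + 1) / 2``
    so the Beta population prior applies).
    """

    def __init__(self, datasets: Sequence, spec: SkillModelSpec | str = "SAO",
                 report_noise_sd: float = 0.1):
        if isinstance(spec, str):
            spec = SkillModelSpec.from_name(spec)
        if len(datasets) == 0:
            raise ValueError("at least one participant dataset is required")
        self.datasets = list(datasets)
        self.spec = spec
        self.report_noise_sd = float(report_noise_sd)
        self._cache = []
        for ds in self.datasets:
            outcome, idx, t0 = _probe_arrays(spec, ds)
            reports = np.asarray(ds.skill_report, dtype=float)
            valid = np.isfinite(reports)
            self._cache.append((outcome, idx, t0, reports, valid))

    @classmethod
    def from_dataframe(cls, df, spec="SAO", **kwargs) -> "SkillModel":
        from .task import datasets_from_frame

        return cls(datasets_from_frame(df), spec=spec, **kwargs)

    @property
    def param_names(self) -> list[str]:
        return self.spec.rate_labels() + ["s0", "session_offset"]

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    def _theta_loglik(self, participant: int, theta: np.ndarray) -> float:
        outcome, idx, t0, reports, valid = self._cache[participant]
        k = self.spec.n_rates
        latent, _ = _recursion(theta[:k], theta[k], theta[k + 1], outcome, idx, t0)
        return _gauss_loglik(reports[valid] - latent[valid], self.report_noise_sd)

    def loglike(self, params: SkillParams, participant: int = 0) -> float:
        return log_likelihood(params, self.spec, self.datasets[participant])

    def fit(
        self,
        mode: str = "hierarchical",
        draws: int = 300,
        warmup: int | None = None,
        chains: int = 2,
        seed: int = 0,
    ) -> "SkillModelResults":
        from .sampling import ParamSpec, sample_posterior

        k = self.spec.n_rates
        # alphas and s0 live on (0,1); the session offset on (-1,1)
        supports = [("unit",)] * (k + 1) + [("interval", -1.0, 1.0)]
        pspec = ParamSpec(names=self.param_names, supports=supports)
        samples = sample_posterior(
            self._theta_loglik,
            n_participants=len(self.datasets),
            param_spec=pspec,
            mode=mode,
            draws=draws,
            warmup=warmup,
            chains=chains,
            seed=seed,
        )
        return SkillModelResults(self, samples)

    def data_fingerprint(self) -> int:
        from .task import cohort_fingerprint

        return cohort_fingerprint(self.datasets)


class SkillModelResults:
    """Posterior summaries of a fitted skill model."""

    def __init__(self, model: SkillModel, samples):
        self.model = model
        self.samples = samples
        self._pointwise = None

    @property
    def spec(self) -> SkillModelSpec:
        return self.model.spec

    def posterior_mean_params(self):
        """Per-participant posterior-mean parameters as a DataFrame."""
        import pandas as pd

        means = self.samples.individual_flat.mean(axis=0)  # (P, K)
        return pd.DataFrame(means, columns=self.model.param_names)

    def participant_params(self, participant: int) -> SkillParams:
        theta = self.samples.individual_flat.mean(axis=0)[participant]
        k = self.spec.n_rates
        return SkillParams(
            alphas=np.clip(theta[:k], 0.0, 1.0),
            s0=float(np.clip(theta[k], 0.0, 1.0)),
            session_offset=float(theta[k + 1]),
            report_noise_sd=self.model.report_noise_sd,
        )

    def pointwise_loglik(self) -> np.ndarray:
        """Participant x posterior-sample log-likelihood matrix (for WAIC)."""
        if self._pointwise is None:
            flat = self.samples.individual_flat  # (S, P, K)
            s_tot, p_tot = flat.shape[0], flat.shape[1]
            out = np.empty((p_tot, s_tot))
            for p in range(p_tot):
                for s in range(s_tot):
                    out[p, s] = self.model._theta_loglik(p, flat[s, p])
            self._pointwise = out
        return self._pointwise

    def waic(self):
        from .inference import waic

        return waic(self.pointwise_loglik())

    def internal_minus_external(self):
        """Per participant, mean over session x outcome cells of the fitted
        internal minus external learning rate.  Requires an A-containing spec."""
        spec = self.spec
        if not spec.vary_by_attribution:
            raise ValueError("internal/external contrast requires an A-containing spec")
        means = self.samples.individual_flat.mean(axis=0)
        diffs = []
        sessions = (1, 2) if spec.vary_by_session else (1,)
        outcomes = (0, 1) if spec.vary_by_outcome else (0,)
        for row in means:
            cells = [
                row[learning_rate_index(spec, s, o, "internal")]
                - row[learning_rate_index(spec, s, o, "external")]
                for s in sessions
                for o in outcomes
            ]
            diffs.append(float(np.mean(cells)))
        return np.asarray(diffs)

    def r_squared(self) -> np.ndarray:
        """Squared correlation between reports and the posterior-mean latent
        trajectory, one value per participant."""
        out = []
        for p, ds in enumerate(self.model.datasets):
            traj = predict_trajectory(self.participant_params(p), self.spec, ds)
            reports = np.asarray(ds.skill_report, dtype=float)
            valid = np.isfinite(reports)
            if valid.sum() < 2 or np.std(reports[valid]) == 0 or np.std(traj.latent[valid]) == 0:
                out.append(np.nan)
                continue
            r = np.corrcoef(reports[valid], traj.latent[valid])[0, 1]
            out.append(float(r**2))
        return np.asarray(out)

    def summary(self):
        """Population-level posterior summary table."""
        return self.samples.summary()

    def plot_learning_rates(self, ax=None):
        """Box plot of per-participant posterior-mean learning rates."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        means = self.posterior_mean_params()
        labels = self.spec.rate_labels()
        ax.boxplot([means[c] for c in labels], tick_labels=labels)
        ax.set_ylabel("learning rate")
        ax.tick_params(axis="x", rotation=60)
        return ax

    def data_fingerprint(self) -> int:
        return self.model.data_fingerprint()
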