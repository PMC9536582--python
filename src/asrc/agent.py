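"""Simulated agents with reciprocally coupled attributions and skill beliefs.

An agent repeatedly performs a task with binary outcomes and maintains a
scalar belief ``s`` about its own skill.  The coupling between the two
processes runs in both directions:

* **belief -> attribution**: the probability of attributing an outcome
  internally is a sigmoid of the current skill belief for wins, and an
  inverse sigmoid for losses (indifference points ``x0_win``/``x0_loss``,
  slopes ``beta_win``/``beta_loss``);
* **attribution -> belief**: the belief is corrected by a fraction of the
  prediction error ``delta = o - sigmoid(s)``, with a learning rate that
  depends on the (attribution, outcome) pair.

Ensembles of runs share a single fixed outcome sequence, so run-to-run
variability arises exclusively from the stochastic sampling of attributions.
The :func:`decouple_attributions` ablation removes the belief -> attribution
arrow while matching the average internal-attribution propensity per outcome
valence, isolating the contribution of the closed loop to belief divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit as _sigmoid
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "AgentParams",
    "OutcomeSchedule",
    "AgentTrajectory",
    "Ensemble",
    "attribution_probability",
    "update_skill",
    "simulate_ensemble",
    "decouple_attributions",
    "ensemble_summaries",
]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the attribution/belief agent.

    ``alpha_internal_win`` etc. are the four learning rates, one per
    (attribution, outcome) cell; all must lie in [0, 1].  Slopes must be
    non-negative: a negative slope would invert the postulated direction of
    the belief -> attribution coupling and is rejected.
    """

    x0_win: float = 0.0
    x0_loss: float = 0.0
    beta_win: float = 2.0
    beta_loss: float = 2.0
    alpha_internal_win: float = 0.1
    alpha_external_win: float = 0.05
    alpha_internal_loss: float = 0.1
    alpha_external_loss: float = 0.05
    s0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x0_win", "x0_loss", "beta_win", "beta_loss", "s0"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.beta_win < 0 or self.beta_loss < 0:
            raise ValueError("sigmoid slopes beta_win/beta_loss must be >= 0")
        for name in (
            "alpha_internal_win",
            "alpha_external_win",
            "alpha_internal_loss",
            "alpha_external_loss",
        ):
            a = getattr(self, name)
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {a}")

    def alpha(self, attribution: int, outcome: int) -> float:
        """Learning rate for an (attribution, outcome) cell (1 = internal/win)."""
        table = {
            (1, 1): self.alpha_internal_win,
            (0, 1): self.alpha_external_win,
            (1, 0): self.alpha_internal_loss,
            (0, 0): self.alpha_external_loss,
        }
        return table[(int(attribution), int(outcome))]

    @property
    def alpha_matrix(self) -> np.ndarray:
        """2x2 array indexed [attribution, outcome]."""
        m = np.empty((2, 2))
        for a in (0, 1):
            for o in (0, 1):
                m[a, o] = self.alpha(a, o)
        return m

    @classmethod
    def control(cls) -> "AgentParams":
        """Reference parameter set used for the baseline simulations."""
        return cls()

    @classmethod
    def vulnerable(cls) -> "AgentParams":
        """Latently vulnerable agent: low win slope, high loss slope,
        heightened learning from internally attributed outcomes."""
        return cls(
            beta_win=0.5,
            beta_loss=5.0,
            alpha_internal_win=0.12,
            alpha_internal_loss=0.15,
        )

    @classmethod
    def amplifying(cls) -> "AgentParams":
        """Positive-feedback regime: near-step win attribution and zero
        learning from externally attributed outcomes."""
        return cls(
            x0_win=-0.03,
            beta_win=100.0,
            beta_loss=1.0,
            alpha_internal_win=0.15,
            alpha_external_win=0.0,
            alpha_internal_loss=0.15,
            alpha_external_loss=0.0,
        )


@dataclass(frozen=True)
class OutcomeSchedule:
    """A fixed binary outcome sequence shared by every run of an ensemble."""

    outcomes: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.outcomes, dtype=int)
        if arr.ndim != 1:
            raise ValueError("outcomes must be a 1-d sequence")
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("outcomes must contain only 0 (loss) and 1 (win)")
        object.__setattr__(self, "outcomes", arr)

    def __len__(self) -> int:
        return len(self.outcomes)

    @classmethod
    def random(cls, n_trials: int, seed: int | np.random.Generator = 0) -> "OutcomeSchedule":
        """Fair-coin schedule, drawn once and reused across runs."""
        rng = np.random.default_rng(seed)
        return cls(rng.integers(0, 2, size=n_trials))

    def with_streak(self, n_losses: int) -> "OutcomeSchedule":
        """Append a negative streak of ``n_losses`` losses."""
        if n_losses < 0:
            raise ValueError("streak length must be >= 0")
        return OutcomeSchedule(np.concatenate([self.outcomes, np.zeros(n_losses, dtype=int)]))


@dataclass(frozen=True)
class AgentTrajectory:
    skill: np.ndarray  # length T+1, s^0 ... s^T
    attribution: np.ndarray  # length T, 1 = internal
    outcome: np.ndarray  # length T
    prediction_error: np.ndarray  # length T

    def __post_init__(self) -> None:
        if len(self.skill) != len(self.outcome) + 1:
            raise ValueError("skill must have one more entry than outcome")


@dataclass(frozen=True)
class Ensemble:
    """A set of runs sharing one outcome schedule and one parameter set.

    ``skill`` has shape (n_runs, T+1); ``attribution`` has shape (n_runs, T).
    """

    skill: np.ndarray
    attribution: np.ndarray
    outcome: np.ndarray
    params: AgentParams
    seed: int
    decoupled: bool = False

    @property
    def n_runs(self) -> int:
        return self.skill.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.outcome)

    @property
    def prediction_error(self) -> np.ndarray:
        return self.outcome[None, :] - _sigmoid(self.skill[:, :-1])

    def trajectories(self):
        for r in range(self.n_runs):
            yield AgentTrajectory(
                skill=self.skill[r],
                attribution=self.attribution[r],
                outcome=self.outcome,
                prediction_error=self.prediction_error[r],
            )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(run, trial) table of the simulated quantities."""
        n, t = self.n_runs, self.n_trials
        return pd.DataFrame(
            {
                "run": np.repeat(np.arange(n), t),
                "trial": np.tile(np.arange(t), n),
                "skill": self.skill[:, :-1].ravel(),
                "outcome": np.tile(self.outcome, n),
                "attribution": self.attribution.ravel(),
            }
        )

    def plot(self, ax=None, color="C0", alpha=0.25, **kwargs):
        """Plot the skill-belief trajectories of every run."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.skill.T, color=color, alpha=alpha, lw=0.8, **kwargs)
        ax.set_xlabel("trial")
        ax.set_ylabel("skill belief")
        return ax


def attribution_probability(skill, outcome: int, params: AgentParams):
    """Probability of an internal attribution given the current skill belief.

    ``sigmoid(beta_win * (s - x0_win))`` for wins; one minus the analogous
    sigmoid for losses. Accepts scalar or array ``skill``.
    """
    skill = np.asarray(skill, dtype=float)
    if not np.all(np.isfinite(skill)):
        raise ValueError("skill must be finite")
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    if outcome == 1:
        p = _sigmoid(params.beta_win * (skill - params.x0_win))
    else:
        p = 1.0 - _sigmoid(params.beta_loss * (skill - params.x0_loss))
    return float(p) if p.ndim == 0 else p


def update_skill(skill: float, outcome: int, attribution: int, params: AgentParams) -> float:
    """One belief update: ``s + alpha[a, o] * (o - sigmoid(s))``."""
    if not np.isfinite(skill):
        raise ValueError("skill must be finite")
    if outcome not in (0, 1) or attribution not in (0, 1):
        raise ValueError("outcome and attribution must be 0 or 1")
    delta = outcome - _sigmoid(skill)
    return float(skill + params.alpha(attribution, outcome) * delta)


def _simulate(
    params: AgentParams,
    schedule: OutcomeSchedule,
    n_runs: int,
    seed: int,
    fixed_rates: dict[int, float] | None,
    decoupled: bool,
) -> Ensemble:
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    outcomes = schedule.outcomes
    t_max = len(outcomes)
    rng = np.random.default_rng(seed)
    alpha = params.alpha_matrix
    skill = np.empty((n_runs, t_max + 1))
    skill[:, 0] = params.s0
    attributions = np.empty((n_runs, t_max), dtype=int)
    for t in range(t_max):
        o = int(outcomes[t])
        s = skill[:, t]
        if fixed_rates is None:
            p = attribution_probability(s, o, params)
            p = np.broadcast_to(np.asarray(p), (n_runs,))
        else:
            p = np.full(n_runs, fixed_rates[o])
        a = (rng.random(n_runs) < p).astype(int)
        attributions[:, t] = a
        delta = o - _sigmoid(s)
        skill[:, t + 1] = s + alpha[a, o] * delta
    return Ensemble(
        skill=skill,
        attribution=attributions,
        outcome=outcomes.copy(),
        params=params,
        seed=seed,
        decoupled=decoupled,
    )


def simulate_ensemble(
    params: AgentParams, schedule: OutcomeSchedule, n_runs: int = 100, seed: int = 0
) -> Ensemble:
    """Simulate ``n_runs`` agents on one shared outcome schedule.

    Every run starts at ``params.s0``; attributions are sampled per trial
    from :func:`attribution_probability`, and the skill belief is advanced
    with :func:`update_skill`. Equal seeds give bitwise-equal ensembles.
    """
    return _simulate(params, schedule, n_runs, seed, fixed_rates=None, decoupled=False)


def decouple_attributions(
    params: AgentParams,
    schedule: OutcomeSchedule,
    n_runs: int = 100,
    seed: int = 0,
    reference: Ensemble | None = None,
) -> Ensemble:
    """Ablated ensemble with the belief -> attribution arrow removed.

    Attributions are drawn i.i.d. per outcome valence with probability equal
    to the *coupled* ensemble's empirical internal-attribution rate for that
    valence (wins and losses matched separately), so average propensity is
    matched while skill beliefs no longer influence attribution.  If no
    ``reference`` coupled ensemble is supplied, one is simulated first with
    the same arguments.
    """
    if reference is None:
        reference = simulate_ensemble(params, schedule, n_runs, seed)
    rates: dict[int, float] = {}
    for o in (0, 1):
        mask = reference.outcome == o
        if mask.any():
            rates[o] = float(reference.attribution[:, mask].mean())
        else:
            rates[o] = 0.5  # valence absent from the schedule; never sampled
    return _simulate(params, schedule, n_runs, seed + 1, fixed_rates=rates, decoupled=True)


def _quintile_bins(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-count bins from pooled values; ties broken by rank order."""
    ranks = rankdata(values, method="ordinal") - 1
    return (ranks * n_bins // len(values)).astype(int)


def ensemble_summaries(
    ensemble: Ensemble,
    first_wins: int = 5,
    split_trial: int = 50,
    batch_size: int = 10,
) -> dict[str, pd.DataFrame]:
    """Summary tables of the trial-level reciprocal effects in an ensemble.

    Returns a dict with four tables:

    - ``attribution_by_skill``: internal-attribution proportion per pooled
      pre-update skill quintile x outcome;
    - ``update_by_cell``: mean skill update per outcome x attribution cell;
    - ``median_split``: mean +/- s.e.m. skill trajectories for runs above vs
      below the median proportion of internal attributions over each run's
      first ``first_wins`` wins (runs with fewer wins are excluded and the
      exclusion count logged);
    - ``loss_batches``: internal-attribution proportions for the first and
      second batch of ``batch_size`` losses after trial ``split_trial``, for
      runs in the top and bottom quartile of skill at that trial.
    """
    if ensemble.n_runs == 0 or ensemble.n_trials == 0:
        raise ValueError("ensemble must contain at least one run and one trial")
    skill_pre = ensemble.skill[:, :-1]
    attribution = ensemble.attribution
    outcome = ensemble.outcome
    n_runs, n_trials = attribution.shape

    # (i) internal proportion by skill quintile x outcome, pooled
    bins = _quintile_bins(skill_pre.ravel()).reshape(skill_pre.shape)
    rows = []
    for o in (0, 1):
        for q in range(5):
            mask = (bins == q) & (outcome[None, :] == o)
            rows.append(
                {
                    "outcome": o,
                    "skill_quintile": q,
                    "p_internal": float(attribution[mask].mean()) if mask.any() else np.nan,
                    "n": int(mask.sum()),
                }
            )
    by_skill = pd.DataFrame(rows)

    # (ii) mean update per outcome x attribution cell
    updates = np.diff(ensemble.skill, axis=1)
    rows = []
    for o in (0, 1):
        for a in (0, 1):
            mask = (outcome[None, :] == o) & (attribution == a)
            rows.append(
                {
                    "outcome": o,
                    "attribution": a,
                    "mean_update": float(updates[mask].mean()) if mask.any() else np.nan,
                    "n": int(mask.sum()),
                }
            )
    by_cell = pd.DataFrame(rows)

    # (iii) median split on internal proportion over first `first_wins` wins
    win_idx = np.flatnonzero(outcome == 1)
    rows = []
    if len(win_idx) >= first_wins:
        first = win_idx[:first_wins]
        props = attribution[:, first].mean(axis=1)
        included = np.ones(n_runs, dtype=bool)  # shared schedule: all runs see the wins
        median = np.median(props)
        high = props >= median
        for label, mask in (("high", high), ("low", ~high)):
            if not mask.any():
                continue
            traj = ensemble.skill[mask]
            mean = traj.mean(axis=0)
            sem = traj.std(axis=0, ddof=1) / np.sqrt(mask.sum()) if mask.sum() > 1 else np.zeros(traj.shape[1])
            for t in range(traj.shape[1]):
                rows.append({"group": label, "trial": t, "mean": mean[t], "sem": sem[t]})
    else:
        logger.warning(
            "median-split summary skipped: schedule has %d wins (< %d); %d runs excluded",
            len(win_idx), first_wins, n_runs,
        )
    median_split = pd.DataFrame(rows, columns=["group", "trial", "mean", "sem"])

    # (iv) loss batches after split_trial, top vs bottom skill quartile
    rows = []
    if n_trials > split_trial:
        loss_after = np.flatnonzero((outcome == 0) & (np.arange(n_trials) >= split_trial))
        s_at = ensemble.skill[:, split_trial]
        quart = _quintile_bins(s_at, n_bins=4)
        groups = {"top": quart == 3, "bottom": quart == 0}
        for b, name in ((0, "first"), (1, "second")):
            idx = loss_after[b * batch_size : (b + 1) * batch_size]
            if len(idx) < batch_size:
                logger.warning("loss-batch summary: only %d losses available for batch %s", len(idx), name)
            if len(idx) == 0:
                continue
            for gname, gmask in groups.items():
                rows.append(
                    {
                        "batch": name,
                        "group": gname,
                        "p_internal": float(attribution[np.ix_(gmask, idx)].mean()),
                        "n_losses": len(idx),
                    }
                )
    loss_batches = pd.DataFrame(rows, columns=["batch", "group", "p_internal", "n_losses"])

    return {
        "attribution_by_skill": by_skill,
        "update_by_cell": by_cell,
        "median_split": median_split,
        "loss_batches": loss_batches,
    }
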