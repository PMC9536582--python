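"""Model comparison, parameter recovery, and the attribution-shuffle refit.

The comparison criterion is a participant-grain WAIC: with posterior
samples theta_ps for participant p,

    WAIC = -(1/P) sum_p log( (1/S) sum_s p(X_p | theta_ps) )
           + (1/P) sum_p Var_s( log p(X_p | theta_ps) )

i.e. the negative average log pointwise predictive density plus the average
posterior variance of the log-likelihood as the effective-parameter
penalty.  Smaller scores indicate better models.  The log of the mean
likelihood is computed with log-sum-exp; the variance uses the n-1 sample
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import spearmanr

from .skill import SkillModel, SkillModelSpec, learning_rate_index
from .task import CohortConfig, ParticipantDataset, generate_cohort

__all__ = [
    "WAICResult",
    "RecoveryReport",
    "ShuffleRefitResult",
    "waic",
    "compare_models",
    "posterior_mean_params",
    "recovery_experiment",
    "shuffle_refit",
]


@dataclass(frozen=True)
class WAICResult:
    """WAIC score with its two components at the participant grain."""

    waic: float
    lppd: float  # (1/P) sum_p log mean_s p(X_p | theta_ps)
    penalty: float  # (1/P) sum_p Var_s log p
    pointwise: np.ndarray  # per-participant contributions (-log mean + var)
    n_participants: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")


def waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC from a (participants x posterior samples) log-likelihood matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be 2-d (participants x samples)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihoods must be finite")
    p, s = ll.shape
    if s < 2:
        raise ValueError("need at least 2 posterior samples (variance undefined)")
    log_mean = logsumexp(ll, axis=1) - np.log(s)
    var = ll.var(axis=1, ddof=1)
    pointwise = -log_mean + var
    return WAICResult(
        waic=float(pointwise.mean()),
        lppd=float(log_mean.mean()),
        penalty=float(var.mean()),
        pointwise=pointwise,
        n_participants=p,
        n_samples=s,
    )


def compare_models(fits, names=None) -> pd.DataFrame:
    """Rank fitted models by WAIC (ascending; Delta relative to the best).

    ``fits`` are Results objects (Skill/AttributionModelResults).  All fits
    must be on identical data; mismatched cohorts are rejected.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    if names is None:
        names = []
        for f in fits:
            spec = f.spec
            names.append(getattr(spec, "name", None) or getattr(spec, "feature_set"))
    prints = {f.data_fingerprint() for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were produced on different datasets; comparison refused")
    rows = []
    for name, f in zip(names, fits):
        w = f.waic()
        rows.append({"model": name, "waic": w.waic, "lppd": w.lppd, "penalty": w.penalty})
    df = pd.DataFrame(rows).sort_values("waic", kind="stable").reset_index(drop=True)
    df["delta_waic"] = df["waic"] - df["waic"].iloc[0]
    return df


def posterior_mean_params(samples) -> np.ndarray:
    """Arithmetic posterior-mean point estimates, (participants x params)."""
    return samples.posterior_mean()


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of a parameter-recovery experiment."""

    parameter_table: pd.DataFrame  # per-parameter bias, rmse, rank correlation
    sign_recovery_rate: float | None  # fraction of participants with a positive
    # fitted internal-external learning-rate difference (A-containing specs)
    per_participant_diff: np.ndarray | None
    waic_table: pd.DataFrame | None
    selected_model: str | None
    true_params: pd.DataFrame
    fitted_params: pd.DataFrame


def _recovery_rows(true_df: pd.DataFrame, fit_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in fit_df.columns:
        if col not in true_df.columns:
            continue
        t = true_df[col].to_numpy(dtype=float)
        f = fit_df[col].to_numpy(dtype=float)
        err = f - t
        rho = spearmanr(t, f).statistic if len(t) > 2 and np.std(t) > 0 else np.nan
        rows.append(
            {
                "param": col,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "rank_corr": float(rho) if rho == rho else np.nan,
            }
        )
    return pd.DataFrame(rows)


def recovery_experiment(
    generator_config: CohortConfig | None = None,
    model_specs: tuple[str, ...] = ("SAO", "SO"),
    mode: str = "hierarchical",
    draws: int = 300,
    warmup: int | None = None,
    chains: int = 2,
    seed: int = 0,
) -> RecoveryReport:
    """Generate a cohort, fit the requested skill specs, audit recovery.

    The first spec in ``model_specs`` is treated as the fitted counterpart
    of the generating model: its posterior-mean parameters are compared
    with the generating values (bias, RMSE, Spearman rank correlation), and
    if it contains the attribution factor the per-participant internal
    minus external learning-rate difference and its sign-recovery rate are
    reported.  All specs are ranked by WAIC.
    """
    cfg = generator_config or CohortConfig()
    datasets, true_df = generate_cohort(cfg, seed=seed)
    results = []
    for name in model_specs:
        model = SkillModel(datasets, spec=name)
        results.append(
            model.fit(mode=mode, draws=draws, warmup=warmup, chains=chains, seed=seed + 1)
        )
    primary = results[0]
    fitted = primary.posterior_mean_params()
    table = _recovery_rows(true_df, fitted)
    sign_rate, diffs = None, None
    if primary.spec.vary_by_attribution:
        diffs = primary.internal_minus_external()
        sign_rate = float((diffs > 0).mean())
    waic_table = compare_models(results, names=list(model_specs)) if len(results) > 1 else None
    selected = waic_table["model"].iloc[0] if waic_table is not None else model_specs[0]
    return RecoveryReport(
        parameter_table=table,
        sign_recovery_rate=sign_rate,
        per_participant_diff=diffs,
        waic_table=waic_table,
        selected_model=selected,
        true_params=true_df,
        fitted_params=fitted,
    )


@dataclass(frozen=True)
class ShuffleRefitResult:
    """Null distribution of learning-rate contrasts under attribution shuffles.

    ``observed`` holds the across-participant mean internal minus external
    learning rate per (session, outcome) cell from the fit to the intact
    data; ``null`` has one row per permutation with the same cells.
    """

    cells: tuple[tuple[int, int], ...]  # (session, outcome) pairs
    observed: np.ndarray
    null: np.ndarray  # (n_perm, n_cells)

    @property
    def observed_mean(self) -> float:
        return float(self.observed.mean())

    @property
    def null_mean(self) -> np.ndarray:
        return self.null.mean(axis=1)


def _shuffled_copy(ds: ParticipantDataset, rng: np.random.Generator) -> ParticipantDataset:
    perm = rng.permutation(len(ds))
    return ParticipantDataset(
        participant_id=ds.participant_id,
        probe=ds.probe,
        session=ds.session,
        outcome=ds.outcome,
        attribution=ds.attribution[perm],
        skill_report=ds.skill_report,
        path_length=ds.path_length,
        prop_nonup=ds.prop_nonup,
        prop_correct_keys=ds.prop_correct_keys,
        prop_pauses=ds.prop_pauses,
        time_limit=ds.time_limit,
        difficulty=ds.difficulty,
    )


def _cell_diffs(result, cells) -> np.ndarray:
    spec = result.spec
    means = result.samples.posterior_mean()
    out = np.empty(len(cells))
    for j, (s, o) in enumerate(cells):
        d = [
            row[learning_rate_index(spec, s, o, "internal")]
            - row[learning_rate_index(spec, s, o, "external")]
            for row in means
        ]
        out[j] = float(np.mean(d))
    return out


def shuffle_refit(
    datasets,
    spec: str | SkillModelSpec = "SAO",
    n_perm: int = 50,
    mode: str = "hierarchical",
    draws: int = 300,
    warmup: int | None = None,
    chains: int = 2,
    seed: int = 0,
    observed_result=None,
) -> ShuffleRefitResult:
    """Refit the skill model to attribution-shuffled data.

    Per permutation, each participant's attribution responses are shuffled
    (preserving their label counts), the model is refitted, and the across-
    participant mean internal minus external learning rate is recorded per
    session x outcome cell.  The observed values come from a fit to the
    intact data (supplied or computed here).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(spec, str):
        spec = SkillModelSpec.from_name(spec)
    if not spec.vary_by_attribution:
        raise ValueError("shuffle refit requires an A-containing spec")
    sessions = (1, 2) if spec.vary_by_session else (1,)
    outcomes = (0, 1) if spec.vary_by_outcome else (0,)
    cells = tuple((s, o) for s in sessions for o in outcomes)

    if observed_result is None:
        observed_result = SkillModel(datasets, spec=spec).fit(
            mode=mode, draws=draws, warmup=warmup, chains=chains, seed=seed
        )
    observed = _cell_diffs(observed_result, cells)

    root = np.random.SeedSequence(seed).spawn(n_perm)
    null = np.empty((n_perm, len(cells)))
    for k in range(n_perm):
        rng = np.random.default_rng(root[k])
        shuffled = [_shuffled_copy(ds, rng) for ds in datasets]
        res = SkillModel(shuffled, spec=spec).fit(
            mode=mode, draws=draws, warmup=warmup, chains=chains, seed=seed + 1 + k
        )
        null[k] = _cell_diffs(res, cells)
    return ShuffleRefitResult(cells=cells, observed=observed, null=null)
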