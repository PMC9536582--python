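"""Softmax linear models of causal-attribution choices.

After each probed trial the participant assigns the outcome to one of four
causes: ability (internal), maze, rotations, or luck.  Each option ``o``
receives a linear score ``s_o = w_o . f`` from a feature vector ``f`` (a
bias plus, depending on the model, the previous skill estimate, performance
features and task features, all z-scored within participant), and choice
probabilities are the softmax of the scores.  Weights are valence-specific
(separate parameter sets for wins and losses), free for three options only:
the luck weights are the negative sum of the other three, so the four
scores sum to zero for every feature vector and the model is identified.

Two parameter transforms make fitted weights comparable across options:
baseline preferences (softmax of the bias terms alone) and average marginal
feature effects (the analytic softmax derivative with the feature of
interest clamped to zero, averaged over valence-matched trials).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_softmax, softmax

__all__ = [
    "OPTIONS",
    "FEATURE_SETS",
    "AttributionModelSpec",
    "OptionWeights",
    "build_features",
    "option_scores",
    "choice_probabilities",
    "log_likelihood",
    "bias_preferences",
    "feature_effect",
    "AttributionModel",
]

OPTIONS = ("ability", "maze", "rotations", "luck")
_FREE_OPTIONS = OPTIONS[:3]
_VALENCES = ("win", "loss")

# feature sets: name -> features beyond the constant bias term
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "bias": (),
    "bias_skill": ("skill_estimate",),
    "bias_performance": ("prop_correct_keys", "prop_pauses"),
    "bias_performance_task": (
        "prop_correct_keys",
        "prop_pauses",
        "path_length",
        "prop_nonup",
    ),
    "bias_skill_task": ("skill_estimate", "path_length", "prop_nonup"),
    "full": (
        "skill_estimate",
        "prop_correct_keys",
        "prop_pauses",
        "path_length",
        "prop_nonup",
    ),
}


@dataclass(frozen=True)
class AttributionModelSpec:
    """One member of the six-model family, defined by its feature set."""

    feature_set: str = "full"

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(
                f"unknown feature set {self.feature_set!r}; "
                f"expected one of {sorted(FEATURE_SETS)}"
            )

    @property
    def features(self) -> tuple[str, ...]:
        return FEATURE_SETS[self.feature_set]

    @property
    def n_features(self) -> int:
        """Columns of the design matrix, including the bias."""
        return 1 + len(self.features)

    @property
    def n_params(self) -> int:
        """Free parameters per participant: 2 valences x 3 options x features."""
        return 2 * 3 * self.n_features


@dataclass(frozen=True)
class OptionWeights:
    """Valence-specific weights for the three free options.

    ``win`` and ``loss`` are (3, n_features) arrays with rows in the order
    (ability, maze, rotations) and the bias in column 0; luck weights are
    derived as the negative sum, enforcing the sum-to-zero score constraint.
    """

    win: np.ndarray
    loss: np.ndarray

    def __post_init__(self) -> None:
        for name in ("win", "loss"):
            w = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if w.shape[0] != 3:
                raise ValueError(f"{name} weights must have 3 rows (ability, maze, rotations)")
            object.__setattr__(self, name, w)
        if self.win.shape != self.loss.shape:
            raise ValueError("win and loss weight matrices must have equal shapes")

    @property
    def n_features(self) -> int:
        return self.win.shape[1]

    def for_valence(self, valence) -> np.ndarray:
        """Weights of the free options for a valence (1/'win' or 0/'loss')."""
        if valence in (1, "win"):
            return self.win
        if valence in (0, "loss"):
            return self.loss
        raise ValueError(f"unknown valence {valence!r}")

    def full_matrix(self, valence) -> np.ndarray:
        """(4, n_features) weights including the derived luck row."""
        w = self.for_valence(valence)
        return np.vstack([w, -w.sum(axis=0)])

    @classmethod
    def zeros(cls, spec: AttributionModelSpec | int) -> "OptionWeights":
        f = spec if isinstance(spec, int) else spec.n_features
        return cls(win=np.zeros((3, f)), loss=np.zeros((3, f)))

    @classmethod
    def from_vector(cls, theta: np.ndarray, n_features: int) -> "OptionWeights":
        theta = np.asarray(theta, dtype=float)
        if theta.size != 2 * 3 * n_features:
            raise ValueError("parameter vector length does not match the spec")
        half = theta.size // 2
        return cls(
            win=theta[:half].reshape(3, n_features),
            loss=theta[half:].reshape(3, n_features),
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.win.ravel(), self.loss.ravel()])


def param_names(spec: AttributionModelSpec) -> list[str]:
    cols = ("bias",) + spec.features
    return [
        f"w[{v},{o},{f}]"
        for v in _VALENCES
        for o in _FREE_OPTIONS
        for f in cols
    ]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def build_features(dataset, spec: AttributionModelSpec) -> np.ndarray:
    """Design matrix for one participant: bias column plus z-scored features.

    Continuous features are z-scored within participant.  The skill feature
    for probe ``t`` is the z-scored skill report from probe ``t - 1``; the
    first probe takes 0, the z-scored mean.
    """
    n = len(dataset.outcome)
    cols = [np.ones(n)]
    for name in spec.features:
        if name == "skill_estimate":
            z = _zscore(np.asarray(dataset.skill_report, dtype=float))
            lagged = np.concatenate([[0.0], z[:-1]])
            cols.append(lagged)
        else:
            cols.append(_zscore(np.asarray(getattr(dataset, name), dtype=float)))
    return np.column_stack(cols)


def option_scores(weights: OptionWeights, features: np.ndarray, valence) -> np.ndarray:
    """Scores of the four options; the derived luck score makes them sum to 0.

    ``features`` may be a single vector or an (n, F) matrix, giving a (4,)
    or (n, 4) result.
    """
    w = weights.for_valence(valence)
    f = np.asarray(features, dtype=float)
    if f.shape[-1] != w.shape[1]:
        raise ValueError(
            f"feature vector has {f.shape[-1]} entries but weights expect {w.shape[1]}"
        )
    free = f @ w.T
    return np.concatenate(
        [free, -free.sum(axis=-1, keepdims=True)], axis=-1
    )


def choice_probabilities(scores: np.ndarray) -> np.ndarray:
    """Softmax of option scores (max-subtracted; translation invariant)."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return softmax(scores, axis=-1)


def _choice_indices(dataset) -> np.ndarray:
    att = np.asarray(dataset.attribution, dtype=object)
    idx = np.full(len(att), -1, dtype=int)
    for k, opt in enumerate(OPTIONS):
        idx[att == opt] = k
    return idx  # -1 marks a missing response


def log_likelihood(weights: OptionWeights, spec: AttributionModelSpec, dataset) -> float:
    """Log-probability of the observed choices under valence-specific weights.

    Missing attributions carry no choice information and are excluded.
    """
    features = build_features(dataset, spec)
    choice = _choice_indices(dataset)
    outcome = np.asarray(dataset.outcome, dtype=int)
    observed = choice >= 0
    if not observed.any():
        raise ValueError("dataset contains no non-missing attribution responses")
    total = 0.0
    for o in (0, 1):
        mask = observed & (outcome == o)
        if not mask.any():
            continue
        scores = option_scores(weights, features[mask], o)
        logp = log_softmax(scores, axis=-1)
        total += float(logp[np.arange(mask.sum()), choice[mask]].sum())
    return total


def bias_preferences(weights: OptionWeights) -> pd.DataFrame:
    """Baseline option probabilities per valence: softmax of the biases only
    (all feature weights clamped to zero)."""
    rows = {}
    bias_vec = np.zeros(weights.n_features)
    bias_vec[0] = 1.0
    for v in _VALENCES:
        rows[v] = choice_probabilities(option_scores(weights, bias_vec, v))
    return pd.DataFrame(rows, index=list(OPTIONS)).T


def feature_effect(
    weights: OptionWeights,
    dataset_or_features,
    spec: AttributionModelSpec,
    feature: str,
    option: str,
    valence,
) -> float:
    """Average marginal effect of a feature on choosing an option.

    The analytic softmax derivative ``p_A (w_{A,x} - sum_B p_B w_{B,x})`` is
    evaluated with the feature of interest clamped to 0 (other features at
    their trial values) and averaged over the trials whose outcome matches
    the valence of the weights being differentiated.
    """
    if feature not in spec.features:
        raise ValueError(f"feature {feature!r} is not part of spec {spec.feature_set!r}")
    if option not in OPTIONS:
        raise ValueError(f"unknown option {option!r}")
    col = 1 + spec.features.index(feature)
    if hasattr(dataset_or_features, "outcome"):
        features = build_features(dataset_or_features, spec)
        outcome = np.asarray(dataset_or_features.outcome, dtype=int)
        o = 1 if valence in (1, "win") else 0
        features = features[outcome == o]
    else:
        features = np.atleast_2d(np.asarray(dataset_or_features, dtype=float))
    if features.shape[0] == 0:
        return 0.0
    f0 = features.copy()
    f0[:, col] = 0.0
    w_full = weights.full_matrix(valence)  # (4, F)
    scores = option_scores(weights, f0, valence)
    p = choice_probabilities(scores)  # (n, 4)
    a = OPTIONS.index(option)
    wx = w_full[:, col]  # (4,)
    deriv = p[:, a] * (wx[a] - p @ wx)
    return float(deriv.mean())


def feature_effect_table(weights: OptionWeights, dataset, spec: AttributionModelSpec) -> pd.DataFrame:
    """All (feature, option, valence) average marginal effects."""
    rows = []
    for feat in spec.features:
        for opt in OPTIONS:
            for v in _VALENCES:
                rows.append(
                    {
                        "feature": feat,
                        "option": opt,
                        "valence": v,
                        "effect": feature_effect(weights, dataset, spec, feat, opt, v),
                    }
                )
    return pd.DataFrame(rows)


class AttributionModel:
    """Attribution-choice model for a cohort of participants.

    ``fit`` samples posterior weights either independently per participant
    (Normal priors) or hierarchically with Normal population distributions
    over each weight.
    """

    def __init__(self, datasets: Sequence, spec: AttributionModelSpec | str = "full"):
        if isinstance(spec, str):
            spec = AttributionModelSpec(spec)
        if len(datasets) == 0:
            raise ValueError("at least one participant dataset is required")
        self.datasets = list(datasets)
        self.spec = spec
        self._cache = []
        for ds in self.datasets:
            features = build_features(ds, spec)
            choice = _choice_indices(ds)
            outcome = np.asarray(ds.outcome, dtype=int)
            observed = choice >= 0
            if not observed.any():
                raise ValueError("a dataset contains no non-missing attributions")
            per_valence = []
            for o in (0, 1):
                mask = observed & (outcome == o)
                per_valence.append((features[mask], choice[mask]))
            self._cache.append(per_valence)

    @classmethod
    def from_dataframe(cls, df, spec="full") -> "AttributionModel":
        from .task import datasets_from_frame

        return cls(datasets_from_frame(df), spec=spec)

    @property
    def param_names(self) -> list[str]:
        return param_names(self.spec)

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    def _theta_loglik(self, participant: int, theta: np.ndarray) -> float:
        nf = self.spec.n_features
        half = 3 * nf
        total = 0.0
        for o, (feats, choice) in zip((0, 1), self._cache[participant]):
            if len(choice) == 0:
                continue
            # theta layout: win block first (see param_names)
            w = (theta[:half] if o == 1 else theta[half:]).reshape(3, nf)
            free = feats @ w.T
            scores = np.concatenate([free, -free.sum(axis=1, keepdims=True)], axis=1)
            logp = log_softmax(scores, axis=1)
            total += float(logp[np.arange(len(choice)), choice].sum())
        return total

    def loglike(self, weights: OptionWeights, participant: int = 0) -> float:
        return log_likelihood(weights, self.spec, self.datasets[participant])

    def fit(
        self,
        mode: str = "hierarchical",
        draws: int = 300,
        warmup: int | None = None,
        chains: int = 2,
        seed: int = 0,
    ) -> "AttributionModelResults":
        from .sampling import ParamSpec, sample_posterior

        pspec = ParamSpec(
            names=self.param_names,
            supports=[("real",)] * self.n_params,
            real_prior_sd=2.5,
        )
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
        return AttributionModelResults(self, samples)

    def data_fingerprint(self) -> int:
        from .task import cohort_fingerprint

        return cohort_fingerprint(self.datasets)


class AttributionModelResults:
    """Posterior summaries of a fitted attribution model."""

    def __init__(self, model: AttributionModel, samples):
        self.model = model
        self.samples = samples
        self._pointwise = None

    @property
    def spec(self) -> AttributionModelSpec:
        return self.model.spec

    def posterior_mean_params(self) -> pd.DataFrame:
        means = self.samples.individual_flat.mean(axis=0)
        return pd.DataFrame(means, columns=self.model.param_names)

    def participant_weights(self, participant: int) -> OptionWeights:
        theta = self.samples.individual_flat.mean(axis=0)[participant]
        return OptionWeights.from_vector(theta, self.spec.n_features)

    def pointwise_loglik(self) -> np.ndarray:
        if self._pointwise is None:
            flat = self.samples.individual_flat
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

    def bias_preferences(self) -> pd.DataFrame:
        """Baseline option preferences per participant and valence."""
        rows = []
        for p in range(len(self.model.datasets)):
            prefs = bias_preferences(self.participant_weights(p))
            for v in _VALENCES:
                rows.append({"participant": p, "valence": v, **prefs.loc[v].to_dict()})
        return pd.DataFrame(rows)

    def feature_effects(self) -> pd.DataFrame:
        """Average marginal feature effects per participant."""
        tables = []
        for p, ds in enumerate(self.model.datasets):
            t = feature_effect_table(self.participant_weights(p), ds, self.spec)
            t.insert(0, "participant", p)
            tables.append(t)
        return pd.concat(tables, ignore_index=True)

    def skill_weight(self, option: str = "ability") -> pd.DataFrame:
        """Posterior-mean skill-estimate weight per participant and valence."""
        if "skill_estimate" not in self.spec.features:
            raise ValueError("spec has no skill_estimate feature")
        col = 1 + self.spec.features.index("skill_estimate")
        rows = []
        for p in range(len(self.model.datasets)):
            w = self.participant_weights(p)
            rows.append(
                {
                    "participant": p,
                    "win": float(w.win[_FREE_OPTIONS.index(option), col]),
                    "loss": float(w.loss[_FREE_OPTIONS.index(option), col]),
                }
            )
        return pd.DataFrame(rows)

    def summary(self):
        return self.samples.summary()

    def data_fingerprint(self) -> int:
        return self.model.data_fingerprint()
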