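"""Synthetic maze-game experiment generator.

Emulates the statistical structure of the probe-based task: binary trial
outcomes whose difficulty is adapted toward 50% wins by a double staircase,
per-trial task features (correct-path length, proportion of frames in a
non-UP orientation, time limit) and performance features (proportion of
correct key presses, proportion of paused frames), and — after every second
trial — a probe consisting of a 4-option causal attribution followed by a
continuous skill report on [0, 1].  Each condition comprises two sessions
with a between-session break.

The generative participant composes the two fitted model families: the
attribution choice is sampled from a softmax attribution model (optionally
replaced by a missing response), and the skill report is a noisy reading of
a Rescorla-Wagner latent skill trajectory whose learning rate may depend on
session, outcome and the attribution class just produced.  Because every
downstream fit runs on these datasets with known generating parameters,
parameter recovery is fully testable without any external data.

Difficulty is a scalar controller state; trial outcomes follow
``p(win) = sigmoid(kappa * (ability - difficulty))`` with slope ``kappa``
(default 2).  This outcome model, and the affine maps from difficulty to
task features, are plumbing choices of this package, not measured task
psychophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit as _sigmoid

from .attribution import (
    OPTIONS,
    AttributionModelSpec,
    OptionWeights,
    choice_probabilities,
    option_scores,
)
from .skill import SkillModelSpec, SkillParams, learning_rate_index

__all__ = [
    "TrialFeatures",
    "DoubleStaircase",
    "GenerativeParticipant",
    "ParticipantDataset",
    "CohortConfig",
    "staircase_update",
    "generate_trial",
    "generate_dataset",
    "generate_cohort",
    "read_dataset",
    "write_dataset",
    "datasets_from_frame",
    "cohort_fingerprint",
]

ATTRIBUTION_VALUES = OPTIONS + ("missing",)
DEFAULT_KAPPA = 2.0

_FEATURE_COLS = (
    "path_length",
    "prop_nonup",
    "prop_correct_keys",
    "prop_pauses",
    "time_limit",
    "difficulty",
)

_SCHEMA = (
    "participant",
    "probe",
    "session",
    "outcome",
    "attribution",
    "skill_report",
) + _FEATURE_COLS


@dataclass(frozen=True)
class TrialFeatures:
    """Observable features of a single trial."""

    path_length: int
    prop_nonup: float
    prop_correct_keys: float
    prop_pauses: float
    time_limit: float
    difficulty: float

    def __post_init__(self) -> None:
        if self.path_length < 1:
            raise ValueError("path_length must be >= 1")
        for name in ("prop_nonup", "prop_correct_keys", "prop_pauses"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class DoubleStaircase:
    """Two interleaved 1-up/1-down tracks over a scalar difficulty.

    The active track drives the next trial and moves one step harder after
    a win, one step easier after a loss; tracks alternate between trials,
    which resists gaming of the adaptation.  Difficulty is clamped to
    ``[d_min, d_max]``.
    """

    difficulties: tuple[float, float] = (0.0, 0.0)
    step: float = 0.25
    d_min: float = -3.0
    d_max: float = 3.0
    active: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if not (self.d_min < self.d_max):
            raise ValueError("need d_min < d_max")
        if self.active not in (0, 1):
            raise ValueError("active track must be 0 or 1")
        d = tuple(float(np.clip(x, self.d_min, self.d_max)) for x in self.difficulties)
        object.__setattr__(self, "difficulties", d)

    @property
    def current_difficulty(self) -> float:
        return self.difficulties[self.active]


def staircase_update(state: DoubleStaircase, outcome: int) -> DoubleStaircase:
    """Advance the active track on an outcome and toggle the active track."""
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    d = list(state.difficulties)
    move = state.step if outcome == 1 else -state.step
    d[state.active] = float(np.clip(d[state.active] + move, state.d_min, state.d_max))
    return replace(state, difficulties=tuple(d), active=1 - state.active)


@dataclass(frozen=True)
class GenerativeParticipant:
    """Latent description of one synthetic participant.

    ``ability`` drives win probability (against the staircase difficulty)
    and key-press accuracy; the skill and attribution parameters generate
    the probe responses; ``missing_prob`` is the chance an attribution probe
    goes unanswered.
    """

    ability: float = 0.0
    skill_spec: SkillModelSpec = field(default_factory=lambda: SkillModelSpec.from_name("b"))
    skill_params: SkillParams = field(default_factory=lambda: SkillParams(alphas=np.array([0.15])))
    attribution_spec: AttributionModelSpec = field(
        default_factory=lambda: AttributionModelSpec("bias")
    )
    attribution_weights: OptionWeights | None = None
    missing_prob: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_prob <= 1.0):
            raise ValueError("missing_prob must lie in [0, 1]")
        if len(self.skill_params.alphas) != self.skill_spec.n_rates:
            raise ValueError("skill_params does not match skill_spec")
        w = self.attribution_weights
        if w is None:
            w = OptionWeights.zeros(self.attribution_spec)
            object.__setattr__(self, "attribution_weights", w)
        if w.n_features != self.attribution_spec.n_features:
            raise ValueError("attribution_weights do not match attribution_spec")


@dataclass
class ParticipantDataset:
    """Probe-aligned observations of one participant.

    One row per probe: the probed trial's outcome, the attribution response
    (one of ability/maze/rotations/luck, or ``missing``), the skill report
    on [0, 1] (NaN if unanswered), and the probed trial's features.  Within
    a probe the attribution precedes the skill report, so the response time
    series alternates A^t, S^t, A^{t+1}, S^{t+1}, ...  ``t0_ii`` is the
    index of the first probe of session 2.
    """

    participant_id: str
    probe: np.ndarray
    session: np.ndarray
    outcome: np.ndarray
    attribution: np.ndarray
    skill_report: np.ndarray
    path_length: np.ndarray
    prop_nonup: np.ndarray
    prop_correct_keys: np.ndarray
    prop_pauses: np.ndarray
    time_limit: np.ndarray
    difficulty: np.ndarray

    def __post_init__(self) -> None:
        self.probe = np.asarray(self.probe, dtype=int)
        self.session = np.asarray(self.session, dtype=int)
        self.outcome = np.asarray(self.outcome, dtype=int)
        self.attribution = np.asarray(self.attribution, dtype=object)
        self.skill_report = np.asarray(self.skill_report, dtype=float)
        for name in _FEATURE_COLS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.probe)
        lengths = {
            name: len(getattr(self, name))
            for name in ("session", "outcome", "attribution", "skill_report") + _FEATURE_COLS
        }
        if any(l != n for l in lengths.values()):
            raise ValueError(f"column lengths differ: {lengths}")
        if n and (np.diff(self.probe) <= 0).any():
            raise ValueError("probes must be strictly increasing")
        if not np.isin(self.session, (1, 2)).all():
            raise ValueError("session must be 1 or 2")
        if n and (np.diff(self.session) < 0).any():
            raise ValueError("session 2 must follow session 1")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcomes must be 0 or 1")
        bad = ~np.isin(self.attribution.astype(str), ATTRIBUTION_VALUES)
        if bad.any():
            raise ValueError(
                f"unknown attribution values: {sorted(set(self.attribution[bad]))}"
            )
        finite = np.isfinite(self.skill_report)
        if ((self.skill_report[finite] < 0) | (self.skill_report[finite] > 1)).any():
            raise ValueError("skill reports must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.probe)

    @property
    def t0_ii(self) -> int | None:
        """Index of the first probe of session 2 (None if single-session)."""
        second = np.flatnonzero(self.session == 2)
        return int(second[0]) if second.size else None

    @property
    def attribution_class(self) -> np.ndarray:
        """internal / external / missing relabelling of the four options."""
        att = self.attribution.astype(str)
        out = np.where(
            att == "ability", "internal", np.where(att == "missing", "missing", "external")
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {name: getattr(self, name) for name in _SCHEMA if name != "participant"}
        df = pd.DataFrame(data)
        df.insert(0, "participant", self.participant_id)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, participant_id: str | None = None) -> "ParticipantDataset":
        missing_cols = set(_SCHEMA) - set(df.columns)
        if missing_cols:
            raise ValueError(f"missing columns: {sorted(missing_cols)}")
        if participant_id is None:
            ids = df["participant"].unique()
            if len(ids) != 1:
                raise ValueError("frame contains multiple participants")
            participant_id = str(ids[0])
        df = df.sort_values("probe")
        return cls(
            participant_id=participant_id,
            **{name: df[name].to_numpy() for name in _SCHEMA if name != "participant"},
        )


def generate_trial(
    state: DoubleStaircase,
    ability: float,
    rng: np.random.Generator,
    kappa: float = DEFAULT_KAPPA,
) -> tuple[int, TrialFeatures, DoubleStaircase]:
    """Simulate one trial against the staircase controller.

    Win probability is ``sigmoid(kappa * (ability - difficulty))``; task
    features increase with difficulty (affine maps plus noise, clipped);
    key-press accuracy increases with ability; pauses are bounded noise.
    """
    d = state.current_difficulty
    p_win = _sigmoid(kappa * (ability - d))
    outcome = int(rng.random() < p_win)
    features = TrialFeatures(
        path_length=int(np.clip(np.rint(10.0 + 2.5 * d + 1.5 * rng.standard_normal()), 3, 40)),
        prop_nonup=float(np.clip(0.35 + 0.08 * d + 0.08 * rng.standard_normal(), 0.0, 1.0)),
        prop_correct_keys=float(_sigmoid(1.0 * ability + 0.5 * rng.standard_normal())),
        prop_pauses=float(rng.beta(2.0, 10.0)),
        time_limit=float(np.clip(30.0 - 2.0 * d, 5.0, 60.0)),
        difficulty=d,
    )
    return outcome, features, staircase_update(state, outcome)


# Fixed standardisation of the previous skill report used when *sampling*
# attributions (the fitted models z-score reports within participant, which
# is only possible once the full series exists).
_SKILL_FEATURE_LOC = 0.5
_SKILL_FEATURE_SCALE = 0.2


def _zscore_cols(mat: np.ndarray) -> np.ndarray:
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        sd = col.std(ddof=1) if len(col) > 1 else 0.0
        out[:, j] = 0.0 if sd == 0 else (col - col.mean()) / sd
    return out


def generate_dataset(
    participant: GenerativeParticipant,
    n_probes: int = 120,
    seed: int | np.random.Generator = 0,
    participant_id: str = "p0",
    kappa: float = DEFAULT_KAPPA,
    staircase: DoubleStaircase | None = None,
) -> ParticipantDataset:
    """Generate one participant's probe-aligned dataset.

    Trials run in pairs through the staircase; every second trial is probed.
    The first half of the probes belongs to session 1.  At each probe the
    attribution is sampled from the participant's attribution model given
    the probed trial's (z-scored) features and the standardised previous
    skill report, then replaced by ``missing`` with ``missing_prob``; the
    latent skill then advances by the Rescorla-Wagner rule using the
    attribution class just produced, and the report is the latent value
    plus Gaussian noise, clipped to [0, 1].
    """
    if n_probes < 2:
        raise ValueError("n_probes must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = staircase or DoubleStaircase()
    sp = participant.skill_params
    spec = participant.skill_spec
    aspec = participant.attribution_spec
    weights = participant.attribution_weights

    outcomes = np.empty(n_probes, dtype=int)
    feats: list[TrialFeatures] = []
    for t in range(n_probes):
        _, _, state = generate_trial(state, participant.ability, rng, kappa)
        o, f, state = generate_trial(state, participant.ability, rng, kappa)
        outcomes[t] = o
        feats.append(f)

    session = np.where(np.arange(n_probes) < n_probes // 2, 1, 2)
    t0 = int(n_probes // 2)

    raw = np.array(
        [
            [f.prop_correct_keys, f.prop_pauses, f.path_length, f.prop_nonup]
            for f in feats
        ]
    )
    zcols = dict(zip(("prop_correct_keys", "prop_pauses", "path_length", "prop_nonup"),
                     _zscore_cols(raw).T))

    attributions = np.empty(n_probes, dtype=object)
    reports = np.empty(n_probes)
    s = sp.s0
    prev_report = None
    for t in range(n_probes):
        fvec = np.ones(aspec.n_features)
        for j, name in enumerate(aspec.features, start=1):
            if name == "skill_estimate":
                if prev_report is None:
                    fvec[j] = 0.0
                else:
                    fvec[j] = (prev_report - _SKILL_FEATURE_LOC) / _SKILL_FEATURE_SCALE
            else:
                fvec[j] = zcols[name][t]
        if rng.random() < participant.missing_prob:
            attributions[t] = "missing"
            att_class = "missing"
        else:
            probs = choice_probabilities(option_scores(weights, fvec, int(outcomes[t])))
            attributions[t] = OPTIONS[rng.choice(4, p=probs)]
            att_class = "internal" if attributions[t] == "ability" else "external"
        alpha = sp.alphas[learning_rate_index(spec, int(session[t]), int(outcomes[t]), att_class)]
        s = s + alpha * (outcomes[t] - s)
        if t == t0:
            s += sp.session_offset
        s = float(np.clip(s, 0.0, 1.0))
        reports[t] = float(np.clip(s + sp.report_noise_sd * rng.standard_normal(), 0.0, 1.0))
        prev_report = reports[t]

    return ParticipantDataset(
        participant_id=participant_id,
        probe=np.arange(n_probes),
        session=session,
        outcome=outcomes,
        attribution=attributions,
        skill_report=reports,
        path_length=np.array([f.path_length for f in feats], dtype=float),
        prop_nonup=np.array([f.prop_nonup for f in feats]),
        prop_correct_keys=np.array([f.prop_correct_keys for f in feats]),
        prop_pauses=np.array([f.prop_pauses for f in feats]),
        time_limit=np.array([f.time_limit for f in feats]),
        difficulty=np.array([f.difficulty for f in feats]),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Population settings of a synthetic cohort.

    Individual abilities are Normal(``ability_loc``, ``ability_scale``).
    Skill learning rates are drawn per participant and rate cell from a Beta
    distribution with mean ``alpha_mean`` (concentration ``alpha_conc``);
    for A-containing specs the internal-attribution rates sit
    ``internal_advantage`` above the external ones, and missing-attribution
    rates at the external level.  Attribution weights are Normal around
    ``attribution_weight_means`` (a mapping from parameter name patterns to
    means) with s.d. ``attribution_weight_sd``.
    """

    n_participants: int = 40
    n_probes: int = 120
    skill_spec: str = "SAO"
    attribution_spec: str = "bias_skill"
    ability_loc: float = 0.0
    ability_scale: float = 1.0
    alpha_mean: float = 0.15
    alpha_conc: float = 40.0
    internal_advantage: float = 0.1
    s0_mean: float = 0.5
    s0_conc: float = 20.0
    session_offset_sd: float = 0.02
    report_noise_sd: float = 0.1
    missing_prob: float = 0.1
    bias_internal_win: float = 0.5
    bias_internal_loss: float = -0.5
    skill_weight_win: float = 0.8
    skill_weight_loss: float = -0.8
    weight_sd: float = 0.3
    kappa: float = DEFAULT_KAPPA


def _draw_skill_params(cfg: CohortConfig, spec: SkillModelSpec, rng) -> SkillParams:
    a, b = cfg.alpha_mean * cfg.alpha_conc, (1 - cfg.alpha_mean) * cfg.alpha_conc
    alphas = np.empty(spec.n_rates)
    if spec.vary_by_attribution:
        sessions = (1, 2) if spec.vary_by_session else (1,)
        outcomes = (0, 1) if spec.vary_by_outcome else (0,)
        for s in sessions:
            for o in outcomes:
                ext = rng.beta(a, b)
                alphas[learning_rate_index(spec, s, o, "external")] = ext
                alphas[learning_rate_index(spec, s, o, "internal")] = min(
                    ext + cfg.internal_advantage, 1.0
                )
                alphas[learning_rate_index(spec, s, o, "missing")] = rng.beta(a, b)
    else:
        alphas[:] = rng.beta(a, b, size=spec.n_rates)
    s0 = rng.beta(cfg.s0_mean * cfg.s0_conc, (1 - cfg.s0_mean) * cfg.s0_conc)
    offset = cfg.session_offset_sd * rng.standard_normal()
    return SkillParams(
        alphas=alphas,
        s0=float(s0),
        session_offset=float(np.clip(offset, -1.0, 1.0)),
        report_noise_sd=cfg.report_noise_sd,
    )


def _draw_attribution_weights(cfg: CohortConfig, aspec: AttributionModelSpec, rng) -> OptionWeights:
    nf = aspec.n_features
    win = cfg.weight_sd * rng.standard_normal((3, nf))
    loss = cfg.weight_sd * rng.standard_normal((3, nf))
    win[0, 0] += cfg.bias_internal_win
    loss[0, 0] += cfg.bias_internal_loss
    if "skill_estimate" in aspec.features:
        j = 1 + aspec.features.index("skill_estimate")
        win[0, j] += cfg.skill_weight_win
        loss[0, j] += cfg.skill_weight_loss
    return OptionWeights(win=win, loss=loss)


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[list[ParticipantDataset], pd.DataFrame]:
    """Generate a cohort plus a table of the generating parameters."""
    cfg = config or CohortConfig()
    spec = SkillModelSpec.from_name(cfg.skill_spec)
    aspec = AttributionModelSpec(cfg.attribution_spec)
    root = np.random.SeedSequence(seed)
    keys = root.spawn(cfg.n_participants)
    datasets, rows = [], []
    for p in range(cfg.n_participants):
        rng = np.random.default_rng(keys[p])
        sp = _draw_skill_params(cfg, spec, rng)
        w = _draw_attribution_weights(cfg, aspec, rng)
        gp = GenerativeParticipant(
            ability=float(cfg.ability_loc + cfg.ability_scale * rng.standard_normal()),
            skill_spec=spec,
            skill_params=sp,
            attribution_spec=aspec,
            attribution_weights=w,
            missing_prob=cfg.missing_prob,
        )
        pid = f"p{p:03d}"
        datasets.append(
            generate_dataset(gp, n_probes=cfg.n_probes, seed=rng, participant_id=pid,
                             kappa=cfg.kappa)
        )
        row = {"participant": pid, "ability": gp.ability, "s0": sp.s0,
               "session_offset": sp.session_offset}
        for lbl, val in zip(spec.rate_labels(), sp.alphas):
            row[lbl] = float(val)
        from .attribution import param_names as _apn

        for name, val in zip(_apn(aspec), w.to_vector()):
            row[name] = float(val)
        rows.append(row)
    return datasets, pd.DataFrame(rows)


def write_dataset(datasets: Sequence[ParticipantDataset], path) -> None:
    """Write a cohort as tidy CSV (one row per participant x probe)."""
    frames = [ds.to_frame() for ds in datasets]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(_SCHEMA))
    df.to_csv(path, index=False)


def datasets_from_frame(df: pd.DataFrame) -> list[ParticipantDataset]:
    if "participant" not in df.columns:
        raise ValueError("frame lacks a 'participant' column")
    out = []
    for pid, grp in df.groupby("participant", sort=True):
        out.append(ParticipantDataset.from_frame(grp, participant_id=str(pid)))
    return out


def read_dataset(path) -> list[ParticipantDataset]:
    """Read a cohort CSV, validating the schema row by row.

    Malformed rows are reported with their line numbers (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = set(_SCHEMA) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    if df.empty:
        return []
    errors = []
    for i, row in df.iterrows():
        line = i + 2  # header occupies line 1
        try:
            o = float(row["outcome"])
            if o not in (0.0, 1.0):
                raise ValueError(f"outcome must be 0 or 1, got {row['outcome']!r}")
            if str(row["attribution"]) not in ATTRIBUTION_VALUES:
                raise ValueError(f"unknown attribution {row['attribution']!r}")
            if int(row["session"]) not in (1, 2):
                raise ValueError(f"session must be 1 or 2, got {row['session']!r}")
            r = float(row["skill_report"])
            if np.isfinite(r) and not (0.0 <= r <= 1.0):
                raise ValueError(f"skill_report out of [0, 1]: {r}")
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(errors[:20]))
    return datasets_from_frame(df)


def cohort_fingerprint(datasets: Sequence[ParticipantDataset]) -> int:
    """Stable hash of a cohort's observable data (used to refuse comparing
    models fitted to different datasets)."""
    h = 0
    for ds in datasets:
        df = ds.to_frame()
        h ^= int(pd.util.hash_pandas_object(df.astype(str)).sum()) & 0x7FFFFFFFFFFFFFFF
    return h
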