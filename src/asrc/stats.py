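"""Model-agnostic analyses: permutation tests on updates, attributions and
correlations.

All hypothesis tests are permutation tests: labels are shuffled *within
participant*, the statistic of interest (a paired t across participants, a
two-way repeated-measures interaction F, or a Pearson r) is recomputed per
permutation, and the two-sided p-value uses the add-one convention
``p = (1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_perm)``, which respects
the floor ``1 / (n_perm + 1)``.  Effect sizes are Hedges' bias-corrected d.

Skill-estimate updates are first differences of within-participant z-scored
reports; attribution proportions are computed per quartile of a z-scored
continuous factor (quartiles assigned by rank, so bins are balanced even
with ties).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationTestResult",
    "EffectSizeInputs",
    "skill_updates",
    "updates_table",
    "paired_permutation_test",
    "hedges_d",
    "quartile_proportions",
    "rm_anova_interaction_F",
    "interaction_permutation_test",
    "bh_adjust",
    "correlation_permutation",
    "attribution_update_test",
    "outcome_update_test",
]


@dataclass(frozen=True)
class PermutationTestResult:
    """A permutation-test outcome.

    ``p_value`` uses the add-one convention; ``exceedances`` is the raw
    count of permutations at least as extreme, so ``exceedances == 0``
    corresponds to the conventional report "p < 1/n_perm".
    """

    statistic: float
    p_value: float
    n_perm: int
    exceedances: int
    statistic_name: str = "t"
    effect_size: float | None = None
    n_units: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")

    def __str__(self) -> str:
        p = (
            f"p < 1/{self.n_perm}"
            if self.exceedances == 0
            else f"p = {self.p_value:.4g}"
        )
        d = f", d = {self.effect_size:.3g}" if self.effect_size is not None else ""
        return f"{self.statistic_name} = {self.statistic:.4g}, {p}{d} ({self.n_perm} permutations)"


@dataclass(frozen=True)
class EffectSizeInputs:
    mu1: float
    mu2: float
    sd1: float
    sd2: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("sample sizes must be >= 2")


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        warnings.warn("constant series: z-scores undefined, returning zeros", RuntimeWarning)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def skill_updates(reports) -> np.ndarray:
    """First differences of within-participant z-scored skill reports."""
    reports = np.asarray(reports, dtype=float)
    if len(reports) < 2:
        raise ValueError("need at least 2 reports")
    return np.diff(_zscore(reports))


def updates_table(datasets) -> pd.DataFrame:
    """Tidy table of skill-estimate updates with outcome and attribution.

    The update at probe ``t`` (z-scored report difference S_t - S_{t-1}) is
    paired with the outcome and attribution class of probe ``t``, i.e. the
    attribution given for the outcome that produced the update.
    """
    rows = []
    for ds in datasets:
        updates = skill_updates(ds.skill_report)
        cls = ds.attribution_class
        for i, u in enumerate(updates):
            t = i + 1
            rows.append(
                {
                    "participant": ds.participant_id,
                    "probe": int(ds.probe[t]),
                    "update": float(u),
                    "outcome": int(ds.outcome[t]),
                    "attribution_class": str(cls[t]),
                }
            )
    return pd.DataFrame(rows)


def _paired_t(diffs: np.ndarray) -> float:
    n = len(diffs)
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 0.0 if np.mean(diffs) == 0 else np.inf * np.sign(np.mean(diffs))
    return float(diffs.mean() / (sd / np.sqrt(n)))


def hedges_d(inputs: EffectSizeInputs | None = None, **kwargs) -> float:
    """Hedges' bias-corrected d:

        d = (1 - 3 / (4 (l1 + l2) - 9)) * (mu1 - mu2) / s_pooled

    with the pooled s.d. using (l - 1) weights.  Accepts an
    :class:`EffectSizeInputs` or the keyword fields directly.
    """
    e = inputs if inputs is not None else EffectSizeInputs(**kwargs)
    pooled = np.sqrt(
        ((e.n1 - 1) * e.sd1**2 + (e.n2 - 1) * e.sd2**2) / (e.n1 + e.n2 - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation: effect size undefined")
    correction = 1.0 - 3.0 / (4.0 * (e.n1 + e.n2) - 9.0)
    return float(correction * (e.mu1 - e.mu2) / pooled)


def _hedges_from_samples(x1: np.ndarray, x2: np.ndarray) -> float | None:
    try:
        return hedges_d(
            mu1=float(np.mean(x1)),
            mu2=float(np.mean(x2)),
            sd1=float(np.std(x1, ddof=1)),
            sd2=float(np.std(x2, ddof=1)),
            n1=len(x1),
            n2=len(x2),
        )
    except ValueError:
        return None


def paired_permutation_test(samples, n_perm: int = 5000, seed: int | None = None) -> PermutationTestResult:
    """Within-participant label permutation test with a paired t statistic.

    ``samples`` is a sequence of ``(values, labels)`` pairs, one per
    participant, where ``labels`` assigns each underlying observation to
    condition 0 or 1.  Per permutation, labels are shuffled within
    participant, per-participant condition means are recomputed, and the
    paired (condition 1 vs 0) t across participants is recorded.
    Participants lacking one of the conditions are excluded (count logged).
    """
    values, labels = [], []
    excluded = 0
    for v, l in samples:
        v = np.asarray(v, dtype=float)
        l = np.asarray(l, dtype=int)
        if len(v) != len(l):
            raise ValueError("values and labels must have equal length")
        if not np.isin(l, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if l.sum() == 0 or l.sum() == len(l):
            excluded += 1
            continue
        values.append(v)
        labels.append(l)
    if excluded:
        logger.info("paired permutation test: %d participants lacked a condition", excluded)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 participants with both conditions")
    rng = np.random.default_rng(seed)

    obs_diff = np.array([v[l == 1].mean() - v[l == 0].mean() for v, l in zip(values, labels)])
    t_obs = _paired_t(obs_diff)

    perm_diff = np.empty((n_perm, n))
    for i, (v, l) in enumerate(zip(values, labels)):
        m, n1 = len(v), int(l.sum())
        order = np.argsort(rng.random((n_perm, m)), axis=1)
        shuffled = v[order]
        perm_diff[:, i] = shuffled[:, :n1].mean(axis=1) - shuffled[:, n1:].mean(axis=1)
    means = perm_diff.mean(axis=1)
    sds = perm_diff.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(sds > 0, means / (sds / np.sqrt(n)), 0.0)
    exceed = int(np.sum(np.abs(t_perm) >= np.abs(t_obs)))
    p = (1 + exceed) / (1 + n_perm)

    m1 = np.array([v[l == 1].mean() for v, l in zip(values, labels)])
    m0 = np.array([v[l == 0].mean() for v, l in zip(values, labels)])
    return PermutationTestResult(
        statistic=t_obs,
        p_value=p,
        n_perm=n_perm,
        exceedances=exceed,
        statistic_name="paired t",
        effect_size=_hedges_from_samples(m1, m0),
        n_units=n,
        seed=seed,
    )


def _rank_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bins with ties broken by rank (bins as balanced as possible)."""
    ranks = rankdata(values, method="ordinal") - 1
    return (ranks * n_bins // len(values)).astype(int)


def _factor_values(ds, factor: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe factor values and a validity mask.

    ``skill_estimate`` means the previous probe's skill report (the first
    probe has none and is dropped).
    """
    n = len(ds.outcome)
    valid = np.ones(n, dtype=bool)
    if factor == "skill_estimate":
        vals = np.concatenate([[np.nan], np.asarray(ds.skill_report, dtype=float)[:-1]])
        valid &= np.isfinite(vals)
    else:
        vals = np.asarray(getattr(ds, factor), dtype=float)
    return vals, valid


def quartile_proportions(
    datasets, option: str, factor: str, n_bins: int = 4
) -> pd.DataFrame:
    """Per participant, quartile bin and outcome: the proportion of probes
    attributed to ``option`` out of all non-missing attributions in the cell.

    The factor is z-scored within participant before rank-based quartile
    discretisation.  Empty cells are recorded as NaN.
    """
    rows = []
    for ds in datasets:
        vals, valid = _factor_values(ds, factor)
        att = ds.attribution.astype(str)
        mask = valid & (att != "missing")
        if mask.sum() < n_bins:
            logger.info("participant %s skipped: too few probes", ds.participant_id)
            continue
        z = _zscore(vals[mask])
        bins = _rank_bins(z, n_bins)
        outcome = ds.outcome[mask]
        hit = (att[mask] == option).astype(float)
        for b in range(n_bins):
            for o in (0, 1):
                cell = (bins == b) & (outcome == o)
                rows.append(
                    {
                        "participant": ds.participant_id,
                        "bin": b,
                        "outcome": o,
                        "proportion": float(hit[cell].mean()) if cell.any() else np.nan,
                        "n": int(cell.sum()),
                    }
                )
    return pd.DataFrame(rows)


def rm_anova_interaction_F(cells: np.ndarray) -> float:
    """Two-way repeated-measures interaction F from a complete cell table.

    ``cells`` has shape (participants, levels_A, levels_B); the error term
    is the A x B x participant residual.
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3:
        raise ValueError("cells must be (participants, A, B)")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if not np.all(np.isfinite(y)):
        raise ValueError("cell table contains missing values")
    grand = y.mean()
    m_ab = y.mean(axis=0)  # (a, b)
    m_a = y.mean(axis=(0, 2))  # (a,)
    m_b = y.mean(axis=(0, 1))  # (b,)
    m_s = y.mean(axis=(1, 2))  # (n,)
    m_as = y.mean(axis=2)  # (n, a)
    m_bs = y.mean(axis=1)  # (n, b)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_err = np.sum(resid**2)
    df_ab = (a - 1) * (b - 1)
    df_err = df_ab * (n - 1)
    eps = 1e-12 * (1.0 + np.abs(y).max() ** 2)
    if ss_err <= eps:
        return 0.0 if ss_ab <= eps else np.inf
    return float((ss_ab / df_ab) / (ss_err / df_err))


def _cell_table_perms(bins, outcome, hit, n_bins, n_perm, rng):
    """Cell proportions for permuted bin labels, shape (n_perm, n_bins, 2).

    Shuffling the raw factor values within participant and re-binning is
    equivalent to shuffling the precomputed bin labels, because the rank
    bins are a deterministic function of the value multiset.
    """
    m = len(bins)
    order = np.argsort(rng.random((n_perm, m)), axis=1)
    b_perm = bins[order]  # (n_perm, m)
    cell = b_perm * 2 + outcome[None, :]
    flat = (cell + (np.arange(n_perm) * (2 * n_bins))[:, None]).ravel()
    counts = np.bincount(flat, minlength=2 * n_bins * n_perm).reshape(n_perm, n_bins, 2)
    numer = np.bincount(
        flat, weights=np.broadcast_to(hit, (n_perm, m)).ravel(), minlength=2 * n_bins * n_perm
    ).reshape(n_perm, n_bins, 2)
    with np.errstate(invalid="ignore"):
        prop = numer / counts
    # rare empty cells: fall back to the participant's outcome-marginal rate
    if np.any(counts == 0):
        marg_n = np.bincount(outcome, weights=hit, minlength=2)
        marg_d = np.bincount(outcome, minlength=2)
        marg = np.where(marg_d > 0, marg_n / np.maximum(marg_d, 1), hit.mean())
        prop = np.where(counts == 0, marg[None, None, :], prop)
    return prop


def interaction_permutation_test(
    datasets,
    option: str,
    factor: str,
    n_bins: int = 4,
    n_perm: int = 5000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Factor-quartile x outcome interaction on attribution proportions.

    The observed statistic is the two-way repeated-measures interaction F
    on the participants x quartile x outcome cell table; the null shuffles
    each participant's factor values (within participant) before
    re-binning.  Participants with an incomplete observed cell table are
    excluded; fewer than 3 remaining participants is an error.
    """
    rng = np.random.default_rng(seed)
    per_part = []
    for ds in datasets:
        vals, valid = _factor_values(ds, factor)
        att = ds.attribution.astype(str)
        mask = valid & (att != "missing")
        if mask.sum() < 2 * n_bins:
            continue
        bins = _rank_bins(_zscore(vals[mask]), n_bins)
        outcome = ds.outcome[mask].astype(int)
        hit = (att[mask] == option).astype(float)
        obs = np.full((n_bins, 2), np.nan)
        for b in range(n_bins):
            for o in (0, 1):
                cell = (bins == b) & (outcome == o)
                if cell.any():
                    obs[b, o] = hit[cell].mean()
        if np.all(np.isfinite(obs)):
            per_part.append((bins, outcome, hit, obs))
    if len(per_part) < 3:
        raise ValueError("need at least 3 participants with complete cell tables")

    observed = np.stack([p[3] for p in per_part])
    f_obs = rm_anova_interaction_F(observed)

    perm_cells = np.stack(
        [
            _cell_table_perms(bins, outcome, hit, n_bins, n_perm, rng)
            for bins, outcome, hit, _ in per_part
        ],
        axis=1,
    )  # (n_perm, participants, bins, 2)
    f_perm = np.array([rm_anova_interaction_F(perm_cells[k]) for k in range(n_perm)])
    exceed = int(np.sum(f_perm >= f_obs))
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(
        statistic=f_obs,
        p_value=p,
        n_perm=n_perm,
        exceedances=exceed,
        statistic_name="interaction F",
        n_units=len(per_part),
        seed=seed,
    )


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: rejection mask plus the p threshold.

    The threshold is the largest rejected p-value (0.0 if nothing is
    rejected).
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


def correlation_permutation(
    x, y, n_perm: int = 5000, seed: int | None = None
) -> PermutationTestResult:
    """Pearson correlation with a permutation null (y permuted)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / (x.std(ddof=1) * np.sqrt(n - 1))
    yc = (y - y.mean()) / (y.std(ddof=1) * np.sqrt(n - 1))
    r_obs = float(xc @ yc)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = yc[order] @ xc
    exceed = int(np.sum(np.abs(r_perm) >= np.abs(r_obs)))
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(
        statistic=r_obs,
        p_value=p,
        n_perm=n_perm,
        exceedances=exceed,
        statistic_name="r",
        n_units=n,
        seed=seed,
    )


def outcome_update_test(datasets, n_perm: int = 5000, seed: int | None = None) -> PermutationTestResult:
    """Wins vs losses effect on z-scored skill-estimate updates."""
    table = updates_table(datasets)
    samples = [
        (grp["update"].to_numpy(), grp["outcome"].to_numpy())
        for _, grp in table.groupby("participant")
    ]
    return paired_permutation_test(samples, n_perm=n_perm, seed=seed)


def attribution_update_test(
    datasets, outcome: int, n_perm: int = 5000, seed: int | None = None
) -> PermutationTestResult:
    """Internal vs external effect on updates, conditioned on an outcome."""
    table = updates_table(datasets)
    table = table[
        (table["outcome"] == outcome)
        & table["attribution_class"].isin(["internal", "external"])
    ]
    samples = [
        (
            grp["update"].to_numpy(),
            (grp["attribution_class"] == "internal").to_numpy().astype(int),
        )
        for _, grp in table.groupby("participant")
    ]
    return paired_permutation_test(samples, n_perm=n_perm, seed=seed)
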