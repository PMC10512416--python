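"""Group-level inference for the anxiety × emotion sensitivity analysis.

Covers the full inferential chain: the trait-anxiety cutoff split (score
≤ 39 → Low), normality (Lilliefors / Kolmogorov–Smirnov against a fitted
normal) and Mauchly sphericity checks, a 2 × 4 mixed-design ANOVA
(between: anxiety group; within: target emotion) with partial η² and
Bonferroni-corrected simple main effects, the Mann–Whitney U test with
rank-biserial and z/√N effect sizes, and the η² → Cohen's f conversion
with a noncentral-F sample-size utility for the within-between interaction.

The ANOVA uses unweighted-means classical sums of squares: the within
layout is complete (every subject contributes all four emotions) and only
the between factor is unbalanced, so cell means are weighted by the
harmonic mean of the group sizes, matching the Type-III convention of
mainstream statistics packages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .design import EMOTIONS

TRAIT_CUTOFF = 39
ALPHA = 0.05

#: no-tie sample sizes up to which the Mann–Whitney p is computed exactly
_EXACT_N_MAX = 20


# ---------------------------------------------------------------- group split


@dataclass(frozen=True)
class GroupSplit:
    low_ids: tuple[str, ...]
    high_ids: tuple[str, ...]
    cutoff: int = TRAIT_CUTOFF


def split_by_cutoff(traits: dict[str, int], cutoff: int = TRAIT_CUTOFF) -> GroupSplit:
    """Partition ids into Low (score ≤ cutoff) and High (score > cutoff)."""
    if not traits:
        raise ValueError("traits map is empty")
    low = tuple(sorted(i for i, s in traits.items() if s <= cutoff))
    high = tuple(sorted(i for i, s in traits.items() if s > cutoff))
    if not low:
        raise ValueError(f"no participants with trait score <= {cutoff} (empty Low group)")
    if not high:
        raise ValueError(f"no participants with trait score > {cutoff} (empty High group)")
    return GroupSplit(low_ids=low, high_ids=high, cutoff=cutoff)


# ------------------------------------------------------------- normality etc.


@dataclass(frozen=True)
class NormalityResult:
    kind: str
    statistic: float
    p: float
    passed: bool  # True when normality is not rejected at α = 0.05


def normality_tests(sample, kind: str = "lilliefors") -> NormalityResult:
    """D statistic against a normal with parameters estimated from the sample.

    ``lilliefors`` corrects the p-value for parameter estimation
    (Monte-Carlo table); ``ks`` reports the naive Kolmogorov–Smirnov p
    against the fitted normal, as applied in practice when the correction is
    omitted.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("normality tests require n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: scale is undefined")
    if kind == "lilliefors":
        d, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    elif kind == "ks":
        d, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown normality test kind {kind!r}")
    return NormalityResult(kind=kind, statistic=float(d), p=float(p), passed=bool(p > ALPHA))


@dataclass(frozen=True)
class SphericityResult:
    W: float
    chi2: float
    df: int
    p: float
    passed: bool


def mauchly_sphericity(matrix) -> SphericityResult:
    """Mauchly's W for a participants × k repeated-measures matrix.

    W = det(S*) / (tr(S*)/(k−1))^(k−1) with S* the covariance projected onto
    orthonormal (Helmert) contrasts; p from the standard chi-square
    approximation.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5:
        raise ValueError("need a 2-D matrix with at least 5 rows")
    n, k = x.shape
    if k < 3:
        raise ValueError("sphericity needs at least 3 repeated measures")
    contrasts = linalg.helmert(k)  # (k-1, k), orthonormal rows
    s = contrasts @ np.cov(x, rowvar=False, ddof=1) @ contrasts.T
    det = np.linalg.det(s)
    trace = np.trace(s)
    if not np.isfinite(det) or det <= 0 or trace <= 0:
        raise ValueError("singular covariance of differences; W undefined")
    w = float(det / (trace / (k - 1)) ** (k - 1))
    correction = 1 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6 * (k - 1) * (n - 1))
    chi2 = float(-(n - 1) * correction * math.log(w))
    df = k * (k - 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return SphericityResult(W=w, chi2=chi2, df=df, p=p, passed=bool(p > ALPHA))


# ----------------------------------------------------------------- mixed ANOVA


@dataclass(frozen=True)
class EffectRow:
    ss: float
    df_num: int
    df_den: int
    ms: float
    F: float
    p: float
    partial_eta2: float


@dataclass(frozen=True)
class MixedAnovaResult:
    effects: dict[str, EffectRow]  # "group", "emotion", "interaction"
    ss_subject_error: float
    ss_within_error: float
    ss_total: float
    ss_between_subjects: float
    ss_within_subjects: float
    n_per_group: dict[str, int]

    @property
    def interaction(self) -> EffectRow:
        return self.effects["interaction"]


def mixed_anova(table: pd.DataFrame, groups: pd.Series | dict | None = None) -> MixedAnovaResult:
    """2 (anxiety group) × 4 (emotion) mixed ANOVA on an eAUC table.

    ``table`` holds one row per participant with one column per emotion;
    group labels come from ``groups`` (id → label) or a ``group`` column.
    Unweighted-means SS for the between, within and interaction effects;
    error terms are the subjects-within-groups and emotion × subjects
    mean squares from the raw data.
    """
    if groups is None:
        if "group" not in table.columns:
            raise ValueError("provide groups or a 'group' column")
        labels = table["group"]
    else:
        labels = pd.Series(dict(groups)).reindex(table.index)
    if labels.isna().any():
        raise ValueError(f"missing group labels for {list(table.index[labels.isna()])}")

    y = table[list(EMOTIONS)].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing cells in the eAUC table")
    level_names = sorted(labels.unique())
    if len(level_names) < 2:
        raise ValueError("both groups must be non-empty")
    group_idx = [np.flatnonzero((labels == g).to_numpy()) for g in level_names]

    n, m = y.shape
    g = len(level_names)
    sizes = np.array([len(ix) for ix in group_idx])
    n_h = g / np.sum(1.0 / sizes)

    cell = np.stack([y[ix].mean(axis=0) for ix in group_idx])  # (g, m)
    row = cell.mean(axis=1, keepdims=True)
    col = cell.mean(axis=0, keepdims=True)
    grand = cell.mean()

    ss_group = m * n_h * float(np.sum((row - grand) ** 2))
    ss_emotion = g * n_h * float(np.sum((col - grand) ** 2))
    ss_inter = n_h * float(np.sum((cell - row - col + grand) ** 2))

    subj_mean = y.mean(axis=1)
    group_of = np.empty(n, dtype=int)
    for gi, ix in enumerate(group_idx):
        group_of[ix] = gi
    group_mean = np.array([subj_mean[ix].mean() for ix in group_idx])
    ss_subj_err = m * float(np.sum((subj_mean - group_mean[group_of]) ** 2))
    resid = y - subj_mean[:, None] - cell[group_of] + group_mean[group_of, None]
    ss_within_err = float(np.sum(resid**2))

    df_group, df_emotion = g - 1, m - 1
    df_inter = df_group * df_emotion
    df_subj_err = n - g
    df_within_err = (n - g) * (m - 1)
    if ss_subj_err <= 0 or ss_within_err <= 0:
        raise ValueError("zero error variance; F statistics undefined")

    def effect(ss: float, df_num: int, ss_err: float, df_den: int) -> EffectRow:
        ms, ms_err = ss / df_num, ss_err / df_den
        f = ms / ms_err
        return EffectRow(
            ss=ss,
            df_num=df_num,
            df_den=df_den,
            ms=ms,
            F=f,
            p=float(sps.f.sf(f, df_num, df_den)),
            partial_eta2=ss / (ss + ss_err),
        )

    grand_all = y.mean()
    return MixedAnovaResult(
        effects={
            "group": effect(ss_group, df_group, ss_subj_err, df_subj_err),
            "emotion": effect(ss_emotion, df_emotion, ss_within_err, df_within_err),
            "interaction": effect(ss_inter, df_inter, ss_within_err, df_within_err),
        },
        ss_subject_error=ss_subj_err,
        ss_within_error=ss_within_err,
        ss_total=float(np.sum((y - grand_all) ** 2)),
        ss_between_subjects=m * float(np.sum((subj_mean - grand_all) ** 2)),
        ss_within_subjects=float(np.sum((y - subj_mean[:, None]) ** 2)),
        n_per_group={name: int(s) for name, s in zip(level_names, sizes)},
    )


# --------------------------------------------------------- simple main effects


@dataclass(frozen=True)
class SimpleEffectResult:
    emotion: str
    mean_diff: float  # Low − High
    sem: float
    p_uncorrected: float
    p_bonferroni: float


def simple_main_effects(
    table: pd.DataFrame, split: GroupSplit, family_size: int = 4
) -> list[SimpleEffectResult]:
    """Per-emotion Low − High contrasts, Bonferroni-corrected over the family.

    Each contrast is a pooled-variance two-sample comparison of group means
    at that emotion (the follow-up to a significant interaction).
    """
    low = table.loc[list(split.low_ids), list(EMOTIONS)].to_numpy(dtype=float)
    high = table.loc[list(split.high_ids), list(EMOTIONS)].to_numpy(dtype=float)
    n1, n2 = low.shape[0], high.shape[0]
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    out = []
    for j, emo in enumerate(EMOTIONS):
        diff = low[:, j].mean() - high[:, j].mean()
        pooled = (
            (n1 - 1) * low[:, j].var(ddof=1) + (n2 - 1) * high[:, j].var(ddof=1)
        ) / (n1 + n2 - 2)
        sem = math.sqrt(pooled * (1 / n1 + 1 / n2))
        t = diff / sem
        p = float(2 * sps.t.sf(abs(t), n1 + n2 - 2))
        out.append(
            SimpleEffectResult(
                emotion=emo,
                mean_diff=float(diff),
                sem=float(sem),
                p_uncorrected=p,
                p_bonferroni=min(1.0, p * family_size),
            )
        )
    return out


# ----------------------------------------------------------------- Mann–Whitney


@dataclass(frozen=True)
class MWUResult:
    U: float
    z: float
    p: float
    r_rank_biserial: float
    r_z: float
    exact: bool


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Exact null distribution of U (counts over 0..n1·n2), no ties."""
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_null_counts(n1 - 1, n2)  # shifted by n2
    b = _u_null_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney(x, y) -> MWUResult:
    """Mann–Whitney U with midrank ties, tie-corrected z (no continuity
    correction), and exact two-tailed p for small untied samples.

    ``U`` is the count of (x, y) pairs where x exceeds y (midranks giving
    half credit); ``r_rank_biserial = 1 − 2U/(n1·n2)`` is positive when x
    tends to fall below y.  ``r_z = |z|/√(n1+n2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    z = 0.0 if var == 0 else (u1 - mu) / math.sqrt(var)

    has_ties = bool(np.any(tie_counts > 1))
    if not has_ties and n <= _EXACT_N_MAX:
        counts = _u_null_counts(n1, n2)
        total = math.comb(n, n1)
        u_low = int(min(u1, n1 * n2 - u1))
        p = min(1.0, 2.0 * sum(counts[: u_low + 1]) / total)
        exact = True
    else:
        p = float(2 * sps.norm.sf(abs(z)))
        exact = False

    return MWUResult(
        U=u1,
        z=float(z),
        p=float(p),
        r_rank_biserial=float(1 - 2 * u1 / (n1 * n2)),
        r_z=float(abs(z) / math.sqrt(n)),
        exact=exact,
    )


# ------------------------------------------------- effect size and sample size


def eta2_to_f(partial_eta2: float) -> float:
    """Cohen's f = √(η² / (1 − η²))."""
    if not 0 <= partial_eta2 < 1:
        raise ValueError("partial eta squared must lie in [0, 1)")
    return math.sqrt(partial_eta2 / (1 - partial_eta2))


def f_to_eta2(f: float) -> float:
    """Inverse conversion: η² = f² / (1 + f²)."""
    if f < 0:
        raise ValueError("f must be non-negative")
    return f * f / (1 + f * f)


def interaction_power(
    n_total: int,
    f: float,
    alpha: float = 0.05,
    n_groups: int = 2,
    n_measurements: int = 4,
    rho: float = 0.5,
    epsilon: float = 1.0,
) -> float:
    """Power of the within-between interaction F test at total sample N.

    Noncentrality λ = N·f²·(m·ε)/(1 − ρ) with df = ((g−1)(m−1)ε, (N−g)(m−1)ε),
    the convention of standard a-priori power calculators for repeated
    measures with equicorrelation ρ.
    """
    df1 = (n_groups - 1) * (n_measurements - 1) * epsilon
    df2 = (n_total - n_groups) * (n_measurements - 1) * epsilon
    if df2 < 1:
        return 0.0
    lam = n_total * f * f * (n_measurements * epsilon) / (1 - rho)
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def required_sample_size(
    f: float,
    alpha: float = 0.05,
    power: float = 0.8,
    n_groups: int = 2,
    n_measurements: int = 4,
    rho: float = 0.5,
    epsilon: float = 1.0,
    n_max: int = 10_000,
) -> int:
    """Smallest total N whose interaction-test power meets the target."""
    if f <= 0:
        raise ValueError("effect size f must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    for n_total in range(2 * n_groups, n_max + 1):
        if interaction_power(n_total, f, alpha, n_groups, n_measurements, rho, epsilon) >= power:
            return n_total
    raise ValueError(f"no N <= {n_max} reaches the requested power")
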