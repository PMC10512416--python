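"""Rating-scale signal detection: corrected hit / false-alarm rates, the
six-point empirical ROC, trapezoidal eAUC, and the chance-level exclusion
rule.

Rates use the loglinear correction (h + 0.5)/(n + 1), which keeps every
operating point strictly inside the unit square so the ROC is well defined
even for degenerate observers.  The six operating points come from
cumulative thresholding of confidence-graded "target" judgments: at level k
a response counts toward the hit (or false-alarm) tally if it was a
"target" judgment with confidence ≥ k.  Sweeping k = 6 … 1 traces the ROC
from conservative to liberal; the curve is closed with (0,0) and (1,1) and
the area is the trapezoidal (chord) area, i.e. linear interpolation
between observed points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import EMOTIONS

CONF_LEVELS = (1, 2, 3, 4, 5, 6)
CHANCE_LEVEL = 0.50


@dataclass(frozen=True)
class RatingCounts:
    n_signal: int
    n_noise: int
    hits_by_conf: dict[int, int]
    fas_by_conf: dict[int, int]

    def __post_init__(self) -> None:
        for name, table, total in (
            ("hits_by_conf", self.hits_by_conf, self.n_signal),
            ("fas_by_conf", self.fas_by_conf, self.n_noise),
        ):
            if any(k not in CONF_LEVELS for k in table):
                raise ValueError(f"{name} keys must be confidence levels 1..6")
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{name} counts must be non-negative")
            if sum(table.values()) > total:
                raise ValueError(f"{name} counts exceed the trial total {total}")


@dataclass(frozen=True)
class OperatingPoint:
    fa_rate: float
    hit_rate: float
    conf_threshold: int | None  # None for the (0,0)/(1,1) anchors


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[OperatingPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) != 8:
            raise ValueError("ROCCurve holds six operating points plus two anchors")
        fa = [p.fa_rate for p in self.points]
        hit = [p.hit_rate for p in self.points]
        if any(b < a for a, b in zip(fa, fa[1:])) or any(b < a for a, b in zip(hit, hit[1:])):
            raise ValueError("ROC points must be sorted and monotone in both coordinates")


def corrected_rate(successes: int, n_trials: int) -> float:
    """Loglinear-corrected proportion (successes + 0.5) / (n_trials + 1)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 <= successes <= n_trials:
        raise ValueError(f"successes must lie in [0, {n_trials}], got {successes}")
    return (successes + 0.5) / (n_trials + 1)


def tabulate_counts(trials: Iterable, target_emotion: str) -> RatingCounts:
    """Per-confidence hit and false-alarm tallies for one session's records.

    Accepts any records carrying ``session_target``, ``is_target``,
    ``judgment`` and ``confidence`` attributes.
    """
    hits = {k: 0 for k in CONF_LEVELS}
    fas = {k: 0 for k in CONF_LEVELS}
    n_signal = n_noise = 0
    for t in trials:
        if t.session_target != target_emotion:
            raise ValueError(
                f"trial from session {t.session_target!r} mixed into {target_emotion!r} tabulation"
            )
        if t.is_target:
            n_signal += 1
        else:
            n_noise += 1
        if t.judgment == "target":
            (hits if t.is_target else fas)[t.confidence] += 1
    return RatingCounts(n_signal=n_signal, n_noise=n_noise, hits_by_conf=hits, fas_by_conf=fas)


def rating_roc(counts: RatingCounts) -> ROCCurve:
    """Six-point empirical ROC from cumulative confidence thresholding."""
    if counts.n_signal < 1 or counts.n_noise < 1:
        raise ValueError("need at least one signal and one noise trial")
    pts: list[OperatingPoint] = [OperatingPoint(0.0, 0.0, None)]
    cum_h = cum_f = 0
    for k in range(6, 0, -1):  # conservative → liberal
        cum_h += counts.hits_by_conf.get(k, 0)
        cum_f += counts.fas_by_conf.get(k, 0)
        pts.append(
            OperatingPoint(
                fa_rate=corrected_rate(cum_f, counts.n_noise),
                hit_rate=corrected_rate(cum_h, counts.n_signal),
                conf_threshold=k,
            )
        )
    pts.append(OperatingPoint(1.0, 1.0, None))
    return ROCCurve(points=tuple(pts))


def eauc(roc: ROCCurve) -> float:
    """Trapezoidal area under the ROC; duplicated points contribute zero width."""
    fa = np.array([p.fa_rate for p in roc.points])
    hit = np.array([p.hit_rate for p in roc.points])
    return float(np.trapezoid(hit, fa))


def empirical_auc_from_counts(
    hits_by_conf: np.ndarray, fas_by_conf: np.ndarray, n_signal: int, n_noise: int
) -> np.ndarray:
    """Vectorized eAUC from per-confidence count arrays.

    ``hits_by_conf``/``fas_by_conf`` have a trailing length-6 confidence axis
    (index 0 ↔ confidence 1); leading axes are broadcast (participants,
    sessions, replicates ...).  Identical construction to
    ``eauc(rating_roc(...))`` — cumulative counts, loglinear correction,
    anchors, trapezoid — evaluated without intermediate objects.
    """
    h = np.asarray(hits_by_conf)[..., ::-1].cumsum(axis=-1)  # threshold 6 → 1
    f = np.asarray(fas_by_conf)[..., ::-1].cumsum(axis=-1)
    hit = (h + 0.5) / (n_signal + 1)
    fa = (f + 0.5) / (n_noise + 1)
    shape = hit.shape[:-1] + (1,)
    hit = np.concatenate([np.zeros(shape), hit, np.ones(shape)], axis=-1)
    fa = np.concatenate([np.zeros(shape), fa, np.ones(shape)], axis=-1)
    return np.trapezoid(hit, fa, axis=-1)


def score_trials(trials: Sequence) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a pooled trial-record list into (eAUC table, ROC point table).

    The eAUC table has one row per participant and one column per emotion;
    the ROC table has one row per operating point with columns
    ``participant_id, emotion, conf_threshold, fa_rate, hit_rate``.
    """
    by_ps: dict[tuple[str, str], list] = {}
    for t in trials:
        by_ps.setdefault((t.participant_id, t.session_target), []).append(t)

    rows: dict[str, dict[str, float]] = {}
    roc_rows = []
    for (pid, emo), sess_trials in sorted(by_ps.items()):
        curve = rating_roc(tabulate_counts(sess_trials, emo))
        rows.setdefault(pid, {})[emo] = eauc(curve)
        for p in curve.points:
            roc_rows.append(
                {
                    "participant_id": pid,
                    "emotion": emo,
                    "conf_threshold": p.conf_threshold,
                    "fa_rate": p.fa_rate,
                    "hit_rate": p.hit_rate,
                }
            )
    table = pd.DataFrame.from_dict(rows, orient="index")[list(EMOTIONS)]
    table.index.name = "participant_id"
    return table, pd.DataFrame(roc_rows)


def apply_exclusion(
    table: pd.DataFrame, threshold: float = CHANCE_LEVEL
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Retain rows whose eAUC is strictly above ``threshold`` in all emotions.

    Returns the retained table and a map of excluded participant id →
    offending emotion(s).
    """
    cells = table[list(EMOTIONS)]
    if cells.isna().any().any():
        missing = cells.isna().any(axis=1)
        raise ValueError(f"missing eAUC cells for {list(table.index[missing])}")
    excluded: dict[str, list[str]] = {}
    for pid, row in cells.iterrows():
        offending = [e for e in EMOTIONS if row[e] <= threshold]
        if offending:
            excluded[pid] = offending
    retained = table.drop(index=list(excluded))
    return retained, excluded
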