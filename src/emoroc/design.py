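"""Trial-structure generation for the emotion-detection-in-noise task.

Each participant runs four sessions, one per target emotion (happy HA,
neutral NE, fear FE, disgust DI).  A session holds 60 trials: 30 with the
session's target emotion and 10 from each of the three other emotions
(5 female-speaker and 5 male-speaker stimuli per non-target emotion).
Trial order, session order, non-target set assignment and fixation jitter
are all drawn from independent sub-streams of one master seed, so a design
is fully reproducible from ``(catalog, participant_id, seed)``.

Because only 10 of an emotion's 30 stimuli can serve as non-targets in any
one session, each emotion's stimulus set is partitioned into three disjoint
sex-balanced sets of 10, one per session in which that emotion is a
non-target; every stimulus therefore appears exactly twice per experiment
(once as a target, once as a non-target).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EMOTIONS: tuple[str, ...] = ("HA", "NE", "FE", "DI")
SEXES: tuple[str, ...] = ("F", "M")

#: per-session composition constants
N_TARGET_PER_SESSION = 30
N_NONTARGET_PER_EMOTION = 10
N_TRIALS_PER_SESSION = 60
STIMULUS_MS = 3000
POST_BLANK_MS = 3000
ITI_MS = 500
FIXATION_RANGE_MS = (300, 500)

# fixed spawn keys for the independent randomization sub-streams
_STREAMS = {"selection": 0, "session_order": 1, "partition": 2, "trial_order": 3, "fixation": 4}


class CatalogError(ValueError):
    """Stimulus catalog cannot support the required session composition."""


@dataclass(frozen=True)
class StimulusRef:
    stimulus_id: str
    emotion: str
    speaker_sex: str

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion code {self.emotion!r}; expected one of {EMOTIONS}")
        if self.speaker_sex not in SEXES:
            raise ValueError(f"unknown speaker sex {self.speaker_sex!r}; expected one of {SEXES}")


@dataclass(frozen=True)
class TrialSpec:
    trial_index: int
    stimulus: StimulusRef
    is_target: bool
    fixation_ms: int
    stimulus_ms: int = STIMULUS_MS
    post_blank_ms: int = POST_BLANK_MS
    iti_ms: int = ITI_MS


@dataclass(frozen=True)
class SessionSpec:
    target_emotion: str
    trials: tuple[TrialSpec, ...]


@dataclass(frozen=True)
class ExperimentDesign:
    participant_id: str
    session_order: tuple[str, ...]
    sessions: tuple[SessionSpec, ...]
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(len(s.trials) for s in self.sessions)


@dataclass(frozen=True)
class Check:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[Check] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[Check]:
        return [c for c in self.checks if not c.passed]


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[name],)))


def synthetic_catalog(n_per_cell: int = 15) -> list[StimulusRef]:
    """A stand-in stimulus catalog with ``n_per_cell`` ids per (emotion, sex) cell.

    Stimulus ids are synthetic placeholders (``HA_F_01`` ...), standing in for
    the emotional-speech recordings the task would draw from a validated
    corpus; the design layer only needs identities, emotions and speaker sex.
    """
    return [
        StimulusRef(f"{emo}_{sex}_{i:02d}", emo, sex)
        for emo in EMOTIONS
        for sex in SEXES
        for i in range(1, n_per_cell + 1)
    ]


def sample_session_order(rng: np.random.Generator) -> tuple[str, ...]:
    """Uniformly random permutation of the four target emotions."""
    return tuple(str(e) for e in rng.permutation(EMOTIONS))


def build_design(catalog: list[StimulusRef], participant_id: str, seed: int) -> ExperimentDesign:
    """Assemble one participant's 4-session, 240-trial experiment.

    Raises :class:`CatalogError` naming the deficient (emotion, sex) cell if
    the catalog cannot supply 15 stimuli per cell.
    """
    by_cell: dict[tuple[str, str], list[StimulusRef]] = {(e, s): [] for e in EMOTIONS for s in SEXES}
    seen: set[str] = set()
    for ref in catalog:
        if ref.stimulus_id in seen:
            raise CatalogError(f"duplicate stimulus_id {ref.stimulus_id!r} in catalog")
        seen.add(ref.stimulus_id)
        by_cell[(ref.emotion, ref.speaker_sex)].append(ref)

    for cell, refs in by_cell.items():
        if len(refs) < 15:
            raise CatalogError(
                f"catalog has {len(refs)} stimuli for cell (emotion={cell[0]}, sex={cell[1]}); 15 required"
            )

    sel_rng = _substream(seed, "selection")
    chosen: dict[tuple[str, str], list[StimulusRef]] = {}
    for cell in sorted(by_cell):
        refs = sorted(by_cell[cell], key=lambda r: r.stimulus_id)
        idx = sel_rng.choice(len(refs), size=15, replace=False)
        chosen[cell] = [refs[i] for i in sorted(idx)]

    session_order = sample_session_order(_substream(seed, "session_order"))

    # Partition each emotion's 15F + 15M into three sex-balanced sets of 10,
    # one per session where the emotion is a non-target (in session order).
    part_rng = _substream(seed, "partition")
    nontarget_sets: dict[str, dict[str, list[StimulusRef]]] = {e: {} for e in EMOTIONS}
    for emo in EMOTIONS:
        females = list(part_rng.permutation(np.array(chosen[(emo, "F")], dtype=object)))
        males = list(part_rng.permutation(np.array(chosen[(emo, "M")], dtype=object)))
        hosts = [t for t in session_order if t != emo]
        for k, host in enumerate(hosts):
            nontarget_sets[emo][host] = females[5 * k : 5 * (k + 1)] + males[5 * k : 5 * (k + 1)]

    trial_rng = _substream(seed, "trial_order")
    fix_rng = _substream(seed, "fixation")
    sessions = []
    for target in session_order:
        pool: list[tuple[StimulusRef, bool]] = [
            (ref, True) for cell_sex in SEXES for ref in chosen[(target, cell_sex)]
        ]
        for emo in EMOTIONS:
            if emo != target:
                pool.extend((ref, False) for ref in nontarget_sets[emo][target])
        order = trial_rng.permutation(len(pool))
        trials = tuple(
            TrialSpec(
                trial_index=i,
                stimulus=pool[j][0],
                is_target=pool[j][1],
                fixation_ms=int(np.round(fix_rng.uniform(*FIXATION_RANGE_MS))),
            )
            for i, j in enumerate(order)
        )
        sessions.append(SessionSpec(target_emotion=target, trials=trials))

    return ExperimentDesign(
        participant_id=participant_id,
        session_order=session_order,
        sessions=tuple(sessions),
        seed=int(seed),
    )


def design_to_frame(design: ExperimentDesign):
    """Flatten a design to a table, one row per trial (for CSV export)."""
    import pandas as pd

    rows = [
        {
            "participant_id": design.participant_id,
            "session_index": si,
            "session_target": sess.target_emotion,
            "trial_index": t.trial_index,
            "stimulus_id": t.stimulus.stimulus_id,
            "stimulus_emotion": t.stimulus.emotion,
            "is_target": t.is_target,
            "fixation_ms": t.fixation_ms,
        }
        for si, sess in enumerate(design.sessions)
        for t in sess.trials
    ]
    return pd.DataFrame(rows)


def validate_design(design: ExperimentDesign) -> ValidationReport:
    """Check every structural invariant; reports failures instead of raising."""
    rep = ValidationReport()

    order_ok = sorted(design.session_order) == sorted(EMOTIONS) and len(design.sessions) == 4
    rep.checks.append(Check("session_count", order_ok, f"order={design.session_order}"))
    rep.checks.append(
        Check("total_trials", design.n_trials == 240, f"found {design.n_trials} trials")
    )

    for si, sess in enumerate(design.sessions):
        label = f"session {si} ({sess.target_emotion})"
        n_target = sum(t.is_target for t in sess.trials)
        rep.checks.append(
            Check(
                "session_composition",
                len(sess.trials) == N_TRIALS_PER_SESSION and n_target == N_TARGET_PER_SESSION,
                f"{label}: {len(sess.trials)} trials, {n_target} targets",
            )
        )
        target_consistent = all(
            t.is_target == (t.stimulus.emotion == sess.target_emotion) for t in sess.trials
        )
        rep.checks.append(Check("target_flag_consistency", target_consistent, label))

        for emo in EMOTIONS:
            if emo == sess.target_emotion:
                continue
            refs = [t.stimulus for t in sess.trials if t.stimulus.emotion == emo]
            n_f = sum(r.speaker_sex == "F" for r in refs)
            rep.checks.append(
                Check(
                    "nontarget_counts",
                    len(refs) == N_NONTARGET_PER_EMOTION and n_f == 5,
                    f"{label}: {len(refs)} {emo} non-targets ({n_f} F)",
                )
            )

        ids = [t.stimulus.stimulus_id for t in sess.trials]
        rep.checks.append(
            Check("within_session_uniqueness", len(ids) == len(set(ids)), label)
        )
        fix_ok = all(
            FIXATION_RANGE_MS[0] <= t.fixation_ms <= FIXATION_RANGE_MS[1] for t in sess.trials
        )
        rep.checks.append(Check("fixation_bounds", fix_ok, label))

    return rep
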