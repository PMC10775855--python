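"""Forced-choice observer simulation and synthetic cohort generation.

Responses follow a high-threshold 4AFC model: on each stimulus the observer
either truly perceives the target (probability ``d``) and reports its
orientation, or guesses among the four alternatives; a small lapse rate
produces occasional errors regardless. Monocular controls are always
perceivable (they verify task compliance, not stereopsis).

Cohorts emulate a four-group screening study — amblyopia, amblyogenic (risk
factors without amblyopia), nonamblyogenic refractive errors, and emmetropic
controls — with per-group Beta distributions over the latent detection
probability and an additive benefit of refractive correction for the
refractive groups. Subjects with prescription glasses are tested both
without (NC) and with (WC) correction, and the two sessions are merged into
a single dataset of four-dimensional score vectors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimgen import Condition, SessionProtocol, STEREO_CONDITIONS


class Group(str, enum.Enum):
    AMBLYOPIA = "amblyopia"
    AMBLYOGENIC = "amblyogenic"
    NONAMBLYOGENIC = "nonamblyogenic"
    CONTROL = "control"


#: groups counted as pathologic for the screening decision
PATHOLOGIC_GROUPS = (Group.AMBLYOPIA, Group.AMBLYOGENIC)


class CorrectionStatus(str, enum.Enum):
    NC = "NC"   # without refractive correction
    WC = "WC"   # with refractive correction


SCORE_COLUMNS = ("s_srds8", "s_drds1", "s_drds07", "s_drds1n")
_CONDITION_TO_COLUMN = dict(zip(STEREO_CONDITIONS, SCORE_COLUMNS))

#: per-condition difficulty multipliers on the latent detection probability;
#: harder stimuli (lower density, added noise) carry partially independent
#: information, which is what score fusion exploits
CONDITION_DIFFICULTY = {
    Condition.SRDS8: 1.0,
    Condition.DRDS1: 0.95,
    Condition.DRDS07: 0.90,
    Condition.DRDS1N: 0.85,
}


@dataclass
class ObserverProfile:
    """Latent performance of one simulated subject."""

    subject_id: str
    group: Group
    detection_prob: dict[Condition, float]
    guess_success_prob: float = 0.25
    lapse_rate: float = 0.02
    correction_effect: dict[Condition, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.guess_success_prob, self.lapse_rate,
                  *self.detection_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SessionResult:
    """Per-condition scores (0-5 each) of one testing session."""

    subject_id: str
    correction_status: CorrectionStatus
    scores: dict[Condition, int]
    control_correct: int
    group: Group

    def __post_init__(self) -> None:
        if not all(0 <= s <= 5 for s in self.scores.values()):
            raise ValueError("scores must lie in [0, 5]")
        if not 0 <= self.control_correct <= 4:
            raise ValueError("control_correct must lie in [0, 4]")

    @property
    def score_vector(self) -> np.ndarray:
        return np.array([self.scores[c] for c in STEREO_CONDITIONS], dtype=float)

    @property
    def pathologic(self) -> bool:
        return self.group in PATHOLOGIC_GROUPS


def p_correct(observer: ObserverProfile, condition: Condition,
              correction: CorrectionStatus = CorrectionStatus.NC) -> float:
    """Probability of a correct response on one stimulus.

    High-threshold model: (1 - lapse) * (d' + (1 - d') * guess) with
    d' = clip(d + correction effect) under correction; monocular controls
    have d' = 1 for every group.
    """
    if condition is Condition.MONO_CONTROL:
        d = 1.0
    elif condition in CONDITION_DIFFICULTY:
        d = observer.detection_prob[condition]
        if correction is CorrectionStatus.WC:
            d = d + observer.correction_effect.get(condition, 0.0)
        d = float(np.clip(d, 0.0, 1.0))
    else:
        raise ValueError(f"unknown condition: {condition!r}")
    return (1.0 - observer.lapse_rate) * (
        d + (1.0 - d) * observer.guess_success_prob)


def simulate_session(observer: ObserverProfile, protocol: SessionProtocol,
                     correction: CorrectionStatus, seed: int) -> SessionResult:
    """Answer every stimulus of ``protocol`` as an independent Bernoulli trial."""
    rng = np.random.default_rng(seed)
    scores = {c: 0 for c in STEREO_CONDITIONS}
    control_correct = 0
    for spec in protocol.stimuli:
        p = p_correct(observer, spec.condition, correction)
        correct = rng.random() < p
        if spec.condition is Condition.MONO_CONTROL:
            control_correct += int(correct)
        else:
            scores[spec.condition] += int(correct)
    return SessionResult(subject_id=observer.subject_id,
                         correction_status=correction, scores=scores,
                         control_correct=control_correct, group=observer.group)


@dataclass
class CohortConfig:
    """Parameters of the synthetic study population.

    Defaults emulate the merged-session study structure: group sizes
    23/23/39/45 (the subjects examined with all four conditions), 52 subjects
    with prescription glasses retested with correction, giving 130 + 52 = 182
    four-dimensional score vectors.
    """

    group_sizes: dict[Group, int] = field(default_factory=lambda: {
        Group.AMBLYOPIA: 23, Group.AMBLYOGENIC: 23,
        Group.NONAMBLYOGENIC: 39, Group.CONTROL: 45})
    # Beta(a, b) over the base detection probability, per group
    detection_beta: dict[Group, tuple[float, float]] = field(default_factory=lambda: {
        Group.AMBLYOPIA: (1.0, 6.0), Group.AMBLYOGENIC: (2.5, 2.5),
        Group.NONAMBLYOGENIC: (6.0, 1.5), Group.CONTROL: (12.0, 1.0)})
    correction_benefit: dict[Group, float] = field(default_factory=lambda: {
        Group.AMBLYOPIA: 0.0, Group.AMBLYOGENIC: 0.15,
        Group.NONAMBLYOGENIC: 0.15, Group.CONTROL: 0.0})
    # subjects per group holding a glasses prescription (retested WC);
    # emmetropic controls have none by definition
    glasses_counts: dict[Group, int] = field(default_factory=lambda: {
        Group.AMBLYOPIA: 23, Group.AMBLYOGENIC: 23,
        Group.NONAMBLYOGENIC: 6, Group.CONTROL: 0})
    guess_success_prob: float = 0.25
    lapse_rate: float = 0.02
    # weight of a shared per-subject ability factor mixed into each
    # condition's draw; 0 keeps conditions conditionally independent
    shared_ability_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if sum(self.group_sizes.values()) == 0:
            raise ValueError("cohort is empty")
        for g, k in self.glasses_counts.items():
            if k > self.group_sizes.get(g, 0):
                raise ValueError(f"more glasses wearers than subjects in {g}")


@dataclass
class Cohort:
    observers: list[ObserverProfile]
    sessions: list[SessionResult]

    def to_frame(self) -> pd.DataFrame:
        """Tidy session table, one row per (subject, correction status)."""
        rows = []
        for s in self.sessions:
            row = {"subject_id": s.subject_id, "group": s.group.value,
                   "correction_status": s.correction_status.value,
                   "control_correct": s.control_correct,
                   "pathologic": s.pathologic}
            row.update({_CONDITION_TO_COLUMN[c]: s.scores[c]
                        for c in STEREO_CONDITIONS})
            rows.append(row)
        return pd.DataFrame(rows)


def _draw_profile(group: Group, subject_id: str, config: CohortConfig,
                  rng: np.random.Generator) -> ObserverProfile:
    a, b = config.detection_beta[group]
    rho = config.shared_ability_weight
    shared = rng.beta(a, b)
    detection = {}
    for cond in STEREO_CONDITIONS:
        indep = rng.beta(a, b)
        base = rho * shared + (1.0 - rho) * indep
        detection[cond] = float(np.clip(base * CONDITION_DIFFICULTY[cond], 0, 1))
    benefit = config.correction_benefit.get(group, 0.0)
    return ObserverProfile(
        subject_id=subject_id, group=group, detection_prob=detection,
        guess_success_prob=config.guess_success_prob,
        lapse_rate=config.lapse_rate,
        correction_effect={c: benefit for c in STEREO_CONDITIONS})


def generate_cohort(config: CohortConfig,
                    protocol: SessionProtocol | None = None) -> Cohort:
    """Draw a labelled cohort and simulate its sessions.

    Every subject is tested without correction; subjects with a glasses
    prescription are additionally tested with correction, and both sessions
    enter the merged dataset (pathologic = amblyopia or amblyogenic).
    """
    protocol = protocol or SessionProtocol.default()
    rng = np.random.default_rng(config.seed)
    observers: list[ObserverProfile] = []
    sessions: list[SessionResult] = []
    idx = 0
    for group in Group:
        n = config.group_sizes.get(group, 0)
        n_glasses = config.glasses_counts.get(group, 0)
        for i in range(n):
            obs = _draw_profile(group, f"{group.value}_{i:03d}", config, rng)
            observers.append(obs)
            session_seed = int(rng.integers(2**31))
            sessions.append(simulate_session(
                obs, protocol, CorrectionStatus.NC, session_seed))
            if i < n_glasses:
                session_seed = int(rng.integers(2**31))
                sessions.append(simulate_session(
                    obs, protocol, CorrectionStatus.WC, session_seed))
            idx += 1
    return Cohort(observers=observers, sessions=sessions)


def frame_to_matrices(frame: pd.DataFrame,
                      positive: str = "joint") -> tuple[np.ndarray, np.ndarray]:
    """Score matrix (n x 4) and pathologic label vector from a session table.

    ``positive`` selects the positive-class definition: "amblyopia" (the
    amblyopia-weighted variant), or "joint" (amblyopia or amblyogenic).
    """
    X = frame[list(SCORE_COLUMNS)].to_numpy(dtype=float)
    if positive == "amblyopia":
        y = (frame["group"] == Group.AMBLYOPIA.value).to_numpy()
    elif positive == "joint":
        y = frame["group"].isin([g.value for g in PATHOLOGIC_GROUPS]).to_numpy()
    else:
        raise ValueError("positive must be 'amblyopia' or 'joint'")
    return X, y
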