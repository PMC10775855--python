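"""Bernoulli pass criteria for forced-choice screening scores.

With only five stimuli per condition the pass/fail decision is anchored to
the binomial distribution of a pure guesser: the criterion is chosen so the
probability that guessing alone passes stays below a significance level.
The behavioural rule used in practice is a fixed 3-of-5 threshold per
condition; for combined 0-20 scores the criterion threshold is floored at
the alpha-derived minimum (9 of 20 at guess rate 1/4, alpha 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .observer import SessionResult
from .stimgen import Condition, STEREO_CONDITIONS


@dataclass(frozen=True)
class PassCriterion:
    n_trials: int
    min_correct: int
    guess_success_prob: float = 0.25
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.min_correct <= self.n_trials:
            raise ValueError("min_correct must lie in [0, n_trials]")
        if not 0.0 < self.guess_success_prob < 1.0:
            raise ValueError("guess_success_prob must lie in (0, 1)")


def false_pass_probability(criterion: PassCriterion) -> float:
    """P(X >= min_correct) for X ~ Binomial(n_trials, guess_success_prob):
    the chance that a pure guesser passes."""
    return float(stats.binom.sf(criterion.min_correct - 1, criterion.n_trials,
                                criterion.guess_success_prob))


def min_correct_for_alpha(n_trials: int, guess_success_prob: float,
                          alpha: float) -> int:
    """Smallest k whose guessing tail P(X >= k) falls below alpha;
    n_trials + 1 if no attainable k does."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    for k in range(n_trials + 1):
        if stats.binom.sf(k - 1, n_trials, guess_success_prob) < alpha:
            return k
    return n_trials + 1


@dataclass
class SessionPassReport:
    passed: dict[Condition, bool]
    session_valid: bool
    combined_score: int
    combined_passed: bool


def combined_threshold(guess_success_prob: float = 0.25,
                       alpha: float = 0.05, n_trials: int = 20) -> int:
    """Bernoulli floor for the combined 0-20 score (9 at the defaults)."""
    return min_correct_for_alpha(n_trials, guess_success_prob, alpha)


def apply_pass_criterion(session: SessionResult, per_test_threshold: int = 3,
                         combined_min: int | None = None) -> SessionPassReport:
    """Per-condition pass/fail at the fixed threshold (default 3 of 5).

    A session is valid only if all four monocular controls were answered
    correctly; invalid sessions are flagged, not failed. The combined 0-20
    score passes at ``combined_min`` (default: the alpha-derived floor).
    """
    if not 0 <= per_test_threshold <= 5:
        raise ValueError("per_test_threshold must lie in [0, 5]")
    passed = {c: session.scores[c] >= per_test_threshold
              for c in STEREO_CONDITIONS}
    total = int(sum(session.scores[c] for c in STEREO_CONDITIONS))
    if combined_min is None:
        combined_min = combined_threshold()
    return SessionPassReport(
        passed=passed,
        session_valid=session.control_correct == 4,
        combined_score=total,
        combined_passed=total >= combined_min)
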