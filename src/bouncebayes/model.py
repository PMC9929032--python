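"""Two-timestep POMDP observer model of ball-bounce anticipation.

The observer starts a trial in a "start" state, transitions to a hidden
"high bounce" or "low bounce" state, and receives a categorical cue
observation whose reliability is governed by a sensory-precision
parameter SP. The prior probability of transitioning into the low-bounce
state is pB (values above 0.5 mean low bounces are expected a priori).
Belief updating combines the transition prior and the cue likelihood via
a softmax over summed log-messages, yielding a posterior over the two
bounce states; the probability of responding "high" equals that
posterior (probability matching).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

# State / observation label order used by all matrices and vectors.
STATES = ("start", "high", "low")
OBSERVATIONS = ("start_obs", "high_cue", "low_cue")
CUES = ("high_cue", "low_cue")
RESPONSES = ("high", "low")
GROUPS = ("expert", "novice")
KICK_TYPES = ("grubber", "chip")
OCCLUSIONS = ("PC", "BF", "PC_BF")

_LIK_CLIP = 1e-8  # floor on a single trial's response probability
_BELIEF_TOL = 1e-9


class InvalidParameterError(ValueError):
    """A model parameter lies outside the open interval (0, 1)."""


class InvalidObservationError(ValueError):
    """An observation label is invalid for its timestep."""


class MissingResponseError(ValueError):
    """A trial passed to a likelihood routine carries no response."""


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the observer.

    SP : probability that the cue matches the underlying bounce state
        (0.5 = uninformative, near 1 = fully reliable).
    pB : prior probability of transitioning from start to the
        low-bounce state (above 0.5 = low bounces expected).
    """

    SP: float
    pB: float

    def __post_init__(self) -> None:
        for name, value in (("SP", self.SP), ("pB", self.pB)):
            if not (0.0 < value < 1.0):
                raise InvalidParameterError(
                    f"{name}={value!r} must lie strictly inside (0, 1)"
                )


@dataclass(frozen=True)
class GenerativeModel:
    """Likelihood (A), transition (B) and initial-state (D) arrays.

    A[o, s] = P(observation o | state s); B[s', s] = P(state s' at t=2 |
    state s at t=1); D[s] = P(state s at t=1). Columns of A and B are
    probability distributions.
    """

    A: np.ndarray
    B: np.ndarray
    D: np.ndarray


@dataclass(frozen=True)
class BeliefMarginals:
    """Posterior state marginals at the two trial timesteps."""

    s_bar_t1: np.ndarray
    s_bar_t2: np.ndarray


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation, optionally with the observed response.

    outcome_cue is the veridical bounce outcome of the clip (high_cue or
    low_cue) and is identical across occlusion conditions; occlusion
    differences enter only through condition-specific fitted parameters.
    """

    kick_type: str
    occlusion: str
    outcome_cue: str
    response: Optional[str] = None
    participant_id: str = ""
    group: Optional[str] = None
    clip_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.kick_type not in KICK_TYPES:
            raise ValueError(f"kick_type must be one of {KICK_TYPES}, got {self.kick_type!r}")
        if self.occlusion not in OCCLUSIONS:
            raise ValueError(f"occlusion must be one of {OCCLUSIONS}, got {self.occlusion!r}")
        if self.outcome_cue not in CUES:
            raise InvalidObservationError(
                f"outcome_cue must be a cue observation {CUES}, got {self.outcome_cue!r}"
            )
        if self.response is not None and self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES} or None, got {self.response!r}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS} or None, got {self.group!r}")

    @property
    def cell(self) -> tuple[str, str]:
        return (self.kick_type, self.occlusion)

    def with_response(self, response: str) -> "TrialRecord":
        return replace(self, response=response)


def build_generative_model(params: ModelParams) -> GenerativeModel:
    """Construct the A, B, D arrays implied by (SP, pB).

    The start state deterministically emits the start observation and
    transitions to high with probability 1-pB, low with probability pB;
    the two bounce states are absorbing. In a bounce state, the matching
    cue is observed with probability SP.
    """
    SP, pB = params.SP, params.pB
    A = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, SP, 1.0 - SP],
            [0.0, 1.0 - SP, SP],
        ]
    )
    B = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0 - pB, 1.0, 0.0],
            [pB, 0.0, 1.0],
        ]
    )
    D = np.array([1.0, 0.0, 0.0])
    return GenerativeModel(A=A, B=B, D=D)


def _one_hot(label: str, vocabulary: Sequence[str]) -> np.ndarray:
    v = np.zeros(len(vocabulary))
    v[vocabulary.index(label)] = 1.0
    return v


def _softmax_log(logv: np.ndarray) -> np.ndarray:
    """Softmax of a log-message vector; -inf entries get probability 0."""
    finite = np.isfinite(logv)
    out = np.zeros_like(logv)
    shifted = logv[finite] - np.max(logv[finite])
    w = np.exp(shifted)
    out[finite] = w / w.sum()
    return out


def belief_update(
    params: ModelParams,
    o_t1: str = "start_obs",
    o_t2: str = "high_cue",
    tol: float = _BELIEF_TOL,
    max_iter: int = 100,
) -> BeliefMarginals:
    """Fixed-point belief updating over the two trial timesteps.

    Iterates
        s_bar_t1 = softmax( (ln D + ln B^T s_bar_t2) / 2 + ln A^T o_t1 )
        s_bar_t2 = softmax( ln(B s_bar_t1) + ln A^T o_t2 )
    until the largest marginal change falls below ``tol``. Exact zeros
    produce -inf log-messages, which simply exclude the impossible
    states from the softmax; because D is degenerate at the start state
    the sweep converges in a single pass.
    """
    if o_t1 != "start_obs":
        raise InvalidObservationError(f"o_t1 must be 'start_obs', got {o_t1!r}")
    if o_t2 not in CUES:
        raise InvalidObservationError(f"o_t2 must be a cue observation, got {o_t2!r}")

    gm = build_generative_model(params)
    o1 = _one_hot(o_t1, OBSERVATIONS)
    o2 = _one_hot(o_t2, OBSERVATIONS)

    with np.errstate(divide="ignore"):
        lnD = np.log(gm.D)
        lnA_o1 = np.log(gm.A.T @ o1)
        lnA_o2 = np.log(gm.A.T @ o2)

    s1 = np.full(3, 1.0 / 3.0)
    s2 = np.full(3, 1.0 / 3.0)
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            msg_t1 = 0.5 * (lnD + np.log(gm.B.T @ s2)) + lnA_o1
        new_s1 = _softmax_log(msg_t1)
        with np.errstate(divide="ignore"):
            msg_t2 = np.log(gm.B @ new_s1) + lnA_o2
        new_s2 = _softmax_log(msg_t2)
        delta = max(np.max(np.abs(new_s1 - s1)), np.max(np.abs(new_s2 - s2)))
        s1, s2 = new_s1, new_s2
        if delta < tol:
            break
    return BeliefMarginals(s_bar_t1=s1, s_bar_t2=s2)


def posterior_high_closed_form(SP, pB, cue: str):
    """Closed-form posterior P(high | cue) over the two bounce states.

    Vectorized over SP and pB. Used by the grid-search oracle; tested to
    agree with :func:`belief_update` to within 1e-9.
    """
    SP = np.asarray(SP, dtype=float)
    pB = np.asarray(pB, dtype=float)
    if cue == "high_cue":
        num = (1.0 - pB) * SP
        den = num + pB * (1.0 - SP)
    elif cue == "low_cue":
        num = (1.0 - pB) * (1.0 - SP)
        den = num + pB * SP
    else:
        raise InvalidObservationError(f"cue must be a cue observation, got {cue!r}")
    return num / den


def response_probability(params: ModelParams, outcome_cue: str) -> float:
    """P(respond "high") for a trial whose veridical cue is outcome_cue.

    Equals the posterior probability of the high-bounce state at t=2
    (probability matching).
    """
    beliefs = belief_update(params, "start_obs", outcome_cue)
    return float(beliefs.s_bar_t2[STATES.index("high")])


def trial_log_likelihood(params: ModelParams, trial: TrialRecord) -> float:
    """Log-probability of one trial's response under the model."""
    if trial.response is None:
        raise MissingResponseError("trial has no response")
    p_high = response_probability(params, trial.outcome_cue)
    p = p_high if trial.response == "high" else 1.0 - p_high
    return float(np.log(np.clip(p, _LIK_CLIP, 1.0 - _LIK_CLIP)))


def dataset_log_likelihood(params: ModelParams, trials: Sequence[TrialRecord]) -> float:
    """Sum of trial log-likelihoods; empty sequence gives 0.

    The response probability depends on the trial only through its
    outcome cue, so it is computed once per cue.
    """
    if len(trials) == 0:
        return 0.0
    p_by_cue = {}
    total = 0.0
    for trial in trials:
        if trial.response is None:
            raise MissingResponseError("trial has no response")
        p_high = p_by_cue.get(trial.outcome_cue)
        if p_high is None:
            p_high = response_probability(params, trial.outcome_cue)
            p_by_cue[trial.outcome_cue] = p_high
        p = p_high if trial.response == "high" else 1.0 - p_high
        total += np.log(np.clip(p, _LIK_CLIP, 1.0 - _LIK_CLIP))
    return float(total)


def cue_response_counts(trials: Sequence[TrialRecord]) -> np.ndarray:
    """2x2 counts [cue, response] with rows (high_cue, low_cue) and
    columns (high, low) — the sufficient statistic for the likelihood."""
    counts = np.zeros((2, 2), dtype=int)
    for trial in trials:
        if trial.response is None:
            raise MissingResponseError("trial has no response")
        counts[CUES.index(trial.outcome_cue), RESPONSES.index(trial.response)] += 1
    return counts


def log_likelihood_from_counts(SP, pB, counts: np.ndarray):
    """Vectorized dataset log-likelihood from the 2x2 cue/response counts."""
    p_h = np.clip(posterior_high_closed_form(SP, pB, "high_cue"), _LIK_CLIP, 1 - _LIK_CLIP)
    p_l = np.clip(posterior_high_closed_form(SP, pB, "low_cue"), _LIK_CLIP, 1 - _LIK_CLIP)
    return (
        counts[0, 0] * np.log(p_h)
        + counts[0, 1] * np.log(1.0 - p_h)
        + counts[1, 0] * np.log(p_l)
        + counts[1, 1] * np.log(1.0 - p_l)
    )
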