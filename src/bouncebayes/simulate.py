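"""Synthetic study design and cohorts of simulated responders.

Reproduces the anticipation-test design — 23 grubber and 14 chip kick
clips, each shown at three occlusion points (postural cues only, ball
flight only, both) for 111 trials, with 48 low / 21 high grubber and
21 / 21 chip outcomes — and simulates participants whose responses are
Bernoulli draws from the observer model's posterior (probability
matching), with known ground-truth parameters for recovery analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .model import (
    KICK_TYPES,
    OCCLUSIONS,
    ModelParams,
    TrialRecord,
    response_probability,
)

Cell = tuple[str, str]
ParamsSpec = Union[ModelParams, Mapping[Cell, ModelParams]]

_SHUFFLE_RETRIES = 1000
_PARAM_CLIP = (0.02, 0.98)  # truncation of sampled parameter distributions


class OrderingError(RuntimeError):
    """No trial ordering without adjacent repeats of a clip was found."""


class ConfigurationError(ValueError):
    """A simulation request is internally inconsistent."""


@dataclass(frozen=True)
class DesignSpec:
    """Stimulus composition of one anticipation test."""

    n_grubber_clips: int = 23
    n_chip_clips: int = 14
    n_occlusions: int = 3
    grubber_low_clips: int = 16
    chip_low_clips: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grubber_low_clips > self.n_grubber_clips:
            raise ConfigurationError("grubber_low_clips exceeds n_grubber_clips")
        if self.chip_low_clips > self.n_chip_clips:
            raise ConfigurationError("chip_low_clips exceeds n_chip_clips")
        if self.n_occlusions < 1 or self.n_occlusions > len(OCCLUSIONS):
            raise ConfigurationError(f"n_occlusions must be in 1..{len(OCCLUSIONS)}")

    @property
    def n_trials(self) -> int:
        return (self.n_grubber_clips + self.n_chip_clips) * self.n_occlusions


@dataclass(frozen=True)
class GroupCellDistribution:
    """Normal parameter distribution (truncated to (0.02, 0.98)) for one
    group x cell."""

    SP_mean: float
    SP_sd: float
    pB_mean: float
    pB_sd: float


def _default_param_dists() -> dict[str, dict[Cell, GroupCellDistribution]]:
    # Experts: higher cue sensitivity than novices, with the PC < BF ~ PC&BF
    # occlusion ordering, and prior weight (|pB - 0.5|) attenuating as later,
    # more precise cues become available. Novices: flatter profile.
    expert_sp = {"PC": 0.66, "BF": 0.78, "PC_BF": 0.80}
    novice_sp = {"PC": 0.56, "BF": 0.64, "PC_BF": 0.66}
    expert_pb = {"PC": 0.40, "BF": 0.45, "PC_BF": 0.48}
    novice_pb = {"PC": 0.45, "BF": 0.45, "PC_BF": 0.45}
    dists: dict[str, dict[Cell, GroupCellDistribution]] = {"expert": {}, "novice": {}}
    for kick in KICK_TYPES:
        for occ in OCCLUSIONS:
            dists["expert"][(kick, occ)] = GroupCellDistribution(
                SP_mean=expert_sp[occ], SP_sd=0.06, pB_mean=expert_pb[occ], pB_sd=0.05
            )
            dists["novice"][(kick, occ)] = GroupCellDistribution(
                SP_mean=novice_sp[occ], SP_sd=0.06, pB_mean=novice_pb[occ], pB_sd=0.05
            )
    return dists


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes and per-group x cell parameter distributions."""

    n_expert: int = 38
    n_novice: int = 20
    param_dists: Mapping[str, Mapping[Cell, GroupCellDistribution]] = field(
        default_factory=_default_param_dists
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_expert + self.n_novice < 1:
            raise ConfigurationError("cohort must contain at least one participant")


def build_design(spec: DesignSpec = DesignSpec()) -> list[TrialRecord]:
    """Lay out the trial sequence for one participant.

    Each clip appears once per occlusion condition with a fixed outcome;
    the order is a seeded shuffle rejected (up to 1000 times) until no
    clip repeats on consecutive trials, mirroring the sequencing check
    applied to the real test video.
    """
    clips: list[tuple[str, str, str]] = []  # (clip_id, kick_type, outcome_cue)
    for i in range(spec.n_grubber_clips):
        cue = "low_cue" if i < spec.grubber_low_clips else "high_cue"
        clips.append((f"g{i + 1:02d}", "grubber", cue))
    for i in range(spec.n_chip_clips):
        cue = "low_cue" if i < spec.chip_low_clips else "high_cue"
        clips.append((f"c{i + 1:02d}", "chip", cue))

    trials = [
        TrialRecord(kick_type=kick, occlusion=occ, outcome_cue=cue, clip_id=clip_id)
        for clip_id, kick, cue in clips
        for occ in OCCLUSIONS[: spec.n_occlusions]
    ]

    rng = np.random.default_rng(spec.seed)
    clip_ids = [t.clip_id for t in trials]
    for _ in range(_SHUFFLE_RETRIES):
        order = rng.permutation(len(trials))
        seq = [clip_ids[k] for k in order]
        if all(a != b for a, b in zip(seq, seq[1:])):
            return [trials[k] for k in order]
    raise OrderingError(
        "could not order trials without adjacent clip repeats "
        f"after {_SHUFFLE_RETRIES} shuffles"
    )


def _params_for_cell(true_params: ParamsSpec, cell: Cell) -> ModelParams:
    if isinstance(true_params, ModelParams):
        return true_params
    try:
        return true_params[cell]
    except KeyError:
        raise ConfigurationError(f"no parameters supplied for cell {cell}") from None


def simulate_participant(
    design: Sequence[TrialRecord],
    true_params: ParamsSpec,
    seed: int,
    participant_id: str = "",
    group: str | None = None,
) -> list[TrialRecord]:
    """Draw probability-matching responses for every trial in a design.

    Each response is Bernoulli with P(high) equal to the model posterior
    for the trial's cell parameters and outcome cue.
    """
    rng = np.random.default_rng(seed)
    p_cache: dict[tuple[Cell, str], float] = {}
    out = []
    for trial in design:
        params = _params_for_cell(true_params, trial.cell)
        key = (trial.cell, trial.outcome_cue)
        if key not in p_cache:
            p_cache[key] = response_probability(params, trial.outcome_cue)
        response = "high" if rng.random() < p_cache[key] else "low"
        out.append(
            TrialRecord(
                kick_type=trial.kick_type,
                occlusion=trial.occlusion,
                outcome_cue=trial.outcome_cue,
                response=response,
                participant_id=participant_id or trial.participant_id,
                group=group if group is not None else trial.group,
                clip_id=trial.clip_id,
            )
        )
    return out


def _draw_params(dist: GroupCellDistribution, rng: np.random.Generator) -> ModelParams:
    lo, hi = _PARAM_CLIP

    def draw(mean: float, sd: float) -> float:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))

    return ModelParams(SP=draw(dist.SP_mean, dist.SP_sd), pB=draw(dist.pB_mean, dist.pB_sd))


def simulate_cohort(
    design_spec: DesignSpec = DesignSpec(),
    cohort: CohortSpec = CohortSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial table, ground-truth table).

    Each participant gets their own shuffled realization of the design
    and per-cell parameters drawn from their group's distributions. The
    ground-truth table records the sampled parameters per cell for
    recovery checks.
    """
    master = np.random.SeedSequence(cohort.seed)
    n_total = cohort.n_expert + cohort.n_novice
    children = master.spawn(n_total)

    trial_rows = []
    truth_rows = []
    participants = [("expert", f"E{i + 1:02d}") for i in range(cohort.n_expert)] + [
        ("novice", f"N{i + 1:02d}") for i in range(cohort.n_novice)
    ]
    for (group, pid), child in zip(participants, children):
        design_seed, sim_seed, param_seed = (
            int(s) % 2**31 for s in child.generate_state(3)
        )
        rng = np.random.default_rng(param_seed)
        params = {
            cell: _draw_params(dist, rng) for cell, dist in cohort.param_dists[group].items()
        }
        design = build_design(
            DesignSpec(
                n_grubber_clips=design_spec.n_grubber_clips,
                n_chip_clips=design_spec.n_chip_clips,
                n_occlusions=design_spec.n_occlusions,
                grubber_low_clips=design_spec.grubber_low_clips,
                chip_low_clips=design_spec.chip_low_clips,
                seed=design_seed,
            )
        )
        for trial in simulate_participant(design, params, sim_seed, pid, group):
            trial_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "kick_type": trial.kick_type,
                    "occlusion": trial.occlusion,
                    "outcome_cue": trial.outcome_cue,
                    "response": trial.response,
                }
            )
        for cell, p in params.items():
            truth_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "cell": f"{cell[0]}:{cell[1]}",
                    "SP_true": p.SP,
                    "pB_true": p.pB,
                }
            )
    return pd.DataFrame(trial_rows), pd.DataFrame(truth_rows)
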