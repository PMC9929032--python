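"""MAP estimation: transforms, penalized objective, optimizer vs grid oracle."""

import dataclasses

import numpy as np
import pytest

from bouncebayes.fitting import (
    EmptyDataError,
    FitConfig,
    fit_by_cell,
    fit_participant,
    from_unconstrained,
    grid_oracle,
    penalized_objective,
    to_unconstrained,
)
from bouncebayes.model import (
    InvalidParameterError,
    ModelParams,
    TrialRecord,
    dataset_log_likelihood,
)
from bouncebayes.simulate import DesignSpec, build_design, simulate_participant


def mirror_trials(trials):
    return [
        TrialRecord(
            t.kick_type,
            t.occlusion,
            "low_cue" if t.outcome_cue == "high_cue" else "high_cue",
            response="low" if t.response == "high" else "high",
        )
        for t in trials
    ]


class TestTransforms:
    def test_logit_values_and_round_trip(self):
        assert to_unconstrained(0.5) == 0.0
        assert from_unconstrained(0.0) == 0.5
        assert to_unconstrained(0.8) == pytest.approx(np.log(4), abs=1e-12)
        for p in (0.01, 0.3, 0.5, 0.77, 0.999):
            assert from_unconstrained(to_unconstrained(p)) == pytest.approx(p, abs=1e-12)

    def test_bound_keeps_probabilities_interior(self):
        assert 0.0 < from_unconstrained(50.0, theta_bound=8.0) < 1.0
        assert from_unconstrained(50.0, theta_bound=8.0) == from_unconstrained(8.0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_probability_rejected(self, p):
        with pytest.raises(InvalidParameterError):
            to_unconstrained(p)


class TestPenalizedObjective:
    def test_zero_theta_has_no_penalty(self, two_trial_example, fit_config):
        # at theta = (0,0) the prior penalty vanishes and SP = pB = 0.5,
        # where each response has probability one half
        obj = penalized_objective((0.0, 0.0), two_trial_example, fit_config)
        assert obj == pytest.approx(2 * np.log(0.5), abs=1e-9)

    def test_zero_precision_reduces_to_log_likelihood(self, two_trial_example, fit_config):
        cfg = dataclasses.replace(fit_config, prior_precision=0.0)
        theta = (0.7, -1.2)
        params = ModelParams(from_unconstrained(theta[0]), from_unconstrained(theta[1]))
        assert penalized_objective(theta, two_trial_example, cfg) == pytest.approx(
            dataset_log_likelihood(params, two_trial_example), abs=1e-9
        )

    def test_finite_at_extreme_theta_on_constant_responses(self, fit_config):
        trials = [TrialRecord("grubber", "PC", "low_cue", response="high")] * 10
        assert np.isfinite(penalized_objective((8.0, -8.0), trials, fit_config))

    def test_empty_trials_raise(self, fit_config):
        with pytest.raises(EmptyDataError):
            penalized_objective((0.0, 0.0), [], fit_config)


class TestFitParticipant:
    def test_matches_grid_oracle_on_fixtures(self, fixture_datasets, fit_config):
        for _, trials in fixture_datasets[:5]:
            fit = fit_participant(trials, fit_config)
            grid = grid_oracle(trials, fit_config, resolution=0.001)
            assert fit.SP_hat == pytest.approx(grid.SP_hat, abs=0.005)
            assert fit.pB_hat == pytest.approx(grid.pB_hat, abs=0.005)
            assert fit.log_posterior >= grid.log_posterior - 1e-6

    def test_perfectly_consistent_responder(self, default_design, fit_config):
        # every response matches the cue: SP is pushed high but held
        # inside (0,1) by the shrinkage prior
        trials = [
            t.with_response("high" if t.outcome_cue == "high_cue" else "low")
            for t in default_design
        ]
        fit = fit_participant(trials, fit_config)
        grid = grid_oracle(trials, fit_config, resolution=0.001)
        assert 0.9 < fit.SP_hat < 1.0
        assert fit.SP_hat == pytest.approx(grid.SP_hat, abs=0.005)
        assert fit.pB_hat == pytest.approx(grid.pB_hat, abs=0.005)

    def test_coin_flip_responder_recovers_indifference(self, default_design, fit_config):
        rng = np.random.default_rng(5)
        big_design = default_design * 10
        trials = [
            t.with_response("high" if rng.random() < 0.5 else "low") for t in big_design
        ]
        fit = fit_participant(trials, fit_config)
        assert fit.SP_hat == pytest.approx(0.5, abs=0.05)
        assert fit.pB_hat == pytest.approx(0.5, abs=0.05)

    def test_shrinkage_increases_with_prior_precision(self, fixture_datasets, fit_config):
        _, trials = fixture_datasets[0]
        dist = []
        for prec in (0.1, 0.5, 2.0, 10.0):
            cfg = dataclasses.replace(fit_config, prior_precision=prec)
            fit = fit_participant(trials, cfg)
            dist.append(abs(fit.SP_hat - 0.5) + abs(fit.pB_hat - 0.5))
        assert all(a >= b - 1e-9 for a, b in zip(dist, dist[1:]))

    def test_deterministic(self, fixture_datasets, fit_config):
        _, trials = fixture_datasets[1]
        a = fit_participant(trials, fit_config)
        b = fit_participant(trials, fit_config)
        assert (a.SP_hat, a.pB_hat, a.log_posterior) == (b.SP_hat, b.pB_hat, b.log_posterior)

    def test_mirror_property(self, fixture_datasets, fit_config):
        _, trials = fixture_datasets[2]
        fit = fit_participant(trials, fit_config)
        mirrored = fit_participant(mirror_trials(trials), fit_config)
        assert mirrored.SP_hat == pytest.approx(fit.SP_hat, abs=1e-6)
        assert mirrored.pB_hat == pytest.approx(1.0 - fit.pB_hat, abs=1e-6)

    def test_no_responses_raises(self, default_design, fit_config):
        with pytest.raises(EmptyDataError):
            fit_participant(default_design, fit_config)


class TestFitByCell:
    def test_full_design_yields_six_cells(self, default_design, fit_config):
        trials = simulate_participant(default_design, ModelParams(0.75, 0.45), seed=3)
        results = fit_by_cell(trials, fit_config)
        assert len(results) == 6
        cells = [r.cell for r in results]
        assert len(set(cells)) == 6
        # smallest real cell: 14 chip trials per occlusion
        n_by_cell = {r.cell: r.n_trials for r in results}
        assert n_by_cell[("chip", "PC")] == 14
        assert n_by_cell[("grubber", "PC")] == 23

    def test_single_cell_matches_fit_participant(self, default_design, fit_config):
        trials = simulate_participant(default_design, ModelParams(0.7, 0.5), seed=4)
        one_cell = [t for t in trials if t.cell == ("grubber", "BF")]
        (result,) = fit_by_cell(one_cell, fit_config)
        direct = fit_participant(one_cell, fit_config)
        assert result.cell == ("grubber", "BF")
        assert result.SP_hat == direct.SP_hat
        assert result.pB_hat == direct.pB_hat

    def test_single_response_class_cell_is_regularized(self, fit_config):
        trials = [
            TrialRecord("chip", "PC", "high_cue", response="high") for _ in range(14)
        ]
        (result,) = fit_by_cell(trials, fit_config)
        assert 0.0 < result.SP_hat < 1.0 and 0.0 < result.pB_hat < 1.0


class TestGridOracle:
    def test_optimizer_dominates_grid(self, fixture_datasets, fit_config):
        for _, trials in fixture_datasets[:3]:
            fit = fit_participant(trials, fit_config)
            grid = grid_oracle(trials, fit_config, resolution=0.01)
            assert grid.log_posterior <= fit.log_posterior + 1e-6

    def test_symmetric_data_ties_break_toward_center(self, fit_config):
        # alternating responses on balanced cues: objective symmetric around 0.5
        trials = []
        for resp in ("high", "low"):
            trials += [TrialRecord("grubber", "PC", "high_cue", response=resp)] * 5
            trials += [TrialRecord("grubber", "PC", "low_cue", response=resp)] * 5
        grid = grid_oracle(trials, fit_config, resolution=0.05)
        assert grid.SP_hat == pytest.approx(0.5, abs=0.05)
        assert grid.pB_hat == pytest.approx(0.5, abs=0.05)

    def test_two_trial_argmax_matches_direct_scan(self, two_trial_example, fit_config):
        grid = grid_oracle(two_trial_example, fit_config, resolution=0.1)
        best, arg = -np.inf, None
        for SP in np.arange(0.1, 0.95, 0.1):
            for pB in np.arange(0.1, 0.95, 0.1):
                theta = (to_unconstrained(SP), to_unconstrained(pB))
                val = penalized_objective(theta, two_trial_example, fit_config)
                if val > best:
                    best, arg = val, (SP, pB)
        assert grid.SP_hat == pytest.approx(arg[0], abs=1e-9)
        assert grid.pB_hat == pytest.approx(arg[1], abs=1e-9)

    def test_resolution_validation(self, two_trial_example, fit_config):
        with pytest.raises(ValueError):
            grid_oracle(two_trial_example, fit_config, resolution=0.5)
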