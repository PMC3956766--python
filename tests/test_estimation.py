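"""Parameter estimation from per-woman pathway data."""

import numpy as np
import pytest

import menomark as mm
from menomark.estimation import (
    Observation,
    WomanPathway,
    _fit_beta_moments,
    assign_observations_to_states,
    counts_to_row_specs,
    estimate_transition_counts,
    estimate_utilities,
)
from menomark.states import INITIAL


def _pathway(states, obs=(), arm=mm.ARM_LNG, woman_id=0):
    return WomanPathway(woman_id=woman_id, arm=arm,
                        monthly_state=tuple(states),
                        observations=tuple(obs))


def _well_forever(obs=()):
    return _pathway([INITIAL] + ["well_allocated"] * 24, obs)


OBS_6_12_24 = tuple(Observation(m, "eq5d", 0.8) for m in (0, 6, 12, 24))


class TestAssignment:
    def test_well_throughout_assigns_all_to_well(self):
        out = assign_observations_to_states(_well_forever(OBS_6_12_24))
        assert [a.state for a in out] == ["well_allocated"] * 3
        assert all(a.month > 0 for a in out)  # baseline excluded

    def test_coincident_change_at_24_months(self):
        states = ([INITIAL] + ["symptomatic"] * 23 + ["no_treatment"])
        p = _pathway(states, OBS_6_12_24)
        subs = assign_observations_to_states(p, "subsequent")
        prior = assign_observations_to_states(p, "prior")
        assert [a.state for a in subs] == ["symptomatic", "symptomatic",
                                          "no_treatment"]
        assert [a.state for a in prior] == ["symptomatic"] * 3

    def test_no_observations_yields_empty_list(self):
        assert assign_observations_to_states(_well_forever()) == []

    def test_rule_toggle_only_affects_coincident_dates(self):
        states = ([INITIAL] + ["symptomatic"] * 9 + ["no_treatment"] * 15)
        p = _pathway(states, OBS_6_12_24)  # change at month 10, not observed
        subs = assign_observations_to_states(p, "subsequent")
        prior = assign_observations_to_states(p, "prior")
        assert subs == prior

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            assign_observations_to_states(_well_forever(), "nearest")

    def test_every_post_baseline_observation_assigned_once(self):
        states = [INITIAL] + ["symptomatic"] * 11 + ["change_to_other"] * 13
        p = _pathway(states, OBS_6_12_24)
        for rule in ("subsequent", "prior"):
            out = assign_observations_to_states(p, rule)
            assert sorted(a.month for a in out) == [6, 12, 24]


class TestPathwayValidation:
    def test_graph_violation_identifies_woman_and_cycle(self):
        with pytest.raises(ValueError, match="woman 7, cycle 2"):
            _pathway([INITIAL, "no_treatment", "well_allocated"] +
                     ["well_allocated"] * 22, woman_id=7)

    def test_observation_beyond_horizon(self):
        with pytest.raises(ValueError, match="beyond"):
            _pathway([INITIAL] + ["well_allocated"] * 11,
                     obs=[Observation(24, "eq5d", 0.8)])

    def test_duplicate_observation_timepoint(self):
        with pytest.raises(ValueError, match="duplicate"):
            _well_forever([Observation(6, "eq5d", 0.8),
                           Observation(6, "eq5d", 0.7)])


class TestUtilityEstimation:
    def test_single_observation(self):
        p = _well_forever([Observation(6, "eq5d", 0.756)])
        table = estimate_utilities(assign_observations_to_states(p),
                                   "eq5d", mm.ARM_LNG)
        assert table.values["well_allocated"] == pytest.approx(0.756)
        assert table.medians["well_allocated"] == pytest.approx(0.756)

    def test_two_observations_mean_and_median(self):
        p = _well_forever([Observation(6, "eq5d", 0.6),
                           Observation(12, "eq5d", 0.8)])
        table = estimate_utilities(assign_observations_to_states(p),
                                   "eq5d", mm.ARM_LNG)
        assert table.values["well_allocated"] == pytest.approx(0.7)
        assert table.medians["well_allocated"] == pytest.approx(0.7)

    def test_unobserved_states_flagged_not_defaulted(self):
        p = _well_forever([Observation(6, "eq5d", 0.8)])
        with pytest.warns(UserWarning, match="no eq5d observations"):
            table = estimate_utilities(assign_observations_to_states(p),
                                       "eq5d", mm.ARM_LNG)
        assert "surgery" not in table.values

    def test_per_woman_averaging(self):
        p1 = _well_forever([Observation(6, "eq5d", 0.2),
                            Observation(12, "eq5d", 0.4)])
        p2 = _pathway([INITIAL] + ["well_allocated"] * 24,
                      [Observation(6, "eq5d", 0.9)], woman_id=1)
        assigned = (assign_observations_to_states(p1)
                    + assign_observations_to_states(p2))
        with pytest.warns(UserWarning):
            by_obs = estimate_utilities(assigned, "eq5d", mm.ARM_LNG)
            by_woman = estimate_utilities(assigned, "eq5d", mm.ARM_LNG,
                                          per_woman=True)
        assert by_obs.values["well_allocated"] == pytest.approx(0.5)
        assert by_woman.values["well_allocated"] == pytest.approx(0.6)

    def test_beta_moments_recover_parameters(self):
        rng = np.random.default_rng(11)
        sample = rng.beta(653, 211, size=20_000)
        a, b = _fit_beta_moments(sample)
        assert a / (a + b) == pytest.approx(sample.mean(), abs=1e-12)
        assert a == pytest.approx(653, rel=0.1)

    def test_degenerate_beta_sample_falls_back_wide(self):
        with pytest.warns(UserWarning, match="Beta"):
            assert _fit_beta_moments(np.array([0.7, 0.7])) == (1.0, 1.0)


class TestTransitionCounts:
    def test_one_woman_well_throughout(self):
        counts = estimate_transition_counts([_well_forever()])
        lng = counts[mm.ARM_LNG]
        assert lng["first_cycle"] == {"well_allocated": 1}
        assert lng["rows"]["well_allocated"] == {"well_allocated": 23}

    def test_empty_input_flagged(self):
        with pytest.warns(UserWarning, match="no pathways"):
            counts = estimate_transition_counts([])
        assert counts[mm.ARM_LNG]["first_cycle"] == {}

    def test_recovery_from_simulated_cohort(self, lng_model):
        """Counts from 5,000 simulated women recover the generating
        probabilities within 0.02."""
        pathways = mm.simulate_pathways(lng_model, 5_000, seed=42)
        counts = estimate_transition_counts(pathways)[mm.ARM_LNG]
        first_total = sum(counts["first_cycle"].values())
        assert first_total == 5_000
        for dest, p in lng_model.first_cycle_row.probs.items():
            est = counts["first_cycle"].get(dest, 0) / first_total
            assert est == pytest.approx(p, abs=0.02)
        for source in ("symptomatic", "change_to_other"):
            row = counts["rows"][source]
            total = sum(row.values())
            for dest, p in lng_model.rows[source].probs.items():
                assert row.get(dest, 0) / total == pytest.approx(p, abs=0.02)

    def test_counts_round_trip_into_model(self, lng_model):
        pathways = mm.simulate_pathways(lng_model, 2_000, seed=3)
        counts = estimate_transition_counts(pathways)[mm.ARM_LNG]
        rebuilt = mm.build_transition_model(
            mm.HealthStateGraph(arm=mm.ARM_LNG),
            counts["first_cycle"],
            counts_to_row_specs(counts),
        )
        M = rebuilt.matrix(first_cycle=True)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-9)
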