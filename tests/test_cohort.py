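"""Cohort generator: recovery of configured summaries, bounds, determinism,
and the dosing-breakpoint weight trajectories."""

import numpy as np
import pandas as pd
import pytest

from cuprank.cohort import (
    generate_cohort,
    generate_weight_trajectory,
    measurement_days,
    relative_weight_change,
    weight_backbone,
    weight_loss_percent,
)
from cuprank.design import DoseSchedule, EndpointSpec, GroupParams
from cuprank.errors import ConfigurationError

from conftest import small_params


class TestGenerateCohort:
    def test_zero_variance_reproduces_group_means_exactly(self):
        params = small_params(
            endpoint_names=("PLP_OD", "IBA1_OD"),
            sems={(g, e): 0.0 for g in ("control", "cuprizone_A") for e in ("PLP_OD", "IBA1_OD")},
            means={
                ("control", "PLP_OD"): 96.8,
                ("control", "IBA1_OD"): 10.0,
                ("cuprizone_A", "PLP_OD"): 4.8,
                ("cuprizone_A", "IBA1_OD"): 51.9,
            },
        )
        cohort = generate_cohort(params)
        for (g, e), expected in {
            ("control", "PLP_OD"): 96.8,
            ("cuprizone_A", "IBA1_OD"): 51.9,
        }.items():
            vals = cohort.endpoints.query("group == @g and endpoint == @e")["value"]
            assert (vals == expected).all()

    def test_large_cohort_recovers_printed_control_plp_mean(self):
        """Control PLP optical density 96.8 +/- 0.5 (SEM, n=5): with 10,000
        simulated animals the sample mean lands within 0.1 of 96.8."""
        params = small_params(
            groups=("control",),
            endpoint_names=("PLP_OD",),
            n_per_group=10_000,
            means={("control", "PLP_OD"): 96.8},
            sems={("control", "PLP_OD"): 0.5},
        )
        vals = generate_cohort(params).endpoints.query("endpoint == 'PLP_OD'")["value"]
        assert abs(vals.mean() - 96.8) < 0.1
        # SEM->SD conversion: per-animal SD should be ~0.5*sqrt(5)
        assert abs(vals.std(ddof=1) - 0.5 * np.sqrt(5)) < 0.05

    def test_same_seed_bit_identical_different_seed_differs(self):
        a = generate_cohort(small_params(seed=42))
        b = generate_cohort(small_params(seed=42))
        c = generate_cohort(small_params(seed=43))
        pd.testing.assert_frame_equal(a.endpoints, b.endpoints)
        pd.testing.assert_frame_equal(a.weights, b.weights)
        assert not np.allclose(
            a.endpoints["value"].to_numpy(), c.endpoints["value"].to_numpy()
        )

    def test_growing_cohort_preserves_existing_animals(self):
        """Per-animal substreams: enlarging n_per_group never reshuffles
        already-generated animals."""
        small = generate_cohort(small_params(n_per_group=3, seed=7)).endpoints
        big = generate_cohort(small_params(n_per_group=6, seed=7)).endpoints
        merged = small.merge(
            big, on=["animal_id", "endpoint", "region"], suffixes=("_s", "_b")
        )
        assert len(merged) == len(small)
        assert (merged["value_s"] == merged["value_b"]).all()

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_values_respect_endpoint_bounds(self, seed):
        from cuprank import load_study_params

        ep = generate_cohort(load_study_params(seed=seed)).endpoints
        for name, (lo, hi) in {
            "PLP_OD": (0, 100),
            "IBA1_OD": (0, 100),
            "GFAP_OD": (0, 100),
            "APP_DENSITY": (0, np.inf),
            "LFB_SCORE": (1, 4),
        }.items():
            v = ep.loc[ep["endpoint"] == name, "value"]
            assert ((v >= lo) & (v <= hi)).all(), name

    def test_weight_loss_identical_across_regions_and_matches_trajectory(self, study_params):
        cohort = generate_cohort(study_params)
        wl = cohort.endpoints.query("endpoint == 'WEIGHT_LOSS'").pivot_table(
            index="animal_id", columns="region", values="value"
        )
        assert np.allclose(wl[215], wl[265])
        for animal, traj in cohort.weights.groupby("animal_id"):
            series = traj.set_index("day")["grams"]
            assert weight_loss_percent(series) == pytest.approx(
                wl.loc[animal, 215], abs=1e-9
            )

    def test_missing_group_params_is_a_configuration_error(self):
        params = small_params()
        params.group_params = [
            p for p in params.group_params if p.group != "cuprizone_A"
        ]
        with pytest.raises(ConfigurationError):
            params.params_for("cuprizone_A", "PLP_OD", 265)
        with pytest.raises(ConfigurationError):
            generate_cohort(params)


class TestWeightTrajectory:
    schedule = DoseSchedule()

    def test_measurement_cadence_twice_weekly_then_weekly(self):
        assert list(measurement_days(self.schedule)) == [0, 3, 7, 10, 14, 21, 28, 35]

    def test_noiseless_control_ends_at_configured_final_weight(self):
        traj = generate_weight_trajectory(
            "control", self.schedule, start_weight=22.0, noise_sd=0.0, final_weight=26.7
        )
        assert traj.iloc[-1] == pytest.approx(26.7)
        assert (np.diff(traj.to_numpy()) >= 0).all()

    def test_noiseless_cuprizone_dips_to_ninety_percent_of_start(self):
        traj = generate_weight_trajectory(
            "cuprizone_C", self.schedule, start_weight=20.0, noise_sd=0.0, final_weight=19.0
        )
        assert traj.min() <= 0.90 * 20.0 + 1e-12
        assert traj.loc[14] == pytest.approx(18.0)

    def test_backbone_slope_turns_positive_only_after_reduction_day(self):
        """Piecewise evaluation of the deterministic curve: the slope is
        negative through day 14, flat across the dose-reduction window, and
        first becomes positive after day 16."""
        days = np.arange(0, 36)
        w = weight_backbone(days, self.schedule, 22.0, 21.0, is_control=False)
        slopes = np.diff(w)
        first_positive = int(np.argmax(slopes > 1e-12))
        assert first_positive >= 16
        assert (slopes[:14] < 0).all()

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_weight_trajectory("control", self.schedule, 22.0, noise_sd=-1.0)


class TestRelativeWeightChange:
    def test_ten_percent_loss(self):
        traj = pd.Series([20.0, 19.0, 18.0], index=pd.Index([0, 14, 35], name="day"))
        assert relative_weight_change(traj) == pytest.approx(-10.0)

    def test_constant_trajectory_is_zero(self):
        traj = pd.Series([24.0, 24.0], index=pd.Index([0, 35], name="day"))
        assert relative_weight_change(traj) == 0.0

    def test_hand_arithmetic(self):
        traj = pd.Series([24.0, 21.6], index=pd.Index([0, 35], name="day"))
        assert relative_weight_change(traj) == pytest.approx(-10.0)

    def test_requires_day_zero_and_nonzero_start(self):
        with pytest.raises(ValueError):
            relative_weight_change(pd.Series([20.0], index=pd.Index([7], name="day")))
        with pytest.raises(ValueError):
            relative_weight_change(pd.Series([0.0, 1.0], index=pd.Index([0, 35], name="day")))

    def test_max_drop_definition_uses_trajectory_minimum(self):
        traj = pd.Series([20.0, 17.0, 19.0], index=pd.Index([0, 14, 35], name="day"))
        assert weight_loss_percent(traj, "max_drop") == pytest.approx(15.0)
        assert weight_loss_percent(traj, "final") == pytest.approx(5.0)
        with pytest.raises(ValueError):
            weight_loss_percent(traj, "banana")


class TestDesignValidation:
    def test_direction_conventions_are_enforced(self):
        with pytest.raises(ValueError):
            EndpointSpec(
                name="PLP_OD", region=265, direction="higher_is_stronger", bounds=(0, 100)
            )
        spec = EndpointSpec.standard("PLP_OD", 265)
        assert spec.direction.value == "lower_is_stronger"

    def test_sem_to_sd_uses_source_n(self):
        gp = GroupParams(
            group="g", endpoint="IBA1_OD", region=215, mean=20.0, sem=2.0, source_n=5
        )
        assert gp.sd == pytest.approx(2.0 * np.sqrt(5))

    def test_packaged_fixture_is_complete(self, study_params):
        d = study_params.design
        assert len(d.groups) == 7 and d.n_per_group == 5
        names = {(e.name, e.region) for e in d.endpoints}
        for region in (215, 265):
            for n in ("PLP_OD", "IBA1_OD", "GFAP_OD", "APP_DENSITY", "LFB_SCORE", "WEIGHT_LOSS"):
                assert (n, region) in names
        # spot-check a printed summary and the derived weight loss
        assert study_params.params_for("control", "PLP_OD", 265).mean == 96.8
        wl = study_params.params_for("control", "WEIGHT_LOSS", 215)
        assert wl.mean == pytest.approx(100 * (22.0 - 26.7) / 22.0)
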