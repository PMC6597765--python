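"""Within-host model: point operations, simulated infections, scans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coemerge.within_host import (
    WithinHostParams,
    cotransmission_probs,
    derivatives,
    dominance,
    pathology,
    scan_phenotype,
    simulate_infection,
    theta,
    total_transmission,
    transmission_rate,
)

DEFAULTS = WithinHostParams()


class TestPointOperations:
    @pytest.mark.parametrize(
        "state, params, expected",
        [
            ((1.0, 0.0, 1.0), DEFAULTS, (0.9999, 0.0, 0.8 / 1001)),
            ((0.0, 0.0, 1.0), DEFAULTS, (0.0, 0.0, 0.0)),
            ((1.0, 1.0, 0.0), DEFAULTS, (1.0, 1.0, 0.0)),
        ],
    )
    def test_derivatives(self, state, params, expected):
        assert derivatives(state, params) == pytest.approx(expected, rel=1e-12)

    def test_derivatives_rejects_negative_state(self):
        with pytest.raises(ValueError):
            derivatives((-1.0, 0.0, 1.0), DEFAULTS)

    @pytest.mark.parametrize(
        "W, M, expected",
        [(10.0, 0.0, 1.0), (1.0, 0.0, 0.0), (0.5, 0.0, 0.0), (0.0, 0.0, 0.0)],
    )
    def test_transmission_rate_with_clamp(self, W, M, expected):
        assert transmission_rate(W, M, DEFAULTS, mutant_present=False) == pytest.approx(
            expected
        )

    def test_transmission_rate_infectivity_boost_needs_mutant(self):
        p = WithinHostParams(x=9.0)
        assert transmission_rate(10.0, 0.0, p, mutant_present=True) == pytest.approx(2.0)
        assert transmission_rate(10.0, 0.0, p, mutant_present=False) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "W, M, v, expected", [(5.0, 0.0, 2.0, 5.0), (0.0, 10.0, 0.5, 5.0), (1.0, 1.0, 1.0, 2.0)]
    )
    def test_pathology(self, W, M, v, expected):
        assert pathology(W, M, v) == expected

    @pytest.mark.parametrize(
        "W, M, z, expected", [(3.0, 0.0, 1.0, 0.0), (2.0, 2.0, 1.0, 0.5), (1.0, 1.0, 3.0, 0.75)]
    )
    def test_theta(self, W, M, z, expected):
        assert theta(W, M, z) == pytest.approx(expected)

    def test_theta_undefined_when_both_strains_absent(self):
        with pytest.raises(ValueError):
            theta(0.0, 0.0, 1.0)

    @given(
        W=st.floats(0.0, 1e9),
        M=st.floats(0.0, 1e9),
        z=st.floats(1e-3, 1e3),
    )
    @settings(deadline=None, derandomize=True)
    def test_theta_bounded(self, W, M, z):
        if W + z * M > 0:
            assert 0.0 <= theta(W, M, z) <= 1.0


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rw": -1.0},
            {"z": 0.0},
            {"phi": 0.5, "omega": 1.0},
            {"omega": 0.0},
            {"t_max": 0.0},
            {"bottlenecks": (0,)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WithinHostParams(**kwargs)


class TestSimulateInfection:
    def test_default_wild_type_is_immune_controlled(self, wild_type_run):
        traj, outcome = wild_type_run
        assert outcome.end_cause == "clearance"
        assert 0 < outcome.tau <= DEFAULTS.t_max
        assert outcome.total_transmission > 0
        assert np.all(traj.W >= 0) and np.all(traj.M >= 0) and np.all(traj.I >= 0)
        assert np.all(np.diff(traj.Lambda_cum) >= 0)

    def test_low_pathology_threshold_ends_in_pathology(self):
        _, outcome = simulate_infection(WithinHostParams(phi=1e6))
        assert outcome.end_cause == "pathology"

    def test_decay_only_infection_clears(self):
        traj, outcome = simulate_infection(WithinHostParams(rw=0.0, w0=1.0, i0=1.0))
        assert outcome.end_cause == "clearance"
        assert np.all(np.diff(traj.W) <= 1e-12)

    def test_mutant_only_theta_is_one(self, mutant_only_run):
        traj, outcome = mutant_only_run
        body = traj.theta[traj.W + traj.M > 0]
        assert np.allclose(body, 1.0)
        b, c = outcome.bottleneck_stats[5]
        assert c == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_wild_only_never_cotransmits_mutant(self, wild_type_run):
        _, outcome = wild_type_run
        b, c = outcome.bottleneck_stats[5]
        assert c == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_empty_inoculum_rejected(self):
        with pytest.raises(ValueError):
            simulate_infection(WithinHostParams(w0=0.0, m0=0.0))

    def test_quadrature_oracle(self, neutral_coinfection_run):
        """Auxiliary-state integrals agree with trapezoid recomputation."""
        traj, outcome = neutral_coinfection_run
        lam_int = np.trapezoid(traj.lam, traj.t)
        assert lam_int == pytest.approx(outcome.total_transmission, rel=1e-3)
        for n in (2, 5, 10):
            co = np.trapezoid(
                (1 - traj.theta**n - (1 - traj.theta) ** n) * traj.lam, traj.t
            )
            mut = np.trapezoid(traj.theta**n * traj.lam, traj.t)
            b, c = outcome.bottleneck_stats[n]
            assert co / lam_int == pytest.approx(c, rel=1e-3)
            assert mut / (lam_int - co) == pytest.approx(b, rel=1e-3)

    def test_total_transmission_accessor(self, wild_type_run):
        traj, outcome = wild_type_run
        assert total_transmission(traj) == pytest.approx(outcome.total_transmission)


class TestCotransmission:
    def test_neutral_closed_form(self, neutral_coinfection_run):
        """Identical strains at equal inocula: c = 1 - (1/2)**(n-1), b = 1/2."""
        _, outcome = neutral_coinfection_run
        for n in (1, 2, 5, 10):
            b, c = outcome.bottleneck_stats[n]
            assert c == pytest.approx(1 - 0.5 ** (n - 1), abs=1e-3)
            assert b == pytest.approx(0.5, abs=1e-3)

    def test_bottleneck_of_one_never_cotransmits(self):
        """n = 1 forces c = 0 exactly, whatever the trajectory."""
        _, outcome = simulate_infection(
            WithinHostParams(rm=1.4, w0=0.5, m0=0.5, phi=1e12, bottlenecks=(1,))
        )
        assert outcome.bottleneck_stats[1].c == 0.0

    def test_mass_balance(self, neutral_coinfection_run):
        """c·Λc + (1−c)·b·Λc + (1−c)·(1−b)·Λc recovers Λc."""
        _, outcome = neutral_coinfection_run
        lam_c = outcome.total_transmission
        for n in (2, 5, 10):
            b, c = outcome.bottleneck_stats[n]
            total = c * lam_c + (1 - c) * b * lam_c + (1 - c) * (1 - b) * lam_c
            assert total == pytest.approx(lam_c, rel=1e-12)

    def test_label_swap_symmetry(self):
        """Relabelling strains in a neutral co-infection maps b to 1−b."""
        _, out_a = simulate_infection(WithinHostParams(w0=0.3, m0=0.7))
        _, out_b = simulate_infection(WithinHostParams(w0=0.7, m0=0.3))
        assert out_a.total_transmission == pytest.approx(
            out_b.total_transmission, rel=1e-8
        )
        for n in (2, 5):
            assert out_a.bottleneck_stats[n].b == pytest.approx(
                1 - out_b.bottleneck_stats[n].b, abs=1e-8
            )
            assert out_a.bottleneck_stats[n].c == pytest.approx(
                out_b.bottleneck_stats[n].c, abs=1e-8
            )

    def test_unrequested_bottleneck_falls_back_to_quadrature(
        self, neutral_coinfection_run
    ):
        traj, _ = neutral_coinfection_run
        b, c = cotransmission_probs(traj, 3)
        assert c == pytest.approx(1 - 0.5**2, abs=1e-3)
        assert b == pytest.approx(0.5, abs=1e-3)

    def test_zero_transmission_rejected(self):
        traj, _ = simulate_infection(WithinHostParams(rw=0.0, w0=1.0))
        with pytest.raises(ValueError):
            cotransmission_probs(traj, 2)


class TestDominance:
    @pytest.mark.parametrize(
        "lw, lm, lc, expected",
        [(10.0, 20.0, 20.0, 1.0), (10.0, 20.0, 10.0, 0.0), (10.0, 20.0, 15.0, 0.5)],
    )
    def test_dominance_values(self, lw, lm, lc, expected):
        assert dominance(lw, lm, lc) == expected

    def test_dominance_undefined_for_neutral_mutant(self):
        with pytest.raises(ValueError):
            dominance(10.0, 10.0, 12.0)


class TestScanPhenotype:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            scan_phenotype("faster_sneezing")

    def test_increased_growth_is_dominant_well_above_wild_type(self):
        df = scan_phenotype("increased_growth", grid=[1.5, 1.7])
        assert (df["d"] > 0.9).all()
        assert (df["end_cause_m"] == "clearance").all()

    def test_decreased_growth_is_recessive(self):
        df = scan_phenotype("decreased_growth", grid=[0.3, 0.5])
        assert (df["d"] < 0.1).all()

    def test_increased_infectivity_is_completely_dominant(self):
        df = scan_phenotype("increased_infectivity", grid=[1.0, 3.0])
        rel = (df["lambda_c"] - df["lambda_m"]).abs() / df["lambda_m"]
        assert (rel < 1e-3).all()
        assert df["d"].to_numpy() == pytest.approx(1.0, abs=1e-3)

    def test_transmissibility_scan_monotone_in_z(self):
        df = scan_phenotype("increased_transmissibility", grid=[1.0, 2.0, 3.0, 4.0])
        assert (np.diff(df["lambda_m"]) >= 0).all()

    def test_neutral_grid_point_has_missing_dominance(self):
        df = scan_phenotype("decreased_growth", grid=[0.5, 1.0])
        assert math.isnan(df["d"].iloc[1])
        assert not math.isnan(df["d"].iloc[0])

    def test_grid_outside_range_rejected(self):
        with pytest.raises(ValueError):
            scan_phenotype("increased_growth", grid=[0.5])
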