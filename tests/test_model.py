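"""Closed-form model: sedimentation, spreading, enhancement, conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aureole as a

approx = pytest.approx


# ---------------------------------------------------------------------------
# Sedimentation and coating
# ---------------------------------------------------------------------------

class TestSedimentation:
    @pytest.mark.parametrize(
        "rho, expected",
        [(2000.0, 0.80), (1050.0, 16.0)],  # heavy silica sinks; polystyrene floats high
    )
    def test_length_examples(self, rho, expected):
        p = a.ParticleSpec(d_um=1.0, rho_kg_m3=rho)
        l_s, sediments = a.sedimentation_length(p)
        assert sediments
        assert l_s == approx(expected, rel=0.01)

    def test_neutral_buoyancy_flagged_infinite(self):
        p = a.ParticleSpec(d_um=1.0, rho_kg_m3=1000.0)
        l_s, sediments = a.sedimentation_length(p)
        assert math.isinf(l_s) and not sediments

    def test_scales_as_inverse_diameter_cubed(self):
        p1 = a.ParticleSpec(d_um=1.0, rho_kg_m3=2000.0)
        p2 = a.ParticleSpec(d_um=2.0, rho_kg_m3=2000.0)
        assert a.sedimentation_length(p2)[0] / a.sedimentation_length(p1)[0] == approx(1 / 8)


class TestCoating:
    def test_zero_concentration(self, silica):
        c = a.coating_from_suspension(0.0, 4000.0, silica)
        assert c.nu_um2 == 0 and c.phi_S == 0

    def test_chamber_sedimentation(self, silica):
        c = a.coating_from_suspension(1.25e-4, 4000.0, silica)
        assert c.nu_um2 == approx(0.5)
        assert c.phi_S == approx(0.393, abs=0.001)

    def test_surface_fraction_from_measured_density(self):
        p = a.ParticleSpec(d_um=0.8, rho_kg_m3=1050.0)
        c = a.coating_from_suspension(1e-4, 4000.0, p, fully_sedimented=False,
                                      measured_nu_um2=1.0)
        assert c.phi_S == approx(0.503, abs=0.001)

    def test_refuses_to_predict_without_measurement(self, ps1000):
        with pytest.raises(ValueError, match="measured optically"):
            a.coating_from_suspension(1e-4, 4000.0, ps1000, fully_sedimented=False)


# ---------------------------------------------------------------------------
# Spreading law and friction regime
# ---------------------------------------------------------------------------

class TestSpreadingLaw:
    def test_initial_area_and_linearity(self):
        sp = a.SpreadingParams(V_star_um_s=6.2e-2, R0_um=75.0)
        assert a.spread_area(0.0, sp) == approx(math.pi * 75**2)
        # 15 h of spreading at the discussion velocity
        assert a.spread_area(54000.0, sp) - sp.A0_um2 == approx(251100.0)

    def test_growth_rate_proportional_to_R0(self):
        slow = a.SpreadingParams(V_star_um_s=5e-2, R0_um=50.0)
        fast = a.SpreadingParams(V_star_um_s=5e-2, R0_um=100.0)
        dA = lambda sp: a.spread_area(100.0, sp) - sp.A0_um2
        assert dA(fast) == approx(2 * dA(slow))

    def test_diffusion_coefficient(self):
        sp = a.SpreadingParams(V_star_um_s=5e-2, R0_um=80.0)
        assert sp.D_um2_s == approx(4.0)

    def test_radius_accessor_inverts_area(self):
        assert a.film_radius(math.pi * 123.0**2) == approx(123.0)

    def test_negative_time_rejected(self):
        sp = a.SpreadingParams(V_star_um_s=5e-2, R0_um=80.0)
        with pytest.raises(ValueError):
            a.spread_area(-1.0, sp)


class TestFrictionRegime:
    def test_dissipation_terms_closed_form(self):
        fp = a.FrictionParams(eta=1.0, k=1.0, xi=1.0, contact_radius=1.0)
        perm, slip = a.dissipation_terms(2.0, 1.0, fp)
        assert perm == approx(4 * math.pi)
        assert slip == approx(8 * math.pi * math.log(2))

    def test_no_slippage_at_contact_line_or_zero_friction(self):
        fp = a.FrictionParams(eta=2.0, k=3.0, xi=1.0, contact_radius=5.0)
        assert a.dissipation_terms(5.0, 1.0, fp)[1] == 0.0
        fp0 = a.FrictionParams(eta=2.0, k=0.0, xi=1.0, contact_radius=5.0)
        perm, slip = a.dissipation_terms(10.0, 1.0, fp0)
        assert slip == 0.0
        assert perm == approx(2 * math.pi * 2.0 * 10.0 / 5.0)

    def test_domain_error_inside_contact_line(self):
        fp = a.FrictionParams(eta=1.0, k=1.0, xi=1.0, contact_radius=10.0)
        with pytest.raises(ValueError):
            a.dissipation_terms(5.0, 1.0, fp)

    @pytest.mark.parametrize(
        "eta, k, R, expected",
        [(1.0, 5.0, 1.0, True),      # at the contact line, ln term vanishes
         (1.0, 0.0, 100.0, True),    # frictionless film
         (1.0, 10.0, math.e, False)],
    )
    def test_permeation_dominance(self, eta, k, R, expected):
        fp = a.FrictionParams(eta=eta, k=k, xi=1.0, contact_radius=1.0)
        assert a.permeation_dominant(fp, R) is expected


class TestEnhancedVelocity:
    def test_bare_and_plateau_values(self):
        ep = a.EnhancementParams(V0_um_s=4.9e-2, alpha=1.3, phi_S_plateau=0.6)
        assert a.enhanced_velocity(0.0, ep) == approx(4.9e-2)
        assert a.enhanced_velocity(0.6, ep) == approx(8.72e-2, rel=1e-3)
        # hard clamp above dense packing
        assert a.enhanced_velocity(1.2, ep) == a.enhanced_velocity(0.6, ep)

    @settings(derandomize=True, max_examples=50)
    @given(
        alpha=st.floats(0.0, 5.0),
        phi1=st.floats(0.0, 2.0),
        phi2=st.floats(0.0, 2.0),
    )
    def test_monotone_nondecreasing(self, alpha, phi1, phi2):
        ep = a.EnhancementParams(V0_um_s=5e-2, alpha=alpha, phi_S_plateau=0.6)
        lo, hi = sorted((phi1, phi2))
        assert a.enhanced_velocity(hi, ep) >= a.enhanced_velocity(lo, ep)


# ---------------------------------------------------------------------------
# Aureole conservation model
# ---------------------------------------------------------------------------

class TestCriticalRadius:
    def test_printed_coefficient(self, geometry, silica):
        up = a.UptakeParams(phi_is=0.17)
        rc = a.critical_radius(0.22, up, geometry, silica)
        assert rc * 0.22 / up.phi_is == approx(137.0, abs=1.0)

    def test_worked_example(self, geometry, silica):
        up = a.UptakeParams(phi_is=0.17)
        assert a.critical_radius(0.22, up, geometry, silica) == approx(106.0, abs=1.0)

    def test_proportional_to_phi_is(self, geometry, silica):
        r1 = a.critical_radius(0.3, a.UptakeParams(phi_is=0.1), geometry, silica)
        r2 = a.critical_radius(0.3, a.UptakeParams(phi_is=0.2), geometry, silica)
        assert r2 == approx(2 * r1)

    def test_hyperbola_invariant(self, geometry, silica):
        up = a.UptakeParams(phi_is=0.21)
        products = [
            a.critical_radius(phi, up, geometry, silica) * phi for phi in (0.1, 0.5, 1.4)
        ]
        assert max(products) == approx(min(products))

    def test_zero_coverage_never_saturates(self, geometry, silica):
        assert math.isinf(a.critical_radius(0.0, a.UptakeParams(phi_is=0.2), geometry, silica))


class TestAureoleWidth:
    def test_first_row_below_critical_radius(self, geometry, silica):
        up = a.UptakeParams(phi_is=0.21)
        rc = a.critical_radius(0.22, up, geometry, silica)
        assert a.aureole_width(0.5 * rc, 0.22, up, geometry, silica) == geometry.d_cell_um

    @settings(derandomize=True, max_examples=100)
    @given(
        phi_is=st.floats(0.01, 0.5),
        phi_S=st.floats(0.01, 1.5),
        d=st.floats(0.2, 5.0),
    )
    def test_continuous_at_critical_radius(self, phi_is, phi_S, d):
        """Both conservation branches give exactly d_cell at R = R_c."""
        g = a.CellGeometry()
        p = a.ParticleSpec(d_um=d, rho_kg_m3=2000.0)
        up = a.UptakeParams(phi_is=phi_is, phi_s=0.0)
        rc = a.critical_radius(phi_S, up, g, p)
        below = a.aureole_width(rc, phi_S, up, g, p)
        above = a.aureole_width(rc * (1 + 1e-12), phi_S, up, g, p)
        assert below == g.d_cell_um
        assert above == pytest.approx(g.d_cell_um, rel=1e-9)

    def test_plateau_ratio_silica_high_coverage(self, geometry, silica):
        up = a.UptakeParams(phi_is=0.21, phi_s=0.87)
        R = 1000.0
        assert a.aureole_width(R, 1.42, up, geometry, silica) / R == approx(0.30, abs=0.02)

    def test_zero_coverage_gives_no_aureole(self, geometry, silica):
        assert a.aureole_width(500.0, 0.0, a.UptakeParams(phi_is=0.2), geometry, silica) == 0.0

    def test_particles_must_go_somewhere(self, geometry, silica):
        up = a.UptakeParams(phi_is=0.0, phi_s=0.0)
        with pytest.raises(a.ModelViolationError):
            a.aureole_width(500.0, 0.5, up, geometry, silica)


class TestMembraneFraction:
    @pytest.mark.parametrize(
        "a_, phi_S0, phi_S, expected",
        [(0.9, 0.5, 0.3, 0.0), (0.9, 0.5, 1.2, 0.63), (0.0, 0.5, 1.2, 0.0)],
    )
    def test_threshold_law(self, a_, phi_S0, phi_S, expected):
        up = a.UptakeParams(phi_is=0.2, a=a_, phi_S0=phi_S0)
        assert a.membrane_fraction(phi_S, up) == approx(expected)


class TestConservationResidual:
    @settings(derandomize=True, max_examples=100)
    @given(
        phi_is=st.floats(0.01, 0.5),
        phi_s=st.floats(0.0, 1.0),
        phi_S=st.floats(0.01, 1.5),
        R_factor=st.floats(1.1, 20.0),
    )
    def test_zero_for_conserving_states(self, phi_is, phi_s, phi_S, R_factor):
        """The width law is exactly the particle balance, rearranged."""
        g = a.CellGeometry()
        p = a.ParticleSpec(d_um=1.0, rho_kg_m3=2000.0)
        up = a.UptakeParams(phi_is=phi_is, phi_s=phi_s)
        rc = a.critical_radius(phi_S, up, g, p)
        R = rc * R_factor
        delta = a.aureole_width(R, phi_S, up, g, p)
        C_i = 6 * phi_is / (math.pi * p.d_um**3)
        C_S = 4 * phi_s / (math.pi * p.d_um**2)
        nu = 4 * phi_S / (math.pi * p.d_um**2)
        assert abs(a.conservation_residual(R, delta, C_i, C_S, g, nu)) < 1e-9

    def test_trivial_and_linear_cases(self, geometry):
        assert a.conservation_residual(100.0, 0.0, 0.0, 0.0, geometry, 0.0) == 0.0
        # halving Delta at fixed everything else halves the held term
        p = a.ParticleSpec(d_um=1.0, rho_kg_m3=2000.0)
        up = a.UptakeParams(phi_is=0.2, phi_s=0.1)
        R, phi_S = 500.0, 0.8
        delta = a.aureole_width(R, phi_S, up, geometry, p)
        C_i = 6 * up.phi_is / math.pi
        C_S = 4 * up.phi_s / math.pi
        nu = 4 * phi_S / math.pi
        res = a.conservation_residual(R, delta / 2, C_i, C_S, geometry, nu)
        assert res == approx(-0.5, abs=1e-9)


class TestParticleCounts:
    def test_printed_loads(self, geometry, ps1000, silica):
        n_i, _, _ = a.particle_counts(a.UptakeParams(phi_is=0.11), geometry, ps1000)
        assert n_i == approx(330, rel=0.05)
        _, n_s, _ = a.particle_counts(
            a.UptakeParams(phi_is=0.11, phi_s=0.80), geometry, ps1000
        )
        assert n_s == approx(1550, rel=0.05)

    def test_zero_fractions_zero_counts(self, geometry, ps1000):
        assert a.particle_counts(a.UptakeParams(phi_is=0.0), geometry, ps1000) == (0, 0, 0)

    def test_cluster_factor_counts_clusters(self, geometry):
        p1 = a.ParticleSpec(d_um=0.8, rho_kg_m3=1050.0, cluster_factor=1.0)
        p2 = a.ParticleSpec(d_um=0.8, rho_kg_m3=1050.0, cluster_factor=2.0)
        up = a.UptakeParams(phi_is=0.23, phi_s=0.4)
        n1 = a.particle_counts(up, geometry, p1)
        n2 = a.particle_counts(up, geometry, p2)
        assert n2[0] == approx(n1[0] / 2, abs=1) and n2[1] == approx(n1[1] / 2, abs=1)

    @settings(derandomize=True, max_examples=50)
    @given(phi_is=st.floats(0.01, 0.5), d=st.floats(0.5, 3.0))
    def test_round_trip_phi_is_from_count(self, phi_is, d):
        g = a.CellGeometry()
        p = a.ParticleSpec(d_um=d, rho_kg_m3=2000.0)
        n_i, _, _ = a.particle_counts(a.UptakeParams(phi_is=phi_is), g, p)
        recovered = n_i * p.volume_um3 / g.V_cell_um3
        assert recovered == approx(phi_is, abs=p.volume_um3 / g.V_cell_um3)


class TestClearing:
    def test_passage_time_is_six_minutes(self, geometry):
        tau_p = a.passage_time(geometry, 6.2e-2)
        assert tau_p == approx(355.0, abs=1.0)
        assert round(tau_p / 60) == 6

    def test_limits(self, geometry):
        assert math.isinf(a.passage_time(geometry, 0.0))
        assert a.passage_time(geometry, 1e6) == approx(0.0, abs=1e-3)

    @pytest.mark.parametrize(
        "tau_i, tau_p, feasible",
        [(120.0, 355.0, True),   # 1-um beads internalize in ~2 min
         (355.0, 355.0, False),  # boundary excluded
         (600.0, 355.0, False)], # >5-um beads are too slow to engulf
    )
    def test_feasibility(self, tau_i, tau_p, feasible):
        assert a.clearing_feasible(a.ClearingTimes(tau_i_s=tau_i, tau_p_s=tau_p)) is feasible


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------

class TestConfigRoundTrip:
    @pytest.mark.parametrize(
        "obj",
        [
            a.ParticleSpec(d_um=1.0, rho_kg_m3=2000.0, label="x"),
            a.CellGeometry(V_cell_um3=1620.0),
            a.UptakeParams(phi_is=0.11, phi_s=0.8, a=0.9, phi_S0=0.2),
            a.EnhancementParams(V0_um_s=4.9e-2, alpha=1.3),
        ],
    )
    def test_dict_round_trip(self, obj):
        assert type(obj).from_dict(obj.to_dict()) == obj

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            a.UptakeParams.from_dict({"phi_is": 0.1, "bogus": 1})
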