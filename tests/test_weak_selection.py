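import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import solve_banded

from lvfix import (
    phi_near_equilibrium,
    phi_weak_selection,
    psi_ode_residual,
    solve_psi,
)
from lvfix.model import p_star
from lvfix.weak_selection import (
    generator_apply,
    weak_selection_surface,
)

from conftest import make_spec


def fd_psi_oracle(spec, regime, z_grid):
    """Independent oracle: direct second-order finite-difference solve of the
    linear boundary-value problem on a prescribed (nonuniform) mesh.

    Discretizes the printed ODE with three-point nonuniform central
    differences and solves the banded linear system in one shot -- no
    collocation, no mesh adaptation.
    """
    beta, gamma, d, M = spec.beta, spec.gamma, spec.d, spec.M
    z = np.asarray(z_grid)
    n = z.size
    if regime == "internal":
        bc0 = z[0] / (3 * (beta + gamma) * d)
    else:
        bc0 = z[0] / ((beta + gamma) * d)
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    ab[1, 0] = 1.0
    rhs[0] = bc0
    zi = z[1:-1]
    F, A, C, D = [
        np.asarray(v)
        for v in _coeffs(zi, d, beta, gamma, M, regime)
    ]
    hm = zi - z[:-2]
    hp = z[2:] - zi
    w_mm = 2 / (hm * (hm + hp))
    w_mp = 2 / (hp * (hm + hp))
    d_m = -hp / (hm * (hm + hp))
    d_p = hm / (hp * (hm + hp))
    d_0 = (hp - hm) / (hm * hp)
    ab[2, :-2] = D * w_mm + A * d_m
    ab[1, 1:-1] = D * (-(w_mm + w_mp)) + A * d_0 + C
    ab[0, 2:] = D * w_mp + A * d_p
    rhs[1:-1] = -F
    h1 = z[-1] - z[-2]
    ab[2, -2] = -1 / h1
    ab[1, -1] = 1 / h1
    rhs[-1] = 1.0 / (z[-1] - (beta - gamma) * d)
    return solve_banded((1, 1), ab, rhs)


def _coeffs(z, d, beta, gamma, M, regime):
    if regime == "internal":
        return (
            z + 1 / M,
            z * ((beta - gamma) * d - z),
            -(3 / (z * M)) * ((beta + gamma) * d + z),
            (z / (2 * M)) * ((beta + gamma) * d + z),
        )
    return (
        (z + 1 / M) / d,
        z * (beta - gamma - z / d),
        -(1 / (z * M)) * (beta + gamma + z / d),
        (z / (2 * M)) * (beta + gamma + z / d),
    )


class TestPsiResidual:
    def test_zero_function_leaves_inhomogeneous_term(self, neutral_spec):
        z = np.array([0.3, 1.0, 2.5])
        r_int = psi_ode_residual(z, 0, 0, 0, neutral_spec, "internal")
        assert r_int == pytest.approx(z + 1 / neutral_spec.M, rel=1e-14)

    def test_dominance_inhomogeneity_carries_1_over_d(self, dominance_spec):
        z = np.array([0.5, 1.5])
        r_dom = psi_ode_residual(z, 0, 0, 0, dominance_spec, "dominance")
        assert r_dom == pytest.approx((z + 0.01) / 0.975, rel=1e-14)

    def test_singular_origin_rejected(self, neutral_spec):
        with pytest.raises(ValueError):
            psi_ode_residual(0.0, 1.0, 1.0, 1.0, neutral_spec, "internal")


class TestSolvePsi:
    def test_positive_increasing_small_residual(self, psi_internal):
        assert np.all(psi_internal.psi > 0)
        assert np.all(np.diff(psi_internal.psi) >= 0)
        assert psi_internal.max_residual < 1e-6

    def test_dominance_regime_properties(self, psi_dominance):
        assert np.all(psi_dominance.psi > 0)
        assert np.all(np.diff(psi_dominance.psi) >= 0)
        assert psi_dominance.max_residual < 1e-6

    def test_origin_slope_internal(self, psi_internal):
        """Dominant balance at z -> 0: psi(z)/z -> 1/(3 (beta+gamma) d)."""
        z0 = psi_internal.z_min
        assert psi_internal(z0) / z0 == pytest.approx(1 / (3 * 0.7), rel=1e-6)

    def test_origin_slope_dominance(self, psi_dominance):
        z0 = psi_dominance.z_min
        assert psi_dominance(z0) / z0 == pytest.approx(1 / (0.7 * 0.975), rel=1e-6)

    @pytest.mark.parametrize("regime", ["internal", "dominance"])
    def test_matches_finite_difference_oracle(self, regime, neutral_spec, dominance_spec):
        spec = neutral_spec if regime == "internal" else dominance_spec
        sol = solve_psi(spec, regime=regime)
        z = np.geomspace(sol.z_min, sol.z_max, 60000)
        oracle = fd_psi_oracle(spec, regime, z)
        window = (z >= 0.1) & (z <= 2.0)
        rel = np.abs(sol(z[window]) - oracle[window]) / oracle[window]
        assert rel.max() < 1e-4

    def test_z_max_insensitivity(self, neutral_spec, psi_internal):
        """Doubling z_max changes psi on the lower half of the original
        window by less than 1e-4 relative."""
        wide = solve_psi(neutral_spec, regime="internal", z_max=2 * psi_internal.z_max)
        z = np.linspace(0.05, psi_internal.z_max / 2, 200)
        rel = np.abs(wide(z) - psi_internal(z)) / psi_internal(z)
        assert rel.max() < 1e-4

    def test_large_M_nonconvergence_surfaces(self):
        spec = make_spec(1, 1, 1, 1, M=50_000)
        with pytest.raises(RuntimeError, match="unstable|converge"):
            solve_psi(spec, regime="internal", max_nodes=20_000)

    def test_serialization_round_trip(self, tmp_path, psi_internal):
        path = tmp_path / "psi.csv"
        psi_internal.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (psi_internal.z_grid.size, 3)
        assert np.allclose(data[:, 1], psi_internal.psi)
        assert (tmp_path / "psi.csv.json").exists()


class TestPhiWeakSelection:
    def test_neutral_reduces_to_p(self, neutral_spec):
        p = np.linspace(0, 1, 11)
        assert phi_weak_selection(p, 0.75, neutral_spec) == pytest.approx(p, abs=0)

    def test_equilibrium_identity(self, coexistence_spec, coordination_spec):
        """phi(p*, z) = p* exactly under weak selection."""
        for spec in (coexistence_spec, coordination_spec):
            ps = p_star(spec)
            for z in (0.2, 0.75, 2.0):
                assert phi_weak_selection(ps, z, spec) == ps

    def test_boundaries_exact(self, coexistence_spec, dominance_spec):
        for spec in (coexistence_spec, dominance_spec):
            assert phi_weak_selection(0.0, 0.75, spec) == 0.0
            assert phi_weak_selection(1.0, 0.75, spec) == 1.0

    def test_symmetric_formula_identity(self, coexistence_spec, psi_internal):
        """For a = d, b = c the interior formula equals the symmetric special
        case p + p(1-p)(1-2p)(1-d/b) psi(z) (p* = 1/2 makes them identical)."""
        p = np.linspace(0.05, 0.95, 19)
        z = 0.75
        sel = 1 - 1 / 1.1
        sym = p + p * (1 - p) * (1 - 2 * p) * sel * psi_internal(z)
        assert phi_weak_selection(p, z, coexistence_spec) == pytest.approx(sym, abs=1e-15)

    def test_full_result_flags_strong_selection(self):
        strong = make_spec(1, 2.0, 2.0, 1)
        res = phi_weak_selection(0.3, 0.75, strong, full_result=True)
        assert res.conditions_violated
        weak = make_spec(1, 1.02, 1.02, 1)
        assert not phi_weak_selection(0.3, 0.75, weak, full_result=True).conditions_violated

    @given(p=st.floats(0.0, 1.0), z=st.floats(0.05, 4.5))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_clamped_probability_in_unit_interval(self, p, z):
        strong = make_spec(1, 1.5, 1.5, 1)
        res = phi_weak_selection(p, z, strong, full_result=True)
        assert 0.0 <= res.phi <= 1.0

    def test_regime_mismatch_raises(self, coexistence_spec, psi_dominance):
        with pytest.raises(ValueError, match="regime"):
            phi_weak_selection(0.3, 0.75, coexistence_spec, psi=psi_dominance)

    def test_dominance_sign_fixed_for_all_p(self, dominance_spec):
        """A dominant mutant (b > d) is above neutral at every frequency."""
        p = np.linspace(0.05, 0.95, 10)
        phi = phi_weak_selection(p, 0.5, dominance_spec)
        assert np.all(phi > p)
        sub = make_spec(1, 1, 1.05, 1.05)  # dominated mutant, b < d
        assert np.all(phi_weak_selection(p, 0.5, sub) < p)


class TestCorollaryProperties:
    SWEEP = [
        (a, c, b)
        for a in (0.9, 1.0, 1.1)
        for c in (0.9, 1.0, 1.1)
        for b in (0.95, 1.05)
    ]

    @pytest.mark.parametrize("a,c,b", SWEEP)
    def test_invasion_direction_set_by_b_vs_d(self, a, c, b):
        """For p below the interior equilibrium, phi > p iff b > d (and in
        dominance games for every p)."""
        spec = make_spec(a, b, c, 1.0)
        try:
            ps = p_star(spec)
            p = ps / 2
        except Exception:
            p = 0.3
        phi = phi_weak_selection(p, 0.75, spec)
        assert np.sign(phi - p) == np.sign(b - 1.0)

    @pytest.mark.parametrize(
        "a,c,b",
        [(a, c, b) for a, c, b in SWEEP
         if (a < c and b > 1.0) or (a > c and b < 1.0)],
    )
    def test_phi_increases_with_own_payoff_a(self, a, c, b):
        """d phi / d a > 0 (interior-equilibrium games; psi is unchanged
        since it depends on the payoffs only through d)."""
        h = 1e-5
        lo = phi_weak_selection(0.3, 0.75, make_spec(a - h, b, c, 1.0))
        hi = phi_weak_selection(0.3, 0.75, make_spec(a + h, b, c, 1.0))
        assert hi > lo


class TestNearEquilibrium:
    def test_zero_deviation_returns_p_star(self, coexistence_spec):
        ps = p_star(coexistence_spec)
        assert phi_near_equilibrium(0.0, 0.75, coexistence_spec) == ps

    def test_stable_equilibrium_damps_positive_deviations(self, coexistence_spec):
        ps = p_star(coexistence_spec)
        val = phi_near_equilibrium(0.1, 0.75, coexistence_spec)
        assert val < ps + 0.1

    def test_unstable_equilibrium_amplifies_positive_deviations(self, coordination_spec):
        ps = p_star(coordination_spec)
        val = phi_near_equilibrium(0.1, 0.75, coordination_spec)
        assert val > ps + 0.1

    def test_algebraic_identity_with_first_order_formula(self, coexistence_spec):
        """At p = p* + eps the interior first-order formula and the
        near-equilibrium expansion coincide exactly (1 - p = 1 - p* - eps)."""
        ps = p_star(coexistence_spec)
        for eps in (-0.2, -0.05, 0.05, 0.2):
            direct = phi_weak_selection(ps + eps, 0.75, coexistence_spec, full_result=True).raw
            near = phi_near_equilibrium(eps, 0.75, coexistence_spec)
            assert near == pytest.approx(direct, rel=1e-12)

    def test_dominance_specs_rejected(self, dominance_spec):
        with pytest.raises(ValueError):
            phi_near_equilibrium(0.05, 0.75, dominance_spec)


class TestGenerator:
    P = np.linspace(0.02, 0.98, 193)
    Z = np.geomspace(0.2, 2.0, 161)

    def test_annihilates_constants(self, coexistence_spec):
        const = np.ones((self.P.size, self.Z.size))
        res = generator_apply(self.P, self.Z, const, coexistence_spec)
        assert np.abs(res).max() < 1e-12

    def test_neutral_solution_is_p(self, neutral_spec):
        """phi(p, z) = p solves the absorption problem for a neutral game."""
        surf = np.broadcast_to(self.P[:, None], (self.P.size, self.Z.size)).copy()
        res = generator_apply(self.P, self.Z, surf, neutral_spec)
        assert np.abs(res).max() < 1e-12

    def test_residual_order_is_quadratic_in_selection(self):
        """max |G phi_1| scales like (1 - d/b)^2: doubling the selection
        strength roughly quadruples the residual."""
        maxres = {}
        for b in (1.02, 1.04):
            spec = make_spec(1, b, b, 1)
            surf = weak_selection_surface(self.P, self.Z, spec)
            maxres[b] = np.abs(generator_apply(self.P, self.Z, surf, spec)).max()
        ratio = maxres[1.04] / maxres[1.02]
        assert 3.0 <= ratio <= 5.0

    def test_coarse_grid_rejected(self, coexistence_spec):
        with pytest.raises(ValueError):
            generator_apply([0.1, 0.5, 0.9], self.Z, np.zeros((3, self.Z.size)), coexistence_spec)
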