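"""Model variants: effective growth rates, RHS correctness, LV analysis."""

import numpy as np
import pytest
from scipy.optimize import fsolve

import mgecomm as mg
from mgecomm.models import Kernel

from conftest import random_growth_state


class TestEffectiveGrowthRates:
    def test_no_acquired_mge_gives_basal_rate(self):
        model = mg.two_species(0.5, 0.5, eta=0.2)
        state = mg.CommunityState(np.array([0.3, 0.4]))  # p_offdiag = 0
        np.testing.assert_allclose(mg.effective_growth_rates(model, state), model.mu)

    def test_full_carriage_two_species(self):
        # species 1 fully carries the competitor's element with effect -0.04
        model = mg.two_species(0.5, 0.48, eta=0.2)  # lam_22 = -0.04
        s = np.array([0.3, 0.4])
        p = np.array([[0.3, 0.3], [0.0, 0.4]])
        mue = mg.effective_growth_rates(model, mg.CommunityState(s, p))
        assert mue[0] == pytest.approx(0.96 * model.mu[0], rel=1e-12)

    def test_full_carriage_product_five_species(self, five_species):
        """mu_i prod_{j!=i}(1+lam_j) at full carriage, vs a plain-python product."""
        m = 5
        s = np.full(m, 0.2)
        p = np.full((m, m), 0.2)
        mue = mg.effective_growth_rates(five_species, mg.CommunityState(s, p))
        lam_diag = np.diag(five_species.lam)
        for i in range(m):
            expect = five_species.mu[i]
            for j in range(m):
                if j != i:
                    expect *= 1.0 + lam_diag[j]
            assert mue[i] == pytest.approx(expect, rel=1e-12)

    def test_extinct_species_ratio_is_zero(self):
        model = mg.two_species(0.5, 0.5, eta=0.2)
        state = mg.CommunityState(np.array([0.0, 0.4]))
        mue = mg.effective_growth_rates(model, state)
        assert np.all(np.isfinite(mue))
        assert mue[0] == pytest.approx(model.mu[0])


class TestRHS:
    def test_classic_lv_fixed_point_is_stationary(self, lv_symmetric):
        fp = mg.lv_fixed_points(lv_symmetric)
        for pt in fp.points:
            if pt is None:
                continue
            d = mg.rhs(lv_symmetric, mg.CommunityState(np.array(pt)))
            assert np.abs(d.s).max() < 1e-12

    def test_hgt_model_without_transfer_reduces_to_lv(self, rng):
        """With p = 0 and eta = 0 the s-equations equal the classic LV RHS."""
        lv = mg.two_species(0.4, 0.7, gamma=1.1, eta=0.0, variant="classic_lv")
        hgt = mg.two_species(0.4, 0.7, gamma=1.1, eta=0.0)
        for _ in range(100):
            s = rng.uniform(0.0, 1.2, 2)
            state = mg.CommunityState(s)  # carriers: native only
            np.testing.assert_allclose(
                mg.rhs(hgt, state).s, mg.rhs(lv, state).s, rtol=0, atol=1e-14
            )

    def test_multispecies_reduction_to_lv(self, rng):
        """m-species RHS with p_offdiag = 0, eta = 0 matches per-species LV form."""
        m = 6
        mu = rng.uniform(0.3, 0.7, m)
        model = mg.multispecies_from_mu(mu, gamma=1.1, eta=0.0)
        for _ in range(100):
            s = rng.uniform(0.0, 1.0, m)
            ds = mg.rhs(model, mg.CommunityState(s)).s
            comp = model.gamma.T @ s - np.diag(model.gamma) * s
            expect = model.mu * s * (1.0 - s - comp) - model.D * s
            np.testing.assert_allclose(ds, expect, rtol=0, atol=1e-13)

    def test_two_species_hgt_gain_term(self):
        """dp1/dt transfer gain is eta*(s2 + p1)*(s1 - p1) in the symmetric-capacity form."""
        eta, kappa = 0.2, 0.005
        model = mg.two_species(0.5, 0.5, eta=eta, kappa=kappa)
        s = np.array([0.6, 0.3])
        p1 = 0.2
        p = np.diag(s).astype(float)
        p[0, 1] = p1
        d = mg.rhs(model, mg.CommunityState(s, p))
        growth = 1.0 - s[0] - 1.1 * s[1]
        expect = (
            model.mu[0] * (1.0 + model.lam[0, 1]) * p1 * growth
            + eta * (s[1] + p1) * (s[0] - p1)
            - (model.D + kappa) * p1
        )
        assert d.p[0, 1] == pytest.approx(expect, rel=1e-12)

    def test_selection_without_hgt_noncarriers_decay(self):
        model = mg.demo_selection(4, eta=0.0)
        s = np.array([0.5, 0.4, 0.3, 0.2])
        p = np.zeros((4, 4))
        p[0, 0] = s[0]  # donor fully carries
        d = mg.rhs(model, mg.CommunityState(s, p))
        # non-donor species have no carriers: ds_i/dt = -D s_i
        np.testing.assert_allclose(d.s[1:], -model.D * s[1:], rtol=1e-12)

    def test_carrier_bound_preserved_along_trajectory(self, rng):
        """Trajectories keep p_ij <= s_i (max violation below 1e-6)."""
        model = mg.demo_five_species(eta=0.4)
        state = random_growth_state(5, rng)
        traj = mg.integrate(model, state, 500.0, t_eval=np.linspace(0, 500, 101))
        for st in traj.states:
            assert np.max(st.p - st.s[:, None]) <= 1e-6
            assert np.min(st.s) >= 0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            mg.CommunityModel(variant="mystery", m=2, mu0=[0.5, 0.5])


class TestLVFixedPoints:
    def test_single_species_points(self):
        model = mg.two_species(0.5, 0.5, gamma=1.1, eta=0.0, variant="classic_lv")
        fp = mg.lv_fixed_points(model)
        assert fp.points[0] == (0.0, 0.0)
        assert fp.points[1] == pytest.approx((0.0, 0.6))
        assert fp.points[2] == pytest.approx((0.6, 0.0))

    def test_coexistence_point_matches_root_finding(self, lv_symmetric):
        """Closed-form g4 agrees with an independent numerical root of the RHS."""
        fp = mg.lv_fixed_points(lv_symmetric)
        g4 = np.array(fp.points[3])
        np.testing.assert_allclose(g4, [0.6 / 2.1] * 2, rtol=1e-12)

        def f(s):
            return mg.rhs(lv_symmetric, mg.CommunityState(s)).s

        root = fsolve(f, [0.3, 0.25], full_output=False)
        np.testing.assert_allclose(g4, root, atol=1e-9)

    def test_stability_matches_finite_difference_jacobian(self):
        """Stability flags agree with eigenvalues of a numerically built Jacobian."""
        model = mg.two_species(0.3, 0.8, gamma=1.1, eta=0.0, variant="classic_lv")
        fp = mg.lv_fixed_points(model)
        assert fp.stability[1] is True  # species-2 dominance attracts
        assert fp.stability[2] is False  # species-1 dominance does not
        eps = 1e-7
        for pt, flag in zip(fp.points, fp.stability):
            if pt is None:
                continue
            J = np.zeros((2, 2))
            base = np.array(pt)
            for k in range(2):
                dplus = base.copy()
                dplus[k] += eps
                dminus = base.copy()
                dminus[k] -= eps
                fplus = mg.rhs(model, mg.CommunityState(np.clip(dplus, 0, None))).s
                fminus = mg.rhs(model, mg.CommunityState(np.clip(dminus, 0, None))).s
                J[:, k] = (fplus - fminus) / (2 * eps)
            assert flag == (np.max(np.linalg.eigvals(J).real) < 0)

    def test_degenerate_gamma_product(self):
        gam = np.array([[0.0, 2.0], [0.5, 0.0]])
        model = mg.two_species(0.5, 0.5, gamma=gam, eta=0.0, variant="classic_lv")
        fp = mg.lv_fixed_points(model)
        assert fp.points[3] is None


class TestLVBistable:
    @pytest.mark.parametrize(
        "mu1,mu2,gamma,expect",
        [
            (0.5, 0.5, 1.1, True),  # symmetric: thresholds are exactly 1
            (0.4, 0.6, 1.1, False),  # phi2/phi1 = (2/3)/0.5 > 1.1
            (0.5, 0.5, 0.9, False),  # below the symmetric threshold
        ],
    )
    def test_printed_conditions(self, mu1, mu2, gamma, expect):
        model = mg.two_species(mu1, mu2, gamma=gamma, eta=0.0, variant="classic_lv")
        assert mg.lv_bistable(model) is expect

    def test_nonviable_species_is_never_bistable(self):
        model = mg.two_species(0.15, 0.6, gamma=2.0, eta=0.0, variant="classic_lv")
        assert mg.lv_bistable(model) is False  # mu1 < D = 0.2

    def test_equivalent_to_joint_stability_of_exclusion_states(self, rng):
        """Bistable iff both single-species fixed points are attractors."""
        for _ in range(50):
            mu = rng.uniform(0.25, 1.0, 2)
            gam = rng.uniform(0.5, 1.8, 2)
            model = mg.two_species(
                mu[0], mu[1], gamma=np.array([[0, gam[0]], [gam[1], 0]]),
                eta=0.0, variant="classic_lv",
            )
            fp = mg.lv_fixed_points(model)
            assert mg.lv_bistable(model) == (fp.stability[1] and fp.stability[2])


class TestRateConversion:
    @pytest.mark.parametrize(
        "eta,Nm,eta_c", [(1e-2, 1e9, 1e-11), (1e-2, 1e12, 1e-14), (0.0, 1e9, 0.0)]
    )
    def test_round_trip(self, eta, Nm, eta_c):
        assert mg.eta_to_empirical(eta, Nm) == pytest.approx(eta_c)
        assert mg.eta_from_empirical(eta_c, Nm) == pytest.approx(eta)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mg.eta_from_empirical(-1e-12, 1e9)


class TestSerialization:
    def test_json_round_trip(self, five_species, tmp_path):
        path = tmp_path / "model.json"
        five_species.to_json(path)
        back = mg.CommunityModel.from_json(path)
        assert back.variant == five_species.variant
        np.testing.assert_allclose(back.lam, five_species.lam)
        np.testing.assert_allclose(back.mu0, five_species.mu0)
        assert back.eta == five_species.eta

    def test_schema_required(self):
        with pytest.raises(ValueError, match="schema"):
            mg.CommunityModel.from_dict({"variant": "classic_lv", "m": 2, "mu0": [0.5, 0.5]})

    @pytest.mark.parametrize(
        "bad",
        [
            {"lam": -1.5},  # 1 + lam <= 0
            {"gamma": -0.1},
            {"eta": -0.2},
            {"D": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(variant="multispecies", m=3, mu0=[0.5] * 3)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            mg.CommunityModel(**kwargs)

    def test_carrier_state_invariants(self):
        with pytest.raises(ValueError):
            mg.CommunityState(np.array([0.2, 0.2]), np.full((2, 2), 0.5)).validate()
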