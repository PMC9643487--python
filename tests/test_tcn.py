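import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from sundaland import synthetic, tcn


class TestDecayAndScaling:
    def test_decay_constant_identity(self):
        lam = tcn.decay_constant(1.387e6)
        assert lam * 1.387e6 == pytest.approx(math.log(2))
        assert math.exp(-lam * 1.387e6) == pytest.approx(0.5)

    def test_al_decays_faster(self, constants):
        assert constants.lambda_26Al > constants.lambda_10Be

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError):
            tcn.decay_constant(0.0)

    def test_slhl_normalization(self):
        assert tcn.stone_scaling(60.0, 0.0) == pytest.approx(1.0)

    def test_scaling_increases_with_elevation(self):
        factors = [tcn.stone_scaling(-7.5, h) for h in (0, 500, 1000, 2000, 4000)]
        assert np.all(np.diff(factors) > 0)

    def test_equator_below_high_latitude(self):
        assert tcn.stone_scaling(0.0, 0.0) < tcn.stone_scaling(60.0, 0.0)


class TestInheritance:
    def test_vanishes_at_fast_denudation(self, constants):
        n9 = tcn.steady_state_inheritance(4.0, constants.lambda_10Be, 1e9, constants)
        n12 = tcn.steady_state_inheritance(4.0, constants.lambda_10Be, 1e12, constants)
        assert n12 < n9 < 1e-2
        assert n12 < 1e-5

    def test_spallation_closed_form_stable_nuclide(self, constants):
        """Spallation-only with lambda = 0: N = P * Lambda / (rho * eps)."""
        c = constants.spallation_only()
        eps = 100.0  # m/Ma
        n = tcn.steady_state_inheritance(4.0, 0.0, eps, c)
        expected = 4.0 * c.attenuation_spallation / (c.density_source * eps * 1e-4)
        assert n == pytest.approx(expected, rel=1e-12)

    def test_ratio_tends_to_production_ratio(self, site, constants):
        """At very fast source denudation both inventories are
        attenuation-dominated and the inherited ratio approaches R0."""
        P10 = constants.slhl_spallation_P10 * site.scaling_factor
        P26 = constants.production_ratio_R0 * P10
        eps = 1e6
        r = tcn.steady_state_inheritance(
            P26, constants.lambda_26Al, eps, constants
        ) / tcn.steady_state_inheritance(P10, constants.lambda_10Be, eps, constants)
        assert r == pytest.approx(constants.production_ratio_R0, rel=1e-3)

    def test_zero_everything_rejected(self, constants):
        with pytest.raises(ValueError):
            tcn.steady_state_inheritance(4.0, 0.0, 0.0, constants)


class TestForwardModel:
    def test_zero_age_equals_inheritance(self, site, constants):
        N10, N26 = tcn.forward_concentrations(2.0, 0.0, 50.0, 400.0, site, constants)
        P10 = constants.slhl_spallation_P10 * site.scaling_factor
        assert N10 == pytest.approx(
            tcn.steady_state_inheritance(P10, constants.lambda_10Be, 50.0, constants)
        )
        assert N26 == pytest.approx(
            tcn.steady_state_inheritance(
                constants.production_ratio_R0 * P10, constants.lambda_26Al, 50.0, constants
            )
        )

    def test_pure_decay_at_depth(self, site, constants):
        """No post-burial denudation and great depth: only decay operates, so
        the ratio falls as exp(-(l26 - l10) t)."""
        t = 1.5e6
        depth = 2000.0  # deep enough to shield even the deepest muon pathway
        N10_0, N26_0 = tcn.forward_concentrations(depth, 0.0, 30.0, 0.0, site, constants)
        N10_t, N26_t = tcn.forward_concentrations(depth, t, 30.0, 0.0, site, constants)
        dl = constants.lambda_26Al - constants.lambda_10Be
        assert N10_t / N10_0 == pytest.approx(math.exp(-constants.lambda_10Be * t), rel=1e-9)
        assert (N26_t / N10_t) / (N26_0 / N10_0) == pytest.approx(
            math.exp(-dl * t), rel=1e-9
        )

    @pytest.mark.parametrize(
        "t,E,depth",
        [
            (1.8e6, 436.0, 3.0),
            (1.0e5, 30.0, 0.5),
            (5.0e6, 2000.0, 6.0),
            (4.0e3, 600.0, 1.0),
        ],
    )
    def test_post_burial_closed_form_vs_quadrature(self, site, constants, t, E, depth):
        """The closed-form post-burial integral matches numerical time
        integration of the exhumation history to better than 0.1%."""
        S = site.scaling_factor
        P10 = constants.slhl_spallation_P10 * S
        lam = constants.lambda_10Be
        frac, lam_att = constants.pathways()
        rho = constants.density_sediment
        z_cm = depth * 100.0
        E_cm = E * 1e-4

        def integrand(tau):  # tau = time before present
            depth_then = z_cm + E_cm * tau
            prod = sum(
                P10 * f * math.exp(-rho * depth_then / L) for f, L in zip(frac, lam_att)
            )
            return prod * math.exp(-lam * tau)

        numeric, _ = quad(integrand, 0.0, t, limit=400)
        closed = tcn._post_burial_term(P10, lam, depth, t, E, constants)
        assert closed == pytest.approx(numeric, rel=1e-3)

    @settings(max_examples=60, deadline=None)
    @given(
        t=st.floats(0.0, 6.0e6),
        eps=st.floats(1.0, 1000.0),
        E=st.floats(0.0, 2000.0),
        depth=st.floats(0.0, 20.0),
    )
    def test_ratio_never_exceeds_production_ratio(self, t, eps, E, depth):
        site = tcn.SiteContext(-7.466, 99.0)
        constants = tcn.NuclideConstants()
        N10, N26 = tcn.forward_concentrations(depth, t, eps, E, site, constants)
        assert N26 / N10 <= constants.production_ratio_R0 * (1 + 1e-9)

    def test_negative_parameters_rejected(self, site, constants):
        with pytest.raises(ValueError):
            tcn.forward_concentrations(1.0, -5.0, 50.0, 0.0, site, constants)


def _profile_samples(df):
    return [
        tcn.NuclideSample(
            str(r["sample_id"]), float(r["depth_m"]),
            float(r["N10_at_g"]), float(r["N10_sigma"]),
            float(r["N26_at_g"]), float(r["N26_sigma"]),
        )
        for _, r in df.iterrows()
    ]


class TestJointInversion:
    def test_noiseless_recovery(self, site, constants):
        """Noiseless profile at the study parameter values is recovered to
        1e-3 relative in burial age."""
        sc = synthetic.ProfileScenario(seed=42, relative_noise=0.0)
        df = synthetic.make_profiles(sc, constants)
        model = tcn.JointBurialModel.from_dataframe(df, site, constants)
        res = model.fit(n_restarts=8, n_mc=0, seed=1)
        assert res.burial_age == pytest.approx(1.78e6, rel=1e-3)
        assert res.post_denudation == pytest.approx(436.0, rel=5e-3)
        # sigmas are 1e-6 relative here, so chi2 ~ 0.1 means the fit matches
        # the data to a few parts in 1e7
        assert res.chi2 < 1.0
        truth = df["true_pre_denudation_m_per_Ma"].to_numpy()
        assert np.allclose(res.pre_denudation, truth, rtol=1e-2)

    def test_duplicate_sample_same_optimum(self, site, constants):
        sc = synthetic.ProfileScenario(seed=8, n_samples=6, relative_noise=0.0)
        df = synthetic.make_profiles(sc, constants)
        samples = _profile_samples(df)
        r1 = tcn.JointBurialModel(samples, site, constants).fit(n_restarts=4, n_mc=0, seed=0)
        r2 = tcn.JointBurialModel(samples + [samples[0]], site, constants).fit(
            n_restarts=4, n_mc=0, seed=0
        )
        assert r2.burial_age == pytest.approx(r1.burial_age, rel=1e-3)

    def test_mc_uncertainty_shrinks_with_sample_count(self, site, constants):
        """Measurement-only Monte-Carlo age scatter scales roughly like
        1/sqrt(n) on homogeneous profiles."""
        def sigma_for(n):
            sc = synthetic.ProfileScenario(
                seed=3, n_samples=n,
                depths=tuple(np.linspace(0.3, 5.7, n)),
                true_pre_denudation=tuple([50.0] * n),
                relative_noise=0.0,
            )
            df = synthetic.make_profiles(sc, constants)
            df["N10_sigma"] = 0.05 * df["N10_at_g"]
            df["N26_sigma"] = 0.05 * df["N26_at_g"]
            model = tcn.JointBurialModel.from_dataframe(df, site, constants)
            res = model.fit(
                n_restarts=2, n_mc=120, include_constants_uncertainty=False, seed=0
            )
            return res.burial_age_sigma

        ratio = sigma_for(4) / sigma_for(16)
        assert 1.2 < ratio < 3.3  # ideal 2.0, Monte-Carlo slack

    def test_requires_two_samples(self, site):
        with pytest.raises(ValueError):
            tcn.JointBurialModel([], site)

    def test_summary_mentions_key_quantities(self, site, constants):
        sc = synthetic.ProfileScenario(seed=12, n_samples=5, relative_noise=0.0)
        df = synthetic.make_profiles(sc, constants)
        res = tcn.JointBurialModel.from_dataframe(df, site, constants).fit(
            n_restarts=2, n_mc=10, seed=0
        )
        text = res.summary()
        assert "burial age" in text and "denudation" in text


class TestMinimumInversion:
    def _pure_decay_sample(self, site, constants, t, eps, depth=3.0, rel=0.03):
        P10 = constants.slhl_spallation_P10 * site.scaling_factor
        P26 = constants.production_ratio_R0 * P10
        N10 = tcn.steady_state_inheritance(
            P10, constants.lambda_10Be, eps, constants
        ) * math.exp(-constants.lambda_10Be * t)
        N26 = tcn.steady_state_inheritance(
            P26, constants.lambda_26Al, eps, constants
        ) * math.exp(-constants.lambda_26Al * t)
        return tcn.NuclideSample("S", depth, N10, rel * N10, N26, rel * N26)

    def test_noiseless_roundtrip(self, site, constants):
        s = self._pure_decay_sample(site, constants, t=1.0e6, eps=50.0)
        res = tcn.MinimumBurialModel(s, site, constants).fit(n_mc=0)
        assert res.min_burial_age == pytest.approx(1.0e6, rel=1e-3)
        assert res.pre_denudation == pytest.approx(50.0, rel=1e-3)
        assert not res.boundary

    def test_ratio_on_steady_state_curve_gives_zero_age(self, site, constants):
        s = self._pure_decay_sample(site, constants, t=0.0, eps=80.0)
        res = tcn.MinimumBurialModel(s, site, constants).fit(n_mc=0)
        assert res.boundary
        assert res.min_burial_age == 0.0

    def test_age_monotone_in_ratio(self, site, constants):
        """At fixed 10Be, a lower 26Al/10Be ratio means a longer burial."""
        base = self._pure_decay_sample(site, constants, t=1.2e6, eps=40.0)
        ages = []
        for factor in (1.0, 0.9, 0.8, 0.7):
            s = tcn.NuclideSample(
                "S", base.depth, base.N10, base.sigma10,
                base.N26 * factor, base.sigma26 * factor,
            )
            ages.append(tcn.MinimumBurialModel(s, site, constants).fit(n_mc=0).min_burial_age)
        assert np.all(np.diff(ages) > 0)


class TestWeightedMean:
    def _sol(self, sid, age, sigma):
        return tcn.MinimumBurialResults(sid, age, sigma, 50.0, False, np.array([]), 0)

    def test_identical_ages_nothing_removed(self):
        sols = [self._sol(f"S{i}", 1.0e6, 0.1e6) for i in range(5)]
        wm = tcn.weighted_mean_with_outliers(sols)
        assert wm.mean_age == pytest.approx(1.0e6)
        assert wm.removed_ids == []

    def test_hand_computed_weighted_mean(self):
        sols = [
            self._sol("A", 1.0, 0.1),
            self._sol("B", 2.0, 0.1),
            self._sol("C", 1.5, 1e6),  # negligible weight, keeps n >= 3
        ]
        # chi2 of A/B alone would trigger rejection; use a generous threshold
        wm = tcn.weighted_mean_with_outliers(sols, confidence=1.0 - 1e-12)
        assert wm.mean_age == pytest.approx(1.5, rel=1e-9)
        assert wm.sigma == pytest.approx(0.1 / math.sqrt(2), rel=1e-6)

    def test_planted_outliers_removed(self):
        """13 concordant ages plus 3 planted 5-sigma outliers: the filter
        removes exactly the planted ones."""
        rng = np.random.default_rng(0)
        sols = [
            self._sol(f"S{i}", 1.45e6 + rng.normal(0.0, 0.3e5), 1.0e5) for i in range(13)
        ]
        for i, sign in zip((13, 14, 15), (1, -1, 1)):
            sols.append(self._sol(f"OUT{i}", 1.45e6 + sign * 5.0e5, 1.0e5))
        rng.shuffle(sols)
        wm = tcn.weighted_mean_with_outliers(sols)
        assert sorted(wm.removed_ids) == ["OUT13", "OUT14", "OUT15"]
        assert wm.mean_age == pytest.approx(1.45e6, rel=0.02)
        assert all(s.outlier for s in sols if s.sample_id.startswith("OUT"))


class TestPostBurialFraction:
    def test_zero_cases(self, site, constants):
        f10, f26 = tcn.post_burial_fraction(2000.0, 1.8e6, 50.0, 0.0, site, constants)
        assert f10 == pytest.approx(0.0, abs=1e-12)
        f10, f26 = tcn.post_burial_fraction(1.0, 0.0, 50.0, 400.0, site, constants)
        assert f10 == 0.0 and f26 == 0.0

    def test_al_fraction_exceeds_be_fraction(self, site, constants):
        f10, f26 = tcn.post_burial_fraction(1.0, 1.78e6, 50.0, 436.0, site, constants)
        assert f26 > f10 > 0.0

    def test_decreases_with_depth(self, site, constants):
        f = [
            tcn.post_burial_fraction(d, 1.78e6, 50.0, 436.0, site, constants)[0]
            for d in (0.5, 1.0, 2.0, 4.0, 6.0)
        ]
        assert np.all(np.diff(f) < 0)


def test_section_denudation_rate():
    assert tcn.section_denudation_rate(100.0, 0.25e6) == pytest.approx(400.0)
    with pytest.raises(ValueError):
        tcn.section_denudation_rate(100.0, 0.0)
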