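import numpy as np
import pandas as pd
import pytest

from retipulse.attenuation import (
    assemble_records,
    compare_attenuation,
    descriptive,
    fit_coefficient_models,
    fit_interaction,
    fit_marginal,
    kruskal_wallis,
)
from retipulse.exceptions import DegenerateDataError
from retipulse.harmonic import HarmonicFit
from retipulse.synthetic import SyntheticStudyConfig, generate_attenuation_records


def make_fit(hrw_a, **meta):
    return HarmonicFit(
        order=2, intercept=100.0, a=np.array([1.0, 0.1]),
        b=np.array([-0.5, 0.05]), spline=np.zeros(3), rho=0.2, sigma2=0.5,
        aic=100.0, loglik=-48.0, hrw_a=hrw_a, n_obs=70, metadata=meta,
    )


class TestAssembleRecords:
    def test_log10_transform_and_drop_counter(self):
        fits = [
            make_fit(10.0, v_dist_dd=0.2, odf_g=50.0),
            make_fit(0.0, v_dist_dd=0.4, odf_g=50.0),
            make_fit(1.0, v_dist_dd=0.6, odf_g=50.0),
        ]
        df, dropped = assemble_records(fits)
        assert dropped == 1
        assert len(df) == 2
        assert df["log_hrwa"].iloc[0] == pytest.approx(1.0)
        assert df["log_hrwa"].iloc[1] == pytest.approx(0.0)

    def test_unresolvable_metadata_names_key(self):
        with pytest.raises(KeyError, match="odf_g"):
            assemble_records([make_fit(5.0, v_dist_dd=0.2)])

    def test_synthetic_study_bookkeeping(self):
        cfg = SyntheticStudyConfig(
            n_eyes=2, runs_per_eye=3, points_per_vessel=4, seed=1
        )
        rec = generate_attenuation_records(cfg)
        assert len(rec) == 2 * 3 * 4


class TestDescriptive:
    def test_hand_computed_quartiles(self):
        d = descriptive([1.0, 2.0, 3.0, 4.0])
        assert d.median == 2.5
        assert d.iqr == pytest.approx(1.5)  # linear-interpolation quartiles
        assert d.range == (1.0, 4.0)

    def test_symmetric_sample_has_zero_skew(self):
        d = descriptive([-1.0, 0.0, 1.0] * 5)
        assert d.skewness == pytest.approx(0.0, abs=1e-12)
        assert d.pearson_criterion == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample_flagged_degenerate(self):
        d = descriptive([3.0, 3.0, 3.0, 3.0])
        assert d.degenerate
        assert np.isnan(d.pearson_criterion)

    def test_too_small_sample(self):
        with pytest.raises(DegenerateDataError):
            descriptive([1.0, 2.0, 3.0])

    def test_log_transform_reduces_right_skew(self, rng):
        amp = 10 ** rng.normal(0.8, 0.4, 500)  # log-normal amplitudes
        assert abs(descriptive(np.log10(amp)).skewness) < abs(
            descriptive(amp).skewness
        )


class TestKruskalWallis:
    def test_identical_groups_give_null_result(self):
        h, p = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        h, p = kruskal_wallis([np.arange(10), np.arange(10) + 100])
        assert p < 0.001

    def test_null_p_values_spread(self, rng):
        ps = []
        for _ in range(200):
            x = rng.normal(0, 1, 20)
            ps.append(kruskal_wallis([x[:10], x[10:]])[1])
        ps = np.array(ps)
        assert 0.35 < (ps < 0.5).mean() < 0.65


def noiseless_records(coeffs, vessel="vein", seed=1):
    cfg = SyntheticStudyConfig(
        n_eyes=4, runs_per_eye=3, points_per_vessel=8,
        random_effect_sd=(0, 0), log_residual_sd=0.0,
        fixed_coeffs=coeffs, vessel_type=vessel, seed=seed,
    )
    return generate_attenuation_records(cfg)


class TestMarginalModel:
    def test_noiseless_slope_recovered_exactly(self):
        rec = noiseless_records((1.012, -0.40, 0.0, 0.0))
        res = fit_marginal(rec, "v_dist")
        assert res["slope"].estimate == pytest.approx(-0.40, abs=1e-8)
        assert res["intercept"].estimate == pytest.approx(1.012, abs=1e-8)

    def test_recovery_within_wald_interval(self):
        hits = 0
        for r in range(20):
            cfg = SyntheticStudyConfig(
                n_eyes=10, runs_per_eye=5, points_per_vessel=10,
                fixed_coeffs=(1.012, -0.40, 0.0, 0.0), seed=3000 + r,
            )
            res = fit_marginal(generate_attenuation_records(cfg), "v_dist")
            s = res["slope"]
            if abs(s.estimate + 0.40) <= 2 * s.se:
                hits += 1
        assert hits >= 17

    def test_constant_predictor_rejected(self):
        rec = noiseless_records((1.0, -0.4, 0.0, 0.0))
        rec["odf_g"] = 50.0
        with pytest.raises(DegenerateDataError):
            fit_marginal(rec, "odf")


class TestInteractionModel:
    def test_noiseless_coefficients_recovered(self):
        rec = noiseless_records(None)  # venous defaults
        res = fit_interaction(rec)
        assert res.fixed["I0"].estimate == pytest.approx(0.90, abs=1e-8)
        assert res.fixed["C_VD"].estimate == pytest.approx(-0.34, abs=1e-8)
        assert res.fixed["C_ODF"].estimate == pytest.approx(0.0015, abs=1e-8)
        assert res.fixed["C_VDxODF"].estimate == pytest.approx(-0.00084, abs=1e-8)

    def test_r2_ordering_invariant(self):
        rec = generate_attenuation_records(
            SyntheticStudyConfig(n_eyes=8, runs_per_eye=5,
                                 points_per_vessel=10, seed=21)
        )
        res = fit_interaction(rec)
        assert 0.0 <= res.r2_marginal <= res.r2_conditional <= 1.0

    def test_null_fixed_effects_give_near_zero_marginal_r2(self):
        rec = generate_attenuation_records(
            SyntheticStudyConfig(n_eyes=8, runs_per_eye=5,
                                 points_per_vessel=10,
                                 fixed_coeffs=(0.8, 0.0, 0.0, 0.0),
                                 random_effect_sd=(0.1, 0.0), seed=22)
        )
        res = fit_interaction(rec)
        assert res.r2_marginal < 0.02

    def test_zero_random_variance_matches_ols(self):
        import statsmodels.formula.api as smf

        rec = generate_attenuation_records(
            SyntheticStudyConfig(n_eyes=6, runs_per_eye=5,
                                 points_per_vessel=10,
                                 random_effect_sd=(0, 0), seed=23)
        )
        res = fit_interaction(rec)
        ols = smf.ols("log_hrwa ~ v_dist_dd * odf_g", rec).fit()
        assert res.fixed["C_VD"].estimate == pytest.approx(
            ols.params["v_dist_dd"], abs=1e-6
        )
        assert res.fixed["I0"].estimate == pytest.approx(
            ols.params["Intercept"], abs=1e-6
        )

    def test_standardized_betas_invariant_to_predictor_units(self):
        rec = generate_attenuation_records(
            SyntheticStudyConfig(n_eyes=8, runs_per_eye=5,
                                 points_per_vessel=10, seed=24)
        )
        res = fit_interaction(rec)
        rescaled = rec.copy()
        rescaled["odf_g"] = rescaled["odf_g"] / 1000.0  # grams -> kilograms
        res2 = fit_interaction(rescaled)
        for term in ("C_VD", "C_ODF", "C_VDxODF"):
            assert res2.beta_std[term] == pytest.approx(
                res.beta_std[term], rel=1e-3
            )

    def test_wald_ci_brackets_estimate(self):
        rec = generate_attenuation_records(
            SyntheticStudyConfig(n_eyes=8, runs_per_eye=5,
                                 points_per_vessel=10, seed=25)
        )
        res = fit_interaction(rec)
        for term in res.fixed.values():
            assert term.ci_lo <= term.estimate <= term.ci_hi


class TestAgainstLme4:
    def test_interaction_fit_matches_lme4(self, tmp_path):
        """Fixed effects and SEs agree with lme4 (independent REML
        implementation) on the same data and model."""
        import subprocess

        rec = generate_attenuation_records(
            SyntheticStudyConfig(seed=5, n_eyes=10, runs_per_eye=5,
                                 points_per_vessel=10)
        )
        rec = rec.assign(grp=rec.subject_id + "/" + rec.eye_id)
        csv = tmp_path / "rec.csv"
        rec.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(log_hrwa ~ v_dist_dd * odf_g + (1 + v_dist_dd | grp),"
            " d, REML=TRUE)\n"
            "cf <- summary(m)$coefficients\n"
            f"write.csv(cf, '{tmp_path / 'lme4.csv'}')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True, text=True)
        ref = pd.read_csv(tmp_path / "lme4.csv", index_col=0)
        ours = fit_interaction(rec)
        mapping = {"(Intercept)": "I0", "v_dist_dd": "C_VD",
                   "odf_g": "C_ODF", "v_dist_dd:odf_g": "C_VDxODF"}
        for rname, label in mapping.items():
            assert ours.fixed[label].estimate == pytest.approx(
                ref.loc[rname, "Estimate"], rel=1e-5, abs=1e-8
            )
            assert ours.fixed[label].se == pytest.approx(
                ref.loc[rname, "Std. Error"], rel=1e-3
            )


class TestCompareAttenuation:
    def test_distinct_slopes_detected(self):
        vein = generate_attenuation_records(
            SyntheticStudyConfig(n_eyes=10, runs_per_eye=5,
                                 points_per_vessel=10, seed=31)
        )
        artery = generate_attenuation_records(
            SyntheticStudyConfig(n_eyes=10, runs_per_eye=5,
                                 points_per_vessel=10, vessel_type="artery",
                                 seed=32)
        )
        f, p = compare_attenuation(pd.concat([vein, artery]))
        assert p < 0.001
        assert f > 0

    def test_single_vessel_type_rejected(self):
        vein = generate_attenuation_records(
            SyntheticStudyConfig(n_eyes=4, runs_per_eye=3,
                                 points_per_vessel=4, seed=33)
        )
        with pytest.raises(DegenerateDataError):
            compare_attenuation(vein)


class TestCoefficientModels:
    def test_known_a1_dependence_recovered(self, rng):
        rows = []
        for eye in range(10):
            for v in np.linspace(0, 1, 10):
                for odf in np.linspace(0, 180, 5):
                    rows.append({
                        "subject_id": f"S{eye // 2}", "eye_id": f"E{eye}",
                        "v_dist_dd": v, "odf_g": odf,
                        "a1": 2.0 - 3.79 * v + rng.normal(0, 0.5),
                        "b1": rng.normal(0, 0.5),
                    })
        out = fit_coefficient_models(pd.DataFrame(rows),
                                     coefficients=("a1", "b1"))
        est = out["a1"]["v_dist_dd"]
        assert abs(est.estimate + 3.79) <= 2 * est.se
        null = out["b1"]["v_dist_dd"]
        assert abs(null.estimate) <= 3 * null.se

    def test_constant_coefficient_rejected(self):
        rec = noiseless_records(None)
        rec["a1"] = 1.0
        with pytest.raises(DegenerateDataError):
            fit_coefficient_models(rec, coefficients=("a1",))
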