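"""Mixed-model fitting and explained-variation decomposition.

The in-package REML fitter is cross-checked against two independent
oracles: statsmodels MixedLM on the same data, and the balanced one-way
nested ANOVA closed form (which coincides with REML for balanced designs
with interior estimates).
"""

import numpy as np
import pandas as pd
import pytest

from organspectra.lmm import (
    FACTORS,
    bootstrap_ci,
    decompose,
    decompose_stratified,
    decompose_table,
    fit_lmm,
    median_across_wavelengths,
    _frame_at_band,
)
from organspectra.synthetic import (
    GenerativeComponents,
    make_standardized_design,
    simulate_spectra,
)


def nested_frame(n_pigs=6, n_images=4, n_reps=3, s_pig=1.0, s_img=0.5, s_rep=0.25,
                 organ_effects=None, angle_effects=None, seed=0):
    """Balanced nested layout with optional organ/angle fixed effects."""
    rng = np.random.default_rng(seed)
    rows = []
    organs = list(organ_effects or {"stomach": 0.0})
    angles = list(angle_effects or {"perpendicular": 0.0})
    for i in range(n_pigs):
        d = rng.normal(0, np.sqrt(s_pig))
        for j in range(n_images):
            g = rng.normal(0, np.sqrt(s_img))
            organ = organs[(i * n_images + j) % len(organs)]
            angle = angles[j % len(angles)]
            for k in range(n_reps):
                e = rng.normal(0, np.sqrt(s_rep))
                y = (organ_effects or {}).get(organ, 0.0) + \
                    (angle_effects or {}).get(angle, 0.0) + d + g + e
                rows.append((f"P{i}", f"P{i}_img{j}", organ, angle, y))
    return pd.DataFrame(rows, columns=["pig_id", "image_id", "organ", "angle", "y"])


class TestFitLMM:
    def test_matches_mixedlm_oracle(self):
        frame = nested_frame(
            n_pigs=5, n_images=6, seed=1,
            organ_effects={"stomach": 0.0, "liver": 1.0, "spleen": -0.5},
            angle_effects={"perpendicular": 0.0, "side_a_25deg": 0.3},
        )
        fast = fit_lmm(frame, engine="nested")
        import statsmodels.formula.api as smf

        md = smf.mixedlm(
            "y ~ C(organ, Treatment('stomach')) + C(angle, Treatment('perpendicular'))",
            frame, groups=frame["pig_id"], re_formula="1",
            vc_formula={"image": "0 + C(image_id)"},
        )
        res = md.fit(reml=True)
        assert fast.sigma2_pig == pytest.approx(float(np.asarray(res.cov_re)[0, 0]), rel=2e-2, abs=1e-4)
        assert fast.sigma2_image == pytest.approx(float(res.vcomp[0]), rel=1e-2, abs=1e-4)
        assert fast.sigma2_rep == pytest.approx(float(res.scale), rel=1e-2, abs=1e-4)
        fe = res.fe_params.to_numpy()
        mine = np.concatenate([[fast.alpha], fast.beta.to_numpy(), fast.theta.to_numpy()])
        assert np.allclose(mine, fe, atol=1e-6)

    def test_balanced_anova_closed_form_oracle(self):
        # intercept-only balanced design: REML equals the ANOVA estimators
        frame = nested_frame(n_pigs=8, n_images=5, n_reps=3, seed=2)
        fit = fit_lmm(frame)
        y = frame["y"].to_numpy()
        m, r, P = 5, 3, 8
        cell = y.reshape(P, m, r)
        img_mean = cell.mean(axis=2)
        pig_mean = img_mean.mean(axis=1)
        grand = y.mean()
        ms_rep = ((cell - img_mean[:, :, None]) ** 2).sum() / (P * m * (r - 1))
        ms_img = r * ((img_mean - pig_mean[:, None]) ** 2).sum() / (P * (m - 1))
        ms_pig = m * r * ((pig_mean - grand) ** 2).sum() / (P - 1)
        assert fit.sigma2_rep == pytest.approx(ms_rep, rel=1e-6)
        assert fit.sigma2_image == pytest.approx((ms_img - ms_rep) / r, rel=1e-6)
        assert fit.sigma2_pig == pytest.approx((ms_pig - ms_img) / (m * r), rel=1e-5, abs=1e-8)

    def test_pure_residual_simulation(self):
        # no pig/image/fixed structure: everything lands in the residual
        frame = nested_frame(n_pigs=10, n_images=8, s_pig=0.0, s_img=0.0, s_rep=1.0, seed=3)
        fit = fit_lmm(frame)
        n = len(frame)
        se = np.sqrt(2.0 / n)
        assert abs(fit.sigma2_rep - 1.0) < 3 * se
        assert fit.sigma2_pig < 0.05
        assert fit.sigma2_image < 0.05
        assert abs(fit.alpha) < 3 * np.sqrt(1.0 / n) * 3

    def test_single_organ_drops_factor(self):
        frame = nested_frame(n_pigs=3, n_images=4, seed=4)
        fit = fit_lmm(frame)  # all rows are stomach
        assert len(fit.beta) == 0
        assert fit.converged

    def test_non_nested_grouping_rejected(self):
        frame = nested_frame(n_pigs=3, n_images=2, seed=0)
        frame.loc[0, "image_id"] = frame["image_id"].iloc[-1]  # image spans 2 pigs
        with pytest.raises(ValueError, match="not nested"):
            fit_lmm(frame)

    def test_too_few_pigs_rejected(self):
        frame = nested_frame(n_pigs=1, n_images=4)
        with pytest.raises(ValueError, match="2 pigs"):
            fit_lmm(frame)

    def test_unbalanced_reps_fall_back_to_mixedlm(self):
        frame = nested_frame(n_pigs=4, n_images=3, seed=5)
        frame = frame.iloc[:-1]  # one image loses a repetition
        fit = fit_lmm(frame)
        assert fit.engine == "mixedlm"
        assert fit.converged


class TestDecompose:
    def test_single_source_limit(self):
        frame = nested_frame(
            n_pigs=4, n_images=6, s_pig=0.0, s_img=0.0, s_rep=1e-8,
            organ_effects={"stomach": 0.0, "liver": 5.0}, seed=6,
        )
        d = decompose(fit_lmm(frame))
        assert d.proportions["organ"] > 0.999

    def test_known_mixture_recovered(self):
        # organ term variance 3 (effects 0/2sqrt3 balanced), all sigma2 = 1
        eff = 2.0 * np.sqrt(3.0)
        frame = nested_frame(
            n_pigs=60, n_images=8, n_reps=3, s_pig=1.0, s_img=1.0, s_rep=1.0,
            organ_effects={"stomach": 0.0, "liver": eff}, seed=7,
        )
        d = decompose(fit_lmm(frame))
        expect = {"organ": 0.5, "angle": 0.0, "pig": 1 / 6, "image": 1 / 6, "repetition": 1 / 6}
        for f in FACTORS:
            assert d.proportions[f] == pytest.approx(expect[f], abs=0.05)

    def test_balanced_design_cross_covariance_vanishes(self, small_table):
        fit = fit_lmm(_frame_at_band(small_table, small_table.grid.band_columns[0]))
        d = decompose(fit)
        assert d.cross_term_share < 1e-10

    def test_proportions_sum_to_one_and_in_range(self, small_table):
        vd = decompose_table(small_table)
        p = vd.proportions.to_numpy()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((p >= 0) & (p <= 1))

    def test_scale_equivariance(self, small_table):
        band = small_table.grid.band_columns[10]
        frame = _frame_at_band(small_table, band)
        d1 = decompose(fit_lmm(frame))
        frame2 = frame.assign(y=frame["y"] * 250.0)
        d2 = decompose(fit_lmm(frame2))
        for f in FACTORS:
            assert d1.proportions[f] == pytest.approx(d2.proportions[f], abs=1e-6)

    def test_monotone_in_pig_variance(self, small_lib):
        design = make_standardized_design(8, organs=small_lib.organs, n_positions=2)
        medians = []
        for s_pig in (1e-7, 6e-7, 3e-6):
            comps = GenerativeComponents(s_pig, 2e-7, 1e-7)
            t = simulate_spectra(design, small_lib, comps, seed=21)
            sub = t.subset(t.df.index < len(t.df))
            vd = decompose_table(sub)
            medians.append(vd.medians()["pig"])
        assert medians[0] < medians[1] < medians[2]


class TestStratified:
    def test_known_pig_sd_recovered(self, small_lib):
        design = make_standardized_design(40, organs=small_lib.organs[:1], n_positions=4)
        comps = GenerativeComponents(0.04, 1e-4, 1e-4)
        t = simulate_spectra(design, small_lib, comps, seed=8)
        sd = decompose_stratified(t, small_lib.organs[0])
        med = sd.medians()
        assert med["pig"] == pytest.approx(0.2, rel=0.25)
        assert med["angle"] == pytest.approx(0.0, abs=1e-3)

    def test_single_noise_source(self, small_lib):
        design = make_standardized_design(6, organs=small_lib.organs[:1], n_positions=3)
        comps = GenerativeComponents(0.0, 0.0, 1e-4)
        t = simulate_spectra(design, small_lib, comps, seed=9)
        sd = decompose_stratified(t, small_lib.organs[0])
        med = sd.medians()
        assert med["repetition"] > 0
        assert med["pig"] < 0.2 * med["repetition"]
        assert med["image"] < 0.2 * med["repetition"]


class TestBootstrap:
    def test_smoke_bands_contain_point_estimate(self, small_table):
        band = small_table.grid.band_columns[0]
        fit = fit_lmm(_frame_at_band(small_table, band))
        point = decompose(fit).proportions
        ci = bootstrap_ci(fit, B=200, seed=0)
        for f in FACTORS:
            lo, hi = ci[f]
            assert lo <= hi
            # parametric resamples center near the point estimate
            assert lo - 0.1 <= point[f] <= hi + 0.1

    def test_determinism(self, small_table):
        band = small_table.grid.band_columns[0]
        fit = fit_lmm(_frame_at_band(small_table, band))
        a = bootstrap_ci(fit, B=30, seed=5)
        b = bootstrap_ci(fit, B=30, seed=5)
        assert a == b


class TestMedians:
    def test_constant_and_odd_count(self):
        from organspectra.lmm import VarianceDecomposition

        # constant factor -> its own value; odd-count median -> middle value
        props = pd.DataFrame(
            {"organ": [0.8, 0.8, 0.8], "angle": [0.0, 0.0, 0.0],
             "pig": [0.1, 0.03, 0.15], "image": [0.05, 0.12, 0.02],
             "repetition": [0.05, 0.05, 0.03]},
            index=pd.Index([500.0, 505.0, 510.0], name="wavelength_nm"),
        )
        vd = VarianceDecomposition(props)
        med = median_across_wavelengths(vd)
        assert med["organ"] == 0.8
        assert med["pig"] == 0.1

    def test_matches_sort_oracle(self, small_table):
        vd = decompose_table(small_table)
        med = vd.medians()
        for f in FACTORS:
            vals = np.sort(vd.proportions[f].to_numpy())
            n = len(vals)
            oracle = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert med[f] == pytest.approx(oracle, abs=1e-15)
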