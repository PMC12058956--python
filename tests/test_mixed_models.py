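"""Mixed-model battery: cross-checks against statsmodels' MixedLM (an
independent general-purpose REML implementation), Type III Wald behavior,
and post-hoc contrast properties."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from shoalnet import inference
from shoalnet._lmm import VarianceComponentsLMM
from shoalnet.synthetic_data import SimulationConfig, simulate_traits


@pytest.fixture(scope="module")
def design():
    cfg = SimulationConfig(seed=5)
    meta = simulate_traits(cfg)
    return meta[["fish_id", "population", "ecotype", "family", "group_id"]].copy()


def simulate_response(design, rng, ecotype_shift=0.0, pop_sd=0.5, fam_sd=0.3,
                      group_sd=0.3, resid_sd=1.0):
    pops = design["population"].unique()
    fams = design["family"].unique()
    grps = design["group_id"].unique()
    pop_dev = dict(zip(pops, rng.normal(0, pop_sd, len(pops))))
    fam_dev = dict(zip(fams, rng.normal(0, fam_sd, len(fams))))
    grp_dev = dict(zip(grps, rng.normal(0, group_sd, len(grps))))
    return (
        np.where(design["ecotype"] == "limnetic", 0.5, -0.5) * ecotype_shift
        + design["population"].map(pop_dev).to_numpy()
        + design["family"].map(fam_dev).to_numpy()
        + design["group_id"].map(grp_dev).to_numpy()
        + rng.normal(0, resid_sd, len(design))
    )


class TestEngineAgainstStatsmodels:
    def test_single_factor_reml_matches_mixedlm(self):
        rng = np.random.default_rng(0)
        n_id, n_rep = 50, 2
        ids = np.repeat(np.arange(n_id), n_rep)
        pop = np.repeat(np.arange(5), n_id // 5 * n_rep)
        y = (
            rng.normal(0, 0.9, n_id)[ids]
            + 0.4 * pop
            + rng.normal(0, 1.1, n_id * n_rep)
        )
        X = np.column_stack(
            [np.ones(len(y))] + [(pop == k).astype(float) for k in range(4)]
        )
        fit = VarianceComponentsLMM(X, {"id": ids}).fit(y)
        ref = sm.MixedLM(y, X, groups=ids).fit(reml=True)
        assert fit.sigma2["id"] == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-4, abs=1e-6
        )
        assert fit.sigma2["residual"] == pytest.approx(ref.scale, rel=1e-4)
        np.testing.assert_allclose(fit.beta, ref.fe_params, rtol=1e-6, atol=1e-8)

    def test_crossed_components_match_mixedlm_vc(self, design):
        rng = np.random.default_rng(1)
        d = design.copy()
        d["y"] = simulate_response(d, rng, ecotype_shift=0.8)
        res = inference.fit_ecotype_model(d, "y")
        df = d.assign(one=1)
        ref = sm.MixedLM.from_formula(
            "y ~ C(ecotype, Sum)",
            groups="one",
            vc_formula={
                "population": "0 + C(population)",
                "family": "0 + C(family)",
                "group_id": "0 + C(group_id)",
            },
            data=df,
        ).fit(reml=True, method="powell", maxiter=2000)
        for name in ("population", "family", "group_id"):
            assert res.variance_components[name] == pytest.approx(
                ref.vcomp[list(ref.model.exog_vc.names).index(name)],
                rel=5e-3,
                abs=1e-4,
            )
        assert res.variance_components["residual"] == pytest.approx(
            ref.scale, rel=5e-3
        )
        # same ecotype contrast magnitude (sum coding in both)
        assert abs(res.fixed_effects.iloc[1]) == pytest.approx(
            abs(ref.fe_params[1]), rel=1e-2
        )


class TestTypeIIIWald:
    def test_ecotype_df_is_one(self, design):
        rng = np.random.default_rng(2)
        d = design.copy()
        d["y"] = simulate_response(d, rng)
        res = inference.fit_ecotype_model(d, "y")
        _, df, _ = res.wald_for("ecotype")
        assert df == 1

    def test_population_df_is_seven_at_full_design(self, design):
        rng = np.random.default_rng(3)
        d = design.copy()
        d["y"] = simulate_response(d, rng)
        res = inference.fit_population_model(d, "y")
        _, df, _ = res.wald_for("population")
        assert df == 7

    def test_constant_response_degenerate(self, design):
        d = design.copy()
        d["y"] = 1.0
        res = inference.fit_ecotype_model(d, "y")
        assert res.degenerate
        chi2, _, p = res.wald_for("ecotype")
        assert chi2 == 0.0 and p == 1.0

    def test_large_ecotype_shift_detected(self, design):
        # 2-SD shift between ecotypes: essentially always significant
        rng = np.random.default_rng(4)
        hits = 0
        reps = 20
        for _ in range(reps):
            d = design.copy()
            d["y"] = simulate_response(
                d, rng, ecotype_shift=2.0, pop_sd=0.3, fam_sd=0.2, group_sd=0.2
            )
            res = inference.fit_ecotype_model(d, "y")
            hits += res.wald_for("ecotype")[2] < 0.05
        assert hits >= reps * 0.9

    def test_shifted_population_drives_significance(self, design):
        rng = np.random.default_rng(5)
        d = design.copy()
        d["y"] = simulate_response(d, rng, pop_sd=0.05)
        shifted = d["population"].unique()[0]
        d.loc[d["population"] == shifted, "y"] += 3.0
        res = inference.fit_population_model(d, "y")
        assert res.wald_for("population")[2] < 1e-4
        posthoc = inference.posthoc_pairwise(res, "population")
        involving = posthoc[
            (posthoc["level_1"] == shifted) | (posthoc["level_2"] == shifted)
        ]
        assert (involving["p_tukey"] < 0.05).mean() > 0.8
        letters = posthoc.attrs["letters"]
        others = [p for p in d["population"].unique() if p != shifted]
        assert all(
            set(letters[shifted]) & set(letters[o]) == set() for o in others[:3]
        )


class TestPosthoc:
    def test_contrast_count_28_for_8_populations(self, design):
        rng = np.random.default_rng(6)
        d = design.copy()
        d["y"] = simulate_response(d, rng)
        res = inference.fit_population_model(d, "y")
        posthoc = inference.posthoc_pairwise(res, "population")
        assert len(posthoc) == 28

    def test_tukey_never_below_unadjusted(self, design):
        rng = np.random.default_rng(7)
        d = design.copy()
        d["y"] = simulate_response(d, rng)
        res = inference.fit_population_model(d, "y")
        posthoc = inference.posthoc_pairwise(res, "population")
        assert (posthoc["p_tukey"] >= posthoc["p_unadjusted"] - 1e-12).all()

    def test_null_contrasts_rarely_significant(self, design):
        # no population differences at all: adjusted p-values should stay high
        rng = np.random.default_rng(8)
        sig = 0
        total = 0
        for _ in range(5):
            d = design.copy()
            d["y"] = rng.normal(0, 1, len(d))
            res = inference.fit_population_model(d, "y")
            posthoc = inference.posthoc_pairwise(res, "population")
            sig += (posthoc["p_tukey"] < 0.05).sum()
            total += len(posthoc)
        assert sig / total < 0.05
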