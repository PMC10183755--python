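"""Trimming, mixed-effects models, AIC selection, marginal effects, and
the CI-plus-p significance rule."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from callosim.cohort import (
    CohortConfig,
    generate_cohort,
    generate_truth_table,
    generate_voxel_measures,
)
from callosim.stats import (
    MixedModelResult,
    ModelSpec,
    fit_mixed_model,
    marginal_effects,
    select_model,
    significance_flag,
    trim_quantiles,
)


def _cohort_table(seed, n=30, voxels=20, measure="da", **cfg_kw):
    cfg = CohortConfig(**cfg_kw)
    prof = generate_cohort(n, seed, cfg)
    truth = generate_truth_table(prof, seed, cfg)
    vox = generate_voxel_measures(truth, voxels, seed, cfg)
    return vox[vox.measure == measure].merge(prof, on="subject")


class TestTrimQuantiles:
    def test_distinct_sequence_drops_extremes(self):
        out = trim_quantiles(np.arange(1.0, 101.0))
        assert len(out) == 98
        assert out.min() == 2.0 and out.max() == 99.0

    def test_constant_vector_unchanged(self):
        x = np.full(50, 3.3)
        np.testing.assert_array_equal(trim_quantiles(x), x)

    def test_small_sample_returned_untrimmed_with_warning(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning, match="untrimmed"):
            out = trim_quantiles(x)
        np.testing.assert_array_equal(out, x)

    def test_retains_contiguous_interior_range(self, rng):
        x = rng.normal(size=1000)
        out = trim_quantiles(x)
        ql, qh = np.quantile(x, [0.01, 0.99])
        assert np.all((out >= ql) & (out <= qh))
        # a pass removes at most ~1% from each tail
        assert len(x) - len(out) <= 2 * (int(0.01 * len(x)) + 1)
        assert set(out) <= set(x)


def _spec_interaction():
    return ModelSpec(dv="value",
                     fixed=("age", "PDSA", "sex*region", "sex:PDSA",
                            "sex:PDSA:region"),
                     random=("subject", "subject_region"))


class TestFitMixedModel:
    def test_recovers_injected_region_contrasts(self):
        table = _cohort_table(0, n=50, voxels=30)
        res = fit_mixed_model(table, _spec_interaction())
        assert res.converged
        b_sex = res.fe_params[res.term_index("sex:region[S]")]
        b_int = res.fe_params[res.term_index("sex:PDSA:region[S]")]
        assert b_sex > 0 and significance_flag(res, "sex:region[S]")
        assert b_int < 0 and significance_flag(res, "sex:PDSA:region[S]")

    def test_standardization_invariance_under_unit_rescaling(self):
        table = _cohort_table(1)
        spec = ModelSpec(dv="value", fixed=("age", "sex"), random=("subject",))
        res_a = fit_mixed_model(table, spec)
        table2 = table.copy()
        table2["age"] = table2["age"] * 1000.0   # years -> millennia
        res_b = fit_mixed_model(table2, spec)
        np.testing.assert_allclose(res_a.fe_params.to_numpy(),
                                   res_b.fe_params.to_numpy(), atol=1e-8)

    def test_duplicating_rows_keeps_estimates_shrinks_cis(self):
        table = _cohort_table(2, n=20, voxels=10)
        spec = ModelSpec(dv="value", fixed=("age", "sex"), random=("subject",))
        res_a = fit_mixed_model(table, spec)
        doubled = pd.concat([table, table], ignore_index=True)
        res_b = fit_mixed_model(doubled, spec)
        np.testing.assert_allclose(res_a.fe_params.to_numpy(),
                                   res_b.fe_params.to_numpy(), atol=1e-2)
        width_a = (res_a.conf_int["hi"] - res_a.conf_int["lo"]).to_numpy()
        width_b = (res_b.conf_int["hi"] - res_b.conf_int["lo"]).to_numpy()
        assert np.all(width_b < width_a)

    def test_single_subject_rejected(self):
        table = _cohort_table(3, n=5, voxels=10)
        table = table[table.subject == table.subject.iloc[0]]
        with pytest.raises(ValueError, match="subject"):
            fit_mixed_model(table, ModelSpec(dv="value", fixed=("age",),
                                             random=("subject",)))

    def test_agrees_with_lme4_oracle(self):
        """Independent cross-check: the same model fitted with lme4 in R
        must give the same fixed effects."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        table = _cohort_table(4, n=15, voxels=8)
        spec = ModelSpec(dv="value", fixed=("age", "sex"), random=("subject",))
        res = fit_mixed_model(table, spec)
        df = res.data[["dv", "age", "male", "subject"]]
        import tempfile, os
        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "d.csv")
            df.to_csv(csv, index=False)
            script = textwrap.dedent(f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- lmer(dv ~ age + male + (1|subject), data=d, REML=FALSE)
                cat(fixef(m), sep="\\n")
            """)
            out = subprocess.run(["Rscript", "-e", script],
                                 capture_output=True, text=True, check=True)
        r_fe = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(res.fe_params.to_numpy(), r_fe, atol=2e-4)


class TestSelectModel:
    def test_interaction_detected_when_present(self):
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            table = _cohort_table(seed, n=40, voxels=20)
            base = fit_mixed_model(table, ModelSpec(
                dv="value", fixed=("age", "sex", "region"),
                random=("subject", "subject_region")))
            inter = fit_mixed_model(table, _spec_interaction())
            wins += select_model([base, inter]) is inter
        assert wins >= 0.8 * n_seeds

    def test_simpler_model_wins_under_null(self):
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            table = _cohort_table(seed + 100, n=40, voxels=20,
                                  effect_scale=0.0)
            base = fit_mixed_model(table, ModelSpec(
                dv="value", fixed=("age", "sex", "region"),
                random=("subject", "subject_region")))
            inter = fit_mixed_model(table, _spec_interaction())
            wins += select_model([base, inter]) is base
        assert wins >= 0.7 * n_seeds

    def test_tie_breaks_toward_fewer_parameters(self):
        a = MixedModelResult(spec=None, fe_params=pd.Series(dtype=float),
                             conf_int=pd.DataFrame(), pvalues=pd.Series(dtype=float),
                             aic=100.0, llf=0.0, n_params=5, n_obs=10,
                             converged=True)
        b = MixedModelResult(spec=None, fe_params=pd.Series(dtype=float),
                             conf_int=pd.DataFrame(), pvalues=pd.Series(dtype=float),
                             aic=100.0, llf=0.0, n_params=3, n_obs=10,
                             converged=True)
        assert select_model([a, b]) is b

    def test_different_row_sets_rejected(self):
        a = MixedModelResult(spec=None, fe_params=pd.Series(dtype=float),
                             conf_int=pd.DataFrame(), pvalues=pd.Series(dtype=float),
                             aic=1.0, llf=0.0, n_params=2, n_obs=10,
                             converged=True)
        b = MixedModelResult(spec=None, fe_params=pd.Series(dtype=float),
                             conf_int=pd.DataFrame(), pvalues=pd.Series(dtype=float),
                             aic=2.0, llf=0.0, n_params=2, n_obs=12,
                             converged=True)
        with pytest.raises(ValueError, match="row sets"):
            select_model([a, b])


class TestMarginalEffects:
    def test_intercept_only_model_gives_flat_predictions(self):
        table = _cohort_table(5, effect_scale=0.0)
        spec = ModelSpec(dv="value", fixed=(), random=("subject",))
        res = fit_mixed_model(table, spec)
        grid = marginal_effects(res, {"PDSA": [-1.5, 0.0, 1.5]})
        assert grid["predicted"].nunique() == 1

    def test_injected_crossing_shrinks_sex_gap_with_puberty(self):
        table = _cohort_table(6, n=50, voxels=30)
        sub = table[table.region == "S"]
        spec = ModelSpec(dv="value", fixed=("age", "sex", "PDSA", "sex:PDSA"),
                         random=("subject",))
        res = fit_mixed_model(sub, spec)
        grid = marginal_effects(res, {"PDSA": [-1.5, 1.5], "sex": [0.0, 1.0]})
        piv = grid.pivot_table(index="PDSA", columns="male",
                               values="predicted")
        gap_early = piv.loc[-1.5, 1.0] - piv.loc[-1.5, 0.0]
        gap_late = piv.loc[1.5, 1.0] - piv.loc[1.5, 0.0]
        assert gap_early > gap_late

    def test_observed_predictions_match_fixed_design(self):
        table = _cohort_table(7)
        spec = ModelSpec(dv="value", fixed=("age", "sex"), random=("subject",))
        res = fit_mixed_model(table, spec)
        pred = marginal_effects(res)
        manual = (np.asarray(res.sm_result.model.exog)
                  @ res.fe_params.to_numpy())
        np.testing.assert_allclose(pred["predicted"].to_numpy(), manual,
                                   atol=1e-6)

    def test_unknown_grid_variable_rejected(self):
        table = _cohort_table(8)
        res = fit_mixed_model(table, ModelSpec(dv="value", fixed=("age",),
                                               random=("subject",)))
        with pytest.raises(ValueError, match="grid"):
            marginal_effects(res, {"banana": [0, 1]})


class TestSignificanceFlag:
    def _result(self, lo, hi, p, beta=0.5):
        return MixedModelResult(
            spec=None,
            fe_params=pd.Series({"male": beta}),
            conf_int=pd.DataFrame({"lo": [lo], "hi": [hi]}, index=["male"]),
            pvalues=pd.Series({"male": p}),
            aic=0.0, llf=0.0, n_params=1, n_obs=10, converged=True)

    def test_requires_both_ci_and_p(self):
        assert significance_flag(self._result(0.2, 0.8, 0.001), "sex")
        assert not significance_flag(self._result(-0.1, 1.1, 0.001), "sex")
        assert not significance_flag(self._result(0.2, 0.8, 0.01), "sex")

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            significance_flag(self._result(0.2, 0.8, 0.001), "region[S]")
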