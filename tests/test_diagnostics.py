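"""Diagnostics: residuals in degenerate limits, pcVPC correction, bootstrap."""

from dataclasses import replace

import numpy as np
import pytest

from rifpk import DesignSpec, load_preset, simulate_study
from rifpk.diagnostics import bootstrap, pc_vpc, residuals
from rifpk.saem import SAEMSettings

TINY = SAEMSettings(n_burnin=5, n_explore=50, n_smooth=30, n_chains=1,
                    ofv_mc_size=200, seed=2)


@pytest.fixture(scope="module")
def zero_var_study(base_model):
    """Zero variability and exactly noiseless uncensored observations."""
    from rifpk.dataio import EventTable
    from rifpk.structural import StructuralParams, predict_conc_fast
    model = replace(base_model, iiv_cv={}, iov_cv={}, corr_iov_tlag_tk0=0.0,
                    error_a=1e-10, error_b=0.0)
    study = simulate_study(model, DesignSpec(n_male=2, n_female=2),
                          np.random.default_rng(19))
    p = StructuralParams(**{k: model.theta[k] for k in
                            ("Tlag", "Tk0", "V", "Vmax", "Km")})
    df = study.table.df.copy()
    unc = (df["EVID"] == 0) & (df["CENS"] == 0)
    df.loc[unc, "DV"] = predict_conc_fast(
        p, 600.0, df.loc[unc, "TIME"].to_numpy()).conc
    study.table = EventTable(df, lloq=study.table.lloq)
    return study


class TestResiduals:
    def test_iwres_zero_for_noiseless_data(self, zero_var_study):
        res = residuals(zero_var_study.table, zero_var_study.model, None,
                        k_sim=100, rng=np.random.default_rng(1))
        unc = res[res["CENS"] == 0]
        assert np.abs(unc["IWRES"]).max() < 1e-4

    def test_censored_rows_flagged_as_imputed(self, small_study):
        res = residuals(small_study.table, small_study.model, None,
                        k_sim=200, rng=np.random.default_rng(2))
        assert (res.loc[res["CENS"] == 1, "imputed"]).all()
        assert not res.loc[res["CENS"] == 0, "imputed"].any()
        # imputed values live inside the censoring interval
        bql = res[res["CENS"] == 1]
        assert (bql["DV"] >= 0).all() and (bql["DV"] <= 0.1 + 1e-12).all()

    def test_low_k_sim_rejected(self, small_study):
        with pytest.raises(ValueError, match="k_sim"):
            residuals(small_study.table, small_study.model, None, k_sim=10)

    def test_npde_moments_sane_under_true_model(self, small_study):
        res = residuals(small_study.table, small_study.model, None,
                        k_sim=400, rng=np.random.default_rng(3))
        assert abs(res["NPDE"].mean()) < 0.25
        assert 0.7 < res["NPDE"].std() < 1.3


class TestPcVPC:
    def test_correction_is_identity_when_pred_constant(self, small_study):
        """Under a covariate-free model every subject shares PRED, so the
        prediction correction changes nothing within a bin."""
        base = load_preset("base")
        vpc = pc_vpc(small_study.table, base, None, n_rep=100,
                     rng=np.random.default_rng(4))
        obs = small_study.table.observations()
        t0 = vpc["bin_time"].iloc[3]
        sel = obs[np.isclose(obs["TIME"], t0)]["DV"].clip(lower=0.1)
        want = np.percentile(sel, [10, 50, 90])
        got = vpc[vpc["bin_time"] == t0].sort_values("percentile")["observed"]
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_percentile_ordering_within_bins(self, small_study):
        vpc = pc_vpc(small_study.table, small_study.model, None, n_rep=120,
                     rng=np.random.default_rng(5))
        for _, grp in vpc.groupby("bin_time"):
            g = grp.sort_values("percentile")
            assert g["observed"].is_monotonic_increasing
            assert (g["sim_lo"] <= g["sim_hi"]).all()

    def test_minimum_replicates_enforced(self, small_study):
        with pytest.raises(ValueError):
            pc_vpc(small_study.table, small_study.model, None, n_rep=10)


class TestBootstrap:
    def test_zero_variability_gives_identical_replicates(self, zero_var_study):
        reps, summ = bootstrap(zero_var_study.table, zero_var_study.model,
                               n_boot=3, settings=TINY,
                               rng=np.random.default_rng(6))
        assert len(reps) == 3
        for p in ("Tlag", "Tk0", "V", "Vmax", "Km"):
            vals = reps[p].to_numpy()
            assert np.allclose(vals, vals[0], rtol=2e-3), p
            # and the bootstrap CI collapses onto the point estimate
            row = summ[summ["parameter"] == p].iloc[0]
            assert row["ci_hi"] / row["ci_lo"] < 1.01

    def test_stratification_preserves_sex_counts(self, small_study):
        """Every replicate dataset keeps the original female/male split."""
        covs = small_study.table.covariates()
        import rifpk.diagnostics as diag
        captured = []
        orig = diag.fit_saem

        def spy(table, model, st, compute_ofv=True):
            sexes = [c.sex for c in table.covariates().values()]
            captured.append((sexes.count("female"), sexes.count("male")))
            return orig(table, model, st, compute_ofv=compute_ofv)

        diag.fit_saem = spy
        try:
            bootstrap(small_study.table, small_study.model, n_boot=2,
                      settings=TINY, rng=np.random.default_rng(7))
        finally:
            diag.fit_saem = orig
        want = ([c.sex for c in covs.values()].count("female"),
                [c.sex for c in covs.values()].count("male"))
        assert captured == [want, want]

    def test_too_few_replicates_rejected(self, small_study):
        with pytest.raises(ValueError):
            bootstrap(small_study.table, small_study.model, n_boot=1)
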