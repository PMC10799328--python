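"""Bayesian engine: conjugate checks, convergence, determinism, league tables."""

import numpy as np
import pytest

from hifnma import (
    ConvergenceError,
    DEFAULT_OUTCOMES,
    NMAModelSpec,
    PosteriorDraws,
    TrialContrast,
    ValidationError,
    build_network,
    fit_fe_nma,
    gls_fe_nma,
    league_entry,
    read_contrasts,
    rhat,
    summarize_posterior,
)
from conftest import make_nma_data

FAST = NMAModelSpec(n_chains=2, n_burnin=500, n_iter=10_000, master_seed=11)


def _single_edge(y=0.5, se=0.1, n_trials=1, ys=None, ses=None):
    ys = [y] * n_trials if ys is None else ys
    ses = [se] * n_trials if ses is None else ses
    contrasts = [
        TrialContrast(f"T{i}", "drug", "ESA", "hgb_cfb", yi, se=si)
        for i, (yi, si) in enumerate(zip(ys, ses))
    ]
    net = build_network(contrasts, reference="ESA")
    return net, make_nma_data(contrasts)


class TestModelSpec:
    @pytest.mark.parametrize(
        "kwargs", [dict(n_chains=1), dict(n_iter=10), dict(thin=0), dict(prior_sd=0)]
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            NMAModelSpec(**kwargs)

    def test_default_run_design(self):
        spec = NMAModelSpec()
        assert (spec.n_chains, spec.n_burnin, spec.n_iter, spec.thin) == (
            3, 10_000, 50_000, 1,
        )


class TestFit:
    def test_single_observation_conjugate_posterior(self):
        """With a vague prior, posterior of d is essentially Normal(y, se²)."""
        net, data = _single_edge(0.5, 0.1)
        draws = fit_fe_nma(net, data, FAST).pooled()[:, 0]
        n = draws.size
        mc_se_mean = 0.1 / np.sqrt(n)
        shrunk = 0.5 * 100**2 / (100**2 + 0.1**2)
        assert draws.mean() == pytest.approx(shrunk, abs=4 * mc_se_mean)
        # MC standard error of the median of normal draws: 1.2533 sigma/sqrt(n)
        assert np.median(draws) == pytest.approx(0.5, abs=3 * 1.2533 * mc_se_mean)
        assert draws.std() == pytest.approx(0.1, rel=0.05)

    def test_two_trials_inverse_variance_pooling(self):
        net, data = _single_edge(ys=[0.5, 0.3], ses=[0.1, 0.2])
        draws = fit_fe_nma(net, data, FAST).pooled()[:, 0]
        mc_se_median = 1.2533 * 0.0894427 / np.sqrt(draws.size)
        assert np.median(draws) == pytest.approx(0.46, abs=3 * mc_se_median)
        assert draws.std() == pytest.approx(0.0894427, rel=0.05)

    def test_draw_count_contract(self):
        spec = NMAModelSpec(n_chains=3, n_burnin=100, n_iter=3000, thin=3, master_seed=5)
        net, data = _single_edge()
        draws = fit_fe_nma(net, data, spec)
        assert draws.draws.shape == (3, 1000, 1)

    def test_refuses_disconnected_network(self):
        contrasts = [
            TrialContrast("T1", "A", "B", "hgb_cfb", 0.5, se=0.1),
            TrialContrast("T2", "C", "D", "hgb_cfb", 0.3, se=0.2),
        ]
        net = build_network(contrasts)
        from hifnma import DisconnectedNetworkError

        with pytest.raises(DisconnectedNetworkError):
            fit_fe_nma(net, make_nma_data(contrasts), FAST)

    def test_seed_determinism_bit_identical(self):
        net, data = _single_edge()
        a = fit_fe_nma(net, data, FAST)
        b = fit_fe_nma(net, data, FAST)
        assert np.array_equal(a.draws, b.draws)
        c = fit_fe_nma(net, data, NMAModelSpec(
            n_chains=2, n_burnin=500, n_iter=10_000, master_seed=12))
        assert not np.array_equal(a.draws, c.draws)

    def test_prior_irrelevance_on_fixture(self, nd_mace_path, analysis_sets):
        from hifnma import filter_analysis_set

        contrasts = filter_analysis_set(
            read_contrasts(nd_mace_path), analysis_sets["all"]
        )
        net = build_network(contrasts, reference="ESA")
        data = make_nma_data(contrasts)
        meds = []
        for prior_sd in (100.0, 200.0):
            spec = NMAModelSpec(
                prior_sd=prior_sd, n_chains=3, n_burnin=1000,
                n_iter=50_000, master_seed=3,
            )
            table = summarize_posterior(
                fit_fe_nma(net, data, spec), DEFAULT_OUTCOMES["mace"]
            )
            meds.append(np.log(
                league_entry(table, "roxadustat", "vadadustat")[0]
            ))
        assert abs(meds[0] - meds[1]) < 1e-3

    def test_reference_invariance(self, dialysis_hgb_path):
        contrasts = read_contrasts(dialysis_hgb_path)
        data = make_nma_data(contrasts)
        tables = []
        for ref in ("ESA", "vadadustat"):
            net = build_network(contrasts, reference=ref)
            spec = NMAModelSpec(n_chains=2, n_burnin=500, n_iter=50_000, master_seed=9)
            tables.append(summarize_posterior(
                fit_fe_nma(net, data, spec), DEFAULT_OUTCOMES["hgb_cfb"]
            ))
        for t, c in [("daprodustat", "roxadustat"), ("roxadustat", "vadadustat")]:
            m0 = league_entry(tables[0], t, c)[0]
            m1 = league_entry(tables[1], t, c)[0]
            assert m0 == pytest.approx(m1, abs=1e-3)


class TestRhat:
    def test_iid_chains_converge(self):
        rng = np.random.default_rng(0)
        draws = PosteriorDraws(
            parameters=("d",),
            draws=rng.standard_normal((3, 5000, 1)),
            reference="ESA",
            outcome_id="hgb_cfb",
        )
        assert rhat(draws)["d"] < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((2, 2000, 1))
        arr[1] += 10.0
        draws = PosteriorDraws(("d",), arr, "ESA", "hgb_cfb")
        assert rhat(draws)["d"] > 1.1

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(42)
        arr = rng.standard_normal((4, 1000, 1)) + rng.normal(0, 0.05, (4, 1, 1))
        draws = PosteriorDraws(("d",), arr, "ESA", "hgb_cfb")
        # arviz rank-normalises; plain split-Rhat agrees closely for
        # near-normal chains
        ours = rhat(draws)["d"]
        theirs = float(az.rhat(az.convert_to_dataset(arr[:, :, 0]))["x"])
        assert ours == pytest.approx(theirs, abs=0.005)

    def test_single_chain_rejected(self):
        draws = PosteriorDraws(("d",), np.zeros((1, 100, 1)), "ESA", "hgb_cfb")
        with pytest.raises(ValidationError):
            rhat(draws)

    def test_convergence_error_carries_diagnostics(self, monkeypatch):
        import hifnma.nma_engine as eng

        net, data = _single_edge()
        monkeypatch.setattr(eng, "RHAT_THRESHOLD", 0.5)
        with pytest.raises(ConvergenceError) as err:
            eng.fit_fe_nma(net, data, FAST)
        assert "drug" in err.value.rhats

    def test_full_run_design_converges_on_fixture(self, nd_sf36_path):
        contrasts = read_contrasts(nd_sf36_path)
        net = build_network(contrasts, reference="placebo")
        draws = fit_fe_nma(net, make_nma_data(contrasts), NMAModelSpec(master_seed=2))
        assert all(r <= 1.01 for r in rhat(draws).values())


@pytest.fixture(scope="module")
def mace_table(nd_mace_path, analysis_sets):
    from hifnma import filter_analysis_set

    contrasts = filter_analysis_set(
        read_contrasts(nd_mace_path), analysis_sets["all"]
    )
    net = build_network(contrasts, reference="ESA")
    spec = NMAModelSpec(n_chains=2, n_burnin=500, n_iter=20_000, master_seed=4)
    draws = fit_fe_nma(net, make_nma_data(contrasts), spec)
    return summarize_posterior(draws, DEFAULT_OUTCOMES["mace"])


class TestLeagueTable:

    def test_diagonal_exact_unity_on_hr_scale(self, mace_table):
        for node in ("ESA", "roxadustat", "vadadustat"):
            assert league_entry(mace_table, node, node) == (1.0, 1.0, 1.0)

    def test_exponentiated_antisymmetry(self, mace_table):
        fwd = league_entry(mace_table, "roxadustat", "vadadustat")
        rev = league_entry(mace_table, "vadadustat", "roxadustat")
        assert fwd[0] == pytest.approx(1.0 / rev[0], rel=1e-9)
        # interval bounds swap under inversion
        assert fwd[1] == pytest.approx(1.0 / rev[2], rel=1e-9)

    def test_identity_antisymmetry(self, dialysis_hgb_path):
        contrasts = read_contrasts(dialysis_hgb_path)
        net = build_network(contrasts, reference="ESA")
        spec = NMAModelSpec(n_chains=2, n_burnin=500, n_iter=10_000, master_seed=6)
        table = summarize_posterior(
            fit_fe_nma(net, make_nma_data(contrasts), spec),
            DEFAULT_OUTCOMES["hgb_cfb"],
        )
        fwd = league_entry(table, "daprodustat", "roxadustat")
        rev = league_entry(table, "roxadustat", "daprodustat")
        assert fwd[0] == pytest.approx(-rev[0], abs=1e-12)
        assert fwd[1] == pytest.approx(-rev[2], abs=1e-12)

    def test_hr_contrast_is_exp_of_median_difference(self, mace_table, nd_mace_path,
                                                     analysis_sets):
        from hifnma import filter_analysis_set

        contrasts = filter_analysis_set(
            read_contrasts(nd_mace_path), analysis_sets["all"]
        )
        net = build_network(contrasts, reference="ESA")
        spec = NMAModelSpec(n_chains=2, n_burnin=500, n_iter=20_000, master_seed=4)
        draws = fit_fe_nma(net, make_nma_data(contrasts), spec)
        diff = draws.node_draws("roxadustat") - draws.node_draws("vadadustat")
        expected = float(np.exp(np.median(diff)))
        assert league_entry(mace_table, "roxadustat", "vadadustat")[0] == expected
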