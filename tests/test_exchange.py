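"""Global exchange fitting: identifiable-case recovery, constraint
handling, Monte Carlo error machinery and model selection.

The heavy 20-replicate coverage study lives in the acceptance suite; here
the fits are kept small (single probes, reduced starts)."""

import numpy as np
import pytest

from methyldyn.exchange import (
    CestDataset,
    CestGlobalModel,
    ConstraintGraph,
    CpmgDataset,
    Fix,
    FitConfigurationError,
    ProbeExchangeModel,
    Share,
    concerted_constraints,
    consistency_cv,
    select_model,
)
from methyldyn.spin import (
    Experiment,
    ExchangeModel,
    ExperimentGeometry,
    Topology,
    simulate_cest,
    simulate_sq_cpmg,
)

OFFSETS = tuple(np.arange(-350.0, 475.0, 25.0))
NU = tuple([25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0, 400.0, 600.0, 1000.0])


def _cest_dataset(model, probe="p1", power=25.0, noise=0.0, seed=0, err=None):
    geom = ExperimentGeometry(Experiment.CEST, 600.0, 0.4,
                              offset_list=OFFSETS, spinlock_power=power)
    prof = simulate_cest(model, geom)
    rng = np.random.default_rng(seed)
    if noise:
        prof = prof + rng.normal(0.0, noise, prof.size)
    return CestDataset(probe, 600.0, power, 0.4, np.array(OFFSETS), prof,
                       np.full(len(OFFSETS), err if err is not None else
                               max(noise, 1e-4)))


def _cpmg_dataset(model, probe="p1", noise=0.0, seed=0):
    geom = ExperimentGeometry(Experiment.SQ_CPMG, 850.0, 0.04, NU)
    r2eff = simulate_sq_cpmg(model, geom)
    rng = np.random.default_rng(seed)
    if noise:
        r2eff = r2eff + rng.normal(0.0, noise, r2eff.size)
    return CpmgDataset(probe, Experiment.SQ_CPMG, 850.0, 0.04,
                       np.array(NU), r2eff,
                       np.full(len(NU), max(noise, 1e-3)))


SLOW = ExchangeModel(k_ab=3.12, k_ba=236.88, dw_C_ab=1.0, r2_base=20.0,
                     r1_base=2.0)


class TestCestGlobal:
    def test_noise_free_single_probe_recovery(self):
        ds = [_cest_dataset(SLOW, power=p) for p in (41.0, 25.0)]
        res = CestGlobalModel(ds).fit(n_starts=4, seed=0)
        assert res.kex_ab == pytest.approx(240.0, rel=1e-3)
        assert res.p_b == pytest.approx(0.013, rel=1e-3)
        assert res.value(CestGlobalModel._pname("dw", "p1")) == pytest.approx(
            1.0, rel=1e-3)

    def test_flat_profile_flagged_non_identifiable(self):
        flat = SLOW.replace(dw_C_ab=0.0)
        informative = [_cest_dataset(SLOW, probe="good", power=p, noise=0.005,
                                     seed=1) for p in (41.0, 25.0)]
        blind = [_cest_dataset(flat, probe="blind", power=p, noise=0.005,
                               seed=2) for p in (41.0, 25.0)]
        model = CestGlobalModel(informative + blind)
        assert model.flags.get("non_identifiable:blind")
        assert "non_identifiable:good" not in model.flags

    def test_dw_sign_determined_by_cest(self):
        neg = SLOW.replace(dw_C_ab=-0.8)
        ds = [_cest_dataset(neg, power=p) for p in (41.0, 25.0)]
        res = CestGlobalModel(ds).fit(n_starts=4, seed=0)
        assert res.value(CestGlobalModel._pname("dw", "p1")) == pytest.approx(
            -0.8, rel=1e-2)


class TestProbeGlobal:
    def test_bifurcated_recovery_with_fixed_slow_process(self):
        truth = ExchangeModel(
            topology=Topology.BIFURCATED_THREE_STATE,
            k_ab=3.12, k_ba=236.88, k_ac=3.0, k_ca=1497.0,
            dw_C_ab=1.0, dw_C_ac=3.0, r2_base=9.0, r1_base=2.0,
        )
        cp = [_cpmg_dataset(truth, noise=0.3, seed=3)]
        ce = [_cest_dataset(truth.replace(r2_base=20.0), power=p, noise=0.005,
                            seed=4 + i) for i, p in enumerate((41.0, 25.0))]
        cons = ConstraintGraph(fixes=(
            Fix("k_ab", 3.12, "truth"), Fix("k_ba", 236.88, "truth"),
            Fix("dw_ab__p1", 1.0, "truth"),
        ))
        pm = ProbeExchangeModel(cp, ce, constraints=cons)
        res = pm.fit(n_starts=4, seed=0)
        res = pm.monte_carlo(res, n=25, seed=1)
        assert abs(res.kex_ac - 1500.0) <= 3 * np.std(
            res.mc_values["kex_ac"], ddof=1)
        assert abs(res.p_c - 0.002) <= 3 * np.std(res.mc_values["p_c"], ddof=1)

    def test_geminal_pair_shares_rates_by_construction(self):
        truth = SLOW.replace(r2_base=9.0)
        cp = [_cpmg_dataset(truth, probe=p, noise=0.2, seed=i)
              for i, p in enumerate(("L10-CD1", "L10-CD2"))]
        pm = ProbeExchangeModel(cp, topology=Topology.TWO_STATE)
        res = pm.fit(n_starts=3, seed=0)
        # one shared rate pair, per-probe dw
        assert "k_ab" in res.params and "k_ba" in res.params
        assert pm._pname("dw_ab", "L10-CD1") in res.params
        assert pm._pname("dw_ab", "L10-CD2") in res.params

    def test_conflicting_fix_share_rejected_before_fitting(self):
        with pytest.raises(FitConfigurationError, match="fixed and shared"):
            ConstraintGraph(fixes=(Fix("k_ab", 3.0, "x"),),
                            shares=(Share("k_ab", ("a", "b")),))

    def test_fix_at_fitted_value_leaves_rest_unchanged(self):
        ds = [_cest_dataset(SLOW, power=p, noise=0.005, seed=7) for p in
              (41.0, 25.0)]
        m = CestGlobalModel(ds)
        res = m.fit(n_starts=4, seed=0)
        params = res.params.copy()
        params["k_ab"].vary = False
        import lmfit

        refit = lmfit.minimize(m._residuals, params, method="leastsq")
        for name in refit.params:
            assert refit.params[name].value == pytest.approx(
                res.params[name].value, rel=1e-4, abs=1e-8)


class TestMonteCarlo:
    def test_zero_noise_gives_zero_sigma(self):
        ds = [_cest_dataset(SLOW, power=25.0, err=1e-12)]
        m = CestGlobalModel(ds)
        res = m.fit(n_starts=3, seed=0)
        res = m.monte_carlo(res, n=8, seed=0)
        assert np.std(res.mc_values["k_ab"]) < 1e-6

    def test_fixed_seed_reproduces_error_bars_bitwise(self):
        ds = [_cest_dataset(SLOW, power=25.0, noise=0.01, seed=8)]
        m = CestGlobalModel(ds)
        res = m.fit(n_starts=3, seed=0)
        r1 = m.monte_carlo(res, n=10, seed=5)
        sig1 = {k: v.copy() for k, v in r1.mc_values.items()}
        r2 = m.monte_carlo(res, n=10, seed=5)
        for k in sig1:
            assert np.array_equal(sig1[k], r2.mc_values[k])


class TestModelSelection:
    def _fits(self, truth, noise=0.25, seed=9):
        """Two SQ CPMG datasets (different noise draws) so the sample size
        supports the AICc comparison."""
        cp = [_cpmg_dataset(truth, noise=noise, seed=seed),
              _cpmg_dataset(truth.replace(r2_base=truth.r2_base + 2.0),
                            noise=noise, seed=seed + 1)]
        cp[1].field_MHz = 600.0
        cp[1].r2eff = simulate_sq_cpmg(
            truth.replace(r2_base=truth.r2_base + 2.0),
            ExperimentGeometry(Experiment.SQ_CPMG, 600.0, 0.04, NU),
        ) + np.random.default_rng(seed + 1).normal(0, noise, len(NU))
        fits = {}
        for topo in (Topology.TWO_STATE, Topology.BIFURCATED_THREE_STATE):
            pm = ProbeExchangeModel(cp, topology=topo)
            fits[topo] = pm.fit(n_starts=4, seed=0)
        return fits

    def test_two_state_truth_selects_two_state(self):
        truth = ExchangeModel(k_ab=30.0, k_ba=1470.0, dw_C_ab=2.0, r2_base=9.0)
        fits = self._fits(truth)
        choice = select_model(fits[Topology.TWO_STATE],
                              fits[Topology.BIFURCATED_THREE_STATE])
        assert choice["chosen"] == "probe_2state"

    def test_bifurcated_truth_selects_bifurcated(self):
        truth = ExchangeModel(
            topology=Topology.BIFURCATED_THREE_STATE,
            k_ab=3.12, k_ba=236.88, k_ac=4.0, k_ca=1996.0,
            dw_C_ab=1.2, dw_C_ac=3.5, r2_base=9.0,
        )
        fits = self._fits(truth, noise=0.15)
        choice = select_model(fits[Topology.TWO_STATE],
                              fits[Topology.BIFURCATED_THREE_STATE])
        assert choice["chosen"] == "probe_bifurcated_3state"

    def test_mismatched_data_rejected(self):
        truth = ExchangeModel(k_ab=30.0, k_ba=1470.0, dw_C_ab=2.0, r2_base=9.0)
        f1 = ProbeExchangeModel([_cpmg_dataset(truth, noise=0.2, seed=1)],
                                topology=Topology.TWO_STATE).fit(3, 0)
        short = CpmgDataset("p1", Experiment.SQ_CPMG, 850.0, 0.04,
                            np.array(NU[:5]), np.full(5, 10.0), np.full(5, 0.2))
        f2 = ProbeExchangeModel([short],
                                topology=Topology.TWO_STATE).fit(3, 0)
        with pytest.raises(FitConfigurationError):
            select_model(f1, f2)

    def test_consistency_cv_small_for_shared_process(self):
        results = []
        for seed in range(3):
            ds = [_cest_dataset(SLOW, power=p, noise=0.005, seed=20 + seed)
                  for p in (41.0, 25.0)]
            results.append(CestGlobalModel(ds).fit(n_starts=3, seed=0))
        cv = consistency_cv(results)
        assert cv["k_ba"] < 0.15


class TestConstraintProvenance:
    def test_concerted_constraints_record_source(self):
        ds = [_cest_dataset(SLOW, power=25.0)]
        res = CestGlobalModel(ds).fit(n_starts=3, seed=0)
        cons = concerted_constraints(res, "p1")
        assert all(f.provenance == "cest_global_2state" for f in cons.fixes)
        assert cons.fixed_value("k_ab") == pytest.approx(res.value("k_ab"))
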