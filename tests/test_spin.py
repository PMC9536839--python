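"""Forward-simulator tests against independent oracles: closed forms
(Luz-Meiboom fast exchange, Carver-Richards), a brute-force scipy expm
propagation coded separately from the cached-eigendecomposition simulators,
and exact physical limits."""

import numpy as np
import pytest
from scipy.linalg import expm, null_space

from methyldyn.constants import ppm_to_rad_s
from methyldyn.spin import (
    DegenerateExchangeError,
    Experiment,
    ExchangeModel,
    ExperimentGeometry,
    Topology,
    simulate_cest,
    simulate_mq_cpmg,
    simulate_sq_cpmg,
    stationary_populations,
)


def carver_richards(kex, p_b, dw_ppm, r2, nu, field=850.0):
    """Two-state equal-R2 closed form for the CPMG decay rate
    (nu_cpmg = 1/(4 delta) convention, matching the simulator)."""
    p_a = 1.0 - p_b
    dw = ppm_to_rad_s(dw_ppm, field, "13C")
    psi = kex**2 - dw**2
    zeta = -2.0 * dw * kex * (p_a - p_b)
    root = np.sqrt(psi**2 + zeta**2)
    d_pos = 0.5 * (1.0 + (psi + 2 * dw**2) / root)
    d_neg = 0.5 * (-1.0 + (psi + 2 * dw**2) / root)
    eta_pos = np.sqrt(psi + root) / (2.0 * np.sqrt(2.0) * nu)
    eta_neg = np.sqrt(np.maximum(-psi + root, 0.0)) / (2.0 * np.sqrt(2.0) * nu)
    arg = d_pos * np.cosh(eta_pos) - d_neg * np.cos(eta_neg)
    return r2 + 0.5 * (kex - 2.0 * nu * np.arccosh(arg))


def brute_force_sq(model, geom):
    """Independent SQ CPMG oracle: per-step scipy expm propagation with the
    180 pulses implemented as complex conjugation."""
    pops = stationary_populations(model)
    n = model.n_states
    dws = [0.0, model.dw_C_ab, model.dw_C_ac][:n]
    omega = np.array([ppm_to_rad_s(d, geom.spectrometer_1H_freq, "13C") for d in dws])
    L = model.generator() - model.r2_base * np.eye(n) + 1j * np.diag(omega)
    out = []
    for nu in geom.nu_cpmg_list:
        delta = 1.0 / (4.0 * nu)
        U = expm(L * delta)
        m = pops.astype(complex)
        for _ in range(int(round(2 * geom.T_relax * nu))):
            m = np.conj(U @ m)
            m = U @ m
        out.append(-np.log(abs(m.sum())) / geom.T_relax)
    return np.array(out)


class TestStationaryPopulations:
    def test_two_state_detailed_balance(self):
        p = stationary_populations(ExchangeModel(k_ab=3.12, k_ba=236.88))
        assert p[1] == pytest.approx(0.013, abs=1e-12)
        assert p.sum() == pytest.approx(1.0)

    def test_symmetric_rates_split_evenly(self):
        p = stationary_populations(ExchangeModel(k_ab=50.0, k_ba=50.0))
        assert np.allclose(p, [0.5, 0.5])

    def test_bifurcated_matches_nullspace_oracle(self):
        m = ExchangeModel(
            topology=Topology.BIFURCATED_THREE_STATE,
            k_ab=10.0, k_ba=990.0, k_ac=5.0, k_ca=995.0,
        )
        p = stationary_populations(m)
        ns = null_space(m.generator()).ravel()
        ns = ns / ns.sum()
        assert np.allclose(p, ns, atol=1e-12)
        assert p[1] == pytest.approx(p[0] * 10.0 / 990.0)
        assert p[2] == pytest.approx(p[0] * 5.0 / 995.0)

    def test_generator_columns_sum_to_zero(self):
        m = ExchangeModel(
            topology=Topology.BIFURCATED_THREE_STATE,
            k_ab=3.0, k_ba=240.0, k_ac=4.0, k_ca=1500.0,
        )
        assert np.allclose(m.generator().sum(axis=0), 0.0, atol=1e-12)

    def test_all_rates_zero_is_degenerate(self):
        with pytest.raises(DegenerateExchangeError):
            stationary_populations(ExchangeModel(k_ab=0.0, k_ba=0.0))


class TestSqCpmg:
    def test_no_exchange_gives_flat_profile_at_r2(self, sq_geom):
        m = ExchangeModel(k_ab=0.0, k_ba=100.0, dw_C_ab=2.0, r2_base=12.0)
        r = simulate_sq_cpmg(m, sq_geom)
        assert np.allclose(r, 12.0, atol=1e-9)

    def test_fast_exchange_matches_luz_meiboom(self, sq_geom):
        kex, p_b, dw_ppm = 20000.0, 0.02, 0.5
        m = ExchangeModel(k_ab=p_b * kex, k_ba=(1 - p_b) * kex,
                          dw_C_ab=dw_ppm, r2_base=10.0)
        sim = simulate_sq_cpmg(m, sq_geom)
        nu = np.array(sq_geom.nu_cpmg_list)
        dw = ppm_to_rad_s(dw_ppm, 850.0, "13C")
        lm = 10.0 + (1 - p_b) * p_b * dw**2 / kex * (
            1.0 - 4 * nu / kex * np.tanh(kex / (4 * nu))
        )
        assert np.max(np.abs(sim - lm)) < 5e-3

    def test_approach_to_refocusing_limit(self, sq_geom, slow_model):
        """R2,eff decays toward r2_base as pulsing gets fast; the decay is
        strictly monotone in the fast-exchange regime (slow exchange shows
        genuine low-nu ripples)."""
        r = simulate_sq_cpmg(slow_model, sq_geom)
        assert r[0] > r[-1]
        assert r[-1] >= slow_model.r2_base - 1e-6
        assert r[-1] - slow_model.r2_base < 0.5 * (r[0] - slow_model.r2_base)
        m_fast = ExchangeModel(k_ab=100.0, k_ba=4900.0, dw_C_ab=1.0, r2_base=10.0)
        assert np.all(np.diff(simulate_sq_cpmg(m_fast, sq_geom)) < 1e-9)

    def test_matches_brute_force_expm_oracle(self, slow_model):
        geom = ExperimentGeometry(
            Experiment.SQ_CPMG, 850.0, 0.04, (25.0, 100.0, 400.0, 1000.0)
        )
        m = slow_model.replace(dw_C_ab=1.3)
        assert np.allclose(
            simulate_sq_cpmg(m, geom), brute_force_sq(m, geom), atol=1e-10
        )

    def test_matches_carver_richards_rate(self):
        """Two-period rate extraction (amplitude factor cancels) agrees with
        the Carver-Richards decay rate."""
        nu = np.arange(25.0, 1001.0, 25.0)
        g1 = ExperimentGeometry(Experiment.SQ_CPMG, 850.0, 0.2, tuple(nu))
        g2 = ExperimentGeometry(Experiment.SQ_CPMG, 850.0, 0.4, tuple(nu))
        for kex, p_b, dw in [(240.0, 0.013, 1.0), (2000.0, 0.05, 2.0)]:
            m = ExchangeModel(k_ab=p_b * kex, k_ba=(1 - p_b) * kex,
                              dw_C_ab=dw, r2_base=10.0)
            rate = (simulate_sq_cpmg(m, g2) * 0.4 - simulate_sq_cpmg(m, g1) * 0.2) / 0.2
            assert np.max(np.abs(rate - carver_richards(kex, p_b, dw, 10.0, nu))) < 0.01

    def test_signal_preserved_without_relaxation_or_shifts(self, sq_geom):
        m = ExchangeModel(k_ab=3.12, k_ba=236.88, dw_C_ab=0.0, r2_base=0.0)
        assert np.allclose(simulate_sq_cpmg(m, sq_geom), 0.0, atol=1e-9)


class TestMqCpmg:
    def test_reduces_to_sq_when_dwh_zero(self, sq_geom, mq_geom, slow_model):
        assert np.max(np.abs(
            simulate_mq_cpmg(slow_model, mq_geom)
            - simulate_sq_cpmg(slow_model, sq_geom)
        )) < 1e-6

    def test_no_exchange_gives_flat_profile(self, mq_geom):
        m = ExchangeModel(k_ab=0.0, k_ba=100.0, dw_C_ab=1.0, dw_H_ab=0.3,
                          r2_base=11.0)
        assert np.allclose(simulate_mq_cpmg(m, mq_geom), 11.0, atol=1e-9)

    def test_matches_brute_force_mq_oracle(self):
        """Independent oracle: step-by-step expm propagation with explicit
        sign bookkeeping for the 13C train and the mid-period 1H 180."""
        geom = ExperimentGeometry(
            Experiment.MQ_CPMG, 600.0, 0.04, (25.0, 150.0, 500.0)
        )
        m = ExchangeModel(k_ab=3.12, k_ba=236.88, dw_C_ab=1.0, dw_H_ab=0.1,
                          r2_base=10.0)
        pops = stationary_populations(m)
        wC = np.array([0.0, ppm_to_rad_s(m.dw_C_ab, 600.0, "13C")])
        wH = np.array([0.0, ppm_to_rad_s(m.dw_H_ab, 600.0, "1H")])
        K = m.generator() - m.r2_base * np.eye(2)
        expected = []
        for nu in geom.nu_cpmg_list:
            delta = 1.0 / (4.0 * nu)
            n_el = int(round(2 * geom.T_relax * nu))
            mvec = pops.astype(complex)
            sC = 1
            for sH in (1, -1):
                for _ in range(n_el // 2):
                    mvec = expm((K + 1j * np.diag(sH * wH + sC * wC)) * delta) @ mvec
                    sC = -sC
                    mvec = expm((K + 1j * np.diag(sH * wH + sC * wC)) * delta) @ mvec
            expected.append(-np.log(abs(mvec.sum())) / geom.T_relax)
        assert np.allclose(simulate_mq_cpmg(m, geom), expected, atol=1e-9)

    def test_dispersion_is_field_dependent(self):
        """The shift differences enter in rad/s, so the two fields give
        distinct dispersion profiles — the leverage the multi-field global
        fit relies on."""
        m = ExchangeModel(k_ab=3.12, k_ba=236.88, dw_C_ab=1.0, dw_H_ab=0.1,
                          r2_base=10.0)
        nu = tuple(np.arange(25.0, 1001.0, 25.0))
        amp = {}
        for field in (600.0, 850.0):
            g = ExperimentGeometry(Experiment.MQ_CPMG, field, 0.04, nu)
            r = simulate_mq_cpmg(m, g)
            amp[field] = r[0] - r[-1]
        assert abs(amp[850.0] - amp[600.0]) > 0.05 * max(amp.values())

    def test_odd_element_count_rejected(self):
        g = ExperimentGeometry(Experiment.MQ_CPMG, 850.0, 0.02, (25.0,))
        m = ExchangeModel(k_ab=3.0, k_ba=240.0, dw_C_ab=1.0)
        with pytest.raises(ValueError, match="even"):
            simulate_mq_cpmg(m, g)


class TestBifurcatedReduction:
    def test_simulators_reduce_to_two_state_when_c_rates_zero(
        self, sq_geom, mq_geom, cest_geom
    ):
        m2 = ExchangeModel(k_ab=3.12, k_ba=236.88, dw_C_ab=1.0, dw_H_ab=0.05,
                           r2_base=10.0, r1_base=2.0)
        m3 = ExchangeModel(
            topology=Topology.BIFURCATED_THREE_STATE,
            k_ab=3.12, k_ba=236.88, k_ac=0.0, k_ca=0.0,
            dw_C_ab=1.0, dw_C_ac=3.0, dw_H_ab=0.05, dw_H_ac=0.2,
            r2_base=10.0, r1_base=2.0,
        )
        assert np.allclose(simulate_sq_cpmg(m3, sq_geom),
                           simulate_sq_cpmg(m2, sq_geom), atol=1e-10)
        assert np.allclose(simulate_mq_cpmg(m3, mq_geom),
                           simulate_mq_cpmg(m2, mq_geom), atol=1e-10)
        assert np.allclose(simulate_cest(m3, cest_geom),
                           simulate_cest(m2, cest_geom), atol=1e-10)


class TestCest:
    @staticmethod
    def _minor_dip_asymmetry(prof, offsets, minor_hz):
        """Depth of the minor dip measured against the mirror image of the
        profile (a single symmetric dip at 0 gives ~0)."""
        window = np.abs(offsets - minor_hz) < 30.0
        mirror = np.interp(-offsets[window], offsets, prof)
        return float(np.max(mirror - prof[window]))

    def test_two_dips_at_state_positions_and_minor_deepens_with_pb(
        self, cest_geom
    ):
        offsets = np.array(cest_geom.offset_list)
        minor_hz = ppm_to_rad_s(1.0, 600.0, "13C") / (2 * np.pi)
        depths = []
        for k_ab in (3.12, 6.24):  # p_B and 2 p_B at fixed kex scale
            m = ExchangeModel(k_ab=k_ab, k_ba=240.0 - k_ab, dw_C_ab=1.0,
                              r2_base=20.0, r1_base=2.0)
            prof = simulate_cest(m, cest_geom)
            assert abs(offsets[np.argmin(prof)]) <= 10.0  # major dip at 0
            depths.append(self._minor_dip_asymmetry(prof, offsets, minor_hz))
        assert depths[1] > depths[0] > 0.02

    def test_no_exchange_single_dip(self, cest_geom):
        m = ExchangeModel(k_ab=0.0, k_ba=100.0, dw_C_ab=1.0, r2_base=20.0,
                          r1_base=2.0)
        prof = simulate_cest(m, cest_geom)
        offsets = np.array(cest_geom.offset_list)
        minor_hz = ppm_to_rad_s(1.0, 600.0, "13C") / (2 * np.pi)
        assert self._minor_dip_asymmetry(prof, offsets, minor_hz) < 0.005
        assert abs(offsets[np.argmin(prof)]) <= 10.0

    def test_intensities_bounded(self, cest_geom, slow_model):
        prof = simulate_cest(slow_model.replace(r2_base=20.0), cest_geom)
        assert prof.max() <= 1.0 + 1e-9
        assert prof.min() >= -0.01  # small coherent undershoot near resonance

    def test_plateau_tracks_r1_decay(self, cest_geom, slow_model):
        prof = simulate_cest(slow_model.replace(r2_base=20.0), cest_geom)
        plateau = prof[0]  # far off-resonance
        assert plateau == pytest.approx(np.exp(-2.0 * 0.4), abs=0.05)

    def test_invalid_spinlock_rejected(self):
        with pytest.raises(ValueError, match="spinlock"):
            ExperimentGeometry(Experiment.CEST, 600.0, 0.4,
                               offset_list=(0.0,), spinlock_power=0.0)


class TestGeometryValidation:
    def test_non_integer_element_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            ExperimentGeometry(Experiment.SQ_CPMG, 850.0, 0.04, (33.0,))

    def test_two_state_with_c_rates_rejected(self):
        with pytest.raises(ValueError):
            ExchangeModel(k_ab=1.0, k_ba=1.0, k_ac=5.0, k_ca=5.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ExchangeModel(k_ab=-1.0, k_ba=1.0)
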