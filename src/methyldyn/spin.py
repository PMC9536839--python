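"""Forward simulators for methyl CPMG and CEST observables under chemical
exchange, by numerical propagation of the Bloch-McConnell equations.

Two exchange topologies are supported: plain two-state exchange A<->B and the
bifurcated linear three-state topology B<->A<->C in which both excited states
exchange with the ground state A but not with each other.  Rates are the
four first-order rate constants (k_ab, k_ba, k_ac, k_ca); populations are
always derived from the rates, never fitted independently, because when only
one of the two processes is shared across probes it is the rates and not the
populations that are common.

Conventions
-----------
* The ground state A resonates at 0; excited-state offsets are the shift
  differences dw (ppm), converted to rad/s at the 13C (or 1H) Larmor
  frequency derived from the stated 1H field.
* CPMG: the constant-time element train is ``n = 2 * T_relax * nu_cpmg``
  repeats of (delta - 180 - delta) with ``delta = 1/(4 nu_cpmg)``, i.e.
  ``nu_cpmg = 1/(4 delta)``.  ``n`` must come out integer (and even for MQ,
  which places a single 1H 180 between two equal half-trains).
* A single intrinsic R2 is shared by all exchanging states per simulated
  experiment; CEST additionally uses a single intrinsic R1.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass

import numpy as np

from .constants import ppm_to_rad_s


class Topology(str, enum.Enum):
    TWO_STATE = "two_state"
    BIFURCATED_THREE_STATE = "bifurcated_three_state"


class Experiment(str, enum.Enum):
    SQ_CPMG = "sq_cpmg"
    MQ_CPMG = "mq_cpmg"
    CEST = "cest"


class DegenerateExchangeError(ValueError):
    """All exchange rates zero with more than one state declared."""


class PropagationError(RuntimeError):
    """Simulated signal became non-positive during propagation."""


@dataclass(frozen=True)
class ExchangeModel:
    """Exchange topology, rates (s^-1), shift differences (ppm) and intrinsic
    relaxation rates (s^-1) for one methyl probe.

    ``r2_base`` is the intrinsic transverse rate of the experiment being
    simulated; ``r1_base`` the intrinsic longitudinal rate (CEST only).
    """

    topology: Topology = Topology.TWO_STATE
    k_ab: float = 0.0
    k_ba: float = 0.0
    k_ac: float = 0.0
    k_ca: float = 0.0
    dw_C_ab: float = 0.0
    dw_C_ac: float = 0.0
    dw_H_ab: float = 0.0
    dw_H_ac: float = 0.0
    r2_base: float = 10.0
    r1_base: float = 1.5

    def __post_init__(self) -> None:
        for name in ("k_ab", "k_ba", "k_ac", "k_ca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.topology is Topology.TWO_STATE and (self.k_ac or self.k_ca):
            raise ValueError("two_state topology requires k_ac = k_ca = 0")

    @property
    def n_states(self) -> int:
        return 2 if self.topology is Topology.TWO_STATE else 3

    def replace(self, **kw) -> "ExchangeModel":
        return dataclasses.replace(self, **kw)

    def generator(self) -> np.ndarray:
        """Exchange generator K with dp/dt = K p; columns sum to zero."""
        n = self.n_states
        K = np.zeros((n, n))
        K[0, 0] -= self.k_ab
        K[1, 1] -= self.k_ba
        K[0, 1] += self.k_ba
        K[1, 0] += self.k_ab
        if n == 3:
            K[0, 0] -= self.k_ac
            K[2, 2] -= self.k_ca
            K[0, 2] += self.k_ca
            K[2, 0] += self.k_ac
        return K


@dataclass(frozen=True)
class ExperimentGeometry:
    """Acquisition geometry of one simulated experiment."""

    experiment: Experiment
    spectrometer_1H_freq: float  # MHz
    T_relax: float  # s; CPMG constant-time or CEST exchange period
    nu_cpmg_list: tuple[float, ...] = ()  # Hz, CPMG only
    offset_list: tuple[float, ...] = ()  # Hz (13C frame), CEST only
    spinlock_power: float = 0.0  # Hz, CEST only

    def __post_init__(self) -> None:
        if self.T_relax <= 0:
            raise ValueError("T_relax must be positive")
        if self.experiment in (Experiment.SQ_CPMG, Experiment.MQ_CPMG):
            if not self.nu_cpmg_list:
                raise ValueError("CPMG geometry requires nu_cpmg_list")
            for nu in self.nu_cpmg_list:
                n_el = 2.0 * self.T_relax * nu
                if abs(n_el - round(n_el)) > 1e-6 or round(n_el) < 1:
                    raise ValueError(
                        f"nu_cpmg={nu} Hz does not give an integer number of "
                        f"refocusing elements in T_relax={self.T_relax}"
                    )
        if self.experiment is Experiment.CEST:
            if self.spinlock_power <= 0:
                raise ValueError("spinlock_power must be > 0 for CEST")
            if not len(self.offset_list):
                raise ValueError("CEST geometry requires offset_list")


def stationary_populations(model: ExchangeModel) -> np.ndarray:
    """Stationary state populations implied by the exchange rates.

    Detailed balance on the star topology gives p_B = p_A k_ab / k_ba and
    p_C = p_A k_ac / k_ca; a state with both of its rates zero is decoupled
    and gets population zero.
    """
    rates = [(model.k_ab, model.k_ba)]
    if model.n_states == 3:
        rates.append((model.k_ac, model.k_ca))
    if all(kf == 0 and kr == 0 for kf, kr in rates) and model.n_states > 1:
        raise DegenerateExchangeError(
            "all exchange rates are zero; stationary populations undefined"
        )
    ratios = []
    for kf, kr in rates:
        if kf == 0 and kr == 0:
            ratios.append(0.0)
        elif kr == 0:
            raise DegenerateExchangeError(
                "forward rate nonzero with zero reverse rate traps all "
                "population in an excited state"
            )
        else:
            ratios.append(kf / kr)
    p_a = 1.0 / (1.0 + sum(ratios))
    pops = np.array([p_a] + [p_a * r for r in ratios])
    return pops


def _state_offsets_rad(model: ExchangeModel, field_mhz: float, nucleus: str) -> np.ndarray:
    if nucleus == "13C":
        dws = [0.0, model.dw_C_ab, model.dw_C_ac]
    else:
        dws = [0.0, model.dw_H_ab, model.dw_H_ac]
    dws = dws[: model.n_states]
    return np.array([ppm_to_rad_s(d, field_mhz, nucleus) for d in dws])


def _expm_eig(A: np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """exp(A t) for one (possibly complex) square matrix via
    eigendecomposition, vectorized over an array of times ``t``."""
    w, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    # (nt, n, n)
    return np.einsum("ij,tj,jk->tik", V, np.exp(np.outer(t, w)), Vinv)


def _cpmg_train_propagators(L_plus: np.ndarray, L_minus: np.ndarray,
                            nu_list: np.ndarray, T_relax: float):
    """Yield (n_elements, E_plus(delta), E_minus(delta)) per nu_cpmg.

    L_plus / L_minus are the evolution matrices with the refocused nucleus'
    offsets at +/- sign; the 180 pulses alternate between them.
    """
    deltas = 1.0 / (4.0 * nu_list)
    Ep = _expm_eig(L_plus, deltas)
    Em = _expm_eig(L_minus, deltas)
    for i, nu in enumerate(nu_list):
        n_el = int(round(2.0 * T_relax * nu))
        yield n_el, Ep[i], Em[i]


def _propagate_train(m0: np.ndarray, n_el: int, Ep: np.ndarray, Em: np.ndarray) -> np.ndarray:
    """Apply n_el elements of (delta - 180 - delta), starting with the
    refocused offsets at + sign.  Element k maps m -> E(-s) E(+s) m and flips
    the running sign s."""
    A1 = Em @ Ep  # element entered with sign +
    A2 = Ep @ Em  # element entered with sign -
    pair = A2 @ A1
    m = m0
    n_pairs, odd = divmod(n_el, 2)
    if n_pairs:
        m = np.linalg.matrix_power(pair, n_pairs) @ m
    if odd:
        m = A1 @ m
    return m


def _signal_to_r2eff(sig: np.ndarray, T_relax: float) -> np.ndarray:
    if np.any(sig <= 0):
        raise PropagationError("non-positive simulated CPMG signal")
    return -np.log(sig) / T_relax


def simulate_sq_cpmg(model: ExchangeModel, geom: ExperimentGeometry) -> np.ndarray:
    """R2,eff (s^-1) per nu_cpmg for the 13C single-quantum CPMG experiment.

    Magnetization starts on the observed coherence at the stationary
    populations; R2,eff = -(1/T) ln(S(T)/S(0)) with S the magnitude of the
    summed complex transverse magnetization.
    """
    if geom.experiment is not Experiment.SQ_CPMG:
        raise ValueError("geometry is not sq_cpmg")
    pops = stationary_populations(model)
    K = model.generator()
    omega = _state_offsets_rad(model, geom.spectrometer_1H_freq, "13C")
    n = model.n_states
    L = {s: K - model.r2_base * np.eye(n) + 1j * s * np.diag(omega) for s in (+1, -1)}
    nu = np.asarray(geom.nu_cpmg_list, dtype=float)
    out = np.empty(nu.size)
    for i, (n_el, Ep, Em) in enumerate(
        _cpmg_train_propagators(L[+1], L[-1], nu, geom.T_relax)
    ):
        m = _propagate_train(pops.astype(complex), n_el, Ep, Em)
        out[i] = abs(m.sum())
    return _signal_to_r2eff(out, geom.T_relax)


def simulate_mq_cpmg(model: ExchangeModel, geom: ExperimentGeometry) -> np.ndarray:
    """R2,eff (s^-1) per nu_cpmg for the 1H-13C multiple-quantum CPMG
    experiment.

    Zero- and double-quantum coherences evolve at dw_H -/+ dw_C; the 13C 180
    pulses of the train flip the sign of the 13C offsets and the single 1H
    180 between the two half-trains flips the sign of the 1H offsets,
    interconverting ZQ and DQ.  With dw_H = 0 the profile reduces to the SQ
    dispersion in the 13C shifts.
    """
    if geom.experiment is not Experiment.MQ_CPMG:
        raise ValueError("geometry is not mq_cpmg")
    pops = stationary_populations(model)
    K = model.generator()
    wC = _state_offsets_rad(model, geom.spectrometer_1H_freq, "13C")
    wH = _state_offsets_rad(model, geom.spectrometer_1H_freq, "1H")
    n = model.n_states
    R = model.r2_base * np.eye(n)

    def L(sH: int, sC: int) -> np.ndarray:
        return K - R + 1j * np.diag(sH * wH + sC * wC)

    nu = np.asarray(geom.nu_cpmg_list, dtype=float)
    deltas = 1.0 / (4.0 * nu)
    mats = {(sH, sC): _expm_eig(L(sH, sC), deltas) for sH in (1, -1) for sC in (1, -1)}
    out = np.empty(nu.size)
    for i, v in enumerate(nu):
        n_el = int(round(2.0 * geom.T_relax * v))
        if n_el % 2:
            raise ValueError(
                f"MQ CPMG needs an even element count; nu_cpmg={v} Hz gives {n_el}"
            )
        half = n_el // 2
        m = pops.astype(complex)
        sC = 1
        for sH in (1, -1):  # 1H 180 between the two half-trains
            for _ in range(half):
                m = mats[(sH, sC)][i] @ m
                sC = -sC
                m = mats[(sH, sC)][i] @ m
        out[i] = abs(m.sum())
    return _signal_to_r2eff(out, geom.T_relax)


def _cest_evolution_matrices(model: ExchangeModel, geom: ExperimentGeometry) -> np.ndarray:
    """Stacked (n_offsets, 3N, 3N) Bloch-McConnell matrices (x,y,z per state)."""
    n = model.n_states
    K = model.generator()
    omega = _state_offsets_rad(model, geom.spectrometer_1H_freq, "13C")
    w1 = 2.0 * np.pi * geom.spinlock_power
    offsets = 2.0 * np.pi * np.asarray(geom.offset_list, dtype=float)
    A = np.zeros((offsets.size, 3 * n, 3 * n))
    A += np.kron(K, np.eye(3))
    for i in range(n):
        b = 3 * i
        delta = omega[i] - offsets  # rad/s, per offset
        A[:, b + 0, b + 0] -= model.r2_base
        A[:, b + 1, b + 1] -= model.r2_base
        A[:, b + 2, b + 2] -= model.r1_base
        A[:, b + 0, b + 1] = A[:, b + 0, b + 1] - delta
        A[:, b + 1, b + 0] = A[:, b + 1, b + 0] + delta
        A[:, b + 1, b + 2] += w1
        A[:, b + 2, b + 1] -= w1
    return A


def simulate_cest(model: ExchangeModel, geom: ExperimentGeometry) -> np.ndarray:
    """Normalized CEST intensity I/I_ref per spin-lock offset.

    The full (Mx, My, Mz per state) Bloch-McConnell matrix, including the
    spin-lock field, state offsets, R1 and R2, is propagated for T_relax from
    +z magnetization at the stationary populations.  The reference is the
    plane without the exchange period, so I/I_ref = Mz_A(T)/p_A.
    """
    if geom.experiment is not Experiment.CEST:
        raise ValueError("geometry is not cest")
    pops = stationary_populations(model)
    n = model.n_states
    A = _cest_evolution_matrices(model, geom)
    M0 = np.zeros(3 * n)
    M0[2::3] = pops
    w, V = np.linalg.eig(A)
    c = np.linalg.solve(V, np.tile(M0.astype(complex), (A.shape[0], 1))[..., None])
    MT = (V @ (np.exp(w * geom.T_relax)[..., None] * c)).real[..., 0]
    return MT[:, 2] / pops[0]


def simulate_profile(model: ExchangeModel, geom: ExperimentGeometry) -> np.ndarray:
    """Dispatch to the simulator matching ``geom.experiment``."""
    if geom.experiment is Experiment.SQ_CPMG:
        return simulate_sq_cpmg(model, geom)
    if geom.experiment is Experiment.MQ_CPMG:
        return simulate_mq_cpmg(model, geom)
    return simulate_cest(model, geom)
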