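"""Synthetic-data generation for every stage of the pipeline.

The default scenario emulates the statistical structure of the study the
package is built around: a 72 kDa homodimeric enzyme whose apo form shows

* a slow concerted exchange process shared by 10 methyl probes
  (kex = 240 s^-1, minor-state population 1.3%), visible in CEST and CPMG;
* additional faster, localized processes on 8 of those probes with variable
  rates (~1000-2500 s^-1), small populations (0.11-0.24%) and 13C shift
  differences roughly 3x those of the slow process;
* five exchange datasets per probe: MQ CPMG at 850 and 600 MHz, 13C SQ CPMG
  at 850 MHz, and CEST at 41 and 25 Hz spin lock (600 MHz);
* per-point Gaussian noise calibrated the way the real data's errors were
  (duplicate-point RMSD for CPMG; 1.5x base-plane noise for CEST);
* 2H-relaxation order parameters per ligation state, 15N relaxation
  consistent with isotropic tumbling, RDCs from a known alignment tensor,
  and sPRE intensity ratios following A r^-6 with planted exposed probes.

Every generator takes explicit seeds; regeneration with the same seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import larmor_mhz
from .dynamics import r2d_from_s2
from .exchange import CestDataset, CpmgDataset
from .relax import PLANE_COLUMNS, PlaneIntensityTable
from .spin import (
    Experiment,
    ExchangeModel,
    ExperimentGeometry,
    Topology,
    simulate_cest,
    simulate_mq_cpmg,
    simulate_sq_cpmg,
)
from .tumbling import rigid_rotor_rates


@dataclass(frozen=True)
class ProbeTruth:
    """Ground-truth exchange parameters of one synthetic probe."""

    probe_id: str
    dw_C_ab: float  # ppm, concerted slow process
    k_ac: float = 0.0  # fast local process (0 = two-state probe)
    k_ca: float = 0.0
    dw_C_ac: float = 0.0
    dw_H_ac: float = 0.0
    r2_base: dict = field(default_factory=lambda: {
        "sq_cpmg_850": 9.0, "mq_cpmg_850": 12.0, "mq_cpmg_600": 10.0,
    })
    r2_cest: float = 20.0
    r1_cest: float = 2.0

    def model(self, k_ab: float, k_ba: float, r2: float, r1: float = 2.0) -> ExchangeModel:
        three = self.k_ac > 0 or self.k_ca > 0
        return ExchangeModel(
            topology=Topology.BIFURCATED_THREE_STATE if three else Topology.TWO_STATE,
            k_ab=k_ab, k_ba=k_ba,
            k_ac=self.k_ac if three else 0.0, k_ca=self.k_ca if three else 0.0,
            dw_C_ab=self.dw_C_ab, dw_C_ac=self.dw_C_ac if three else 0.0,
            dw_H_ac=self.dw_H_ac if three else 0.0,
            r2_base=r2, r1_base=r1,
        )


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete description of the synthetic study conditions."""

    seed: int = 0
    k_ab: float = 3.12  # shared slow process: kex = 240 s^-1, p_B = 1.3%
    k_ba: float = 236.88
    probes: tuple[ProbeTruth, ...] = ()
    # experiment design
    cpmg_T_relax: float = 0.04
    cpmg_nu: tuple[float, ...] = (
        25., 50., 75., 100., 125., 150., 200., 250., 300., 400., 500.,
        600., 800., 1000.,
    )
    cpmg_duplicate_nu: tuple[float, ...] = (25., 150.)
    cest_T_ex: float = 0.4
    cest_powers: tuple[float, ...] = (41.0, 25.0)
    cest_field: float = 600.0
    cest_offsets_hz: tuple[float, ...] = tuple(np.arange(-350.0, 475.0, 25.0))
    # noise: fractional on CPMG intensities (duplicate-RMSD calibrated),
    # absolute on normalized CEST intensities (1.5x base-plane analogue)
    noise_cpmg: float = 0.01
    noise_cest: float = 0.008
    #: whether the fast local processes contribute to the CEST profiles.
    #: Off by default: the ms-timescale CEST experiment emulated here senses
    #: only the slow concerted process (see docs/methods.md); enable to
    #: study contamination of the CEST stage by the faster processes.
    cest_includes_fast: bool = False

    @property
    def kex(self) -> float:
        return self.k_ab + self.k_ba

    @property
    def p_b(self) -> float:
        return self.k_ab / self.kex

    def probe(self, probe_id: str) -> ProbeTruth:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def truth_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "k_ab": self.k_ab, "k_ba": self.k_ba,
            "kex": self.kex, "p_b": self.p_b,
            "probes": [
                {
                    "probe_id": p.probe_id, "dw_C_ab": p.dw_C_ab,
                    "k_ac": p.k_ac, "k_ca": p.k_ca,
                    "kex_fast": p.k_ac + p.k_ca,
                    "p_c": p.k_ac / (p.k_ac + p.k_ca) if p.k_ac + p.k_ca else 0.0,
                    "dw_C_ac": p.dw_C_ac, "dw_H_ac": p.dw_H_ac,
                }
                for p in self.probes
            ],
        }


#: probes of the concerted process in the system emulated here; 8 of the 10
#: additionally undergo a faster localized process
_DEFAULT_PROBES = (
    # probe_id, dw_ab, kex_fast, p_c, dw_ac
    ("L74-CD1", 0.55, 1200.0, 0.0016, 1.7),
    ("V79-CG1", 0.40, 1200.0, 0.0015, 1.3),
    ("L101-CD1", 0.80, 1800.0, 0.0011, 2.4),
    ("L121-CD1", 1.20, 2200.0, 0.0020, 3.4),
    ("L131-CD1", 0.65, 0.0, 0.0, 0.0),
    ("L187-CD1", 0.90, 1600.0, 0.0024, 2.8),
    ("L192-CD1", 1.40, 2500.0, 0.0018, 4.0),
    ("L198-CD1", 1.00, 1500.0, 0.0020, 3.0),
    ("L221-CD1", 0.30, 0.0, 0.0, 0.0),
    ("I237-CD1", 0.75, 1000.0, 0.0022, 2.2),
)


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """The canonical 10-probe concerted-process scenario."""
    probes = tuple(
        ProbeTruth(
            probe_id=pid,
            dw_C_ab=dw_ab,
            k_ac=kex_f * p_c,
            k_ca=kex_f * (1.0 - p_c),
            dw_C_ac=dw_ac,
        )
        for pid, dw_ab, kex_f, p_c, dw_ac in _DEFAULT_PROBES
    )
    return SyntheticScenario(seed=seed, probes=probes)


_CPMG_DESIGN = {
    "sq_cpmg_850": (Experiment.SQ_CPMG, 850.0),
    "mq_cpmg_850": (Experiment.MQ_CPMG, 850.0),
    "mq_cpmg_600": (Experiment.MQ_CPMG, 600.0),
}


def _plane_rows(probe, experiment, field_mhz, keys, trelax, inten, err,
                is_ref, is_dup):
    return pd.DataFrame({
        "probe_id": probe, "experiment": experiment, "field_MHz": field_mhz,
        "plane_key": keys, "Trelax_s": trelax, "intensity": inten,
        "intensity_error": err, "is_ref": is_ref, "is_duplicate": is_dup,
    })[PLANE_COLUMNS]


def generate_cpmg_tables(
    scenario: SyntheticScenario, seed: int | None = None
) -> dict[str, PlaneIntensityTable]:
    """Plane-intensity tables for the three CPMG datasets (SQ 850, MQ 850,
    MQ 600): intensities I_ref exp(-R2,eff T) plus Gaussian noise, with
    duplicate planes emitted for the error calibration."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    tables = {}
    for tag, (experiment, field_mhz) in _CPMG_DESIGN.items():
        geom = ExperimentGeometry(
            experiment, field_mhz, scenario.cpmg_T_relax,
            tuple(scenario.cpmg_nu),
        )
        frames = []
        for p in scenario.probes:
            model = p.model(scenario.k_ab, scenario.k_ba, p.r2_base[tag])
            sim = simulate_sq_cpmg(model, geom) if experiment is Experiment.SQ_CPMG \
                else simulate_mq_cpmg(model, geom)
            nu = np.array(scenario.cpmg_nu)
            ideal = np.exp(-sim * scenario.cpmg_T_relax)
            keys = list(nu)
            vals = list(ideal)
            dups = [False] * len(nu)
            for dnu in scenario.cpmg_duplicate_nu:
                keys.append(dnu)
                vals.append(float(ideal[nu == dnu][0]))
                dups.append(True)
            vals = np.array(vals) + rng.normal(0.0, scenario.noise_cpmg, len(vals))
            ref_int = 1.0 + rng.normal(0.0, scenario.noise_cpmg)
            frames.append(_plane_rows(
                p.probe_id, experiment.value, field_mhz,
                keys + [0.0], [scenario.cpmg_T_relax] * len(keys) + [0.0],
                list(vals) + [ref_int],
                scenario.noise_cpmg, [False] * len(keys) + [True],
                dups + [False],
            ))
        tables[tag] = PlaneIntensityTable(
            pd.concat(frames, ignore_index=True),
            meta={"tag": tag, "T_relax": scenario.cpmg_T_relax,
                  "field_MHz": field_mhz, "experiment": experiment.value},
        )
    return tables


def generate_cest_tables(
    scenario: SyntheticScenario, seed: int | None = None
) -> dict[str, PlaneIntensityTable]:
    """Plane-intensity tables for the CEST datasets (one per spin-lock
    power); the reference plane is the no-exchange-period plane."""
    rng = np.random.default_rng(
        (scenario.seed if seed is None else seed) + 1_000_003
    )
    tables = {}
    for power in scenario.cest_powers:
        tag = f"cest_{power:g}"
        geom = ExperimentGeometry(
            Experiment.CEST, scenario.cest_field, scenario.cest_T_ex,
            offset_list=tuple(scenario.cest_offsets_hz), spinlock_power=power,
        )
        frames = []
        for p in scenario.probes:
            if scenario.cest_includes_fast:
                model = p.model(scenario.k_ab, scenario.k_ba, p.r2_cest, p.r1_cest)
            else:
                model = ExchangeModel(
                    topology=Topology.TWO_STATE,
                    k_ab=scenario.k_ab, k_ba=scenario.k_ba,
                    dw_C_ab=p.dw_C_ab, r2_base=p.r2_cest, r1_base=p.r1_cest,
                )
            prof = simulate_cest(model, geom)
            vals = prof + rng.normal(0.0, scenario.noise_cest, prof.size)
            offs = list(scenario.cest_offsets_hz)
            frames.append(_plane_rows(
                p.probe_id, "cest", scenario.cest_field,
                offs + [np.nan], [scenario.cest_T_ex] * len(offs) + [0.0],
                list(vals) + [1.0],
                scenario.noise_cest, [False] * len(offs) + [True],
                False,
            ))
        tables[tag] = PlaneIntensityTable(
            pd.concat(frames, ignore_index=True),
            meta={"tag": tag, "T_ex": scenario.cest_T_ex,
                  "field_MHz": scenario.cest_field, "spinlock_hz": power,
                  "experiment": "cest"},
        )
    return tables


def cpmg_datasets_from_table(
    table: PlaneIntensityTable, r2eff_df: pd.DataFrame | None = None
) -> list[CpmgDataset]:
    """Convert one CPMG plane table into fitter datasets via the standard
    intensity -> R2,eff conversion (duplicates averaged)."""
    from .relax import average_duplicates, r2eff_from_intensities

    if r2eff_df is None:
        r2eff_df = r2eff_from_intensities(table)
    prof = average_duplicates(r2eff_df.rename(columns={"r2eff_err": "err"}))
    out = []
    for probe, sub in prof.groupby("probe_id", sort=False):
        sub = sub.sort_values("plane_key")
        out.append(CpmgDataset(
            probe_id=probe,
            experiment=Experiment(table.meta["experiment"]),
            field_MHz=table.meta["field_MHz"],
            T_relax=table.meta["T_relax"],
            nu_cpmg=sub.plane_key.to_numpy(),
            r2eff=sub.r2eff.to_numpy(),
            r2eff_err=sub.err.to_numpy(),
        ))
    return out


def cest_datasets_from_table(table: PlaneIntensityTable) -> list[CestDataset]:
    """Convert one CEST plane table into fitter datasets (intensities
    normalized to the reference plane)."""
    out = []
    for probe in table.probes:
        sub = table.probe(probe)
        ref = sub[sub.is_ref.astype(bool)].iloc[0]
        planes = sub[~sub.is_ref.astype(bool)]
        out.append(CestDataset(
            probe_id=probe,
            field_MHz=table.meta["field_MHz"],
            spinlock_hz=table.meta["spinlock_hz"],
            T_ex=table.meta["T_ex"],
            offsets_hz=planes.plane_key.to_numpy(dtype=float),
            intensity=planes.intensity.to_numpy(dtype=float) / ref.intensity,
            intensity_err=planes.intensity_error.to_numpy(dtype=float)
            / ref.intensity,
        ))
    return out


# ---------------------------------------------------------------------------
# ps-ns dynamics / tumbling / RDC / sPRE generators


def make_s2_states(
    n_probes: int = 47,
    shifts: dict[str, float] | None = None,
    seed: int = 0,
    s2_err: float = 0.02,
) -> dict[str, pd.DataFrame]:
    """Ground-truth S2 tables per ligation state.

    ``shifts`` maps state name -> mean S2 offset from the apo baseline
    (default: the dUMP-bound state rigidified by +0.027).  Probe-level
    scatter around each mean shift is included; errors are uniform.
    """
    rng = np.random.default_rng(seed)
    shifts = shifts if shifts is not None else {"dUMP": 0.027}
    probes = [f"P{i:03d}" for i in range(n_probes)]
    base = rng.uniform(0.35, 0.85, n_probes)
    out = {}
    apo = pd.DataFrame({
        "probe_id": probes, "state": "apo", "S2_axis": base, "S2_err": s2_err,
    })
    out["apo"] = apo
    for state, shift in shifts.items():
        delta = rng.normal(0.0, 0.04, n_probes)
        delta += shift - delta.mean()  # exact planted mean shift
        out[state] = pd.DataFrame({
            "probe_id": probes, "state": state,
            "S2_axis": base + delta, "S2_err": s2_err,
        })
    return out


def generate_2h_decay_table(
    s2_table: pd.DataFrame,
    tau_c_ns: float,
    delays: tuple[float, ...] = (0.0, 0.0006, 0.0013, 0.0022, 0.0033, 0.005),
    noise_frac: float = 0.01,
    seed: int = 0,
) -> PlaneIntensityTable:
    """2H transverse decay planes from an S2 truth table at tau_c (ns)."""
    rng = np.random.default_rng(seed)
    frames = []
    state = s2_table.state.iloc[0] if "state" in s2_table.columns else "apo"
    for _, row in s2_table.iterrows():
        r2 = r2d_from_s2(row.S2_axis, tau_c_ns)
        t = np.array(delays)
        ideal = np.exp(-r2 * t)
        vals = ideal + rng.normal(0.0, noise_frac, t.size)
        frames.append(_plane_rows(
            row.probe_id, "decay_2H", 600.0, list(t), list(t), list(vals),
            noise_frac, [d == 0.0 for d in delays], False,
        ))
    return PlaneIntensityTable(
        pd.concat(frames, ignore_index=True),
        meta={"tag": f"decay2H_{state}", "state": state, "tau_c_ns": tau_c_ns},
    )


def generate_n15_rate_table(
    tau_c_ns: float,
    field_mhz: float = 600.0,
    n_residues: int = 100,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-residue 15N R1/R2/NOE table from the rigid isotropic rotor at
    tau_c, with fractional Gaussian noise; NOE is set to a rigid-limit
    plateau value."""
    rng = np.random.default_rng(seed)
    r1, r2 = rigid_rotor_rates(tau_c_ns, field_mhz)
    res = np.arange(30, 30 + n_residues)
    r1v = r1 * (1.0 + rng.normal(0.0, noise_frac, n_residues))
    r2v = r2 * (1.0 + rng.normal(0.0, noise_frac, n_residues))
    return pd.DataFrame({
        "residue_id": res,
        "R1": r1v, "R1_err": r1 * noise_frac,
        "R2": r2v, "R2_err": r2 * noise_frac,
        "NOE": 0.82 + rng.normal(0.0, 0.01, n_residues),
        "NOE_err": 0.02,
    })


def random_unit_vectors(n: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return pd.DataFrame({
        "residue_id": np.arange(1, n + 1),
        "ux": v[:, 0], "uy": v[:, 1], "uz": v[:, 2],
    })


def generate_rdc_tables(
    saupe: np.ndarray,
    vectors: pd.DataFrame,
    j_iso: float = 93.0,
    noise_hz: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(isotropic, aligned) coupling tables from an alignment-tensor truth;
    aligned couplings are J + u^T S u + noise."""
    rng = np.random.default_rng(seed)
    u = vectors[["ux", "uy", "uz"]].to_numpy(dtype=float)
    d = np.einsum("ni,ij,nj->n", u, saupe, u)
    iso = pd.DataFrame({
        "residue_id": vectors.residue_id,
        "J_Hz": j_iso + rng.normal(0.0, noise_hz, len(vectors)),
        "J_err": max(noise_hz, 1e-6),
    })
    aligned = pd.DataFrame({
        "residue_id": vectors.residue_id,
        "J_Hz": iso.J_Hz + d + rng.normal(0.0, noise_hz, len(vectors)),
        "J_err": max(noise_hz, 1e-6),
    })
    return iso, aligned


def generate_spre_table(
    n_probes: int = 40,
    amplitude: float = 700.0,
    depth_range: tuple[float, float] = (3.0, 12.0),
    elevated: dict[str, float] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Intensity-pair table whose 1-ratio follows amplitude * depth^-6, with
    ``elevated`` probes boosted additively above the curve (the planted
    exposed set)."""
    rng = np.random.default_rng(seed)
    probes = [f"M{i:03d}" for i in range(n_probes)]
    depths = np.linspace(*depth_range, n_probes)
    one_minus = amplitude * depths**-6.0
    elevated = elevated or {}
    for pid, boost in elevated.items():
        one_minus[probes.index(pid)] += boost
    one_minus = np.clip(one_minus + rng.normal(0.0, noise, n_probes), None, 0.98)
    i0 = np.full(n_probes, 1.0)
    return pd.DataFrame({
        "probe_id": probes,
        "intensity_0mM": i0,
        "intensity_2mM": i0 * (1.0 - one_minus),
        "intensity_0mM_err": noise if noise else 1e-6,
        "intensity_2mM_err": noise if noise else 1e-6,
        "depth_A": depths,
    })
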