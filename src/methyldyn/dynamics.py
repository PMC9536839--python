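"""Methyl-axis order parameters from 2H transverse relaxation, the
conformational-entropy meter, the thermodynamic-cycle decomposition, and
methyl chemical-shift perturbations.

The 2H transverse rate of a CHD2 methyl in a slowly tumbling protein is
dominated by the quadrupolar interaction modulated by overall tumbling and
methyl-axis order:

    R2(2H) = (1/80) (2 pi qcc)^2 S2_axis tau_c

with qcc = 167 kHz, so S2_axis = 80 R2 / ((2 pi qcc)^2 tau_c).  tau_c must
be the value in the sample's solvent (D2O-corrected where appropriate).

The entropy meter converts a mean order-parameter change into a
conformational entropy change,

    -T dS_conf = -T * s_d * <dS2_axis> * N_chi,

with slope s_d = -0.0011 kcal/(mol K) per dihedral and N_chi the number of
side-chain dihedrals (1136 for residues 26-307 of the construct studied
here).  Only probes whose dS2 error is below 0.07 enter the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ENTROPY_METER_SLOPE, QCC_2H, T_KELVIN

S2_COLUMNS = ["probe_id", "state", "S2_axis", "S2_err"]

#: side-chain chi dihedral count per residue type (standard rotatable
#: chi angles; convention-dependent — see docs/methods.md)
CHI_PER_RESIDUE = {
    "A": 0, "G": 0, "P": 0,
    "S": 1, "C": 1, "T": 1, "V": 1,
    "D": 2, "N": 2, "F": 2, "H": 2, "I": 2, "L": 2, "W": 2, "Y": 2,
    "E": 3, "Q": 3, "M": 3,
    "K": 4, "R": 4,
}


def s2_from_r2d(r2_2h, tau_c_ns: float, qcc_hz: float = QCC_2H):
    """Methyl symmetry-axis order parameter from the 2H transverse rate.

    Inverts R2(2H) = (1/80)(2 pi qcc)^2 S2 tau_c.  ``r2_2h`` in s^-1 (scalar
    or array), ``tau_c_ns`` in ns.  Values above 1 are returned as-is
    (callers flag them); negative rates are rejected.
    """
    r2 = np.asarray(r2_2h, dtype=float)
    if np.any(r2 < 0):
        raise ValueError("R2(2H) must be >= 0")
    if tau_c_ns <= 0:
        raise ValueError("tau_c must be positive")
    s2 = 80.0 * r2 / ((2 * np.pi * qcc_hz) ** 2 * tau_c_ns * 1e-9)
    return float(s2) if np.isscalar(r2_2h) else s2


def r2d_from_s2(s2_axis, tau_c_ns: float, qcc_hz: float = QCC_2H):
    """Forward relation: 2H transverse rate from S2_axis and tau_c (ns)."""
    s2 = np.asarray(s2_axis, dtype=float)
    r2 = (2 * np.pi * qcc_hz) ** 2 * s2 * tau_c_ns * 1e-9 / 80.0
    return float(r2) if np.isscalar(s2_axis) else r2


def order_parameter_table(
    probe_ids, r2_2h, r2_err, tau_c_ns: float, state: str, qcc_hz: float = QCC_2H
) -> pd.DataFrame:
    """Per-probe S2_axis table for one ligation state; errors propagate
    linearly from the R2 errors.  Unphysical S2 > 1 are retained but flagged
    in the ``unphysical`` column."""
    s2 = s2_from_r2d(np.asarray(r2_2h, dtype=float), tau_c_ns, qcc_hz)
    err = s2_from_r2d(np.asarray(r2_err, dtype=float), tau_c_ns, qcc_hz)
    df = pd.DataFrame(
        {
            "probe_id": list(probe_ids),
            "state": state,
            "S2_axis": s2,
            "S2_err": err,
            "R2_2H": np.asarray(r2_2h, dtype=float),
            "tau_c_ns": tau_c_ns,
        }
    )
    df["unphysical"] = df.S2_axis > 1.0
    dup = df.probe_id.duplicated()
    if dup.any():
        raise ValueError(f"duplicate probes in state {state!r}: "
                         f"{sorted(df.probe_id[dup])}")
    return df


@dataclass
class DeltaS2Result:
    table: pd.DataFrame  # per-probe dS2 with errors and inclusion flag
    mean: float
    se: float
    n: int

    def summary(self) -> str:
        return (
            f"<dS2_axis> = {self.mean:.4f} +/- {self.se:.4f} (n = {self.n}; "
            f"{int((~self.table.included).sum())} probes dropped by the "
            f"error filter)"
        )


def delta_s2(
    set_x: pd.DataFrame, set_y: pd.DataFrame, err_max: float = 0.07
) -> DeltaS2Result:
    """Per-probe dS2 = S2(Y) - S2(X) over the common probes, with the mean
    and standard error over probes whose propagated error is < err_max.

    Error propagation is root-sum-square of the two states' S2 errors.
    """
    merged = set_x.merge(set_y, on="probe_id", suffixes=("_x", "_y"))
    if merged.empty:
        raise ValueError("no probes in common between the two states")
    ds2 = merged.S2_axis_y - merged.S2_axis_x
    err = np.sqrt(merged.S2_err_x**2 + merged.S2_err_y**2)
    included = err < err_max
    table = pd.DataFrame(
        {
            "probe_id": merged.probe_id,
            "dS2": ds2,
            "dS2_err": err,
            "included": included,
        }
    )
    kept = table[included]
    if kept.empty:
        raise ValueError("error filter removed every common probe")
    mean = float(kept.dS2.mean())
    se = float(kept.dS2.std(ddof=1) / np.sqrt(len(kept)))
    return DeltaS2Result(table=table, mean=mean, se=se, n=int(len(kept)))


def entropy_meter(
    mean_ds2: float,
    n_chi: int,
    mean_se: float = 0.0,
    s_d: float = ENTROPY_METER_SLOPE,
    temperature: float = T_KELVIN,
) -> tuple[float, float]:
    """Conformational entropy change (-T dS_conf, kcal/mol) from a mean
    order-parameter change; the error scales linearly with the mean's SE.

    With the negative slope s_d, rigidification (positive mean dS2) yields a
    positive -T dS_conf.
    """
    if n_chi <= 0:
        raise ValueError("n_chi must be positive")
    value = -temperature * s_d * mean_ds2 * n_chi
    err = abs(temperature * s_d * n_chi) * mean_se
    return float(value), float(err)


@dataclass
class ThermodynamicCycle:
    """Entropy decomposition of ligand binding into a direct path (A) and a
    three-step path (B) through the N-terminally truncated enzyme.

    Legs hold (-T dS_conf, error) in kcal/mol: path A = full-length binding;
    path B steps = (1) N-terminus removal from apo, (2) truncated-enzyme
    binding, (3) N-terminus re-addition to the bound form.  The step1+step3
    sum is the N-terminus/binding coupling.
    """

    path_a: tuple[float, float]
    step1: tuple[float, float]
    step2: tuple[float, float]
    step3: tuple[float, float]

    @property
    def coupling(self) -> tuple[float, float]:
        v = self.step1[0] + self.step3[0]
        e = float(np.hypot(self.step1[1], self.step3[1]))
        return v, e

    @property
    def closure(self) -> tuple[float, float]:
        """Path A minus the path-B sum; zero within error on a common probe
        set."""
        v = self.path_a[0] - (self.step1[0] + self.step2[0] + self.step3[0])
        e = float(np.sqrt(sum(x[1] ** 2 for x in (self.path_a, self.step1,
                                                  self.step2, self.step3))))
        return v, e

    def summary(self) -> str:
        c, ce = self.coupling
        z, ze = self.closure
        rows = [
            ("path A (direct binding)", self.path_a),
            ("B1: N-term removal (apo)", self.step1),
            ("B2: truncated binding", self.step2),
            ("B3: N-term re-addition", self.step3),
        ]
        lines = ["Thermodynamic cycle (-T dS_conf, kcal/mol):"]
        lines += [f"  {k:<28}{v[0]:>8.2f} +/- {v[1]:.2f}" for k, v in rows]
        lines.append(f"  {'coupling (B1+B3)':<28}{c:>8.2f} +/- {ce:.2f}")
        lines.append(f"  {'closure A-(B1+B2+B3)':<28}{z:>8.2f} +/- {ze:.2f}")
        return "\n".join(lines)


def thermo_cycle(path_a, step1, step2, step3) -> ThermodynamicCycle:
    """Assemble the cycle from four (-T dS_conf, error) pairs."""
    legs = dict(path_a=path_a, step1=step1, step2=step2, step3=step3)
    for name, leg in legs.items():
        if leg is None or len(leg) != 2:
            raise ValueError(f"incomplete cycle: leg {name!r} missing")
    return ThermodynamicCycle(tuple(path_a), tuple(step1), tuple(step2),
                              tuple(step3))


def methyl_csp(shifts_x: pd.DataFrame, shifts_y: pd.DataFrame) -> pd.DataFrame:
    """Methyl 1H/13C chemical-shift perturbations between two states:
    CSP = sqrt(dwH^2 + 0.25 dwC^2) (ppm).  Inputs carry columns
    probe_id, H_ppm, C_ppm."""
    merged = shifts_x.merge(shifts_y, on="probe_id", suffixes=("_x", "_y"))
    dh = merged.H_ppm_y - merged.H_ppm_x
    dc = merged.C_ppm_y - merged.C_ppm_x
    return pd.DataFrame(
        {"probe_id": merged.probe_id,
         "csp_ppm": np.sqrt(dh**2 + 0.25 * dc**2)}
    )


def count_chi_dihedrals(sequence: str) -> int:
    """Total side-chain chi dihedral count of a one-letter sequence, using
    the per-residue-type table above (a counting convention; pass an
    explicit N_chi where a different convention is required)."""
    try:
        return sum(CHI_PER_RESIDUE[aa] for aa in sequence.upper())
    except KeyError as e:
        raise ValueError(f"unknown residue code {e.args[0]!r}") from None
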