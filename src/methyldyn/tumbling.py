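"""Isotropic rotational-correlation-time estimation from backbone 15N
relaxation.

The molecule is treated as a rigid isotropic rotor with spectral density
J(w) = (2/5) tau_c / (1 + (w tau_c)^2); per-residue R1 and R2 are predicted
from the standard 15N dipolar (N-H bond length 1.02 A) and CSA (-160 ppm)
interactions and tau_c is chosen to minimize the weighted misfit of the
observed R2/R1 ratios, which cancels site-to-site variations in the
interaction amplitudes to first order.

Residue filtering before the fit: terminal residues are removed, log2(R1)
and log2(R2) are trimmed at mean +/- 1 SD, and residues with a heteronuclear
NOE below the cutoff (default 0.65) are dropped.  An optional second pass
flags residues whose R2 misfit exceeds +3 sigma (exchange-broadened) and
refits without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .constants import (
    D2O_H2O_VISCOSITY_RATIO,
    GAMMA_H1,
    GAMMA_N15,
    HBAR,
    MU_0,
    N15_CSA,
    NH_BOND_LENGTH,
    larmor_mhz,
)

RATE_COLUMNS = ["residue_id", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"]


class InsufficientDataError(ValueError):
    pass


def _interaction_constants(field_mhz: float) -> tuple[float, float]:
    """(d^2, c^2) for the 15N dipolar and CSA interactions at the stated
    1H field; d = mu0 hbar gH gN / (4 pi r^3), c = wN * CSA / sqrt(3)."""
    d = MU_0 * HBAR * GAMMA_H1 * abs(GAMMA_N15) / (4 * np.pi * NH_BOND_LENGTH**3)
    wN = 2 * np.pi * larmor_mhz(field_mhz, "15N") * 1e6
    c = wN * abs(N15_CSA) / np.sqrt(3.0)
    return d * d, c * c


def rigid_rotor_rates(tau_c_ns: float, field_mhz: float) -> tuple[float, float]:
    """(R1, R2) in s^-1 of a rigid isotropic rotor at tau_c (ns)."""
    tau = tau_c_ns * 1e-9
    d2, c2 = _interaction_constants(field_mhz)
    wH = 2 * np.pi * field_mhz * 1e6
    wN = 2 * np.pi * larmor_mhz(field_mhz, "15N") * 1e6

    def J(w):
        return 0.4 * tau / (1.0 + (w * tau) ** 2)

    r1 = (d2 / 4.0) * (J(wH - wN) + 3 * J(wN) + 6 * J(wH + wN)) + c2 * J(wN)
    r2 = (d2 / 8.0) * (
        4 * J(0.0) + J(wH - wN) + 3 * J(wN) + 6 * J(wH) + 6 * J(wH + wN)
    ) + (c2 / 6.0) * (4 * J(0.0) + 3 * J(wN))
    return float(r1), float(r2)


def filter_relaxation_residues(
    rates: pd.DataFrame,
    noe_cutoff: float = 0.65,
    terminal_residues: tuple = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a per-residue rate table into (used, excluded).

    Exclusion reasons (one per excluded residue, first rule that fires):
    ``terminal``, ``log2_trim_R1``, ``log2_trim_R2``, ``low_NOE``.
    Terminal residues are removed before the log2 mean/SD are computed.
    A zero SD (all rates identical) trims nothing.
    """
    df = rates.copy()
    excluded = []

    is_term = df.residue_id.isin(terminal_residues)
    for _, row in df[is_term].iterrows():
        excluded.append((row.residue_id, "terminal"))
    df = df[~is_term]

    for col, reason in (("R1", "log2_trim_R1"), ("R2", "log2_trim_R2")):
        logv = np.log2(df[col].to_numpy(dtype=float))
        mu, sd = logv.mean(), logv.std(ddof=0)
        if sd > 0:
            out = np.abs(logv - mu) > sd
            for _, row in df[out].iterrows():
                excluded.append((row.residue_id, reason))
            df = df[~out]

    if "NOE" in df.columns and df.NOE.notna().any():
        low = df.NOE.notna() & (df.NOE < noe_cutoff)
        for _, row in df[low].iterrows():
            excluded.append((row.residue_id, "low_NOE"))
        df = df[~low]

    excluded_df = pd.DataFrame(excluded, columns=["residue_id", "reason"])
    if len(df) < 5:
        raise InsufficientDataError(
            f"only {len(df)} residues survive filtering (need >= 5)"
        )
    return df.reset_index(drop=True), excluded_df


@dataclass
class TumblingResults:
    tau_c: float  # ns
    tau_c_err: float  # ns
    residues_used: list
    residues_excluded: pd.DataFrame
    solvent: str = "5pct_D2O"
    chisqr: float = 0.0
    mc_tau_c: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def tau_c_d2o(self) -> float:
        return correct_tauc_d2o(self.tau_c)

    def summary(self) -> str:
        return (
            f"Isotropic tumbling fit: tau_c = {self.tau_c:.3f} +/- "
            f"{self.tau_c_err:.3f} ns ({self.solvent}; "
            f"{len(self.residues_used)} residues used, "
            f"{len(self.residues_excluded)} excluded; chi2 = {self.chisqr:.3g})\n"
            f"  99.8% D2O equivalent: {self.tau_c_d2o:.3f} ns"
        )


class TumblingModel:
    """R2/R1-based isotropic tau_c model over one or two fields.

    ``rates`` maps field (MHz) -> filtered per-residue rate table; a single
    DataFrame with a ``field`` argument is also accepted.
    """

    def __init__(self, rates, field_mhz: float | None = None,
                 bracket_ns: tuple[float, float] = (1.0, 100.0)):
        if isinstance(rates, pd.DataFrame):
            if field_mhz is None:
                raise ValueError("field_mhz required with a single rate table")
            rates = {float(field_mhz): rates}
        self.rates = {float(k): v.reset_index(drop=True) for k, v in rates.items()}
        self.bracket = bracket_ns

    def _misfit(self, tau_c: float) -> float:
        chi = 0.0
        for fld, df in self.rates.items():
            r1p, r2p = rigid_rotor_rates(tau_c, fld)
            ratio_pred = r2p / r1p
            ratio = df.R2.to_numpy() / df.R1.to_numpy()
            err = ratio * np.sqrt(
                (df.R2_err.to_numpy() / df.R2.to_numpy()) ** 2
                + (df.R1_err.to_numpy() / df.R1.to_numpy()) ** 2
            )
            err = np.where(err > 0, err, np.maximum(0.02 * ratio, 1e-6))
            chi += float(np.sum(((ratio - ratio_pred) / err) ** 2))
        return chi

    def _solve(self) -> float:
        sol = minimize_scalar(self._misfit, bounds=self.bracket, method="bounded",
                              options={"xatol": 1e-6})
        tau = float(sol.x)
        lo, hi = self.bracket
        if tau <= lo * 1.001 or tau >= hi * 0.999:
            raise ValueError(
                f"tau_c optimum {tau:.2f} ns is at the edge of ({lo}, {hi}) ns"
            )
        return tau

    def fit(
        self,
        n_monte_carlo: int = 200,
        seed: int = 0,
        solvent: str = "5pct_D2O",
        excluded: pd.DataFrame | None = None,
        rex_flag_sigma: float | None = None,
    ) -> TumblingResults:
        """Fit tau_c; errors by Monte Carlo over the rate errors.

        With ``rex_flag_sigma`` set, residues whose R2 residual after a first
        pass exceeds +sigma times the robust residual scatter are excluded
        with reason ``Rex_flag`` and the fit is repeated.
        """
        excluded = excluded if excluded is not None else pd.DataFrame(
            columns=["residue_id", "reason"]
        )
        if rex_flag_sigma is not None:
            tau0 = self._solve()
            new_rates = {}
            flagged = []
            for fld, df in self.rates.items():
                _, r2p = rigid_rotor_rates(tau0, fld)
                resid = df.R2.to_numpy() - r2p
                scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
                keep = resid <= np.median(resid) + rex_flag_sigma * max(scale, 1e-9)
                flagged.extend(df.residue_id[~keep])
                new_rates[fld] = df[keep].reset_index(drop=True)
            self.rates = new_rates
            if flagged:
                excluded = pd.concat(
                    [excluded, pd.DataFrame(
                        {"residue_id": flagged, "reason": "Rex_flag"})],
                    ignore_index=True,
                )
        tau = self._solve()
        rng = np.random.default_rng(seed)
        originals = {f: df.copy() for f, df in self.rates.items()}
        mc = []
        for _ in range(n_monte_carlo):
            for fld, df0 in originals.items():
                df = df0.copy()
                df["R1"] = df0.R1 + rng.normal(0.0, df0.R1_err.fillna(0.0))
                df["R2"] = df0.R2 + rng.normal(0.0, df0.R2_err.fillna(0.0))
                self.rates[fld] = df
            try:
                mc.append(self._solve())
            except ValueError:
                pass
        self.rates = originals
        mc = np.asarray(mc)
        used = sorted(
            set().union(*(set(df.residue_id) for df in self.rates.values()))
        )
        return TumblingResults(
            tau_c=tau,
            tau_c_err=float(np.std(mc, ddof=1)) if len(mc) > 1 else 0.0,
            residues_used=used,
            residues_excluded=excluded,
            solvent=solvent,
            chisqr=self._misfit(tau),
            mc_tau_c=mc,
        )


def correct_tauc_d2o(tau_c_5pct: float) -> float:
    """Viscosity correction from 5% to 99.8% D2O at 25 C:
    tau_D2O = 1.235 tau_5% / (0.95 + 0.05 * 1.235)."""
    r = D2O_H2O_VISCOSITY_RATIO
    return r * tau_c_5pct / (0.95 + 0.05 * r)
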