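"""Conversion of raw plane intensities into relaxation observables.

Pseudo-3D experiments come in as long-format tables (one row per probe per
plane) with the schema documented in :mod:`methyldyn.io`:

    probe_id, experiment, field_MHz, plane_key, Trelax_s,
    intensity, intensity_error, is_ref, is_duplicate

For CPMG planes ``plane_key`` is nu_cpmg (Hz); for CEST planes the spin-lock
offset; for decay series the relaxation delay (s).  Each probe has exactly
one reference plane per experiment.  Duplicate plane_keys are allowed and
are the basis of the duplicate-point RMSD error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLANE_COLUMNS = [
    "probe_id", "experiment", "field_MHz", "plane_key", "Trelax_s",
    "intensity", "intensity_error", "is_ref", "is_duplicate",
]


class PlaneTableError(ValueError):
    pass


@dataclass
class PlaneIntensityTable:
    """Validated probe x plane intensity table for one pseudo-3D dataset."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PLANE_COLUMNS if c not in self.df.columns]
        if missing:
            raise PlaneTableError(f"missing columns: {missing}")
        refs = self.df[self.df.is_ref.astype(bool)].groupby("probe_id").size()
        probes = self.df.probe_id.unique()
        for p in probes:
            if refs.get(p, 0) != 1:
                raise PlaneTableError(
                    f"probe {p!r}: expected exactly one reference plane, "
                    f"found {refs.get(p, 0)}"
                )

    @property
    def probes(self) -> list[str]:
        return list(dict.fromkeys(self.df.probe_id))

    def probe(self, probe_id: str) -> pd.DataFrame:
        sub = self.df[self.df.probe_id == probe_id]
        if sub.empty:
            raise KeyError(probe_id)
        return sub


def duplicate_point_rmsd(table: PlaneIntensityTable) -> float:
    """Pooled duplicate-point RMSD of a dataset.

    Duplicate pairs (same probe, same plane_key, non-reference) estimate the
    per-point intensity noise as the RMS of half-differences of the pairs,
    pooled over all probes of the dataset.  Returns NaN when the dataset
    contains no duplicate pair.
    """
    df = table.df[~table.df.is_ref.astype(bool)]
    half_diffs = []
    for (_, _), grp in df.groupby(["probe_id", "plane_key"]):
        vals = grp.intensity.to_numpy()
        if len(vals) >= 2:
            for i in range(0, len(vals) - 1, 2):
                half_diffs.append(0.5 * (vals[i] - vals[i + 1]))
    if not half_diffs:
        return float("nan")
    return float(np.sqrt(np.mean(np.square(half_diffs))) * np.sqrt(2.0))


def r2eff_from_intensities(
    table: PlaneIntensityTable, intensity_error: float | None = None
) -> pd.DataFrame:
    """R2,eff per non-reference plane: -(1/Trelax) ln(I/I_ref).

    ``intensity_error`` overrides the per-point error; by default the pooled
    duplicate-point RMSD is used when duplicates exist, else the table's
    ``intensity_error`` column.  Errors are first-order propagated:
    sigma(R2,eff) = (1/T) sqrt((sI/I)^2 + (sIref/Iref)^2).
    """
    dup_rmsd = duplicate_point_rmsd(table) if intensity_error is None else None
    rows = []
    for probe in table.probes:
        sub = table.probe(probe)
        ref = sub[sub.is_ref.astype(bool)].iloc[0]
        if ref.intensity <= 0:
            raise PlaneTableError(f"probe {probe!r}: non-positive reference intensity")
        planes = sub[~sub.is_ref.astype(bool)]
        T = planes.Trelax_s.to_numpy(dtype=float)
        I = planes.intensity.to_numpy(dtype=float)
        if np.any(I <= 0):
            bad = planes.plane_key.to_numpy()[I <= 0]
            raise PlaneTableError(
                f"probe {probe!r}: non-positive intensity at plane(s) {bad}"
            )
        if intensity_error is not None:
            sI = np.full_like(I, intensity_error)
            sref = intensity_error
        elif np.isfinite(dup_rmsd):
            sI = np.full_like(I, dup_rmsd)
            sref = dup_rmsd
        else:
            sI = planes.intensity_error.to_numpy(dtype=float)
            sref = float(ref.intensity_error)
        r2eff = -np.log(I / ref.intensity) / T
        err = np.sqrt((sI / I) ** 2 + (sref / ref.intensity) ** 2) / T
        for pk, r, e in zip(planes.plane_key, r2eff, err):
            rows.append((probe, float(pk), float(r), float(e)))
    return pd.DataFrame(rows, columns=["probe_id", "plane_key", "r2eff", "r2eff_err"])


def average_duplicates(profile: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate plane_keys of an R2,eff (or intensity) profile."""
    val_cols = [c for c in profile.columns if c not in ("probe_id", "plane_key")]
    return (
        profile.groupby(["probe_id", "plane_key"], as_index=False)[val_cols].mean()
    )


@dataclass
class MonoExpResults:
    """Monoexponential decay fit: I(t) = I0 exp(-rate t)."""

    rate: float
    rate_err: float
    i0: float
    residuals: np.ndarray
    mc_rates: np.ndarray
    flagged_nondecaying: bool = False

    def summary(self) -> str:
        flag = "  [flagged: non-decaying]" if self.flagged_nondecaying else ""
        return (
            f"Monoexponential fit: rate = {self.rate:.4g} +/- "
            f"{self.rate_err:.2g} s^-1 (I0 = {self.i0:.4g}, "
            f"{len(self.mc_rates)} Monte Carlo refits){flag}"
        )


class MonoExpModel:
    """Least-squares monoexponential decay model for one probe's delay series.

    Intensities are normalized to the reference (first) point before
    fitting; the fit is therefore invariant to the overall intensity scale.
    Errors come from refits of Monte Carlo simulations of the data
    (Gaussian per-point noise at the supplied error level).
    """

    def __init__(self, delays, intensities, intensity_errors=None):
        self.delays = np.asarray(delays, dtype=float)
        self.intensities = np.asarray(intensities, dtype=float)
        if self.delays.size < 3:
            raise ValueError("need >= 3 delay points")
        if np.any(self.intensities <= 0):
            raise ValueError("non-positive intensity in decay series")
        if intensity_errors is None:
            intensity_errors = np.zeros_like(self.intensities)
        self.intensity_errors = np.broadcast_to(
            np.asarray(intensity_errors, dtype=float), self.intensities.shape
        ).copy()

    @classmethod
    def from_table(cls, table: PlaneIntensityTable, probe_id: str) -> "MonoExpModel":
        sub = table.probe(probe_id).sort_values("Trelax_s")
        return cls(sub.Trelax_s, sub.intensity, sub.intensity_error)

    @staticmethod
    def _fit_once(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        # log-linear solution; exact for noise-free data, used as the
        # starting point of the nonlinear refinement
        ylog = np.log(np.maximum(y, 1e-300))
        A = np.vstack([np.ones_like(t), -t]).T
        c, rate = np.linalg.lstsq(A, ylog, rcond=None)[0]
        from scipy.optimize import least_squares

        def resid(p):
            return p[0] * np.exp(-p[1] * t) - y

        sol = least_squares(resid, [np.exp(c), rate], method="lm")
        return float(sol.x[1]), float(sol.x[0])

    def fit(self, n_monte_carlo: int = 200, seed: int | None = 0) -> MonoExpResults:
        scale = self.intensities[0]
        y = self.intensities / scale
        errs = self.intensity_errors / scale
        rate, i0 = self._fit_once(self.delays, y)
        resid = i0 * np.exp(-rate * self.delays) - y
        rng = np.random.default_rng(seed)
        mc = []
        yhat = i0 * np.exp(-rate * self.delays)
        for _ in range(n_monte_carlo):
            ysim = yhat + rng.normal(0.0, errs)
            ysim = np.maximum(ysim, 1e-12)
            mc.append(self._fit_once(self.delays, ysim)[0])
        mc = np.asarray(mc)
        return MonoExpResults(
            rate=rate,
            rate_err=float(np.std(mc, ddof=1)) if len(mc) > 1 else 0.0,
            i0=i0 * scale,
            residuals=resid,
            mc_rates=mc,
            flagged_nondecaying=rate <= 0,
        )


def r2_from_r1rho(r1rho: float, r1: float, theta_deg: float) -> float:
    """Off-resonance correction: R2 = R1rho/sin^2(theta) - R1/tan^2(theta).

    theta is the tilt angle of the effective field (90 deg = on resonance).
    """
    theta = np.deg2rad(theta_deg)
    if not 0 < theta_deg <= 90:
        raise ValueError("tilt angle must be in (0, 90] degrees")
    return float(r1rho / np.sin(theta) ** 2 - r1 / np.tan(theta) ** 2)


def het_noe(i_sat: float, i_ref: float, noise: float = 0.0) -> tuple[float, float]:
    """Heteronuclear NOE = I_sat/I_ref, with error from 1x base-plane noise."""
    if i_ref == 0:
        raise ZeroDivisionError("reference intensity is zero")
    noe = i_sat / i_ref
    err = abs(noe) * np.sqrt(
        (noise / i_sat) ** 2 + (noise / i_ref) ** 2
    ) if i_sat != 0 and noise else (noise / abs(i_ref) if noise else 0.0)
    return float(noe), float(err)


def two_plane_rex(
    i_low_nu: float, i_high_nu: float, t_relax: float
) -> tuple[float, bool]:
    """Exchange flag from a two-plane CPMG: Delta R2,eff between the lowest
    and highest pulsing rates.  Positive values indicate exchange broadening;
    negative values are noise-dominated and flagged."""
    if i_low_nu <= 0 or i_high_nu <= 0:
        raise ValueError("two-plane intensities must be positive")
    d = -np.log(i_low_nu / i_high_nu) / t_relax
    return float(d), bool(d < 0)
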