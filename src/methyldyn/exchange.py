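"""Global fitting of multi-experiment, multi-field CPMG + CEST data to
two-state and bifurcated three-state exchange models.

The fitting strategy mirrors standard dispersion-analysis practice for a
slow concerted process plus faster local processes:

1. ``CestGlobalModel`` fits the CEST data alone with a two-state model,
   sharing k_ab and k_ba across the probes of the concerted process, with
   per-probe shift differences (whose sign CEST determines) and intrinsic
   rates.
2. ``ProbeExchangeModel`` then jointly fits all CPMG and CEST datasets of a
   single probe (or a geminal methyl pair, which shares exchange rates) to a
   two-state or bifurcated B<->A<->C model, with the concerted-process
   parameters (k_ab, k_ba, dw_C_ab) fixed from step 1.  1H shift
   differences stay fixed at 0 unless explicitly released.

Parameter errors are the standard deviations over refits of Monte Carlo
simulations of the data (default n=200).  Model choice between nested
two-/three-state fits uses AICc plus a cross-probe consistency diagnostic
(coefficient of variation of the shared rates).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .spin import (
    Experiment,
    ExchangeModel,
    ExperimentGeometry,
    Topology,
    simulate_cest,
    simulate_mq_cpmg,
    simulate_sq_cpmg,
)

RATE_BOUNDS = (1e-3, 1e5)
DW_BOUNDS = (-10.0, 10.0)


class FitConfigurationError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CpmgDataset:
    """One CPMG R2,eff profile for one probe."""

    probe_id: str
    experiment: Experiment
    field_MHz: float
    T_relax: float
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    r2eff_err: np.ndarray

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.r2eff_err = np.asarray(self.r2eff_err, dtype=float)
        self.experiment = Experiment(self.experiment)
        if self.experiment is Experiment.CEST:
            raise ValueError("CpmgDataset cannot hold a CEST experiment")

    def geometry(self) -> ExperimentGeometry:
        return ExperimentGeometry(
            self.experiment, self.field_MHz, self.T_relax, tuple(self.nu_cpmg)
        )

    @property
    def tag(self) -> str:
        return f"{self.experiment.value}_{self.field_MHz:g}"


@dataclass
class CestDataset:
    """One CEST profile (normalized intensities vs offset) for one probe."""

    probe_id: str
    field_MHz: float
    spinlock_hz: float
    T_ex: float
    offsets_hz: np.ndarray
    intensity: np.ndarray
    intensity_err: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_hz = np.asarray(self.offsets_hz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.intensity_err = np.asarray(self.intensity_err, dtype=float)

    def geometry(self) -> ExperimentGeometry:
        return ExperimentGeometry(
            Experiment.CEST,
            self.field_MHz,
            self.T_ex,
            offset_list=tuple(self.offsets_hz),
            spinlock_power=self.spinlock_hz,
        )

    @property
    def tag(self) -> str:
        return f"cest_{self.spinlock_hz:g}"


@dataclass(frozen=True)
class Fix:
    param: str
    value: float
    provenance: str = ""


@dataclass(frozen=True)
class Share:
    param: str
    probes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.probes) < 2:
            raise FitConfigurationError(
                f"share({self.param}) needs >= 2 probes, got {self.probes}"
            )


@dataclass
class ConstraintGraph:
    """Fix/share directives applied to a fit's parameter set.

    Every fixed parameter records where its value came from; conflicting
    fix and share directives on the same parameter are rejected before any
    fitting happens.
    """

    fixes: tuple[Fix, ...] = ()
    shares: tuple[Share, ...] = ()

    def __post_init__(self) -> None:
        fixed = {f.param for f in self.fixes}
        if len(fixed) != len(self.fixes):
            raise FitConfigurationError("duplicate fix directives")
        shared = [s.param for s in self.shares]
        conflict = fixed.intersection(shared)
        if conflict:
            raise FitConfigurationError(
                f"parameters both fixed and shared: {sorted(conflict)}"
            )

    def fixed_value(self, param: str):
        for f in self.fixes:
            if f.param == param:
                return f.value
        return None


def _apply_leastsq(params, residual_fn, **kw):
    return lmfit.minimize(
        residual_fn, params, method="leastsq", nan_policy="raise", **kw
    )


@dataclass
class GlobalFitResult:
    """Best-fit parameters, chi-square, and Monte Carlo error distributions."""

    params: lmfit.Parameters
    chisqr: float
    ndata: int
    nvarys: int
    model_label: str
    residuals_by_dataset: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    mc_values: dict = field(default_factory=dict)
    n_mc_failed: int = 0
    _model: object = None

    @property
    def redchi(self) -> float:
        dof = max(self.ndata - self.nvarys, 1)
        return self.chisqr / dof

    @property
    def aicc(self) -> float:
        """Corrected Akaike information criterion from the weighted
        chi-square (Gaussian likelihood with known per-point errors)."""
        k = self.nvarys
        n = self.ndata
        aic = self.chisqr + 2 * k
        if n - k - 1 > 0:
            aic += 2 * k * (k + 1) / (n - k - 1)
        return aic

    def value(self, name: str) -> float:
        return float(self.params[name].value)

    @property
    def kex_ab(self) -> float:
        return self.value("k_ab") + self.value("k_ba")

    @property
    def p_b(self) -> float:
        return self.value("k_ab") / self.kex_ab

    @property
    def kex_ac(self) -> float:
        return self.value("k_ac") + self.value("k_ca")

    @property
    def p_c(self) -> float:
        return self.value("k_ac") / self.kex_ac

    def mc_std(self, name: str) -> float:
        vals = self.mc_values.get(name)
        if vals is None or len(vals) < 2:
            return 0.0
        return float(np.std(vals, ddof=1))

    def mc_quantile(self, name: str, q) -> float:
        vals = self.mc_values.get(name)
        if vals is None:
            raise KeyError(f"no Monte Carlo distribution for {name}")
        return float(np.quantile(vals, q))

    def error(self, name: str) -> float:
        """Monte Carlo error when available, else the covariance stderr."""
        if name in self.mc_values:
            return self.mc_std(name)
        p = self.params[name]
        return float(p.stderr) if p.stderr else float("nan")

    def summary(self) -> str:
        lines = [
            f"Global fit [{self.model_label}]",
            f"  chi2 = {self.chisqr:.4g}  (n = {self.ndata}, "
            f"varied = {self.nvarys}, red. chi2 = {self.redchi:.4g}, "
            f"AICc = {self.aicc:.4g})",
            f"  {'parameter':<18}{'value':>12}{'error':>12}  status",
        ]
        for name, p in self.params.items():
            err = self.error(name)
            status = "fixed" if not p.vary else ""
            err_s = f"{err:.3g}" if np.isfinite(err) else "-"
            lines.append(f"  {name:<18}{p.value:>12.5g}{err_s:>12}  {status}")
        for k, v in self.flags.items():
            lines.append(f"  flag: {k} = {v}")
        return "\n".join(lines)


class _ExchangeFitBase:
    """Shared machinery: residuals over dataset collections, multi-start
    optimization, and Monte Carlo error estimation."""

    model_label = "exchange"

    def _datasets(self):
        raise NotImplementedError

    def _build_params(self) -> lmfit.Parameters:
        raise NotImplementedError

    def _simulate_dataset(self, params: lmfit.Parameters, ds) -> np.ndarray:
        raise NotImplementedError

    def _param_key(self, params: lmfit.Parameters, ds) -> tuple:
        """Values of the parameters a dataset's simulation depends on; used
        to memoize simulations so that Jacobian steps on one probe's
        parameters do not re-simulate every other probe."""
        return tuple(p.value for p in params.values())

    def _cached_simulate(self, params, i, ds) -> np.ndarray:
        cache = getattr(self, "_sim_cache", None)
        if cache is None:
            cache = self._sim_cache = {}
        key = (i, self._param_key(params, ds))
        sim = cache.get(key)
        if sim is None:
            sim = self._simulate_dataset(params, ds)
            if len(cache) > 50000:
                cache.clear()
            cache[key] = sim
        return sim

    def _residuals(self, params: lmfit.Parameters) -> np.ndarray:
        out = []
        for i, ds in enumerate(self._datasets()):
            sim = self._cached_simulate(params, i, ds)
            obs = ds.intensity if isinstance(ds, CestDataset) else ds.r2eff
            err = ds.intensity_err if isinstance(ds, CestDataset) else ds.r2eff_err
            out.append((sim - obs) / err)
        return np.concatenate(out)

    def _start_grid(self, params, n_starts, seed):
        """Yield parameter sets for multi-start optimization; subclasses
        override to perturb their kinetic parameters."""
        yield params

    def fit(self, n_starts: int = 10, seed: int = 0,
            early_stop_redchi: float | None = None) -> GlobalFitResult:
        """Multi-start weighted least squares; ``early_stop_redchi`` accepts
        the first start whose reduced chi-square falls below it (the noise
        floor is 1 when the per-point errors are correct)."""
        base = self._build_params()
        best = None
        start_report = []
        for start in self._start_grid(base, n_starts, seed):
            try:
                res = _apply_leastsq(start, self._residuals)
            except Exception:  # singular step, overflow: try next start
                start_report.append(float("inf"))
                continue
            start_report.append(res.chisqr)
            if best is None or res.chisqr < best.chisqr:
                best = res
            if (early_stop_redchi is not None
                    and best.redchi < early_stop_redchi):
                break
        if best is None or not np.isfinite(best.chisqr):
            raise ConvergenceError(
                f"no start converged; per-start chi2: {start_report}"
            )
        result = GlobalFitResult(
            params=best.params,
            chisqr=float(best.chisqr),
            ndata=int(best.ndata),
            nvarys=int(best.nvarys),
            model_label=self.model_label,
            residuals_by_dataset=self._split_residuals(best.params),
            flags=dict(getattr(self, "flags", {})),
            _model=self,
        )
        return result

    def _split_residuals(self, params) -> dict:
        out = {}
        for i, ds in enumerate(self._datasets()):
            sim = self._simulate_dataset(params, ds)
            obs = ds.intensity if isinstance(ds, CestDataset) else ds.r2eff
            err = ds.intensity_err if isinstance(ds, CestDataset) else ds.r2eff_err
            out[f"{ds.probe_id}:{ds.tag}:{i}"] = (sim - obs) / err
        return out

    def monte_carlo(
        self, result: GlobalFitResult, n: int = 200, seed: int = 0
    ) -> GlobalFitResult:
        """Refit ``n`` synthetic datasets drawn from the best-fit curves plus
        per-point Gaussian errors; store per-parameter Monte Carlo values.

        Refits start from the central solution.  More than 10% failed refits
        raises."""
        rng = np.random.default_rng(seed)
        datasets = list(self._datasets())
        curves = [self._simulate_dataset(result.params, ds) for ds in datasets]
        errs = [
            ds.intensity_err if isinstance(ds, CestDataset) else ds.r2eff_err
            for ds in datasets
        ]
        originals = [
            (ds.intensity if isinstance(ds, CestDataset) else ds.r2eff).copy()
            for ds in datasets
        ]
        varied = [name for name, p in result.params.items() if p.vary]
        mc = {name: [] for name in varied}
        failed = 0
        try:
            for _ in range(n):
                for ds, curve, err in zip(datasets, curves, errs):
                    noisy = curve + rng.normal(0.0, err)
                    if isinstance(ds, CestDataset):
                        ds.intensity = noisy
                    else:
                        ds.r2eff = noisy
                try:
                    refit = _apply_leastsq(result.params.copy(), self._residuals)
                    for name in varied:
                        mc[name].append(refit.params[name].value)
                except Exception:
                    failed += 1
        finally:
            for ds, orig in zip(datasets, originals):
                if isinstance(ds, CestDataset):
                    ds.intensity = orig
                else:
                    ds.r2eff = orig
        if failed > 0.1 * n:
            raise ConvergenceError(f"{failed}/{n} Monte Carlo refits failed")
        result.mc_values = {k: np.asarray(v) for k, v in mc.items()}
        result.n_mc_failed = failed
        self._derive_mc_rates(result)
        return result

    def _derive_mc_rates(self, result: GlobalFitResult) -> None:
        """Augment the Monte Carlo distributions with derived exchange rates
        and populations."""
        mv = result.mc_values
        for minor in ("b", "c"):
            kf, kr = f"k_a{minor}", f"k_{minor}a"
            if kf in mv and kr in mv:
                mv[f"kex_a{minor}"] = mv[kf] + mv[kr]
                mv[f"p_{minor}"] = mv[kf] / (mv[kf] + mv[kr])


def _dip_guess(ds: CestDataset) -> tuple[float, float]:
    """Heuristic (dw_ppm, dip_depth) of the largest minor dip of a CEST
    profile.

    The minor dip is measured as the asymmetry of the profile about the
    ground-state dip (profile minus its mirror image), which is insensitive
    to the symmetric tails of the main dip."""
    from .constants import larmor_mhz

    off = ds.offsets_hz
    inten = ds.intensity
    order = np.argsort(off)
    off_s, int_s = off[order], inten[order]
    i0 = int(np.argmin(int_s))
    step = float(np.median(np.diff(off_s))) if len(off_s) > 1 else 1.0
    guard = max(1.5 * ds.spinlock_hz, 15.0)

    def paired_asymmetries(center: float):
        """Exact grid-pair asymmetries about ``center`` (no interpolation —
        it would fabricate asymmetry on the steep main-dip flanks)."""
        rel = off_s - center
        out = []
        for i, r in enumerate(rel):
            if r <= 0.25 * step:
                continue
            match = np.where(np.abs(rel + r) < 0.25 * step)[0]
            if match.size:
                out.append((r, int_s[match[0]] - int_s[i]))
        return out

    # the main dip is symmetric; choose the center (near the noisy argmin)
    # that minimizes overall paired asymmetry
    candidates = [off_s[j] for j in range(max(i0 - 2, 0),
                                          min(i0 + 3, len(off_s)))]
    def total_asym(c):
        # judge candidate centers on the innermost pairs only: the steep
        # main-dip core towers over any (broad, shallow) minor-dip
        # contribution there
        pairs = [(r, a) for r, a in paired_asymmetries(c) if r <= 2.5 * step]
        return sum(abs(a) for _, a in pairs) / len(pairs) if pairs else np.inf

    ground = min(candidates, key=total_asym)
    best_dw_hz, best_depth = 0.0, 0.0
    for r, asym in paired_asymmetries(ground):
        if r > guard and abs(asym) > best_depth:
            best_depth = abs(asym)
            best_dw_hz = r if asym > 0 else -r
    return float(best_dw_hz / larmor_mhz(ds.field_MHz, "13C")), float(best_depth)


class CestGlobalModel(_ExchangeFitBase):
    """Global two-state fit of CEST profiles with k_ab, k_ba shared across
    the probe set of the concerted process.

    Per-probe parameters: dw_C (sign determined by the CEST dip position),
    intrinsic R1 and R2.  Probes whose profiles carry no detectable minor
    dip (depth below ``identifiability_sigma`` times the median intensity
    error) are flagged non-identifiable; their dw is still fitted but the
    shared rates are driven by the informative probes.
    """

    model_label = "cest_global_2state"

    def __init__(self, datasets: list[CestDataset], identifiability_sigma: float = 3.0):
        if not datasets:
            raise FitConfigurationError("no CEST datasets supplied")
        self.datasets = list(datasets)
        self.probe_ids = list(dict.fromkeys(ds.probe_id for ds in self.datasets))
        self.flags = {}
        self._dips = {}
        for p in self.probe_ids:
            own = [ds for ds in self.datasets if ds.probe_id == p]
            dws, depths = zip(*(_dip_guess(ds) for ds in own))
            noise = float(np.median(np.concatenate([ds.intensity_err for ds in own])))
            best = int(np.argmax(depths))
            self._dips[p] = dws[best]
            # paired-sample asymmetry noise is sqrt(2) x per-point noise
            if max(depths) < identifiability_sigma * np.sqrt(2.0) * noise:
                self.flags[f"non_identifiable:{p}"] = True

    def _datasets(self):
        return self.datasets

    @staticmethod
    def _pname(kind: str, probe: str) -> str:
        clean = "".join(ch if ch.isalnum() else "_" for ch in probe)
        return f"{kind}__{clean}"

    def _build_params(self) -> lmfit.Parameters:
        params = lmfit.Parameters()
        params.add("k_ab", value=3.0, min=RATE_BOUNDS[0], max=RATE_BOUNDS[1])
        params.add("k_ba", value=250.0, min=RATE_BOUNDS[0], max=RATE_BOUNDS[1])
        for p in self.probe_ids:
            own = [ds for ds in self.datasets if ds.probe_id == p]
            dw0 = self._dips[p] or 1.0
            plateau = float(np.median([np.median(ds.intensity) for ds in own]))
            r1_0 = max(-np.log(max(plateau, 0.05)) / own[0].T_ex, 0.2)
            params.add(self._pname("dw", p), value=dw0, min=DW_BOUNDS[0], max=DW_BOUNDS[1])
            params.add(self._pname("r1", p), value=r1_0, min=0.01, max=30.0)
            params.add(self._pname("r2", p), value=20.0, min=0.1, max=300.0)
        return params

    def _start_grid(self, params, n_starts, seed):
        n = max(n_starts, 1)
        kex_grid = np.geomspace(50.0, 2500.0, n) if n > 1 else [250.0]
        pb_grid = (0.01, 0.04)
        for i, kex in enumerate(kex_grid):
            p = params.copy()
            pb = pb_grid[i % len(pb_grid)]
            p["k_ab"].value = kex * pb
            p["k_ba"].value = kex * (1 - pb)
            yield p

    def _param_key(self, params, ds: CestDataset) -> tuple:
        p = ds.probe_id
        return (
            params["k_ab"].value, params["k_ba"].value,
            params[self._pname("dw", p)].value,
            params[self._pname("r1", p)].value,
            params[self._pname("r2", p)].value,
        )

    def _simulate_dataset(self, params, ds: CestDataset) -> np.ndarray:
        p = ds.probe_id
        model = ExchangeModel(
            topology=Topology.TWO_STATE,
            k_ab=params["k_ab"].value,
            k_ba=params["k_ba"].value,
            dw_C_ab=params[self._pname("dw", p)].value,
            r2_base=params[self._pname("r2", p)].value,
            r1_base=params[self._pname("r1", p)].value,
        )
        return simulate_cest(model, ds.geometry())


class ProbeExchangeModel(_ExchangeFitBase):
    """Joint fit of all CPMG and CEST datasets of one probe (or a geminal
    methyl pair sharing exchange rates) to a two-state or bifurcated
    three-state model.

    For concerted-process probes, pass ``constraints`` fixing k_ab, k_ba and
    the per-probe dw_C_ab at the values of the prior CEST-only global fit.
    dw_H parameters are fixed at 0 unless listed in ``free_dw_h``.
    Intrinsic R2 is per (experiment, field) dataset; CEST datasets add a
    per-probe R1 and one R2 shared across spin-lock powers.
    """

    def __init__(
        self,
        cpmg_datasets: list[CpmgDataset],
        cest_datasets: list[CestDataset] | None = None,
        topology: Topology = Topology.BIFURCATED_THREE_STATE,
        constraints: ConstraintGraph | None = None,
        free_dw_h: tuple[str, ...] = (),
    ):
        self.cpmg = list(cpmg_datasets)
        self.cest = list(cest_datasets or [])
        if not self.cpmg and not self.cest:
            raise FitConfigurationError("no datasets supplied")
        self.topology = Topology(topology)
        self.constraints = constraints or ConstraintGraph()
        self.free_dw_h = tuple(free_dw_h)
        self.probe_ids = list(
            dict.fromkeys(ds.probe_id for ds in self.cpmg + self.cest)
        )
        self.flags = {}
        self.model_label = (
            "probe_2state"
            if self.topology is Topology.TWO_STATE
            else "probe_bifurcated_3state"
        )

    def _datasets(self):
        return self.cpmg + self.cest

    @staticmethod
    def _pname(kind: str, key: str) -> str:
        clean = "".join(ch if ch.isalnum() else "_" for ch in key)
        return f"{kind}__{clean}"

    def _add(self, params, name, value, minv, maxv):
        fixed = self.constraints.fixed_value(name)
        if fixed is not None:
            params.add(name, value=fixed, vary=False)
        else:
            params.add(name, value=value, min=minv, max=maxv)

    def _build_params(self) -> lmfit.Parameters:
        params = lmfit.Parameters()
        self._add(params, "k_ab", 3.0, *RATE_BOUNDS)
        self._add(params, "k_ba", 250.0, *RATE_BOUNDS)
        three = self.topology is Topology.BIFURCATED_THREE_STATE
        if three:
            self._add(params, "k_ac", 3.0, *RATE_BOUNDS)
            self._add(params, "k_ca", 1500.0, *RATE_BOUNDS)
        for p in self.probe_ids:
            self._add(params, self._pname("dw_ab", p), 1.0, *DW_BOUNDS)
            if three:
                self._add(params, self._pname("dw_ac", p), 3.0, *DW_BOUNDS)
            for kind in ("dwH_ab",) + (("dwH_ac",) if three else ()):
                name = self._pname(kind, p)
                if self.constraints.fixed_value(name) is not None:
                    self._add(params, name, 0.0, -2.0, 2.0)
                elif p in self.free_dw_h:
                    params.add(name, value=0.0, min=-2.0, max=2.0)
                else:
                    params.add(name, value=0.0, vary=False)
        for ds in self.cpmg:
            r2_0 = float(np.median(ds.r2eff[np.argsort(ds.nu_cpmg)][-3:]))
            self._add(params, self._pname("r20", f"{ds.probe_id}_{ds.tag}"),
                      max(r2_0, 1.0), 0.1, 300.0)
        for p in {ds.probe_id for ds in self.cest}:
            own = [ds for ds in self.cest if ds.probe_id == p]
            plateau = float(np.median([np.median(ds.intensity) for ds in own]))
            r1_0 = max(-np.log(max(plateau, 0.05)) / own[0].T_ex, 0.2)
            self._add(params, self._pname("r1", p), r1_0, 0.01, 30.0)
            self._add(params, self._pname("r2c", p), 20.0, 0.1, 300.0)
        return params

    def _start_grid(self, params, n_starts, seed):
        if self.topology is Topology.TWO_STATE:
            kex_grid = np.geomspace(100.0, 4000.0, max(n_starts, 1))
            for kex in kex_grid:
                p = params.copy()
                if p["k_ab"].vary:
                    p["k_ab"].value = 0.01 * kex
                if p["k_ba"].vary:
                    p["k_ba"].value = 0.99 * kex
                yield p
        else:
            kex_grid = np.geomspace(300.0, 5000.0, max(n_starts, 1))
            for kex in kex_grid:
                p = params.copy()
                if p["k_ac"].vary:
                    p["k_ac"].value = 0.003 * kex
                if p["k_ca"].vary:
                    p["k_ca"].value = 0.997 * kex
                yield p

    def _exchange_model(self, params, probe: str, r2: float, r1: float) -> ExchangeModel:
        three = self.topology is Topology.BIFURCATED_THREE_STATE
        return ExchangeModel(
            topology=self.topology,
            k_ab=params["k_ab"].value,
            k_ba=params["k_ba"].value,
            k_ac=params["k_ac"].value if three else 0.0,
            k_ca=params["k_ca"].value if three else 0.0,
            dw_C_ab=params[self._pname("dw_ab", probe)].value,
            dw_C_ac=params[self._pname("dw_ac", probe)].value if three else 0.0,
            dw_H_ab=params[self._pname("dwH_ab", probe)].value,
            dw_H_ac=params[self._pname("dwH_ac", probe)].value if three else 0.0,
            r2_base=r2,
            r1_base=r1,
        )

    def _param_key(self, params, ds) -> tuple:
        p = ds.probe_id
        three = self.topology is Topology.BIFURCATED_THREE_STATE
        key = [params["k_ab"].value, params["k_ba"].value,
               params[self._pname("dw_ab", p)].value,
               params[self._pname("dwH_ab", p)].value]
        if three:
            key += [params["k_ac"].value, params["k_ca"].value,
                    params[self._pname("dw_ac", p)].value,
                    params[self._pname("dwH_ac", p)].value]
        if isinstance(ds, CestDataset):
            key += [params[self._pname("r1", p)].value,
                    params[self._pname("r2c", p)].value,
                    ds.spinlock_hz]
        else:
            key.append(params[self._pname("r20", f"{p}_{ds.tag}")].value)
        return tuple(key)

    def _simulate_dataset(self, params, ds) -> np.ndarray:
        if isinstance(ds, CestDataset):
            model = self._exchange_model(
                params,
                ds.probe_id,
                params[self._pname("r2c", ds.probe_id)].value,
                params[self._pname("r1", ds.probe_id)].value,
            )
            return simulate_cest(model, ds.geometry())
        r2 = params[self._pname("r20", f"{ds.probe_id}_{ds.tag}")].value
        model = self._exchange_model(params, ds.probe_id, r2, 1.0)
        if ds.experiment is Experiment.SQ_CPMG:
            return simulate_sq_cpmg(model, ds.geometry())
        return simulate_mq_cpmg(model, ds.geometry())


def fit_cest_global_2state(
    cest_datasets: list[CestDataset],
    n_starts: int = 10,
    seed: int = 0,
    n_monte_carlo: int = 0,
) -> GlobalFitResult:
    """Convenience wrapper: global two-state CEST fit with shared rates,
    optionally followed by Monte Carlo error estimation."""
    model = CestGlobalModel(cest_datasets)
    res = model.fit(n_starts=n_starts, seed=seed)
    if n_monte_carlo:
        res = model.monte_carlo(res, n=n_monte_carlo, seed=seed)
    return res


def concerted_constraints(cest_fit: GlobalFitResult, probe_id: str) -> ConstraintGraph:
    """Fix k_ab, k_ba and the probe's dw_C_ab at the CEST-only global-fit
    values, recording provenance — the constraint set used for joint
    bifurcated fits of concerted-process probes."""
    dw_name = CestGlobalModel._pname("dw", probe_id)
    return ConstraintGraph(
        fixes=(
            Fix("k_ab", cest_fit.value("k_ab"), "cest_global_2state"),
            Fix("k_ba", cest_fit.value("k_ba"), "cest_global_2state"),
            Fix(
                ProbeExchangeModel._pname("dw_ab", probe_id),
                cest_fit.value(dw_name),
                "cest_global_2state",
            ),
        )
    )


def select_model(fit_2state: GlobalFitResult, fit_3state: GlobalFitResult) -> dict:
    """AICc-based choice between nested two-state and bifurcated fits of the
    same data; ties break toward fewer parameters."""
    if fit_2state.ndata != fit_3state.ndata:
        raise FitConfigurationError("model selection requires identical data")
    a2, a3 = fit_2state.aicc, fit_3state.aicc
    chosen = fit_3state.model_label if a3 < a2 else fit_2state.model_label
    return {
        "chosen": chosen,
        "aicc_2state": a2,
        "aicc_3state": a3,
        "delta_aicc": a3 - a2,
        "chisq_2state": fit_2state.chisqr,
        "chisq_3state": fit_3state.chisqr,
    }


def consistency_cv(results: list[GlobalFitResult], params=("k_ab", "k_ba")) -> dict:
    """Cross-probe coefficient of variation of (nominally shared) rates — the
    consistency diagnostic supporting the concerted-process interpretation."""
    out = {}
    for name in params:
        vals = np.array([r.value(name) for r in results])
        out[name] = float(np.std(vals, ddof=1) / np.mean(vals)) if len(vals) > 1 else 0.0
    return out
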