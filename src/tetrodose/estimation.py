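"""Two-stage parameter estimation for the tetrofosmin PBPK model.

Stage one fits an empirical biexponential forcing function to the
venous-blood data and uses it (passed through the lung equation to
obtain an arterial input) to fit each organ sub-model in isolation
(open loop).  Stage two re-estimates the 11 structural parameters by
maximum likelihood on all tissues simultaneously in the closed-loop
model, with a separate proportional error term per tissue,
Y = F * (1 + eps),  eps ~ N(0, sigma_t^2).

The per-tissue error SDs are profiled out analytically, so the search
runs over the 11 structural parameters only (log-transformed for
positivity).  Standard errors come from the numerically differentiated
Hessian of the profile -2 log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lmfit import Model as LmModel
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d
from scipy.optimize import least_squares, minimize

from .model import build_matrix, observables, simulate_closed_loop
from .parameters import DrugParams, PhysiologyParams

#: the 11 structural parameters re-estimated in the closed-loop fit
FIT_PARAM_NAMES = (
    "kp_lung", "kp_heart", "ps_heart", "kp_kidney", "ps_kidney",
    "kp_liver", "kp_thyroid", "kp_other", "cl_renal", "cl_liver", "k_gb",
)

#: observable tissues that inform each structural parameter
_PARAM_TISSUES = {
    "kp_lung": {"lung", "blood"},
    "kp_heart": {"heart"},
    "ps_heart": {"heart"},
    "kp_kidney": {"kidney"},
    "ps_kidney": {"kidney"},
    "kp_liver": {"liver"},
    "kp_thyroid": {"thyroid"},
    "kp_other": {"blood"},
    "cl_renal": {"urine", "kidney"},
    "cl_liver": {"gi", "liver"},
    "k_gb": {"gi"},
}

_SIGMA_FLOOR = 1e-14
_F_FLOOR = 1e-10


class ScanOffsetError(ValueError):
    """The scan-midpoint lag was applied more than once."""


class FitConvergenceError(RuntimeError):
    """Optimiser failed to converge; carries the best parameters found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class ObservationDataset:
    """Per-tissue time series of percent injected dose.

    ``table`` has columns ``tissue, time_min, pct_dose`` and, once the
    scan-midpoint lag has been applied, ``offset_min``.
    """

    table: pd.DataFrame
    dose: float = 100.0
    decay_corrected: bool = True
    lag_min: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"tissue", "time_min", "pct_dose"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"observation table needs columns {sorted(required)}")
        for tissue, g in self.table.groupby("tissue"):
            t = g["time_min"].to_numpy()
            if np.any(t < 0) or np.any(np.diff(t) <= 0):
                raise ValueError(f"times for {tissue!r} must be nonnegative increasing")
        if (self.table["pct_dose"] < 0).any():
            raise ValueError("observed values must be nonnegative")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def times(self, tissue: str, offset: bool = True) -> np.ndarray:
        g = self.table[self.table["tissue"] == tissue]
        col = "offset_min" if (offset and "offset_min" in g.columns) else "time_min"
        return g[col].to_numpy(dtype=float)

    def values(self, tissue: str) -> np.ndarray:
        return self.table.loc[self.table["tissue"] == tissue, "pct_dose"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ObservationDataset":
        return cls(table=pd.read_csv(path), **kwargs)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def apply_scan_offset(dataset: ObservationDataset, lag_min: float = 10.0) -> ObservationDataset:
    """Shift every nominal time to the scan midpoint (nominal + lag).

    A single application is enforced: applying a lag to a dataset that
    already carries one raises :class:`ScanOffsetError`.
    """
    if lag_min < 0:
        raise ValueError("lag must be nonnegative")
    if dataset.lag_min is not None:
        raise ScanOffsetError(
            f"scan offset of {dataset.lag_min} min already applied")
    table = dataset.table.copy()
    table["offset_min"] = table["time_min"] + lag_min
    return replace(dataset, table=table, lag_min=lag_min)


@dataclass(frozen=True)
class ForcingFunction:
    """Empirical biexponential blood concentration C_ven(t) = c1 e^-k1 t + c2 e^-k2 t.

    Coefficients are in % dose per litre; rate constants in 1/h by
    default (``rate_unit`` = "per_hour") or 1/min.
    """

    c1: float
    c2: float
    k1: float
    k2: float
    rate_unit: str = "per_hour"

    def __post_init__(self):
        if self.c1 < 0 or self.c2 < 0 or self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("coefficients must be >= 0 and rates > 0")
        if self.rate_unit not in ("per_hour", "per_min"):
            raise ValueError("rate_unit must be 'per_hour' or 'per_min'")

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        scale = 1.0 / 60.0 if self.rate_unit == "per_hour" else 1.0
        return (self.c1 * np.exp(-self.k1 * t * scale)
                + self.c2 * np.exp(-self.k2 * t * scale))


def fit_biexponential(times_min, conc, rate_unit: str = "per_hour") -> ForcingFunction:
    """Fit C(t) = c1 e^-k1 t + c2 e^-k2 t to a blood concentration series."""
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(conc, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 blood samples for a biexponential fit")
    if np.any(y <= 0):
        raise ValueError("blood concentrations must be positive")
    scale = 1.0 / 60.0 if rate_unit == "per_hour" else 1.0
    th = t * scale

    def biexp(x, c1, k1, c2, k2):
        return c1 * np.exp(-k1 * x) + c2 * np.exp(-k2 * x)

    model = LmModel(biexp)
    # crude initialisation: terminal slope from the last points, fast phase from the first
    k_init = max(1e-3, -np.polyfit(th[-3:], np.log(y[-3:]), 1)[0])
    params = model.make_params(
        c1=dict(value=y[0] * 0.8, min=0),
        k1=dict(value=k_init, min=1e-6),
        c2=dict(value=y[0] * 0.2, min=0),
        k2=dict(value=k_init * 10, min=1e-6),
    )
    result = model.fit(y, params, x=th, weights=1.0 / np.maximum(y, _F_FLOOR))
    p = result.params
    pairs = sorted([(p["k1"].value, p["c1"].value), (p["k2"].value, p["c2"].value)])
    ff = ForcingFunction(c1=pairs[0][1], c2=pairs[1][1], k1=pairs[0][0],
                         k2=pairs[1][0], rate_unit=rate_unit)
    if not result.success:
        raise FitConvergenceError(f"biexponential fit failed: {result.message}", best=ff)
    return ff


def arterial_input(forcing: ForcingFunction, phys: PhysiologyParams,
                   kp_lung: float, t_max: float = 2880.0):
    """Derive the open-loop arterial input by passing the forcing through the lung.

    Solves the forced lung + arterial-blood equations and returns a
    callable C_art(t_min) (% dose / L).
    """
    Q = phys.flows["lung"]
    V_lung, V_art = phys.volumes["lung"], phys.volumes["art"]

    def rhs(t, y):
        a_lung, a_art = y
        out_lung = a_lung / (kp_lung * V_lung)
        return [Q * (forcing(t) - out_lung), Q * (out_lung - a_art / V_art)]

    grid = np.linspace(0.0, t_max, 2001)
    sol = solve_ivp(rhs, (0.0, t_max), [0.0, 0.0], t_eval=grid,
                    method="LSODA", rtol=1e-8, atol=1e-12)
    c_art = sol.y[1] / V_art
    return interp1d(grid, c_art, kind="cubic", bounds_error=False,
                    fill_value=(c_art[0], c_art[-1]))


def _open_loop_predict(tissue, theta, names, dataset, forcing, phys, drug, c_art):
    """Predicted open-loop observable for one tissue at its observation times."""
    V, Q = phys.volumes, phys.flows
    R = drug.blood_plasma_ratio
    par = dict(zip(names, theta))
    kp = dict(drug.kp)
    t_obs = dataset.times(tissue)
    t_end = float(t_obs.max())

    if tissue == "lung":
        k_out = Q["lung"] / (par["kp_lung"] * V["lung"])

        def rhs(t, y):
            return [Q["lung"] * forcing(t) - k_out * y[0]]
        y0 = [0.0]
        pick = lambda y, t: y[0]
    elif tissue == "heart":
        kp_h, ps = par["kp_heart"], par["ps_heart"]

        def rhs(t, y):
            av, aev = y
            ex = ps * (R * aev / (kp_h * V["heart_ev"]) - av / V["heart_v"])
            return [Q["heart"] * (c_art(t) - av / V["heart_v"]) + ex, -ex]
        y0 = [0.0, 0.0]
        pick = lambda y, t: y[0] + y[1] + V["heart_ch"] * (forcing(t) + c_art(t))
    elif tissue == "kidney" or tissue == "urine":
        kp_k, ps, cl = par["kp_kidney"], par["ps_kidney"], par["cl_renal"]

        def rhs(t, y):
            av, aev, ur = y
            ex = ps * (R * aev / (kp_k * V["kidney_ev"]) - av / V["kidney_v"])
            dv = Q["kidney"] * (c_art(t) - av / V["kidney_v"]) - cl * av / V["kidney_v"] + ex
            return [dv, -ex, cl * av / V["kidney_v"]]
        y0 = [0.0, 0.0, 0.0]
        if tissue == "kidney":
            pick = lambda y, t: y[0] + y[1]
        else:
            pick = lambda y, t: y[2]
    elif tissue in ("liver", "gi"):
        kp_l = par.get("kp_liver", drug.kp["liver"])
        cl = par.get("cl_liver", drug.cl_liver)
        kgb = par.get("k_gb", drug.k_gb)

        def rhs(t, y):
            liver, gb, gi, cont, spl, pan = y
            ca = c_art(t)
            gi_out = Q["gi"] * R * gi / (kp["gi"] * V["gi"])
            spl_out = Q["spleen"] * R * spl / (kp["spleen"] * V["spleen"])
            pan_out = Q["pancreas"] * R * pan / (kp["pancreas"] * V["pancreas"])
            bile = cl * liver / V["liver"]
            gb_out = kgb * gb / V["gb"]
            d_liver = (Q["hepatic_artery"] * ca + gi_out + spl_out + pan_out
                       - Q["liver"] * R * liver / (kp_l * V["liver"]) - bile)
            return [d_liver, bile - gb_out, Q["gi"] * ca - gi_out, gb_out,
                    Q["spleen"] * ca - spl_out, Q["pancreas"] * ca - pan_out]
        y0 = [0.0] * 6
        if tissue == "liver":
            pick = lambda y, t: y[0]
        else:
            pick = lambda y, t: y[2] + y[3]
    else:  # generic perfusion-limited tissue
        kp_t = theta[0]

        def rhs(t, y):
            return [Q[tissue] * (c_art(t) - R * y[0] / (kp_t * V[tissue]))]
        y0 = [0.0]
        pick = lambda y, t: y[0]

    sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=t_obs, method="LSODA",
                    rtol=1e-8, atol=1e-12)
    return np.array([pick(sol.y[:, i], t_obs[i]) for i in range(t_obs.size)])


# tissue -> parameters its open-loop data can inform.  The gallbladder
# emptying constant only shows up downstream, in the GI contents.  The
# liver amount depends on (Kp_liver, CL_liver) only through the total
# exit rate Q_liver*R/Kp + CL (a structural ridge), so the open-loop
# liver step holds Kp_liver at its prior and calibrates CL_liver; both
# are re-estimated in the closed loop where the blood feedback separates
# them.
_OPEN_LOOP_PARAMS = {
    "lung": ("kp_lung",),
    "heart": ("kp_heart", "ps_heart"),
    "kidney": ("kp_kidney", "ps_kidney", "cl_renal"),
    "liver": ("cl_liver",),
    "gi": ("cl_liver", "k_gb"),
}


def fit_open_loop(tissue: str, dataset: ObservationDataset, forcing: ForcingFunction,
                  phys: PhysiologyParams, drug: DrugParams,
                  model_variant: str = "perfusion", kp_lung: float | None = None,
                  init: dict | None = None) -> dict:
    """Fit one organ sub-model against the forcing-function input.

    Returns the tissue-level estimates together with diagnostics; a
    near-flat objective direction (e.g. the permeability variant on
    perfusion-limited data, where PS runs to its upper bound) is
    reported via ``diagnostics["warnings"]``.
    """
    if tissue not in dataset.tissues:
        raise ValueError(f"dataset has no tissue {tissue!r}")
    if tissue in _OPEN_LOOP_PARAMS:
        names = _OPEN_LOOP_PARAMS[tissue]
    elif model_variant == "permeability":
        names = (f"kp_{tissue}", f"ps_{tissue}")
    else:
        names = (f"kp_{tissue}",)

    y = dataset.values(tissue)
    c_art = (lambda t: forcing(t)) if tissue == "lung" else arterial_input(
        forcing, phys, kp_lung if kp_lung is not None else drug.kp["lung"],
        t_max=float(dataset.times(tissue).max()) + 1.0)

    defaults = {"kp_lung": drug.kp["lung"], "kp_heart": drug.kp["heart"],
                "ps_heart": max(drug.ps_heart, 1e-4),
                "kp_kidney": drug.kp["kidney"], "ps_kidney": max(drug.ps_kidney, 1e-4),
                "kp_liver": drug.kp["liver"], "cl_liver": max(drug.cl_liver, 1e-4),
                "k_gb": max(drug.k_gb, 1e-4), "cl_renal": max(drug.cl_renal, 1e-4)}
    x0 = np.log([(init or {}).get(n, defaults.get(n, 1.0)) for n in names])

    if tissue not in _OPEN_LOOP_PARAMS and model_variant == "permeability":
        def resid(logx):
            # generic permeability variant: vascular + extravascular sub-compartments
            kp_t, ps = np.exp(logx)
            V, Q, R = phys.volumes, phys.flows, drug.blood_plasma_ratio
            v_vas = 0.1 * V[tissue]

            def rhs(t, yv):
                av, aev = yv
                ex = ps * (R * aev / (kp_t * (V[tissue] - v_vas)) - av / v_vas)
                return [Q[tissue] * (c_art(t) - av / v_vas) + ex, -ex]
            t_obs = dataset.times(tissue)
            sol = solve_ivp(rhs, (0.0, float(t_obs.max())), [0.0, 0.0],
                            t_eval=t_obs, method="LSODA", rtol=1e-8, atol=1e-12)
            F = sol.y.sum(axis=0)
            return (y - F) / np.maximum(F, _F_FLOOR)
        ub = np.log([1e4, 1e3])
    else:
        def resid(logx):
            F = _open_loop_predict(tissue, np.exp(logx), names, dataset,
                                   forcing, phys, drug, c_art)
            return (y - F) / np.maximum(F, _F_FLOOR)
        ub = np.full(len(names), np.log(1e4))

    res = least_squares(resid, x0, bounds=(np.full(len(x0), np.log(1e-8)), ub),
                        xtol=1e-12, ftol=1e-12)
    est = dict(zip(names, np.exp(res.x)))
    warnings = []
    if np.any(res.x > ub - 1e-3):
        hit = [n for n, v, u in zip(names, res.x, ub) if v > u - 1e-3]
        warnings.append(f"parameter(s) at upper bound (flat objective direction): {hit}")
    # profile flatness: a parameter that can grow tenfold without degrading
    # the fit is practically unidentifiable (e.g. PS in the fast-exchange
    # limit, where the permeability variant collapses onto the perfusion one)
    flat = []
    for i, name in enumerate(names):
        x10 = res.x.copy()
        x10[i] = min(x10[i] + np.log(10.0), ub[i])
        try:
            c10 = 0.5 * float(np.sum(resid(x10) ** 2))
        except Exception:
            continue
        if c10 - res.cost < 1e-4:
            flat.append(name)
    if flat:
        warnings.append(f"practically non-identifiable (flat) parameters: {flat}")
    return {"tissue": tissue, "estimates": est, "cost": float(res.cost),
            "diagnostics": {"success": bool(res.success), "warnings": warnings}}


@dataclass
class FitResult:
    """Closed-loop maximum-likelihood fit output."""

    estimates: dict[str, float]
    sigmas: dict[str, float]
    m2ll: float
    n_obs: int
    converged: bool
    trace: list = field(default_factory=list)
    se: dict[str, float] | None = None
    rse_pct: dict[str, float] | None = None
    r2: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates, "sigmas": self.sigmas,
            "minus2_loglik": self.m2ll, "n_obs": self.n_obs,
            "converged": self.converged, "se": self.se,
            "rse_pct": self.rse_pct, "r2": self.r2,
            "diagnostics": self.diagnostics,
        }


def drug_with_params(base: DrugParams, estimates: dict[str, float]) -> DrugParams:
    """Insert the 11 fitted structural parameters into a DrugParams object."""
    kp = dict(base.kp)
    for name in ("lung", "heart", "kidney", "liver", "thyroid", "other"):
        key = f"kp_{name}"
        if key in estimates:
            kp[name] = estimates[key]
    return replace(
        base, kp=kp,
        ps_heart=estimates.get("ps_heart", base.ps_heart),
        ps_kidney=estimates.get("ps_kidney", base.ps_kidney),
        cl_renal=estimates.get("cl_renal", base.cl_renal),
        cl_liver=estimates.get("cl_liver", base.cl_liver),
        k_gb=estimates.get("k_gb", base.k_gb),
    )


def predict_tissues(phys: PhysiologyParams, drug: DrugParams,
                    dataset: ObservationDataset, dose: float | None = None
                    ) -> dict[str, np.ndarray]:
    """Model-predicted observables at each tissue's (offset) times."""
    dose = dataset.dose if dose is None else dose
    per_tissue = {t: dataset.times(t) for t in dataset.tissues}
    t_union = np.unique(np.concatenate([np.r_[0.0, v] for v in per_tissue.values()]))
    sim = simulate_closed_loop(phys, drug, dose=dose, t_grid=t_union)
    obs = observables(sim, phys)
    out = {}
    for tissue, t_obs in per_tissue.items():
        if tissue not in obs:
            raise ValueError(f"no model observable for tissue {tissue!r}")
        idx = np.searchsorted(t_union, t_obs)
        out[tissue] = obs[tissue][idx]
    return out


def _prepare_fit_data(dataset: ObservationDataset, tissues) -> tuple:
    """Pre-extract per-tissue times/values so the objective avoids pandas."""
    per: dict[str, tuple] = {}
    all_t = [np.array([0.0])]
    for t in tissues:
        tt = dataset.times(t)
        per[t] = (tt, dataset.values(t))
        all_t.append(tt)
    t_union = np.unique(np.concatenate(all_t))
    return t_union, {t: (tt, y, np.searchsorted(t_union, tt))
                     for t, (tt, y) in per.items()}


def _predict_fast(phys, drug, dose, t_union, per):
    sim = simulate_closed_loop(phys, drug, dose=dose, t_grid=t_union)
    obs = observables(sim, phys)
    return {t: obs[t][idx] for t, (_, _, idx) in per.items()}


def _concentrated_m2ll_fast(per, preds) -> float:
    total = 0.0
    for tissue, (_, y, _) in per.items():
        F = np.maximum(preds[tissue], _F_FLOOR)
        s2 = max(np.mean(((y - F) / F) ** 2), _SIGMA_FLOOR)
        total += y.size * (math.log(2 * math.pi * s2) + 1.0) + 2.0 * np.sum(np.log(F))
    return float(total)


def _loglik_terms(dataset, preds, tissues):
    terms = {}
    for tissue in tissues:
        y = dataset.values(tissue)
        F = np.maximum(preds[tissue], _F_FLOOR)
        terms[tissue] = (y, F)
    return terms


def minus2ll(dataset: ObservationDataset, preds: dict[str, np.ndarray],
             sigmas: dict[str, float], tissues=None) -> float:
    """Full -2 log-likelihood of the proportional-error model."""
    tissues = tissues or list(preds)
    total = 0.0
    for tissue, (y, F) in _loglik_terms(dataset, preds, tissues).items():
        s2 = max(sigmas[tissue] ** 2, _SIGMA_FLOOR)
        total += np.sum(np.log(2 * np.pi * s2 * F ** 2) + (y - F) ** 2 / (s2 * F ** 2))
    return float(total)


def profiled_sigmas(dataset: ObservationDataset, preds: dict[str, np.ndarray],
                    tissues=None) -> dict[str, float]:
    """Analytic ML estimate of each tissue's proportional error SD."""
    tissues = tissues or list(preds)
    out = {}
    for tissue, (y, F) in _loglik_terms(dataset, preds, tissues).items():
        out[tissue] = float(np.sqrt(max(np.mean(((y - F) / F) ** 2), _SIGMA_FLOOR)))
    return out


def concentrated_m2ll(dataset: ObservationDataset, preds: dict[str, np.ndarray],
                      tissues=None) -> float:
    """Profile -2LL with the per-tissue sigmas concentrated out."""
    tissues = tissues or list(preds)
    total = 0.0
    for tissue, (y, F) in _loglik_terms(dataset, preds, tissues).items():
        s2 = max(np.mean(((y - F) / F) ** 2), _SIGMA_FLOOR)
        n = y.size
        total += n * (math.log(2 * math.pi * s2) + 1.0) + 2.0 * np.sum(np.log(F))
    return float(total)


def fit_closed_loop(dataset: ObservationDataset, init: dict[str, float],
                    phys: PhysiologyParams, base_drug: DrugParams,
                    exclude_tissues=("gallbladder",), n_starts: int = 3,
                    seed: int = 0, with_se: bool = True,
                    maxiter: int = 400) -> FitResult:
    """Simultaneous maximum-likelihood fit of the 11 structural parameters.

    ``init`` supplies starting values (typically open-loop estimates)
    for the parameters in :data:`FIT_PARAM_NAMES`.  Gallbladder data are
    excluded from the objective.  Parameters whose informing tissues are
    absent from the dataset are flagged non-identifiable and held at
    their initial values.  The search uses ``n_starts`` seeded starts
    (the first at ``init``) of L-BFGS-B on log-parameters followed by a
    Nelder-Mead polish of the best candidate.
    """
    tissues = [t for t in dataset.tissues if t not in exclude_tissues]
    if len(tissues) < 1:
        raise ValueError("no usable tissues in dataset")
    fixed = [n for n in FIT_PARAM_NAMES if not (_PARAM_TISSUES[n] & set(tissues))]
    free = [n for n in FIT_PARAM_NAMES if n not in fixed]

    missing = [n for n in FIT_PARAM_NAMES if n not in init]
    if missing:
        raise ValueError(f"init missing parameters: {missing}")

    rng = np.random.default_rng(seed)
    ds_sub = replace(dataset, table=dataset.table[dataset.table["tissue"].isin(tissues)])
    t_union, per = _prepare_fit_data(ds_sub, tissues)
    trace: list[float] = []
    n_fail = 0

    def objective(logx):
        nonlocal n_fail
        if np.any(np.abs(logx) > 50):
            n_fail += 1
            return 1e12
        est = dict(zip(free, np.exp(logx)))
        full = {**init, **est}
        try:
            preds = _predict_fast(phys, drug_with_params(base_drug, full),
                                  ds_sub.dose, t_union, per)
        except Exception:
            n_fail += 1
            return 1e12
        val = _concentrated_m2ll_fast(per, preds)
        if not np.isfinite(val):
            n_fail += 1
            return 1e12
        if not trace or val < trace[-1]:
            trace.append(val)
        return val

    x_init = np.log([init[n] for n in free])
    best_x, best_f = None, np.inf
    for s in range(max(1, n_starts)):
        x0 = x_init if s == 0 else x_init + rng.normal(0.0, 0.2, size=len(free))
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-10})
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    polish = minimize(objective, best_x, method="Nelder-Mead",
                      options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-10})
    if polish.fun <= best_f:
        best_f, best_x = float(polish.fun), polish.x

    if not np.isfinite(best_f) or best_f >= 1e12:
        raise FitConvergenceError("closed-loop fit failed to find a finite optimum",
                                  best=dict(zip(free, np.exp(best_x))))

    estimates = {**{n: init[n] for n in fixed}, **dict(zip(free, np.exp(best_x)))}
    drug_hat = drug_with_params(base_drug, estimates)
    preds = predict_tissues(phys, drug_hat, ds_sub)
    sigmas = profiled_sigmas(ds_sub, preds, tissues)
    m2ll = minus2ll(ds_sub, preds, sigmas, tissues)
    obs_all = np.concatenate([ds_sub.values(t) for t in tissues])
    pred_all = np.concatenate([preds[t] for t in tissues])
    fit = FitResult(
        estimates=estimates, sigmas=sigmas, m2ll=m2ll,
        n_obs=int(obs_all.size),
        converged=bool(best_f <= objective(x_init) + 1e-9),
        trace=trace,
        r2=compute_r2(obs_all, pred_all),
        diagnostics={"non_identifiable": fixed, "tissues": tissues,
                     "objective_at_init": float(objective(x_init)),
                     "objective_at_optimum": best_f,
                     "rejected_candidates": n_fail,
                     "n_starts": n_starts, "seed": seed},
    )
    if with_se:
        compute_standard_errors(fit, ds_sub, phys, base_drug)
    return fit


def numeric_hessian(f, theta, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of a scalar function at ``theta``."""
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    h = np.maximum(np.abs(theta) * rel_step, 1e-10)
    H = np.zeros((n, n))
    f0 = f(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def compute_standard_errors(fit: FitResult, dataset: ObservationDataset,
                            phys: PhysiologyParams, base_drug: DrugParams,
                            rel_step: float = 1e-3) -> FitResult:
    """Asymptotic SEs from the numeric Hessian of the profile -2LL.

    Central second differences on the natural parameter scale; the
    covariance is 2 * H^-1.  A non-positive-definite Hessian is
    reported via ``diagnostics["hessian_warning"]`` and handled with a
    pseudo-inverse.
    """
    free = [n for n in FIT_PARAM_NAMES
            if n not in fit.diagnostics.get("non_identifiable", [])]
    tissues = fit.diagnostics.get("tissues", dataset.tissues)
    ds_sub = replace(dataset, table=dataset.table[dataset.table["tissue"].isin(tissues)])
    t_union, per = _prepare_fit_data(ds_sub, tissues)
    theta = np.array([fit.estimates[n] for n in free])

    def f(x):
        est = {**fit.estimates, **dict(zip(free, x))}
        preds = _predict_fast(phys, drug_with_params(base_drug, est),
                              ds_sub.dose, t_union, per)
        return _concentrated_m2ll_fast(per, preds)

    H = numeric_hessian(f, theta, rel_step=rel_step)
    eigvals = np.linalg.eigvalsh(H)
    warning = None
    if np.any(eigvals <= 0):
        warning = ("Hessian of -2LL not positive definite "
                   f"(min eigenvalue {eigvals.min():.3g}); pseudo-inverse used")
        cov = 2.0 * np.linalg.pinv(H)
    else:
        cov = 2.0 * np.linalg.inv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    fit.se = dict(zip(free, se))
    fit.rse_pct = {n_: 100.0 * s / fit.estimates[n_] if fit.estimates[n_] else np.inf
                   for n_, s in fit.se.items()}
    fit.diagnostics["hessian_warning"] = warning
    fit.diagnostics["se_method"] = "profile-likelihood numeric Hessian"
    return fit


def compute_r2(observed, predicted) -> float:
    """Pooled coefficient of determination, 1 - SS_res/SS_tot."""
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape:
        raise ValueError("observed and predicted must have the same shape")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant observed vector")
    return float(1.0 - np.sum((y - f) ** 2) / ss_tot)
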