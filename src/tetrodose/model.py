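"""Closed-loop whole-body PBPK ODE system for Tc99m-tetrofosmin.

The model tracks the fraction of the administered dose, A_organ(t), in
19 compartments: arterial and venous blood, lung, heart (vascular +
extravascular), brain (vascular only; the tracer does not cross the
blood-brain barrier), skeletal muscle, the hepatic system (liver,
gallbladder, GI tissue, GI contents, spleen, pancreas), kidney
(vascular + extravascular) with cumulative urine, adipose, thyroid and
a lumped "other" compartment that closes the mass balance.  All rate
equations are linear and time-invariant, so the system is dA/dt = M A
for a constant matrix M whose columns each sum to zero (mass
conservation by construction).

Time is measured in minutes throughout (flows and clearances in L/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .parameters import DrugParams, PhysiologyParams

#: state registry (order defines the rows of the state matrix)
STATES = (
    "art", "ven", "lung", "heart_v", "heart_ev", "brain_v", "muscle",
    "liver", "gb", "gi", "gi_contents", "spleen", "pancreas",
    "kidney_v", "kidney_ev", "urine", "adipose", "thyroid", "other",
)
IDX = {name: i for i, name in enumerate(STATES)}

#: tissues observable by imaging, mapped to the states they pool
OBSERVABLE_TISSUES = ("blood", "heart", "lung", "liver", "kidney", "thyroid", "gi", "urine")


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries the time of failure."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass
class SimulationResult:
    """Time grid (min), state matrix (time x 19, % of dose) and metadata."""

    t: np.ndarray
    states: np.ndarray
    dose: float
    age_label: str
    metadata: dict = field(default_factory=dict)

    def state(self, name: str) -> np.ndarray:
        return self.states[:, IDX[name]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_min, compartment, amount_pct."""
        rows = []
        for i, name in enumerate(STATES):
            rows.append(pd.DataFrame({
                "time_min": self.t, "compartment": name,
                "amount_pct": self.states[:, i],
            }))
        return pd.concat(rows, ignore_index=True)


def build_matrix(phys: PhysiologyParams, drug: DrugParams) -> np.ndarray:
    """Assemble the 19x19 rate matrix M with dA/dt = M A.

    Every printed organ equation is implemented verbatim: perfusion
    limited tissues leave via R*A/(Kp*V) while the lung and the vascular
    sub-compartments of heart and kidney leave via A/V, the hepatic
    system routes biliary excretion through the gallbladder into the GI
    contents with effective rate K_gb/V_gb, and renal clearance drains
    the kidney vascular space into cumulative urine.
    """
    phys.validate()
    drug.validate()
    V, Q, kp = phys.volumes, phys.flows, drug.kp
    R = drug.blood_plasma_ratio
    M = np.zeros((len(STATES), len(STATES)))

    def add(dst: str | None, src_state: str, coeff: float) -> None:
        # flux coeff * A[src_state] leaves src_state and enters dst (None = external)
        M[IDX[src_state], IDX[src_state]] -= coeff
        if dst is not None:
            M[IDX[dst], IDX[src_state]] += coeff

    def move(dst: str, src: str, coeff: float) -> None:
        M[IDX[dst], IDX[src]] += coeff
        M[IDX[src], IDX[src]] -= coeff

    c_art = 1.0 / V["art"]
    # lung: fed by venous blood, drains (without R) into arterial blood
    move("lung", "ven", Q["lung"] / V["ven"])
    move("art", "lung", Q["lung"] / (kp["lung"] * V["lung"]))

    # perfusion-limited tissues fed from arterial blood, returning via R*A/(Kp*V)
    for organ, ret in (("muscle", "ven"), ("adipose", "ven"), ("thyroid", "ven"),
                       ("other", "ven"), ("spleen", "liver"), ("pancreas", "liver"),
                       ("gi", "liver")):
        move(organ, "art", Q[organ] * c_art)
        move(ret, organ, Q[organ] * R / (kp[organ] * V[organ]))

    # heart: permeability limited, vascular sub-compartment exchanges with blood
    move("heart_v", "art", Q["heart"] * c_art)
    move("ven", "heart_v", Q["heart"] / V["heart_v"])
    move("heart_v", "heart_ev", drug.ps_heart * R / (kp["heart"] * V["heart_ev"]))
    move("heart_ev", "heart_v", drug.ps_heart / V["heart_v"])

    # brain: vascular only (PS_brain = 0, no extravascular uptake)
    move("brain_v", "art", Q["brain"] * c_art)
    move("ven", "brain_v", Q["brain"] / V["brain_v"])

    # hepatic system: arterial inflow, biliary excretion, venous outflow
    move("liver", "art", Q["hepatic_artery"] * c_art)
    move("ven", "liver", Q["liver"] * R / (kp["liver"] * V["liver"]))
    move("gb", "liver", drug.cl_liver / V["liver"])
    move("gi_contents", "gb", drug.k_gb / V["gb"])

    # kidney: permeability limited with renal clearance to urine
    move("kidney_v", "art", Q["kidney"] * c_art)
    move("ven", "kidney_v", Q["kidney"] / V["kidney_v"])
    move("kidney_v", "kidney_ev", drug.ps_kidney * R / (kp["kidney"] * V["kidney_ev"]))
    move("kidney_ev", "kidney_v", drug.ps_kidney / V["kidney_v"])
    move("urine", "kidney_v", drug.cl_renal / V["kidney_v"])

    assert abs(M.sum(axis=0)).max() < 1e-12 * max(1.0, abs(M).max())
    return M


def build_rhs(phys: PhysiologyParams, drug: DrugParams):
    """Return f(t, A) -> dA/dt for the closed-loop system."""
    M = build_matrix(phys, drug)
    return lambda t, y: M @ y


def initial_state(dose: float) -> np.ndarray:
    """IV bolus: the full dose starts in venous blood."""
    y0 = np.zeros(len(STATES))
    y0[IDX["ven"]] = dose
    return y0


def _propagate_expm(M: np.ndarray, y0: np.ndarray, t: np.ndarray) -> np.ndarray:
    out = np.empty((len(t), len(y0)))
    y = y0.copy()
    t_prev = 0.0
    cache: dict[float, np.ndarray] = {}
    for i, ti in enumerate(t):
        dt = ti - t_prev
        if dt > 0:
            key = round(dt, 12)
            P = cache.get(key)
            if P is None:
                P = expm(M * dt)
                cache[key] = P
            y = P @ y
        out[i] = y
        t_prev = ti
    return out


def simulate_closed_loop(phys: PhysiologyParams, drug: DrugParams,
                         dose: float = 100.0, t_grid=None,
                         rtol: float = 1e-8, atol: float = 1e-10,
                         method: str = "expm") -> SimulationResult:
    """Simulate the closed-loop model after an IV bolus.

    ``method`` is either ``"expm"`` (exact matrix-exponential
    propagation, exploiting linearity; the default) or any stiff-capable
    ``solve_ivp`` method name such as ``"LSODA"`` or ``"BDF"``.
    ``t_grid`` is in minutes and defaults to a dense 48 h grid.
    """
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    if t_grid is None:
        t_grid = np.linspace(0.0, 2880.0, 577)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be nondecreasing")

    M = build_matrix(phys, drug)
    y0 = initial_state(dose)
    if method == "expm":
        states = _propagate_expm(M, y0, t_grid)
    else:
        sol = solve_ivp(lambda t, y: M @ y, (0.0, float(t_grid[-1])), y0,
                        method=method, t_eval=t_grid, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"integrator {method} failed: {sol.message}",
                t_fail=float(sol.t[-1]) if sol.t.size else 0.0)
        states = sol.y.T
    return SimulationResult(
        t=t_grid, states=states, dose=dose, age_label=phys.age_label,
        metadata={"method": method, "rtol": rtol, "atol": atol,
                  "drug": drug.name, "age_label": phys.age_label},
    )


def observables(sim: SimulationResult, phys: PhysiologyParams) -> dict[str, np.ndarray]:
    """Map states to the imaging observables, as % of dose.

    blood = venous amount; heart = vascular + extravascular + chamber
    blood; kidney = vascular + extravascular; GI = tissue + contents;
    urine is cumulative.
    """
    V = phys.volumes
    chamber = V["heart_ch"] * (sim.state("ven") / V["ven"] + sim.state("art") / V["art"])
    return {
        "blood": sim.state("ven"),
        "heart": sim.state("heart_v") + sim.state("heart_ev") + chamber,
        "lung": sim.state("lung"),
        "liver": sim.state("liver"),
        "kidney": sim.state("kidney_v") + sim.state("kidney_ev"),
        "thyroid": sim.state("thyroid"),
        "gi": sim.state("gi") + sim.state("gi_contents"),
        "urine": sim.state("urine"),
    }


def mass_balance_report(sim: SimulationResult) -> float:
    """Maximum over time of |sum of states - dose| / dose."""
    if sim.dose == 0:
        return float(np.abs(sim.states.sum(axis=1)).max())
    return float(np.abs(sim.states.sum(axis=1) - sim.dose).max() / sim.dose)
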