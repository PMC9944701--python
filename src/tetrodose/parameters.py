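"""Physiology and drug parameters for the tetrofosmin PBPK model.

Holds validated physiological parameter sets (organ volumes and blood
flows) for an adult and for children of 1, 5, 10 and 15 years, the drug
specific parameters of Tc99m-tetrofosmin, mechanistic prediction of
tissue-to-plasma partition coefficients (Kp) for tissues without imaging
data, and allometric scaling of permeability and clearance parameters
from the adult to a paediatric physiology.

Bundled physiology tables are compiled from standard reference-man /
reference-child anatomy and haemodynamics; they can be overridden with a
user CSV of the same layout (columns ``organ, volume_L, flow_L_per_min``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

AGE_LABELS = ("adult", "15y", "10y", "5y", "1y")

#: organs whose venous return must add up to the cardiac output
VENOUS_RETURN_ORGANS = ("muscle", "heart", "brain", "liver", "thyroid", "adipose", "kidney", "other")
#: inflows feeding the liver (hepatic artery plus splanchnic outflows)
HEPATIC_INFLOWS = ("hepatic_artery", "gi", "spleen", "pancreas")

_VOLUME_KEYS = (
    "art", "ven", "lung", "heart_v", "heart_ev", "heart_ch", "brain_v",
    "muscle", "liver", "gb", "gi", "spleen", "pancreas", "kidney_v",
    "kidney_ev", "adipose", "thyroid", "other",
)
_FLOW_KEYS = (
    "lung", "heart", "brain", "muscle", "liver", "hepatic_artery", "gi",
    "spleen", "pancreas", "kidney", "adipose", "thyroid", "other",
)

# CSV row name -> (volume key, flow key)
_CSV_MAP = {
    "arterial_blood": ("art", None),
    "venous_blood": ("ven", None),
    "lung": ("lung", "lung"),
    "heart_vascular": ("heart_v", "heart"),
    "heart_extravascular": ("heart_ev", None),
    "heart_chambers": ("heart_ch", None),
    "brain_vascular": ("brain_v", "brain"),
    "muscle": ("muscle", "muscle"),
    "liver": ("liver", "liver"),
    "hepatic_artery": (None, "hepatic_artery"),
    "gallbladder": ("gb", None),
    "gi": ("gi", "gi"),
    "spleen": ("spleen", "spleen"),
    "pancreas": ("pancreas", "pancreas"),
    "kidney_vascular": ("kidney_v", "kidney"),
    "kidney_extravascular": ("kidney_ev", None),
    "adipose": ("adipose", "adipose"),
    "thyroid": ("thyroid", "thyroid"),
}

#: assumed whole-body density used to close the "other" volume (kg/L)
BODY_DENSITY_KG_PER_L = 1.05


class PhysiologyError(ValueError):
    """Base class for physiology table validation failures."""


class MissingOrganError(PhysiologyError):
    """A required organ volume or flow is absent from the source table."""


class NonPositiveValueError(PhysiologyError):
    """An organ volume or flow is zero or negative."""


class FlowBalanceError(PhysiologyError):
    """Blood-flow mass balance is violated."""


class UnsupportedCompoundTypeError(ValueError):
    """Partition-coefficient prediction requested for an unhandled ionisation class."""


@dataclass(frozen=True)
class PhysiologyParams:
    """Organ volumes (L) and regional blood flows (L/min) for one age.

    ``volumes`` and ``flows`` are keyed by the internal organ registry
    (see :data:`_VOLUME_KEYS` / :data:`_FLOW_KEYS`).  The lumped "other"
    compartment is closed by balance: its flow is the cardiac output
    minus all named venous returns and its volume is the whole-body
    volume minus all named volumes.
    """

    age_label: str
    body_weight: float  # kg
    volumes: dict[str, float]
    flows: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def volume(self, key: str) -> float:
        return self.volumes[key]

    def flow(self, key: str) -> float:
        return self.flows[key]

    @property
    def cardiac_output(self) -> float:
        return self.flows["lung"]

    def validate(self, rel_tol: float = 1e-6) -> None:
        """Check positivity and the two flow balances; raise on violation."""
        problems = []
        for k in _VOLUME_KEYS:
            if k not in self.volumes:
                raise MissingOrganError(f"V_{k}")
            if not self.volumes[k] > 0:
                problems.append(f"V_{k} = {self.volumes[k]!r} not positive")
        for k in _FLOW_KEYS:
            if k not in self.flows:
                raise MissingOrganError(f"Q_{k}")
            if not self.flows[k] > 0:
                problems.append(f"Q_{k} = {self.flows[k]!r} not positive")
        if problems:
            raise NonPositiveValueError("; ".join(problems))
        co = self.flows["lung"]
        venous = sum(self.flows[k] for k in VENOUS_RETURN_ORGANS)
        if abs(venous - co) > rel_tol * co:
            raise FlowBalanceError(
                f"venous return {venous:.6g} != cardiac output {co:.6g}"
            )
        hep = sum(self.flows[k] for k in HEPATIC_INFLOWS)
        if abs(hep - self.flows["liver"]) > rel_tol * self.flows["liver"]:
            raise FlowBalanceError(
                f"hepatic inflow {hep:.6g} != liver outflow {self.flows['liver']:.6g}"
            )


@dataclass(frozen=True)
class DrugParams:
    """Drug-specific model parameters of Tc99m-tetrofosmin.

    ``kp`` maps tissue -> tissue:plasma partition coefficient.  PS are
    permeability-surface products (L/min) of the permeability-limited
    organs, CL are clearances (L/min), ``k_gb`` the gallbladder emptying
    rate constant (1/min) and ``blood_plasma_ratio`` the fixed whole
    blood : plasma concentration ratio R.
    """

    kp: dict[str, float]
    ps_heart: float
    ps_kidney: float
    cl_renal: float
    cl_liver: float
    k_gb: float
    blood_plasma_ratio: float = 0.8
    logp: float = 1.14
    pka: float = 8.3
    fu: float = 0.7353
    molecular_weight: float = 898.86
    compound_type: str = "monoprotic base"
    name: str = "Tc99m-tetrofosmin"
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        bad = [t for t, v in self.kp.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive Kp for: {', '.join(bad)}")
        for label, v in (("PS_heart", self.ps_heart), ("PS_kidney", self.ps_kidney),
                         ("CL_renal", self.cl_renal), ("CL_liver", self.cl_liver),
                         ("K_gb", self.k_gb)):
            if v < 0:
                raise ValueError(f"{label} must be >= 0, got {v}")
        if not 0 < self.fu <= 1:
            raise ValueError(f"fu must be in (0, 1], got {self.fu}")
        if not self.blood_plasma_ratio > 0:
            raise ValueError("blood:plasma ratio must be positive")


@dataclass(frozen=True)
class TissueComposition:
    """Fractional tissue composition used by the mechanistic Kp method.

    Per tissue: fractional extracellular/intracellular water, neutral
    lipid and neutral phospholipid (all v/v) and acidic phospholipid
    content (mg/g).  Plasma and blood-cell compositions plus haematocrit
    and compartment pH values complete the inputs.
    """

    tissues: pd.DataFrame  # indexed by tissue name
    hematocrit: float = 0.45
    ph_plasma: float = 7.4
    ph_intracellular: float = 7.0
    ph_blood_cells: float = 7.22
    edition: str = "default"

    def row(self, tissue: str) -> pd.Series:
        if tissue not in self.tissues.index:
            raise KeyError(f"no composition data for tissue {tissue!r}")
        return self.tissues.loc[tissue]


def _data_path(name: str):
    return resources.files("tetrodose.data").joinpath(name)


def load_physiology(age_label: str, source_table=None) -> PhysiologyParams:
    """Load and validate the physiology for one age.

    ``source_table`` may be a path to a CSV with columns
    ``organ, volume_L, flow_L_per_min`` or a DataFrame of that layout; by
    default the bundled table for ``age_label`` is used.  The lumped
    "other" compartment is closed by balance and recorded in metadata.
    """
    if age_label not in AGE_LABELS:
        raise ValueError(f"age_label must be one of {AGE_LABELS}, got {age_label!r}")
    if source_table is None:
        with resources.as_file(_data_path(f"physiology_{age_label}.csv")) as p:
            table = pd.read_csv(p)
    elif isinstance(source_table, (str, Path)):
        table = pd.read_csv(source_table)
    else:
        table = pd.DataFrame(source_table)

    table = table.set_index("organ")
    if "body_weight" not in table.index:
        raise MissingOrganError("body_weight")
    bw = float(table.loc["body_weight", "volume_L"])

    volumes: dict[str, float] = {}
    flows: dict[str, float] = {}
    for organ, (vkey, fkey) in _CSV_MAP.items():
        if organ not in table.index:
            missing = f"V_{vkey}" if vkey else f"Q_{fkey}"
            raise MissingOrganError(missing)
        row = table.loc[organ]
        if vkey is not None:
            v = row["volume_L"]
            if pd.isna(v):
                raise MissingOrganError(f"V_{vkey}")
            volumes[vkey] = float(v)
        if fkey is not None:
            q = row["flow_L_per_min"]
            if pd.isna(q):
                raise MissingOrganError(f"Q_{fkey}")
            flows[fkey] = float(q)

    # close the lumped compartment by balance
    q_named = sum(flows[k] for k in VENOUS_RETURN_ORGANS if k != "other")
    flows["other"] = flows["lung"] - q_named
    v_named = sum(volumes.values())
    volumes["other"] = bw / BODY_DENSITY_KG_PER_L - v_named
    if flows["other"] <= 0:
        raise FlowBalanceError(
            f"named venous returns ({q_named:.4g} L/min) exceed cardiac output "
            f"({flows['lung']:.4g} L/min); Q_other would be non-positive"
        )
    if volumes["other"] <= 0:
        raise NonPositiveValueError("V_other closed by balance is non-positive")

    phys = PhysiologyParams(
        age_label=age_label,
        body_weight=bw,
        volumes=volumes,
        flows=flows,
        metadata={"Q_other_closed_by_balance": flows["other"],
                  "V_other_closed_by_balance": volumes["other"],
                  "body_density_kg_per_L": BODY_DENSITY_KG_PER_L},
    )
    phys.validate()
    return phys


def load_drug_params(source=None) -> DrugParams:
    """Load drug parameters from a JSON document (bundled defaults otherwise)."""
    if source is None:
        with resources.as_file(_data_path("drug_tetrofosmin.json")) as p:
            doc = json.loads(Path(p).read_text())
    elif isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
    else:
        doc = dict(source)
    drug = DrugParams(
        kp={k: float(v) for k, v in doc["kp"].items()},
        ps_heart=float(doc["ps_heart"]),
        ps_kidney=float(doc["ps_kidney"]),
        cl_renal=float(doc["cl_renal"]),
        cl_liver=float(doc["cl_liver"]),
        k_gb=float(doc["k_gb"]),
        blood_plasma_ratio=float(doc.get("blood_plasma_ratio", 0.8)),
        logp=float(doc.get("logp", 1.14)),
        pka=float(doc.get("pka", 8.3)),
        fu=float(doc.get("fu", 0.7353)),
        molecular_weight=float(doc.get("molecular_weight", 898.86)),
        compound_type=doc.get("compound_type", "monoprotic base"),
        name=doc.get("name", "drug"),
    )
    drug.validate()
    return drug


def load_tissue_composition(source=None, edition: str = "default") -> TissueComposition:
    if source is None:
        with resources.as_file(_data_path("tissue_composition.csv")) as p:
            df = pd.read_csv(p).set_index("tissue")
    elif isinstance(source, (str, Path)):
        df = pd.read_csv(source).set_index("tissue")
    else:
        df = pd.DataFrame(source).set_index("tissue")
    return TissueComposition(tissues=df, edition=edition)


def rodgers_rowland_kp(drug: DrugParams, comp: TissueComposition | None = None,
                       tissue: str = "muscle") -> float:
    """Predict the tissue:plasma partition coefficient of a base mechanistically.

    For a moderate-to-strong monoprotic base (pKa above plasma pH) the
    unbound tissue:plasma water partition coefficient is built from
    extracellular water, pH-partitioned intracellular water, neutral
    lipid/phospholipid partitioning, and electrostatic association with
    intracellular acidic phospholipids.  The acidic-phospholipid
    association constant is back-calculated from the blood cell : plasma
    partitioning implied by the blood:plasma ratio and the haematocrit;
    when the implied affinity is negative (blood-cell uptake already
    over-explained by water and lipid terms) it is clamped at zero,
    since a binding constant cannot be negative.

    Returns Kp = Kpu * fu (tissue:plasma, referenced to total plasma
    concentration), which is the scale on which the model's fixed Kp
    inputs are given.
    """
    if "base" not in drug.compound_type.lower() or drug.pka <= 7.0:
        raise UnsupportedCompoundTypeError(
            f"only moderate-to-strong monoprotic bases are supported, "
            f"got {drug.compound_type!r} with pKa {drug.pka}"
        )
    if comp is None:
        comp = load_tissue_composition()
    t = comp.row(tissue)
    bc = comp.row("blood_cells")
    P = 10.0 ** drug.logp
    Y = 1.0 + 10.0 ** (drug.pka - comp.ph_plasma)
    X = 1.0 + 10.0 ** (drug.pka - comp.ph_intracellular)
    X_bc = 1.0 + 10.0 ** (drug.pka - comp.ph_blood_cells)

    kpu_bc = (drug.blood_plasma_ratio - (1.0 - comp.hematocrit)) / (
        comp.hematocrit * drug.fu
    )
    lipid_bc = (P * bc["f_neutral_lipid"]
                + (0.3 * P + 0.7) * bc["f_neutral_phospholipid"]) / Y
    ka = (kpu_bc - X_bc / Y * bc["f_intracellular_water"] - lipid_bc) * Y / (
        bc["acidic_phospholipid_mg_g"] * 10.0 ** (drug.pka - comp.ph_blood_cells)
    )
    ka_clamped = max(float(ka), 0.0)

    kpu = (
        t["f_extracellular_water"]
        + X / Y * t["f_intracellular_water"]
        + (P * t["f_neutral_lipid"] + (0.3 * P + 0.7) * t["f_neutral_phospholipid"]) / Y
        + ka_clamped * t["acidic_phospholipid_mg_g"]
        * 10.0 ** (drug.pka - comp.ph_intracellular) / Y
    )
    return float(kpu * drug.fu)


def predicted_kp_table(drug: DrugParams | None = None,
                       comp: TissueComposition | None = None) -> dict[str, float]:
    """Mechanistic Kp predictions for the tissues lacking imaging data."""
    if drug is None:
        drug = load_drug_params()
    if comp is None:
        comp = load_tissue_composition()
    return {t: rodgers_rowland_kp(drug, comp, t)
            for t in ("muscle", "adipose", "gi", "spleen", "pancreas")}


def scale_drug_params(adult_drug: DrugParams, adult_phys: PhysiologyParams,
                      child_phys: PhysiologyParams, a_ps: float = 2.0 / 3.0,
                      a_cl: float = 3.0 / 4.0) -> DrugParams:
    """Scale adult drug parameters to a paediatric physiology.

    Partition coefficients are kept constant across ages.  PS parameters
    scale with the (total) organ-volume ratio to the power ``a_ps``
    (default 2/3, surface-area argument) and clearances with the ratio
    to the power ``a_cl`` (default 3/4, metabolic allometry).  The
    gallbladder emptying rate constant is a first-order rate, not a
    clearance, and is left unscaled.
    """
    if not (0 < a_ps <= 1 and 0 < a_cl <= 1):
        raise ValueError("allometric exponents must lie in (0, 1]")

    def ratio(*keys: str) -> float:
        adult_v = sum(adult_phys.volumes[k] for k in keys)
        if adult_v <= 0:
            raise NonPositiveValueError(f"adult volume for {'+'.join(keys)} is zero")
        return sum(child_phys.volumes[k] for k in keys) / adult_v

    heart_r = ratio("heart_v", "heart_ev")
    kidney_r = ratio("kidney_v", "kidney_ev")
    liver_r = ratio("liver")
    scaled = replace(
        adult_drug,
        ps_heart=adult_drug.ps_heart * heart_r ** a_ps,
        ps_kidney=adult_drug.ps_kidney * kidney_r ** a_ps,
        cl_renal=adult_drug.cl_renal * kidney_r ** a_cl,
        cl_liver=adult_drug.cl_liver * liver_r ** a_cl,
        metadata={**adult_drug.metadata,
                  "scaled_from": adult_phys.age_label,
                  "scaled_to": child_phys.age_label,
                  "a_ps": a_ps, "a_cl": a_cl,
                  "volume_ratio_interpretation": "total organ volume"},
    )
    scaled.validate()
    return scaled
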