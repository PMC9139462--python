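"""Configuration, dataset CSV round-trips, SBML and PEtab export.

CSV is the canonical tabular interchange (fixed headers, one record per
row).  The model is exported as an SBML Level 3 document written
directly as XML, and as a PEtab v1 problem (model plus observables,
measurements, conditions and parameters tables with a problem YAML);
:func:`validate_petab` performs the structural cross-checks a PEtab
linter enforces (required files/columns, referential integrity between
tables).

Condition inputs are encoded as SBML parameters (ligand inputs ``u_*``,
per-dimer inhibition factors ``inh_*``, antibody phosphorylation and
lumretuzumab degradation rates) that the PEtab condition table
overrides per condition; the exported kinetic laws describe the
ligand-on regime of the two-phase protocol.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import (
    ANTIBODY_PHOS_DRUGS,
    DIMER_COMPOSITION,
    DIMERS,
    DRUG_TARGETS,
    LIGAND_DIMER_COMPAT,
    ReactionNetwork,
    drug_inhibition_factor,
)
from .synthetic import (
    TIMECOURSE_COLUMNS,
    VIABILITY_COLUMNS,
    DesignMatrix,
    TimeCourseDataset,
    ViabilityDataset,
)

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "read_params_yaml",
    "write_params_yaml",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_viability_csv",
    "write_viability_csv",
    "export_sbml",
    "export_petab",
    "validate_petab",
    "export_model",
]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully-populated run settings (see ``default_config.yaml``)."""

    seed: int = 0
    output_dir: str = "results"
    cell_lines: list = field(default_factory=lambda: ["MCF7"])
    noise_sd: float = 0.05
    replicates: int = 3
    bounds_lower: float = -5.0
    bounds_upper: float = 3.0
    n_starts: int = 3
    maxiter: int = 200
    ftol: float = 1e-9
    profile_delta: float = 3.84
    profile_max_steps: int = 100
    lambda_min: float = 1e-2
    lambda_max: float = 1e3
    n_lambda: int = 20
    fit_free_parameters: list = field(default_factory=list)
    l1_candidates: list = field(default_factory=list)
    regression_truth: dict = field(default_factory=lambda: {
        "alpha1": -0.8, "beta1": 0.005, "beta2": 0.004})

    @property
    def lambda_grid(self):
        return np.logspace(np.log10(self.lambda_min),
                           np.log10(self.lambda_max), self.n_lambda)


def _default_config_text() -> str:
    return (importlib.resources.files("erbbsig") / "default_config.yaml"
            ).read_text()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration (package default when no path)."""
    text = Path(path).read_text() if path else _default_config_text()
    raw = yaml.safe_load(text) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonicalized configuration."""
    blob = yaml.safe_dump(
        {k: getattr(cfg, k) for k in sorted(RunConfig.__dataclass_fields__)},
        sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_params_yaml(params: dict, path) -> None:
    """Save a dynamic-parameter set as YAML (name -> positive value)."""
    Path(path).write_text(yaml.safe_dump(
        {k: float(v) for k, v in sorted(params.items())}, sort_keys=True))


def read_params_yaml(path) -> dict:
    """Load a dynamic-parameter set; values must be positive numbers."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for k, v in raw.items():
        v = float(v)
        if v < 0:
            raise ValueError(f"parameter {k!r} must be >= 0, got {v}")
        out[str(k)] = v
    return out


# ---------------------------------------------------------------------------
# dataset CSV round-trips
# ---------------------------------------------------------------------------


def _read_checked(path, columns, numeric) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_lines = []
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & (df[col] != "")]
        # header is line 1, data starts at line 2
        bad_lines.extend((int(i) + 2, col) for i in bad)
        df[col] = converted
    if bad_lines:
        desc = ", ".join(f"line {ln} ({col})" for ln, col in bad_lines[:10])
        raise ValueError(f"{path}: malformed numeric values at {desc}")
    return df


def read_timecourse_csv(path) -> TimeCourseDataset:
    df = _read_checked(path, TIMECOURSE_COLUMNS, numeric=("time", "value"))
    if len(df) == 0:
        df = pd.DataFrame(columns=TIMECOURSE_COLUMNS)
    return TimeCourseDataset(df)


def write_timecourse_csv(dataset: TimeCourseDataset, path) -> None:
    dataset.data.to_csv(path, index=False)


def read_viability_csv(path) -> ViabilityDataset:
    df = _read_checked(path, VIABILITY_COLUMNS, numeric=("value",))
    if len(df) == 0:
        df = pd.DataFrame(columns=VIABILITY_COLUMNS)
    return ViabilityDataset(df)


def write_viability_csv(dataset: ViabilityDataset, path) -> None:
    dataset.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SBML export
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _mathml_times(factors: list[str]) -> ET.Element:
    math = ET.Element(f"{{{_MATHML_NS}}}math")
    def ci(tag):
        el = ET.Element(f"{{{_MATHML_NS}}}ci")
        el.text = f" {tag} "
        return el
    def build(items):
        if len(items) == 1:
            return ci(items[0])
        ap = ET.Element(f"{{{_MATHML_NS}}}apply")
        ap.append(ET.Element(f"{{{_MATHML_NS}}}times"))
        for it in items:
            ap.append(ci(it))
        return ap
    math.append(build(factors))
    return math


def _mathml_group_b(short: str) -> ET.Element:
    """(sum_lig u_lig * dim_<short>_lig) * inh_<short> * educts..."""
    math = ET.Element(f"{{{_MATHML_NS}}}math")
    def ci(tag):
        el = ET.Element(f"{{{_MATHML_NS}}}ci")
        el.text = f" {tag} "
        return el
    top = ET.Element(f"{{{_MATHML_NS}}}apply")
    top.append(ET.Element(f"{{{_MATHML_NS}}}times"))
    plus = ET.Element(f"{{{_MATHML_NS}}}apply")
    plus.append(ET.Element(f"{{{_MATHML_NS}}}plus"))
    for lig in LIGAND_DIMER_COMPAT[f"D_{short}"]:
        term = ET.Element(f"{{{_MATHML_NS}}}apply")
        term.append(ET.Element(f"{{{_MATHML_NS}}}times"))
        term.append(ci(f"u_{lig}"))
        term.append(ci(f"dim_{short}_{lig}"))
        plus.append(term)
    top.append(plus)
    top.append(ci(f"inh_{short}"))
    comp = DIMER_COMPOSITION[f"D_{short}"]
    for rec, m in comp.items():
        for _ in range(m):
            top.append(ci(rec))
    math.append(top)
    return math


def export_sbml(
    network: ReactionNetwork,
    params: dict[str, float],
    path,
) -> None:
    """Write the network as an SBML Level 3 Version 2 document.

    All 22 species live in one compartment; every dynamic parameter plus
    the condition-input parameters (``u_<ligand>``, ``inh_<dimer>``,
    effective antibody-phosphorylation and lumretuzumab-degradation
    rates) become global parameters referenced by the kinetic laws.
    """
    network.validate()
    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("math", _MATHML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{_SBML_NS}}}model",
                          {"id": "erbb_signaling", "name": "ERBB signaling"})
    lo_comp = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(lo_comp, f"{{{_SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true",
                   "spatialDimensions": "3"})
    lo_sp = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for sp in network.species:
        ET.SubElement(lo_sp, f"{{{_SBML_NS}}}species", {
            "id": sp, "compartment": "cell", "initialConcentration": "0",
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
            "constant": "false"})
    lo_par = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")

    def add_param(pid, value, constant=True):
        ET.SubElement(lo_par, f"{{{_SBML_NS}}}parameter", {
            "id": pid, "value": repr(float(value)),
            "constant": "true" if constant else "false"})

    for name in network.parameters:
        add_param(name, params.get(name, 0.0))
    for lig in ("EGF", "BTC", "TGFa", "NRG1"):
        add_param(f"u_{lig}", 0.0)
    for d in DIMERS:
        add_param(f"inh_{d.removeprefix('D_')}", 1.0)
    for rec in ("EGFR", "ERBB2", "ERBB3"):
        add_param(f"abphos_{rec}_eff", 0.0)
    add_param("lumdeg_eff", 0.0)

    lo_rxn = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rx = ET.SubElement(lo_rxn, f"{{{_SBML_NS}}}reaction",
                           {"id": r.name, "reversible": "false"})
        if r.educts:
            lo = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
            for sp, m in r.educts.items():
                ET.SubElement(lo, f"{{{_SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(m),
                               "constant": "true"})
        if r.products:
            lo = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
            for sp, m in r.products.items():
                ET.SubElement(lo, f"{{{_SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(m),
                               "constant": "true"})
        if r.activator_pool:
            lo = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfModifiers")
            for sp in r.activator_pool:
                ET.SubElement(lo, f"{{{_SBML_NS}}}modifierSpeciesReference",
                              {"species": sp})
        law = ET.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        law.append(_kinetic_law_math(r))
    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")


def _kinetic_law_math(r) -> ET.Element:
    educts = [sp for sp, m in r.educts.items() for _ in range(m)]
    if r.group == "B":
        return _mathml_group_b(r.name.removeprefix("lig_dim_"))
    if r.group == "C":
        short = r.name.removeprefix("bas_dim_")
        return _mathml_times([r.rate_constant, f"inh_{short}"] + educts)
    if r.group == "E":
        rec = r.name.removeprefix("abphos_")
        return _mathml_times([f"abphos_{rec}_eff"] + educts)
    if r.group == "G":
        return _mathml_times(["lumdeg_eff"] + educts)
    if r.activator_pool:
        # pooled activation: k * cRAF * (D_EE + D_E2 + D_E3 + D_23)
        math = ET.Element(f"{{{_MATHML_NS}}}math")
        def ci(tag):
            el = ET.Element(f"{{{_MATHML_NS}}}ci")
            el.text = f" {tag} "
            return el
        top = ET.Element(f"{{{_MATHML_NS}}}apply")
        top.append(ET.Element(f"{{{_MATHML_NS}}}times"))
        top.append(ci(r.rate_constant))
        for sp in educts:
            top.append(ci(sp))
        plus = ET.Element(f"{{{_MATHML_NS}}}apply")
        plus.append(ET.Element(f"{{{_MATHML_NS}}}plus"))
        for sp in r.activator_pool:
            plus.append(ci(sp))
        top.append(plus)
        math.append(top)
        return math
    return _mathml_times([r.rate_constant] + educts)


def count_sbml_entities(path) -> tuple[int, int]:
    """(n_species, n_reactions) of an SBML file, by re-parsing."""
    root = ET.parse(path).getroot()
    sp = root.findall(f".//{{{_SBML_NS}}}listOfSpecies/{{{_SBML_NS}}}species")
    rx = root.findall(f".//{{{_SBML_NS}}}listOfReactions/{{{_SBML_NS}}}reaction")
    return len(sp), len(rx)


# ---------------------------------------------------------------------------
# PEtab export
# ---------------------------------------------------------------------------


def _condition_id(cond) -> str:
    drugs = "_".join(cond.drugs) if cond.drugs else "control"
    return f"{cond.cell_line}__{cond.ligand}__{drugs}".replace("-", "_")


def export_petab(
    network: ReactionNetwork,
    params: dict[str, float],
    obs_map,
    design: DesignMatrix,
    dataset: TimeCourseDataset | None,
    out_dir,
) -> dict[str, Path]:
    """Write a PEtab v1 problem: SBML model, observables, conditions,
    measurements and parameters tables plus the problem YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sbml_path = out / "model.xml"
    export_sbml(network, params, sbml_path)

    # observables: log10-transformed sums with per-observable scale/offset
    obs_rows = []
    for o in obs_map.observables:
        total = " + ".join(
            f"{w:g} * {sp}" if w != 1 else sp
            for sp, w in obs_map.states[o].items())
        obs_rows.append({
            "observableId": f"obs_{o}",
            "observableFormula": f"{obs_map.scale[o]:g} * ({total}) "
                                 f"+ {obs_map.offset[o]:g}",
            "observableTransformation": "log10",
            "noiseFormula": obs_map.sigma[o],
            "noiseDistribution": "normal",
        })
    obs_df = pd.DataFrame(obs_rows)

    cond_rows = []
    for cond in design.conditions:
        row = {"conditionId": _condition_id(cond)}
        for lig in ("EGF", "BTC", "TGFa", "NRG1"):
            row[f"u_{lig}"] = 1.0 if cond.ligand == lig else 0.0
        for d in DIMERS:
            short = d.removeprefix("D_")
            ks = [params[f"k_{dr}"] for dr in cond.drugs
                  if DRUG_TARGETS[dr] in DIMER_COMPOSITION[d]]
            row[f"inh_{short}"] = drug_inhibition_factor(ks)
        ab = [dr for dr in cond.drugs if dr in ANTIBODY_PHOS_DRUGS]
        for rec in ("EGFR", "ERBB2", "ERBB3"):
            row[f"abphos_{rec}_eff"] = float(
                sum(params[f"abphos_{rec}_{dr}"] for dr in ab))
        lum = "lumretuzumab" in cond.drugs
        enh = 1.0 + params["lumdeg_NRG1_enh"] * (cond.ligand == "NRG1")
        row["lumdeg_eff"] = params["lumdeg_ERBB3"] * enh if lum else 0.0
        cond_rows.append(row)
    cond_df = pd.DataFrame(cond_rows)

    meas_rows = []
    if dataset is not None and len(dataset):
        cond_ids = {(c.cell_line, c.ligand, "+".join(c.drugs)):
                    _condition_id(c) for c in design.conditions}
        for rec in dataset.data.itertuples():
            key = (rec.cell_line, rec.ligand, rec.drug)
            if key not in cond_ids:
                continue
            meas_rows.append({
                "observableId": f"obs_{rec.observable}",
                "simulationConditionId": cond_ids[key],
                "time": rec.time,
                "measurement": rec.value,
            })
    meas_df = pd.DataFrame(
        meas_rows, columns=["observableId", "simulationConditionId", "time",
                            "measurement"])

    par_rows = []
    for name in network.parameters:
        par_rows.append({
            "parameterId": name,
            "parameterScale": "log10",
            "lowerBound": 1e-5,
            "upperBound": 1e3,
            "nominalValue": params.get(name, 1.0),
            "estimate": 1,
        })
    par_df = pd.DataFrame(par_rows)

    files = {
        "sbml": sbml_path,
        "observables": out / "observables.tsv",
        "conditions": out / "conditions.tsv",
        "measurements": out / "measurements.tsv",
        "parameters": out / "parameters.tsv",
        "yaml": out / "problem.yaml",
    }
    obs_df.to_csv(files["observables"], sep="\t", index=False)
    cond_df.to_csv(files["conditions"], sep="\t", index=False)
    meas_df.to_csv(files["measurements"], sep="\t", index=False)
    par_df.to_csv(files["parameters"], sep="\t", index=False)
    problem = {
        "format_version": 1,
        "parameter_file": "parameters.tsv",
        "problems": [{
            "sbml_files": ["model.xml"],
            "observable_files": ["observables.tsv"],
            "condition_files": ["conditions.tsv"],
            "measurement_files": ["measurements.tsv"],
        }],
    }
    files["yaml"].write_text(yaml.safe_dump(problem, sort_keys=False))
    return files


def validate_petab(out_dir) -> list[str]:
    """Structural PEtab checks; returns a list of problems (empty = pass)."""
    out = Path(out_dir)
    problems: list[str] = []
    yaml_path = out / "problem.yaml"
    if not yaml_path.exists():
        return ["problem.yaml missing"]
    spec = yaml.safe_load(yaml_path.read_text())
    if spec.get("format_version") != 1:
        problems.append("format_version must be 1")
    try:
        block = spec["problems"][0]
        names = {
            "sbml": block["sbml_files"][0],
            "observables": block["observable_files"][0],
            "conditions": block["condition_files"][0],
            "measurements": block["measurement_files"][0],
            "parameters": spec["parameter_file"],
        }
    except (KeyError, IndexError) as exc:
        return problems + [f"problem.yaml incomplete: {exc}"]
    for key, fname in names.items():
        if not (out / fname).exists():
            problems.append(f"{key} file {fname} missing")
    if problems:
        return problems

    obs = pd.read_csv(out / names["observables"], sep="\t")
    con = pd.read_csv(out / names["conditions"], sep="\t")
    mea = pd.read_csv(out / names["measurements"], sep="\t")
    par = pd.read_csv(out / names["parameters"], sep="\t")
    for df, req, tag in (
        (obs, ["observableId", "observableFormula", "noiseFormula"],
         "observables"),
        (con, ["conditionId"], "conditions"),
        (mea, ["observableId", "simulationConditionId", "time",
               "measurement"], "measurements"),
        (par, ["parameterId", "parameterScale", "lowerBound", "upperBound",
               "nominalValue", "estimate"], "parameters"),
    ):
        missing = [c for c in req if c not in df.columns]
        if missing:
            problems.append(f"{tag}: missing columns {missing}")
    if problems:
        return problems
    if obs["observableId"].duplicated().any():
        problems.append("observables: duplicate observableId")
    if con["conditionId"].duplicated().any():
        problems.append("conditions: duplicate conditionId")
    bad_obs = set(mea["observableId"]) - set(obs["observableId"])
    if bad_obs:
        problems.append(f"measurements reference unknown observables "
                        f"{sorted(bad_obs)}")
    bad_con = set(mea["simulationConditionId"]) - set(con["conditionId"])
    if bad_con:
        problems.append(f"measurements reference unknown conditions "
                        f"{sorted(bad_con)}")
    root = ET.parse(out / names["sbml"]).getroot()
    model_params = {
        el.get("id") for el in
        root.findall(f".//{{{_SBML_NS}}}listOfParameters/"
                     f"{{{_SBML_NS}}}parameter")}
    model_species = {
        el.get("id") for el in
        root.findall(f".//{{{_SBML_NS}}}listOfSpecies/"
                     f"{{{_SBML_NS}}}species")}
    for col in con.columns:
        if col == "conditionId":
            continue
        if col not in model_params and col not in model_species:
            problems.append(f"condition column {col} is not a model entity")
    unknown_par = set(par["parameterId"]) - model_params
    if unknown_par:
        problems.append(f"parameters not in the model: {sorted(unknown_par)}")
    return problems


def export_model(
    network: ReactionNetwork,
    params: dict[str, float],
    obs_map,
    design: DesignMatrix,
    dataset: TimeCourseDataset | None,
    sbml_path,
    petab_dir,
) -> dict[str, Path]:
    """SBML + PEtab export; raises if the PEtab problem fails validation."""
    export_sbml(network, params, sbml_path)
    files = export_petab(network, params, obs_map, design, dataset, petab_dir)
    problems = validate_petab(petab_dir)
    if problems:
        raise RuntimeError("PEtab validation failed: " + "; ".join(problems))
    files["sbml_standalone"] = Path(sbml_path)
    return files
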