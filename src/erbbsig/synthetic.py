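"""Synthetic study generator: design matrix, ground truth, noisy data.

Emulates the structure of the RPPA study the model is built for: four
breast cancer cell lines covering three subtypes, a 4-ligand x
(5-drug + control) panel per line (reduced to EGF/NRG1 x three
antibodies + control for SKBR3), drug pre-treatment for 60 min followed
by ligand stimulation, ten sampling times (five for SKBR3), fifteen
observables, triplicates merged on the log10 scale, and Gaussian noise
on log-transformed values.

The ground-truth parameters encode the subtype biology that drives the
study's qualitative regimes: luminal lines (MCF7, T47D) are
ERBB2/ERBB3-dominant with elevated basal PI3K activation (PIK3CA
hotspot mutations), MDA-MB-231 is EGFR-dominant with elevated basal MEK
phosphorylation and a reduced c-RAF activation ratio (KRAS/b-RAF), and
SKBR3 is ERBB2-amplified with PI3K-biased downstream kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .network import (
    CELL_LINES,
    DRUGS,
    LIGANDS,
    ConditionSpec,
    ObservationMap,
    default_observation_map,
)
from .simulate import CompiledNetwork, observe, simulate_condition, steady_state_initialize

__all__ = [
    "LUMINAL_TIME_GRID",
    "SKBR3_TIME_GRID",
    "TIMECOURSE_COLUMNS",
    "VIABILITY_COLUMNS",
    "DesignMatrix",
    "TimeCourseDataset",
    "ViabilityDataset",
    "SyntheticTruth",
    "build_design",
    "sample_true_parameters",
    "calibrate_receptor_synthesis",
    "generate_timecourse",
    "merge_replicates",
    "generate_viability",
]

LUMINAL_TIME_GRID: tuple[float, ...] = (0, 15, 30, 60, 65, 75, 90, 120, 180, 240)
SKBR3_TIME_GRID: tuple[float, ...] = (0, 60, 75, 120, 240)

SKBR3_LIGANDS: tuple[str, ...] = ("EGF", "NRG1")
SKBR3_DRUGS: tuple[str, ...] = ("pertuzumab", "trastuzumab", "lumretuzumab")

TIMECOURSE_COLUMNS = ["cell_line", "ligand", "drug", "observable", "time",
                      "replicate", "value"]
VIABILITY_COLUMNS = ["cell_line", "ligand", "drugs", "value"]


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class TimeCourseDataset:
    """RPPA-like measurements, one record per (condition, observable, time,
    replicate); values are on the log10 scale."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in TIMECOURSE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"time-course dataset missing columns: {missing}")
        self.data = self.data[TIMECOURSE_COLUMNS].reset_index(drop=True)
        if len(self.data) and not np.all(np.isfinite(self.data["value"])):
            raise ValueError("non-finite measurement values")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ViabilityDataset:
    """Viability screen records: log2 fold-change vs the ligand-only
    control; ``drugs`` is '' (control), one drug name, or 'a+b'."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in VIABILITY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"viability dataset missing columns: {missing}")
        self.data = self.data[VIABILITY_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DesignMatrix:
    """The study design: one ConditionSpec per row plus per-line time grids."""

    conditions: list[ConditionSpec]
    time_grids: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conditions)

    def for_cell_line(self, cell_line: str) -> list[ConditionSpec]:
        return [c for c in self.conditions if c.cell_line == cell_line]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_line": [c.cell_line for c in self.conditions],
                "ligand": [c.ligand for c in self.conditions],
                "drug": ["+".join(c.drugs) for c in self.conditions],
            }
        )


def build_design(
    cell_lines=None,
    full_study: bool = False,
    ligands=None,
    drugs=None,
) -> DesignMatrix:
    """Enumerate the condition panel.

    The full study is three complete panels (4 ligands x 5 drugs + control
    = 24 conditions each) plus the reduced SKBR3 panel (2 ligands x
    3 antibodies + control = 8 conditions), 80 conditions in total.
    ``ligands``/``drugs`` override the per-line panels (for scaled-down
    synthetic experiments).
    """
    if full_study:
        cell_lines = list(CELL_LINES)
    elif cell_lines is None:
        cell_lines = ["MCF7"]
    for cl in cell_lines:
        if cl not in CELL_LINES:
            raise ValueError(f"unknown cell line: {cl!r}")

    conditions: list[ConditionSpec] = []
    grids: dict[str, tuple[float, ...]] = {}
    for cl in cell_lines:
        if cl == "SKBR3":
            panel_ligands = SKBR3_LIGANDS if ligands is None else tuple(ligands)
            panel_drugs = SKBR3_DRUGS if drugs is None else tuple(drugs)
            grids[cl] = SKBR3_TIME_GRID
        else:
            panel_ligands = LIGANDS if ligands is None else tuple(ligands)
            panel_drugs = DRUGS if drugs is None else tuple(drugs)
            grids[cl] = LUMINAL_TIME_GRID
        for lig in panel_ligands:
            conditions.append(ConditionSpec(cl, lig, ()))
            for drug in panel_drugs:
                conditions.append(ConditionSpec(cl, lig, (drug,)))
    return DesignMatrix(conditions=conditions, time_grids=grids)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

#: luminal-baseline kinetic rates (1/min, or 1/(a.u. min) for bimolecular)
_BASE_KINETICS: dict[str, float] = {
    # receptor turnover
    "deg_EGFR": 0.003, "deg_ERBB2": 0.003, "deg_ERBB3": 0.003,
    # ligand-specific dimerization
    "dim_EE_EGF": 0.40, "dim_EE_TGFa": 0.30, "dim_EE_BTC": 0.20,
    "dim_E2_EGF": 0.30, "dim_E2_TGFa": 0.25, "dim_E2_BTC": 0.20,
    "dim_E3_EGF": 0.15, "dim_E3_TGFa": 0.10, "dim_E3_BTC": 0.10,
    "dim_E3_NRG1": 0.50, "dim_23_NRG1": 0.60,
    # basal dimerization
    "bas_dim_EE": 2e-4, "bas_dim_E2": 3e-4, "bas_dim_E3": 3e-4,
    "bas_dim_23": 5e-4,
    # active-dimer degradation
    "deg_D_EE": 0.05, "deg_D_E2": 0.05, "deg_D_E3": 0.04, "deg_D_23": 0.04,
    # antibody-induced inactive phosphorylation
    "abphos_EGFR_trastuzumab": 0.002, "abphos_ERBB2_trastuzumab": 0.004,
    "abphos_ERBB3_trastuzumab": 0.001,
    "abphos_EGFR_pertuzumab": 0.001, "abphos_ERBB2_pertuzumab": 0.002,
    "abphos_ERBB3_pertuzumab": 0.0005,
    "dephos_pEGFR_i": 0.01, "dephos_pERBB2_i": 0.01, "dephos_pERBB3_i": 0.01,
    # lumretuzumab-induced ERBB3 degradation
    "lumdeg_ERBB3": 0.03, "lumdeg_NRG1_enh": 2.0,
    # PI3K module (ERBB3-containing dimers carry the p85 docking sites)
    "act_PI3K_D_EE": 0.1, "act_PI3K_D_E2": 0.4,
    "act_PI3K_D_E3": 2.0, "act_PI3K_D_23": 2.0,
    "bas_PI3K": 0.04, "deact_PI3K": 0.1,
    # MAPK module
    "act_cRAF_dimers": 2.0, "bas_cRAF": 0.005, "deact_cRAF": 0.4,
    "phos_MEK_pcRAF": 1.0, "bas_MEK": 0.0008, "dephos_MEK": 0.8,
    "phos_ERK_pMEK": 2.0, "dephos_ERK": 0.8,
    # PI3K-AKT and convergence on S6K
    "phos_AKT_aPI3K": 2.0, "dephos_AKT": 0.3,
    "phos_S6K_AKT": 0.8, "phos_S6K_ERK": 0.8, "dephos_S6K": 0.2,
    # drug inhibition strengths
    "k_cetuximab": 8.0, "k_erlotinib": 12.0, "k_trastuzumab": 3.0,
    "k_pertuzumab": 6.0, "k_lumretuzumab": 10.0,
    # downstream pool totals (a.u.)
    "total_PI3K": 0.5, "total_cRAF": 0.3, "total_MEK": 1.0,
    "total_ERK": 1.5, "total_AKT": 1.0, "total_S6K": 1.0,
}

#: receptor abundances (a.u.), qualitative Fig-1b-style pattern:
#: luminal ERBB2/ERBB3-dominant, TNBC EGFR-dominant, HER2+ ERBB2-amplified
CELL_LINE_ABUNDANCE: dict[str, dict[str, float]] = {
    "MCF7": {"EGFR": 0.30, "ERBB2": 1.20, "ERBB3": 0.90},
    "T47D": {"EGFR": 0.25, "ERBB2": 1.00, "ERBB3": 0.80},
    "MDA-MB-231": {"EGFR": 2.50, "ERBB2": 0.12, "ERBB3": 0.04},
    "SKBR3": {"EGFR": 0.50, "ERBB2": 6.00, "ERBB3": 0.35},
}

#: multiplicative deviations from the luminal baseline encoding mutation
#: states and subtype biology
CELL_LINE_MODIFIERS: dict[str, dict[str, float]] = {
    "MCF7": {},                                # PIK3CA E545K: baseline bas_PI3K
    "T47D": {"bas_PI3K": 1.25},                # PIK3CA H1047R, slightly stronger
    "MDA-MB-231": {                            # KRAS G13D / b-RAF G464V
        "bas_PI3K": 0.05,
        "bas_MEK": 150.0,
        "bas_cRAF": 0.2,
        "dephos_S6K": 2.0,
    },
    "SKBR3": {                                 # MAPK-quiet, PI3K-addicted
        "bas_PI3K": 0.5,
        "bas_MEK": 0.3,
        "bas_cRAF": 0.3,
        "phos_S6K_AKT": 2.0,
        "dephos_S6K": 2.0,
    },
}

#: parameters never jittered (structure-defining cell-line modifiers act on
#: the jittered base, abundances are fixed targets)
_NO_JITTER = {"lumdeg_NRG1_enh"}


@dataclass
class SyntheticTruth:
    """Ground-truth dynamic parameters per cell line plus observation map."""

    params: dict[str, dict[str, float]]
    obs_map: ObservationMap
    seed: int

    def for_cell_line(self, cell_line: str) -> dict[str, float]:
        return self.params[cell_line]


def calibrate_receptor_synthesis(
    comp: CompiledNetwork,
    params: dict[str, float],
    abundances: dict[str, float],
    tol: float = 1e-8,
    max_iter: int = 40,
) -> dict[str, float]:
    """Set receptor synthesis rates so the untreated steady state carries the
    target receptor-containing material (monomer + inactive phospho +
    dimers, with multiplicity)."""
    p = dict(params)
    for rec, target in abundances.items():
        p[f"syn_{rec}"] = p[f"deg_{rec}"] * target
    material = {
        "EGFR": {"EGFR": 1, "pEGFR_i": 1, "D_EE": 2, "D_E2": 1, "D_E3": 1},
        "ERBB2": {"ERBB2": 1, "pERBB2_i": 1, "D_E2": 1, "D_23": 1},
        "ERBB3": {"ERBB3": 1, "pERBB3_i": 1, "D_E3": 1, "D_23": 1},
    }
    sidx = {sp: i for i, sp in enumerate(comp.network.species)}
    for _ in range(max_iter):
        x0, _ = steady_state_initialize(comp, p)
        err = 0.0
        for rec, target in abundances.items():
            tot = sum(m * x0[sidx[sp]] for sp, m in material[rec].items())
            err = max(err, abs(tot - target) / target)
            p[f"syn_{rec}"] *= target / max(tot, 1e-300)
        if err < tol:
            break
    return p


def sample_true_parameters(
    seed: int,
    cell_lines=CELL_LINES,
    comp: CompiledNetwork | None = None,
    jitter: float = 0.15,
) -> SyntheticTruth:
    """Draw a reproducible ground truth.

    Kinetic rates are drawn log-uniformly within ``+-jitter`` decades around
    the configured baseline (shared across cell lines); cell-line structure
    (receptor abundances, mutation-state modifiers) is applied on top, and
    receptor synthesis rates are calibrated to the abundance targets.
    Observation scales are drawn log-uniformly in [0.5, 2] with a small
    fixed background offset.
    """
    if comp is None:
        from .network import build_network
        comp = compile_default()
    rng = np.random.default_rng(seed)
    base = {}
    for name, value in _BASE_KINETICS.items():
        if name in _NO_JITTER or jitter == 0:
            base[name] = value
        else:
            base[name] = value * 10 ** rng.uniform(-jitter, jitter)

    params: dict[str, dict[str, float]] = {}
    for cl in cell_lines:
        p = dict(base)
        for name, mult in CELL_LINE_MODIFIERS[cl].items():
            p[name] *= mult
        for rec, ab in CELL_LINE_ABUNDANCE[cl].items():
            p[f"abund_{rec}"] = ab
        p = calibrate_receptor_synthesis(comp, p, CELL_LINE_ABUNDANCE[cl])
        params[cl] = p

    obs_map = default_observation_map()
    for obs in obs_map.observables:
        obs_map.scale[obs] = float(10 ** rng.uniform(np.log10(0.5), np.log10(2.0)))
        obs_map.offset[obs] = 0.005
        obs_map.sigma[obs] = 0.05
    return SyntheticTruth(params=params, obs_map=obs_map, seed=seed)


_DEFAULT_COMP: CompiledNetwork | None = None


def compile_default() -> CompiledNetwork:
    """Compiled instance of the fixed network (cached)."""
    global _DEFAULT_COMP
    if _DEFAULT_COMP is None:
        from .network import build_network
        from .simulate import compile_network
        _DEFAULT_COMP = compile_network(build_network())
    return _DEFAULT_COMP


# ---------------------------------------------------------------------------
# time-course generation
# ---------------------------------------------------------------------------


def generate_timecourse(
    design: DesignMatrix,
    truth: SyntheticTruth,
    noise_sd: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    merged: bool = True,
    comp: CompiledNetwork | None = None,
) -> TimeCourseDataset:
    """Simulate every design condition and emit noisy log10 records.

    Gaussian noise of sd ``noise_sd`` is added independently per replicate
    on the log10 scale; with ``merged`` the replicates are averaged per
    design cell (the study's merging convention).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    comp = comp or compile_default()
    rng = np.random.default_rng(seed)
    obs_map = truth.obs_map
    records = []
    x0_cache: dict[str, tuple] = {}
    for cond in design.conditions:
        p = truth.for_cell_line(cond.cell_line)
        if cond.cell_line not in x0_cache:
            x0_cache[cond.cell_line] = steady_state_initialize(comp, p)
        x0, _ = x0_cache[cond.cell_line]
        times = design.time_grids.get(cond.cell_line, LUMINAL_TIME_GRID)
        try:
            traj = simulate_condition(comp, p, cond, times, x0=x0)
        except Exception as exc:
            raise RuntimeError(f"simulation failed for {cond.label}") from exc
        y = observe(traj, obs_map)
        drug = "+".join(cond.drugs)
        for obs in obs_map.observables:
            clean = y[obs]
            noisy = clean[None, :] + noise_sd * rng.standard_normal(
                (replicates, clean.size))
            for rep in range(replicates):
                for ti, t in enumerate(traj.times):
                    records.append((cond.cell_line, cond.ligand, drug, obs,
                                    float(t), str(rep + 1),
                                    float(noisy[rep, ti])))
    df = pd.DataFrame(records, columns=TIMECOURSE_COLUMNS)
    ds = TimeCourseDataset(df)
    return merge_replicates(ds) if merged else ds


def merge_replicates(dataset: TimeCourseDataset) -> TimeCourseDataset:
    """Arithmetic mean on the log10 scale per design cell."""
    if len(dataset) == 0:
        raise ValueError("cannot merge an empty dataset")
    keys = [c for c in TIMECOURSE_COLUMNS if c not in ("replicate", "value")]
    merged = (
        dataset.data.groupby(keys, sort=False, as_index=False)["value"].mean()
    )
    merged["replicate"] = "merged"
    return TimeCourseDataset(merged[TIMECOURSE_COLUMNS])


# ---------------------------------------------------------------------------
# viability generation
# ---------------------------------------------------------------------------


def generate_viability(
    truth: SyntheticTruth,
    regression_truth: dict[str, float],
    cell_lines=("MCF7",),
    ligands=LIGANDS,
    drugs=DRUGS,
    include_cotreatments: bool = True,
    noise_sd: float = 0.0,
    seed: int = 0,
    comp: CompiledNetwork | None = None,
) -> ViabilityDataset:
    """Viability screen from the truth model and the affine growth law
    ``y = alpha1 + beta1 * AUC_pAKT + beta2 * AUC_pS6K`` (log2 fold-change
    scale; the intercept absorbs the ligand-only control level).

    Ligand-only reference rows are written with value 0 by construction;
    co-treatment rows use the combined (product) inhibition factor via
    direct simulation of the two-drug condition.
    """
    from .proliferation import extract_features  # local import, no cycle

    for key in ("alpha1", "beta1", "beta2"):
        if not np.isfinite(regression_truth[key]):
            raise ValueError(f"regression truth {key} must be finite")
    comp = comp or compile_default()
    rng = np.random.default_rng(seed)
    a1 = regression_truth["alpha1"]
    b1 = regression_truth["beta1"]
    b2 = regression_truth["beta2"]
    grid = np.arange(0.0, 240.0 + 1e-9, 1.0)
    records = []
    for cl in cell_lines:
        p = truth.for_cell_line(cl)
        x0, _ = steady_state_initialize(comp, p)
        for lig in ligands:
            records.append((cl, lig, "", 0.0))
            drug_sets = [(d,) for d in drugs]
            if include_cotreatments:
                drug_sets += list(combinations(drugs, 2))
            for ds in drug_sets:
                cond = ConditionSpec(cl, lig, tuple(ds))
                traj = simulate_condition(comp, p, cond, grid, x0=x0)
                feats = extract_features(traj)
                y = (a1 + b1 * feats.loc["pAKT", "auc"]
                     + b2 * feats.loc["pS6K", "auc"])
                if noise_sd > 0:
                    y += noise_sd * rng.standard_normal()
                records.append((cl, lig, "+".join(ds), float(y)))
    return ViabilityDataset(pd.DataFrame(records, columns=VIABILITY_COLUMNS))
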