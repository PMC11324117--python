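"""Trajectory readouts: viability, arrest stage, size, phases, localization.

This module turns raw trajectories into the phenotypes the model is judged
by: whether a lineage executes repeated complete cycles, where an inviable
mutant arrests, steady-state size as a fold of wildtype, G1 and budded-phase
durations, the decomposition of SBF/MBF activity into its molecular classes
(SBFa1..a5, MBFa), and the cytoplasmic fraction of each START monomer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_core import ModelSystem, build_model
from .simulate import (
    CycleMetrics,
    NonConvergence,
    SimulationConfig,
    Trajectory,
    steady_cycle,
)

__all__ = [
    "PhenotypeReport",
    "ActiveFormBreakdown",
    "detect_milestones",
    "phase_durations",
    "classify_viability",
    "relative_size",
    "active_form_breakdown",
    "localization_fractions",
    "sweep_mdt",
    "characterize",
]

#: mass ceiling (fold of wildtype division mass) beyond which an undivided
#: lineage is scored as growth-arrested/dead
MASS_CEILING_FOLD = 10.0

#: reference wildtype division mass in glucose used for the ceiling
WT_DIVISION_MASS_GLUCOSE = 2.44

#: number of consecutive settled cycles required to call a lineage viable
VIABLE_CYCLES = 3

#: birth-mass convergence tolerance for viability (relative)
VIABLE_TOL = 0.01


@dataclass
class PhenotypeReport:
    """One row of the mutant screen."""

    genotype: str
    viable: bool
    arrest_stage: str  # none | G1 | S/G2 | M | telophase-like | indeterminate
    size_rel_wt: float | None
    cycle_time: float | None
    g1_length: float | None
    budded_period: float | None
    division_mass: float | None = None
    birth_mass: float | None = None
    dominant_forms: list[str] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.viable and self.arrest_stage == "none":
            raise ValueError("an inviable report must carry an arrest stage")


# --------------------------------------------------------------------------
# milestones and phases
# --------------------------------------------------------------------------

def detect_milestones(traj: Trajectory) -> dict[str, list[float]]:
    """Upward-crossing times of BUD/ORI/SPN through 1.0, per marker.

    Crossings are linearly interpolated between samples; the ORI crossing is
    the START marker.  Markers reset at division, so each cycle contributes
    at most one first-crossing per marker (later re-crossings of a decaying
    marker within the same cycle are dropped).
    """
    out: dict[str, list[float]] = {}
    div_times = traj.division_times()
    for kind in ("BUD", "ORI", "SPN"):
        x = traj[kind]
        above = x >= 1.0
        idx = np.flatnonzero(~above[:-1] & above[1:])
        times = []
        for i in idx:
            x0, x1 = x[i], x[i + 1]
            t0, t1 = traj.times[i], traj.times[i + 1]
            times.append(t0 if x1 == x0
                         else float(t0 + (1.0 - x0) * (t1 - t0) / (x1 - x0)))
        # keep only the first crossing in each division-to-division interval
        bounds = [-math.inf] + div_times + [math.inf]
        kept: list[float] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            in_cycle = [t for t in times if lo <= t < hi]
            if in_cycle:
                kept.append(in_cycle[0])
        out[kind] = kept
    return out


def phase_durations(
    milestones: Mapping[str, Sequence[float]],
    division_times: Sequence[float],
) -> list[dict[str, float | None]]:
    """Per-cycle (g1_length, budded_period, cycle_time).

    G1 runs from birth (a division) to the ORI crossing (the START marker);
    the budded period from the BUD crossing to the next division.  Cycles
    without the needed milestones report None for the affected durations.
    """
    rows = []
    for t0, t1 in zip(division_times[:-1], division_times[1:]):
        def first(kind):
            for t in milestones.get(kind, ()):
                if t0 <= t < t1:
                    return t
            return None
        t_ori, t_bud = first("ORI"), first("BUD")
        rows.append({
            "g1_length": (t_ori - t0) if t_ori is not None else None,
            "budded_period": (t1 - t_bud) if t_bud is not None else None,
            "cycle_time": t1 - t0,
            "t_ori": t_ori, "t_bud": t_bud, "t_spn": first("SPN"),
        })
    return rows


# --------------------------------------------------------------------------
# viability
# --------------------------------------------------------------------------

def _arrest_stage(traj: Trajectory) -> str:
    """Stage of the last milestone passed since the last division."""
    t_from = traj.division_times()[-1] if traj.division_times() else 0.0
    ms = detect_milestones(traj)
    passed = {k: any(t >= t_from for t in v) for k, v in ms.items()}
    if passed.get("SPN"):
        return "M"
    if passed.get("ORI"):
        return "S/G2"
    return "G1"


def classify_viability(
    traj: Trajectory,
    steady: CycleMetrics | NonConvergence,
    genotype: str = "",
    wt_division_mass: float = WT_DIVISION_MASS_GLUCOSE,
) -> PhenotypeReport:
    """Viable iff the lineage settles into repeated complete cycles.

    Requires converged birth mass over at least :data:`VIABLE_CYCLES`
    consecutive cycles with the ordered milestones ORI -> SPN -> division,
    and bounded mass.  Otherwise the report carries the arrest stage of the
    last milestone passed; a lineage whose mass exceeds
    ``MASS_CEILING_FOLD x`` wildtype division mass without dividing is dead
    by unbounded growth.
    """
    mass_max = float(traj["MASS"].max())
    if isinstance(steady, NonConvergence):
        stage = _arrest_stage(traj)
        note = steady.reason
        if mass_max > MASS_CEILING_FOLD * wt_division_mass:
            note += "; mass ceiling exceeded"
        return PhenotypeReport(
            genotype=genotype, viable=False, arrest_stage=stage,
            size_rel_wt=None, cycle_time=None, g1_length=None,
            budded_period=None, notes=note)

    # settled map: require the last VIABLE_CYCLES birth masses within tol
    divs = [e for e in traj.events if e.kind == "division"]
    births = [e.payload["post_division_mass"] for e in divs]
    settled = (len(births) >= VIABLE_CYCLES + 1 and all(
        abs(b1 - b0) <= VIABLE_TOL * b0
        for b0, b1 in zip(births[-VIABLE_CYCLES - 1:-1],
                          births[-VIABLE_CYCLES:])))
    ordered = (steady.t_ori is not None and steady.t_spn is not None
               and steady.t_ori < steady.t_spn)
    if not (settled and ordered):
        return PhenotypeReport(
            genotype=genotype, viable=False, arrest_stage=_arrest_stage(traj),
            size_rel_wt=None, cycle_time=None, g1_length=None,
            budded_period=None,
            notes="divides but does not settle into ordered cycles")
    return PhenotypeReport(
        genotype=genotype, viable=True, arrest_stage="none",
        size_rel_wt=None,  # filled by relative_size against a WT baseline
        cycle_time=steady.cycle_time,
        g1_length=steady.g1_length,
        budded_period=steady.budded_period,
        division_mass=steady.division_mass,
        birth_mass=steady.birth_mass)


def relative_size(mutant: CycleMetrics | PhenotypeReport,
                  wildtype: CycleMetrics | PhenotypeReport) -> float:
    """Steady-state mass at division as a fold of wildtype."""
    m = getattr(mutant, "division_mass", None)
    w = getattr(wildtype, "division_mass", None)
    if m is None or w is None:
        raise ValueError("relative size requires two converged viable cycles")
    return m / w


# --------------------------------------------------------------------------
# active forms and localization
# --------------------------------------------------------------------------

@dataclass
class ActiveFormBreakdown:
    """Activity contribution time series of each promoter-bound class.

    SBFa1 = unmodified promoter-bound SBF (SBFB); SBFa2 = SBF phosphorylated
    on Swi6 (SBFB6P + SBFB6PQ); SBFa3 = SBF-Whi5 phosphorylated on Swi6
    (WSB6P + WSB6PQ); SBFa4 = SBF-Whi5 phosphorylated on Whi5 (WSB5P);
    SBFa5 = Bck2-activated Swi4 homodimers (Swi4B); MBFa = Cln- plus
    Bck2-activated promoter-bound MBF.
    """

    times: np.ndarray
    series: dict[str, np.ndarray]

    def total_sbf(self) -> np.ndarray:
        return sum(self.series[k] for k in
                   ("SBFa1", "SBFa2", "SBFa3", "SBFa4", "SBFa5"))

    def dominant(self, threshold: float = 0.05) -> list[str]:
        """Classes whose peak exceeds ``threshold`` x the largest peak."""
        peaks = {k: float(v.max(initial=0.0)) for k, v in self.series.items()}
        top = max(peaks.values(), default=0.0)
        if top <= 0:
            return []
        return sorted((k for k, v in peaks.items() if v >= threshold * top),
                      key=lambda k: -peaks[k])


_FORM_SUMS = {
    "SBFa1": ("SBFB",),
    "SBFa2": ("SBFB6P", "SBFB6PQ"),
    "SBFa3": ("WSB6P", "WSB6PQ"),
    "SBFa4": ("WSB5P",),
    "SBFa5": ("SWI4B", "WSBB"),
    "MBFa": ("MBFBA", "MBFBB"),
}

_FORM_WEIGHTS = {
    "SBFa1": "wa1", "SBFa2": "wa2", "SBFa3": "wa3", "SBFa4": "wa4",
    "SBFa5": "wa5",
}


def active_form_breakdown(traj: Trajectory,
                          model: ModelSystem) -> ActiveFormBreakdown:
    """Decompose SBF/MBF activity into the promoter-bound classes."""
    series = {}
    p = model.parameters
    for form, members in _FORM_SUMS.items():
        x = np.zeros(len(traj.times))
        for sp in members:
            x = x + traj[sp]
        if form == "MBFa":
            x = (p["wma"] * traj["MBFBA"] + p["wmb"] * traj["MBFBB"])
        elif form == "SBFa5":
            x = p["wa5"] * traj["SWI4B"] + p["wab"] * traj["WSBB"]
        else:
            x = p[_FORM_WEIGHTS[form]] * x
        series[form] = x
    return ActiveFormBreakdown(times=traj.times, series=series)


def localization_fractions(
    traj: Trajectory,
    model: ModelSystem,
    monomer: str,
) -> np.ndarray:
    """Cytoplasmic fraction of all forms of one monomer over time.

    Molecule counts are volume-weighted sums over every species containing
    the monomer (complexes included).  Raises for a deleted monomer whose
    total is zero.
    """
    if monomer not in ("Whi5", "Swi6", "Swi4", "Mbp1"):
        raise ValueError("monomer must be one of Whi5, Swi6, Swi4, Mbp1")
    cyto = np.zeros(len(traj.times))
    total = np.zeros(len(traj.times))
    for i, sp in enumerate(model.species):
        n = sp.composition.get(monomer, 0)
        if not n:
            continue
        amount = n * model.layout.volume(sp.compartment) * traj.states[:, i]
        total += amount
        if sp.compartment == "cytoplasmic":
            cyto += amount
    if float(total.max(initial=0.0)) <= 0.0:
        raise ValueError(f"monomer {monomer} absent from this genotype")
    return cyto / total


# --------------------------------------------------------------------------
# growth-rate sweep and the one-call mutant characterization
# --------------------------------------------------------------------------

def sweep_mdt(
    model_or_genotype,
    mdt_values: Sequence[float],
    lineage: str = "daughter",
) -> list[dict]:
    """Converged cycle metrics at each mass doubling time.

    Rows for non-converging MDTs are flagged and the sweep continues.
    """
    rows = []
    for mdt in mdt_values:
        if mdt <= 0:
            raise ValueError("mdt values must be positive")
        model = (model_or_genotype if isinstance(model_or_genotype, ModelSystem)
                 else build_model(mutant=model_or_genotype))
        cfg = SimulationConfig(t_end=300.0, mdt=mdt, lineage=lineage)
        params = dict(model.parameters)
        params["mdt"] = mdt
        model = build_model(params, model.layout)
        sc = steady_cycle(model, cfg)
        if isinstance(sc, NonConvergence):
            rows.append({"mdt": mdt, "converged": False,
                         "reason": sc.reason})
        else:
            rows.append({
                "mdt": mdt, "converged": True,
                "division_mass": sc.division_mass,
                "birth_mass": sc.birth_mass,
                "cycle_time": sc.cycle_time,
                "g1_length": sc.g1_length,
                "budded_period": sc.budded_period,
            })
    return rows


def characterize(
    genotype: str,
    config: SimulationConfig | None = None,
    wildtype: PhenotypeReport | None = None,
) -> PhenotypeReport:
    """Simulate one genotype to steady state and classify its phenotype."""
    config = config or SimulationConfig()
    model = build_model(mutant=genotype)
    params = dict(model.parameters)
    params["mdt"] = config.mdt
    model = build_model(params, model.layout)
    sc = steady_cycle(model, config)
    traj = sc.trajectory
    report = classify_viability(traj, sc, genotype=genotype)
    if report.viable:
        if wildtype is not None and wildtype.division_mass:
            report.size_rel_wt = report.division_mass / wildtype.division_mass
        elif genotype.lower() in ("wildtype", "wt", ""):
            report.size_rel_wt = 1.0
        bd = active_form_breakdown(traj, model)
        report.dominant_forms = bd.dominant()
    return report
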