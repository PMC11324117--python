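"""Species catalog, parameters and assembly of the START-BYCC right-hand side.

The model couples a mechanistically detailed description of the START
transition (SBF/MBF assembly, promoter binding, Cln- and Clb-directed
phosphorylation, Bck2-modified forms, Msn5-mediated nuclear export, Ydj1/Ssa1
gating of nuclear Cln3 and Bck2) to a compact backbone of the remaining cell
cycle (Cln2, Clb5, Clb2, the CKIs Sic1 and Cdc6, Cdh1, Cdc20, Cdc14, Mcm1,
Swi5, the BUD/ORI/SPN event markers and exponentially growing mass).

The model is held as a declarative reaction network — species with
compartment annotations and monomer composition, reactions with integer
stoichiometry and rate-law expressions — and compiled once into a flat Python
right-hand-side function.  Keeping the network declarative is what makes
moiety (conservation-law) analysis, the XPP-dialect ``.ode`` writer and the
SBML exporter straightforward.

Compartments have fixed relative volumes (nucleus 0.2, cytoplasm 0.8); every
reaction is evaluated in concentration units of its home compartment and its
molecular flux is rescaled by volume ratios on arrival, so transport steps
conserve molecule number exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np

from . import kinetics

__all__ = [
    "CompartmentLayout",
    "SpeciesDef",
    "ParameterSet",
    "ModelState",
    "ModelSystem",
    "DEFAULT_PARAMETERS",
    "build_model",
    "initial_conditions",
    "rescale_counts",
    "conserved_moieties",
    "species_catalog",
    "reaction_catalog",
]

LN2 = math.log(2.0)


# --------------------------------------------------------------------------
# layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentLayout:
    """Fixed nuclear/cytoplasmic volume fractions (default 0.2 : 0.8)."""

    nuclear_fraction: float = 0.2
    cytoplasmic_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.nuclear_fraction <= 0 or self.cytoplasmic_fraction <= 0:
            raise ValueError("compartment volume fractions must be positive")
        if abs(self.nuclear_fraction + self.cytoplasmic_fraction - 1.0) > 1e-12:
            raise ValueError("nuclear + cytoplasmic volume fractions must equal 1")

    def volume(self, compartment: str) -> float:
        if compartment == "nuclear":
            return self.nuclear_fraction
        if compartment == "cytoplasmic":
            return self.cytoplasmic_fraction
        if compartment == "cell":
            return 1.0
        raise KeyError(f"unknown compartment {compartment!r}")


DEFAULT_LAYOUT = CompartmentLayout()


# --------------------------------------------------------------------------
# species
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesDef:
    """One state variable: a molecular pool with compartment and composition.

    ``composition`` maps monomer identities (Swi4, Swi6, Whi5, Mbp1, the two
    promoter classes) to stoichiometric counts and drives both moiety
    bookkeeping and the localization readouts.  ``phospho_state`` uses the
    site flags Whi5-P, Swi6-P, Swi6-Q (the distinct S160 site), Swi4-P and
    Bck2-modified.
    """

    name: str
    compartment: str
    role: str
    composition: Mapping[str, int] = field(default_factory=dict)
    phospho_state: frozenset = frozenset()
    promoter_bound: bool = False


def _s(name, comp, role, composition=None, phospho=(), promoter=False):
    return SpeciesDef(
        name=name,
        compartment=comp,
        role=role,
        composition=dict(composition or {}),
        phospho_state=frozenset(phospho),
        promoter_bound=promoter,
    )


def species_catalog() -> list[SpeciesDef]:
    """The full ordered species list; the order defines the state vector."""
    S = []
    # whole-cell backbone
    S += [
        _s("MASS", "cell", "mass"),
        _s("CLN2", "cell", "cyclin"),
        _s("CLB5T", "cell", "cyclin"),
        _s("CLB2T", "cell", "cyclin"),
        _s("SIC1", "cell", "CKI"),
        _s("CDC6", "cell", "CKI"),
        _s("CDH1", "cell", "regulator"),
        _s("CDC20T", "cell", "regulator"),
        _s("CDC20A", "cell", "regulator"),
        _s("CDC14", "cell", "regulator"),
        _s("MCM1", "cell", "transcription-factor complex"),
        _s("SWI5", "cell", "transcription-factor complex"),
        _s("NRM1", "nuclear", "regulator"),
        _s("BUD", "cell", "marker"),
        _s("ORI", "cell", "marker"),
        _s("SPN", "cell", "marker"),
    ]
    # size-control activators, two pools each (ER/cytoplasm and nucleus)
    S += [
        _s("CLN3C", "cytoplasmic", "cyclin"),
        _s("CLN3N", "nuclear", "cyclin"),
        _s("BCK2C", "cytoplasmic", "regulator"),
        _s("BCK2N", "nuclear", "regulator"),
    ]
    # START monomers, nuclear
    S += [
        _s("SWI4", "nuclear", "monomer", {"Swi4": 1}),
        _s("SWI6", "nuclear", "monomer", {"Swi6": 1}),
        _s("WHI5", "nuclear", "monomer", {"Whi5": 1}),
        _s("MBP1", "nuclear", "monomer", {"Mbp1": 1}),
        _s("WHI5P", "nuclear", "monomer", {"Whi5": 1}, ["Whi5-P"]),
        _s("SWI6Q", "nuclear", "monomer", {"Swi6": 1}, ["Swi6-Q"]),
        _s("SWI4P", "nuclear", "monomer", {"Swi4": 1}, ["Swi4-P"]),
    ]
    # free (promoter-unbound) complexes, nuclear
    S += [
        _s("SBFF", "nuclear", "transcription-factor complex", {"Swi4": 1, "Swi6": 1}),
        _s("WSF", "nuclear", "transcription-factor complex",
           {"Swi4": 1, "Swi6": 1, "Whi5": 1}),
        _s("S44F", "nuclear", "transcription-factor complex", {"Swi4": 2}),
        _s("MBFF", "nuclear", "transcription-factor complex", {"Mbp1": 1, "Swi6": 1}),
    ]
    # promoters and promoter-bound complexes, nuclear
    S += [
        _s("PSBF", "nuclear", "promoter-bound complex", {"PromSBF": 1}),
        _s("PMBF", "nuclear", "promoter-bound complex", {"PromMBF": 1}),
        _s("WSB", "nuclear", "promoter-bound complex",
           {"Swi4": 1, "Swi6": 1, "Whi5": 1, "PromSBF": 1}, (), True),
        _s("WSB5P", "nuclear", "promoter-bound complex",
           {"Swi4": 1, "Swi6": 1, "Whi5": 1, "PromSBF": 1}, ["Whi5-P"], True),
        _s("WSB6P", "nuclear", "promoter-bound complex",
           {"Swi4": 1, "Swi6": 1, "Whi5": 1, "PromSBF": 1}, ["Swi6-P"], True),
        _s("WSB6PQ", "nuclear", "promoter-bound complex",
           {"Swi4": 1, "Swi6": 1, "Whi5": 1, "PromSBF": 1},
           ["Swi6-P", "Swi6-Q"], True),
        _s("WSBB", "nuclear", "promoter-bound complex",
           {"Swi4": 1, "Swi6": 1, "Whi5": 1, "PromSBF": 1},
           ["Bck2-modified"], True),
        _s("SBFB", "nuclear", "promoter-bound complex",
           {"Swi4": 1, "Swi6": 1, "PromSBF": 1}, (), True),
        _s("SBFB6P", "nuclear", "promoter-bound complex",
           {"Swi4": 1, "Swi6": 1, "PromSBF": 1}, ["Swi6-P"], True),
        _s("SBFB6PQ", "nuclear", "promoter-bound complex",
           {"Swi4": 1, "Swi6": 1, "PromSBF": 1}, ["Swi6-P", "Swi6-Q"], True),
        _s("S44B", "nuclear", "promoter-bound complex",
           {"Swi4": 2, "PromSBF": 1}, (), True),
        _s("SWI4B", "nuclear", "promoter-bound complex",
           {"Swi4": 2, "PromSBF": 1}, ["Bck2-modified"], True),
        _s("MBFB", "nuclear", "promoter-bound complex",
           {"Mbp1": 1, "Swi6": 1, "PromMBF": 1}, (), True),
        _s("MBFBA", "nuclear", "promoter-bound complex",
           {"Mbp1": 1, "Swi6": 1, "PromMBF": 1}, (), True),
        _s("MBFBB", "nuclear", "promoter-bound complex",
           {"Mbp1": 1, "Swi6": 1, "PromMBF": 1}, ["Bck2-modified"], True),
        _s("MBFW", "nuclear", "promoter-bound complex",
           {"Mbp1": 1, "Swi6": 1, "Whi5": 1, "PromMBF": 1}, (), True),
    ]
    # cytoplasmic monomer pools
    S += [
        _s("WHI5PC", "cytoplasmic", "monomer", {"Whi5": 1}, ["Whi5-P"]),
        _s("WHI5C", "cytoplasmic", "monomer", {"Whi5": 1}),
        _s("SWI6QC", "cytoplasmic", "monomer", {"Swi6": 1}, ["Swi6-Q"]),
        _s("SWI6C", "cytoplasmic", "monomer", {"Swi6": 1}),
        _s("SWI4PC", "cytoplasmic", "monomer", {"Swi4": 1}, ["Swi4-P"]),
        _s("SWI4C", "cytoplasmic", "monomer", {"Swi4": 1}),
    ]
    # sanity: promoter-bound species must contain Swi4 or Mbp1 (catalog invariant)
    for sp in S:
        if sp.promoter_bound and not (sp.composition.get("Swi4") or sp.composition.get("Mbp1")):
            raise AssertionError(f"promoter-bound species {sp.name} lacks Swi4/Mbp1")
    return S


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

# Rate constants are per minute, concentrations dimensionless (a.u.).  This
# set is the package's own calibration of the published model architecture:
# it was tuned so that the wildtype daughter lineage in glucose (MDT 90 min)
# shows G1 ~ 50 min, a converged cycle consistent with the balanced-growth
# identity at a 0.46 daughter mass fraction, division mass ~ 2.5 a.u., and so
# that the mutant battery (deletion, overexpression and phospho-site alleles)
# reproduces the documented phenotypes.
DEFAULT_PARAMETERS: dict[str, float] = {
    # growth & division
    "mdt": 90.0,            # mass doubling time (min); mu = ln2/mdt
    "fdaughter": 0.46,      # daughter fraction of pre-division mass
    "thdiv": 0.2,           # division fires when active Clb2 falls through this

    # monomer totals (nuclear concentration units), ratio 3 : 1 : 0.55 : 0.2
    "SWI6T": 3.0, "WHI5T": 1.0, "SWI4T": 0.55, "MBP1T": 0.55,
    "PSBFT": 0.2, "PMBFT": 0.2,

    # Ydj1 growth/size sensor and Ssa1 retention switch
    "alpha_ydj": 0.10, "jydj": 2.8, "nydj": 2.0,
    "kassa": 1.0, "wb2ssa": 1.0, "wswssa": 0.4,
    "kissa": 0.5, "jassa": 0.01, "jissa": 0.01,

    # Cln3 / Bck2 pools
    "kscln3": 0.06, "kdcln3": 0.10, "kin3p": 0.0005, "kin3": 0.06, "kout3": 1.0,
    "ksbck2": 0.025, "kdbck2": 0.10, "kin2p": 0.0005, "kin2": 0.06, "kout2": 1.0,
    "ksgal_cln3": 0.0, "ksgal_bck2": 0.0,

    # Cln-kinase (Vpcln) Hill switch and kinase efficiencies
    "kpcln": 0.8, "jpcln": 2.0, "npcln": 2.0,
    "ecln3": 1.0, "ecln2": 0.1, "eclb5": 0.1,
    # MBF activation switch
    "kpmbf": 0.35, "jpmbf": 2.0, "npmbf": 2.0,
    "em3": 1.0, "em2": 0.1, "em5": 0.1,
    # relative efficiency of the Cln sites on Swi6 vs Whi5, and the
    # processivity gain on the second site of an engaged complex
    "e6rel": 1.3, "eproc": 5.0,
    # phosphatases
    "kpp2a": 0.2, "kppase": 0.2, "kcdc14w": 1.0, "kcdc14q": 1.0,
    # Clb-directed phosphorylation: Q-site on Swi6, and Swi4 site (promoter release)
    "kq": 0.6, "eq5": 0.3, "eq2": 1.0, "k4s4": 0.4,

    # association / dissociation
    "kasbf": 10.0, "kdsbf": 0.01,
    "kaws": 10.0, "kdws": 0.02,
    "kambf": 10.0, "kdmbf": 0.02,
    "ka44": 2.0, "kd44": 0.2,
    "kbp": 20.0, "kup": 0.05,
    "kbp44": 10.0, "kup44": 0.2,
    # weak excess-Whi5 inhibition of MBF
    "kaw5m": 1.05, "kdw5m": 0.25,

    # Bck2 modification and MBF switching
    "kabck": 0.13, "kibck": 0.15,
    "kabcks": 0.08, "kibcks": 0.15, "jqw5": 0.8, "wab": 0.3,
    "kabckm": 0.03, "kibckm": 0.15,
    "kinrm": 1.2, "kinrm_b": 0.6, "kimbfp": 0.05, "kimbf2": 0.3,
    "ksnrm1": 0.6, "kdnrm1": 0.12,

    # activity weights of promoter-bound classes (light-green classes < 1)
    "wa1": 0.5, "wa2": 1.0, "wa3": 1.0, "wa4": 1.0, "wa5": 0.27,
    "wma": 1.0, "wmb": 0.6,

    # Msn5 export, PP2A/Ppase recycling, re-import
    "MSN5": 1.0, "kexw5": 0.6, "kexs6": 0.6, "kexs4": 0.02, "kimp": 1.0,

    # backbone: Cln2 (mass-independent synthesis), Clb5, Clb2
    "kscln2": 1.1, "rho_mbf_cln2": 0.4, "kdcln2": 0.15, "ksgal_cln2": 0.0,
    "ksclb5p": 0.002, "ksclb5": 0.3, "rho_sbf_clb5": 0.4,
    "kdclb5": 0.08, "kdclb5_20": 1.0, "ksgal_clb5": 0.0,
    "ksclb2p": 0.007, "ksclb2": 0.2,
    "kdclb2p": 0.03, "kdclb2_dh": 0.8, "kdclb2_20": 0.8, "ksgal_clb2": 0.0,
    # CKI stoichiometric binding of Clb pools
    "kdcki": 0.002,
    "kssic1p": 0.012, "kssic1": 0.6, "kdsic1p": 0.01, "kdsic1": 1.2,
    "ksgal_sic1": 0.0,
    "kscdc6p": 0.010, "kscdc6": 0.18, "kdcdc6p": 0.01, "kdcdc6": 0.8,
    "eck2": 0.12, "eck5": 0.6, "eckb2": 1.0, "eck3": 0.001, "eckbck": 2.5,
    # Cdh1
    "kacdh1p": 0.15, "kacdh1": 0.6, "jacdh1": 0.03,
    "kicdh1": 1.0, "jicdh1": 0.03,
    "edh2": 0.25, "edh5": 0.8, "edhb2": 0.6, "edh3": 0.002,
    # Cdc20 / Cdc14 / Mcm1 / Swi5
    "ks20p": 0.005, "ks20": 0.3, "kd20": 0.12,
    "ka20": 0.08, "jspn20": 1.15, "nspn20": 8.0, "ki20": 0.1,
    "ka14": 1.0, "cdc14T": 2.0, "ki14": 0.35,
    "kamcm": 0.35, "jamcm": 0.1, "kimcm": 0.2, "jimcm": 0.1,
    "ksswi5p": 0.004, "ksswi5": 0.25, "kdswi5": 0.1, "j14swi5": 0.25,
    # event markers
    "ksbud": 0.45, "ebud2": 1.0, "ebud3": 0.1, "ebud5": 0.6, "kdbud": 0.25,
    "ksori": 0.5, "eori5": 1.0, "eori2": 0.06, "kdori": 0.05,
    "ksspn": 0.0455, "jspn": 0.35, "kdspn": 0.01,

    # phospho-site allele multipliers (1 = wildtype site intact)
    "whi5_phos": 1.0, "swi6_phos": 1.0, "swi6_qphos": 1.0,
    # abundance multiplier applied to conserved-monomer totals by
    # GAL/multicopy alleles of Whi5/Swi4/Swi6/Mbp1 (1 = wildtype)
    "gal_whi5": 1.0, "gal_swi4": 1.0, "gal_swi6": 1.0, "gal_mbp1": 1.0,
}


class ParameterSet(dict):
    """Named rate constants; unknown names are rejected on update.

    A plain mapping ``name -> value`` seeded from :data:`DEFAULT_PARAMETERS`.
    """

    def __init__(self, overrides: Mapping[str, float] | None = None):
        super().__init__(DEFAULT_PARAMETERS)
        if overrides:
            self.update_checked(overrides)

    def update_checked(self, overrides: Mapping[str, float]) -> None:
        unknown = set(overrides) - set(DEFAULT_PARAMETERS)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        self.update(overrides)

    def validate(self) -> None:
        for k, v in self.items():
            if k in ("whi5_phos", "swi6_phos", "swi6_qphos"):
                continue
            if v < 0:
                raise ValueError(f"rate constant {k} must be >= 0 (got {v})")
        if self["npcln"] < 1 or self["npmbf"] < 1:
            raise ValueError("Hill coefficients must be >= 1")
        if not (0.0 < self["fdaughter"] < 1.0):
            raise ValueError("fdaughter must lie in (0, 1)")


# --------------------------------------------------------------------------
# auxiliary (algebraic) quantities, in evaluation order
# --------------------------------------------------------------------------

AUX_DEFS: list[tuple[str, str]] = [
    ("mu", "0.6931471805599453 / mdt"),
    # competitive stoichiometric sequestration of the Clb pool by the CKIs
    ("CKIT", "SIC1 + CDC6"),
    ("CLBT", "CLB5T + CLB2T"),
    ("CLBF", "0.5*((CLBT - CKIT - kdcki)"
             " + sqrt((CLBT - CKIT - kdcki)**2 + 4.0*kdcki*CLBT))"),
    ("FRCLB", "CLBF / (CLBT + 1e-12)"),
    ("CLB5A", "CLB5T * FRCLB"),
    ("CLB2A", "CLB2T * FRCLB"),
    ("SWI5A", "SWI5 * CDC14 / (j14swi5 + CDC14)"),
    # Ydj1 reads size through a growth-rate-weighted mass signal
    ("YDJ1", "hill(MASS * (0.007701635339554948 / mu)**alpha_ydj, jydj, nydj)"),
    ("SSA1", "gkf(kassa*(wb2ssa*CLB2A + wswssa*SWI5A) + 1e-9,"
             " kissa, jassa, jissa)"),
    ("XCLN", "ecln3*CLN3N + ecln2*CLN2 + eclb5*CLB5A"),
    ("VPCLN", "kpcln * hill(XCLN, jpcln, npcln)"),
    ("XMBF", "em3*CLN3N + em2*CLN2 + em5*CLB5A"),
    ("VPMBF", "kpmbf * hill(XMBF, jpmbf, npmbf)"),
    ("VQ", "kq*(eq5*CLB5A + eq2*CLB2A)"),
    ("V4", "k4s4*CLB2A"),
    ("ASBF", "wa1*SBFB + wa2*(SBFB6P + SBFB6PQ) + wa3*(WSB6P + WSB6PQ)"
             " + wa4*WSB5P + wa5*SWI4B + wab*WSBB"),
    ("AMBF", "wma*MBFBA + wmb*MBFBB"),
    ("VKCKI", "eck2*CLN2 + eck5*CLB5A + eckb2*CLB2A + eck3*CLN3N"
              " + eckbck*BCK2N"),
    ("VKCDH", "edh2*CLN2 + edh5*CLB5A + edhb2*CLB2A + edh3*CLN3N"),
]


# --------------------------------------------------------------------------
# reactions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One elementary step: net stoichiometry plus a rate-law expression.

    ``rate`` is an expression in species, parameters and aux names, in
    concentration units of the ``compartment`` the reaction is evaluated in.
    ``conserving`` marks pure binding/modification/transport steps (no
    synthesis or degradation) — only these enter moiety analysis.
    """

    name: str
    stoich: Mapping[str, int]
    rate: str
    compartment: str = "nuclear"
    conserving: bool = True


def _r(name, stoich, rate, comp="nuclear", conserving=True):
    return Reaction(name, dict(stoich), rate, comp, conserving)


def reaction_catalog() -> list[Reaction]:
    R = []
    # ---- growth ----
    R += [_r("growth", {"MASS": 1}, "mu*MASS", "cell", False)]
    # ---- backbone synthesis / degradation ----
    R += [
        _r("cln2_syn", {"CLN2": 1},
           "kscln2*(ASBF + rho_mbf_cln2*AMBF) + ksgal_cln2", "cell", False),
        _r("cln2_deg", {"CLN2": -1}, "kdcln2*CLN2", "cell", False),
        _r("clb5_syn", {"CLB5T": 1},
           "(ksclb5p + ksclb5*(AMBF + rho_sbf_clb5*ASBF))*MASS + ksgal_clb5",
           "cell", False),
        _r("clb5_deg", {"CLB5T": -1},
           "(kdclb5 + kdclb5_20*CDC20A)*CLB5T", "cell", False),
        _r("clb2_syn", {"CLB2T": 1},
           "(ksclb2p + ksclb2*MCM1)*MASS + ksgal_clb2", "cell", False),
        _r("clb2_deg", {"CLB2T": -1},
           "(kdclb2p + kdclb2_dh*CDH1 + kdclb2_20*CDC20A)*CLB2T", "cell", False),
        _r("sic1_syn", {"SIC1": 1},
           "kssic1p + kssic1*SWI5A + ksgal_sic1", "cell", False),
        _r("sic1_deg", {"SIC1": -1},
           "(kdsic1p + kdsic1*VKCKI)*SIC1", "cell", False),
        _r("cdc6_syn", {"CDC6": 1}, "kscdc6p + kscdc6*SWI5A", "cell", False),
        _r("cdc6_deg", {"CDC6": -1},
           "(kdcdc6p + kdcdc6*VKCKI)*CDC6", "cell", False),
        _r("cdh1_act", {"CDH1": 1},
           "(kacdh1p + kacdh1*CDC14)*pos(1.0-CDH1)/(jacdh1 + pos(1.0-CDH1))",
           "cell", False),
        _r("cdh1_inact", {"CDH1": -1},
           "kicdh1*VKCDH*CDH1/(jicdh1 + CDH1)", "cell", False),
        _r("cdc20_syn", {"CDC20T": 1}, "ks20p + ks20*MCM1", "cell", False),
        _r("cdc20t_deg", {"CDC20T": -1}, "kd20*CDC20T", "cell", False),
        _r("cdc20a_deg", {"CDC20A": -1}, "kd20*CDC20A", "cell", False),
        _r("cdc20_act", {"CDC20A": 1},
           "ka20*pos(CDC20T-CDC20A)*hill(SPN + 1e-12, jspn20, nspn20)",
           "cell", False),
        _r("cdc20_inact", {"CDC20A": -1}, "ki20*CDC20A", "cell", False),
        _r("cdc14_act", {"CDC14": 1},
           "ka14*CDC20A*pos(cdc14T-CDC14)", "cell", False),
        _r("cdc14_inact", {"CDC14": -1}, "ki14*CDC14", "cell", False),
        _r("mcm1_act", {"MCM1": 1},
           "kamcm*CLB2A*pos(1.0-MCM1)/(jamcm + pos(1.0-MCM1))", "cell", False),
        _r("mcm1_inact", {"MCM1": -1}, "kimcm*MCM1/(jimcm + MCM1)", "cell", False),
        _r("swi5_syn", {"SWI5": 1}, "ksswi5p + ksswi5*MCM1", "cell", False),
        _r("swi5_deg", {"SWI5": -1}, "kdswi5*SWI5", "cell", False),
        _r("nrm1_syn", {"NRM1": 1}, "ksnrm1*AMBF", "nuclear", False),
        _r("nrm1_deg", {"NRM1": -1}, "kdnrm1*NRM1", "nuclear", False),
        _r("bud_syn", {"BUD": 1},
           "ksbud*(ebud2*CLN2 + ebud3*CLN3N + ebud5*CLB5A)", "cell", False),
        _r("bud_deg", {"BUD": -1}, "kdbud*BUD", "cell", False),
        _r("ori_syn", {"ORI": 1},
           "ksori*(eori5*CLB5A + eori2*CLB2A)", "cell", False),
        _r("ori_deg", {"ORI": -1}, "kdori*ORI", "cell", False),
        _r("spn_syn", {"SPN": 1}, "ksspn*CLB2A/(jspn + CLB2A)", "cell", False),
        _r("spn_deg", {"SPN": -1}, "kdspn*SPN", "cell", False),
    ]
    # ---- Cln3 and Bck2: synthesis in the ER/cytoplasmic pool, Ydj1-gated
    #      nuclear import, Ssa1-driven retention/export ----
    R += [
        _r("cln3_syn", {"CLN3C": 1},
           "kscln3*MASS + ksgal_cln3", "cytoplasmic", False),
        _r("cln3c_deg", {"CLN3C": -1}, "kdcln3*CLN3C", "cytoplasmic", False),
        _r("cln3n_deg", {"CLN3N": -1}, "kdcln3*CLN3N", "nuclear", False),
        _r("cln3_imp", {"CLN3C": -1, "CLN3N": 1},
           "(kin3p + kin3*YDJ1)*CLN3C", "cytoplasmic"),
        _r("cln3_exp", {"CLN3N": -1, "CLN3C": 1},
           "kout3*SSA1*CLN3N", "nuclear"),
        _r("bck2_syn", {"BCK2C": 1},
           "ksbck2*MASS + ksgal_bck2", "cytoplasmic", False),
        _r("bck2c_deg", {"BCK2C": -1}, "kdbck2*BCK2C", "cytoplasmic", False),
        _r("bck2n_deg", {"BCK2N": -1}, "kdbck2*BCK2N", "nuclear", False),
        _r("bck2_imp", {"BCK2C": -1, "BCK2N": 1},
           "(kin2p + kin2*YDJ1)*BCK2C", "cytoplasmic"),
        _r("bck2_exp", {"BCK2N": -1, "BCK2C": 1},
           "kout2*SSA1*BCK2N", "nuclear"),
    ]
    # ---- complex assembly and promoter binding ----
    R += [
        _r("sbf_asm", {"SWI4": -1, "SWI6": -1, "SBFF": 1}, "kasbf*SWI4*SWI6"),
        _r("sbf_dis", {"SBFF": -1, "SWI4": 1, "SWI6": 1}, "kdsbf*SBFF"),
        _r("ws_asm", {"SBFF": -1, "WHI5": -1, "WSF": 1}, "kaws*SBFF*WHI5"),
        _r("ws_dis", {"WSF": -1, "SBFF": 1, "WHI5": 1}, "kdws*WSF"),
        _r("mbf_asm", {"MBP1": -1, "SWI6": -1, "MBFF": 1}, "kambf*MBP1*SWI6"),
        _r("mbf_dis", {"MBFF": -1, "MBP1": 1, "SWI6": 1}, "kdmbf*MBFF"),
        _r("s44_asm", {"SWI4": -2, "S44F": 1}, "ka44*SWI4*SWI4"),
        _r("s44_dis", {"S44F": -1, "SWI4": 2}, "kd44*S44F"),
        _r("wsb_bind", {"PSBF": -1, "WSF": -1, "WSB": 1}, "kbp*PSBF*WSF"),
        _r("wsb_unbind", {"WSB": -1, "PSBF": 1, "WSF": 1}, "kup*WSB"),
        _r("sbfb_bind", {"PSBF": -1, "SBFF": -1, "SBFB": 1}, "kbp*PSBF*SBFF"),
        _r("sbfb_unbind", {"SBFB": -1, "PSBF": 1, "SBFF": 1}, "kup*SBFB"),
        _r("s44b_bind", {"PSBF": -1, "S44F": -1, "S44B": 1}, "kbp44*PSBF*S44F"),
        _r("s44b_unbind", {"S44B": -1, "PSBF": 1, "S44F": 1}, "kup44*S44B"),
        _r("mbfb_bind", {"PMBF": -1, "MBFF": -1, "MBFB": 1}, "kbp*PMBF*MBFF"),
        _r("mbfb_unbind", {"MBFB": -1, "PMBF": 1, "MBFF": 1}, "kup*MBFB"),
        # Whi5 re-loads directly onto promoter-bound SBF at mitotic exit
        _r("wsb_reform", {"SBFB": -1, "WHI5": -1, "WSB": 1}, "kaws*SBFB*WHI5"),
        _r("wsb_reform_dis", {"WSB": -1, "SBFB": 1, "WHI5": 1}, "kdws*WSB"),
        # weak, excess-only inhibition of MBF by free nuclear Whi5
        _r("mbfw_bind", {"MBFB": -1, "WHI5": -1, "MBFW": 1},
           "kaw5m*MBFB*WHI5*WHI5"),
        _r("mbfw_bind_a", {"MBFBA": -1, "WHI5": -1, "MBFW": 1},
           "kaw5m*MBFBA*WHI5*WHI5"),
        _r("mbfw_bind_b", {"MBFBB": -1, "WHI5": -1, "MBFW": 1},
           "kaw5m*MBFBB*WHI5*WHI5"),
        _r("mbfw_unbind", {"MBFW": -1, "MBFB": 1, "WHI5": 1}, "kdw5m*MBFW"),
    ]
    # ---- Cln-directed phosphorylation of promoter-bound SBF ----
    # doubly phosphorylated trimers are unstable: they dissociate into
    # Swi6-phosphorylated SBF plus free phosphorylated Whi5
    R += [
        _r("wsb_p5", {"WSB": -1, "WSB5P": 1}, "whi5_phos*VPCLN*WSB"),
        _r("wsb_p6", {"WSB": -1, "WSB6P": 1}, "swi6_phos*e6rel*VPCLN*WSB"),
        _r("wsb5p_p6", {"WSB5P": -1, "SBFB6P": 1, "WHI5P": 1},
           "swi6_phos*e6rel*eproc*VPCLN*WSB5P"),
        _r("wsb6p_p5", {"WSB6P": -1, "SBFB6P": 1, "WHI5P": 1},
           "whi5_phos*eproc*VPCLN*WSB6P"),
        _r("pp2a_wsb5p", {"WSB5P": -1, "WSB": 1}, "kpp2a*WSB5P"),
        _r("pp2a_wsb6p", {"WSB6P": -1, "WSB": 1}, "kpp2a*WSB6P"),
        _r("pp2a_sbfb6p", {"SBFB6P": -1, "SBFB": 1}, "kpp2a*SBFB6P"),
    ]
    # ---- Clb-directed Q phosphorylation of Swi6 (S160) and its reversal ----
    R += [
        _r("q_wsb6p", {"WSB6P": -1, "WSB6PQ": 1}, "swi6_qphos*VQ*WSB6P"),
        _r("q_sbfb6p", {"SBFB6P": -1, "SBFB6PQ": 1}, "swi6_qphos*VQ*SBFB6P"),
        _r("dq_wsb6pq", {"WSB6PQ": -1, "WSB6P": 1}, "kcdc14q*CDC14*WSB6PQ"),
        _r("dq_sbfb6pq", {"SBFB6PQ": -1, "SBFB6P": 1}, "kcdc14q*CDC14*SBFB6PQ"),
    ]
    # ---- Clb2 phosphorylation of Swi4 releases the promoter; complexes fall
    #      apart into monomer pools (Q-form Swi6 stays marked for export) ----
    R += [
        _r("rel_sbfb", {"SBFB": -1, "PSBF": 1, "SWI4P": 1, "SWI6": 1},
           "V4*SBFB"),
        _r("rel_sbfb6p", {"SBFB6P": -1, "PSBF": 1, "SWI4P": 1, "SWI6": 1},
           "V4*SBFB6P"),
        _r("rel_sbfb6pq", {"SBFB6PQ": -1, "PSBF": 1, "SWI4P": 1, "SWI6Q": 1},
           "V4*SBFB6PQ"),
        _r("rel_wsb", {"WSB": -1, "PSBF": 1, "SWI4P": 1, "SWI6": 1, "WHI5": 1},
           "V4*WSB"),
        _r("rel_wsb5p", {"WSB5P": -1, "PSBF": 1, "SWI4P": 1, "SWI6": 1,
                         "WHI5P": 1}, "V4*WSB5P"),
        _r("rel_wsb6p", {"WSB6P": -1, "PSBF": 1, "SWI4P": 1, "SWI6": 1,
                         "WHI5": 1}, "V4*WSB6P"),
        _r("rel_wsb6pq", {"WSB6PQ": -1, "PSBF": 1, "SWI4P": 1, "SWI6Q": 1,
                          "WHI5": 1}, "V4*WSB6PQ"),
        _r("rel_wsbb", {"WSBB": -1, "PSBF": 1, "SWI4P": 1, "SWI6": 1,
                        "WHI5": 1}, "V4*WSBB"),
        _r("rel_s44b", {"S44B": -1, "PSBF": 1, "SWI4P": 2}, "V4*S44B"),
        _r("rel_swi4b", {"SWI4B": -1, "PSBF": 1, "SWI4P": 2}, "V4*SWI4B"),
    ]
    # ---- Bck2-modified forms ----
    R += [
        _r("bck_s44b", {"S44B": -1, "SWI4B": 1}, "kabck*BCK2N*S44B"),
        _r("bck_wsb", {"WSB": -1, "WSBB": 1},
           "kabcks*BCK2N*WSB/(1.0 + (WHI5/jqw5)**2)"),
        _r("unbck_wsbb", {"WSBB": -1, "WSB": 1}, "kibcks*WSBB"),
        _r("unbck_swi4b", {"SWI4B": -1, "S44B": 1}, "kibck*SWI4B"),
        _r("mbf_act", {"MBFB": -1, "MBFBA": 1}, "VPMBF*MBFB"),
        _r("mbf_inact", {"MBFBA": -1, "MBFB": 1},
           "(kimbfp + kinrm*NRM1 + kimbf2*CLB2A)*MBFBA"),
        _r("mbf_bck", {"MBFB": -1, "MBFBB": 1}, "kabckm*BCK2N*MBFB"),
        _r("mbf_unbck", {"MBFBB": -1, "MBFB": 1},
           "(kibckm + kinrm_b*NRM1)*MBFBB"),
    ]
    # ---- free nuclear Whi5 phosphorylation and Cdc14 reversal ----
    R += [
        _r("whi5_p", {"WHI5": -1, "WHI5P": 1}, "whi5_phos*VPCLN*WHI5"),
        _r("whi5p_dp_n", {"WHI5P": -1, "WHI5": 1}, "kcdc14w*CDC14*WHI5P"),
        _r("swi6_q_free", {"SWI6": -1, "SWI6Q": 1}, "swi6_qphos*VQ*SWI6"),
        _r("swi6q_dp_n", {"SWI6Q": -1, "SWI6": 1}, "kcdc14q*CDC14*SWI6Q"),
        _r("swi4p_dp_n", {"SWI4P": -1, "SWI4": 1}, "kppase*SWI4P"),
    ]
    # ---- Msn5-mediated export, cytoplasmic dephosphorylation, re-import ----
    R += [
        _r("exp_whi5p", {"WHI5P": -1, "WHI5PC": 1}, "kexw5*MSN5*WHI5P"),
        _r("exp_swi6q", {"SWI6Q": -1, "SWI6QC": 1}, "kexs6*MSN5*SWI6Q"),
        _r("exp_swi4p", {"SWI4P": -1, "SWI4PC": 1}, "kexs4*SWI4P"),
        _r("whi5p_dp_c", {"WHI5PC": -1, "WHI5C": 1},
           "kcdc14w*CDC14*WHI5PC", "cytoplasmic"),
        _r("swi6q_dp_c", {"SWI6QC": -1, "SWI6C": 1},
           "kcdc14q*CDC14*SWI6QC", "cytoplasmic"),
        _r("swi4p_dp_c", {"SWI4PC": -1, "SWI4C": 1},
           "kppase*SWI4PC", "cytoplasmic"),
        _r("imp_whi5", {"WHI5C": -1, "WHI5": 1}, "kimp*WHI5C", "cytoplasmic"),
        _r("imp_swi6", {"SWI6C": -1, "SWI6": 1}, "kimp*SWI6C", "cytoplasmic"),
        _r("imp_swi4", {"SWI4C": -1, "SWI4": 1}, "kimp*SWI4C", "cytoplasmic"),
    ]
    return R


# --------------------------------------------------------------------------
# states and the compiled system
# --------------------------------------------------------------------------

@dataclass
class ModelState:
    """A time point: state vector over the species catalog plus helpers."""

    time: float
    concentrations: np.ndarray
    names: Sequence[str]

    def __getitem__(self, name: str) -> float:
        return float(self.concentrations[list(self.names).index(name)])

    @property
    def mass(self) -> float:
        return self["MASS"]


@dataclass
class ModelSystem:
    """Compiled ODE system: right-hand side, aux evaluator, event functions."""

    species: list[SpeciesDef]
    reactions: list[Reaction]
    parameters: ParameterSet
    layout: CompartmentLayout
    rhs: Callable[[float, np.ndarray], np.ndarray]
    aux_names: list[str]
    aux_eval: Callable[[float, np.ndarray], np.ndarray]
    param_order: list[str]
    param_values: np.ndarray

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def aux(self, name: str, t: float, y: np.ndarray) -> float:
        return float(self.aux_eval(t, y)[self.aux_names.index(name)])

    def conserved_moieties(self):
        return conserved_moieties(self)


_HELPERS = {
    "hill": kinetics.hill_activation,
    "gkf": kinetics.goldbeter_koshland,
    "sqrt": math.sqrt,
    "exp": math.exp,
    "log": math.log,
    "pos": lambda x: x if x > 0.0 else 0.0,
}

_COMPILE_CACHE: dict = {}


def _compile_system(species, reactions, layout):
    """Generate and exec the flat rhs/aux source for this network structure."""
    key = (
        tuple(s.name for s in species),
        tuple((r.name, tuple(sorted(r.stoich.items())), r.rate, r.compartment)
              for r in reactions),
        (layout.nuclear_fraction, layout.cytoplasmic_fraction),
    )
    if key in _COMPILE_CACHE:
        return _COMPILE_CACHE[key]

    names = [s.name for s in species]
    idx = {n: i for i, n in enumerate(names)}
    vol = {s.name: layout.volume(s.compartment) for s in species}
    pnames = sorted(DEFAULT_PARAMETERS)
    pidx = {n: i for i, n in enumerate(pnames)}

    lines = ["def _rhs(t, y, p, out):"]
    for n, i in idx.items():
        lines.append(f"    {n} = y[{i}]")
        lines.append(f"    if {n} < 0.0: {n} = 0.0")
    for n, i in pidx.items():
        lines.append(f"    {n} = p[{i}]")
    for an, expr in AUX_DEFS:
        lines.append(f"    {an} = {expr}")
    accum: dict[int, list[str]] = {i: [] for i in range(len(names))}
    for k, r in enumerate(reactions):
        vhome = layout.volume(r.compartment)
        lines.append(f"    v{k} = {r.rate}")
        for sp, n in r.stoich.items():
            coeff = n * vhome / vol[sp]
            if coeff == 1:
                accum[idx[sp]].append(f"v{k}")
            elif coeff == -1:
                accum[idx[sp]].append(f"-v{k}")
            else:
                accum[idx[sp]].append(f"({coeff!r})*v{k}")
    for i in range(len(names)):
        terms = accum[i]
        lines.append(f"    out[{i}] = {' + '.join(terms) if terms else '0.0'}")
    lines.append("    return out")

    aux_lines = ["def _aux(t, y, p, out):"]
    for n, i in idx.items():
        aux_lines.append(f"    {n} = y[{i}]")
        aux_lines.append(f"    if {n} < 0.0: {n} = 0.0")
    for n, i in pidx.items():
        aux_lines.append(f"    {n} = p[{i}]")
    for j, (an, expr) in enumerate(AUX_DEFS):
        aux_lines.append(f"    {an} = {expr}")
        aux_lines.append(f"    out[{j}] = {an}")
    aux_lines.append("    return out")

    ns: dict = dict(_HELPERS)
    exec("\n".join(lines), ns)          # noqa: S102 - generated from static tables
    exec("\n".join(aux_lines), ns)      # noqa: S102
    compiled = (ns["_rhs"], ns["_aux"], pnames)
    _COMPILE_CACHE[key] = compiled
    return compiled


def build_model(
    params: ParameterSet | Mapping[str, float] | None = None,
    layout: CompartmentLayout | None = None,
    mutant=None,
) -> ModelSystem:
    """Assemble and compile the full ODE system.

    ``mutant`` may be a :class:`startbycc.mutants.MutantSpec`, a genotype
    string (parsed with :func:`startbycc.mutants.parse_genotype`), or None
    for wildtype.  Mutant alterations are applied as parameter overrides
    before compilation; the network structure itself is genotype-independent.
    """
    layout = layout or DEFAULT_LAYOUT
    if params is None:
        params = ParameterSet()
    elif not isinstance(params, ParameterSet):
        params = ParameterSet(params)
    else:
        params = ParameterSet(dict(params))

    if mutant is not None:
        from . import mutants as _mutants
        if isinstance(mutant, str):
            mutant = _mutants.parse_genotype(mutant)
        params = _mutants.apply_mutant_params(params, mutant)
    params.validate()

    species = species_catalog()
    reactions = reaction_catalog()
    rhs_f, aux_f, pnames = _compile_system(species, reactions, layout)
    pvec = np.array([params[n] for n in pnames], dtype=float)
    nsp = len(species)
    naux = len(AUX_DEFS)

    def rhs(t, y, _f=rhs_f, _p=pvec, _n=nsp):
        return _f(t, y, _p, np.empty(_n))

    def aux_eval(t, y, _f=aux_f, _p=pvec, _n=naux):
        return _f(t, y, _p, np.empty(_n))

    return ModelSystem(
        species=species,
        reactions=reactions,
        parameters=params,
        layout=layout,
        rhs=rhs,
        aux_names=[a for a, _ in AUX_DEFS],
        aux_eval=aux_eval,
        param_order=list(pnames),
        param_values=pvec,
    )


# --------------------------------------------------------------------------
# initial conditions
# --------------------------------------------------------------------------

_BACKBONE_ICS = {
    "MASS": 1.2,
    "CLN2": 0.01, "CLB5T": 0.05, "CLB2T": 0.08,
    "SIC1": 0.6, "CDC6": 0.4, "CDH1": 0.95,
    "CDC20T": 0.3, "CDC20A": 0.0, "CDC14": 0.05,
    "MCM1": 0.01, "SWI5": 0.05, "NRM1": 0.05,
    "BUD": 0.0, "ORI": 0.0, "SPN": 0.0,
}


def initial_conditions(
    mutant=None,
    params: ParameterSet | Mapping[str, float] | None = None,
) -> ModelState:
    """Early-G1 state honoring the 3 : 1 : 0.55 : 0.2 monomer stoichiometry.

    The START pools are distributed the way the wildtype network itself
    relaxes in early G1: promoters mostly occupied by inactive Whi5-bound SBF
    and repressed MBF, most Swi4 in trimers, most Mbp1 in MBF, the surplus
    Swi6 and Whi5 free and nuclear.  Deleted monomers simply leave their
    complexes unformed, so the same algorithm covers every mutant.
    """
    if params is None:
        params = ParameterSet()
    elif not isinstance(params, ParameterSet):
        params = ParameterSet(params)
    else:
        params = ParameterSet(dict(params))
    if mutant is not None:
        from . import mutants as _mutants
        if isinstance(mutant, str):
            mutant = _mutants.parse_genotype(mutant)
        params = _mutants.apply_mutant_params(params, mutant)

    species = species_catalog()
    names = [s.name for s in species]
    y = np.zeros(len(names))
    put = dict.fromkeys(names, 0.0)
    put.update(_BACKBONE_ICS)

    swi4 = params["SWI4T"] * params["gal_swi4"]
    swi6 = params["SWI6T"] * params["gal_swi6"]
    whi5 = params["WHI5T"] * params["gal_whi5"]
    mbp1 = params["MBP1T"] * params["gal_mbp1"]
    psbf = params["PSBFT"]
    pmbf = params["PMBFT"]

    # assemble complexes in affinity order: SBF, then MBF, then Whi5 loading
    sbf = min(swi4, swi6)
    swi4_left = swi4 - sbf
    swi6_left = swi6 - sbf
    mbf = min(mbp1, swi6_left)
    swi6_left -= mbf
    ws = min(sbf, whi5)
    sbf_left = sbf - ws
    whi5_left = whi5 - ws
    s44 = swi4_left / 2.0

    occupancy = 0.95
    wsb = min(psbf * occupancy, ws)
    ws_free = ws - wsb
    psbf_left = psbf - wsb
    sbfb = min(psbf_left * occupancy, sbf_left)
    sbf_free = sbf_left - sbfb
    psbf_left -= sbfb
    s44b = min(psbf_left * occupancy, s44)
    s44_free = s44 - s44b
    psbf_left -= s44b
    mbfb = min(pmbf * occupancy, mbf)
    mbf_free = mbf - mbfb
    pmbf_left = pmbf - mbfb

    put.update({
        "SWI4": 0.0, "SWI6": swi6_left, "WHI5": whi5_left, "MBP1": mbp1 - mbf,
        "SBFF": sbf_free, "WSF": ws_free, "S44F": s44_free, "MBFF": mbf_free,
        "PSBF": psbf_left, "PMBF": pmbf_left,
        "WSB": wsb, "SBFB": sbfb, "S44B": s44b, "MBFB": mbfb,
    })

    # size-control activators start at their slow-growth quasi-steady levels
    kd3 = params["kdcln3"]
    if kd3 > 0:
        put["CLN3C"] = (params["kscln3"] * put["MASS"]
                        + params["ksgal_cln3"]) / kd3
    put["CLN3N"] = 0.01 if (params["kscln3"] or params["ksgal_cln3"]) else 0.0
    kd2 = params["kdbck2"]
    if kd2 > 0:
        put["BCK2C"] = (params["ksbck2"] * put["MASS"]
                        + params["ksgal_bck2"]) / kd2
    put["BCK2N"] = 0.01 if (params["ksbck2"] or params["ksgal_bck2"]) else 0.0

    for i, n in enumerate(names):
        y[i] = put[n]
    return ModelState(time=0.0, concentrations=y, names=names)


# --------------------------------------------------------------------------
# stoichiometric count rescaling
# --------------------------------------------------------------------------

#: monomer : promoter abundance ratios (exact, nuclear concentration units)
STOICH_RATIOS = {
    "promoter": Fraction(1, 5),
    "Swi4/Mbp1": Fraction(11, 20),
    "Whi5": Fraction(1),
    "Swi6": Fraction(3),
}


def rescale_counts(promoter_copies: int) -> dict[str, int]:
    """Integer molecule counts at a given promoter copy number.

    Scales the abundance ratios 0.2 : 0.55 : 1 : 3 so the promoter pool has
    the requested copy number, rounding each monomer count to the nearest
    integer in exact rational arithmetic (4 promoters -> 11 Swi4/Mbp1,
    20 Whi5, 60 Swi6).
    """
    if not isinstance(promoter_copies, (int, np.integer)) or promoter_copies < 1:
        raise ValueError("promoter_copies must be a positive integer")
    scale = Fraction(int(promoter_copies)) / STOICH_RATIOS["promoter"]
    out = {}
    for k, r in STOICH_RATIOS.items():
        x = r * scale
        out[k] = int(x + Fraction(1, 2))  # floor(x + 1/2): round half up
    out["promoter"] = int(promoter_copies)
    return out


# --------------------------------------------------------------------------
# moiety (conservation-law) analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Moiety:
    """A linear invariant: sum over species of coeff * molecule number."""

    coefficients: Mapping[str, float]

    def evaluate(self, state: np.ndarray, system: ModelSystem) -> float:
        total = 0.0
        names = system.names
        for sp, c in self.coefficients.items():
            i = names.index(sp)
            total += c * system.layout.volume(system.species[i].compartment) \
                * state[i]
        return total

    def __repr__(self) -> str:
        parts = [f"{c:g}*{s}" if c != 1 else s
                 for s, c in sorted(self.coefficients.items())]
        return "Moiety(" + " + ".join(parts) + ")"


def conserved_moieties(system: ModelSystem) -> list[Moiety]:
    """Left-null-space basis of the conserving-reaction stoichiometry.

    Species that appear in any synthesis/degradation reaction are excluded
    (their pools are open), so the invariants returned hold along any
    trajectory, not only under pure binding/transport.  The basis is computed
    exactly with rational arithmetic via sympy.
    """
    import sympy

    names = system.names
    vol = np.array([system.layout.volume(s.compartment) for s in system.species])
    open_species = set()
    cols = []
    for r in system.reactions:
        if r.conserving:
            col = np.zeros(len(names))
            for sp, n in r.stoich.items():
                # stoichiometry in molecule numbers per unit reaction extent
                col[names.index(sp)] = n
            cols.append(col)
        else:
            open_species.update(r.stoich)
    if not cols:
        return []
    S = np.array(cols).T  # species x reactions
    # strike rows of open species: any invariant touching them is not global
    keep = [i for i, n in enumerate(names) if n not in open_species]
    Sk = sympy.Matrix(S[keep, :].astype(int))

    # composition-based candidates first: the total of each monomer class is
    # the natural (non-negative) moiety whenever it annihilates the
    # stoichiometry, i.e. whenever that monomer has no open reactions
    monomers = sorted({m for sp in system.species for m in sp.composition})
    chosen: list[sympy.Matrix] = []
    moieties: list[Moiety] = []

    def _is_new(vec):
        if not chosen:
            return True
        M = sympy.Matrix.hstack(*chosen)
        return M.rank() < M.row_join(vec).rank()

    for mono in monomers:
        w = sympy.Matrix([system.species[i].composition.get(mono, 0)
                          for i in keep])
        if w.is_zero_matrix or not (w.T * Sk).is_zero_matrix:
            continue
        if _is_new(w):
            chosen.append(w)
            moieties.append(Moiety({
                names[keep[i]]: float(w[i]) for i in range(len(keep))
                if w[i] != 0}))
    # extend with any remaining independent left-null vectors
    for v in Sk.T.nullspace():
        denom = 1
        for x in v:
            denom = sympy.ilcm(denom, sympy.fraction(sympy.nsimplify(x))[1])
        v = v * denom
        if max(v, key=abs) < 0:
            v = -v
        if _is_new(v):
            chosen.append(v)
            moieties.append(Moiety({
                names[keep[i]]: float(v[i]) for i in range(len(keep))
                if v[i] != 0}))
    return moieties


def moiety_totals(system: ModelSystem, state: np.ndarray) -> dict[str, float]:
    """Total molecule number of each monomer class (volume-weighted)."""
    totals: dict[str, float] = {}
    for i, sp in enumerate(system.species):
        v = system.layout.volume(sp.compartment)
        for mono, n in sp.composition.items():
            totals[mono] = totals.get(mono, 0.0) + n * v * state[i]
    return totals
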