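"""Declarative mutant specification and parameter/IC overrides.

Genotype strings in the field's usual notation — ``cln3Δ bck2Δ``,
``GAL-WHI5-12A SWI6-SA4``, ``mc-BCK2`` — are parsed into a
:class:`MutantSpec` of per-gene alterations, which map onto parameter
overrides of the wildtype model: deletions zero synthesis rates and initial
pools, GAL alleles add strong constitutive (mass-independent) synthesis or
raise a conserved monomer's total abundance, multicopy alleles multiply the
wildtype synthesis rate by copy number, and phospho-site knockouts zero the
corresponding phosphorylation rate constants and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .model_core import ParameterSet

__all__ = [
    "Alteration",
    "MutantSpec",
    "MutantCatalogEntry",
    "GenotypeError",
    "parse_genotype",
    "apply_mutant",
    "apply_mutant_params",
    "run_catalog",
    "concordance_report",
    "ConcordanceReport",
    "load_catalog",
    "builtin_catalog",
]


class GenotypeError(ValueError):
    """Unknown gene/site token or conflicting alterations."""


#: genes the catalog knows; CLN1/CLN2 share the model's lumped Cln1,2 pool
KNOWN_GENES = {
    "CLN1", "CLN2", "CLN3", "BCK2", "WHI5", "SWI4", "SWI6", "MBP1",
    "MSN5", "SIC1", "CDC6", "CDH1", "CLB5", "CLB2", "NRM1",
}

#: phospho-site knockout alleles and the site multiplier each one zeroes
ALLELES = {
    "WHI5-12A": ("WHI5", "whi5_phos"),     # all Cln sites on Whi5
    "SWI6-SA4": ("SWI6", "swi6_phos"),     # all Cln sites on Swi6
    "SWI6-S160A": ("SWI6", "swi6_qphos"),  # the distinct Clb site (Q form)
    "CLN3-1": ("CLN3", None),              # hyperstable allele (elevated pool)
}

#: constitutive (mass-independent) GAL synthesis rates, per min — strong
#: overexpression relative to each gene's wildtype maximal synthesis flux
GAL_RATES = {
    "CLN2": 0.5, "CLB5": 0.12, "CLB2": 0.3, "CLN3": 0.6, "BCK2": 0.25,
    "SIC1": 0.3,
}

#: abundance fold applied by GAL alleles of the conserved START monomers
GAL_MONOMER_FOLD = 8.0

#: default copy number for multicopy (mc-) alleles
MC_COPIES = 5


@dataclass(frozen=True)
class Alteration:
    gene: str
    kind: str  # deletion | GAL-overexpression | multicopy | phospho-site-knockout | allele-substitution
    magnitude: float = 0.0
    site: str | None = None


@dataclass(frozen=True)
class MutantSpec:
    """A set of per-gene alterations plus the canonical genotype label."""

    alterations: tuple[Alteration, ...] = ()
    label: str = "wildtype"

    def __post_init__(self) -> None:
        seen: dict[str, list[str]] = {}
        for a in self.alterations:
            seen.setdefault(a.gene, []).append(a.kind)
        for gene, kinds in seen.items():
            if "deletion" in kinds and len(kinds) > 1:
                raise GenotypeError(
                    f"{gene}: deletion conflicts with {sorted(set(kinds) - {'deletion'})}"
                )
            if kinds.count("deletion") > 1 or kinds.count("GAL-overexpression") > 1:
                raise GenotypeError(f"{gene}: duplicate alteration")

    @property
    def is_wildtype(self) -> bool:
        return not self.alterations

    def genes(self) -> set[str]:
        return {a.gene for a in self.alterations}


def _canonical_token(alt: Alteration) -> str:
    if alt.kind == "deletion":
        return alt.gene.lower() + "Δ"
    if alt.kind == "GAL-overexpression":
        if alt.site:  # e.g. GAL-WHI5-12A
            return "GAL-" + alt.site
        return "GAL-" + alt.gene
    if alt.kind == "multicopy":
        return "mc-" + alt.gene
    if alt.kind in ("phospho-site-knockout", "allele-substitution"):
        return alt.site or alt.gene
    raise GenotypeError(f"unknown alteration kind {alt.kind!r}")


def spec_to_label(spec: MutantSpec) -> str:
    if spec.is_wildtype:
        return "wildtype"
    return " ".join(sorted(_canonical_token(a) for a in spec.alterations))


def parse_genotype(label: str) -> MutantSpec:
    """Parse a genotype string into a canonical :class:`MutantSpec`.

    Accepted tokens (whitespace-separated, order-insensitive):

    * ``geneΔ`` or ``geneD`` or ``gene-del`` — deletion
    * ``GAL-GENE`` — galactose-promoter overexpression
    * ``mc-GENE`` — multicopy (5 copies)
    * ``WHI5-12A``, ``SWI6-SA4``, ``SWI6-S160A`` — phospho-site knockouts
    * ``GAL-WHI5-12A`` — overexpression of the non-phosphorylable allele
    * ``CLN3-1`` — hyperstable Cln3
    * ``wildtype`` / ``WT`` / empty — no alterations
    """
    alts: list[Alteration] = []
    text = (label or "").strip()
    if text.lower() in ("", "wildtype", "wt", "wild-type"):
        return MutantSpec((), "wildtype")
    for tok in text.split():
        upper = tok.upper()
        if upper.endswith("Δ") or upper.endswith("-DEL") or upper.endswith("DEL"):
            for suffix in ("Δ", "-DEL", "DEL"):
                if upper.endswith(suffix):
                    gene = upper[: -len(suffix)]
                    break
            if gene not in KNOWN_GENES:
                raise GenotypeError(
                    f"unknown gene in token {tok!r}; known genes: "
                    f"{sorted(KNOWN_GENES)}")
            alts.append(Alteration(gene, "deletion"))
        elif upper.startswith("GAL-"):
            rest = upper[4:]
            if rest in ALLELES:  # GAL-WHI5-12A
                gene, mult = ALLELES[rest]
                alts.append(Alteration(gene, "GAL-overexpression",
                                       GAL_MONOMER_FOLD, site=rest))
                alts.append(Alteration(gene, "phospho-site-knockout",
                                       site=rest))
            elif rest in KNOWN_GENES:
                alts.append(Alteration(rest, "GAL-overexpression",
                                       GAL_RATES.get(rest, GAL_MONOMER_FOLD)))
            else:
                raise GenotypeError(f"unknown gene in token {tok!r}")
        elif upper.startswith("MC-"):
            gene = upper[3:]
            if gene not in KNOWN_GENES:
                raise GenotypeError(f"unknown gene in token {tok!r}")
            alts.append(Alteration(gene, "multicopy", MC_COPIES))
        elif upper in ALLELES:
            gene, mult = ALLELES[upper]
            kind = ("allele-substitution" if upper == "CLN3-1"
                    else "phospho-site-knockout")
            alts.append(Alteration(gene, kind, site=upper))
        else:
            raise GenotypeError(
                f"cannot parse token {tok!r}; valid forms: geneΔ, GAL-GENE, "
                f"mc-GENE, {sorted(ALLELES)}")
    # deduplicate phospho knockouts arriving twice via GAL-allele + explicit
    seen = set()
    uniq = []
    for a in alts:
        key = (a.gene, a.kind, a.site)
        if key not in seen:
            seen.add(key)
            uniq.append(a)
    spec = MutantSpec(tuple(uniq), label=text)
    return spec


# --------------------------------------------------------------------------
# parameter / IC overrides
# --------------------------------------------------------------------------

_DELETION_OVERRIDES: dict[str, dict[str, float]] = {
    "CLN3": {"kscln3": 0.0, "ksgal_cln3": 0.0},
    "BCK2": {"ksbck2": 0.0, "ksgal_bck2": 0.0},
    "WHI5": {"WHI5T": 0.0, "gal_whi5": 1.0},
    "SWI4": {"SWI4T": 0.0, "gal_swi4": 1.0},
    "SWI6": {"SWI6T": 0.0, "gal_swi6": 1.0},
    "MBP1": {"MBP1T": 0.0, "gal_mbp1": 1.0},
    "MSN5": {"MSN5": 0.0},
    "SIC1": {"kssic1p": 0.0, "kssic1": 0.0, "ksgal_sic1": 0.0},
    "CDC6": {"kscdc6p": 0.0, "kscdc6": 0.0},
    "CDH1": {"kacdh1p": 0.0, "kacdh1": 0.0},
    "CLB5": {"ksclb5p": 0.0, "ksclb5": 0.0, "ksgal_clb5": 0.0},
    "CLB2": {"ksclb2p": 0.0, "ksclb2": 0.0, "ksgal_clb2": 0.0},
    "NRM1": {"ksnrm1": 0.0},
}

_GAL_PARAM = {
    "CLN2": "ksgal_cln2", "CLB5": "ksgal_clb5", "CLB2": "ksgal_clb2",
    "CLN3": "ksgal_cln3", "BCK2": "ksgal_bck2", "SIC1": "ksgal_sic1",
}
_GAL_MONOMER = {
    "WHI5": "gal_whi5", "SWI4": "gal_swi4", "SWI6": "gal_swi6",
    "MBP1": "gal_mbp1",
}
_MC_SYNTH = {
    "BCK2": "ksbck2", "CLN3": "kscln3", "CLN2": "kscln2",
    "CLB5": "ksclb5", "CLB2": "ksclb2", "SIC1": "kssic1",
}
_SITE_PARAM = {"WHI5-12A": "whi5_phos", "SWI6-SA4": "swi6_phos",
               "SWI6-S160A": "swi6_qphos"}

#: fold elevation of the Cln3 pool for the hyperstable CLN3-1 allele
CLN3_1_FOLD = 2.5


def apply_mutant_params(
    params: ParameterSet | Mapping[str, float],
    spec: MutantSpec,
) -> ParameterSet:
    """Return a new parameter set with the spec's alterations applied."""
    p = ParameterSet(dict(params))
    cln12_deletions = {a.gene for a in spec.alterations
                       if a.kind == "deletion" and a.gene in ("CLN1", "CLN2")}
    for a in spec.alterations:
        if a.kind == "deletion":
            if a.gene in ("CLN1", "CLN2"):
                continue  # handled jointly below (lumped Cln1,2 pool)
            try:
                p.update(_DELETION_OVERRIDES[a.gene])
            except KeyError:
                raise GenotypeError(f"no deletion mapping for gene {a.gene}")
        elif a.kind == "GAL-overexpression":
            if a.gene in _GAL_MONOMER:
                p[_GAL_MONOMER[a.gene]] = float(a.magnitude or GAL_MONOMER_FOLD)
            elif a.gene in _GAL_PARAM:
                p[_GAL_PARAM[a.gene]] = float(a.magnitude or GAL_RATES[a.gene])
            else:
                raise GenotypeError(f"no overexpression mapping for {a.gene}")
        elif a.kind == "multicopy":
            n = float(a.magnitude or MC_COPIES)
            if a.gene in _GAL_MONOMER:
                p[_GAL_MONOMER[a.gene]] = n
            elif a.gene in _MC_SYNTH:
                p[_MC_SYNTH[a.gene]] = p[_MC_SYNTH[a.gene]] * n
            else:
                raise GenotypeError(f"no multicopy mapping for {a.gene}")
        elif a.kind == "phospho-site-knockout":
            if a.site not in _SITE_PARAM:
                raise GenotypeError(f"unknown phospho-site allele {a.site!r}")
            p[_SITE_PARAM[a.site]] = 0.0
        elif a.kind == "allele-substitution":
            if a.site == "CLN3-1":
                # hyperstable allele: elevated steady pool, normal turnover
                p["kscln3"] = p["kscln3"] * CLN3_1_FOLD
            else:
                raise GenotypeError(f"unknown allele {a.site!r}")
        else:
            raise GenotypeError(f"unknown alteration kind {a.kind!r}")
    if cln12_deletions == {"CLN1", "CLN2"}:
        p["kscln2"] = 0.0
    return p


def apply_mutant(params, ics, spec: MutantSpec):
    """Spec-level override entry point: returns (ParameterSet, ModelState).

    The returned initial state is rebuilt from the mutated parameter set, so
    deletions start with empty pools and monomer overexpression starts at the
    raised totals.
    """
    from .model_core import initial_conditions
    p = apply_mutant_params(params, spec)
    return p, initial_conditions(params=p)


# --------------------------------------------------------------------------
# catalog
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MutantCatalogEntry:
    """One screened genotype with its documented expected phenotype."""

    genotype: str
    expected_viable: bool
    expected_size: tuple[float, float] | None = None  # fold-WT range
    size_class: str | None = None  # small | ~WT | large | very-large
    provenance: str = "experiment"  # experiment | model prediction | validated prediction | contradiction
    notes: str = ""


def builtin_catalog() -> list[MutantCatalogEntry]:
    """The shipped START-mutant catalog (documented phenotypes).

    Loaded from the packaged ``data/mutant_catalog.yaml`` fixture.  Numeric
    folds are quoted where the source prints them; otherwise the qualitative
    size class is recorded.  The five documented model contradictions carry
    provenance ``contradiction`` and are excluded from the concordance
    denominator.
    """
    from importlib import resources

    path = resources.files("startbycc").joinpath("data/mutant_catalog.yaml")
    with resources.as_file(path) as p:
        return load_catalog(p)


def load_catalog(path) -> list[MutantCatalogEntry]:
    """Read a catalog from YAML/JSON: a list of entry mappings."""
    import json

    import yaml

    with open(path) as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    entries = []
    for row in data:
        size = row.get("expected_size")
        entries.append(MutantCatalogEntry(
            genotype=row["genotype"],
            expected_viable=bool(row["expected_viable"]),
            expected_size=tuple(size) if size else None,
            size_class=row.get("size_class"),
            provenance=row.get("provenance", "experiment"),
            notes=row.get("notes", ""),
        ))
    return entries


def run_catalog(catalog, config=None, wildtype=None, progress=False):
    """Simulate every catalog entry; failures are isolated per entry.

    Returns an ordered dict ``genotype -> PhenotypeReport``.  The wildtype
    baseline is computed once at the same configuration and reused for all
    relative sizes.
    """
    from .phenotype import characterize
    from .simulate import SimulationConfig

    config = config or SimulationConfig()
    if wildtype is None:
        wildtype = characterize("wildtype", config)
    reports: dict = {}
    for entry in catalog:
        if entry.genotype in reports:
            continue
        if entry.genotype.lower() in ("wildtype", "wt"):
            reports[entry.genotype] = wildtype
            continue
        if progress:
            print(f"  screening {entry.genotype} ...", flush=True)
        try:
            reports[entry.genotype] = characterize(
                entry.genotype, config, wildtype=wildtype)
        except Exception as exc:  # per-entry isolation
            from .phenotype import PhenotypeReport
            reports[entry.genotype] = PhenotypeReport(
                genotype=entry.genotype, viable=False,
                arrest_stage="indeterminate", size_rel_wt=None,
                cycle_time=None, g1_length=None, budded_period=None,
                notes=f"simulation failure: {exc}")
    return reports


@dataclass
class ConcordanceReport:
    matched: int
    total: int
    mismatches: list[dict]
    contradictions: list[dict]

    @property
    def fraction(self) -> float:
        return self.matched / self.total if self.total else float("nan")


#: relative tolerance on numeric size folds when scoring concordance
SIZE_MATCH_RTOL = 0.15


def concordance_report(reports: Mapping[str, object], catalog) -> ConcordanceReport:
    """Score simulated phenotypes against the catalog's expectations.

    A phenotype matches when viability agrees and — where the catalog quotes
    a numeric fold range — the simulated relative size falls inside the range
    widened by ±15%.  Entries with provenance ``contradiction`` are reported
    separately and excluded from the denominator, as are pure model
    predictions (``model prediction``), which carry no independent
    experimental expectation to be concordant with; validated predictions
    are scored.
    """
    matched = 0
    total = 0
    mismatches: list[dict] = []
    contradictions: list[dict] = []
    for entry in catalog:
        rep = reports.get(entry.genotype)
        if rep is None:
            continue
        detail = {
            "genotype": entry.genotype,
            "expected_viable": entry.expected_viable,
            "viable": rep.viable,
            "expected_size": entry.expected_size,
            "size_rel_wt": rep.size_rel_wt,
            "provenance": entry.provenance,
            "notes": entry.notes,
        }
        if entry.provenance == "contradiction":
            contradictions.append(detail)
            continue
        if entry.provenance == "model prediction":
            continue
        total += 1
        ok = rep.viable == entry.expected_viable
        if ok and entry.expected_size and rep.size_rel_wt is not None:
            lo, hi = entry.expected_size
            lo *= 1.0 - SIZE_MATCH_RTOL
            hi *= 1.0 + SIZE_MATCH_RTOL
            ok = lo <= rep.size_rel_wt <= hi
        if ok:
            matched += 1
        else:
            mismatches.append(detail)
    return ConcordanceReport(matched, total, mismatches, contradictions)
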