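"""Genotype parsing, parameter overrides, catalog mechanics."""

import pytest

from startbycc.model_core import ParameterSet
from startbycc.mutants import (
    GenotypeError,
    MutantCatalogEntry,
    apply_mutant,
    apply_mutant_params,
    builtin_catalog,
    concordance_report,
    parse_genotype,
    spec_to_label,
)


class TestParseGenotype:
    def test_double_deletion(self):
        spec = parse_genotype("cln3Δ bck2Δ")
        kinds = {(a.gene, a.kind) for a in spec.alterations}
        assert kinds == {("CLN3", "deletion"), ("BCK2", "deletion")}

    def test_order_insensitive(self):
        a = parse_genotype("cln3Δ bck2Δ")
        b = parse_genotype("bck2Δ cln3Δ")
        assert set(a.alterations) == set(b.alterations)
        assert spec_to_label(a) == spec_to_label(b)

    def test_label_round_trip_idempotent(self):
        label = spec_to_label(parse_genotype("whi5Δ GAL-BCK2"))
        assert spec_to_label(parse_genotype(label)) == label

    def test_nonphosphorylable_double(self):
        spec = parse_genotype("WHI5-12A SWI6-SA4")
        sites = {a.site for a in spec.alterations}
        assert sites == {"WHI5-12A", "SWI6-SA4"}
        # S160 (Q) site untouched unless asked for
        p = apply_mutant_params(ParameterSet(), spec)
        assert p["whi5_phos"] == 0.0
        assert p["swi6_phos"] == 0.0
        assert p["swi6_qphos"] == 1.0

    def test_gal_allele_combines_overexpression_and_knockout(self):
        spec = parse_genotype("GAL-WHI5-12A SWI6-SA4")
        kinds = {(a.gene, a.kind) for a in spec.alterations}
        assert ("WHI5", "GAL-overexpression") in kinds
        assert ("WHI5", "phospho-site-knockout") in kinds
        assert ("SWI6", "phospho-site-knockout") in kinds

    def test_wildtype_aliases(self):
        for label in ("", "wildtype", "WT"):
            assert parse_genotype(label).is_wildtype

    def test_unknown_token_lists_valid_forms(self):
        with pytest.raises(GenotypeError, match="valid forms"):
            parse_genotype("frobnicate-7")

    def test_unknown_gene_rejected(self):
        with pytest.raises(GenotypeError):
            parse_genotype("xyz9Δ")


class TestApplyMutant:
    def test_wildtype_spec_is_identity(self):
        p0 = ParameterSet()
        p1 = apply_mutant_params(p0, parse_genotype("wildtype"))
        assert dict(p0) == dict(p1)

    def test_deletion_zeroes_synthesis_and_pools(self):
        p, ics = apply_mutant(ParameterSet(), None, parse_genotype("whi5Δ"))
        assert p["WHI5T"] == 0.0
        s = dict(zip(ics.names, ics.concentrations))
        assert s["WHI5"] == 0.0 and s["WSB"] == 0.0 and s["WSF"] == 0.0

    def test_swi6_sa4_leaves_whi5_phosphorylation_intact(self):
        p = apply_mutant_params(ParameterSet(), parse_genotype("SWI6-SA4"))
        assert p["swi6_phos"] == 0.0
        assert p["whi5_phos"] == 1.0

    def test_order_independent_across_genes(self):
        a = apply_mutant_params(ParameterSet(),
                                parse_genotype("cln3Δ whi5Δ mc-BCK2"))
        b = apply_mutant_params(ParameterSet(),
                                parse_genotype("mc-BCK2 whi5Δ cln3Δ"))
        assert dict(a) == dict(b)

    def test_deletion_conflicts_rejected_not_merged(self):
        with pytest.raises(GenotypeError, match="conflicts"):
            parse_genotype("bck2Δ GAL-BCK2")

    def test_multicopy_scales_synthesis_fivefold(self):
        p0 = ParameterSet()
        p = apply_mutant_params(p0, parse_genotype("mc-BCK2"))
        assert p["ksbck2"] == pytest.approx(5.0 * p0["ksbck2"])

    def test_cln12_pool_needs_both_deletions(self):
        p_single = apply_mutant_params(ParameterSet(), parse_genotype("cln1Δ"))
        assert p_single["kscln2"] == ParameterSet()["kscln2"]
        p_double = apply_mutant_params(ParameterSet(),
                                       parse_genotype("cln1Δ cln2Δ"))
        assert p_double["kscln2"] == 0.0


class _FakeReport:
    def __init__(self, viable, size=None):
        self.viable = viable
        self.size_rel_wt = size


class TestConcordance:
    def test_all_match_toy_catalog(self):
        catalog = [
            MutantCatalogEntry("a", True, (1.0, 1.2)),
            MutantCatalogEntry("b", False),
        ]
        reports = {"a": _FakeReport(True, 1.1), "b": _FakeReport(False)}
        conc = concordance_report(reports, catalog)
        assert conc.matched == conc.total == 2
        assert conc.fraction == 1.0

    def test_contradictions_reported_separately(self):
        catalog = [
            MutantCatalogEntry("a", True),
            MutantCatalogEntry("known-gap", False, provenance="contradiction"),
        ]
        reports = {"a": _FakeReport(True),
                   "known-gap": _FakeReport(True, 2.0)}
        conc = concordance_report(reports, catalog)
        assert conc.total == 1 and conc.matched == 1
        assert len(conc.contradictions) == 1
        assert conc.contradictions[0]["genotype"] == "known-gap"

    def test_size_out_of_range_is_mismatch(self):
        catalog = [MutantCatalogEntry("a", True, (1.0, 1.1))]
        reports = {"a": _FakeReport(True, 2.0)}
        conc = concordance_report(reports, catalog)
        assert conc.matched == 0
        assert conc.mismatches[0]["genotype"] == "a"

    def test_builtin_catalog_contains_documented_contradictions(self):
        catalog = builtin_catalog()
        contra = [e for e in catalog if e.provenance == "contradiction"]
        assert len(contra) == 5
        genotypes = " ".join(e.genotype for e in contra)
        assert "msn5Δ swi4Δ" in genotypes and "msn5Δ swi6Δ" in genotypes


class TestEpistasis:
    def test_swi6_epistatic_to_cln3(self, screen_reports):
        """swi6Δ, swi6Δ cln3Δ and swi6Δ CLN3-1 share the same size."""
        base = screen_reports["swi6Δ"].size_rel_wt
        for g in ("cln3Δ swi6Δ", "CLN3-1 swi6Δ"):
            assert screen_reports[g].size_rel_wt == pytest.approx(
                base, rel=0.15)
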