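"""Model assembly: catalog integrity, stoichiometry, ICs, moiety analysis."""

import numpy as np
import pytest

from startbycc.model_core import (
    CompartmentLayout,
    ModelSystem,
    ParameterSet,
    Reaction,
    build_model,
    conserved_moieties,
    initial_conditions,
    moiety_totals,
    rescale_counts,
    species_catalog,
)


class TestLayout:
    def test_defaults(self):
        lay = CompartmentLayout()
        assert lay.nuclear_fraction == 0.2
        assert lay.cytoplasmic_fraction == 0.8

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CompartmentLayout(0.3, 0.8)

    def test_fractions_must_be_positive(self):
        with pytest.raises(ValueError):
            CompartmentLayout(-0.2, 1.2)


class TestSpeciesCatalog:
    def test_promoter_bound_species_contain_swi4_or_mbp1(self):
        for sp in species_catalog():
            if sp.promoter_bound:
                assert sp.composition.get("Swi4") or sp.composition.get("Mbp1")

    def test_q_flag_distinct_from_p_flag(self):
        cat = {s.name: s for s in species_catalog()}
        assert "Swi6-Q" in cat["WSB6PQ"].phospho_state
        assert "Swi6-P" in cat["WSB6PQ"].phospho_state
        assert "Swi6-Q" not in cat["WSB6P"].phospho_state

    def test_complex_composition_decomposes_into_monomers(self):
        allowed = {"Swi4", "Swi6", "Whi5", "Mbp1", "PromSBF", "PromMBF"}
        for sp in species_catalog():
            assert set(sp.composition) <= allowed


class TestBuildModel:
    def test_rhs_finite_on_random_nonnegative_states(self, wt_model):
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = rng.uniform(0.0, 3.0, len(wt_model.names))
            dy = wt_model.rhs(0.0, y)
            assert np.all(np.isfinite(dy))

    def test_empty_mutant_equals_explicit_wildtype(self, wt_model):
        """Empty spec and 'wildtype' label give bit-identical derivatives."""
        m2 = build_model(mutant="wildtype")
        rng = np.random.default_rng(3)
        y = rng.uniform(0.0, 2.0, len(wt_model.names))
        np.testing.assert_array_equal(wt_model.rhs(0.0, y), m2.rhs(0.0, y))

    def test_wildtype_overrides_reproduce_wildtype_rhs(self, wt_model):
        """Setting every mutant-touchable parameter to its default is a no-op."""
        p = ParameterSet({"whi5_phos": 1.0, "swi6_phos": 1.0, "gal_whi5": 1.0,
                          "MSN5": 1.0})
        m2 = build_model(p)
        rng = np.random.default_rng(11)
        y = rng.uniform(0.0, 2.0, len(wt_model.names))
        np.testing.assert_array_equal(wt_model.rhs(0.0, y), m2.rhs(0.0, y))

    def test_cln2_synthesis_mass_independent(self, wt_model):
        """Doubling mass leaves the Cln2 synthesis flux unchanged while the
        mass-dependent cyclins (Clb5, Clb2) scale with it."""
        ic = initial_conditions(params=wt_model.parameters)
        y = ic.concentrations.copy()
        i_mass = wt_model.index("MASS")
        i_cln2 = wt_model.index("CLN2")
        i_clb5 = wt_model.index("CLB5T")
        # zero the degradation contribution by zeroing the pools themselves
        y[i_cln2] = 0.0
        y[i_clb5] = 0.0
        d1 = wt_model.rhs(0.0, y)
        y2 = y.copy()
        y2[i_mass] *= 2.0
        d2 = wt_model.rhs(0.0, y2)
        assert d2[i_cln2] == pytest.approx(d1[i_cln2], rel=1e-12)
        assert d2[i_clb5] == pytest.approx(2.0 * d1[i_clb5], rel=1e-9)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            ParameterSet({"not_a_rate": 1.0})

    def test_negative_rate_rejected(self):
        p = ParameterSet()
        p["kscln3"] = -0.1
        with pytest.raises(ValueError):
            p.validate()


class TestInitialConditions:
    def test_monomer_stoichiometry(self, wt_model):
        ic = initial_conditions(params=wt_model.parameters)
        totals = moiety_totals(wt_model, ic.concentrations)
        assert totals["Swi6"] / totals["Whi5"] == pytest.approx(3.0, rel=1e-9)
        assert totals["PromSBF"] / totals["Swi4"] == pytest.approx(
            0.2 / 0.55, rel=1e-9)
        assert totals["Swi4"] == pytest.approx(totals["Mbp1"], rel=1e-9)

    def test_whi5_deletion_zeroes_pool(self, wt_model):
        ic = initial_conditions(mutant="whi5Δ")
        totals = moiety_totals(wt_model, ic.concentrations)
        assert totals.get("Whi5", 0.0) == 0.0

    def test_early_g1_state(self, wt_model):
        """CKIs and Cdh1 high, cyclins low, promoters mostly occupied."""
        ic = initial_conditions(params=wt_model.parameters)
        s = dict(zip(wt_model.names, ic.concentrations))
        assert s["CDH1"] > 0.8
        assert s["SIC1"] + s["CDC6"] > 0.5
        assert s["CLN2"] < 0.1 and s["CLB2T"] < 0.2
        assert s["WSB"] > 5 * s["PSBF"]   # promoters occupied by inactive SBF
        assert s["MBFB"] > 5 * s["PMBF"]
        assert s["WHI5"] > 0 and s["WHI5PC"] == 0.0  # Whi5 nuclear at birth


class TestRescaleCounts:
    def test_four_promoter_copies(self):
        assert rescale_counts(4) == {
            "promoter": 4, "Swi4/Mbp1": 11, "Whi5": 20, "Swi6": 60}

    def test_single_copy(self):
        assert rescale_counts(1) == {
            "promoter": 1, "Swi4/Mbp1": 3, "Whi5": 5, "Swi6": 15}

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_invalid_copy_number(self, bad):
        with pytest.raises(ValueError):
            rescale_counts(bad)


def _toy_binding_system():
    """A + B <-> AB in one compartment, as a minimal ModelSystem shell."""
    from startbycc.model_core import SpeciesDef

    species = [
        SpeciesDef("A", "cell", "monomer", {"A": 1}),
        SpeciesDef("B", "cell", "monomer", {"B": 1}),
        SpeciesDef("AB", "cell", "transcription-factor complex",
                   {"A": 1, "B": 1}),
    ]
    reactions = [
        Reaction("bind", {"A": -1, "B": -1, "AB": 1}, "ka*A*B", "cell", True),
        Reaction("unbind", {"AB": -1, "A": 1, "B": 1}, "kd*AB", "cell", True),
    ]
    return ModelSystem(
        species=species, reactions=reactions, parameters=ParameterSet(),
        layout=CompartmentLayout(), rhs=None, aux_names=[], aux_eval=None,
        param_order=[], param_values=np.zeros(0))


class TestConservedMoieties:
    def test_toy_reversible_binding(self):
        """A+B<->AB conserves A+AB and B+AB (textbook moiety pair)."""
        moieties = conserved_moieties(_toy_binding_system())
        found = {frozenset(m.coefficients.items()) for m in moieties}
        assert frozenset({("A", 1.0), ("AB", 1.0)}) in found
        assert frozenset({("B", 1.0), ("AB", 1.0)}) in found

    def test_monomer_totals_are_invariants(self, wt_model):
        """Each START monomer and both promoter classes span an invariant."""
        moieties = conserved_moieties(wt_model)
        # every invariant must annihilate the conserving stoichiometry; check
        # that the composition-based totals are in the spanned space by
        # verifying their drift directly in test_promoter_conservation below.
        names_covered = set()
        for m in moieties:
            names_covered.update(m.coefficients)
        for must in ("PSBF", "WSB", "MBFB", "SWI4", "SWI6", "WHI5", "MBP1"):
            assert must in names_covered

    def test_synthesis_breaks_conservation(self, wt_model):
        """Adding Whi5 synthesis removes Whi5-containing invariants."""
        reactions = list(wt_model.reactions) + [
            Reaction("whi5_syn", {"WHI5": 1}, "0.1", "nuclear", False)]
        modified = ModelSystem(
            species=wt_model.species, reactions=reactions,
            parameters=wt_model.parameters, layout=wt_model.layout,
            rhs=None, aux_names=[], aux_eval=None, param_order=[],
            param_values=np.zeros(0))
        for m in conserved_moieties(modified):
            assert "WHI5" not in m.coefficients

    def test_moiety_derivative_vanishes_on_rhs(self, wt_model):
        """Volume-weighted monomer totals have zero time derivative.

        This exercises the assembled right-hand side, not just the transport
        primitive: for random states, d/dt of total Swi4/Swi6/Whi5/Mbp1 and
        of both promoter classes must vanish to round-off.
        """
        rng = np.random.default_rng(5)
        vols = np.array([wt_model.layout.volume(s.compartment)
                         for s in wt_model.species])
        for _ in range(10):
            y = rng.uniform(0.0, 1.5, len(wt_model.names))
            dy = wt_model.rhs(0.0, y)
            for mono in ("Swi4", "Swi6", "Whi5", "Mbp1", "PromSBF", "PromMBF"):
                coeff = np.array([s.composition.get(mono, 0)
                                  for s in wt_model.species], dtype=float)
                drift = float(np.sum(coeff * vols * dy))
                assert drift == pytest.approx(0.0, abs=1e-10), mono
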