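# startbycc

A deterministic, two-compartment ODE model of the budding-yeast
(*Saccharomyces cerevisiae*) cell cycle with a mechanistically detailed
START transition — the G1 commitment point at which a cell irreversibly
initiates budding, DNA replication and spindle-pole duplication.  The
package implements the START-BYCC model family: the classic cell-cycle
backbone (Cln2, Clb5, Clb2, the CKIs Sic1/Cdc6, Cdh1, Cdc20, Cdc14, Mcm1,
Swi5) extended with an explicit molecular description of SBF/MBF regulation,
and ships a mutant-emulation layer, phenotype classification and
size-control analysis on top of the simulator.

## The model

**START machinery.**  The G1/S transcription factors SBF (Swi4·Swi6) and
MBF (Mbp1·Swi6) assemble from free monomers and bind two limiting promoter
classes; the stoichiometric inhibitor Whi5 locks promoter-bound SBF in an
inactive complex.  Cln kinases (Cln3, Cln1,2, Clb5) phosphorylate Whi5 and
Swi6 through an ultrasensitive Hill rate (Vpcln); the doubly phosphorylated
trimer dissociates into active SBF and phospho-Whi5, which Msn5 exports to
the cytoplasm until mitotic exit.  Clb kinases phosphorylate the distinct
Swi6 S160 site (the "Q-form", exported with Msn5) and Swi4 (promoter
release), turning SBF off in late S/M.  Bck2 provides the CDK- and
Whi5-independent route: it converts Swi4 homodimers and Whi5-bound SBF to
less-active forms, activates MBF, and contributes to CKI inactivation.
PP2A reverses Cln-site phosphorylation; Cdc14 reverses Whi5-P and the
Q-form at mitotic exit.

**Size control.**  Mass grows exponentially at rate ln2/MDT (MDT = mass
doubling time).  The chaperone Ydj1 reads a growth-rate-weighted mass
signal and gates nuclear import of Cln3 and Bck2; Ssa1, activated by late
mitotic kinases (a Goldbeter–Koshland switch), re-sequesters them in the
ER.  START therefore fires at a size threshold that shifts with the
nutrient-determined growth rate.

**Compartments and events.**  The nucleus and cytoplasm have fixed volume
fractions 0.2 : 0.8; transport fluxes are volume-scaled so molecule numbers
are conserved exactly.  Division is a discrete event — active Clb2 falling
through a low threshold after the spindle marker SPN has fired — and the
tracked (daughter) cell keeps 0.46 of the pre-division mass.

The reaction network (53 species, ~110 rate constants) is declarative:
species carry compartment and monomer-composition annotations, reactions
carry integer stoichiometry and rate-law expressions, and the right-hand
side is compiled from the tables.  That makes conservation-law (moiety)
analysis, the XPP-dialect `.ode` writer and the SBML Level 3 exporter all
read from a single source of truth.

## Worked example

```python
from startbycc import build_model
from startbycc.simulate import SimulationConfig, steady_cycle
from startbycc.phenotype import characterize

cfg = SimulationConfig(t_end=300.0, mdt=90.0, lineage="daughter")

wt = characterize("wildtype", cfg)
print(f"cycle {wt.cycle_time:.1f} min, G1 {wt.g1_length:.1f} min, "
      f"division mass {wt.division_mass:.2f} a.u.")

mut = characterize("cln3Δ bck2Δ", cfg)
print(mut.viable, mut.arrest_stage)

rescued = characterize("cln3Δ bck2Δ whi5Δ", cfg, wildtype=wt)
print(rescued.viable, f"{rescued.size_rel_wt:.2f}x WT")
```

prints

```
cycle 100.8 min, G1 51.7 min, division mass 2.49 a.u.
False G1
True 1.53x WT
```

The daughter lineage in glucose (MDT 90 min) divides every ~101 min —
the balanced-growth fixed point of the 0.46 division rule — spending
~52 min in G1 before the ORI marker (the START event) fires at a mass of
~1.7 a.u. and dividing at ~2.5 a.u.  Deleting both START activators (Cln3
and Bck2) arrests the cell in G1 with unbounded growth; additionally
removing the inhibitor Whi5 restores cycling at about 1.5× wildtype size,
because the unmodified SBF complex retains residual activity once free of
its inhibitor.

The same interface drives the shell commands:

```bash
start-bycc simulate --genotype "bck2Δ" --mdt 90 --t-end 300 --out traj.csv
start-bycc screen --out report.csv
start-bycc sweep-mdt --from 90 --to 300 --step 30
start-bycc export --format sbml --out model.xml
start-bycc phenotype --genotype "swi6Δ"
```

`screen` runs the shipped mutant catalog (47 genotypes transcribing the
documented phenotypes, `src/startbycc/data/mutant_catalog.yaml`) and prints
the concordance between simulated and expected phenotypes, with the five
documented model/experiment contradictions reported separately.

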