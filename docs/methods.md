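# Methods

## Scope and model structure

The package simulates the budding-yeast cell cycle as a deterministic hybrid
system: 53 ordinary differential equations for molecular concentrations and
cell mass, punctuated by a discrete asymmetric division event.  The START
transition — commitment to budding and DNA replication in late G1 — is
resolved at the level of individual complexes and phosphorylation states;
the remainder of the cycle (S/G2/M and mitotic exit) uses a compact
backbone in the tradition of the classic budding-yeast cell-cycle ODE
models, without the detailed FEAR/MEN mitotic-exit machinery, pheromone
arrest, or stochastic variants.

State variables fall into four groups:

* **Backbone (whole-cell):** Cln2 (the lumped Cln1,2 pool), total Clb5 and
  Clb2, the CKIs Sic1 and Cdc6, Cdh1, Cdc20 (total and active), Cdc14,
  Mcm1, Swi5, Nrm1, the event markers BUD/ORI/SPN, and mass.
* **Size-control activators:** Cln3 and Bck2, each with an ER/cytoplasmic
  and a nuclear pool.
* **START complexes (nuclear):** free monomers Swi4, Swi6, Whi5, Mbp1 and
  their phosphoforms; free complexes SBF, Whi5·SBF, Swi4 homodimer, MBF;
  the two promoter classes and every promoter-bound state — WSB (inactive
  Whi5·SBF), WSB5P, WSB6P, WSB6PQ, WSBB (Bck2-modified), SBFB, SBFB6P,
  SBFB6PQ, the Swi4-dimer states S44B/Swi4B, and MBFB/MBFBA/MBFBB/MBFW.
* **Cytoplasmic monomer pools** produced by Msn5-mediated export.

Concentrations are dimensionless (a.u.), time is minutes.  The nucleus and
cytoplasm have fixed relative volumes 0.2 and 0.8; each reaction is
evaluated in the concentration units of its home compartment and its
molecular flux is rescaled by volume ratios on arrival, so every binding,
modification and transport step conserves molecule number exactly.  The
monomer totals obey the abundance ratios Swi6 : Whi5 : Swi4 (= Mbp1) :
promoter = 3 : 1 : 0.55 : 0.2, and — because the monomers carry no
synthesis or degradation — each monomer class and each promoter class is a
conserved moiety, which the conservation-law analysis recovers from the
stoichiometry and the tests verify along trajectories to ~1e-12 relative
drift.

## Rate-law conventions

* **Vpcln** — the Cln-kinase activity directed at Whi5 and the Cln sites of
  Swi6 — is a Hill function (n = 2, half-saturation 2.0 a.u.) of the
  weighted kinase sum (Cln3 weight 1.0, Cln2 and Clb5 0.1 each), standing
  in for multi-site phosphorylation.  The low Cln2/Clb5 weights make the
  switch firmly Cln3-gated: residual Cln2 left over from the previous cycle
  cannot re-ignite it in early G1.  MBF activation uses the same form with
  its own weights.
* **Processivity:** once a promoter-bound complex carries one Cln-site
  phosphate, the second site is phosphorylated 5× faster.  Without this the
  singly-phosphorylated intermediates (the SBFa3/SBFa4 classes) pool up and
  dominate; with it the doubly-processed, Swi6-phosphorylated SBF (SBFa2)
  is the main wildtype form, with the intermediates transiently visible.
* **Goldbeter–Koshland switch:** the Ssa1 retention switch uses the
  zero-order ultrasensitive steady-state function, evaluated in the
  numerically stable surd form with a 1e-12 discriminant floor.
* **CKI sequestration:** Sic1+Cdc6 bind the combined Clb pool with a single
  tight-binding constant (Kd 0.002); free Clb5/Clb2 come from the smooth
  tight-binding formula rather than explicit trimer ODEs.  This is a
  deliberate reduction — it preserves the stoichiometric-buffer threshold
  behavior at a fraction of the state space.
* **Activity weights:** promoter-bound classes contribute to transcription
  with class-level weights — unmodified SBF 0.5 (residual), all
  Cln-activated forms 1.0, Bck2-modified forms 0.3 (Whi5-bound SBF) and
  0.27 (Swi4 homodimer), Cln-activated MBF 1.0, Bck2-activated MBF 0.6.

## Size control

Mass grows as dm/dt = m·ln2/MDT.  Ydj1 activity is a Hill function (n = 2)
of the signal m·(MDT/90)^0.1 — mass weighted by growth rate, so that slow
growth lowers the effective size threshold; this is what reproduces the
division-size range 2.5 a.u. (MDT 90) down to ~1.5 a.u. (MDT 300) with a
budded period that stays near 50–57 min across the sweep.  Ydj1 gates the
nuclear import of Cln3 and Bck2; Ssa1, switched on by Clb2 and Swi5 at the
end of mitosis, drives them back out, which also terminates Vpcln before
Cdc14 re-imports Whi5 — the ordering that resets G1.

Bck2 acts through four routes: modification of promoter-bound Swi4
homodimers and of Whi5-bound SBF to less-active classes (the latter
quenched by excess free Whi5 through a second-order term, which is why
GAL-WHI5-12A SWI6-SA4 is lethal while WHI5-12A SWI6-SA4 is merely large),
MBF activation, and CKI inactivation.  The CKI route carries most of Bck2's
wildtype contribution; removing it is what makes bck2Δ measurably larger
(1.31×) than wildtype while cln3Δ — left with only the weaker Bck2-driven
classes — grows to ~2× before START fires.

## Division event and lineage tracking

Division fires when active Clb2 falls through 0.2 after SPN has crossed 1
since the previous division (unarmed crossings, e.g. the small Clb2
transient at START, are ignored).  The daughter keeps 0.46 of the
pre-division mass; BUD, ORI and SPN reset to zero; concentrations carry
over unchanged.  The daughter lineage is tracked by default.

A pure mass-fraction rule pins the converged cycle time to the
balanced-growth identity T = MDT·log2(1/f): 100.8 min at MDT 90 with
f = 0.46.  A daughter cycle time of ~107 min would instead require
f ≈ 0.44; we keep the printed fraction 0.46 and the identity, and the
converged cycle time is therefore ~101 min.  G1 (birth to the ORI
crossing, the declared START marker) is ~52 min and the budded period
(BUD crossing to division) ~54 min in glucose.

## Numerics

* Adaptive integration: LSODA with rtol 1e-7, atol 1e-9, max step 1 min;
  concentrations are clipped at zero inside the right-hand side and after
  accepted steps; negativity beyond 100×atol is an error, never silently
  repaired.
* Events are located by the solver's root refinement; integration resumes
  0.05 min past each root so a crossing cannot re-trigger.
* Arrested lineages stop at a mass ceiling of 30 a.u. (the viability
  classifier separately applies a 10× wildtype-division-mass death
  criterion), which bounds the cost of simulating inviable mutants.
* An independent fixed-step RK4 integrator with bisection event refinement
  serves as the verification oracle; the adaptive path agrees with it to
  better than 1e-6 relative max-norm over the opening 40 min of the
  wildtype trajectory (tests assert < 1e-4).
* The steady-cycle routine iterates the division-to-division map until the
  birth mass changes by < 0.1% between cycles, first over a ~17-cycle
  horizon and, for lineages that divide without settling (weakly
  size-controlled mutants such as the cln3Δ bck2Δ whi5Δ rescue), over up to
  45 cycles before declaring non-convergence.  Viability additionally
  requires three consecutive settled cycles with ORI → SPN → division in
  order.

## Mutant emulation

Deletions zero synthesis rates and initial pools; GAL alleles add strong
constitutive, mass-independent synthesis (or an 8-fold abundance for the
conserved monomers); multicopy alleles multiply wildtype synthesis by the
copy number (5 by default); phospho-site knockouts zero the corresponding
phosphorylation rate constants and nothing else — WHI5-12A removes the
Whi5 Cln sites, SWI6-SA4 the Swi6 Cln sites, SWI6-S160A the distinct Q
site.  CLN3-1 is modeled as a 2.5-fold elevated Cln3 pool: with the
two-pool transport architecture, reducing the degradation rate instead
inflates nuclear Cln3 quadratically and breaks the documented epistasis of
Swi6 to Cln3, whereas the elevated-pool form preserves it.

The shipped catalog (`data/mutant_catalog.yaml`) records 47 genotypes with
their documented phenotypes.  Concordance counts an entry as matched when
viability agrees and, where a numeric fold range is quoted, the simulated
relative size falls inside the range widened by ±15%.  Entries tagged
`contradiction` (the five documented model/experiment disagreements:
GAL-WHI5 swi6Δ, msn5Δ swi4Δ, msn5Δ swi6Δ, cln1Δ cln2Δ cdh1Δ with and
without GAL-CLN2) are reported separately and never scored; entries tagged
`model prediction` have no independent experimental expectation and are
likewise excluded from the denominator, while `validated prediction`
entries are scored.

## Calibration

The parameter set is this package's own calibration of the model
architecture, tuned in three passes: (1) wildtype glucose timing (G1
≈ 50 min, BUD and ORI within a few minutes of each other, division mass
≈ 2.5 a.u., the balanced-growth cycle time); (2) the growth-rate sweep
(division mass 2.5 → 1.5 a.u. over MDT 90 → 300 with a near-constant
budded period); (3) the mutant battery (the documented lethality calls,
rescues and size folds — bck2Δ 1.31×, cln3Δ 2.04×, swi6Δ 2.23×,
cln3Δ swi6Δ 2.26×, whi5Δ 0.74×, the non-phosphorylable singles within 10%
of wildtype and their double at 1.41×).  Three structural choices proved
load-bearing: graded (rather than near-step) size sensing so that
downstream gain changes shift the START mass; a Bck2 route into CKI
inactivation; and second-order dependence of the excess-Whi5/MBF
inhibition on free Whi5, which separates overexpression lethality from
wildtype insensitivity.

## Problem sizes used in tests and the acceptance script

Wildtype trajectories run 300 min (≈3 cycles); steady-cycle analyses run
to convergence as above; the RK4 oracle comparison uses the opening 40 min
at dt = 0.002 min; the growth-rate sweep uses the 8-point MDT grid
90–300 min; the screen covers the full 47-entry catalog.  These sizes were
chosen so the whole analysis reruns from scratch in a few minutes on one
CPU.

## Known limitations

* Mitotic exit is the simplified backbone: no FEAR/MEN pathways, no
  Esp1/Pds1, no spindle-position checkpoint; arrest staging is therefore
  coarse (G1, S/G2, M).
* msn5Δ correctly keeps Whi5 and Swi6 nuclear at all times but its
  steady-state size is near wildtype, not enlarged — the localization
  defect alone does not shrink active SBF enough in this parameterization.
* mbp1Δ comes out at 1.05×, below its documented 1.2–1.3× band (though
  within the widened concordance tolerance); MBF's share of wildtype
  Clb5 transcription is the limiting lever.
* The GAL-CLN2 rescues of swi4Δ swi6Δ and bck2Δ swi6Δ divide but never
  fire ORI (no Clb5 source in those backgrounds), so they classify as
  inviable; they are prediction-class entries and are not scored.
* The mother lineage is simulated but population structure (mother/daughter
  balance, age distribution) is out of scope.
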