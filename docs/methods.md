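# Model and methods

## Scope

`meioswitch` models the regulatory decision between mitotic
proliferation and meiotic differentiation in fission yeast at two
levels: the Ste11–Mei2–Pat1 meiotic-entry subsystem driven by the
nutrient inputs Tor2 and PKA, and that subsystem embedded in a mitotic
cell-cycle model.  All state variables are dimensionless activities;
time is in minutes.  The models are deterministic ODE systems; there is
no spatial or stochastic component.

## The meiosis subsystem

Eight state variables: cytoplasmic Ste11, nuclear Ste11 (`ste11n`),
active (dephosphorylated) Mei2, Pat1-phosphorylated Mei2, pheromone
signalling activity PheS (the lumped Byr2–Byr1–Spk1 pathway), Mat1-Pm,
free Mei3, and the stoichiometric Pat1:Mei3 complex.  Two
transcriptional activities are algebraic: Rst2 (repressed by PKA
through a steep Hill function) and Rpol (Pol II CTD phosphorylation,
promoted by total Mei2 through the stress-MAPK/CTDK-I route, with a
small Mei2-independent basal activity).

Kinetic forms follow the usual conventions of this model family:
Ste11n-driven syntheses (its own gene, *mei2*, PheS, *mat1-Pm*) are
Hill functions of the transcriptionally effective nuclear Ste11;
Mei2 phosphorylation/dephosphorylation is Michaelis–Menten with small
Michaelis constants, so the Pat1 phosphorylation cycle behaves as a
zero-order-ultrasensitive switch in Pat1 activity; everything else is
mass action.  Specific structural choices:

* **Pat1 has three hands on the network.**  It phosphorylates Ste11
  (Rad24-dependent), which both promotes nuclear export and reduces the
  transcriptional effectiveness of nuclear Ste11 (the
  `k_tapat` gate); and it phosphorylates Mei2, inactivating it.  These
  parallel couplings are what make a *partial* loss of Pat1 (the 30 °C
  allele of the temperature-sensitive kinase, modelled as half the
  total) sufficient to ignite the network in rich medium while the
  fully active kinase holds it off.
* **Tor2 destabilizes Mei2** rather than inactivating it: degradation
  of active Mei2 is scaled by `(1 + kp_tor·Tor2)` and degradation of
  the Pat1-phosphorylated form by `(1 + kp_torp·Tor2·Pat1-activity)` —
  a synergistic double degron that requires both kinases.  This
  reproduces the epistasis pattern in which removing either kinase arm
  alone (Tor2-site-dead Mei2, or partial Pat1 loss) stabilizes Mei2
  enough to start the positive feedback through Rpol.
* **Mei2 synthesis has two components**: a low-threshold Hill term that
  participates in the ignition feedback, and a weaker high-threshold
  term that lets strongly overexpressed Ste11 keep pushing *mei2*
  transcription.  The second term separates genotypes that differ only
  in how much nuclear Ste11 they accumulate (e.g. Tor2 overexpression
  with and without PKA loss).
* **PheS inhibits Pat1 by rapid-equilibrium binding** (activity
  modulation), whereas **Mei3 sequesters Pat1 stoichiometrically** into
  a tight complex (association 1/min per unit, dissociation and
  turnover 1e-4/min).  Partial inhibition by PheS alone leaves enough
  Pat1 activity to keep Mei2 off; only Mei3 accumulation pushes Pat1
  activity below the dephosphorylation threshold.  The near-
  irreversibility of the complex is what freezes commitment: once the
  complex has formed, returning to rich medium cannot recover Pat1 on
  any relevant timescale.
* **Inputs.**  Tor2 and PKA are piecewise-constant schedule inputs in
  [0, 1.5] (values above 1 encode overexpression); starvation is
  Tor2 = 0 with PKA = 0.75, encoding the assumption that PKA is not
  completely inhibited by nitrogen starvation.  Nutrient export of
  Ste11 uses the product Tor2·PKA (cooperative), so loss of either
  kinase opens the localization gate.

### Calibration

The equations' rate constants are the package's own calibrated set.
Ste11 and Mei2 turnover rates correspond to unstable proteins
(half-lives of minutes to tens of minutes).  All remaining values were
chosen, once, so that the wild type and the full 43-strain mutant panel
reproduce the reported qualitative behaviour: resting in rich medium;
the ordered starvation cascade PheS → Mat1-Pm → Mei3 → active Mei2;
mating-without-meiosis for *mei3Δ*; Mei3-independent meiosis for
complete Pat1 loss and Mei3-dependent meiosis for partial loss; and the
commitment flip between 135 and 150 minutes after starvation in the
return-to-growth experiment.  The Hill thresholds on effective nuclear
Ste11 are ordered `k_mmei2 < k_mste11 < k_mphe < k_mmat`, so Mei2 and
the autoregulatory loop respond first, pheromone signalling needs more
Ste11, and Mat1-Pm needs the most — the structural basis of the
sequential cascade.

## The cell-cycle model and its coupling

The mitotic block is an M-phase-control model in the Novak–Tyson
tradition: total Cdk1:Cdc13 synthesized in proportion to cell mass and
degraded by Ste9/APC and Slp1/APC; Tyr15 inhibitory phosphorylation
with Wee1 and Cdc25 as zero-order ultrasensitive switches; the CKI Rum1
binding Cdk1:Cdc13 in a rapid-equilibrium trimer; a mass-driven starter
kinase; and an intermediary-enzyme delay before Slp1 activation.
Division is an event: when Cdk1 activity falls through the exit
threshold (0.1) after having exceeded the mitotic threshold (0.4), the
mass is halved exactly and the integrator restarts.  Under rich
conditions the limit cycle locks to the mass-doubling time
(μ = 0.00433/min, a 160-minute cycle).

The starvation layer: Tor2 inactivation activates Ppk18 (greatwall),
which phosphorylates Igo1; Igo1-P inhibits PP2A:B55.  B55 normally
keeps Wee1 active and Cdc25 inactive, so its loss advances mitosis at a
smaller size — this removes the Tyr15-phosphorylated (S/G2)
steady-state branch from the cell-size diagram.  B55 also restrains
APC/Slp1 activation (the Slp1 threshold on Cdk1 activity scales with
B55).  This second coupling gives rich cells a stable mitotic
steady-state branch at large size while letting starved cells (B55
off) exit mitosis promptly instead of parking there.  An intracellular
nitrogen pool, released at starvation onset (initial value 1.8 relative
to the external supply, first-order depletion at 0.004/min), sustains
cyclin and starter-kinase synthesis through the accelerated divisions
and then runs out; growth stops at starvation, so the divisions halve
the size step-wise.  The pool size and depletion rate, and the PheS
brake on Rum1 degradation (factor 1/(1 + 4·PheS)), are calibrated —
not printed anywhere — to give exactly two accelerated divisions when
starvation hits late G2 (150 min into a cycle), one when it hits
earlier (135 min), and one extra division when pheromone signalling is
disabled.

Couplings to the meiosis side: Cdk1 activity multiplicatively gates all
regulated *ste11* transcription (so Ste11 pulses in G1 and the
T82-phosphomimetic limit shows sustained elevated Ste11 without
meiosis), and PheS slows Rum1 degradation (pheromone-assisted G1
arrest).  Setting the couplings to zero recovers the standalone
cell-cycle model exactly; a test verifies the uncoupled-limit
equivalence.

## Genotype conventions

Deletions set the relevant synthesis rate or total to zero exactly.
Overexpression (nmt1/pREP41) scales the relevant synthesis rate
tenfold.  Phospho-site-dead (A) mutants zero the corresponding
site-specific coupling; phospho-mimetic (D) mutants clamp the modified
process at its kinase-saturated level (e.g. the Spk1-site mimic runs
nuclear import at the PheS-saturated rate).  Heterothallic strains have
no partner: no pheromone source and no Mei3 synthesis.  Two rows are
provisional: the T173/S218 substitutions of Ste11 are mapped as
impaired Ste11 DNA-binding competence because the responsible kinase is
not identified and both substitution classes are phenotypically
blocked; and the constitutive-*mei2* constructs use a unit-rate
constitutive synthesis.  "Low frequency" phenotypes are treated as
blocks; a deterministic model cannot express frequencies.

Phenotype calls: mating requires peak PheS and peak Mat1-Pm above 50%
of the starved wild-type reference *and* the Mat1-Pm half-maximum
crossing no later than the onset of active Mei2 — a cell already
committed to meiosis cannot conjugate, which is what separates the
ordered cascade (mating) from premature commitment (haploid meiosis in
the byr2-ΔN and Pat1-site-dead Mei2 strains).  Meiosis requires final
active Mei2 above 50% of the reference.  Thresholds are configurable
and logged; calls whose evidence lies within 10 percentage points of a
threshold are flagged `fragile` in the report (the Tor2-overexpression
epistasis rows and the heterothallic SATA row are the flagged cases).

## Bifurcation analysis

Equilibria are found by a multi-start oracle (random starts, Newton,
with relaxation along the flow as a fallback for the stiff switching
terms) and followed by pseudo-arclength continuation with a damped
Newton corrector (tolerance 1e-10, max 25 iterations, adaptive
arclength step within [1e-5, 1e-2] of the parameter range).
Saddle-nodes are detected by the sign change of the parameter component
of the branch tangent and refined by bisection; Hopf points by a
complex-conjugate eigenvalue pair of the finite-difference Jacobian
crossing the imaginary axis.  Outside the physical domain (negative
state components, reachable by Newton trial steps) the right-hand side
restores toward zero so the clamped region is never flat.

Import-rate structure (scan domain k_imste11 ∈ [0.018, 3], log-spaced):
the resting branch ends in an ignition fold near 0.93; with pheromone
signalling removed, an intermediate (autoregulation-driven) Ste11
branch is bistable with the resting branch between roughly 0.3 and
0.95 without Mei2 activation; the wild-type committed high branch,
locked by the Pat1:Mei3 complex, persists across the whole scanned
domain on the down-sweep (irreversible), whereas without Mei3 the high
branch collapses back to rest below k ≈ 0.02 (reversible).  In the wild
type the intermediate branch is crossed dynamically at ignition rather
than appearing as a separate quasi-static plateau; the two switches are
therefore exhibited through the pheromone-free and Mei3-free variants.

Cell-size diagrams treat mass as the bifurcation parameter with growth
and division frozen and the nitrogen pool held at its onset value.
Under rich conditions there are three stable Cdk1 branches (G1 with
high Rum1, S/G2 with high Tyr15 phosphorylation, M) and an oscillatory
window bounded by a Hopf point between S/G2 and the stable mitotic
branch.  Under starvation the S/G2 branch disappears and the G1/S size
threshold drops (≈0.30 versus ≈0.56 mass units rich).  **Known
limitation:** with pheromone signalling clamped on, the G1/S threshold
rises relative to the starved pheromone-free case (≈0.46 versus ≈0.30)
but not above the rich threshold, although the reported
experimental behaviour places it above the rich one.  Every mechanism we tried that pushes
the clamped-pheromone threshold above rich (a stronger Rum1 brake,
pheromone- or Ste11-mediated starter-kinase suppression — the latter
available as the optional `a_sk_arrest` parameters, default off)
engages during the starved post-division G1 and abolishes the second
accelerated division, because in this calibration pheromone signalling
rises within ~45 minutes of starvation while the second division needs
~75.  We kept the division counts and report the threshold honestly.

## Numerical choices

Integration uses LSODA with rtol 1e-8 / atol 1e-10, restarted at every
schedule breakpoint (inputs are never smoothed) and at every division
event; a 2-minute step cap during event detection keeps the dense
interpolant sign-consistent for root localization, and the division
event is latched (armed above the mitotic threshold, disarmed by the
mass halving) so it cannot re-trigger at a restart boundary.  Division
times reproduce to better than 0.5 minutes under tenfold tolerance
refinement.  Default initial conditions are the resting state under the
starting inputs (computed by relaxation plus Newton polishing, which
selects the pre-differentiation state when the system is bistable) or,
for the integrated model, a point on the nutrient-rich limit cycle just
after division.

## What the simulations do and do not show

All inputs are constructed: parameter sets, nutrient schedules and
genotype overrides.  The mutant screen tests whether the network logic
reproduces reported qualitative outcomes; it says nothing about
absolute rates, which were never fitted to time courses (experimental
commitment times vary from 2 to 6 hours; the model's cascade is a
representative instance, not a fit).  The deterministic model cannot
express partially penetrant phenotypes, population variability in
mating frequency, or the pheromone negative-feedback transients that
real cells show.
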