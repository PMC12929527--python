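# Methods

`amyprog` simulates the amyloid-β (Aβ) arm of Alzheimer's disease
progression as one deterministic ODE system integrated over a simulated
lifespan (default ages 20–100, one clock in hours, 1 year = 8766 h).
This note records the model, its assumptions, the defaults and why they
are what they are, and what the synthetic pieces do and do not show.

## Model structure

**APP processing (brain ISF).** Amyloid precursor protein is produced
at a constant rate and processed by two competing secretase pathways,
written as a 24-reaction mass-action table (4 reversible generation
pairs, a 9-step non-amyloidogenic α/γ branch ending in p3, an
11-step amyloidogenic β/γ branch ending in Aβ40 or Aβ42). Enzymes are
catalytic: every secretase bound into a complex is returned by the
cleavage step, so enzyme totals are conserved when their own turnover
is switched off. The γ-cleavage branching to Aβ42 is a single
parameter `r42` (default 0.10, the commonly used ~1:9 ratio); at
steady state J_Aβ42/(J_Aβ40+J_Aβ42) equals `r42` exactly. The table is
compiled to an ODE right-hand side by a generic reaction engine
(`amyprog.reactions`), which also serves as a standalone tool: parse a
plain-text reaction table, build a mass-action RHS, integrate stiffly,
find non-negative steady states.

**Aggregation (per isoform, ISF).** A six-species reduced-order
cascade — monomer M, dimer D, small oligomer o, large oligomer O,
protofibril F, plaque P — with

* the reversible ladder 2M↔D, M+D↔o, M+o↔O, M+O↔F, M+F↔P;
* plaque-catalysed secondary nucleation, rate `k2n·M²·P`, producing a
  dimer from two monomers on plaque surface;
* monomer-driven conversion of oligomers to plaque,
  `kPg·M·(o+O)·max(0, 1−P/Pmax)`;
* fragmentation: F → o/O (configurable split, default 50/50) and
  P → F.

The species above the dimer are lumped assemblies with composite rate
constants, so monomer-equivalent conservation is asserted only for the
isolated M↔D subsystem (and for the literal ladder, which adds one
unit per step, the weighted total M+2D+3o+4O+5F+6P is invariant — a
property the tests exploit). Nominal multiplicities (2, 8, 24, 100,
10⁴) exist for mass reporting only. The two isoforms aggregate
independently (homogeneous aggregates); they interact only through
shared production machinery and the microglial state.

**Whole-body transport.** Eleven compartments: plasma, brain vascular,
BBB endothelium, BCSFB epithelium, ISF, CSF, perivascular space (PVS),
lymph, tissue vascular, tissue barrier, tissue interstitium. Monomer
and dimer circulate everywhere; o/O/F move only along the glymphatic
ISF→PVS→lymph route, throttled by the per-species reflection
coefficients σ_i,pv and σ_pv,L (monomer 0.200/0.650, dimer 0.900/0.900,
small oligomer 0.900/0.900, large oligomer 0.990/0.990, protofibril
0.999/0.999); plaque is immobile apart from first-order macrophage
clearance in the PVS. Fluid permeation carries `Q·(1−σ)·C`; lumped
transporters carry RAGE influx (brain vascular → ISF, scaled by the
unbound plasma fraction `fu_p` = 0.95) and LRP1/P-gp efflux
(ISF → brain vascular), with the Aβ42 efflux rate half the Aβ40 rate.
Outside the CNS monomers degrade at 1.9×10⁻⁴/s (0.684/h). All
transport is linear, one constant matrix per species.

**Clearance and risk.** Soluble monomer in the ISF is degraded by
proteases (NEP/IDE) as a Hill term `Vmax(age)·M^n/(Km^n+M^n)` with
n = 1 (the exponent is not constrained by the source; configurable)
and `Vmax(age) = Vmax0·max(0, 1 − d·(age−40)⁺)`, d = 0.5%/year — a
linear decline law chosen for parsimony. Insoluble species are cleared
by microglia at

    kg_i = μ(t) · [ fr(t)·V_i_high + (1−fr(t))·V_i_low ] · (1−α) · s_sex

with fr the phenotype fraction (0.03 at homeostasis), μ the normalised
microglia density (1 at homeostasis), o/O/F sharing one rate and the
plaque rate fixed at 50% of it. APOE status enters as the factor
(1−α), α ∈ [−0.02, 1] (non-carrier 0, ε2 carriers −0.02, ε4/ε4 1.0,
heterozygotes between — per-genotype values are calibration artifacts,
not printed data). The sex effect multiplies the retained fraction
(1−α) by 0.95 for females, so females run slightly less clearance at
every genotype and the male/female disparity shrinks as α → 1 — chosen
over a multiplier on α itself, which would vanish entirely for
non-carriers.

**Disease-status trajectories.** Healthy subjects hold the functional
phenotype (fr = 1, kg = V_high) with μ = 1 for life; the cascade is
subcritical and aggregates stay at trace levels. AD-prone subjects
keep the homeostatic fr = 0.03 (activation fails; kg sits near V_low)
while μ declines with total ISF plaque burden,
`μ(P) = 1/(1+(P/P_μ)^h)` (midpoint 5 nM in lumped plaque units,
h = 4) — microglial exhaustion. This choice is forced by arithmetic:
with any constant first-order plaque clearance kg_P, steady-state
plaque is capped at (capture flux)/kg_P, i.e. a few hundred nM at
most, while the imaging constants put the SUVR-1.5 load near 3×10⁵ nM.
Clearance must therefore collapse as pathology advances. The
alternative activation response (fr rising with burden,
`phenotype_fraction`) is implemented and pluggable but is not the
default disease trajectory.

## Why the production scale is what it is

In lumped units each plaque increment climbs the six-species ladder,
consuming about six monomer units, so plaque can accrue at most
(production flux)/6 assembly-events per hour. The saturating uptake
relation SUVR = c0 + c1·βL^c2/(c3^c2+βL^c2) (c0 = 1, c1 = 4.65,
c2 = 3.3, c3 = 6.3×10⁵ nM, and βL = o+O+F+c4·P with c4 = 1.95) puts
SUVR 1.5 at βL ≈ 3.3×10⁵ nM. Reaching that by age 70 therefore
requires total Aβ generation near 7 nM/h in the ISF, which the default
APP constants provide (total ISF monomer ≈ 75 nM at homeostasis,
Aβ40:Aβ42 ≈ 9:1). The absolute concentration scale of the model is
thus set by the imaging bridge, not by microdialysis data; ratios and
fractional turnover, not absolute levels, are the quantities the model
is calibrated to reproduce.

## Calibration

The healthy homeostatic steady state is required to reproduce three
physiological anchors: brain Aβ production 7.6%/h of the brain pool
(ISF+CSF+PVS amounts), total clearance 8.3%/h, and an 85% share of
clearance across the BBB. Because the transport system is first-order,
all three fractions are invariant to the production scale, so the
calibration's free parameters are the three rates that move them
independently: RAGE influx `F_in` (sets the clearance−production gap),
LRP1/P-gp efflux `F_out` (sets the BBB share; the Aβ42:Aβ40 ratio is
held fixed), and the glymphatic flow `Q_ipv = Q_pvL` (sets the non-BBB
remainder). The fit is a deterministic bounded least squares; shipped
defaults already satisfy the targets, so calibration from the shipped
set is a fixed point. The late-onset-AD (LOAD) variant scales every
CNS fluid-clearance pathway and the protease capacity by
`load_factor` = 0.7, which reproduces the ~30% clearance reduction at
the LOAD steady state (30.05% measured; scaling efflux routes alone
gives 29.3% because the ISF/CSF exchange distorts the CSF sub-pool).

Aggregation and microglial constants are supplement-free territory;
the shipped values were fixed by calibrating, once, to the model's own
anchors: amyloid-positive default run passing SUVR ≈ 1.5 at age 70,
healthy run flat at SUVR ≈ 1.0 through age 100, and a maximal
(α = 1) APOE onset advance of ISF Aβ42 plaque approaching but not
exceeding 5 years (measured 4.6 y; α = 0.3 and 0.6 give smaller
advances). Aβ42 carries ~30× the secondary-nucleation constant and
~5× the chain-forward constants of Aβ40 — a uniform 5× alone cannot
make the dilute Aβ42 cascade lead, because the autocatalytic gain
scales with M², and ISF Aβ40 is ~6-fold more abundant.

## Numerics

LSODA throughout, lifespan runs at rtol 1e-6 / atol 1e-9 nM (halving
tolerances moves age-100 plaque by <0.1%); the generic engine defaults
to rtol 1e-8 / atol 1e-12. Homeostatic initialisation pins o/O/F/P at
a trace 1e-6 nM (so autocatalysis has a seed), relaxes the remaining
59 states by long-horizon integration, then polishes with bounded
least squares to ‖dC/dt‖∞ ≤ 1e-6 nM/h. States are clipped at zero
inside the RHS and in outputs (tolerated undershoot 1e-9 nM).
Per-species transport matrices are precomputed; only the ISF reaction
terms are state-dependent. Everything is deterministic; the only
stochastic utility is the seeded synthetic SUVR cohort generator.

## Synthetic data

`SyntheticCohortSpec` emulates a cross-sectional amyloid-PET study —
by default 260 subjects aged 70–92, one SUVR each, drawn from a
4-parameter logistic (lower 1.0, upper 2.5, midpoint 75.8 y, slope
0.12/y, chosen so the trajectory passes 1.5 at age 70) plus Gaussian
noise (sd 0.10). It reproduces the *dimensions and error structure*
of such a study, not its selection effects: real cohorts oversample
amyloid-positive elderly, have test–retest error that varies with
uptake, and are not uniform in age. Passing the recovery tests
therefore shows the fitting machinery is correct and well-conditioned
at the reference size, not that the generating sigmoid is the true
population trajectory.

## Known limitations

* Single homogeneous brain region; no intraneuronal APP trafficking;
  no tau/NFT coupling; no co-aggregation of the isoforms.
* The lumped aggregate species have no strict stoichiometric meaning
  above the dimer; absolute insoluble concentrations are meaningful
  only through the calibrated imaging bridge.
* BBB transporter rates are age- and APOE-independent; APOE acts only
  on microglial clearance.
* The carrier-vs-non-carrier relative gap at age 100 is larger for
  plaque than for oligomers in this parameterisation (plaque
  integrates the onset-advance history); the qualitative claim the
  model does support is that oligomer/protofibril elevation persists
  at 100 while the relative plaque gap decays to well under half its
  age-70 value.
* The sigmoid SUVR fit is a 4-parameter logistic; a generalised
  logistic can be substituted behind the same interface.
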