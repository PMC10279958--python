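# Methods

## The model

`spnsim` implements the segment polarity network (SPN) of the *Drosophila*
embryo as a deterministic ODE model on a periodic hexagonal lattice of
cells.  Each cell carries 33 dynamic species: the mRNAs of *engrailed*
(*en*), *wingless* (*wg*), *patched* (*ptc*), *cubitus interruptus* (*ci*)
and *hedgehog* (*hh*); the cytosolic proteins EN, IWG (intracellular
Wingless), CI and CN (the truncated repressor cleaved from CI); and four
membrane proteins — EWG (membrane Wingless), PTC, HH and the
Patched–Hedgehog complex PH — each split into six pools, one per hexagon
side.  On the canonical 1×4 parasegment repeat this gives 132 state
variables.  All concentrations are normalized to the unit interval.

Transcription uses Hill-type laws.  For an inducer–repressor pair the rate
is

    v = V · Ī^h1 / (κ1^h1 + Ī^h1),   Ī = I · ψ(R),
    ψ(R) = 1 − R^h2 / (κ2^h2 + R^h2),

i.e. the repressor attenuates the inducer multiplicatively and the
attenuated inducer enters a single activating Hill function.  The *wg*
promoter uses a saturating two-branch form
(α·φ(CI)·ψ(CN) + β·φ(IWG)) / (1 + α·φ(CI)·ψ(CN) + β·φ(IWG)) — CI
activation gated by CN plus Wingless auto-activation; *ci* is constitutive
(basal inducer B = 1) and repressed by EN.

Every synthesis velocity carries the time scale of its target's half-life:
the maximum transcription rate of species X is `V_max · ln2/H_X` and its
decay rate `ln2/H_X`, so the attainable steady level is `V_max` (= 1) and
the half-life controls only the response time.  Translation follows the
same convention on the protein's half-life.  This normalization is what
makes the half-saturation constants (sampled in [1e-3, 1]) and the unit
initial-condition convention mutually coherent; a synthesis velocity
decoupled from the half-life would push steady levels to H/ln2 ≫ 1 and
detune every Hill function.

Signaling across cells: *en* is induced by EWG_T, the total Wingless on the
six apposed neighbour membrane patches; free Patched promotes CI cleavage
through φ(PTC_T); Patched binds Hedgehog presented on the apposed neighbour
membrane, forming PH and thereby both sequestering PTC (protecting CI) and
consuming HH.  The normalized binding fluxes carry the concentration scale
factors: dPTC_j = −k·HH_0·PTC_j·HH_j′, dHH_j′ = −k·PTC_0·PTC_j·HH_j′,
dPH_j = +k·HH_0·PTC_j·HH_j′.  Membrane pools exchange with the two
cyclically adjacent sides (lateral diffusion) for all four membrane
proteins; Wingless additionally exchanges between apposed membranes
(r_MxferWG) and cycles between IWG and EWG by exo-/endocytosis.

### Lattice

Sides are numbered 1..6 clockwise from the anterior-facing diagonal; side j
apposes side ((j+2) mod 6)+1 of the neighbour, so side 5 of a cell faces
side 2 of its right (posterior) column neighbour.  The lattice is toroidal.
In a single-row grid the four diagonal neighbours wrap into the row: sides
1–3 face the left cell and sides 4–6 the right cell, preserving the
apposition involution and the one-dimensional periodic stripe geometry.
Multi-row grids use constant axial-coordinate offsets, which keep the
involution exact under periodic wrapping for any grid size.

### Guarded exponentiation

`base^exponent` is evaluated in IEEE arithmetic as exp(exponent·log base)
for non-integer exponents, so a concentration pushed infinitesimally below
zero by a predictor–corrector step yields NaN and aborts the run.  Every
state-dependent base in the rate laws is therefore wrapped as
max(ε, base) with ε = 1e-80 (configurable, globally switchable off);
half-saturation constants are strictly positive constants and are never
guarded.  The repression factor additionally clamps its outer (1 − φ)
factor to ≥ ε.  With guards on, the right-hand side is a total function of
finite states; with guards off the package reproduces the raw failure mode
(reported as `invalid_state`, never an unhandled exception).

## Parameters

53 named global parameters, 48 sampled in screens (all log-uniform):

| group | names | range |
|---|---|---|
| half-lives (13) | H_en, H_EN, H_wg, H_IWG, H_EWG, H_ptc, H_PTC, H_ci, H_CI, H_CN, H_hh, H_HH, H_PH | [5, 100] time units |
| regulator pairs (11×2) | κ/ν for WGen, CNen, CIwg, CNwg, WGwg, CIptc, CNptc, ENci, PTCCI, ENhh, CNhh | κ ∈ [1e-3, 1], ν ∈ [1, 10] |
| kinetic rates (11) | α_CIwg, α_WGwg, C_CI, k_PTCHH, r_ExoWG, r_EndoWG, r_MxferWG, r_LMxferWG, r_LMxferPTC, r_LMxferHH, r_LMxferPH | [1e-3, 1e3] per time unit |
| scale factors (2) | PTC_0, HH_0 | [1, 1000] |

Fixed (5): B_ci = 1 (basal ci inducer), V_max = 1 and P_trans = 1 (the
shared transcription/translation scales of the normalization above), and
r_MxferPTC = r_MxferHH = 0 — Patched and membrane-tethered Hedgehog do not
hop between cells, unlike secreted Wingless.  Only the PTC_0/HH_0 range is
anchored in the source; the identity of the five fixed parameters and the
rate ranges are documented reconstructions.  Decay uses ln2/H (H is a
half-life in the literal sense); a 1/H convention would rescale the
sampled half-life range by ln2 but not change its span.

PH diffuses laterally like the other membrane proteins (the source's
network diagram lists it among the diffusing membrane pools); its rate
r_LMxferPH is sampled.

## Dynamics

Time courses integrate with LSODA (stiff/non-stiff switching) at
atol = 1e-13, rtol = 1e-8, sampled every 5 time units to t_end = 1100
("timecourse1").  The integrator is fed an analytic Jacobian compiled
alongside the right-hand side (verified against finite differences in the
test suite); this cuts the cost of the stiff phases by roughly 4× compared
with internal finite-difference Jacobians.  States are never clipped at
zero — the guards make the rate laws well-defined under overshoot, which is
the model-level fix the package adopts.

Steady states are located purely by integration: the model is advanced over
doubling time spans (50, 100, 200, … up to t_max = 1e6) and declared
converged when both the max-norm of the right-hand side and the state
displacement over the last span fall below the resolution (1e-4) — a
"distance and time" criterion.  Newton polishing is deliberately not used,
so only attractors reachable from the initial condition are reported.
Non-converging sets (likely limit cycles) are counted as having no steady
state and are not classified further.

## Robustness screen

Each try draws the 48 sampled parameters log-uniformly (per-record seeds
derived from (seed, index), so batches are order-independent and
resumable), builds the preset initial condition, integrates timecourse1 and
scores the trailing 200 time units.

**Score.** For each scored mRNA (wg, en, hh, ptc) the per-cell
concentrations are time-averaged over the window; with m_on the minimum
over that species' on-cells and m_off the maximum over its off-cells, the
species score is m_off/m_on and the total score the maximum over species.
A score below 0.2 (the hit threshold) therefore demands at least five-fold
on/off separation for every scored species simultaneously.  Both averages
are floored at 1e-12 — far below any resolvable concentration — which
clamps integrator overshoot and makes a fully decayed trajectory score 1
rather than a spurious perfect stripe.  The score is scale-free above that
floor.  The target pattern is wg on in cell 2 (off 1, 3, 4), en and hh on
in cell 3 (off elsewhere), ptc on in cells 2 and 4 and off in cell 3; ptc
in cell 1 is unconstrained, since Patched is repressed only in engrailed
territory.  Failed integrations score +inf and count as tries, never hits.

**Presets.** Verbal range classes map to 0.15 (“<20%”), 0.4 (“20–60%”) and
0.9 (“60–100%”).  A preset assigns the class value to the named gene's
mRNA and its cognate proteins in the same cell (membrane pools split /6);
everything else starts at 0.15 (CN at 0.15, PH at 0.15/6).  The shipped
presets: crisp (wg stripe cell 2, en stripe cell 3), degraded (the same
stripes blurred into neighbours at 0.4), crisp plus ubiquitous 0.4 ci and
ptc, a 3-cell ci band with wg on its posterior margin, a 3-cell ptc band
with en on its anterior margin, a 3-cell ptc band with an out-of-phase ci
band, and close-to-target (the full target pattern pre-formed, with ci on
in the non-engrailed cells).  The exact vectors used by the original
screens were published only in deposited model files; these are documented
reconstructions from the row labels.

## Multistability census

For each sampled parameter set, 15 initial conditions are drawn uniformly
on [0,1]^132 and integrated to steady state as above.  Converged states are
deduplicated with a max-norm tolerance of 1e-2 — two orders of magnitude
above the steady-state resolution, separating numerical jitter from
genuinely distinct attractors; deduplication sorts states first, so it is
independent of the order of the initial conditions.  A set with more than
one surviving state is multistable.  The mono- vs multistable comparison
reports per-parameter medians of both groups and their ratio
(median_multi/median_mono).

## SBML export

Models export as SBML Level 3 Version 1 with the full reaction network: one
unit-size compartment per cell, cell-qualified species ids (`EWG5_0_1`),
all 53 parameters, the derived totals (EWG_T, PTC_T, PH_T) as assignment
rules, and complete kinetic laws in content MathML.  The guard max(ε, x) is
encoded as piecewise (L3V1 MathML has no max); an unguarded model exports
plain powers.  The unequal-scale binding fluxes are encoded as paired
reactions sharing the bimolecular law, since SBML stoichiometries cannot
reference parameters.  The writer/reader are built on the standard-library
XML tools; validation is structural (unique ids, resolvable references,
supported MathML subset), and the operative correctness check is the
round-trip oracle: import(export(M)) must reproduce the right-hand side of
M to 1e-9 relative.  A JSON sidecar records the timecourse1 settings and
provenance, so the full simulation experiment travels with the model.

## Problem sizes and what the tests show

Published reference rates come from cluster-scale experiments (240,000–
750,000 integrations per screen row; 5,000×15 steady-state searches).  The
package's test suite and acceptance script run desk-scale versions: screens
of 1,000–5,000 tries and a census of a few hundred steady-state searches,
compared with the reference rates through exact binomial 99% confidence
intervals.  At these sizes a hit count of a handful carries large sampling
error; the acceptance script prints raw hit counts alongside the
reciprocal rates so the uncertainty is visible.  The synthetic initial
conditions emulate pre-patterned stripe classes, not measured expression
profiles; passing tests demonstrate that the implementation reproduces the
model's documented construction and scoring pipeline, not that the
reconstructed preset vectors equal the deposited ones.

## Known limitations

* The regulatory algebra of the wg promoter, the binding scale factors,
  the preset vectors, the identity of the fixed parameters and the kinetic
  rate ranges are reconstructions from prose; the deposited model files
  remain the authority for bit-level replication.
* Hit rates are sensitive to the unanchored kinetic-rate sampling ranges;
  see the acceptance notes.
* No limit-cycle detection, bifurcation analysis or eigenvalue stability
  classification; non-converging census entries are simply "no steady
  state found".
* SBML import supports the package's own export conventions (and any L3
  document restricted to the same MathML subset), not the full SBML
  feature set.
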