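# spnsim — segment polarity network simulator

`spnsim` is a self-contained re-implementation of the classic *Drosophila*
segment polarity network (SPN) model: the gene circuit of *wingless* (wg),
*engrailed* (en), *hedgehog* (hh), *cubitus interruptus* (ci) and *patched*
(ptc) that maintains stable per-cell expression stripes defining segment
boundaries in the insect embryo.  It is written for modellers who want to
re-run, screen, or extend the model without depending on any single GUI
simulator: the package builds the full multicellular reaction network
programmatically on a hexagonal cell lattice, integrates it with stiff ODE
solvers, screens random parameter sets for stripe formation, censuses
steady-state multistability, and exports the complete reaction network as
SBML Level 3 so the model outlives this package too.

## The model in brief

Each hexagonal cell carries 33 species: 5 mRNAs, 4 cytosolic proteins (EN,
intracellular Wingless IWG, CI and its truncated repressor fragment CN) and
4 membrane proteins (EWG, PTC, HH, PH) in six per-side pools.  On the
canonical 1×4 parasegment repeat this is 132 ODEs sharing 53 global
parameters (48 sampled in screens).  Transcription follows guarded
Hill-type laws — for an inducer–repressor pair

    v = V · Ī^h1 / (κ1^h1 + Ī^h1),   Ī = I · (1 − R^h2/(κ2^h2 + R^h2))

with every state-dependent power base wrapped as max(ε, ·), ε = 1e-80, so
integrator overshoot below zero cannot produce NaN.  Cells communicate by
Wingless presented on apposed membranes (inducing *en*), and by Hedgehog
binding Patched across cell interfaces (sequestering PTC, protecting CI
from cleavage into CN).  The wild-type attractor is the parasegment
pattern: wg on in cell 2, en/hh on in cell 3, ptc flanking the hh source.
See `docs/methods.md` for the full wiring, parameter registry and numerical
choices.

## Worked example

Simulate the stored reference hit parameter set ("timecourse1": 1100 time
units sampled every 5, from the degraded pre-stripe initial condition):

```bash
spnsim simulate --out traj.csv
# {"status": "ok", "rows": 221, "out": "traj.csv"}
```

The final mRNA concentrations (normalized to [0, 1]) show the segment
polarity pattern around the parasegment boundary between cells 2 and 3:

```
cell     1      2      3      4
en    0.032  0.000  0.999  0.000
wg    0.000  0.914  0.000  0.000
ptc   0.914  0.914  0.000  0.914
hh    0.000  0.000  1.000  0.000
```

*wingless* and *patched* end high in cell 2 and *engrailed*/*hedgehog* in
cell 3; the pattern score (worst on/off separation over the four scored
mRNAs) is 0.032, far below the 0.2 hit threshold.

Run a small robustness screen and export the model as SBML:

```bash
spnsim screen --preset crisp --n 500 --seed 1 --out-dir screen_out
spnsim build --rows 1 --cols 4 --out spn_1x4.xml
```

The screen writes one CSV row per try (48 sampled parameter values, score,
hit flag, status) plus a JSON summary with the hit rate; `build` writes
SBML L3V1 with the complete kinetic laws plus a JSON sidecar carrying the
timecourse1 settings.

## Library layout

| module | contents |
|---|---|
| `spnsim.hexlattice` | periodic hexagonal grid, side apposition maps |
| `spnsim.kinetics` | guarded exponentiation, Hill laws, linear terms |
| `spnsim.network` | species/parameter/reaction registries, compiled RHS |
| `spnsim.dynamics` | LSODA time courses, steady states by integration |
| `spnsim.screen` | log-uniform sampling, stripe score, hit-rate screens |
| `spnsim.multistab` | steady-state census, mono/multi parameter contrasts |
| `spnsim.sbmlio` | SBML L3V1 export/import with round-trip verification |
| `spnsim.cli` | `spnsim build / simulate / screen / multistab / ...` |

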