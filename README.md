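# cerebroflow

Steady laminar pipe-network modelling of the anterior cerebral
circulation: the Circle of Willis (CoW), the MCA/ACA/PCA cortical branch
trees, and the leptomeningeal anastomoses (LA), with an experiment
engine that simulates arterial occlusions and quantifies how much flow
the collateral pathways restore.

## Who this is for

Researchers studying collateral capacity in ischemic stroke: how much
protection the CoW provides when an occlusion sits at or below the
circle, and how large the pial (leptomeningeal) anastomoses between the
MCA, ACA and PCA territories must be to keep an occluded territory above
the ischemic threshold.

## The model

The vasculature is a graph of junction nodes joined by rigid cylindrical
pipes. Each pipe obeys the laminar Hagen–Poiseuille law

    R = 128 μ L / (π d⁴),        Q = ΔP / R

with blood treated as Newtonian (μ = 3.5 mPa·s). Imposing mass balance
at every junction (Kirchhoff's current law, hydraulic form) with nodal
pressures as unknowns yields a sparse linear system, solved directly.
Boundary conditions: 75% of total inflow (default 750 mL/min) enters
through the two internal carotid arteries and 25% through the basilar; a
5 kPa pressure is imposed on the outer boundary, which every cortical
tip reaches through a terminal drainage pipe representing runoff into
the capillary bed. An occlusion is a pipe with zero conductance.

The canonical anatomy carries a complete CoW, an MCA dividing equally
into superior (7 cortical arteries) and inferior (5 cortical arteries)
trunks, multi-stem origins for the prefrontal, precentral and central
arteries, and branches down to fifth-order tips where the LA attach:
inter-territorial LA on six MCA arteries (to ACA or PCA partners) and
intra-territorial LA chaining adjacent cortical branches. Eleven
occlusion experiments (1–3 proximal; 4a–4h progressively distal MCA
sites) run under each LA configuration; results are reported per artery
as a signed percent of its own unoccluded baseline, and flow above 30%
of baseline counts as adequate to prevent ischemia.

## Worked example

One experiment: occlude the superior-trunk stem that supplies the
central and the anterior/posterior parietal arteries (experiment 4e),
with intra-territorial LA of 0.25 mm and inter-territorial LA of 1.0 mm:

```bash
$ cerebroflow run --experiment 4e --condition 2b
# experiment 4e  inter-LA 1.0 mm  intra-LA 0.25 mm  (residual 4.40e-23)
R-P1                       96.9
R-Pcom                     82.7
...
R-central                 108.2
R-ant-parietal            -10.4
R-post-parietal            10.3
...
```

Reading the numbers: the central artery keeps 108.2% of its baseline
flow because it arises from *two* stems and the second survives the
occlusion — it stays adequate (>30%). The anterior parietal artery,
single-stemmed on the occluded stem, receives only a trickle backwards
through its anastomosis (−10.4%: the sign marks reversal relative to
baseline direction), and the posterior parietal (no anastomosis of its
own) gets 10.3% second-hand — both below the 30% threshold, so both are
classified critical. With no LA at all (`--condition 1`) both parietal
arteries read exactly 0.0: no path connects them to any inflow.

Other entry points:

```bash
cerebroflow suite --condition 1 --out table1.csv   # all 11 experiments
cerebroflow sweep --experiment 4a                  # LA diameter grid
cerebroflow validate                               # invariant battery
```

The same operations are available as a library
(`cerebroflow.run_experiment_suite`, `cerebroflow.la_diameter_sweep`,
`cerebroflow.solve_flow`, ...), returning pandas tables and solution
objects.

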