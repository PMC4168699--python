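# Methods

## Model and assumptions

The cerebral arterial tree is reduced to a zero-dimensional resistance
network: rigid cylindrical pipes joining junction nodes, steady laminar
flow, Newtonian blood. Each pipe's hydraulic resistance is the
Hagen–Poiseuille value R = 128 μ L / (π d⁴); the network then behaves as
a linear circuit with pressure as potential and volumetric flow as
current. Pulsatility, vessel compliance, non-Newtonian rheology,
autoregulation, anatomical CoW variants, deep perforating arteries and
the venous side are all out of scope: the model isolates the *capacity*
of the collateral topology, not detailed hemodynamics.

Flow is solved by nodal analysis. Every junction contributes one mass
balance equation; the three inflow nodes (two ICAs, basilar) contribute
prescribed-inflow equations of the same form; the outer boundary is a
single fixed-pressure reservoir node to which all drainage pipes
connect. The sparse system is solved by a direct factorization — the
governing equations and the residual tolerance, not the solution
method, are the contract (the residual of every solve is reported on
the solution object; typical values are ~1e-20 relative).

Degenerate inputs are defined, not accidental: an occluded pipe has
conductance exactly zero, which is verified flow-equivalent to deleting
it; a component cut off from every outlet cannot carry steady flow, so
its pressures are reported as NaN sentinels, its flows as exact zeros,
and any inflow prescribed at an inlet stranded there is dropped (an
occluded inflow vessel admits nothing — this situation arises in
experiments 1–3, which occlude the carotid at its base). A network with
no outlet anywhere raises an unconstrained-pressure error rather than
returning an arbitrary pressure level.

## Parameters

| parameter | default | why |
|---|---|---|
| viscosity μ | 3.5 mPa·s | standard large-vessel value for blood |
| total inflow | 750 mL/min | canonical adult cerebral blood flow; every reported quantity is percent-of-baseline, so the value cancels |
| inflow split | ICA 37.5% + 37.5%, BA 25% | the stated 75/25 carotid/basilar partition, split equally between sides as the minimal assumption |
| outlet pressure | 5 kPa | stated outer-boundary condition |
| ischemic threshold | 30% of baseline | stated adequacy criterion; strict inequality, applied to the magnitude (reversed flow still perfuses) |
| LA length | 5 mm | pial bridging distance; not stated anywhere, exposed in `LAConfiguration` |
| LA conditions | none / intra 2.0 + inter 0.25 mm / intra 0.25 + inter 1.0 mm | the three studied configurations |
| sweep grid | 0.0625–2.0 mm | spans sub-cadaveric (~0.06 mm) through pathologically enlarged (~2 mm) anastomosis calibers |

## Geometry

The package ships a documented default geometry
(`src/cerebroflow/data/canonical_geometry.csv`) with Rhoton-derived
calibers: ICA 4 mm, basilar 3.2 mm, M1 3 mm, A1/P1
2.2 mm, Acom/Pcom 1.4 mm, MCA divisions 2 mm, stems 1.6 mm, cortical
arteries 1.2 mm tapering to 0.6 mm fifth-order terminals, and 0.6 mm
drainage pipes whose resistance stands in for the arteriolar bed.
Baseline inlet pressure comes out at ≈14.5 kPa (≈108 mmHg), a sensible
mean arterial pressure. Every machine-checked result is forced by
network *topology* (which arteries are connected to which), not by
these calibers; percentages that do depend on calibers (e.g. how much
flow a 1.0 mm anastomosis restores) are checked qualitatively only.

The superior-division wiring encodes the multi-stem annotations: the
prefrontal artery takes two stems proximal to the experiment-4c site;
the precentral and central arteries each take one stem from each of the
two distal stems of the division; the anterior and posterior parietal
arteries sit on a continuation of the second distal stem. Experiment 4e
occludes that stem along its length, so the parietal arteries lose
every path while the central artery survives through its second stem of
origin. Multi-stem origins are deliberately wired so that no pair of
stems bridges across an occlusion site: such a bridge would act as an
unintended collateral and turn the exact zero-flow cells into small
nonzero values.

Inter-territorial anastomoses attach at the fifth-order tips of the six
MCA cortical arteries annotated as possessing them; the ACA/PCA partner
branch of each pairing is not enumerated publicly, so the chosen
pairing (frontal/parietal → ACA branches, angular/anterior temporal →
PCA branches) is recorded in `data/la_wiring.yaml`. Intra-territorial
anastomoses chain adjacent cortical tips in anatomical order around the
convexity; the ACA→ACA (interhemispheric) anastomosis class is not
wired, since only the MCA-side possession column is specified.
Left/right sides are exact mirrors; at baseline all mirrored flows
agree to 1e-9 relative and the Acom carries zero by symmetry.

## Normalisation and reporting

Percent flow is 100 × (occluded flow) / (baseline flow of the same
segment), signed, rounded to one decimal with halves away from zero.
The baseline is always the identical network — same LA configuration —
without occlusion, so each suite normalises within its own condition.
Flows below 1e-7 mL/min (far above solver roundoff, far below any
physiological flow) are treated as structural zeros; a segment whose
*baseline* is itself structurally zero reports NaN ("not applicable")
rather than a misleading 0.0 or infinity. Because the model is linear,
percentages are invariant to the total inflow and to uniform scaling of
all diameters; this is tested.

Under LA conditions, arteries fed second-hand through an anastomosis
often carry flow *retrograde* through their named proximal segment, so
their small percentages come out negative; the ischemia classification
uses magnitudes and is unaffected.

## Oracles and test design

Three independent checks back the solver: (1) closed-form fixtures
(single pipe, series chain, 1:16 parallel split, symmetric Y, balanced
Wheatstone bridge) asserted to 1e-10; (2) a dense nodal-analysis oracle
written against plain numpy with its own breadth-first component
search, agreeing to better than 1e-8 on 100 seeded random networks
(connected by construction: random spanning tree plus chords); (3) a
pure graph-search oracle for topology-forced zeros — a segment can
carry steady flow iff it lies on a simple inflow→outflow path,
equivalently iff it shares a biconnected component with a virtual
source–sink edge. The exact zero/nonzero correspondence is asserted for
every named table artery across all 33 scenario × condition
combinations; for unnamed segments only the one-sided claim is asserted,
because a flow-capable segment may still carry an exact structural zero
(perfectly symmetric anastomoses between mirrored or sibling branches).

Random test networks are small (≤ 40 nodes) and seeded; hypothesis
property tests run derandomized. The full suite and the acceptance
script each complete in a few seconds on one core.

## Known limitations

Percent values in non-occluded arteries depend on the chosen segment
calibers; only the topology-forced pattern (which cells are zero, which
arteries survive, orderings and monotonicities) is caliber-independent,
and only that pattern is machine-checked. The drainage pipes impose
equal terminal resistance everywhere, so baseline cortical flows are
nearly uniform rather than territory-weighted. Experiments 1–3 occlude
an inflow vessel; with prescribed-inflow boundary conditions the cut
carotid's flow is dropped rather than redistributed, so total delivery
falls by that share in those scenarios. The model says nothing about
perfusion below the cortical surface, infarct volume, or time.
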