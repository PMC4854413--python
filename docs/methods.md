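# Methods

## Logical model

Every node carries a binary state; all reactions take one time increment.
Update rules use only AND, OR and NOT. The curated network has 41 nodes: the
EGF input (clamped ON for all `t`, modelling sustained stimulation at the
leading edge of an RCP/α5β1/EGFR1-driven cell), the Rac1 and RhoA outputs,
and 38 intermediates. At `t = 0` the basally active nodes PDK1, mTor, c-Src,
Pip2 and Rac1 are ON; everything else is OFF. The input-less inhibitors
PTEN, SHIP2 and PP2a are constitutive: they carry no update rule, default
OFF, and their perturbation sets them ON.

The wiring of nodes not fixed by the reported behaviours of the original
curation was transcribed from canonical EGFR pathway biology; each such rule
carries a provenance tag ending in `(inferred)`.
The transcription is constrained by — and the test suite pins — every
quoted behaviour: the node census, both switching chronologies, the
three-way hierarchy taxonomy with RhoA dominance unique to the Sos1E-top
ordering, the knockout predictions, and the asynchronous robustness
ordering. Grb2 is modelled as its own adaptor node upstream of Sos1 (the
main text treats Sos1 recruitment as Grb2-mediated); folding it into Sos1
activation would change no asserted behaviour.

### Rac1 regulator hierarchy

A GEF and a GAP cannot act on the GTPase in the same spatiotemporal state,
so Rac1's rule depends on the precedence among its GEFs {Vav2, RalBP1,
Sos1E} and its GAP pRacGAP1. The compiled rule is

    Rac1' = OR_{A above GAP} A
            OR ((OR_{A below GAP} A OR Rac1) AND NOT pRacGAP1 AND NOT RhoA)

A GEF ranked above the GAP fires unconditionally; one ranked below fires
only while the GAP is OFF. The self-maintenance literal is required so that
basally active Rac1 persists until pRacGAP1 first fires (matching the
one-increment switch-off lag); it is always guarded. The direct RhoA→Rac1
mutual-antagonism edge is grouped with the GAP guard — ranked below any
top-tier GEF — because otherwise Rac1 could never switch ON while RhoA is
still ON, and the observed one-increment Sos1E→Rac1 lag in the cyclic
hierarchy would be unreachable. Only the partition of GEFs above vs below
the single GAP is dynamically meaningful, giving 2³ = 8 canonical
hierarchies.

### Dynamics

Synchronous updates recompute every regulated node simultaneously; nodes
without rules (input, constitutive, knocked-out) hold their value. Because
the map is a function on a finite space, the orbit from the initial state
enters a cycle within 2^N steps; `find_attractor` hashes visited states and
reports transient length, the cycle, and per-node classes (stable active,
stable inactive, cyclic) with ON-fractions over the cycle. Output dynamics
are classified as `rac_persistent` (Rac1 stably ON, RhoA stably OFF),
`switch` (Rac1 stably OFF, RhoA stably ON), `cyclic` (both cycling), or
`other` for remaining combinations, which arise only under perturbation
(e.g. a Vav2 knockout leaves both outputs stably OFF). Note the *global*
attractor is a limit cycle under every hierarchy — the Sos1 negative
feedback loop oscillates with period 11 regardless — so "switch" refers to
the stability of the two output nodes within that cycle, which is what the
binary heatmaps display.

The asynchronous scheme interprets "at most one executable reaction per
increment" as: compute the set of unstable nodes (rule value ≠ current
value), draw one uniformly with a seeded generator and update it; if none
is unstable the state carries over, so fixed points are invariant.
Asynchronous statistics default to 10 repeats of 2000 increments (seeds
0–9). ON-time after the Rac1-OFF/RhoA-ON switch counts per-increment state
occupancy from the first such increment (exclusive) to the end of the
trace; since no numeric ON-times are published, only the ordering
(RhoA > Rac1) and persistence of cycling are asserted.

### Knockouts

`clamp_off` removes the node's rule and sets its initial and clamped state
to 0 — so basally active nodes also "remain OFF for all time" — while
`clamp_on` (constitutive inhibitors only) pins the node to 1. Screens
classify the attractor for every non-output node under both accepted
hierarchies. The two-screen difference table compares *effect signatures*
(None if the knockout leaves that hierarchy's baseline category unchanged,
else the resulting category) rather than raw categories, because the two
baselines already differ: an Eps8 knockout converts the cyclic output into
the switch — exactly the switch hierarchy's unperturbed category — and
only the signature view identifies it as a cyclic-hierarchy-specific
effector. Under this view the feedback-path nodes (Shc, Grb2, Sos1, Ras,
Raf1, MEK1/2, ERK1/2, Eps8, Abi1, Sos1E) are the discriminating set. A
p90RSK-only knockout is *not* discriminating: Sos1 is inhibited by ERK1/2
OR p90RSK, so removing p90RSK alone leaves the loop — and the cyclic
output — intact.

## FRET quantification

Parameters (defaults chosen for 16-bit EMCCD-like acquisitions):

| parameter | default | meaning |
|---|---|---|
| registration upsampling | 100 | shift precision 0.01 px |
| band-pass scales | 2–8 | à-trous detail planes kept |
| threshold | 2000 grey values | fixed segmentation cut on the band-passed direct-acceptor channel |
| ring width | 40 px | erosion depth defining the boundary ring |
| blur σ | 1.0 px | Gaussian smoothing of both ratio channels |
| front hint | crescent index (0/1) | manual identification of the cell front at frame 0 |

Numerical choices:

* Registration estimates per-frame translation of the moving channels onto
  the direct-acceptor reference by upsampled cross-correlation and resamples
  with a Fourier-domain phase shift, avoiding an interpolation-kernel
  choice. Constant frames get zero shift with a warning; a post-alignment
  correlation below 0.2 flags a low-confidence estimate. Cross-channel
  registration is content-limited: channels that genuinely differ in
  structure (a strong front/back ratio step) can bias the estimate by
  ~0.1 px, so accuracy is verified on shared-structure content.
* The à-trous transform uses the separable 3-tap kernel (1, 2, 1)/4 with
  taps dilated by 2^(scale−1) and mirror boundary handling (an assumption;
  the boundary rule is not specified by the acquisition protocol). Summing
  detail planes 2–8 equals smooth(1) − smooth(8); the full plane set
  reconstructs the input exactly, which the tests pin. Scale 8 spans 257 px,
  so frames must be at least that large; the threshold applies to raw
  band-passed values without per-frame normalisation.
* Ring erosion uses a disc structuring element of radius = ring width for
  isotropic thickness, implemented as `distance_transform_edt(mask) > width`
  — exactly the pixels surviving erosion by the radius-`width` disc, at a
  fraction of the cost of direct morphology.
* The bounding box of the *ring* is quartered along its longer axis; the
  extremal quarters intersected with the ring are the crescents. The front
  is chosen by hint at frame 0 and thereafter by maximal pixel overlap with
  the previous front crescent, replacing the manual per-frame intervention
  of an interactive workflow.
* Smoothing strictly precedes the division: `mean(blur(num)/blur(den))` over
  the crescent, excluding pixels where the blurred denominator is zero.
  Swapping the order changes the result on gradient images, so the order is
  pinned by test against a direct oracle. Display LUT bounds are
  presentation-only.

## Synthetic data

Random networks give every node an OR of 1–3 conjunctions over randomly
drawn literals, negated with probability 1 − activator_ratio (default 0.3);
all generators are seed-deterministic. The 1-input/2-output census is a
property of the curated model, not of networks in general, so random
networks are all-intermediate and the census is enforced by the fixture
constructor.

Synthetic biosensor movies emulate the acquisition geometry: a rigid
elliptical cell (default semi-axes 110 × 80 px in a 320 × 320 frame — large
enough for both the scale-8 wavelet span and a 40-px ring) translating
2 px/frame over 20 frames, a bright direct-acceptor channel (30 000 grey
values, segmentable at the fixed 2000 threshold after band-passing), a
1000-count donor and a fret channel equal to donor × true ratio, with a
sharp front/back ratio step through the centre (defaults 1.8 front / 1.1
back, spanning the dynamic range biosensor ratios occupy). Noise is
Poisson counting at a configurable gain plus Gaussian read noise
(sd = 2 × gain), mimicking EMCCD statistics without modelling camera
specifics. The generator does not emulate cell deformation, bleed-through,
photobleaching, or background fluorescence structure — so passing recovery
tests demonstrate correctness of the measurement chain on known ground
truth, not robustness to every property of real movies.

## Problem sizes

Simulations use 50 synchronous increments (the attractor is reached within
a ~9-increment transient plus the period-11 cycle), 2000-increment
asynchronous runs with 10 seeds, 100 random networks of 2–12 nodes for the
exhaustive-enumeration comparison, and 1–2-frame synthetic stacks per FRET
recovery point, which is sufficient because frames are statistically
identical up to translation.

## Known limitations

* The model is Boolean: it orders events but carries no kinetics; "RhoA
  dominance" is an ON-fraction statement, not a concentration ratio.
* Rules marked `(inferred)` follow canonical pathway maps rather than a
  verbatim published table; behaviours outside the pinned set may differ
  from the original model's.
* Double knockouts compose mechanically but are untested against any
  reference; overexpression (clamp-ON of non-constitutive nodes) and
  edge-level perturbations are unsupported.
* The FRET pipeline assumes a single dominant cell per frame and
  translation-only inter-channel misalignment.
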