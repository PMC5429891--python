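# Methods

## Scope and model

`stereovem` implements design-based (sampling-based) stereology for serial
section data of the kind produced by volume scanning electron microscopy, with
the Golgi apparatus as the guiding example. The package has two halves:

1. a **phantom and virtual-microscope half** that builds 3D scenes with exact
   analytic ground truth and sections them under the standard sampling
   designs, and
2. an **estimation half** that turns probe–structure interaction counts into
   volume, surface, number, size and composition estimates with standard
   errors.

Everything is validated by closing the loop: the phantom knows its own V, S
and N in closed form, and Monte-Carlo replication of the full
sampling-and-estimation pipeline must recover them.

## Phantom geometry

Scenes are collections of labelled convex primitives inside a reference
region (an axis-aligned box or a sphere, playing the role of the cell):

- **spheres** for transport vesicles (default diameter 65 ± 5 nm, truncated
  normal, reflecting the 60–70 nm COPI/clathrin class);
- **disc plates** (squat cylinders, thickness ≪ radius) for cisternae
  (defaults: radius 0.5–0.8 µm, thickness 40–60 nm, stack spacing > thickness);
- **cylinders** for tubules;
- **ellipsoids** where a smooth convex test body is wanted (Cavalieri
  precision studies).

All lengths are micrometres. Ground truth is analytic: sphere V = 4πr³/3,
S = 4πr²; disc V = πR²t with S = 2πR² (the rim 2πRt is *excluded* by
default, matching the flat-plate surface model behind t = 2/Sv; a flag
includes it); cylinder and ellipsoid by the standard formulas. Ellipsoid
surface uses the Thomsen approximation (max error ≈ 1.06%); its volume and
plane sections are exact. Vesicle centres are i.i.d. uniform — overlap is
permitted because no estimator's unbiasedness requires a hard core, and
rejection would change the spatial process; a hard-core mode exists where a
physically non-interpenetrating population matters (e.g. whole cells).

Scene ground truth is exactly invariant under rigid rotation, and the test
suite cross-checks V and S against voxel-counting and marching-cubes oracles
that share no code with the analytic path.

## Virtual sectioning

A section is a plane {x·n = o} with a deterministic in-plane frame; slabs
carry a physical thickness `h_phys` and an imaging depth `h_img` with the
half-open convention [o, o + h). Plane–primitive intersection is exact:
spheres give discs, plates and cylinders give an ellipse clipped by a band
(closed-form area via circular-segment integrals; apparent band width
t/sin γ, where γ is the angle between the plate and the section), ellipsoids
give ellipses. Profiles are represented as intersections of implicit linear
and quadratic constraints, so point membership, line chords and
boundary-crossing counts are answered by root finding rather than polygon
approximation. Band profiles record which boundary pieces are plate *faces*
and which are rim, so intersection counting can match the surface model.

Sampling designs:

- **SUR stacks**: equally spaced parallel sections with one uniform random
  phase, spanning the scene caliper plus one extra section so every particle
  edge lies between two sections (required for disector sweeps);
- **IUR sections**: orientation uniform on the sphere (isector-style), and —
  in the validation pipelines — position uniform inside a *spherical*
  container, whose support window is orientation-independent, so position
  and orientation are jointly uniform;
- **vertical sections**: the plane contains a chosen vertical axis, rotation
  about it uniform on [0, π), the in-plane frame oriented so the vertical is
  a coordinate axis (cycloid arcs need it).

Imaging depth is modelled as full-opacity projection over [o, o + h_img) and
blindness below: the simplest model of surface-sensitive SEM imaging. It
reproduces overprojection (projected sphere area exceeds the mean plane
section, checked against numeric integration) and supports a lost-caps
threshold ε below which profiles are dropped (default 0 in analytic mode,
2 pixels in raster mode). Ministack projection tiles a fine stack into
groups of m consecutive sections and projects each group, restoring
one-section-disector behaviour when m·k matches the particle diameter.
Rasterisation samples profiles at pixel centres with
smallest-structure-wins collision resolution (deterministic, order
independent).

## Probes and counting rules

- **Point grids**: square lattice, a = d², uniform random phase.
- **Line grids**: parallel lines with associated points every d along them
  (l_p = d); on IUR sections the in-plane rotation is also randomised.
- **Cycloid arrays**: half-arches x(θ) = r(θ − sin θ), y(θ) = r(1 − cos θ),
  θ ∈ [0, π], minor axis along the vertical; exact arc length 4r = l_p, one
  associated point per arc; cells πr × 4r, alternate columns mirrored within
  their cell. The length-weighted tangent density is sin(α) relative to the
  vertical, which is what makes cycloids on vertical sections equivalent to
  isotropic 3D line probes.
- **Counting frame**: Gundersen rule — select profiles intersecting the
  frame that do not touch the forbidden line (left edge with its infinite
  upward extension, bottom edge, and the downward extension below the
  bottom-right corner). The rule is validated by an exact tiling-invariance
  test and a Monte-Carlo check that the selection measure equals the frame
  area. Guard areas are mandatory for frame counting on bounded images
  (violations raise an error); whole-organelle stacks may disable the frame.
- **Disector**: Q− counts frame-selected profiles whose parent primitive
  yields no profile in the look-up section; both-direction counting is the
  default along stacks.

Tie rules are deterministic: a point exactly on a boundary does not count;
an intersection requires a strict sign change of the implicit function, so
tangencies count zero (numerically, quadratic root pairs closer than 1e-6 µm
are treated as tangent). Cycloid crossings are counted by sign changes along
a dense polyline (default 96 vertices per arc, segment length ≪ the thinnest
structure).

Point-sampled intercepts record one intercept per *transversal pass* of a
test line across a profile trace (half the boundary-crossing count), which
samples profiles proportional to trace length — the weighting the star-area
identity requires. The intercept length l₀ is the exact mid-plane chord in
analytic mode, or (π/2)·I·d from an independently randomised re-probing grid
otherwise.

## Estimators

All ratio estimates pool numerators and denominators over images (ratio of
sums), with the classical Cochran ratio SE
`SE(R) = sqrt(Σ(yᵢ − Rxᵢ)²/(n−1)) · √n / Σx`. Normal-theory intervals from
it run slightly anticonservative below ~15 images (simulated coverage ≈ 94%
at n = 20 for Poisson counts).

Derived constants, each verified by simulation in the test suite:

- arithmetic thickness factor π/4: on hit-weighted IUR sections the apparent
  width of a plate is t/sin γ with orientation density ∝ sin²γ, giving
  E[w] = 4t/π (the finite plate adds a relative O(t/2R) term, ~0.7% at the
  default geometry);
- harmonic thickness factor 8/(3π): E[1/w] = 8/(3πt) under the same law;
- star area constant π/3: for length-weighted planar chords,
  ∫l³ dG = 3A² and ∫l dG = πA, so (π/3)·E_w[l²] = A for convex profiles;
- Buffon length factor π/2: a curve of length B is crossed 2B/(πd) times on
  average by an isotropic grid of spacing d.

The local vertical window (LVW) estimator selects stack profiles whose
apparent width is within (1 + τ) of the thinnest observed width (τ = 0.25
default), treats the in-plane stack axis as a local cis–trans vertical, and
applies cycloids. Because the section is only *approximately* vertical with
respect to the plate over the selection band, the estimate carries a small
known negative bias of factor E[sin γ | selected] (≈ 6% at τ = 0.25,
≈ 3% at τ = 0.1); the estimate reports its τ-sensitivity alongside the
value. Its practical virtue — validated in the test suite — is stability: on
multi-stack phantoms the per-image intersection/point ratio of straight IUR
lines varies with section obliquity, while LVW uses only near-orthogonal
profiles, so a 12-image LVW series reaches a lower ratio-CV than a 20-image
straight-line series.

The one-section-disector workup sweeps adjacent pairs and reports the
fraction of selected profiles that disappear. For ideal sections spaced h
through particles of diameter d that fraction is min(h/d, 1), so the
canonical 60 nm vesicle / 50 nm section regime sits at 5/6; the default
applicability threshold is therefore 0.80 ("a large majority"), adjustable
per study. When the imaging depth is below the physical thickness the
verdict flags the waist-loss risk; very thin sections (e.g. 5 nm) leave the
same waist visible in many sections, drive the fraction toward h/d ≪ 1, and
trigger a recommendation to use ministack projection.

## Validation pipelines and problem sizes

`stereovem.validation` re-runs full pipelines at the scales used by the
`validate` CLI, the test suite and `scripts/acceptance.py`. Choices of
problem size balance Monte-Carlo error against the precision claimed:

- vesicle counting design: 1000 spheres (d = 60 nm) in 5 µm, 20 nm
  sections, pairs every 50 sections, both directions, 500 seeds (SE of the
  mean total Q− ≈ 0.25 counts against an expectation of ~40);
- Cavalieri CE: 2 × 1.5 × 1 µm ellipsoid, 8 sections, 1000 placements,
  exact profile areas (CE ≈ 0.7%, far below the ~5% working rule for 5–8
  sections);
- estimator constants: 10⁵ hit-weighted sections (thickness factors), 8000
  grid placements (Buffon), 2·10⁴ IUR sections (t·Sv), 1.6·10⁴ sections
  (two-cisterna hit ratio, expectation 1.99 for t/R = 0.04);
- unbiasedness suite: 400–4000 replicates per estimator, each asserted
  within 2 Cochran/Monte-Carlo SEs of ground truth.

The mean-reference-volume pipeline samples one uniformly placed cell per
low-magnification field (a dilute population). This keeps the reference
point process stationary across the counting frame's selection region; a
dense hard-core pattern in a bounded box is *not* stationary (boundary
attraction depletes the centre), which biases the narrow area kernel of P
more than the broad selection kernel of Q− and therefore the ratio — an
instructive artefact of the phantom, not of the estimator.

## What the phantoms do and do not show

The generator produces geometric idealisations: perfect discs, spheres and
cylinders, no fenestrations, no ribbon twist, no membrane texture, no
imaging noise, and identification is perfect (profiles carry their parent
identity). Passing tests therefore demonstrate the *sampling* properties of
the estimators — unbiasedness, precision, the documented biases of naive
comparators — under exactly known geometry. They do not address
segmentation or recognition error on real micrographs, electron-optical
effects beyond the opaque-slab projection model, or biological shape
departures from the plate/sphere idealisation. The classifier criteria
(width ≤ 60 nm with a three-fold axis ratio for cisternae; near-circular
60–70 nm profiles for vesicles) are implemented as stated rules for count
sheets, not learned recognisers.

## Numerical conventions

Right-handed continuous coordinates in µm; sections indexed 0-based from the
random start; slab interval [o, o + h) half-open. Grazing plane contacts
within 1e-12 µm count as zero-area hits. Random numbers come from
numpy Generators; every public entry point takes a seed or Generator, and
derived seeds stay below 2³¹. Degenerate inputs (zero reference counts,
zero denominators, empty selections) yield flagged NaN estimates or typed
errors rather than silent zeros.

## Known limitations

- Ellipsoid surface ground truth is the Thomsen approximation (~1%).
- Slab projections of non-spherical primitives use exact membership tests
  but numeric areas and sampled crossing counts.
- The LVW estimator's τ-bias is inherent to the method's selection rule; it
  is reported, not corrected.
- No correction factors for overprojection/lost caps are applied to
  estimates (the biases are simulated and measured, and the workup warns
  when a regime is unsafe, but numeric de-biasing is out of scope).
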