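# Methods

This note documents the models, conventions and numerical choices behind
barrelforge, and what the synthetic fixtures do and do not emulate.

## Heptad registers and seed rules

Sequences carry an explicit per-residue register label from the cyclic
heptad *gabcdef*. By convention sequences start at **g** (matching
helical-wheel presentations of the barrel interface); the offset is
configurable. A seed rule assigns residues to g-a-d-e, uniformly or per
heptad; rules are named by one-letter codes in g-a-d-e order ("LLIA"), with
per-heptad rules appending heptad indices.

The default background is a stated convention, not an experimental fact:
**b**/**c** carry the "bar-magnet" charge pattern (Glu in the N-terminal
half of the heptads, Lys in the C-terminal half, electrostatically favouring
antiparallel neighbour pairing) and **f** cycles through Gln-Lys-Trp-Lys
with exactly one Trp kept per chain as a chromophore (later Trp occurrences
in the cycle are replaced by Lys). Note the Trp and the unpaired Lys make
the full default background carry a net charge of +2; the bar-magnet b/c
blocks alone are charge-balanced by construction. Both pattern and cycle
are overridable through `BackgroundSpec`.

`pairwise_identity` is deliberately gapless (designed families share a fixed
scaffold length); unequal lengths are an error rather than an alignment.

## Backbone geometry

Superposition is classic Kabsch (proper rotations only, via
`scipy.spatial.transform.Rotation.align_vectors`); degenerate inputs (< 3
points, collinear sets) raise. `backbone_rmsd` defaults to the atom set
{N, CA, C, O}; published backbone-RMSD values rarely state their atom set,
so it is configurable. For crystal-vs-model comparisons the
"middle helical turns" mapping pairs helices in order and matches the
central k residues (default 7 ≈ two turns) outward from helix midpoints —
the definition is a package convention because no numeric one is standard.

Helix detection flags residue windows whose CA(i)→CA(i+4) distance lies in
4.8–6.8 Å with bonded-scale consecutive CA spacings, keeping maximal runs of
≥ 7 residues. Axes are least-squares lines through sliding 4-residue CA
centroids (the window cancels the ~3.5–3.6 residue/turn wobble), directed
N→C.

`fit_cn_axis` initialises from the principal component of the backbone
coordinates (barrel helices run along the symmetry axis) and refines four
parameters (two direction, two offset) by Nelder–Mead on the copy-to-copy
RMSD under a 2π/n rotation with nearest-chain reassignment. On ideal
fixtures the initialisation is already exact. For alternating up/down
barrels the true rotational symmetry is C(n/2); callers pass that order.

## Knobs-into-holes

A residue is a knob when its side-chain center lies within the packing
cutoff (default 7.0 Å; 7.5 Å supported as the common looser variant) of at
least four side-chain centers on a single other helix; the four nearest form
its hole. Side-chain centers are centroids of side-chain heavy atoms; Gly
falls back to CA, and backbone-only models must reconstruct CB first (proxy
mode). Register typing (a- vs d-knob) uses the model's register annotation
when present, otherwise the 3/4-residue spacing signature of knobs along
their own helix (a→d is +3, d→a +4); isolated knobs that cannot be typed
stay "unknown". A helix-pair interface requires reciprocated packing: ≥ 2
knobs with ≥ 1 in each direction. The barrel cycle is the longest simple
cycle in the interface graph (ties broken lexicographically); orientations
come from helix-axis dot products.

Lumen profiling measures, at ~1 Å axial stations over the central 90% of the
structure, the largest circle centered on the axis clear of all
van-der-Waals-inflated atoms (Bondi radii). Openness thresholds are exposed
in two flavours: 2.8 Å (a water-sized channel, the default) and 4.5 Å
(large enough for the DPH reporter dye). Neither threshold is an
experimental constant; both are package conventions.

## Connector search, grafting and scaffold assembly

The fragment search is a deliberately small, exact emulation of
tertiary-motif matching: query stubs (default 5-residue backbone windows cut
from the C-terminal end of helix i and the N-terminal start of helix j) are
jointly superposed — one rigid fit over both windows — onto every window
pair of every library entry with intervening separation ≤ max loop length
(search range 0–7 residues; antiparallel targets realistically use 2–7).
Hits below the RMSD cutoff (1.0 Å for short loops, 1.5 Å for three-helix
units) are sorted by RMSD with a stable (source id, position) tie-break.
No sequence scoring, gap penalties or indexing heuristics are applied, which
keeps the implementation provably identical to exhaustive enumeration (the
test suite checks this against an independent brute-force oracle).

Grafting transforms the hit's loop by its alignment, splices it between the
two chains, renumbers contiguously and reports every junction C–N distance;
junctions outside 1.2–1.45 Å are flagged unreconciled, and any loop backbone
atom within 2.0 Å of a non-adjacent atom aborts with a clash listing.

Parallel scaffolds exploit Cn symmetry: a single-chain
helix-turn-helix-turn-helix unit (buttressing-down, central-up,
buttressing-down), with its central helix pre-aligned on one inner barrel
helix, is replicated about the fitted axis. The trailing buttressing helix
of copy k coincides with the leading one of copy k+1; their overlap RMSD is
the symmetry-fit check (error above tolerance) and overlapping coordinates
are averaged. Threading inner→buttressing→inner and dropping the redundant
outer helix at the seam yields n inner + (n−1) buttressing = 2n−1 helices
(13 for n = 7). Unit handedness follows barrel order: left-handed for n = 5
(low-order coiled coils supercoil strongly left-handed), right-handed for
n = 6–8.

## The design loop

External sequence designers and structure predictors are pluggable
interfaces; deterministic mocks ship with the package so the loop is fully
testable offline. What the package owns: constraints (fixed positions are
byte-identical in every candidate — the seed-rule interface sites that
define the open state; biased positions sample preference weights; surface
b/c/f positions are tracked for filtering), the filters (surface
hydrophobic fraction over b/c/f with the hydrophobic set {A,V,L,I,M,F,W,Y,C};
net charge (K+R)−(D+E); an energy threshold; and a greedy < 85% identity
diversity rule, deterministic in candidate order), and convergence: each
round's backbone RMSD between the designer's input template and the
predictor's output must fall below tolerance (default 0.5 Å) with the
round-to-round energy change below 1% relative; the final pick is the
highest-confidence converged model, and exhausting max_rounds (default 10,
batch 100) returns `converged=False`.

The bundled energy is a transparent proxy: minus the sum over CB–CB pairs
within 8 Å (sequence separation ≥ 3) of the product of positive
Kyte–Doolittle hydropathies, rewarding buried hydrophobic contacts. It
ranks candidates and monitors convergence; any external scoring function can
be substituted through the same thresholds.

## Biophysics

MRE = θ·10⁶/(c·l·n) with θ in mdeg, c in µM, l in mm and n the number of
amide bonds — exact formula evaluation, vectorised.

Binding titrations (constant ligand c, varied binder x, fluorescence y) are
fitted to the single-site quadratic tight-binding isotherm
y = B·[(c+x+K_d) − √((c+x+K_d)² − 4cx)]/(2c). The "−" root is the physical
branch: it is the exact mass-action solution bounded by B and saturating as
x → ∞, whereas the "+" root diverges and exceeds B, so it cannot describe
saturating data (published forms of this equation sometimes print the "+"
sign; the package implements the bounded branch and documents the choice).
Fitting is bounded nonlinear least squares (K_d, B > 0) initialised at
K_d⁰ = median nonzero x and B⁰ = max y, retried from 0.1× and 10× scaled
starts on non-convergence; standard errors come from the covariance.
Replicates (quadruplicate pipetting) are fitted jointly, never averaged.
Thermal CD ramps (5–95 °C at 222 nm) are stored and plotted only: the
designed proteins show no cooperative transition, so fitting a melting model
would manufacture a parameter with no support in the data.

## Synthetic fixtures

Fixtures are built from ideal internal coordinates by sequential NeRF
placement (bonds N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; trans ω;
O placed anti to the next N; CB at the L-configuration improper of +122.6°),
so every fixture passes the peptide-bond validity check by construction.
A pseudo side-chain tip atom extends each CB so the per-residue side-chain
centroid sits at its residue-typical distance from CA, making CB-proxy
packing densities comparable to all-atom models.

Helices are straight: the superhelical twist of real coiled coils is
absorbed by solving the per-residue twist to exactly 3.5 residues/turn
(102.857°) at 1.51 Å rise, which keeps the heptad seam in phase along the
helix. Because twist and rise are strongly coupled at fixed bond angles,
the N–CA–C angle is allowed to relax (solved value ≈ 108.3°, within the
observed protein range) alongside φ/ψ. Helices stand on a circle of radius
R0 (7.0/8.5/9.5/11.0 Å for n = 5/6/7/8; smaller canonical values for
n = 2–4), spun so the a/d seam faces the lumen with a 25° offset — the
analogue of the coiled-coil packing angle — so side chains interdigitate
knobs-into-holes instead of colliding tip-to-tip. "Down" helices are
flipped through a rotation of π about a radial axis, so alternating
orientation lists give antiparallel barrels; all-parallel barrels are
exactly Cn-symmetric.

Loops and turns are closed by least squares over their free torsions (ψ of
the anchor residue, φ/ψ per loop residue, φ of the landing residue) so the
implied next residue lands on the target helix start; multi-start with
seeded random initialisations, acceptance at < 0.15 Å coordinate error, and
an optional soft clearance penalty (2.7 Å) that steers bridge loops away
from the rest of the structure. Three-residue loops are underdetermined
(8 parameters vs 9 constraints) and may not close exactly; bridges use ≥ 4.

What the fixtures do **not** emulate: true Crick supercoiling (helices do
not wind around the axis), side-chain rotamers and packing beyond the
centroid proxy, C-terminal fraying, sequence-dependent helix propensity,
and crystallographic detail of any deposited structure. Tests passing on
fixtures therefore validate the algorithms' logic, symmetry handling and
bookkeeping — not their numerical agreement with any particular
experimental structure, which requires the deposited files.

## Problem sizes and determinism

The test suite and the acceptance script run on 4-heptad (28-residue)
helices, 5-entry fragment libraries, 13-point titrations in quadruplicate
and a 500-replicate noise-calibration run — sizes chosen so the full
pipeline (fixture generation through analysis) completes in well under a
minute per component on one core while still exercising every code path.
All stochastic steps (fixture noise, loop-closure starts, mock engines,
titration noise) are driven by explicit integer seeds; identical seeds give
bit-identical outputs.

## Known limitations

- The KIH register typing degrades to "unknown" for isolated knobs on
  unannotated models; a full Crick-phase assignment is not implemented.
- `fit_cn_axis` assumes the symmetry axis is the dominant principal axis;
  extremely short, wide assemblies could defeat the initialisation.
- The left-handed connector unit is the mirror image of the right-handed
  one, which flips backbone chirality at the fixture level; it emulates the
  opposite tertiary twist, not a real left-handed protein backbone.
- The energy proxy is intentionally simple and is not calibrated against
  any physical energy function.
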