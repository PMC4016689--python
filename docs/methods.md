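# Methods

This note documents the models, sampling designs, numerical conventions and
design choices behind `stereovol`, and what the phantom-based validation
does and does not demonstrate.

## The tissue phantom

A phantom is an axis-aligned box (µm) containing `n` convex cells —
spheres by default, axis-aligned triaxial ellipsoids optionally.  Somal
volumes are log-normal with configurable mean and CV; equivalent radii
follow with `σ_r = σ_v / 3`.  Each cell carries a nucleolus, centred by
default or displaced by a uniform random eccentricity fraction along a
uniform random direction (nucleator bias under eccentricity is a property
we need to probe).  Ground truth (layer volume, cell count, mean somal
volume, the full size distribution) is recorded exactly and re-derivable
from the cell table.

Three deliberate idealizations:

- **Lateral periodicity.**  The x and y boundaries wrap, so the box behaves
  like a field deep inside a much larger layer.  Counting-frame tilings
  then partition profiles exactly (no edge losses), which is what makes the
  disector's unbiasedness testable to fractions of a percent.
- **Axial containment.**  Cells lie fully inside the layer along the
  sectioning axis z — a somal layer by definition contains its somata.
  Every cell's slab span therefore stays inside the exhaustively cut
  series.
- **Full slabs.**  Default region extents are integer multiples of the
  section thickness, so the serial slabs tile the layer without a partial
  final slab and the constant-footprint Cavalieri sum is exact in
  expectation.

Packing uses sequential random insertion.  Cells may touch or
interpenetrate (somata in a pyramidal layer are densely apposed), but a
candidate is rejected if an existing cell would contain its nucleolus or
vice versa, or if it violates an optional minimum centre spacing; an
explicit packing error is raised when insertion stalls.

The two-group study generator draws per-animal phantoms around group
parameter means with a log-normal between-animal CV (default 0.08, the
scale of the between-animal CVs a study of this kind reports).  Cell count
covaries with layer volume so the treated condition is "smaller cells in a
smaller layer, unchanged number" — the structure the pipeline is meant to
resolve.

## Virtual sectioning

Serial ("coronal") sections are slabs of thickness t = 2 µm along z; slab
`i` covers the half-open `[i·t, (i+1)·t)` so boundaries are attributed
once.  A cell *appears* in every slab its body intersects with positive
measure; its profile geometry is evaluated at the slab mid-plane (a
semi-thin section is a plane for area measurement but a slab of height
h = t for the disector; both views are exposed).  A cell with caliper
extent below t appears in one or two slabs; in general in
`ceil(extent/t) ± 1` consecutive slabs depending on phase.

Consecutive section pairs are sampled systematically with a uniform random
start in the first `period` sections (default period 200 at full scale;
2600 sections at period 200 give 13 pairs, 2700 give 13–14, the classic
13–15-pair regime).  The series is exhaustive, so the look-up partner of
the final section is the empty plane past the block.  For the disector the
systematic lattice is extended one step below the block (`leading pair`),
which gives both counting directions exactly 1/period coverage of every
slab; reference planes outside the block contribute neither counts nor
examined area.

Vertical sections: the phantom is split into bars along x; each bar
receives an independent uniform azimuth in [0, π) about the fixed vertical
(z) axis and is cut serially along the rotated normal with a uniform
random phase.  The in-plane direction of the vertical axis is recorded per
section.

## Estimators

**Cavalieri.**  `V = t_eff · ΣP · a(p)` with `t_eff = period × t` the
distance between sampled sections and `a(p) = (screen spacing /
magnification)²` (10 mm at ×96 → 0.01085 ≈ 0.011 mm²).  Test points are a
square grid with offset uniform in one grid cell *in the grid's own frame*
(with rotation enabled, an axis-aligned offset square is not a fundamental
domain of the rotated lattice and would bias the count).  Boundary
tie-break, stated bit-exactly: a grid point counts iff the point displaced
by `+δ` in x and y, `δ = 1e-9 × spacing`, lies strictly inside the region —
for axis-aligned edges this includes lower/left edges and excludes
upper/right ones; for random offsets boundary hits have probability zero.
No shrinkage correction is applied to Cavalieri volumes (plastic-embedded
semi-thin material; area shrinkage treated as negligible), mirroring the
asymmetric treatment of the two arms.

**Disector.**  The unbiased counting frame has admission top/right edges
and forbidden left/bottom edges whose extensions run upward from the
top-left corner and downward from the bottom-right corner; a profile is
selected iff it intersects the frame and touches no forbidden line.
Tiling a plane with such frames selects every profile exactly once (tested
directly).  Q⁻ counts frame-selected reference profiles whose cell is
absent from the look-up section; profile identity is resolved by cell id
(the phantom knows it; imported real data would need centroid matching).
Both directions of each pair are used by default, doubling efficiency.
`Nv = ΣQ⁻ / Σ(a·h)` with `h = t` for physical disectors on consecutive
sections, and `N = Nv × V(ref)`, reported in 10⁶ with 3 decimals at
printed-table scale.

**Nucleator.**  Cells are sampled number-weighted on the vertical sections
with the nucleolus as counting unit: a cell is measured when its nucleolus
falls in a systematically sampled slab (each nucleolus lies in exactly one
slab, so every cell has probability 1/period regardless of size).  Rays
are measured in the vertical plane through the nucleolus; the in-plane
angle α to the vertical axis is sine-weighted (`α = arccos(1 − 2u)`),
which together with the uniform azimuth makes ray directions uniform on
the sphere — the condition for `E[(4π/3)·l³] = v` for star-shaped cells.
Rays come in antipodal pairs (default one pair per cell).  For spheres
with centred nucleoli the estimate is exact per cell; replacing the sine
weighting with uniform in-plane angles (`weighting="uniform"`) is a
deliberately biased negative control that overestimates cells elongated
along the vertical axis by tens of percent.

**Shrinkage.**  The glycolmethacrylate arm shrinks volumetrically by
`s = 1 − after/before` (fresh volume from weight × 1.04 cm³/g); the
simulation scales measured ray lengths by `(1 − s)^(1/3)` and the
correction divides per-cell volumes by `(1 − s)` before aggregation
(default s = 0.15).  Swelling (negative s) warns rather than errors.

**Precision.**  The Gundersen–Jensen (1987) m = 1 estimator for systematic
designs: with `A = ΣPᵢ²`, `B = ΣPᵢPᵢ₊₁`, `C = ΣPᵢPᵢ₊₂`,

    noise = 0.0724 · (b/√a) · sqrt(n · ΣP)
    CE    = sqrt((3(A − noise) − 4B + C)/240 + noise) / ΣP

with the profile shape factor `b/√a` defaulting to the circular value
2√π.  Note the truncated covariance sums leave an end effect: a constant
sequence yields `2p²/240`, i.e. CE ≈ 0.091/n rather than exactly zero.
Both terms are exposed separately (`include_noise=False`).

**Statistics.**  Group summaries are mean and CV = SD/mean (sample SD,
n−1).  The default comparison is the classical pooled-variance two-tailed
Student t-test ("independent samples t-test" in the source literature is
read as pooled); Welch is a flag.  `t_test_from_summary` reconstructs SDs
as mean × CV for parity checks against published summary tables.  A
degenerate comparison (zero variance in both groups, equal means) returns
t = 0, p = 1 by convention.  No multiple-testing correction is applied —
a faithful-reproduction choice, not an endorsement.  Size distributions
are compared on common fixed-width bins (default ≥10 bins over the
observed range) with per-animal SEM; single-animal groups carry NaN SEM.

## Default study design (scaled)

A full-scale hippocampal layer (~2 mm³, ~2×10⁵ neurons per subfield) is
needlessly expensive to replicate hundreds of times, so the default phantom
is a scaled layer that preserves every design-relevant regime:
500 cells in a 240 × 120 × 200 µm box (density 87×10³/mm³, the measured
pyramidal-layer scale), mean somal volume 3588 µm³ with CV 0.25,
t = 2 µm sections, period 7 → 13–15 pairs, grid spacing 35 µm → ~300 test
points, 60 × 60 µm frames tiled over the footprint → ΣQ⁻ ≈ 140 (inside
the 100–200 target), vertical arm sampled to ~100 measured cells per
animal, shrinkage 0.15 applied and corrected.  The design-check
diagnostics flag any animal outside those targets.  A further-reduced
configuration (`StudyConfig.reduced()`: ~90 cells per animal) exists for
replication-heavy calibrations such as the 1000-study type-I-error check;
it keeps the ~100-cells-per-animal nucleator regime, at 8 animals per
group.

Seeding is hierarchical (`numpy.random.SeedSequence`): master seed →
study → animal → stage, so runs are bit-reproducible and adding animals
to one group cannot perturb the other.

## What the validation shows — and does not

The test suite demonstrates, on phantoms: exact ground-truth bookkeeping;
unbiasedness of Cavalieri, disector (Nv and N) and nucleator estimates
over replicated designs (3 Monte-Carlo-SE criteria at ≥200 replicates);
exactness of the nucleator for centred-nucleolus spheres; the shrinkage
round-trip; calibration of the null t-test (≈5% rejections over 1000
simulated studies); and the printed-table arithmetic identities
(N = Nv × V, the point-area value, the reconstructed p-value of the
layer-volume comparison).

What passing these tests does *not* show: the phantom has no staining or
optical artefacts, no section compression, chatter or lost sections, no
anatomical delineation problem (regions arrive as polygons), cells are
spheres/ellipsoids rather than pyramidal somata with processes, and
profile matching across sections is by construction error-free.  Real
histology adds all of those error sources on top of the sampling variance
modelled here.

## Known limitations

- The phantom region is a box; curved laminae are not modelled.
- Ellipsoids are axis-aligned (sufficient to stress the vertical design's
  anisotropy handling, but no arbitrary orientations).
- For ellipsoid cells the mid-plane profile table uses the parallel-cut
  area scaling without the in-plane centre shear of oblique cuts; this is
  exact for spheres and for serial sections of axis-aligned ellipsoids
  (the default disector path) but approximate for frame selection on
  vertical sections of ellipsoids, where the default design uses no frame
  restriction.
- The Cavalieri and disector estimates of one animal share sampled
  sections, so `N = Nv × V` multiplies correlated factors, exactly as in
  the laboratory procedure; the replicate-design tests bound the resulting
  bias below the Monte-Carlo resolution.
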