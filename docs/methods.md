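# Methods

## Chip geometries

Both chip families are collections of non-overlapping cylindrical grains
(disks in plan view) in a rectangular channel, L = 990 mm × W = 3 mm ×
H = 50 µm by default, at target areal porosity n = 0.5. Coordinates are
continuous microns, origin at the inlet-side top-left corner, x along the
flow; rasters are row-major with pixel-centre point sampling and no
anti-aliasing, so any mask is bit-reproducible.

**Homogeneous lattice.** Only the pore throat λ (nearest-neighbour surface
gap) and porosity are specified, so pitch p and grain diameter d are solved
from n = 1 − πd²/(4p²) and p − d = λ. For λ = 50 µm, n = 0.5 this gives
d = 197.4 µm, p = 247.4 µm. A square lattice is used (the plainest "regular
lattice" consistent with a single throat value). The unit-cell porosity
equals the target exactly; the channel-averaged value differs by ≲1.5%
because the lattice is centred and the edge margins are pore. Feasibility
requires n > 1 − π/4 ≈ 0.215, otherwise the solved gap would be negative
and a parameter error is raised.

**Heterogeneous packing.** Random sequential addition with an anchor rule:
each new grain is placed at a drawn surface gap from a randomly chosen
existing grain and accepted only if it stays fully inside the channel and
keeps at least max(λ_min, 0.8 × drawn gap) of clearance to every grain;
placement stops at the target porosity, with an error (reporting the
achieved porosity) if 10⁶ attempts do not get there. Two calibration facts
shape the defaults: at fixed porosity the mean nearest-neighbour gap scales
with grain radius (≈0.24 r at n = 0.5), which ties the log-normal radius
median to the target mean gap (300 µm median for a 70 µm mean gap); and a
Gamma(3, ·) gap draw keeps the drawn-gap mode away from λ_min so realised
gaps are not piled at the minimum. With the default envelope
(λ ∈ [25, 350] µm, mean 70 µm) the generated designs land at porosity
0.50 ± 0.005 with per-grain nearest gaps of mean ≈ 70 µm and min ≥ 25 µm.

**Throat statistics.** "Nearest-neighbour surface gap" is evaluated
per grain: the minimum of (centre distance − r_i − r_j) over that grain's
Delaunay neighbours (all pairs for < 4 grains). Pooling *all* Delaunay
edges would be wrong for the square lattice, whose triangulation includes
diagonal edges with gaps ≫ λ; the per-grain minimum recovers exactly λ for
every lattice grain.

**Pore volume.** (area − grain area) × H, in µL. From a design the grain
area is analytic; from a mask it is the foreground pixel area, which is
also the default for the per-position PV_l used in the efficiency formula
(the mask-based value reflects what the image actually shows).

## Synthetic scenes and rendering

The generator's defaults are the study conditions, not tuning knobs:

| parameter | default | basis |
|---|---|---|
| bacterial concentration | 1×10⁸ cells/mL | observed initial range ~0.8–1.03×10⁸ |
| rod length / width | U[2, 4] µm / 1 µm | assumed cell size 4 × 1 µm |
| nucleation onset / stop | 1 h / 4 h | nucleation starts 1 h after CS injection; most growth in first 4–5 h |
| nucleation rate | 2×10⁻³ per cell per h | free parameter, set for realistic counts (~60–300 per full position) |
| final diameter | N(30, 6²) clipped [10, 60] µm | observed 17–46 µm envelope |
| growth law | logistic, ~80% at +3 h, saturated by +11 h | growth essentially complete 12 h after injection start |
| noise σ / illumination ramp | 0.02 / 5% | exercises the residual-outline failure mode |

Nucleation is Poisson with intensity proportional to the number of settled
cells (cells act as nucleation sites); sites split evenly between grain
perimeters — the centre offset from the grain surface equals the final
radius, so a full-grown crystal is tangent to its pillar, matching crystals
that grow from the surface into the pore — and the pore floor. Crystals are
ellipses with aspect U[0.8, 1]; overlapping crystals merge into a single
aggregate whose axes come from the area-weighted union second moments
(rescaled to conserve area) and which continues on the earliest member's
growth curve. Total crystal area is therefore non-decreasing in time.

Rendering paints per-phase intensity levels (brightfield: background 0.90,
grain/crystal outlines 0.20, interiors 0.75/0.60, bacteria 0.87; phase
contrast: background 0.10, bacteria 0.30, grain outline 0.55, crystal
0.80), then applies a multiplicative linear illumination ramp and additive
Gaussian noise. Outlines are drawn as a 1.2 µm annulus *inside* the true
boundary so that filling a detected outline reproduces the ground-truth
shape. What the generator does **not** emulate: optical physics (defocus,
diffraction halos), reactive-transport gradients of calcium along the chip,
bacterial motility/growth between frames, and 3D crystal shape — passing
tests therefore demonstrate the correctness of the measurement chain on
geometrically faithful images, not robustness to every optical artifact of
a real microscope.

## Segmentation

The sensitivity semantics of the adaptive threshold are defined here (the
original platform's are proprietary): foreground iff I < m·(0.5 + s) (dark)
or I > m·(1.5 − s) (bright), with m the mean over a square window of
2⌊min(H, W)/16⌋ + 1 pixels (the common default for local thresholding).
Both polarities make the foreground monotone in s, the property the
workflow's tuning relies on.

* **Grains** (brightfield, t = 0, s = 0.45): binarize dark → keep
  components in the grain-outline area range (≥1000 px by default; this
  removes bacteria and noise) → fill holes. Filling reflects the mask
  across the field border so pillars cut by the field edge fill too.
* **Bacteria** (phase contrast, s ∈ [0.1, 0.2]): binarize *bright* —
  the modality has bright bacteria on a dark background, so polarity
  follows the optics — blank grain pixels, keep components of 10–900 px²
  (treated as pixel counts; at 0.29 µm/px a 4 µm² rod is ≈48 px).
* **Crystals** (brightfield, t > 0, s ∈ [0.4, 0.5]): binarize dark →
  remove speckles < 8 px (otherwise closing welds noise into crystal-sized
  blobs) → morphological closing (disk, r = 2 px) → border-aware hole fill
  → subtract the grain mask dilated by the closing radius → drop components
  smaller than 900 px (bacteria that leak through the binarization; genuine
  crystals at ≥17 µm are ≥2700 px) or with isoperimetric circularity
  4πA/P² < 0.25. The circularity rule is this package's cleanup for
  residual pillar-outline arcs left by illumination drift: a thin arc of
  width w and length ℓ has circularity ≈ πw/ℓ → 0, while compact crystals
  and aggregates sit well above 0.25. (A width-over-closing-radius ratio
  was considered and rejected: at practical widths it removes nothing.)
* **Phase map**: grain(3) > crystal(2) > bacteria(1) > pore(0); the labels
  partition the raster by construction.

## Quantities

Masks convert to physical quantities exactly as the measurement definitions
state, including their known biases: the sphere volume from
D = (minor+major)/2 is applied to aggregates as well as single crystals
(documented bias — merged aggregates are not spheres, and bridged
near-neighbours inflate D³); bacterial concentration uses the full 50 µm
chip depth for pore volume. Efficiencies above 100% are reported with a
warning, not clipped — they are possible under pore-volume apportionment
when precipitation concentrates locally. Replicate aggregation reports the
mean and the mean absolute deviation.

On noisy synthetic runs (3 replicates × 5 positions, 0.7 × 0.5 mm fields)
the chain recovers grain masks at IoU ≥ 0.98 (typically 1.000), bacterial
coverage within ±1%, exact crystal counts for populations whose pairwise
surface gaps exceed the closing diameter, and per-position mass within a
few percent of the mask-derived ground truth. Field sizes in the test suite
are scaled down from the instrument's 2.57 × 3.87 mm stitched fields; all
densities, sizes and noise levels are kept.

## Hydraulics

Pressure differences (sensor mbar → Pa) are Savitzky–Golay smoothed
(window 51, order 3 by default; neither was specified by the source
workflow) within each imposed-flow phase — phase boundaries come from the
injection schedule, not from the data — and Darcy's law is applied per
sample. The channel length L enters as the full 990 mm even though the
sensors sit inboard of the ends, matching how the headline permeabilities
are computed; an effective-length override is exposed. Smoothing precedes
the permeability evaluation (the order the workflow describes). The
reduction is 100·(k₀ − k)/k₀ against the first flow-phase sample.

## Numerical and degenerate-input choices

Binarization windows must be odd and no larger than the image; fields must
lie inside the channel; p₁ ≤ p₂ (no-flow or reversed gradient) is an error
for the scalar permeability and yields no sample in the trace; empty
crystal masks give empty record lists and zero mass; a grain-free field
with positive bacterial concentration is an error. All randomness flows
from `numpy.random.SeedSequence`, with per-(replicate, position) streams
derived from the run seed, so every output of `run_pipeline` is
bit-identical under a fixed seed.

## Known limitations

* 2D plan-view masks with a sphere-volume assumption cannot capture true
  3D crystal habit; the bias is inherited from the measurement definition.
* Grains only partially visible at a field border are recovered by the
  reflective fill, but crystals straddling the border are measured at their
  visible area only.
* Watershed splitting of touching crystals and frame-to-frame identity
  tracking are out of scope; touching crystals are measured as aggregates.
* The heterogeneous generator targets gap statistics, not any particular
  commercial chip layout.
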