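# Methods

## Model and assumptions

The package implements the fTMR transit-dosimetry formalism for a single
photon energy on homogeneous slab phantoms.

**Commissioning.** fTMR(field, thickness, gap) cells are ratios of paired
ion-chamber doses at depth D_max with/without the absorber; duplicates are
averaged (arithmetic mean, warning when the spread exceeds 1 %). Conversion
factors follow

FC = D_TPS / (D_calib · CU) · (SID/SAD)² · fTMR(t) / TMR(d_iso)

per (field, thickness) cell, normalized so the reference cell
(10 × 10 cm², smallest commissioning thickness, 5 cm by default) equals 1;
the raw Gy-per-CU figure of that cell is kept as the table's `scale` so no
information is lost. An iterative correction then multiplies each cell by
D_TPS/D_recon for its setup until the maximum per-cell relative change
falls below 1e-4 (cap: 50 iterations; exceeded → error carrying the
residuals). Because reconstruction at a grid node is linear in that node's
FC value, the correction converges in one step on node setups and is
idempotent at its fixed point; a global scaling of all TPS doses is
absorbed exactly into `scale`.

**Reconstruction.** Per beam and POI: the CU at the POI's imager projection
(transverse offset magnified by SID/axial distance; bilinear sampling via
`scipy.ndimage.map_coordinates`; 1 × 1 images are scalar central readings)
is converted to imager-level dose CU · D_calib · FC(field, path) and
projected to the point as

D = D_epid · (SAD/SID_cal)² · (SID/SID_cal)² · (SAD/r)² · TMR(depth) / fTMR(path)

with r the source-to-point distance, depth and path the water-equivalent
entry-to-point and full-crossing lengths along the POI's ray (axis-aligned
ray/slab intersection), and SID_cal the commissioning SID recorded in the
FC table. At r = SAD and SID = SID_cal this is exactly the algebraic
inverse of the FC equation; the two extra ratios extend it to off-isocenter
points and to deliveries at a different imaging distance. The forward
equation alone does not fix the off-isocenter form; ours is the unique
choice under the round-trip contract (commission → reconstruct is the
identity on the truth model) and makes the reconstruction invariant under
SID changes, which the test suite checks at SID 140 vs 150 cm.

**Evaluation.** Local deviations 100·(D_recon − D_TPS)/D_TPS; per-POI
arithmetic mean and sample SD (n−1 denominator — the convention is our
choice); pass/fail at 5 % on the total dose, warnings at 8 % per beam;
beams below 10 % of the POI's total reference dose are excluded as
low-dose. The "total-dose deviation" (deviation of summed doses) and the
TPS-dose-weighted mean of per-beam local deviations are algebraically
identical — Σw·dev with w = D_TPS/ΣD_TPS telescopes to
(ΣD_recon − ΣD_TPS)/ΣD_TPS — so the report emits both labels with one
value. The MU-sensitivity predictor compounds delivery scaling with the
baseline systematic deviation multiplicatively:
100·(s·(1 + dev/100) − 1), e.g. a −0.6 % baseline with s = 0.95 gives
−5.57 ≈ −5.6 %.

## Tables and interpolation

Axes: equivalent square field side (Sterling 4·Area/Perimeter for
rectangles — the mapping is this package's choice, since square-field data
alone do not constrain it), absorber thickness, air gap, depth. Thickness
and depth interpolate log-linearly (attenuation is near-exponential, so an
exponential truth is interpolated *exactly*, and node queries reproduce
stored values to machine precision by construction); field size and air
gap interpolate linearly; when a query is off-node on both a log axis and a
linear axis, the log axis is reduced first. Queries up to 10 % of an axis
span beyond its range extrapolate with a logged warning, beyond that they
raise naming the axis. fTMR tables enforce: values in (0, 1], exactly 1 at
t = 0, strictly decreasing in thickness, non-decreasing in field size;
violations raise at construction/load time.

The default commissioning protocol measures one SSD_att per thickness
(phantom centered at the isocenter), so the observed air gaps do not form a
common axis across thicknesses; the derived table then collapses the gap
axis to a singleton that lookups ignore. A gap-complete record set yields a
full 3-D grid. TMR is standard beam data rather than a transit-specific
measurement, so the virtual linac supplies it directly as TPS-style
depth-dose ratios (`simulate_tmr_table`).

## Virtual linac

The truth model is deliberately minimal 6 MV-like physics chosen as a
fixture, not fitted to any machine: effective attenuation
μ_eff(f) = μ0·(1 − k·ln(f/10)) with μ0 = 0.05 cm⁻¹ and k = 0.03 (larger
fields send more phantom scatter to the imager, softening the effective
attenuation), output factor OF(f) = 1 + 0.08·ln(f/10), TMR(f, d) =
exp(−μ_eff·(d − D_max)), fTMR(f, t) = exp(−μ_eff·t), inverse-square
divergence, D_calib = 1 Gy/100 MU, D_max = 1.5 cm, SAD 100 cm, SID 150 cm.
CU images are ray-traced per pixel with a hard jaw-aperture edge. Noise is
multiplicative Gaussian on CU and chamber doses, default 0 (exact
fixtures); any noise > 0 requires a seed and is bit-reproducible.

Plan templates mirror the standard multi-beam/IMRT test-suite structures
in beam count and total MU (AP/PA 2 beams/470 MU, bands 2/200, multitarget
7/1043, prostate 7/1452, head-and-neck 9/2577, C-shape 9/1846) as open
fields at spread gantry angles on a 15 × 30 × 30 cm³ slab; per-segment MLC
modulation is deliberately not modeled — the CU at a POI's projection is
the integrated pixel value and the field size comes from the jaw aperture,
which matches the known weakness of the formalism at heavily blocked or
low-dose points. Commissioning defaults: fields {2, 4, 8, 10, 15, 20} cm,
thicknesses {5, 10, 20, 30} cm, 100 MU. Near-horizontal template beams
cross up to ~30.5 cm of slab, slightly beyond the 30 cm node — inside the
declared extrapolation margin and exact for the exponential truth.

**What passing tests show — and don't.** With zero noise and the truth
model shared between fixture generation and reference doses, the round
trip isolates the *formalism and its numerics*: table derivation,
interpolation, geometry, inverse-square bookkeeping. Near-zero deviations
therefore validate internal consistency, not clinical accuracy; real data
adds EPID panel response, couch attenuation, off-axis profiles, scatter
from air gaps, and MLC modulation, none of which the truth model contains.
The bounds used in the acceptance suite (3 % single fields, 5 % all
points, 3 % IMRT high-dose points) are the levels at which the formalism
is clinically useful; the synthetic pipeline must — and does — sit far
inside them.

## Numerical choices and degenerate inputs

- Points shallower than D_max (build-up region) are rejected, not
  extrapolated; a ray that misses the phantom gives radiological depth 0
  with a logged warning (point in air).
- POIs whose projection falls outside a beam's jaw aperture get flagged
  low-confidence rather than corrected; off-panel projections raise.
- Zero CU reconstructs zero dose; zero TPS reference doses flag the point
  as unscorable instead of dividing by zero; thresholds must be positive.
- Auto-POI sampling draws uniformly without replacement from voxels at
  ≥ 90 % of the grid maximum (a stand-in for "inside the target volume"
  when no structure set exists) with a seeded generator; requesting more
  points than qualifying voxels errors with the suggestion to lower the
  fraction.
- Problem sizes: the default dose grid is 5×5×5 voxels at 1 cm around the
  isocenter (kept ≥ D_max deep and inside every template aperture), portal
  images use a 2 mm pitch covering the aperture plus 2 cm margin; these
  sizes make the full acceptance run a ~1 s computation while leaving the
  interpolation/bilinear errors (≲0.1 %) clearly visible above floating-
  point noise.

## Known limitations

- No couch, heterogeneity, off-axis profile or wedge modeling; the couch
  is a known unresolved systematic of this class of system.
- FC is modeled as a function of field size and thickness only (no SSD_att
  axis); the air-gap dependence of fTMR is carried but unresolved by the
  default protocol.
- VMAT/arc deliveries and full 2-D/3-D dose reconstruction are out of
  scope; the DICOM-RT reader maps only the minimal tag subset and is a
  convenience, with JSON fixtures as the source of truth.
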