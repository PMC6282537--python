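# Methods

## Problem and model

Water-sensitive paper (WSP) is a yellow card coated with bromophenol blue that
stains blue where aqueous spray droplets land. Scanned cards give three
per-card metrics: **coverage** (% of card area stained), **droplet density**
(stains cm⁻²) and **liquid deposition** (µL cm⁻²). Because a droplet spreads
on the coating, the stain overstates the droplet; deposition therefore
requires a *spread-factor* model converting stain size back to droplet size
before volumes are summed.

Given a stain of area `A` (µm²), the package supports two conversions:

- **Constant power law** (DepositScan's rule): `d = SF · A^q` with defaults
  `SF = 1.06`, `q = 0.455` (d in µm). Dimensionally impure but standard; the
  exponent close to 0.5 makes `d` roughly proportional to the stain diameter.
- **Diameter-binned table** (paper-manufacturer values for water): the
  equivalent-circle stain diameter `d_s = 2·√(A/π)` is divided by a factor
  that steps with stain size — (0,100] µm → 1.7, (100,200] → 1.8,
  (200,300] → 1.9, (300,400] → 2.0, (400,500] → 2.1, (500,600] → 2.1. Bins
  are half-open at the upper bound (a 100 µm stain uses 1.7); stains above
  600 µm clamp to the 2.1 plateau because the table ends there and the factor
  has visibly flattened.

Droplet volume is the sphere `V = (π/6)·d³·10⁻⁹` µL (d in µm; 1 µL = 10⁹ µm³ —
the only unit convention that yields deposition in µL cm⁻² from µm-scale
diameters). Deposition is the volume sum over stains divided by the card area.

Residue chains onto deposition: with tank-mix active-ingredient concentration
`C` (µg µL⁻¹, default 0.18 — penconazole at 0.18 g L⁻¹), the card-derived
residue is `R = C·D` (µg cm⁻²). Leaf residues measured chemically convert to
the same basis as `R_area = R_leaf / A_leaf` with `A_leaf` the upper-surface
area (all residue is assumed to sit on the upper surface). Card-derived
residues overestimate leaf residues systematically (stain overspread, fine
droplets over-counted, possible in-leaf translocation), so an empirical
**correction factor** is calibrated as the ratio of arm means,
`CF = mean(leaf) / mean(WSP)`, and applied per data point,
`R_corrected = R · CF`. The ratio-of-means form is deliberate: the two arms
are unpaired samples of different sizes and substrates, per-pair ratios do
not exist, and the form makes the corrected WSP mean reproduce the leaf mean
exactly. `CF` is reported to 4 dp; the full-precision value is kept
internally so that the ratio-of-means identity holds to machine precision.

Cards with coverage above a threshold (default 30%) are excluded from any
volume-based analysis: at high coverage stains increasingly touch, and a
connected-component analysis that treats each component as one droplet
inflates volumes without bound. The threshold is configurable; the flag is
carried on every card record.

## Imaging and segmentation

A scan at `dpi` has pixel pitch `25400/dpi` µm (42.3̄ µm at the default
600 dpi). Synthetic cards are rasterized by the pixel-center-in-circle rule:
pixel `(x, y)` (0-based, integer centers) belongs to a stain of diameter `d`
at center `c` iff `|p − c| ≤ d/2` in pixel units. This rule is deterministic
and directly checkable by a brute-force loop, which the tests use as an
independent oracle. No sub-pixel or partial-intensity refinement is applied;
for stains only a few pixels across (e.g. 200 µm at 600 dpi is ~4.7 px) the
discretized area can deviate from `πr²` by several percent, converging below
1% by 2400 dpi for d ≥ 200 µm. The smallest stains of interest (95.5 µm,
~2.3 px) rasterize to 1–5 px — at the honest floor of what 600 dpi supports.

Segmentation binarizes with Otsu's between-class-variance threshold
(parameter-free and adequate for the strongly bimodal WSP histogram; a
uniform image falls back to a fixed threshold with a warning), takes stains
as the darker class, labels connected components (8-connectivity by default)
and drops components below `min_pixels` (default 1: the claimed 17 µm
detection floor of DepositScan is sub-pixel at 600 dpi, so any filtering
stronger than one pixel would be arbitrary). Two stains that touch at a
tangent point merge into one component — reproducing, on purpose, the
DepositScan assumption that touching stains are a single deposit. Under the
constant power law, merging two equal-area stains inflates their summed
volume by exactly `2^(3q−1) − 1 = 2^0.365 − 1 ≈ 28.8%`, which the touching
experiment verifies analytically and reproduces with positive sign on
rasterized pairs at every diameter.

## Synthetic data: what it emulates, what it does not

The generators produce (i) single circular stains of specified diameter,
(ii) tangent/separated equal pairs (tangent pairs place centers exactly one
diameter apart; separated pairs keep ≥ 2 pixel pitches of background),
(iii) field-like cards with non-overlapping stains placed uniformly at
random (seeded, largest-first, with a retry budget) with per-stain
ground-truth pixel counts, and (iv) diameter samplers: log-uniform over
[95.5, 1438] µm standing in for the unpublished 33-stain artificial set
whose printed range that is, and a truncated lognormal (median 134 µm,
σ_log 0.678, truncated to [52.8, 1438] µm) calibrated so that ~33% of
droplets are ≤ 100 µm and ~72% < 200 µm, matching the strong fine-droplet
skew of orchard spray cards.

Synthetic stains are perfect discs at intensity 0 on background 255. Real
WSP scans have ragged stain edges, intensity gradients, coalescence beyond
tangency, and scanner noise; passing tests therefore demonstrate the
*arithmetic and segmentation logic* — area bookkeeping, model conversion,
exclusion and calibration — not robustness to messy scans. The Gaussian-noise
test (σ = 10) shows tolerance to mild intensity noise only.

The calibration generator (`simulate_paired_residues`) emulates a co-located
study: each sampled location carries a latent spray deposit (lognormal,
CV 0.42 by default) shared between the leaf and the card at that location,
with independent multiplicative measurement noise per arm sized so the arm
totals hit the study-scale CVs (leaf 50%, WSP 44%) at n = 90 leaves and 61
retained cards; surplus locations carry one substrate only. Making the
shared spray-field heterogeneity the dominant variance component is the
realistic choice — field CVs of 40–65% dwarf the ~8–12% analytical method
CV — and it is what lets a ratio-of-means estimator recover the true factor
to a median ~3% at study size. With arms simulated fully independently the
same estimator's sampling error alone would be ~5% median, a floor no
implementation can beat at these n and CVs.

## Numerical choices and edge cases

- Zero stain area maps to zero diameter and volume; negative areas,
  diameters, depositions and concentrations raise `ValueError`.
- The binned model requires a positive stain diameter for a factor lookup;
  `transform(0)` returns 0 for interoperability with the constant model.
- Percent differences between the two models' diameters are computed
  directly as `100·(d_const − d_binned)/d_binned` and rounded to 2 dp.
- Bootstrap CIs on experiment summaries (2000 resamples, percentile method)
  are seeded and reproducible; reports embed their config snapshot.
- Welch's t-test uses the Welch–Satterthwaite df for both p-value and the
  95% CI of the difference; if both groups are degenerate (zero variance)
  the comparison short-circuits to exact equality. Group CIs are t-based,
  not normal-based, because per-group n can be as small as 45 or less.
- Card placement failure (retry budget exhausted) raises a `PlacementError`
  suggesting a larger card or fewer stains rather than looping forever.

## Problem sizes

Defaults keep everything desk-scale: synthetic cards are 512–1024 px square,
oracle sweeps use 50 cards with up to ~15 stains each, the calibration
recovery uses 100 replicates at n = 90/61 per arm, and the power sketch for
the two-zone comparison uses 200 replicates at n = 106/109. The full suite
runs in seconds.

## Known limitations

- No color-channel separation, scanner-artifact correction, or leaf-surface
  image analysis; grayscale cards only.
- Volume median diameter and DV percentile statistics are deliberately not
  computed.
- The correction factor is formulation- and regime-specific; nothing in the
  package should be read as transferable calibration.
- Field-survey summary tables from real orchards are supported as I/O and
  statistics but cannot be reproduced numerically without the raw data.
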