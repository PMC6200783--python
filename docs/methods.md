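# Methods

## Slab geometry

An en-face slab is a depth window anchored to the outer RPE surface,
specified in micrometres (`SlabSpec`: offset, width, aggregation rule) and
resolved to per-A-scan half-open index intervals by rounding the µm
boundaries half-up in units of the axial pitch; intervals are forced
non-empty so a slab thinner than one pitch still samples one voxel.
Coordinates are 0-based, row-major, origin top-left, depth increasing
posteriorly.

The choriocapillaris slab is 30–60 µm below the outer RPE (offset 30 µm,
width 30 µm): starting 30 µm down avoids the projection of the retinal
capillaries, and the 30 µm width is deliberately wider than the device's
factory 29–49 µm preset (shipped as `DEVICE_DEFAULT_CC_SLAB`) so that
choriocapillaris signal is not missed when its depth varies between eyes.

Subfoveal choroidal thickness (SCT) is the caliper distance from the outer
RPE to the choroid–sclera interface at the single fovea A-scan. An optional
median over a (2k+1)² lateral window (default k = 0) guards against a
corrupted surface sample in noisy phantoms. The half-choroid slab is a
30 µm window at one half of SCT; "at" is ambiguous, and we **centre** the
window on depth SCT/2 (offset = SCT/2 − 15 µm) for symmetric sampling of
the mid-choroid — starting the window at SCT/2 instead is available via
`placement="start"`. Eyes with SCT < 150 µm are outside the method's
intended population (pathologic-myopia-range thinning) and trigger a
warning here and exclusion in the cohort filter.

The depth-aggregation rule of commercial slab renderers is not public; the
default here is `max` over depth (typical for angiography, where the
brightest decorrelation in the window is displayed), with `mean`
(rounded half-up to 8 bits) as an option. Likewise the axial pitch is a
free input (phantom default 10 µm/sample), not an asserted device constant.

## Projection-artifact subtraction

All three steps use 8-bit saturating subtraction `a ⊖ b = max(a − b, 0)` —
the semantics of ImageJ's Image Calculator on 8-bit images. The clamping is
load-bearing: without it the chain

    sub_A = CC ⊖ HC,  sub_B = HC ⊖ sub_A,  final = HC ⊖ sub_B

would collapse to `CC − HC`; with it, the closed form is
`final = min(max(CC − HC, 0), HC)`, verified exhaustively over all 65,536
8-bit input pairs. Two regimes follow directly:

* **stroma removed exactly** when `CC ≥ HC` — the method's core assumption
  is that the stromal brightness in the half-choroid slab *is* the
  choriocapillaris projection, i.e. approximately equal to the CC slab's
  own brightness;
* **lumen recovered exactly** (`final = HC`) when `CC ≥ 2·HC` — the
  stroma-to-lumen contrast must be at least a factor of two.

RGB screenshots are accepted and collapsed to 8-bit grayscale by the
unweighted channel mean rounded half-up (ImageJ's default RGB→8-bit
conversion); Rec. 601 luma weights are available. Display-oriented
brightness/contrast adjustment is never applied to stored or quantified
images.

## Binarization and flow-area ratio

Bernsen's auto local threshold: per pixel, over the circular neighborhood
of radius `radius_px` intersected with the image at the borders (no
padding), `mid = (local_max + local_min)/2`; if the local contrast
`local_max − local_min` falls below `contrast_threshold` the pixel is flow
iff `mid ≥ 128`, otherwise iff its own intensity `≥ mid`. The low-contrast
tie rule follows the ImageJ plugin convention and decides uniform images
(uniform 200 → all flow, uniform 50 → none). Defaults `radius_px = 15`,
`contrast_threshold = 15` are the plugin defaults — no published values
exist for this analysis, so both are configurable and per-eye ratios from
real exports are not expected to be bit-reproducible. The implementation
uses constant-mode min/max filters with neutral fill (0 for max, 255 for
min), which realizes border intersection exactly; tests compare it to a
brute-force per-pixel scan.

Flow polarity is white-is-flow. The optic disc is excluded with an
elliptical mask (pixel excluded iff `((r−r0)/a)² + ((c−c0)/b)² ≤ 1`) on
wide-field 12 × 12 mm scans only; small-field scans omit it. The flow-area
ratio is 100 × flow pixels / analyzed pixels outside the exclusion; an
exclusion covering the whole image is an error (empty denominator).

When the mean of the artifact-subtracted image falls below a visibility
threshold (default 5/255, a configuration value) the pipeline flags the eye
"vessels not visible" — the spectral-domain regime, where the shorter
wavelength does not penetrate to the half-choroid and the ratio is
meaningless rather than merely small.

## Cohort statistics

The packaged reference table (61 eyes, 45 subjects) carries per-eye SCT and
flow-area ratio. Eligibility retains SCT ≥ 150 µm. Printed "±" values are
treated as mean ± sample SD (n−1 denominator; the denominator is not
stated in the source). Age is summarized per subject (45 values — this is
the only convention that reproduces the printed mean age 38.5), SCT and
flow per eye (61 values). Both eyes of a subject enter the correlation as
independent observations, as the source analysis evidently did; a one-eye
per-subject sensitivity option is provided (ρ = 0.76 vs 0.735, same
conclusion). Spearman's ρ uses average ranks for ties with a two-sided
p-value from the t-approximation on n−2 degrees of freedom
(`scipy.stats.spearmanr`); a constant input vector is an error at the
function level and reported as NaN by the cohort summary. Tests cross-check
ρ against a hand-rolled rank computation and the p-value against the exact
permutation distribution at n = 7.

The source publication is internally inconsistent: it prints both
ρ = 0.738 and ρ = 0.796 for the same association, and both 297 ± 61 µm and
320 ± 62 µm for mean SCT. Recomputation from the per-eye rows gives
ρ = 0.735 and 298 ± 62 µm — matching the first of each pair at the rounding
precision of the printed entries (Pearson on the same rows is 0.825, so
0.796 matches no recomputation). The package always reports what it
computes from the rows.

## Phantom generator

The phantom encodes exactly the image features the pipeline relies on, with
defaults chosen as the study conditions:

| parameter | default | meaning |
|---|---|---|
| grid | 192 × 192 px | lateral grid of the slab pair |
| sct_um | 300 µm | mid-range normal choroidal thickness |
| cc_intensity | 200 | uniform choriocapillaris flow signal (8-bit) |
| lumen_intensity | 80 | flow signal inside vessel lumina (≤ cc/2: full-recovery regime) |
| artifact_gain | 1.0 | stromal projection = gain × cc (1.0 = the method's stated assumption) |
| vessel_fraction | 0.25 | target lumen coverage, near the cohort mean flow area |
| vessel_width_px | 3–9 px | tube diameters; kept below the Bernsen window so every lumen pixel sees stroma |
| noise_sd | 8 | additive Gaussian noise, clipped to 8 bits |
| sd_attenuation | 0.02 | half-choroid signal multiplier in `sd_octa` mode |

Vessels are seeded random-walk tubes: persistent random walks stamped with
disks, strokes added until the target coverage is reached (stroke length is
scaled to the remaining deficit to limit overshoot; fractions above 0.9 are
unattainable for tubes and rejected). This exercises binarization and
area-ratio logic but makes no claim to Sattler/Haller anatomy — passing
tests demonstrate correctness of the *processing*, not performance on real
choroidal morphology. Other real-data features deliberately not emulated:
speckle statistics, depth-dependent artifact decay (only two slabs are
consumed), segmentation error in the reference surfaces, and motion
artifacts.

The projection artifact is multiplicative in the overlying
choriocapillaris signal (`artifact_gain`), the simplest law consistent with
the qualitative mechanism; the true quantitative relationship is unknown,
so the gain is a free parameter. In `sd_octa` mode the entire half-choroid
slab — signal and noise alike — is scaled by `sd_attenuation`, emulating a
device whose light does not reach the deep choroid (no flow signal implies
no decorrelation noise either); with the default 0.02 the subtracted image
mean falls below the visibility threshold and the "not visible" path is
exercised.

Cohort simulation draws SCT uniformly from 180–500 µm (the reference
cohort's range) and maps a coupling-weighted mix of scaled SCT and an
independent uniform draw into a vessel fraction in 0.12–0.40 (about the
reference cohort's flow-area range): coupling 1 makes vessel area a
deterministic function of SCT, coupling 0 makes them independent. All
randomness flows from one master seed; per-eye streams derive from
`SeedSequence((seed, eye_index))`, so eye k is identical in cohorts of any
size.

## Numerical choices and problem sizes

Rounding is half-up everywhere a float meets the 8-bit grid (grayscale
conversion, mean projection, phantom rendering) and at slab index
boundaries. Degenerate inputs fail loudly: slabs exiting the volume name
the offending A-scans, a half-choroid slab is refused when SCT ≤ width,
constant vectors are refused by the correlation, and an all-covering
exclusion is refused by the ratio. Default problem sizes — 192² phantoms,
30-eye simulated cohorts, 64² images for brute-force oracle comparisons —
were chosen so the full validation runs comfortably on a single CPU while
keeping every estimate (Dice ≈ 0.97 at default noise, |ρ| ≈ 0.8 at
coupling 0.6) far from its acceptance boundary.

## Known limitations

* Per-eye flow ratios from device exports are not bit-reproducible without
  the original Bernsen parameters, image dimensions and disc ovals; only
  cohort-level statistics are reproduced quantitatively.
* The subtraction method fails by design when the stroma is not bright
  (thick choroids, attenuated signal) or when the lumen-to-stroma contrast
  is below a factor of two; the visibility flag catches the former.
* Reference surfaces are inputs (device-exported or phantom truth); the
  package performs no RPE/choroid–sclera segmentation.
* Inter-eye correlation within subjects is ignored in the primary analysis,
  matching the source convention; the per-case option is a sensitivity
  check, not a mixed-effects model.
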