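# Methods

This note records the model, the simulation conditions, and the design
choices made where the procedure was genuinely open, in the package's
own terms. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The ganglion-cell model

The simulated cell is an LNLN(P) cascade on a 40 x 40-pixel arena of
Weber contrasts in [-1, +1] (0 = background gray):

1. **L** — each subunit k applies a spatial filter: a 2D Gaussian with
   center, two standard deviations and an orientation, evaluated at
   pixel centers and renormalised to unit discrete volume. Unit volume
   makes the full-field activation exactly equal to the stimulus
   contrast, which keeps the output anchoring exact; polarity (+1 On,
   -1 Off) multiplies the activation.
2. **N** — half-wave rectification, or `max(0, x)^2` in the
   threshold-quadratic variant.
3. **L** — weighted summation. Default weights are equal and sum to 1
   (0.5 per mosaic in dual-layout models; center-weighted in the
   Gaussian-weight variant: weights proportional to a central Gaussian
   with sigma = 0.12 x arena, renormalised).
4. **N** — a pure gain `g`, fixed per model so that the full cascade
   maps a full-field white flash to 30 expected spikes and gray to the
   baseline. The gain is re-anchored for every variant; this is why
   the threshold-quadratic model responds more weakly to sub-maximal
   stimuli (its cascade output for a stripe is further below the
   full-field reference), and why the dual On/Off model gets g = 60
   (full-field white silences the Off mosaic, which carries half the
   weight).
5. **P** — one Poisson draw per flash. Baseline activity (default 0;
   3 spikes/stimulus in the spontaneous-activity variant) is added
   after the gain, before the Poisson draw.

The optional **photoreceptor stage** (LNLNLN) inserts, before step 1,
a mosaic of Gaussian photoreceptors at half the subunit diameter
(about four per subunit), a piecewise-linear nonlinearity (slope 0.5
below zero, 1 above — photoreceptors rectify only weakly), and a
weighted projection onto the subunits: a photoreceptor feeds every
subunit whose 1.5-sigma ellipse covers its center, with weight equal
to the subunit's Gaussian value there, normalised to unit sum per
subunit. Photoreceptors outside all ellipses are discarded; if a
subunit ends up unconnected the mosaic is rejected (benchmarks redraw
it).

The optional **temporal filter** (60 Hz) is convolved with the
per-frame spatial activations before rectification. The shipped
kernel is a biphasic difference of gammas, shorter than 9 frames,
scaled so the summed rectified response to any positively-activating
stimulus held for 9 frames (150 ms) equals the static model's
response. With a biphasic kernel this normalisation can only be
imposed on the rectified sum (the raw convolution sum differs by the
rectification leak of the negative tail), so the rectified-boxcar sum
is the normalisation target; consequences (e.g. the 18-frame/9-frame
response ratio being slightly above 2) are checked in the tests
against an independent convolution oracle.

## Ground-truth mosaics

Subunit layouts emulate bipolar-cell mosaics: a hexagonal lattice with
nearest-neighbour distance arena/8 is perturbed by independent
Gaussian shifts (21 % of the lattice constant), Voronoi-tessellated,
and the N cells whose centroids lie closest to the lattice center are
each fitted with a Gaussian; fitted sigmas are multiplied by 1.35
(1.6 in the high-overlap variant) and the mosaic is recentred on the
arena. Layout size follows an area-preserving rule: all linear
dimensions carry the factor `SIZE_SCALE_C * sqrt(10 / N)`, so the
receptive field occupies a roughly constant area while subunit
diameter shrinks as 1/sqrt(N). `SIZE_SCALE_C = 1.29741` is calibrated
once (committed script) so the mean effective subunit diameter —
diameter of the circle matching the 1.5-sigma ellipse area,
`3 sqrt(sigma_maj sigma_min)` — is 7.0 px at N = 10.

Design choices in this module:

* **Cell fit**: moment matching (polygon centroid and second area
  moments, closed form) rather than a least-squares fit to the
  rasterised cell. Moment matching is deterministic and exact, and it
  is the only convention we found consistent with the receptive-field
  size that the calibrated mosaics should have (a free-amplitude LSQ
  fit to the cell indicator yields ~26 % larger sigmas; after
  recalibrating the lattice to keep the 7-px subunit diameter, the
  fitted receptive-field diameter collapses from ~17.5 px to ~15 px
  and the scale-free RF/subunit diameter ratio falls below 2.2).
* **RF fit** (used for the effective RF diameter and for recentering
  superimposed mosaics): moment matching on the linear RF map, for the
  same reason — on these flat-topped maps a free-amplitude LSQ fit is
  systematically ~18 % wider; it remains available as `method="lsq"`.
* **Cosine subunits**: the positive lobe `cos(pi r / 2R)` (elliptical
  in the subunit frame) with R = 2.137 sigma, the radius at which a
  free-amplitude least-squares Gaussian fit of the lobe recovers the
  nominal sigma. Sizing the lobe by moment matching instead
  (R = 2.499 sigma) makes cosine mosaics measurably coarser than their
  Gaussian counterparts and inverts the (small) performance ordering
  between the two profiles that the benchmarks measure.
* **Lattice extent and retries**: enough lattice rings that the N
  selected cells plus a guard ring are bounded; degenerate
  tessellations are regenerated with a fresh perturbation.
* **Dual mosaics**: each mosaic is shifted so its fitted RF center
  sits on the arena center, rotated by an independent uniform angle
  about it, and reweighted to total 0.5.

## Stimulation and reconstruction

Ricker stripes use the profile `s0(x) (1 - 4x^2/w^2) exp(-2x^2/w^2)`
with `s0 = s` on the sidebands and 1 on the central band, evaluated at
pixel centers (no area integration, keeping rotations and sub-pixel
offsets exact), clipped symmetrically to [-1, +1] (clipping triggers
at the defaults: s = 2.5 puts the sideband minimum at -1.01). The
default plan probes 36 angles (0-175 deg in 5-deg steps) x 60
positions in steps of 2/3 px, offsets symmetric about the arena
center, one presentation per combination. Multi-stripe stimulation
folds the perpendicular coordinate modulo the stripe period, making
the sinogram cyclic; such sinograms are recentred per row on the
cell's RF position before reconstruction (column nearest the RF
projection moved to the central column, values permuted cyclically).

Spiking sinograms are smoothed with a separable Gaussian: sigma_pos =
2.5 % of the arena (1 px = 1.5 position steps) and sigma_ang = 5 deg
(1 angle step). Boundaries: reflection along positions (wrap for
cyclic sinograms); along angles the filter wraps through the 180-deg
seam with the sinogram's natural symmetry, i.e. the continuation row
at angle a + 180 deg is the row at a with positions mirrored.

FBP uses the band-limited ramp kernel (h[0] = 1/4, h[odd] =
-1/(pi k)^2) transformed to the frequency domain — the discretisation
that preserves the DC component — with rows zero-padded to the next
power of two at least twice the row length, linear-interpolation
back-projection onto an n_positions^2 grid centered on the arena
(pixel pitch = position step), and scaling by pi / (2 n_angles). This
implementation agrees with the scikit-image inverse-Radon reference to
well below 2 % relative RMS on exact Radon sinograms (enforced in the
tests); reconstruction amplitude is irrelevant downstream because
hotspot detection is relative.

## Evaluation

Hotspots are pixels at least as large as their eight neighbours
(missing neighbours cannot block; 8-connected plateaus merge into one
hotspot at the component centroid), at or above 30 % of the global
maximum, inside the circle of diameter 90 % of the reconstruction
extent (edge artifacts live outside it). A subunit is detected if a
hotspot lies in its 0.75-sigma ellipse; with several candidates the
highest-valued one is the match and the rest are false positives, and
a hotspot inside overlapping ellipses is assigned to the subunit with
the smallest normalised radius. F = 2TP / (2TP + FP + FN). Errors are
categorised as undetected (false-negative subunit with no hotspot in
its 1.5-sigma ellipse), mislocalized (a hotspot in the 1.5- but not
0.75-sigma ellipse; counted once, consuming one false-positive hotspot
and one false-negative subunit), or spurious (remaining false
positives); the three categories therefore sum to FP + FN minus the
mislocalization count, and reported fractions pool counts over
layouts.

Parameter scaling across subunit counts follows the layout's
area-preserving rule: w and sigma_pos scale with sqrt(10/n) (rounded
to 0.2 px and 0.1 % respectively), s and sigma_ang stay fixed. The
required number of stripe positions enforces an effective resolution
of 7 positions per subunit diameter across the arena (40 at n = 10).
Measurement time counts 0.6 s per flash including recovery;
`time_to_threshold` fixes positions by that rule and sweeps the angle
count upward until the benchmark mean F reaches the target.

## What the generator does and does not emulate

The synthetic mosaics reproduce the statistics relevant to the
identification task — subunit size dispersion, eccentricity,
tiling without 0.75-sigma overlap at the default overlap factor, and
the constant-RF-size scaling — but not anatomical bipolar mosaics
(type-specific regularity, gap junctions, true photoreceptor grids),
receptive-field surrounds, adaptation, or non-Poisson spiking (real
ganglion-cell spiking is more regular than Poisson, so the simulated
noise level is conservative). Passing benchmarks therefore bound the
method's behaviour under these idealised conditions; experimental
performance additionally depends on eye-movement/drift correction,
spike sorting and firing-rate nonstationarities that are out of scope
here.

## Numerical choices and degenerate inputs

Problem sizes: the committed test suite runs the stochastic benchmarks
at 250 layout instantiations (SEM of a mean F about 0.01) and the
acceptance script at 1000 (SEM < 0.01); parameter-sweep checks use
120-150 layouts per grid point. Single seeded generators drive each
benchmark; the CLI expands one global seed into independent layout /
spiking / rotation substreams so that changing, e.g., the repeat count
does not alter which layouts are generated. Ties in `round_to` go away
from zero. `f_score(0, 0, 0)` is defined as 0 with a warning. An
all-nonpositive reconstruction yields an empty hotspot set; a
single-angle sinogram, a zero-area polygon, an empty stimulus
sequence, and a non-cyclic sinogram passed to the recentering step all
raise errors rather than guessing.

## Known limitations

* FBP smears elongated subunits along their major axis and
  reconstructs negative troughs beside them (the stripe response of an
  eccentric subunit depends strongly on stripe angle, which plain
  back-projection cannot model). Even noise-free reconstructions
  occasionally displace such a subunit's peak beyond its 0.75-sigma
  ellipse — roughly one subunit per thousand at the default settings.
* The hotspot detector is deliberately simple (relative threshold on
  local maxima); it reports no sub-pixel positions and no subunit
  shapes.
* Error-category shares are sensitive to implementation details of
  the reconstruction/detection chain that the procedure above does not
  pin down; across the conventions we tested, the undetected share of
  errors in the default benchmark ranged from ~32 % (this
  implementation) to ~60 %, while the mean F-score varied by < 0.06.
* The cyclic recentering assumes the position grid spans exactly one
  stripe period.
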